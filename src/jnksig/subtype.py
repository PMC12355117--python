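"""TNBC molecular subtyping and tumor-immune-microenvironment classes.

Molecular subtyping follows the centroid-score scheme: each of the six
Lehmann subtypes (BL1, BL2, IM, M, LAR, MSL) is described by genes
positively and negatively associated with it; after per-gene centering and
scaling across the cohort, a sample's subtype score is the mean z of the
positive genes minus the mean z of the negative genes, and the subtype
with the highest score wins.  BL2 is unstable, so samples whose top score
is BL2 are reassigned to their second-highest subtype; BL1 is reported as
"BL", yielding five stable calls (BL, IM, M, LAR, MSL) with no sample left
unassigned.

The TIME (tumor immune microenvironment) classifier here is a transparent
two-axis thresholding scheme over an immune and a stromal gene-set score
— a configurable stand-in for spatially derived FI/SR/MR classes, not a
reproduction of the original histology-anchored method: immune-high →
fully inflamed (FI); immune-low & stroma-high → stroma restricted (SR);
both low → margin restricted (MR); scores inside an ambiguity band around
either threshold → unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix
from .sigscore import gene_set_median_score

#: deterministic tie-break order; BL2 last so ties never resurrect it
SUBTYPE_ORDER = ("BL1", "IM", "M", "LAR", "MSL", "BL2")
#: final five-class label map (BL1 is reported as BL)
FINAL_LABELS = {"BL1": "BL", "IM": "IM", "M": "M", "LAR": "LAR", "MSL": "MSL"}
TIME_CLASSES = ("FI", "SR", "MR", "unclassified")


class SubtypeError(ValueError):
    """Raised when a subtyping contract is violated."""


@dataclass
class SubtypeGeneSets:
    """Per-subtype positive/negative marker gene lists.

    ``sets`` maps subtype name → (positive genes, negative genes).  The
    positive list must be non-empty and disjoint from the negative list.
    """

    sets: dict[str, tuple[list[str], list[str]]]

    def __post_init__(self) -> None:
        for name, (pos, neg) in self.sets.items():
            if not pos:
                raise SubtypeError(f"subtype {name!r} has an empty positive gene list")
            if set(pos) & set(neg):
                raise SubtypeError(f"subtype {name!r} has overlapping positive/negative genes")

    @classmethod
    def from_gmt(cls, gene_sets: dict[str, list[str]]) -> "SubtypeGeneSets":
        """Build from GMT-style sets named ``<SUBTYPE>_UP`` / ``<SUBTYPE>_DN``."""
        sets: dict[str, tuple[list[str], list[str]]] = {}
        names = {n.rsplit("_", 1)[0] for n in gene_sets if n.endswith(("_UP", "_DN"))}
        for name in sorted(names):
            pos = gene_sets.get(f"{name}_UP", [])
            neg = gene_sets.get(f"{name}_DN", [])
            sets[name] = (list(pos), list(neg))
        if not sets:
            raise SubtypeError("no <SUBTYPE>_UP/_DN sets found")
        return cls(sets)

    def to_gmt(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, (pos, neg) in self.sets.items():
            out[f"{name}_UP"] = list(pos)
            if neg:
                out[f"{name}_DN"] = list(neg)
        return out


@dataclass
class SubtypeCall:
    """Final subtype calls with the raw 6-way winner and reassignment flag."""

    table: pd.DataFrame  # columns: call, raw_argmax, reassigned, tie_flag

    def __post_init__(self) -> None:
        if (self.table["call"] == "BL2").any():
            raise SubtypeError("final calls must never be BL2")
        bad = self.table["reassigned"] != (self.table["raw_argmax"] == "BL2")
        if bad.any():
            raise SubtypeError("reassigned flag must mark exactly the BL2 raw winners")

    def as_series(self) -> pd.Series:
        return self.table["call"]


def compute_subtype_scores(
    expr: ExpressionMatrix, sets: SubtypeGeneSets
) -> pd.DataFrame:
    """Centroid scores: mean z of positive genes − mean z of negative genes.

    Genes are centered/scaled across the scored cohort (ddof=1); an empty
    or absent negative list contributes 0.  A subtype with no positive
    gene present in the matrix is an error.  Returns samples × subtypes.
    """
    vals = expr.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    ok = sd > 0
    z = vals.loc[ok].sub(mean[ok], axis=0).div(sd[ok], axis=0)
    scores = {}
    for name, (pos, neg) in sets.sets.items():
        pos_present = z.index.intersection(pos)
        if len(pos_present) == 0:
            raise SubtypeError(f"subtype {name!r}: no positive gene present in the matrix")
        s = z.loc[pos_present].mean(axis=0)
        neg_present = z.index.intersection(neg)
        if len(neg_present):
            s = s - z.loc[neg_present].mean(axis=0)
        scores[name] = s
    return pd.DataFrame(scores)


def assign_subtype(scores: pd.DataFrame) -> SubtypeCall:
    """Argmax subtype call with BL2 reassignment to the second-highest score.

    Exact ties for the governing maximum are broken by the fixed
    ``SUBTYPE_ORDER`` (BL2 last) and flagged.  Every sample receives one of
    the five stable labels.
    """
    missing = [s for s in SUBTYPE_ORDER if s not in scores.columns]
    if missing:
        raise SubtypeError(f"score matrix missing subtype column(s) {missing}")
    ordered = scores[list(SUBTYPE_ORDER)]
    arr = ordered.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise SubtypeError("subtype scores must be finite")

    calls, raws, reassigned, ties = [], [], [], []
    names = list(SUBTYPE_ORDER)
    for row in arr:
        top = row.max()
        top_ix = [i for i, v in enumerate(row) if v == top]
        winner = names[top_ix[0]]  # fixed-order tie-break
        tie = len(top_ix) > 1
        raws.append(winner)
        if winner == "BL2":
            rest = [(v, i) for i, v in enumerate(row) if names[i] != "BL2"]
            second = max(v for v, _ in rest)
            second_ix = [i for v, i in rest if v == second]
            tie = tie or len(second_ix) > 1
            final = names[second_ix[0]]
            reassigned.append(True)
        else:
            final = winner
            reassigned.append(False)
        calls.append(FINAL_LABELS[final])
        ties.append(tie)
    table = pd.DataFrame(
        {"call": calls, "raw_argmax": raws, "reassigned": reassigned, "tie_flag": ties},
        index=scores.index,
    )
    return SubtypeCall(table)


@dataclass
class TimeConfig:
    """Two-axis TIME classifier settings.

    Scores are z-scaled gene-set median scores; thresholds default to 0
    (the cohort mean) and ``ambiguity_delta`` is the half-width of the
    unclassified band around each governing threshold.
    """

    immune_genes: list[str] = field(default_factory=list)
    stromal_genes: list[str] = field(default_factory=list)
    immune_threshold: float = 0.0
    stromal_threshold: float = 0.0
    ambiguity_delta: float = 0.25

    def __post_init__(self) -> None:
        if self.ambiguity_delta < 0:
            raise SubtypeError("ambiguity_delta must be >= 0")


def classify_time(expr: ExpressionMatrix, cfg: TimeConfig) -> pd.Series:
    """Classify samples into FI / SR / MR / unclassified.

    The immune axis governs first: immune score above its threshold → FI.
    Otherwise the stromal axis splits SR (high) from MR (low).  A score
    within ``ambiguity_delta`` of the governing threshold leaves the sample
    unclassified.
    """
    if not cfg.immune_genes or not cfg.stromal_genes:
        raise SubtypeError("TIME classification needs immune and stromal gene sets")
    imm = gene_set_median_score(expr, cfg.immune_genes, name="immune").as_series()
    stro = gene_set_median_score(expr, cfg.stromal_genes, name="stromal").as_series()
    zimm = (imm - imm.mean()) / imm.std(ddof=1)
    zstro = (stro - stro.mean()) / stro.std(ddof=1)

    out = pd.Series("unclassified", index=imm.index, name="time_class")
    immune_clear = (zimm - cfg.immune_threshold).abs() > cfg.ambiguity_delta
    fi = immune_clear & (zimm > cfg.immune_threshold)
    low_imm = immune_clear & (zimm <= cfg.immune_threshold)
    stromal_clear = (zstro - cfg.stromal_threshold).abs() > cfg.ambiguity_delta
    out[fi] = "FI"
    out[low_imm & stromal_clear & (zstro > cfg.stromal_threshold)] = "SR"
    out[low_imm & stromal_clear & (zstro <= cfg.stromal_threshold)] = "MR"
    return out
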