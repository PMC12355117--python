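"""Signature and gene-set scoring.

A derived signature is applied to a cohort as the mean product of its
coefficients with per-gene z-normalized log expression; cohorts are then
dichotomized at the median score into "low" and "high" groups.  Simple
gene-set summaries (per-sample median expression of a set, and an
effector/suppressor contrast such as CD8+ T cell vs Treg) live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import Z_SCORED, ExpressionMatrix


class ScoringError(ValueError):
    """Raised when a scoring contract is violated."""


@dataclass
class ScoreVector:
    """Per-sample scores with provenance."""

    sample_ids: list[str]
    scores: np.ndarray
    signature_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.sample_ids) != len(self.scores):
            raise ScoringError("sample_ids and scores lengths differ")
        if not np.isfinite(self.scores).all():
            raise ScoringError("scores must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.signature_id or "score")


@dataclass
class GroupLabels:
    """Median-split group labels; ties at the cutoff go to "low"."""

    sample_ids: list[str]
    labels: np.ndarray
    cutoff_value: float

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ScoringError("sample_ids and labels lengths differ")
        if not set(np.unique(self.labels)) <= {"low", "high"}:
            raise ScoringError("labels must be 'low' or 'high'")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="pjnk_group")


def _z_rows(values: pd.DataFrame, gene_stats: pd.DataFrame | None):
    """z-normalize rows either with cohort statistics (ddof=1) or with
    frozen per-gene (mean, sd) statistics from a training cohort."""
    if gene_stats is None:
        mean = values.mean(axis=1)
        sd = values.std(axis=1, ddof=1)
    else:
        missing = values.index.difference(gene_stats.index)
        if len(missing):
            raise ScoringError(f"frozen statistics missing for genes {list(missing)[:5]}")
        mean = gene_stats.loc[values.index, "mean"]
        sd = gene_stats.loc[values.index, "sd"]
    degenerate = list(sd.index[sd <= 0])
    if degenerate:
        warnings.warn(f"dropping {len(degenerate)} zero-variance gene(s) from scoring")
        values = values.drop(index=degenerate)
        mean = mean.drop(index=degenerate)
        sd = sd.drop(index=degenerate)
    return values.sub(mean, axis=0).div(sd, axis=0)


def score_samples(
    sig,
    expr: ExpressionMatrix,
    gene_stats: pd.DataFrame | None = None,
) -> ScoreVector:
    """Score each sample as mean over signature genes of coef × z-expression.

    Parameters
    ----------
    sig
        A :class:`~jnksig.sigderive.GeneSignature` (anything with
        ``gene_ids`` and ``coefficients``).
    expr
        Log-normalized (or already z-scored) expression for the cohort to
        score.  z-normalisation is computed within this cohort unless
        *gene_stats* provides frozen training-set means and sds (columns
        ``mean``/``sd`` indexed by gene).

    Signature genes absent from *expr* are dropped with a warning; with no
    overlap at all scoring fails.
    """
    coef = pd.Series(np.asarray(sig.coefficients, dtype=float), index=list(sig.gene_ids))
    present = coef.index.intersection(expr.values.index)
    missing = coef.index.difference(expr.values.index)
    if len(present) == 0:
        raise ScoringError("no signature gene present in the expression matrix")
    if len(missing):
        warnings.warn(
            f"{len(missing)} of {len(coef)} signature gene(s) missing from expression; "
            "scoring over the intersection"
        )
    sub = expr.values.loc[present]
    z = sub if expr.units == Z_SCORED and gene_stats is None else _z_rows(sub, gene_stats)
    coef = coef.loc[z.index]
    scores = z.mul(coef, axis=0).mean(axis=0)
    sig_id = getattr(sig, "signature_id", "") or f"signature[{len(coef)} genes]"
    return ScoreVector(list(scores.index), scores.to_numpy(), signature_id=sig_id)


def dichotomize_by_median(s: ScoreVector) -> GroupLabels:
    """Split at the median score: low iff score <= median, high otherwise.

    Ties at the median are assigned to "low" (the high group is strictly
    above the cutoff).  Constant scores admit no split and raise.
    """
    if len(s.scores) < 2:
        raise ScoringError("median split needs at least 2 samples")
    if np.ptp(s.scores) == 0:
        raise ScoringError("all scores identical; median split impossible")
    cutoff = float(np.median(s.scores))
    labels = np.where(s.scores <= cutoff, "low", "high")
    return GroupLabels(list(s.sample_ids), labels, cutoff)


def gene_set_median_score(
    expr: ExpressionMatrix, gene_set, name: str = "gene_set"
) -> ScoreVector:
    """Per-sample median expression of the genes in *gene_set*."""
    idx = pd.Index(pd.unique(pd.Series(list(gene_set))))
    present = idx.intersection(expr.values.index)
    if len(present) == 0:
        raise ScoringError(f"no gene of set {name!r} present in the expression matrix")
    if len(present) < len(idx):
        warnings.warn(f"{len(idx) - len(present)} gene(s) of set {name!r} missing")
    med = expr.values.loc[present].median(axis=0)
    return ScoreVector(list(med.index), med.to_numpy(), signature_id=name)


def effector_suppressor_ratio(
    effector: ScoreVector,
    suppressor: ScoreVector,
    epsilon: float = 1e-6,
    mode: str = "ratio",
) -> ScoreVector:
    """Effector/suppressor contrast (e.g. CD8+ T cell vs Treg scores).

    ``mode="ratio"`` computes ``effector / (suppressor + epsilon)`` for
    non-negative abundance-like scores; ``mode="log_difference"`` computes
    ``effector - suppressor`` for log-scale scores.
    """
    if list(effector.sample_ids) != list(suppressor.sample_ids):
        raise ScoringError("effector and suppressor sample ids are misaligned")
    if mode == "ratio":
        if epsilon <= 0:
            raise ScoringError(f"epsilon must be > 0, got {epsilon}")
        vals = effector.scores / (suppressor.scores + epsilon)
    elif mode == "log_difference":
        vals = effector.scores - suppressor.scores
    else:
        raise ScoringError(f"unknown mode {mode!r}")
    name = f"{effector.signature_id}/{suppressor.signature_id}"
    return ScoreVector(list(effector.sample_ids), vals, signature_id=name)
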