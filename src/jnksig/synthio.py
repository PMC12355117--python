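"""Synthetic TNBC cohort generator.

The analyses in this package were designed for an adjuvant-trial RNA-seq
cohort and matched proteomics that are access-controlled.  This module
generates cohorts with the same statistical structure so that every
downstream stage — signature derivation, subtyping, case-cohort weighting,
interaction testing — can be exercised and validated end to end:

* a latent continuous phospho-JNK level per sample, with a known subset of
  "signal" genes whose log-expression correlates with it at a target
  Pearson r;
* molecular-subtype centroid structure: disjoint positive/negative marker
  gene sets per subtype, shifted up/down on the log2 scale for samples of
  that subtype;
* library-size variation and Poisson count sampling on top of log-normal
  latent expression, so raw matrices behave like count data;
* stromal TIL percentages, higher on average in immunomodulatory (IM)
  tumors;
* proportional-hazards survival for four nested endpoints (DFS as the
  base process; BCFI/DRFI/OS as thinned copies) with a linear predictor
  assembled from named log-hazard-ratio effects, including interaction
  terms such as ``"subtype_IM:pjnk"``;
* stratified case-cohort sampling: every BCFI case is included, non-cases
  are subsampled within strata formed by the four stratification factors
  (tumor size, nodal status, age group, treatment arm) at a target 1:3
  case:non-case ratio.

All randomness flows from ``SimulationConfig.seed`` through fixed,
independent substreams, so each generator is individually deterministic
and mutually consistent (e.g. subtype labels drawn inside the expression
generator equal those used by the clinical generator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import RAW_COUNTS, ExpressionMatrix

# trial-derived defaults: published subtype counts BL=72, IM=86, LAR=47,
# M=89, MSL=53 out of 347 sequenced tumors
_DEFAULT_PROPORTIONS = {
    "BL1": 72 / 347,
    "IM": 86 / 347,
    "M": 89 / 347,
    "LAR": 47 / 347,
    "MSL": 53 / 347,
}

SUBTYPES_6 = ("BL1", "IM", "M", "LAR", "MSL", "BL2")
ENDPOINTS = ("DFS", "OS", "DRFI", "BCFI")
TUMOR_SIZES = ("T1", "T2", "T3")
NODAL_CATEGORIES = ("N0", "N1-3", "N4plus")
AGE_CATEGORIES = ("<40", "40-<50", "50-<60", "60+")

# probability that a DFS event is also an event for the nested endpoint
_THINNING = {"BCFI": 0.8, "DRFI": 0.6, "OS": 0.5}

# substream tags (offsets added to the user seed via SeedSequence spawning)
_SUB_SUBTYPE, _SUB_LATENT, _SUB_EXPR, _SUB_CLINICAL, _SUB_GENESETS = range(5)


class SimulationError(ValueError):
    """Raised when a SimulationConfig field is invalid."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults encode the study conditions: 600 patients, 2000 genes with 25
    pJNK signal genes at target r = 0.5, subtype mix from the published
    counts, per-month baseline hazard 0.004 (≈78% 5-year survival), DFS
    censoring fraction 0.8 (the trial's ≈19% BCFI event rate), and a 1:3
    case:non-case sampling ratio.
    """

    n_samples: int = 600
    n_genes: int = 2000
    n_signal_genes: int = 25
    signal_correlation: float = 0.5
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    centroid_shift: float = 1.0
    markers_per_subtype: int = 20
    baseline_hazard: float = 0.004
    log_hr_effects: dict[str, float] = field(
        default_factory=lambda: {
            "pjnk": math.log(1.29),
            "subtype_IM:pjnk": math.log(0.17),
        }
    )
    censoring_rate: float = 0.8
    case_noncase_ratio: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_signal_genes", "markers_per_subtype"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or (v < 0 if name == "n_signal_genes" else v <= 0):
                raise SimulationError(f"{name} must be a positive integer, got {v!r}")
        if self.n_signal_genes > self.n_genes:
            raise SimulationError(
                f"n_signal_genes ({self.n_signal_genes}) exceeds n_genes ({self.n_genes})"
            )
        if not 0 < self.signal_correlation < 1:
            raise SimulationError(
                f"signal_correlation must be in (0, 1), got {self.signal_correlation}"
            )
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise SimulationError(f"subtype_proportions sum to {total}, not 1")
        unknown = set(self.subtype_proportions) - set(SUBTYPES_6)
        if unknown:
            raise SimulationError(f"unknown subtype(s) in subtype_proportions: {sorted(unknown)}")
        if self.centroid_shift < 0:
            raise SimulationError(f"centroid_shift must be >= 0, got {self.centroid_shift}")
        if self.baseline_hazard <= 0:
            raise SimulationError(f"baseline_hazard must be > 0, got {self.baseline_hazard}")
        if not 0 <= self.censoring_rate < 1:
            raise SimulationError(f"censoring_rate must be in [0, 1), got {self.censoring_rate}")
        if self.case_noncase_ratio <= 0:
            raise SimulationError(f"case_noncase_ratio must be > 0, got {self.case_noncase_ratio}")

    def rng(self, substream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(substream + 1)[substream])


@dataclass
class LatentPhospho:
    """Per-sample latent phospho-protein level, z-scaled."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) != len(self.values):
            raise SimulationError("sample_ids and values lengths differ")
        if not np.isfinite(self.values).all():
            raise SimulationError("latent values must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.sample_ids, name="pjnk_latent")


_CLINICAL_COLUMNS = [
    f"{ep.lower()}_{f}" for ep in ENDPOINTS for f in ("time", "event")
] + ["tumor_size_category", "nodal_category", "age_category", "treatment", "tils_percent"]


@dataclass
class ClinicalCohort:
    """Clinical table: four survival endpoints, stratification factors,
    treatment arm, TILs percentage and (synthetic-only) ground truth."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CLINICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise SimulationError(f"clinical table missing columns {missing}")
        for ep in ENDPOINTS:
            t = self.table[f"{ep.lower()}_time"]
            e = self.table[f"{ep.lower()}_event"]
            if (t <= 0).any():
                raise SimulationError(f"{ep} times must be strictly positive")
            if not e.isin([0, 1]).all():
                raise SimulationError(f"{ep} event indicators must be 0/1")
        if not self.table["tumor_size_category"].isin(TUMOR_SIZES).all():
            raise SimulationError(f"tumor_size_category must be one of {TUMOR_SIZES}")
        if not self.table["nodal_category"].isin(NODAL_CATEGORIES).all():
            raise SimulationError(f"nodal_category must be one of {NODAL_CATEGORIES}")
        if not self.table["age_category"].isin(AGE_CATEGORIES).all():
            raise SimulationError(f"age_category must be one of {AGE_CATEGORIES}")
        tils = self.table["tils_percent"]
        if ((tils < 0) | (tils > 100)).any():
            raise SimulationError("tils_percent must lie in [0, 100]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def endpoint(self, name: str) -> tuple[pd.Series, pd.Series]:
        """Return (time, event) for endpoint name in {DFS, OS, DRFI, BCFI}."""
        name = name.upper()
        if name not in ENDPOINTS:
            raise SimulationError(f"unknown endpoint {name!r}; expected one of {ENDPOINTS}")
        return self.table[f"{name.lower()}_time"], self.table[f"{name.lower()}_event"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path) -> "ClinicalCohort":
        return cls(pd.read_csv(path, index_col="sample_id"))


@dataclass
class CaseCohortSample:
    """Stratified case-cohort inclusion flags and sampling fractions.

    ``table`` has one row per cohort sample: ``included``, ``is_case``,
    ``stratum_id`` and the stratum's ``sampling_fraction``.  ``strata``
    summarises each stratum (size, number sampled, fraction, flag for
    degenerate strata with no non-cases to sample).
    """

    table: pd.DataFrame
    strata: pd.DataFrame

    def __post_init__(self) -> None:
        cases = self.table["is_case"].astype(bool)
        if not self.table.loc[cases, "included"].all():
            raise SimulationError("every case must be included")
        if not np.allclose(self.table.loc[cases, "sampling_fraction"], 1.0):
            raise SimulationError("cases must have sampling fraction 1")
        f = self.table["sampling_fraction"]
        if ((f <= 0) | (f > 1)).any():
            raise SimulationError("sampling fractions must lie in (0, 1]")

    @property
    def included_ids(self) -> list[str]:
        return list(self.table.index[self.table["included"]])


# ----------------------------------------------------------------- labels

def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def draw_subtype_labels(config: SimulationConfig) -> pd.Series:
    """Draw per-sample true subtype labels from ``subtype_proportions``.

    Deterministic under the config seed and shared by the expression and
    clinical generators.
    """
    rng = config.rng(_SUB_SUBTYPE)
    names = list(config.subtype_proportions)
    probs = np.array([config.subtype_proportions[s] for s in names], dtype=float)
    probs = probs / probs.sum()
    labels = rng.choice(names, size=config.n_samples, p=probs)
    return pd.Series(labels, index=_sample_ids(config.n_samples), name="true_subtype")


def draw_latent_phospho(config: SimulationConfig) -> LatentPhospho:
    """Draw the latent phospho-JNK level, z-scaled across the cohort."""
    rng = config.rng(_SUB_LATENT)
    z = rng.standard_normal(config.n_samples)
    z = (z - z.mean()) / z.std(ddof=1)
    return LatentPhospho(_sample_ids(config.n_samples), z)


def _marker_layout(config: SimulationConfig) -> dict:
    """Deterministic allocation of signal genes and subtype marker blocks.

    Signal genes and the 6 × (pos + neg) marker blocks are disjoint so
    centroid structure cannot masquerade as phospho signal.
    """
    k = config.markers_per_subtype
    need = config.n_signal_genes + len(SUBTYPES_6) * 2 * k
    if need > config.n_genes:
        raise SimulationError(
            f"n_genes={config.n_genes} too small for {config.n_signal_genes} signal genes "
            f"plus {len(SUBTYPES_6)}x2x{k} subtype markers ({need} needed)"
        )
    rng = config.rng(_SUB_GENESETS)
    ids = np.array(_gene_ids(config.n_genes))
    chosen = rng.choice(config.n_genes, size=need, replace=False)
    signal = ids[chosen[: config.n_signal_genes]]
    layout = {"signal": list(signal), "markers": {}}
    off = config.n_signal_genes
    for s in SUBTYPES_6:
        pos = ids[chosen[off : off + k]]
        neg = ids[chosen[off + k : off + 2 * k]]
        layout["markers"][s] = (list(pos), list(neg))
        off += 2 * k
    return layout


def generate_expression_with_latent(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, LatentPhospho, list[str]]:
    """Simulate a raw count matrix tied to a latent phospho level.

    Log2 expression of each gene is ``mu_g + sd * noise`` with
    ``mu_g ~ Uniform(5, 9)``; for the ``n_signal_genes`` signal genes the
    noise is ``rho * z + sqrt(1 - rho^2) * eps`` so their log-expression
    correlates with the latent ``z`` at Pearson ``rho`` in expectation
    (Poisson sampling attenuates this slightly).  Subtype marker genes are
    shifted by ``±centroid_shift`` for samples of their subtype.  Counts
    are Poisson around ``2**log2x`` scaled by a log-normal library-size
    factor.
    """
    n, g = config.n_samples, config.n_genes
    labels = draw_subtype_labels(config)
    latent = draw_latent_phospho(config)
    layout = _marker_layout(config)
    rng = config.rng(_SUB_EXPR)

    gene_index = pd.Index(_gene_ids(g))
    mu = rng.uniform(5.0, 9.0, size=g)
    sd = 1.0
    eps = rng.standard_normal((g, n))
    log2x = mu[:, None] + sd * eps

    rho = config.signal_correlation
    sig_pos = gene_index.get_indexer(layout["signal"])
    if len(sig_pos):
        z = latent.values[None, :]
        log2x[sig_pos] = mu[sig_pos, None] + sd * (rho * z + math.sqrt(1 - rho**2) * eps[sig_pos])

    if config.centroid_shift > 0:
        lab = labels.to_numpy()
        for s, (pos, neg) in layout["markers"].items():
            members = lab == s
            if not members.any():
                continue
            ip = gene_index.get_indexer(pos)
            ineg = gene_index.get_indexer(neg)
            log2x[np.ix_(ip, np.flatnonzero(members))] += config.centroid_shift
            log2x[np.ix_(ineg, np.flatnonzero(members))] -= config.centroid_shift

    libsize = np.exp(rng.normal(0.0, 0.35, size=n))
    counts = rng.poisson(np.exp2(log2x) * libsize[None, :]).astype(float)
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_index, columns=latent.sample_ids), units=RAW_COUNTS
    )
    return expr, latent, list(layout["signal"])


def generate_subtype_gene_sets(config: SimulationConfig):
    """Return the marker gene sets matching the generator's centroid shifts.

    These are the same blocks ``generate_expression_with_latent`` shifts,
    so noiseless (large-shift) samples are perfectly classifiable.
    """
    from .subtype import SubtypeGeneSets  # local import: subtype depends on nothing here

    layout = _marker_layout(config)
    return SubtypeGeneSets({s: tuple(pn) for s, pn in layout["markers"].items()})


# --------------------------------------------------------------- clinical

_BASE_TERMS = ("pjnk", "treatment", "tils")


def _term_value(term: str, frame: pd.DataFrame) -> np.ndarray:
    if term in _BASE_TERMS:
        return frame[term].to_numpy(dtype=float)
    if term.startswith("subtype_"):
        name = term[len("subtype_"):]
        if name not in SUBTYPES_6:
            raise SimulationError(f"unknown subtype in covariate term {term!r}")
        return (frame["subtype"] == name).to_numpy(dtype=float)
    raise SimulationError(f"unknown covariate term {term!r}")


def _linear_predictor(effects: dict[str, float], frame: pd.DataFrame) -> np.ndarray:
    eta = np.zeros(len(frame))
    for term, beta in effects.items():
        parts = term.split(":")
        if not 1 <= len(parts) <= 2:
            raise SimulationError(f"covariate term {term!r} must be 'a' or 'a:b'")
        x = np.ones(len(frame))
        for p in parts:
            x = x * _term_value(p, frame)
        eta += beta * x
    return eta


def _solve_accrual_horizon(rates: np.ndarray, target: float) -> float:
    """Administrative censoring: C ~ Uniform(0, tau); solve tau so the mean
    censoring probability E[(1 - exp(-r*tau)) / (r*tau)] hits *target*."""

    def cens_prob(tau: float) -> float:
        x = rates * tau
        return float(np.mean((1 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e-6
    while cens_prob(hi) > target:
        hi *= 2
        if hi > 1e9:
            return hi
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if cens_prob(mid) > target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def generate_clinical_cohort(
    config: SimulationConfig,
    latent: LatentPhospho,
    subtypes: pd.Series,
) -> ClinicalCohort:
    """Simulate survival endpoints, stratification factors, treatment and TILs.

    DFS is the base proportional-hazards event process: exponential event
    times with rate ``baseline_hazard * exp(eta)`` where ``eta`` comes from
    ``log_hr_effects``; censoring is administrative (uniform accrual) tuned
    to ``censoring_rate``.  BCFI, DRFI and OS are thinned copies: a DFS
    event is an event for the nested endpoint with fixed probability (0.8,
    0.6, 0.5), otherwise censored at the DFS time — thinning preserves the
    log hazard ratios.
    """
    if len(latent.sample_ids) != len(subtypes):
        raise SimulationError("latent and subtype label lengths differ")
    n = len(latent.sample_ids)
    rng = config.rng(_SUB_CLINICAL)

    frame = pd.DataFrame(index=latent.sample_ids)
    frame["pjnk"] = latent.values
    frame["subtype"] = subtypes.to_numpy()
    frame["treatment"] = rng.integers(0, 2, size=n)
    tils_mean = np.where(frame["subtype"] == "IM", 40.0, 15.0)
    tils_sd = np.where(frame["subtype"] == "IM", 15.0, 10.0)
    frame["tils"] = np.clip(rng.normal(tils_mean, tils_sd), 0.0, 100.0)

    eta = _linear_predictor(config.log_hr_effects, frame)
    rates = config.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rates)
    if config.censoring_rate > 0:
        tau = _solve_accrual_horizon(rates, config.censoring_rate)
        c = rng.uniform(0.0, tau, size=n)
    else:
        c = np.full(n, np.inf)
    dfs_time = np.maximum(np.minimum(t_event, c), 1e-6)
    dfs_event = (t_event <= c).astype(int)

    table = pd.DataFrame(index=latent.sample_ids)
    table["dfs_time"] = dfs_time
    table["dfs_event"] = dfs_event
    for ep, p in _THINNING.items():
        keep = rng.random(n) < p
        table[f"{ep.lower()}_time"] = dfs_time
        table[f"{ep.lower()}_event"] = (dfs_event.astype(bool) & keep).astype(int)

    table["tumor_size_category"] = rng.choice(TUMOR_SIZES, size=n, p=[0.50, 0.42, 0.08])
    table["nodal_category"] = rng.choice(NODAL_CATEGORIES, size=n, p=[0.55, 0.30, 0.15])
    table["age_category"] = rng.choice(AGE_CATEGORIES, size=n, p=[0.12, 0.30, 0.30, 0.28])
    table["treatment"] = np.where(frame["treatment"] == 1, "CM", "no-CM")
    table["tils_percent"] = frame["tils"].to_numpy()
    table["true_subtype"] = frame["subtype"].to_numpy()
    table["true_pjnk_latent"] = frame["pjnk"].to_numpy()
    return ClinicalCohort(table)


# ------------------------------------------------------------ case-cohort

_STRATIFICATION_FACTORS = (
    "tumor_size_category",
    "nodal_category",
    "age_category",
    "treatment",
)


def case_cohort_sample(
    cohort: ClinicalCohort, ratio: float = 3.0, seed: int = 0
) -> CaseCohortSample:
    """Stratified case-cohort sampling keyed on BCFI events.

    Every BCFI case is included with sampling fraction 1.  Non-cases are
    sampled without replacement within strata formed by the full cross of
    the four stratification factors; the total non-case target is
    ``round(ratio * n_cases)``, allocated to strata proportionally to their
    size.  Per-stratum sampling fractions are recorded for Horvitz–
    Thompson weighting.  A stratum that contains cases but no non-cases is
    recorded with fraction 1 and flagged.
    """
    if ratio <= 0:
        raise SimulationError(f"ratio must be > 0, got {ratio}")
    table = cohort.table
    is_case = table["bcfi_event"].astype(bool)
    n_cases = int(is_case.sum())
    if n_cases == 0:
        raise SimulationError("cohort has no BCFI case; case-cohort sampling undefined")

    rng = np.random.default_rng(seed)
    factor_key = table[list(_STRATIFICATION_FACTORS)].astype(str).agg("|".join, axis=1)
    stratum_id = factor_key + np.where(is_case, "|case", "|noncase")

    out = pd.DataFrame(index=table.index)
    out["is_case"] = is_case
    out["stratum_id"] = stratum_id
    out["included"] = is_case.copy()
    out["sampling_fraction"] = np.where(is_case, 1.0, np.nan)

    noncase_ids = table.index[~is_case]
    target_total = min(int(round(ratio * n_cases)), len(noncase_ids))
    strata_rows = []
    # largest-remainder apportionment of the non-case target over strata,
    # capped at stratum size and floored at one per non-empty stratum so
    # every non-case keeps a positive inclusion probability (required for
    # Horvitz-Thompson unbiasedness); factor cells with no non-case simply
    # contribute no non-case stratum
    groups = out.loc[noncase_ids].groupby("stratum_id", sort=True).groups
    sids = sorted(groups)
    avail = np.array([len(groups[s]) for s in sids])
    raw = target_total * avail / avail.sum()
    quota = np.floor(raw).astype(int)
    short = target_total - quota.sum()
    if short > 0:
        order = np.argsort(-(raw - quota), kind="stable")
        quota[order[:short]] += 1
    quota = np.minimum(avail, np.maximum(quota, 1))
    for sid, n_take, n_avail in zip(sids, quota, avail):
        members = list(groups[sid])
        take = rng.choice(members, size=n_take, replace=False)
        out.loc[list(take), "included"] = True
        frac = n_take / n_avail
        out.loc[members, "sampling_fraction"] = frac
        strata_rows.append(
            {"stratum_id": sid, "n_total": n_avail, "n_sampled": int(n_take),
             "sampling_fraction": frac, "flagged": False}
        )
    for sid, sub in out.loc[is_case].groupby("stratum_id", sort=True):
        strata_rows.append(
            {"stratum_id": sid, "n_total": len(sub), "n_sampled": len(sub),
             "sampling_fraction": 1.0, "flagged": False}
        )
    strata = pd.DataFrame(strata_rows).set_index("stratum_id").sort_index()
    return CaseCohortSample(out, strata)
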