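"""Transcriptional signature derivation for a continuous phospho-protein level.

The derivation pipeline mirrors how expression surrogates for protein
phosphorylation are built from matched RNA-seq/proteomics cohorts:

1. split the cohort into training and held-out test sets;
2. stability correlation filtering — repeatedly subsample one third of the
   training samples (1000 draws), compute each gene's Pearson correlation
   with the phospho response, and keep genes whose |r| exceeds 0.25 in at
   least 75% of draws;
3. elastic-net regression (mixing α = 0.5, 7-fold cross-validation over a
   log-spaced λ grid, minimum mean CV error) on the z-scored candidate
   genes to select the final signature and its coefficients;
4. validation: score the held-out samples and report the Pearson r (and
   two-sided p) against the held-out response.

scikit-learn's ``ElasticNet`` parameterisation matches the glmnet-style
objective used here exactly: ``1/(2n)·‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)``
with ``alpha=λ`` and ``l1_ratio=α``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .preprocess import ExpressionMatrix
from .sigscore import score_samples
from .synthio import LatentPhospho


class DerivationError(ValueError):
    """Raised when a derivation contract is violated."""


class EmptySignatureError(DerivationError):
    """Raised when the penalty shrinks every coefficient to zero."""


@dataclass
class DerivationConfig:
    """Derivation settings; defaults are the published procedure's values:
    1000 subsampling iterations of one third of the training samples,
    |r| > 0.25 required in ≥75% of draws, elastic-net mixing 0.5 with
    7-fold CV, and a 95:46 train:test split (fraction 95/141)."""

    n_iterations: int = 1000
    subsample_fraction: float = 1 / 3
    r_threshold: float = 0.25
    frequency_threshold: float = 0.75
    enet_mixing: float = 0.5
    cv_folds: int = 7
    lambda_grid: str | list[float] = "auto"
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    train_fraction: float = 95 / 141
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise DerivationError("n_iterations must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise DerivationError("subsample_fraction must be in (0, 1]")
        if self.r_threshold <= 0:
            raise DerivationError("r_threshold must be > 0")
        if not 0 < self.frequency_threshold <= 1:
            raise DerivationError("frequency_threshold must be in (0, 1]")
        if not 0 <= self.enet_mixing <= 1:
            raise DerivationError("enet_mixing must be in [0, 1]")
        if self.cv_folds < 2:
            raise DerivationError("cv_folds must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise DerivationError("train_fraction must be in (0, 1)")


@dataclass
class GeneSignature:
    """Ordered gene list with non-zero coefficients plus derivation metadata."""

    gene_ids: list[str]
    coefficients: np.ndarray
    derivation_meta: dict = field(default_factory=dict)
    signature_id: str = "pjnk_signature"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.gene_ids) != len(self.coefficients):
            raise DerivationError("gene_ids and coefficients lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DerivationError("duplicate gene ids in signature")
        if (self.coefficients == 0).any():
            raise DerivationError("zero coefficients must not be stored in a signature")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_files(self, tsv_path, json_path) -> None:
        """Two-column TSV (gene_id, coefficient) + JSON metadata sidecar."""
        pd.DataFrame({"gene_id": self.gene_ids, "coefficient": self.coefficients}).to_csv(
            tsv_path, sep="\t", index=False
        )
        with open(json_path, "w") as fh:
            json.dump(
                {"signature_id": self.signature_id, "derivation_meta": _jsonable(self.derivation_meta)},
                fh, indent=2, sort_keys=True,
            )

    @classmethod
    def from_files(cls, tsv_path, json_path=None) -> "GeneSignature":
        tab = pd.read_csv(tsv_path, sep="\t")
        meta, sig_id = {}, "pjnk_signature"
        if json_path is not None:
            with open(json_path) as fh:
                side = json.load(fh)
            meta = side.get("derivation_meta", {})
            sig_id = side.get("signature_id", sig_id)
        return cls(list(tab["gene_id"]), tab["coefficient"].to_numpy(), meta, sig_id)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


# ------------------------------------------------------------------ split

def split_train_test(
    sample_ids, train_fraction: float = 95 / 141, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Random, reproducible, disjoint and exhaustive train/test split.

    The training side has ``round(train_fraction * n)`` samples (95 of 141
    at the default fraction); the remainder is the test side.
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < 4:
        raise DerivationError(f"need at least 4 samples to split, got {n}")
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise DerivationError(
            f"degenerate split: train_fraction {train_fraction} on {n} samples"
        )
    perm = np.random.default_rng(seed).permutation(n)
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


# -------------------------------------------------- stability selection

def stability_correlation_filter(
    expr: ExpressionMatrix,
    response: LatentPhospho,
    cfg: DerivationConfig,
) -> tuple[list[str], pd.Series]:
    """Stability selection by repeated subsampled Pearson correlation.

    For each of ``cfg.n_iterations`` draws of ``round(subsample_fraction·n)``
    samples (without replacement, floor 3), every gene's Pearson r with the
    response is computed; a gene is a candidate iff ``|r| > r_threshold``
    (strict) in at least ``frequency_threshold`` of the draws.  Genes with
    zero variance within a draw contribute r = 0 for that draw.

    Returns the candidate gene ids (matrix order) and the per-gene
    selection frequency for audit.
    """
    resp = response.as_series()
    common = [s for s in expr.sample_ids if s in resp.index]
    if len(common) != expr.n_samples or len(common) != len(resp):
        raise DerivationError("expression and response sample ids do not align")
    X = expr.values.to_numpy().T  # samples × genes
    y = resp.loc[expr.sample_ids].to_numpy(dtype=float)
    n = len(y)
    m = max(3, int(round(cfg.subsample_fraction * n)))
    if m > n:
        raise DerivationError(f"subsample size {m} exceeds cohort size {n}")

    rng = np.random.default_rng(cfg.seed)
    hits = np.zeros(X.shape[1], dtype=int)
    for _ in range(cfg.n_iterations):
        idx = rng.choice(n, size=m, replace=False)
        Xs, ys = X[idx], y[idx]
        Xc = Xs - Xs.mean(axis=0)
        yc = ys - ys.mean()
        sx = np.sqrt((Xc**2).sum(axis=0))
        sy = np.sqrt((yc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc.T @ yc) / (sx * sy)
        r[~np.isfinite(r)] = 0.0  # zero-variance gene (or response) in this draw
        hits += np.abs(r) > cfg.r_threshold
    freq = pd.Series(hits / cfg.n_iterations, index=expr.gene_ids, name="selection_frequency")
    selected = hits >= cfg.frequency_threshold * cfg.n_iterations - 1e-9
    return list(freq.index[selected]), freq


# ------------------------------------------------------------ elastic net

def _lambda_grid(X: np.ndarray, y: np.ndarray, cfg: DerivationConfig) -> np.ndarray:
    if cfg.lambda_grid != "auto":
        grid = np.sort(np.asarray(cfg.lambda_grid, dtype=float))[::-1]
        if (grid <= 0).any():
            raise DerivationError("lambda grid values must be > 0")
        return grid
    n = len(y)
    # smallest lambda that zeroes every coefficient under the L1 part
    l1 = max(cfg.enet_mixing, 1e-3)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / (n * l1)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, cfg.lambda_min_ratio * lam_max, cfg.n_lambda)


def fit_penalized_signature(
    expr: ExpressionMatrix,
    response: LatentPhospho,
    cfg: DerivationConfig,
    candidates: list[str] | None = None,
) -> GeneSignature:
    """Elastic-net fit of the candidate genes against the phospho response.

    Genes are z-scored with training-cohort statistics (recorded in the
    metadata for train→test transfer), then the coefficient path is fit
    over a 100-point log-spaced λ grid from λ_max down to 1e-4·λ_max; λ is
    chosen by minimum mean squared error over ``cfg.cv_folds``-fold CV
    (ties resolved toward the sparser, larger λ).  Genes with zero
    coefficient at the chosen λ are dropped.
    """
    if candidates is not None:
        if not candidates:
            raise DerivationError("empty candidate gene list")
        expr = ExpressionMatrix(expr.values.loc[candidates], units=expr.units)
    if expr.n_genes < 1:
        raise DerivationError("no candidate genes to fit")
    resp = response.as_series()
    y = resp.loc[expr.sample_ids].to_numpy(dtype=float)

    vals = expr.values
    gmean = vals.mean(axis=1)
    gsd = vals.std(axis=1, ddof=1)
    if (gsd <= 0).any():
        bad = list(gsd.index[gsd <= 0])
        raise DerivationError(f"zero-variance candidate gene(s): {bad[:5]}")
    X = vals.sub(gmean, axis=0).div(gsd, axis=0).to_numpy().T  # samples × genes

    grid = _lambda_grid(X, y, cfg)
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed % (2**31))
    cv_mse = np.zeros((cfg.cv_folds, len(grid)))
    for k, (tr, va) in enumerate(kf.split(X)):
        model = ElasticNet(
            alpha=grid[0], l1_ratio=cfg.enet_mixing, fit_intercept=True,
            max_iter=50_000, tol=1e-8, warm_start=True,
        )
        for j, lam in enumerate(grid):
            model.set_params(alpha=lam)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            pred = model.predict(X[va])
            cv_mse[k, j] = np.mean((pred - y[va]) ** 2)
    mean_mse = cv_mse.mean(axis=0)
    best = int(np.argmin(mean_mse))  # grid is descending: first (largest λ) wins ties

    final = ElasticNet(
        alpha=grid[best], l1_ratio=cfg.enet_mixing, fit_intercept=True,
        max_iter=50_000, tol=1e-8,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    coef = final.coef_
    nz = np.flatnonzero(coef)
    if len(nz) == 0:
        raise EmptySignatureError(
            f"all coefficients zero at the CV-selected lambda {grid[best]:.4g}"
        )
    genes = [expr.gene_ids[i] for i in nz]
    meta = {
        "config": asdict(cfg),
        "candidate_genes": expr.gene_ids,
        "selected_lambda": float(grid[best]),
        "lambda_grid": grid,
        "cv_mean_mse": mean_mse,
        "intercept": float(final.intercept_),
        "train_sample_ids": expr.sample_ids,
        "gene_stats": {
            "mean": {g: float(gmean[g]) for g in genes},
            "sd": {g: float(gsd[g]) for g in genes},
        },
    }
    return GeneSignature(genes, coef[nz], meta)


# ------------------------------------------------------------- validation

def frozen_gene_stats(sig: GeneSignature) -> pd.DataFrame | None:
    """Training-cohort per-gene (mean, sd) recorded at fit time, if any."""
    gs = sig.derivation_meta.get("gene_stats")
    if not gs:
        return None
    return pd.DataFrame({"mean": pd.Series(gs["mean"]), "sd": pd.Series(gs["sd"])})


def validate_signature(
    sig: GeneSignature,
    test_expr: ExpressionMatrix,
    test_response: LatentPhospho,
    use_frozen_stats: bool = True,
) -> tuple[float, float]:
    """Held-out validation: Pearson r (and two-sided p) between signature
    scores and the test response.

    Test samples must be disjoint from the training ids recorded in the
    signature metadata.  By default genes are z-scored with the frozen
    training statistics; ``use_frozen_stats=False`` re-normalises within
    the test cohort instead.
    """
    train_ids = set(sig.derivation_meta.get("train_sample_ids", []))
    overlap = train_ids & set(test_expr.sample_ids)
    if overlap:
        raise DerivationError(
            f"{len(overlap)} test sample(s) overlap the training set, e.g. {sorted(overlap)[:3]}"
        )
    stats_df = frozen_gene_stats(sig) if use_frozen_stats else None
    scores = score_samples(sig, test_expr, gene_stats=stats_df)
    y = test_response.as_series().loc[scores.sample_ids].to_numpy(dtype=float)
    if len(y) == 2:
        warnings.warn("two-sample validation: Pearson r is degenerate (±1)")
    r, p = stats.pearsonr(scores.scores, y)
    sig.derivation_meta["validation_r"] = float(r)
    sig.derivation_meta["validation_p"] = float(p)
    return float(r), float(p)


def derive_signature(
    expr: ExpressionMatrix,
    response: LatentPhospho,
    cfg: DerivationConfig,
) -> tuple[GeneSignature, dict]:
    """Full derivation: split → stability filter → elastic net → validation.

    Returns the signature and a report dict (split ids, candidate list,
    selection frequencies, validation r/p).
    """
    train_ids, test_ids = split_train_test(expr.sample_ids, cfg.train_fraction, cfg.seed)
    sub = lambda ids: ExpressionMatrix(expr.values.loc[:, ids], units=expr.units)
    resp = response.as_series()
    train_resp = LatentPhospho(train_ids, resp.loc[train_ids].to_numpy())
    test_resp = LatentPhospho(test_ids, resp.loc[test_ids].to_numpy())

    candidates, freq = stability_correlation_filter(sub(train_ids), train_resp, cfg)
    if not candidates:
        raise DerivationError(
            "stability filter selected no candidate gene; lower r_threshold or "
            "frequency_threshold"
        )
    sig = fit_penalized_signature(sub(train_ids), train_resp, cfg, candidates=candidates)
    r, p = validate_signature(sig, sub(test_ids), test_resp)
    report = {
        "train_ids": train_ids,
        "test_ids": test_ids,
        "candidates": candidates,
        "selection_frequency": freq,
        "validation_r": r,
        "validation_p": p,
    }
    return sig, report
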