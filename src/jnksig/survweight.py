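"""Case-cohort weighted survival analysis.

A case-cohort design includes every case plus a stratified subsample of
non-cases, so naive estimates over the included samples are biased.  All
analyses here reweight each included subject by the inverse of its
stratum's sampling fraction (generalized Horvitz–Thompson / inverse
probability weighting): cases carry weight 1, a non-case sampled from a
stratum at fraction f carries weight 1/f.

Provided estimators:

* weighted Kaplan–Meier product-limit curves (hand-rolled weighted event
  and at-risk sums; unit weights reproduce the classical estimator);
* weighted Cox proportional hazards: a Newton–Raphson maximiser of the
  weighted Breslow partial likelihood with robust (Lin–Wei sandwich)
  standard errors, and a quasi-likelihood-ratio p value for a declared
  feature of interest from nested weighted fits;
* interaction tests: the hazard-ratio ratio between biomarker strata is
  exp of the product-term coefficient, with a Wald p from its robust SE;
* Benjamini–Hochberg FDR adjustment.

Breslow tie handling makes an integer weight w exactly equivalent to
duplicating that subject w times, which is the contract the tests verify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthio import CaseCohortSample


class SurvivalError(ValueError):
    """Raised when a survival-analysis contract is violated."""


# ---------------------------------------------------------------- weights

def compute_ht_weights(sample: CaseCohortSample) -> pd.Series:
    """Horvitz–Thompson weights for the included samples: 1/sampling_fraction.

    Cases (sampling fraction 1) get weight exactly 1; excluded samples are
    absent from the result.
    """
    tab = sample.table
    frac = tab.loc[tab["included"], "sampling_fraction"]
    if (frac <= 0).any():
        raise SurvivalError("sampling fractions must be > 0")
    if (frac > 1).any():
        raise SurvivalError("sampling fractions must be <= 1")
    w = 1.0 / frac
    w.name = "ht_weight"
    return w


# ----------------------------------------------------------- Kaplan–Meier

@dataclass
class WeightedKMCurve:
    """Weighted product-limit curve over the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    label: str = ""
    max_followup: float = np.inf

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise SurvivalError("survival estimate must be non-increasing")


def weighted_km(
    time, event, weights=None, label: str = ""
) -> WeightedKMCurve:
    """Weighted Kaplan–Meier estimator.

    S(t) = prod over event times t_i <= t of (1 − d_i / Y_i) with d_i and
    Y_i the weighted event and at-risk sums.  Unit weights give the
    classical estimator; a subject with integer weight w contributes like
    w identical unit-weight subjects.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if (t <= 0).any():
        raise SurvivalError("survival times must be strictly positive")
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(t):
        raise SurvivalError("weights not aligned with times")
    if not e.any():
        warnings.warn(f"group {label!r} has zero events; returning a flat curve")
        return WeightedKMCurve(
            np.array([]), np.array([]), np.array([]), np.array([]),
            label=label, max_followup=float(t.max()),
        )
    ev_times = np.unique(t[e == 1])
    d = np.array([w[(t == s) & (e == 1)].sum() for s in ev_times])
    y = np.array([w[t >= s].sum() for s in ev_times])
    surv = np.cumprod(1.0 - d / y)
    return WeightedKMCurve(ev_times, surv, y, d, label=label, max_followup=float(t.max()))


def weighted_km_by_group(time, event, weights, group) -> dict[str, WeightedKMCurve]:
    """Per-group weighted KM curves keyed by group label."""
    g = pd.Series(np.asarray(group))
    out = {}
    for name in g.unique():
        m = (g == name).to_numpy()
        wsub = None if weights is None else np.asarray(weights, dtype=float)[m]
        out[str(name)] = weighted_km(
            np.asarray(time, dtype=float)[m], np.asarray(event)[m], wsub, label=str(name)
        )
    return out


def km_estimate_at(curve: WeightedKMCurve, horizon: float) -> float:
    """Right-continuous step-function value S(horizon).

    Before the first event the estimate is 1; past the last observed
    follow-up time the last value is carried forward with a warning.
    """
    if horizon < 0:
        raise SurvivalError("horizon must be >= 0")
    if len(curve.times) == 0:
        return 1.0
    if horizon > curve.max_followup:
        warnings.warn(
            f"horizon {horizon} exceeds the last observed time {curve.max_followup}; "
            "carrying the last estimate forward"
        )
    ix = np.searchsorted(curve.times, horizon, side="right") - 1
    return 1.0 if ix < 0 else float(curve.survival[ix])


# ------------------------------------------------------------ weighted Cox

@dataclass
class WeightedCoxFit:
    """Weighted Cox fit: coefficients, robust SEs, HRs with 95% CIs, Wald p
    per term, and a (quasi-)likelihood-ratio p for the feature of interest."""

    terms: list[str]
    coef: pd.Series
    se: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    wald_p: pd.Series
    log_likelihood: float
    n: int
    weighted_n: float
    n_events: int
    feature_of_interest: list[str] = field(default_factory=list)
    lr_p: float | None = None
    lr_stat: float | None = None
    robust: bool = True

    def __post_init__(self) -> None:
        if ((self.ci_lower > self.hr) | (self.ci_upper < self.hr)).any():
            raise SurvivalError("confidence bounds must bracket the hazard ratio")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "hr": self.hr,
             "ci_lower": self.ci_lower, "ci_upper": self.ci_upper, "wald_p": self.wald_p}
        )


def _group_bounds(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end indices of the distinct-time groups of a descending-sorted
    time vector (ties share one group and hence one Breslow risk set)."""
    starts = np.flatnonzero(np.r_[True, ts[1:] != ts[:-1]])
    ends = np.r_[starts[1:], len(ts)] - 1
    return starts, ends


def _breslow_quantities(beta, Xs, ts, es, ws, starts, ends):
    """Weighted Breslow log partial likelihood with gradient and observed
    information, over descending-sorted data."""
    p = Xs.shape[1]
    eta = Xs @ beta
    r = ws * np.exp(np.clip(eta, -500, 500))
    cS0 = np.cumsum(r)
    cS1 = np.cumsum(r[:, None] * Xs, axis=0)
    cS2 = np.cumsum(r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    ll, U, H = 0.0, np.zeros(p), np.zeros((p, p))
    for s, e_ix in zip(starts, ends):
        grp = slice(s, e_ix + 1)
        wev = ws[grp] * es[grp]
        d = wev.sum()
        if d == 0:
            continue
        S0, S1, S2 = cS0[e_ix], cS1[e_ix], cS2[e_ix]
        m = S1 / S0
        ll += float(wev @ eta[grp]) - d * np.log(S0)
        U += wev @ Xs[grp] - d * m
        H += d * (S2 / S0 - np.outer(m, m))
    return ll, U, H


def _score_residuals(beta, Xs, ts, es, ws, starts, ends):
    """Per-subject Cox score residuals (Breslow ties) for the Lin-Wei
    robust sandwich; rows follow the descending sort order."""
    n, p = Xs.shape
    eta = Xs @ beta
    r = ws * np.exp(np.clip(eta, -500, 500))
    cS0 = np.cumsum(r)
    cS1 = np.cumsum(r[:, None] * Xs, axis=0)
    n_groups = len(starts)
    a = np.zeros(n_groups)           # d_g / S0_g per distinct-time group
    mg = np.zeros((n_groups, p))     # risk-set mean at each group
    for gi, (s, e_ix) in enumerate(zip(starts, ends)):
        wev = ws[s : e_ix + 1] * es[s : e_ix + 1]
        d = wev.sum()
        mg[gi] = cS1[e_ix] / cS0[e_ix]
        if d > 0:
            a[gi] = d / cS0[e_ix]
    # groups are in descending time order; event groups with t_g <= t_i are
    # the subject's own group and everything after it
    A = np.cumsum(a[::-1])[::-1]
    B = np.cumsum((a[:, None] * mg)[::-1], axis=0)[::-1]
    group_of = np.repeat(np.arange(n_groups), [e - s + 1 for s, e in zip(starts, ends)])
    exp_eta = np.exp(np.clip(eta, -500, 500))
    resid = es[:, None] * (Xs - mg[group_of])
    resid -= exp_eta[:, None] * (Xs * A[group_of, None] - B[group_of])
    return resid


def _fit_breslow(X, t, e, w, max_iter: int = 100, tol: float = 1e-10):
    """Newton-Raphson fit of the weighted Breslow partial likelihood.

    Returns (beta, log-likelihood, model covariance, robust covariance).
    Each subject contributes its sampling weight to the event and risk-set
    sums, so integer weights are exactly equivalent to row duplication.
    """
    order = np.argsort(-t, kind="mergesort")
    Xs, ts, es, ws = X[order], t[order], e[order], w[order]
    starts, ends = _group_bounds(ts)
    p = X.shape[1]
    beta = np.zeros(p)
    ll, U, H = _breslow_quantities(beta, Xs, ts, es, ws, starts, ends)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError as exc:
            raise SurvivalError(f"singular information matrix: {exc}") from exc
        ll_new, U_new, H_new = _breslow_quantities(beta + step, Xs, ts, es, ws, starts, ends)
        n_halv = 0
        while (not np.isfinite(ll_new) or ll_new < ll - 1e-12) and n_halv < 40:
            step = step / 2
            ll_new, U_new, H_new = _breslow_quantities(beta + step, Xs, ts, es, ws, starts, ends)
            n_halv += 1
        beta = beta + step
        if np.linalg.norm(beta) > 100:
            raise SurvivalError(
                "weighted Cox fit failed to converge (monotone likelihood or "
                "separation: a coefficient is diverging)"
            )
        converged = abs(ll_new - ll) < tol and np.abs(U_new).max() < 1e-6
        ll, U, H = ll_new, U_new, H_new
        if converged:
            break
    else:
        raise SurvivalError(
            f"weighted Cox fit did not converge in {max_iter} Newton iterations "
            f"(max |score| = {np.abs(U).max():.3g})"
        )
    try:
        cov_model = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise SurvivalError(f"singular information matrix at optimum: {exc}") from exc
    resid = _score_residuals(beta, Xs, ts, es, ws, starts, ends)
    D = (ws[:, None] * resid) @ cov_model
    cov_robust = D.T @ D
    return beta, ll, cov_model, cov_robust


def weighted_cox_fit(
    time,
    event,
    covariates: pd.DataFrame,
    weights=None,
    feature_of_interest: str | list[str] | None = None,
    robust: bool = True,
    ties: str = "breslow",
) -> WeightedCoxFit:
    """Weighted Cox proportional-hazards regression.

    Maximises the weighted partial likelihood (Breslow tie handling, each
    subject contributing its sampling weight) by Newton-Raphson and
    reports robust (Lin-Wei sandwich) standard errors by default, which
    remain valid when weights are sampling weights rather than
    frequencies; ``robust=False`` uses the model-based inverse
    information.  If *feature_of_interest* names one or more covariate
    columns, a quasi-likelihood-ratio p value is computed from the nested
    weighted fit without those columns.
    """
    if ties != "breslow":
        raise SurvivalError(
            f"only Breslow tie handling is implemented, got {ties!r}"
        )
    cov = covariates.copy()
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(cov) != len(t) or len(e) != len(t):
        raise SurvivalError("time, event and covariates are misaligned")
    for c in cov.columns:
        if cov[c].nunique() <= 1:
            raise SurvivalError(f"covariate {c!r} is constant")
    n_events = int(e.sum())
    if n_events < cov.shape[1]:
        raise SurvivalError(
            f"{n_events} events for {cov.shape[1]} parameters; model not identifiable"
        )
    w = np.ones(len(t)) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise SurvivalError("weights must be > 0")

    X = cov.to_numpy(dtype=float)
    beta, ll, cov_model, cov_robust = _fit_breslow(X, t, e, w)
    se_arr = np.sqrt(np.diag(cov_robust if robust else cov_model))
    coef = pd.Series(beta, index=cov.columns, name="coef")
    se = pd.Series(se_arr, index=cov.columns, name="se")
    zcrit = stats.norm.ppf(0.975)
    zval = coef / se
    fit = WeightedCoxFit(
        terms=list(cov.columns),
        coef=coef,
        se=se,
        hr=np.exp(coef),
        ci_lower=np.exp(coef - zcrit * se),
        ci_upper=np.exp(coef + zcrit * se),
        wald_p=pd.Series(2 * stats.norm.sf(np.abs(zval)), index=cov.columns, name="p"),
        log_likelihood=float(ll),
        n=len(t),
        weighted_n=float(w.sum()),
        n_events=n_events,
        robust=robust,
    )
    if feature_of_interest is not None:
        feats = [feature_of_interest] if isinstance(feature_of_interest, str) else list(feature_of_interest)
        unknown = [f for f in feats if f not in cov.columns]
        if unknown:
            raise SurvivalError(f"feature_of_interest column(s) {unknown} not in covariates")
        fit.feature_of_interest = feats
        reduced_cols = [c for c in cov.columns if c not in feats]
        if reduced_cols:
            X0 = cov[reduced_cols].to_numpy(dtype=float)
            _, ll0, _, _ = _fit_breslow(X0, t, e, w)
        else:
            ll0 = float(_null_log_partial_likelihood(t, e, w))
        fit.lr_stat = 2.0 * (fit.log_likelihood - ll0)
        fit.lr_p = float(stats.chi2.sf(max(fit.lr_stat, 0.0), df=len(feats)))
    return fit


def _null_log_partial_likelihood(t, e, w) -> float:
    """Weighted Breslow log partial likelihood with no covariates."""
    ll = 0.0
    for s in np.unique(t[e == 1]):
        d = w[(t == s) & (e == 1)].sum()
        y = w[t >= s].sum()
        ll -= d * np.log(y)
    return ll


# ------------------------------------------------------------ interactions

@dataclass
class InteractionResult:
    """Ratio of stratum-specific hazard ratios from one interaction fit.

    ``hr_stratum`` is the feature's HR within the modifier=1 stratum,
    ``hr_reference`` within modifier=0; ``hr_inter`` is their ratio, which
    equals exp of the product-term coefficient.  When the modifier encodes
    the low-biomarker group, ``hr_inter`` is the low/high HR ratio.
    """

    hr_stratum: float
    hr_reference: float
    hr_inter: float
    wald_p: float
    coef_interaction: float
    se_interaction: float
    q_value: float | None = None

    def __post_init__(self) -> None:
        if abs(self.hr_inter - self.hr_stratum / self.hr_reference) > 1e-10 * self.hr_inter:
            raise SurvivalError("hr_inter must equal the ratio of stratum-specific HRs")


def interaction_hr_test(
    fit: WeightedCoxFit, feature: str, interaction: str
) -> InteractionResult:
    """Wald interaction test from a fit containing ``feature`` and the
    ``feature × modifier`` product term named *interaction*.

    The feature's HR is ``exp(β_f)`` in the modifier=0 stratum and
    ``exp(β_f + β_int)`` in the modifier=1 stratum; their ratio is
    ``exp(β_int)`` and the Wald p comes from ``β_int`` over its robust SE.
    """
    for term in (feature, interaction):
        if term not in fit.coef.index:
            raise SurvivalError(f"model does not contain term {term!r}")
    b_f = float(fit.coef[feature])
    b_i = float(fit.coef[interaction])
    se_i = float(fit.se[interaction])
    zval = b_i / se_i
    return InteractionResult(
        hr_stratum=float(np.exp(b_f + b_i)),
        hr_reference=float(np.exp(b_f)),
        hr_inter=float(np.exp(b_i)),
        wald_p=float(2 * stats.norm.sf(abs(zval))),
        coef_interaction=b_i,
        se_interaction=se_i,
    )


# ----------------------------------------------------------------- BH FDR

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise SurvivalError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
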