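import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from jnksig.survweight import (
    SurvivalError,
    bh_adjust,
    compute_ht_weights,
    interaction_hr_test,
    km_estimate_at,
    weighted_cox_fit,
    weighted_km,
    weighted_km_by_group,
)
from jnksig.synthio import (
    SimulationConfig,
    case_cohort_sample,
    draw_latent_phospho,
    draw_subtype_labels,
    generate_clinical_cohort,
)

from .conftest import make_clinical


def bh_oracle(p):
    """Brute-force BH step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def sim_survival(n, seed, effects=None, censoring=0.5):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    beta = 0.0 if effects is None else effects
    t_ev = rng.exponential(1.0 / (0.05 * np.exp(beta * x)))
    c = rng.exponential(t_ev.mean() / max(censoring, 1e-9)) if censoring > 0 else np.full(n, np.inf)
    return np.minimum(t_ev, c) + 1e-9, (t_ev <= c).astype(int), x


class TestHTWeights:
    def test_weight_is_inverse_sampling_fraction(self):
        clin = make_clinical(21, 1, seed=0, single_stratum=True)
        ccs = case_cohort_sample(clin, ratio=5.0, seed=1)  # 5 of 20 non-cases
        w = compute_ht_weights(ccs)
        tab = ccs.table.loc[w.index]
        assert np.allclose(w[tab["is_case"]], 1.0)
        assert np.allclose(w[~tab["is_case"]], 4.0)

    def test_excluded_samples_absent(self):
        clin = make_clinical(100, 10, seed=1)
        ccs = case_cohort_sample(clin, ratio=2.0, seed=2)
        w = compute_ht_weights(ccs)
        assert set(w.index) == set(ccs.included_ids)

    def test_full_inclusion_gives_unit_weights(self):
        clin = make_clinical(40, 10, seed=2)
        ccs = case_cohort_sample(clin, ratio=100.0, seed=3)
        assert np.allclose(compute_ht_weights(ccs), 1.0)


class TestWeightedKM:
    def test_hand_computed_curve(self):
        # times [1,2,3], events [1,1,0]: S(1)=2/3, S(2)=1/3, S(3)=1/3
        curve = weighted_km([1.0, 2.0, 3.0], [1, 1, 0])
        assert np.allclose(curve.times, [1.0, 2.0])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3])

    def test_unit_weights_match_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(0)
        t = rng.exponential(10, 80).round(1) + 0.1
        e = rng.integers(0, 2, 80)
        curve = weighted_km(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = [km_estimate_at(curve, h) for h in curve.times]
        theirs = [float(kmf.survival_function_at_times(h).iloc[0]) for h in curve.times]
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_integer_weight_equals_duplication(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 30).round(1) + 0.1
        e = rng.integers(0, 2, 30)
        w = rng.integers(1, 4, 30)
        weighted = weighted_km(t, e, w)
        t_dup = np.repeat(t, w)
        e_dup = np.repeat(e, w)
        duplicated = weighted_km(t_dup, e_dup)
        assert np.allclose(weighted.survival, duplicated.survival, atol=1e-12)

    def test_zero_events_flat_curve_with_warning(self):
        with pytest.warns(UserWarning, match="zero events"):
            curve = weighted_km([1.0, 2.0], [0, 0])
        assert km_estimate_at(curve, 1.5) == 1.0

    def test_step_function_lookup(self):
        curve = weighted_km([1.0, 2.0, 3.0], [1, 1, 0])
        assert km_estimate_at(curve, 0.0) == 1.0
        assert km_estimate_at(curve, 1.5) == pytest.approx(2 / 3)
        assert km_estimate_at(curve, 2.5) == pytest.approx(1 / 3)
        with pytest.warns(UserWarning, match="carrying"):
            assert km_estimate_at(curve, 99.0) == pytest.approx(1 / 3)

    def test_groupwise_curves(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 1, 1]
        g = ["a", "a", "b", "b"]
        curves = weighted_km_by_group(t, e, None, g)
        assert set(curves) == {"a", "b"}
        assert np.allclose(curves["a"].survival, [0.5, 0.0])


class TestWeightedCox:
    def test_unit_weights_match_statsmodels_phreg(self):
        # independent implementation: statsmodels PHReg with Breslow ties
        import statsmodels.api as sm

        t, e, x = sim_survival(300, seed=2, effects=0.7)
        cov = pd.DataFrame({"x": x})
        fit = weighted_cox_fit(t, e, cov, None, robust=False)
        ph = sm.PHReg(t, cov, status=e, ties="breslow").fit()
        assert fit.coef.iloc[0] == pytest.approx(ph.params[0], abs=1e-6)
        assert fit.se.iloc[0] == pytest.approx(np.sqrt(ph.cov_params()[0, 0]), abs=1e-6)

    def test_integer_weights_equal_row_duplication(self):
        rng = np.random.default_rng(3)
        t, e, x = sim_survival(60, seed=3, effects=0.5)
        w = rng.integers(1, 4, 60).astype(float)
        cov = pd.DataFrame({"x": x})
        weighted = weighted_cox_fit(t, e, cov, w)
        rep = np.repeat(np.arange(60), w.astype(int))
        duplicated = weighted_cox_fit(t[rep], e[rep], cov.iloc[rep], None)
        assert weighted.coef.iloc[0] == pytest.approx(duplicated.coef.iloc[0], abs=1e-8)
        assert weighted.log_likelihood == pytest.approx(duplicated.log_likelihood, abs=1e-6)

    def test_lr_test_against_nested_loglik_difference(self):
        from scipy import stats as sps

        t, e, x = sim_survival(200, seed=4, effects=0.6)
        rng = np.random.default_rng(4)
        cov = pd.DataFrame({"x": x, "z": rng.standard_normal(200)})
        fit = weighted_cox_fit(t, e, cov, None, feature_of_interest="x")
        reduced = weighted_cox_fit(t, e, cov[["z"]], None)
        stat = 2 * (fit.log_likelihood - reduced.log_likelihood)
        assert fit.lr_stat == pytest.approx(stat, abs=1e-8)
        assert fit.lr_p == pytest.approx(sps.chi2.sf(stat, 1), abs=1e-10)

    def test_constant_covariate_rejected(self):
        t, e, _ = sim_survival(50, seed=5)
        with pytest.raises(SurvivalError, match="constant"):
            weighted_cox_fit(t, e, pd.DataFrame({"c": np.ones(50)}), None)

    def test_more_parameters_than_events_rejected(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 0, 0])
        cov = pd.DataFrame({"a": [1, 2, 3, 4.0], "b": [4, 3, 1, 2.0]})
        with pytest.raises(SurvivalError, match="events"):
            weighted_cox_fit(t, e, cov, None)

    def test_efron_ties_not_available(self):
        t, e, x = sim_survival(30, seed=6)
        with pytest.raises(SurvivalError, match="[Bb]reslow"):
            weighted_cox_fit(t, e, pd.DataFrame({"x": x}), None, ties="efron")


class TestInteraction:
    def _interaction_fit(self, beta_int, seed, n=2500):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 2, n).astype(float)
        x = rng.integers(0, 2, n).astype(float)
        eta = 0.3 * g - 0.2 * x + beta_int * g * x
        t = rng.exponential(1.0 / (0.05 * np.exp(eta))) + 1e-9
        e = np.ones(n, int)
        cov = pd.DataFrame({"g": g, "x": x, "g:x": g * x})
        return weighted_cox_fit(t, e, cov, None)

    def test_algebraic_identity_hr_ratio_equals_exp_beta(self):
        fit = self._interaction_fit(-0.8, seed=7, n=400)
        res = interaction_hr_test(fit, "g", "g:x")
        assert res.hr_inter == pytest.approx(res.hr_stratum / res.hr_reference, rel=1e-12)
        assert res.hr_inter == pytest.approx(np.exp(fit.coef["g:x"]), rel=1e-12)

    def test_generator_encoded_hr_ratio_recovered(self):
        # beta_int = log(0.25): stratum HRs differ by a factor 4
        fit = self._interaction_fit(np.log(0.25), seed=8)
        res = interaction_hr_test(fit, "g", "g:x")
        assert res.hr_inter == pytest.approx(0.25, rel=0.25)
        assert res.wald_p < 0.01

    def test_null_interaction_near_one(self):
        fit = self._interaction_fit(0.0, seed=9)
        res = interaction_hr_test(fit, "g", "g:x")
        assert res.hr_inter == pytest.approx(1.0, abs=0.2)
        assert res.wald_p > 0.01

    def test_missing_product_term_rejected(self):
        fit = self._interaction_fit(0.0, seed=10, n=300)
        with pytest.raises(SurvivalError, match="nope"):
            interaction_hr_test(fit, "g", "nope")


class TestPower:
    def test_interaction_sign_recovered_under_encoded_effect(self):
        # generator encodes an IM x pJNK hazard-ratio ratio of 0.2; the
        # estimated interaction log-HR should carry the right sign in a
        # clear majority of replicates
        correct = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = SimulationConfig(
                n_samples=600,
                log_hr_effects={"pjnk": np.log(1.3), "subtype_IM:pjnk": np.log(0.2)},
                seed=70_000 + rep,
            )
            latent = draw_latent_phospho(cfg)
            labels = draw_subtype_labels(cfg)
            clin = generate_clinical_cohort(cfg, latent, labels)
            ccs = case_cohort_sample(clin, 3.0, seed=rep)
            w = compute_ht_weights(ccs)
            inc = list(w.index)
            cov = pd.DataFrame(index=clin.sample_ids)
            cov["subtype_IM"] = (labels == "IM").astype(float)
            cov["pjnk"] = latent.values
            cov["subtype_IM:pjnk"] = cov["subtype_IM"] * cov["pjnk"]
            t, e = clin.endpoint("DFS")
            fit = weighted_cox_fit(t.loc[inc], e.loc[inc], cov.loc[inc], w)
            if fit.coef["subtype_IM:pjnk"] < 0:
                correct += 1
        assert correct >= 0.8 * n_rep


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_equal_ps_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(SurvivalError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, pvals):
        assert np.allclose(bh_adjust(pvals), bh_oracle(pvals), atol=1e-12)

    def test_order_preserving_monotone(self):
        rng = np.random.default_rng(11)
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
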