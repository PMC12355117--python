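import dataclasses

import numpy as np
import pandas as pd
import pytest

from jnksig.preprocess import log_normalize
from jnksig.synthio import (
    SimulationConfig,
    SimulationError,
    case_cohort_sample,
    draw_latent_phospho,
    draw_subtype_labels,
    generate_clinical_cohort,
    generate_expression_with_latent,
    generate_subtype_gene_sets,
)

from .conftest import make_clinical


def small_config(**kw):
    base = dict(n_samples=120, n_genes=500, n_signal_genes=10,
                markers_per_subtype=10, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value, match",
        [
            ("n_genes", -5, "n_genes"),
            ("signal_correlation", 1.5, "signal_correlation"),
            ("baseline_hazard", 0.0, "baseline_hazard"),
            ("case_noncase_ratio", -1.0, "case_noncase_ratio"),
            ("subtype_proportions", {"IM": 0.5}, "subtype_proportions"),
            ("subtype_proportions", {"IM": 0.5, "XX": 0.5}, "unknown subtype"),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value, match):
        with pytest.raises(SimulationError, match=match):
            small_config(**{field: value})

    def test_signal_genes_cannot_exceed_genes(self):
        with pytest.raises(SimulationError, match="n_signal_genes"):
            SimulationConfig(n_samples=10, n_genes=10, n_signal_genes=11)


class TestExpressionGenerator:
    def test_deterministic_under_seed(self):
        cfg = small_config(seed=42)
        e1, l1, s1 = generate_expression_with_latent(cfg)
        e2, l2, s2 = generate_expression_with_latent(cfg)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        assert np.array_equal(l1.values, l2.values)
        assert s1 == s2

    def test_different_seed_changes_output(self):
        e1, _, _ = generate_expression_with_latent(small_config(seed=1))
        e2, _, _ = generate_expression_with_latent(small_config(seed=2))
        assert not e1.values.equals(e2.values)

    def test_high_target_correlation_achieved(self):
        # at rho = 0.99 and n = 500 every signal gene must correlate with
        # the latent at |r| > 0.9 on the log scale despite Poisson noise
        cfg = small_config(n_samples=500, n_genes=400, n_signal_genes=15,
                           signal_correlation=0.99, seed=3)
        expr, latent, signal = generate_expression_with_latent(cfg)
        logm = log_normalize(expr)
        rs = [np.corrcoef(logm.values.loc[g], latent.values)[0, 1] for g in signal]
        assert min(np.abs(rs)) > 0.9

    def test_null_genes_have_null_scale_correlations(self):
        # with no signal genes the max |r| must look like a Pearson null:
        # at n = 200 and 500 genes, P(max |r| > 0.30) is ~1e-2
        cfg = small_config(n_samples=200, n_genes=500, n_signal_genes=0, seed=4)
        expr, latent, signal = generate_expression_with_latent(cfg)
        assert signal == []
        logm = log_normalize(expr)
        X = logm.values.to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        y = latent.values - latent.values.mean()
        r = (Xc @ y) / np.sqrt((Xc**2).sum(axis=1) * (y**2).sum())
        assert np.abs(r).max() < 0.30

    def test_counts_are_nonnegative_integers(self):
        expr, _, _ = generate_expression_with_latent(small_config())
        arr = expr.values.to_numpy()
        assert (arr >= 0).all()
        assert np.allclose(arr, np.round(arr))


class TestSubtypeGeneSets:
    def test_marker_sets_disjoint_and_sized(self):
        cfg = small_config(markers_per_subtype=10)
        sets = generate_subtype_gene_sets(cfg)
        all_genes = []
        for pos, neg in sets.sets.values():
            assert len(pos) == 10 and len(neg) == 10
            all_genes += pos + neg
        assert len(all_genes) == len(set(all_genes)) == 6 * 20

    def test_same_seed_identical_sets(self):
        s1 = generate_subtype_gene_sets(small_config(seed=9))
        s2 = generate_subtype_gene_sets(small_config(seed=9))
        assert s1.sets == s2.sets

    def test_insufficient_genes_rejected(self):
        with pytest.raises(SimulationError, match="too small"):
            generate_expression_with_latent(
                small_config(n_genes=100, markers_per_subtype=20)
            )


class TestClinicalCohort:
    def test_no_censoring_means_all_events(self):
        cfg = small_config(censoring_rate=0.0)
        latent = draw_latent_phospho(cfg)
        labels = draw_subtype_labels(cfg)
        clin = generate_clinical_cohort(cfg, latent, labels)
        assert (clin.table["dfs_event"] == 1).all()

    def test_censoring_rate_approximately_achieved(self):
        cfg = small_config(n_samples=2000, censoring_rate=0.7, seed=5)
        clin = generate_clinical_cohort(cfg, draw_latent_phospho(cfg), draw_subtype_labels(cfg))
        cens = 1 - clin.table["dfs_event"].mean()
        assert abs(cens - 0.7) < 0.05

    def test_endpoint_nesting_bcfi_subset_of_dfs(self):
        cfg = small_config(seed=6)
        clin = generate_clinical_cohort(cfg, draw_latent_phospho(cfg), draw_subtype_labels(cfg))
        tab = clin.table
        for ep in ("bcfi", "os", "drfi"):
            assert not ((tab[f"{ep}_event"] == 1) & (tab["dfs_event"] == 0)).any()

    def test_unknown_covariate_term_rejected(self):
        cfg = small_config(log_hr_effects={"not_a_term": 0.3})
        with pytest.raises(SimulationError, match="not_a_term"):
            generate_clinical_cohort(cfg, draw_latent_phospho(cfg), draw_subtype_labels(cfg))

    def test_tils_higher_in_im_tumors(self):
        cfg = small_config(n_samples=1000, seed=7)
        clin = generate_clinical_cohort(cfg, draw_latent_phospho(cfg), draw_subtype_labels(cfg))
        tab = clin.table
        im = tab.loc[tab["true_subtype"] == "IM", "tils_percent"].mean()
        rest = tab.loc[tab["true_subtype"] != "IM", "tils_percent"].mean()
        assert im > rest + 10

    def test_binary_log_hr_recovered_without_censoring(self):
        # true HR 2 for the treatment arm; unweighted full-cohort Cox at
        # n = 2000 with no censoring must land near log 2
        from jnksig.survweight import weighted_cox_fit

        cfg = small_config(n_samples=2000, censoring_rate=0.0,
                           log_hr_effects={"treatment": np.log(2.0)}, seed=8)
        clin = generate_clinical_cohort(cfg, draw_latent_phospho(cfg), draw_subtype_labels(cfg))
        t, e = clin.endpoint("DFS")
        cov = pd.DataFrame({"cm": (clin.table["treatment"] == "CM").astype(float)})
        fit = weighted_cox_fit(t, e, cov, None)
        assert fit.ci_lower.iloc[0] < 2.0 < fit.ci_upper.iloc[0]


class TestCaseCohortSampling:
    def test_all_cases_included_and_ratio_hit(self):
        clin = make_clinical(400, 40, seed=0)
        ccs = case_cohort_sample(clin, ratio=3.0, seed=1)
        tab = ccs.table
        assert tab.loc[tab["is_case"], "included"].all()
        n_noncase = int((tab["included"] & ~tab["is_case"]).sum())
        # target 120; largest-remainder allocation with a min-1 floor can
        # overshoot by a few small strata
        assert 115 <= n_noncase <= 135

    def test_saturating_ratio_includes_everyone(self):
        clin = make_clinical(60, 20, seed=1)
        ccs = case_cohort_sample(clin, ratio=100.0, seed=2)
        assert ccs.table["included"].all()
        assert np.allclose(ccs.table["sampling_fraction"], 1.0)

    def test_single_stratum_fraction_recorded(self):
        # 1 case, 20 non-cases, ratio 5 -> 5 sampled -> fraction 0.25
        clin = make_clinical(21, 1, seed=2, single_stratum=True)
        ccs = case_cohort_sample(clin, ratio=5.0, seed=3)
        noncase = ccs.table[~ccs.table["is_case"]]
        assert np.allclose(noncase["sampling_fraction"], 0.25)
        assert int(noncase["included"].sum()) == 5

    def test_empirical_inclusion_matches_recorded_fraction(self):
        clin = make_clinical(500, 50, seed=3)
        ccs = case_cohort_sample(clin, ratio=3.0, seed=4)
        for _, sub in ccs.table[~ccs.table["is_case"]].groupby("stratum_id"):
            assert abs(sub["included"].mean() - sub["sampling_fraction"].iloc[0]) <= 1 / len(sub)

    def test_invalid_ratio_and_caseless_cohort_rejected(self):
        clin = make_clinical(50, 5, seed=4)
        with pytest.raises(SimulationError, match="ratio"):
            case_cohort_sample(clin, ratio=0.0)
        no_cases = make_clinical(50, 0, seed=5)
        with pytest.raises(SimulationError, match="case"):
            case_cohort_sample(no_cases, ratio=3.0)

    def test_deterministic_under_seed(self):
        clin = make_clinical(200, 20, seed=6)
        a = case_cohort_sample(clin, 3.0, seed=7)
        b = case_cohort_sample(clin, 3.0, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)
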