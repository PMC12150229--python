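"""Association scans: routing, recovery, calibration, FDR, hierarchy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fwtrace.models import (ModelSpec, compare_demographics,
                            cross_sectional_scan, fdr_adjust,
                            interaction_scan, longitudinal_scan,
                            _longitudinal_design)
from fwtrace.synthetic import default_truth, generate_study

from conftest import matched_cohorts


class TestFDR:
    def test_bh_stepup_oracle(self):
        """p = (0.01..0.05), m = 5: every q is 0.05 (hand-computed
        step-up: q_(i) = min over j>=i of p_(j) * m / j = 0.05)."""
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(q, 0.05)

    def test_degenerate_cases(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_q_dominates_p_and_preserves_order(self, p):
        """q >= p elementwise, and the q ordering follows the p ordering."""
        q = fdr_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestDemographics:
    def test_gaussian_equal_variance_routes_to_anova(self):
        """Exactly normal-shaped samples (normal quantiles) with equal
        variances pass Shapiro-Wilk and Levene and route to ANOVA."""
        v = stats.norm.ppf((np.arange(200) + 0.5) / 200)
        df = pd.DataFrame({"cohort": np.repeat(["a", "b"], 200),
                           "v": np.concatenate([v, v + 0.1])})
        out = compare_demographics(df, variables=["v"])
        assert out.loc[0, "test"] == "ANOVA"

    def test_unequal_variance_routes_to_welch(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.standard_normal(300),
                            4.0 * rng.standard_normal(300)])
        df = pd.DataFrame({"cohort": np.repeat(["a", "b"], 300), "v": v})
        out = compare_demographics(df, variables=["v"])
        assert out.loc[0, "test"] == "Welch ANOVA"

    def test_heavy_tails_route_to_kruskal(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"cohort": np.repeat(["a", "b"], 250),
                           "v": rng.standard_t(2, 500)})
        out = compare_demographics(df, variables=["v"])
        assert out.loc[0, "test"] == "Kruskal-Wallis"

    def test_low_expected_counts_route_to_fisher(self):
        """2x2 table with an expected cell count below 5 (checked by
        row x col / total arithmetic) uses Fisher's exact test."""
        df = pd.DataFrame({"cohort": ["a"] * 20 + ["b"] * 20,
                           "flag": ["y"] * 3 + ["n"] * 17
                                   + ["y"] * 1 + ["n"] * 19})
        ct = pd.crosstab(df["flag"], df["cohort"]).to_numpy()
        assert (stats.contingency.expected_freq(ct) < 5).any()
        out = compare_demographics(df, variables=["flag"])
        assert out.loc[0, "test"] == "Fisher exact"

    def test_constant_variable_untestable(self):
        df = pd.DataFrame({"cohort": ["a", "a", "b", "b"], "v": 1.0})
        out = compare_demographics(df, variables=["v"])
        assert "untestable" in out.loc[0, "test"]


class TestCrossSectionalScan:
    def test_outcome_equals_feature(self, null_study):
        """Cognition identical to the standardized feature: beta = 1 with
        p ~ 0 (no covariates)."""
        base = null_study.table[null_study.table["visit_index"] == 0].copy()
        base["memory"] = base["t0_FW"]
        res = cross_sectional_scan(base, ["t0_FW"],
                                   ModelSpec(covariates=()))
        assert res.loc[0, "beta"] == pytest.approx(1.0, abs=1e-9)
        assert res.loc[0, "p"] < 1e-12

    def test_effect_recovery_and_null_features(self):
        """A standardized effect of -0.5 on memory is recovered within its
        95% CI; null features stay above q = 0.05."""
        truth = default_truth(beta_wm_cross=-0.5, theta_wm_slope=0.0,
                              gamma_batch={}, delta_batch={})
        feats = ["fornix_FW"] + [f"t{i}_FW" for i in range(9)]
        study = generate_study(matched_cohorts(340, visits=1.2), truth,
                               seed=12, features=feats)
        base = study.table[study.table["visit_index"] == 0]
        res = cross_sectional_scan(base, feats,
                                   ModelSpec(scale_outcome=False,
                                             scale_features=False))
        row = res[res["feature"] == "fornix_FW"].iloc[0]
        assert row.beta - 1.96 * row.se <= -0.5 <= row.beta + 1.96 * row.se
        nulls = res[res["feature"] != "fornix_FW"]
        assert (nulls["q"] >= 0.05).mean() >= 0.8

    def test_permuted_outcome_type_one_error(self, null_study):
        """Permuting the outcome: raw p < 0.05 at roughly the nominal rate
        and the p distribution is consistent with uniform."""
        base = null_study.table[null_study.table["visit_index"] == 0].copy()
        rng = np.random.default_rng(5)
        pvals = []
        feats = [f"t{i}_FW" for i in range(6)]
        for rep in range(40):
            base["memory"] = rng.permutation(base["memory"].to_numpy())
            res = cross_sectional_scan(base, feats)
            pvals.extend(res["p"].tolist())
        pvals = np.asarray(pvals)
        frac = (pvals < 0.05).mean()
        # binomial 99% bounds around 0.05 at n = 240
        se = np.sqrt(0.05 * 0.95 / len(pvals))
        assert abs(frac - 0.05) < 2.58 * se + 1e-9
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_covariate_rescaling_invariance(self, effect_study):
        """Multiplying a continuous covariate by a constant leaves the WM
        term's beta and p unchanged (z-scoring absorbs the scale)."""
        base = effect_study.table[effect_study.table["visit_index"] == 0]
        res1 = cross_sectional_scan(base, ["fornix_FW"])
        scaled = base.copy()
        scaled["education"] = scaled["education"] * 12.0
        res2 = cross_sectional_scan(scaled, ["fornix_FW"])
        assert res1.loc[0, "beta"] == pytest.approx(res2.loc[0, "beta"],
                                                    abs=1e-10)
        assert res1.loc[0, "p"] == pytest.approx(res2.loc[0, "p"], abs=1e-10)


class TestLongitudinalScan:
    def test_theta_recovery(self, effect_study):
        """The generating WM x interval coefficient (-0.15) lies in the
        reported 95% CI."""
        res = longitudinal_scan(effect_study.table, ["fornix_FW"],
                                ModelSpec(scale_outcome=False,
                                          scale_features=False)).iloc[0]
        assert res.converged
        lo, hi = res.beta - 1.96 * res.se, res.beta + 1.96 * res.se
        assert lo <= -0.15 <= hi

    def test_null_scan_nonsignificant(self, null_study):
        feats = [f"t{i}_FW" for i in range(6)]
        res = longitudinal_scan(null_study.table, feats)
        assert (res["q"] >= 0.05).mean() >= 0.95

    def test_single_visit_is_clean_error(self, null_study):
        single = null_study.table[null_study.table["visit_index"] == 0]
        with pytest.raises(ValueError, match="inestimable"):
            longitudinal_scan(single, ["t0_FW"])

    def test_hierarchy_terms_present(self, effect_study):
        """The fitted design carries interval and both lower-order terms
        of every interaction."""
        _, _, _, _, _, names = _longitudinal_design(
            effect_study.table, "fornix_FW", ModelSpec())
        assert {"wm0", "interval", "wm0_x_interval",
                "age0_x_interval"} <= set(names)
        _, _, _, _, _, names = _longitudinal_design(
            effect_study.table, "fornix_FW", ModelSpec(),
            endophenotype="hippocampal_volume")
        assert {"endo", "wm0_x_endo", "endo_x_interval",
                "wm0_x_endo_x_interval"} <= set(names)


class TestInteractionScan:
    def test_three_way_recovery(self):
        """A generated WM x hippocampal-volume x interval effect is
        recovered within its 95% CI."""
        truth = default_truth(theta_wm_slope=-0.10, beta_wm_cross=-0.20,
                              phi_endo={"hippocampal_volume": 0.12},
                              gamma_batch={}, delta_batch={})
        df = generate_study(matched_cohorts(250, visits=3.0), truth,
                            seed=21, features=["fornix_FW"]).table
        res = interaction_scan(df, ["fornix_FW"], "hippocampal_volume",
                               mode="longitudinal",
                               spec=ModelSpec(scale_outcome=False,
                                              scale_features=False)).iloc[0]
        assert res.converged
        lo, hi = res.beta - 1.96 * res.se, res.beta + 1.96 * res.se
        assert lo <= 0.12 <= hi

    def test_null_interactions_nonsignificant(self, null_study):
        feats = [f"t{i}_FW" for i in range(6)]
        res = interaction_scan(null_study.table, feats, "hippocampal_volume",
                               mode="longitudinal")
        assert (res["q"] >= 0.05).mean() >= 0.95

    def test_constant_endophenotype_flagged(self, null_study):
        df = null_study.table.copy()
        df["amyloid_positive"] = 1
        with pytest.raises(ValueError, match="single level"):
            interaction_scan(df, ["t0_FW"], "amyloid_positive")

    def test_cross_sectional_mode_reports_two_way(self, null_study):
        res = interaction_scan(null_study.table, ["t0_FW"],
                               "hippocampal_volume", mode="cross-sectional")
        assert res.loc[0, "term"] == "wm_x_endo"
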