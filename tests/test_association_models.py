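import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from famdelay.association_models import (
    bh_fdr,
    build_results_tables,
    fit_stacked_hlm,
    pearson_r,
)
from famdelay.exceptions import DomainError, ModelFitError, ValidationError
from famdelay.synthetic_cohort import SyntheticConfig, simulate_analysis_dataset


def stacked_frame(n_families, parent_slope, child_slope, rng,
                  noise_sd=0.2, family_sd=0.0):
    """Direct generator of stacked AUC-style data with known slopes."""
    x = rng.normal(size=n_families)
    fam_eff = rng.normal(scale=family_sd, size=n_families) if family_sd else 0.0
    rows = []
    for member, slope, offset in (("parent", parent_slope, 0.7),
                                  ("child", child_slope, 0.5)):
        y = offset + slope * x + fam_eff + rng.normal(scale=noise_sd, size=n_families)
        rows.append(pd.DataFrame({
            "family_id": np.arange(n_families),
            "member": member,
            "auc_ord": y,
            "x": x,
        }))
    return pd.concat(rows, ignore_index=True)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(1, 11)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_hand_computed_example(self):
        r, p = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(DomainError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1, 2], [3, 4])

    def test_nan_pairs_dropped(self):
        r, _ = pearson_r([1, 2, 3, 4, np.nan], [2, 4, 6, 8, 1])
        assert r == pytest.approx(1.0)

    def test_point_biserial_equivalence(self, rng):
        # Pearson on a 0/1 dummy must equal the dedicated formula to 1e-12
        d = (rng.random(200) < 0.4).astype(float)
        y = rng.normal(size=200) + 0.5 * d
        r, p = pearson_r(d, y)
        rb, pb = sps.pointbiserialr(d, y)
        assert r == pytest.approx(rb, abs=1e-12)
        assert p == pytest.approx(pb, abs=1e-12)


class TestBhFdr:
    def test_step_up_example(self):
        flags = bh_fdr([0.001, 0.01, 0.02, 0.04, 0.2], q=0.1)
        assert flags.tolist() == [True, True, True, True, False]

    def test_all_large_none_flagged(self):
        assert not bh_fdr([0.9] * 6, q=0.1).any()

    def test_single_pvalue(self):
        assert bh_fdr([0.05], q=0.1).tolist() == [True]
        assert bh_fdr([0.11], q=0.1).tolist() == [False]

    def test_step_up_rescues_larger_p(self):
        # p=0.04 alone fails 1*q/m but is flagged via the larger rank
        flags = bh_fdr([0.04, 0.05], q=0.1)
        assert flags.tolist() == [True, True]

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(DomainError):
            bh_fdr([0.5, np.nan])
        with pytest.raises(DomainError):
            bh_fdr([0.5], q=0.0)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
           st.integers(min_value=0, max_value=39))
    def test_lowering_a_pvalue_never_unflags(self, pvals, idx):
        idx = idx % len(pvals)
        base = bh_fdr(pvals, q=0.1)
        lowered = list(pvals)
        lowered[idx] = lowered[idx] / 2.0
        after = bh_fdr(lowered, q=0.1)
        # every originally flagged index other than idx stays flagged
        keep = base.copy()
        keep[idx] = False
        assert np.all(after[keep])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_flags_nested_in_q(self, pvals):
        strict = bh_fdr(pvals, q=0.05)
        loose = bh_fdr(pvals, q=0.10)
        assert np.all(loose[strict])


class TestStackedHlm:
    def test_null_interaction_within_two_se(self, rng):
        data = stacked_frame(500, -0.1, -0.1, rng, family_sd=0.1)
        res = fit_stacked_hlm(data, "x")
        inter = res.interaction
        assert abs(inter.estimate) <= 2 * inter.se
        assert res.n_families == 500
        assert res.n_rows == 1000

    def test_known_slope_difference_recovered(self, rng):
        data = stacked_frame(500, -0.2, 0.0, rng, family_sd=0.1)
        res = fit_stacked_hlm(data, "x")
        # child dummy = 1: interaction = child slope - parent slope = +0.2
        inter = res.interaction
        assert inter.estimate == pytest.approx(0.2, abs=2 * inter.se)
        assert inter.pvalue < 1e-6

    def test_single_family_rejected(self, rng):
        data = stacked_frame(1, 0.0, 0.0, rng)
        with pytest.raises(ModelFitError):
            fit_stacked_hlm(data, "x")

    def test_single_member_type_rejected(self, rng):
        data = stacked_frame(50, 0.0, 0.0, rng)
        with pytest.raises(ModelFitError):
            fit_stacked_hlm(data[data["member"] == "parent"], "x")

    def test_constant_predictor_rejected(self, rng):
        data = stacked_frame(50, 0.0, 0.0, rng)
        data["x"] = 1.0
        with pytest.raises(ModelFitError):
            fit_stacked_hlm(data, "x")

    def test_duplicate_member_rows_rejected(self, rng):
        data = stacked_frame(50, 0.0, 0.0, rng)
        data = pd.concat([data, data.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError):
            fit_stacked_hlm(data, "x")

    def test_zero_family_variance_degrades_to_ols(self, rng):
        # no family effect in truth: REML lands on the boundary and the
        # fixed effects must match plain least squares
        data = stacked_frame(300, -0.1, 0.05, rng, family_sd=0.0)
        res = fit_stacked_hlm(data, "x")
        member = (data["member"] == "child").astype(float).to_numpy()
        X = np.column_stack([
            np.ones(len(data)), data["x"], member, data["x"] * member,
        ])
        beta_ols = np.linalg.lstsq(X, data["auc_ord"].to_numpy(), rcond=None)[0]
        fitted = [res.coefficients[t].estimate
                  for t in ("intercept", "x", "member", "x:member")]
        assert np.allclose(fitted, beta_ols, atol=1e-6)

    def test_engines_agree(self, rng):
        data = stacked_frame(150, -0.15, 0.0, rng, family_sd=0.12)
        fast = fit_stacked_hlm(data, "x")
        slow = fit_stacked_hlm(data, "x", engine="statsmodels")
        for term in fast.coefficients:
            assert fast.coefficients[term].estimate == pytest.approx(
                slow.coefficients[term].estimate, abs=1e-6
            )
            assert fast.coefficients[term].se == pytest.approx(
                slow.coefficients[term].se, abs=1e-6
            )
        assert fast.random_intercept_var == pytest.approx(
            slow.random_intercept_var, abs=1e-5
        )

    def test_engines_agree_with_covariates(self, rng):
        data = stacked_frame(120, -0.1, 0.0, rng, family_sd=0.1)
        data["age"] = rng.normal(30, 5, len(data))
        data["sex_code"] = rng.integers(1, 3, len(data))
        data["minority"] = rng.integers(0, 2, len(data))
        fast = fit_stacked_hlm(data, "x", with_covariates=True)
        slow = fit_stacked_hlm(data, "x", with_covariates=True, engine="statsmodels")
        for term in fast.coefficients:
            assert fast.coefficients[term].estimate == pytest.approx(
                slow.coefficients[term].estimate, abs=1e-6
            )
        assert set(fast.coefficients) == {
            "intercept", "x", "member", "x:member", "age", "sex_code", "minority",
        }


class TestResultsTables:
    def test_empty_predictor_list(self, rng):
        data = stacked_frame(10, 0.0, 0.0, rng)
        data["systematic"] = True
        res = build_results_tables(data, [])
        assert res.correlations.empty
        assert res.interactions.empty
        assert res.n_tests == 0

    def test_parent_only_effect_structure(self):
        cfg = SyntheticConfig(
            n_families=600, seed=42, gamma1_parent=1.0, gamma1_child=0.0,
            nonsystematic_rate_parent=0.1, nonsystematic_rate_child=0.2,
        )
        ds = simulate_analysis_dataset(cfg)
        res = build_results_tables(ds, ["income"])
        corr = res.correlations.set_index(["sample", "member"])
        r_parent = corr.loc[("all", "parent"), "r"]
        r_child = corr.loc[("all", "child"), "r"]
        assert r_parent > 0.2  # higher income -> less discounting in parents
        assert abs(r_child) < 0.1
        inter = res.interactions.set_index("sample")
        assert inter.loc["all", "p"] < 0.01
        assert bool(inter.loc["all", "fdr_flag"])
        assert res.n_tests == 6

    def test_battery_counts_54_tests_for_9_predictors(self):
        cfg = SyntheticConfig(n_families=150, seed=5)
        ds = simulate_analysis_dataset(cfg)
        ds["bmi"] = np.random.default_rng(0).normal(30, 5, len(ds))
        predictors = ["income", "education_years", "medicaid", "minority",
                      "family_size", "age", "sex_code", "bmi", "true_scarcity_z"]
        res = build_results_tables(ds, predictors)
        assert res.n_tests == 54
        assert len(res.correlations) == 36
        assert len(res.interactions) == 18
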