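import numpy as np
import pandas as pd
import pytest

from famdelay.association_models import pearson_r
from famdelay.discounting_metrics import auc_ordinal
from famdelay.exceptions import ValidationError
from famdelay.pipeline import score_choices_frame
from famdelay.response_qc import classify_systematic
from famdelay.synthetic_cohort import (
    SyntheticConfig,
    auc_ordinal_matrix,
    generate_cohort,
    generate_raw_choices,
    profiles_to_objects,
    recover_parameters,
    simulate_analysis_dataset,
    simulate_profiles,
    systematic_matrix,
)
from famdelay.task_engine import IndifferenceProfile, TaskConfig


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_families": 0},
            {"medicaid_rate": 1.5},
            {"nonsystematic_rate_child": -0.1},
            {"family_k_corr": 1.0},
            {"child_age_range": (5.0, 12.0)},
            {"income_log_sd": 0.0},
            {"high_temperature": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SyntheticConfig(**kwargs)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(n_families=120, seed=9)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_cohort(SyntheticConfig(n_families=50, seed=1))
        b = generate_cohort(SyntheticConfig(n_families=50, seed=2))
        assert not a["income"].equals(b["income"])

    def test_structure(self):
        cohort = generate_cohort(SyntheticConfig(n_families=30, seed=0))
        assert len(cohort) == 60
        counts = cohort.groupby("family_id")["member"].apply(
            lambda s: sorted(s.tolist())
        )
        assert all(c == ["child", "parent"] for c in counts)
        assert cohort["age"].between(6, 75).all()
        child_age = cohort.loc[cohort["member"] == "child", "age"]
        assert child_age.between(6, 12).all()

    def test_marginals_converge(self):
        cfg = SyntheticConfig(n_families=10_000, seed=3)
        cohort = generate_cohort(cfg)
        fam = cohort[cohort["member"] == "parent"]
        n = len(fam)
        # income: lognormal moment-matched to mean ~84.5k, sd ~55k
        se = 55_134 / np.sqrt(n)
        assert abs(fam["income"].mean() - 84_459) < 3 * se + 1500
        assert abs(fam["education_years"].mean() - cfg.education_mean) < 0.1
        assert abs(fam["age"].mean() - cfg.parent_age_mean) < 0.3
        assert abs((fam["insurance"] == "Medicaid").mean() - cfg.medicaid_rate) < 0.05
        minority = (fam["race"] != "White") | (fam["ethnicity"] == "Hispanic/Latino")
        assert abs(minority.mean() - cfg.minority_rate) < 0.02
        child = cohort[cohort["member"] == "child"]
        assert abs(child["age"].mean() - cfg.child_age_mean) < 0.1

    def test_medicaid_concentrated_in_lower_income(self):
        cohort = generate_cohort(SyntheticConfig(n_families=4000, seed=4))
        fam = cohort[cohort["member"] == "parent"]
        on = fam.loc[fam["insurance"] == "Medicaid", "income"]
        off = fam.loc[fam["insurance"] != "Medicaid", "income"]
        assert on.mean() < off.mean()

    def test_scarcity_z_standardized(self):
        cohort = generate_cohort(SyntheticConfig(n_families=3000, seed=5))
        z = cohort[cohort["member"] == "parent"]["true_scarcity_z"]
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)


class TestTaskSimulation:
    def test_profiles_deterministic(self):
        cohort = generate_cohort(SyntheticConfig(n_families=40, seed=6))
        a = simulate_profiles(cohort, seed=6)
        b = simulate_profiles(cohort, seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_batch_matches_scalar_engine(self, task_config):
        """Vectorized staircase agrees with the scalar engine for temp=0."""
        from famdelay.task_engine import Agent, run_full_task

        cohort = generate_cohort(
            SyntheticConfig(n_families=25, seed=7,
                            nonsystematic_rate_parent=0, nonsystematic_rate_child=0)
        )
        cohort = cohort.assign(true_temperature=0.0)
        profiles = simulate_profiles(cohort, task_config, seed=7)
        for _, row in cohort.head(20).iterrows():
            scalar = run_full_task(Agent(k=np.exp(row["true_log_k"])), task_config)
            got = profiles.loc[
                profiles["participant_id"] == row["participant_id"]
            ].iloc[0]
            for d in task_config.delays:
                assert got[f"ip_{d}"] == scalar.points[d]

    def test_choice_log_round_trip(self, task_config):
        cfg = SyntheticConfig(n_families=25, seed=8)
        cohort = generate_cohort(cfg)
        profiles = simulate_profiles(cohort, task_config, seed=cfg.seed)
        choices = generate_raw_choices(cohort, task_config, cfg)
        rescored = score_choices_frame(choices, task_config)
        for _, row in profiles.iterrows():
            prof = rescored[row["participant_id"]]
            for d in task_config.delays:
                assert prof.points[d] == pytest.approx(row[f"ip_{d}"], abs=1e-12)

    def test_zero_noise_everywhere_all_systematic(self, task_config):
        # logk_sd narrowed so no near-zero discounter produces a profile too
        # flat to clear the 10%-of-llr first-to-last drop
        cfg = SyntheticConfig(
            n_families=200, seed=11,
            nonsystematic_rate_parent=0.0, nonsystematic_rate_child=0.0,
            nonsystematic_income_coef=0.0, nonsystematic_child_age_coef=0.0,
            base_temperature=1e-9, logk_sd=0.5,
        )
        ds = simulate_analysis_dataset(cfg)
        assert ds["systematic"].all()

    def test_qc_pass_rates_track_designation(self):
        # designation 0.42 / 0.19 should land near 58% / 81% passing
        ds = simulate_analysis_dataset(SyntheticConfig(n_families=452, seed=12))
        child = ds[ds["member"] == "child"]["systematic"].mean()
        parent = ds[ds["member"] == "parent"]["systematic"].mean()
        assert child == pytest.approx(0.58, abs=0.07)
        assert parent == pytest.approx(0.81, abs=0.07)

    def test_latent_k_maps_monotonically_to_auc(self, task_config):
        cfg = SyntheticConfig(
            n_families=300, seed=13,
            nonsystematic_rate_parent=0.0, nonsystematic_rate_child=0.0,
            nonsystematic_income_coef=0.0, nonsystematic_child_age_coef=0.0,
            base_temperature=1e-9,
        )
        ds = simulate_analysis_dataset(cfg)
        ds = ds.sort_values("true_log_k")
        diffs = np.diff(ds["auc_ord"].to_numpy())
        assert np.all(diffs <= 1e-12)  # non-increasing; ties only at staircase grid
        assert ds["auc_ord"].iloc[0] > ds["auc_ord"].iloc[-1]

    def test_null_income_correlation_small(self):
        # full null: discounting slopes off AND no income-linked designation
        # (the QC channel otherwise couples income to AUC by construction)
        cfg = SyntheticConfig(
            n_families=2000, seed=14, gamma1_parent=0.0, gamma1_child=0.0,
            nonsystematic_income_coef=0.0,
        )
        ds = simulate_analysis_dataset(cfg)
        parents = ds[ds["member"] == "parent"]
        r, _ = pearson_r(parents["income"], parents["auc_ord"])
        assert abs(r) < 0.05


class TestVectorHelpers:
    def test_matrix_auc_matches_scalar(self, rng, task_config):
        pts = rng.uniform(0, 100, size=(200, 5))
        vec = auc_ordinal_matrix(pts, 100.0)
        for i in range(200):
            prof = IndifferenceProfile(
                "p", dict(zip(task_config.delays, pts[i])), 100.0
            )
            assert vec[i] == pytest.approx(auc_ordinal(prof).auc_ord, abs=1e-12)

    def test_matrix_qc_matches_scalar(self, rng, task_config):
        pts = rng.uniform(0, 100, size=(200, 5))
        vec = systematic_matrix(pts, 100.0)
        for i in range(200):
            prof = IndifferenceProfile(
                "p", dict(zip(task_config.delays, pts[i])), 100.0
            )
            assert vec[i] == classify_systematic(prof).systematic


class TestRecovery:
    def test_truth_columns_required(self):
        ds = simulate_analysis_dataset(SyntheticConfig(n_families=30, seed=15))
        cfg = SyntheticConfig(n_families=30, seed=15)
        with pytest.raises(ValidationError):
            recover_parameters(
                ds.drop(columns=["true_scarcity_z"]),
                ds.drop(columns=["true_scarcity_z"]),
                cfg,
            )

    def test_strong_parent_effect_detected(self):
        cfg = SyntheticConfig(n_families=800, seed=16, gamma1_parent=-0.5,
                              gamma1_child=0.0)
        ds = simulate_analysis_dataset(cfg)
        report = recover_parameters(ds, ds, cfg)
        assert report["sign_recovered"]
        assert report["significant"]
        assert report["expected_sign"] == -1

    def test_null_difference_not_systematically_signed(self):
        cfg = SyntheticConfig(n_families=300, seed=17, gamma1_parent=0.2,
                              gamma1_child=0.2)
        ds = simulate_analysis_dataset(cfg)
        report = recover_parameters(ds, ds, cfg)
        assert report["expected_sign"] == 0
        assert report["sign_recovered"]
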