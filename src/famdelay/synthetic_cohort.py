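"""Synthetic parent-child dyad generator.

Builds families with the marginal structure the analysis assumes: one
parent and one 6-12-year-old child per family, log-normal household
income, normal education years, Medicaid coverage tied to lower income, a
family-level minority indicator, and anthropometrics drawn around the
configured means.  Each member gets a latent hyperbolic discount rate: the
parent's log-k responds to a standardized scarcity composite with slope
``gamma1_parent``, the child's with slope ``gamma1_child`` (zero by
default), plus a within-family correlation.  Non-systematic responding is
produced mechanistically by assigning a very high choice-noise temperature
to designated members — designation is more likely for children and for
lower-income families — so downstream QC sees realistic failure shapes.

All latent quantities are retained in ``true_*`` columns for parameter
recovery; everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .anthropometrics import make_synthetic_reference
from .exceptions import ValidationError
from .task_engine import IndifferenceProfile, TaskConfig
from .association_models import fit_stacked_hlm

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "simulate_profiles",
    "generate_raw_choices",
    "simulate_analysis_dataset",
    "recover_parameters",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = (
    "true_scarcity_z",
    "true_log_k",
    "true_temperature",
    "true_nonsystematic",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults calibrated to plausible cohort marginals."""

    n_families: int = 452
    seed: int = 0

    # household economics (family-level)
    income_log_mean: float = 11.166  # lognormal moment-matched to mean ~84.5k, sd ~55k
    income_log_sd: float = 0.596
    education_mean: float = 15.0
    education_sd: float = 2.2
    medicaid_rate: float = 0.207
    medicaid_income_coef: float = 1.0  # logit shift per -1 SD of log income
    minority_rate: float = 0.346
    family_size_mean: float = 4.5
    family_size_sd: float = 1.2

    # ages and sex
    parent_age_mean: float = 41.4
    parent_age_sd: float = 7.3
    parent_male_rate: float = 0.141
    child_age_mean: float = 9.4
    child_age_sd: float = 1.8
    child_age_range: Tuple[float, float] = (6.0, 12.0)
    child_male_rate: float = 0.479

    # anthropometrics
    parent_bmi_mean: float = 37.1
    parent_bmi_sd: float = 7.9
    parent_bmi_min: float = 25.0
    child_zbmi_mean: float = 2.2
    child_zbmi_sd: float = 0.4
    child_zbmi_min: float = 1.04

    # latent discounting
    logk_parent_mean: float = -5.3
    logk_child_mean: float = -3.7
    logk_sd: float = 1.0
    gamma1_parent: float = 0.5  # scarcity-z -> parent log-k slope
    gamma1_child: float = 0.0
    family_k_corr: float = 0.3
    scarcity_weights: Tuple[float, float, float] = (1.0, 0.5, 0.5)  # -income z, -edu z, medicaid

    # choice noise and non-systematic designation
    base_temperature: float = 1.0
    base_temperature_sd: float = 0.5  # lognormal sigma of the low-noise temperature
    high_temperature: float = 500.0
    nonsystematic_rate_parent: float = 0.19
    nonsystematic_rate_child: float = 0.42
    nonsystematic_income_coef: float = 0.06  # added per +1 SD of scarcity
    nonsystematic_child_age_coef: float = 0.02  # added per year below the child mean age

    def __post_init__(self):
        if self.n_families < 1:
            raise ValidationError("n_families must be >= 1")
        for name in (
            "medicaid_rate",
            "minority_rate",
            "parent_male_rate",
            "child_male_rate",
            "nonsystematic_rate_parent",
            "nonsystematic_rate_child",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not -1 < self.family_k_corr < 1:
            raise ValidationError("family_k_corr must be in (-1, 1)")
        lo, hi = self.child_age_range
        if not (lo < hi and lo >= 6.0 - 1e-9 and hi <= 12.0 + 1e-9):
            raise ValidationError("child_age_range must be within [6, 12]")
        if self.income_log_sd <= 0 or self.logk_sd <= 0:
            raise ValidationError("scale parameters must be positive")
        if self.high_temperature <= 0 or self.base_temperature <= 0:
            raise ValidationError("temperatures must be positive")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _race_ethnicity(minority: np.ndarray, rng: np.random.Generator):
    """Assign race/ethnicity labels consistent with a minority indicator."""
    n = minority.size
    race = np.full(n, "White", dtype=object)
    ethnicity = np.full(n, "Not Hispanic/Latino", dtype=object)
    idx = np.nonzero(minority)[0]
    if idx.size:
        hispanic_white = rng.random(idx.size) < 0.25
        nonwhite = idx[~hispanic_white]
        race[nonwhite] = rng.choice(
            ["Black", "Multiracial", "Asian", "Other"],
            size=nonwhite.size,
            p=[0.6, 0.2, 0.1, 0.1],
        )
        hisp = idx[hispanic_white]
        ethnicity[hisp] = "Hispanic/Latino"
    return race, ethnicity


def generate_cohort(
    config: SyntheticConfig,
    reference: Optional[list] = None,
) -> pd.DataFrame:
    """Generate the participant table (two rows per family) with latent truth.

    Returns one row per member with demographics, anthropometrics and the
    ``true_*`` latent columns (scarcity z-score, log discount rate, choice
    temperature, non-systematic designation).
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_families
    if reference is None:
        reference = make_synthetic_reference()

    income = np.exp(rng.normal(config.income_log_mean, config.income_log_sd, n))
    education = np.clip(rng.normal(config.education_mean, config.education_sd, n), 8, 22)
    income_z = _standardize(np.log(income))
    edu_z = _standardize(education)
    medicaid_logit = (
        np.log(config.medicaid_rate / (1 - config.medicaid_rate))
        - config.medicaid_income_coef * income_z
        - 0.3 * edu_z
    )
    medicaid = (rng.random(n) < expit(medicaid_logit)).astype(int)
    minority = (rng.random(n) < config.minority_rate).astype(int)
    family_size = np.clip(
        np.round(rng.normal(config.family_size_mean, config.family_size_sd, n)), 2, 12
    ).astype(int)

    w_inc, w_edu, w_med = config.scarcity_weights
    scarcity = _standardize(
        w_inc * (-income_z) + w_edu * (-edu_z) + w_med * medicaid.astype(float)
    )

    e_parent = rng.normal(size=n)
    rho = config.family_k_corr
    e_child = rho * e_parent + np.sqrt(1 - rho**2) * rng.normal(size=n)
    logk_parent = (
        config.logk_parent_mean + config.gamma1_parent * scarcity + config.logk_sd * e_parent
    )
    logk_child = (
        config.logk_child_mean + config.gamma1_child * scarcity + config.logk_sd * e_child
    )

    # non-systematic designation: higher for children, lower-income families
    p_parent = np.clip(
        config.nonsystematic_rate_parent + config.nonsystematic_income_coef * scarcity,
        0.0,
        1.0,
    )
    child_age = np.clip(
        rng.normal(config.child_age_mean, config.child_age_sd, n), *config.child_age_range
    )
    p_child = np.clip(
        config.nonsystematic_rate_child
        + config.nonsystematic_income_coef * scarcity
        + config.nonsystematic_child_age_coef * (config.child_age_mean - child_age),
        0.0,
        1.0,
    )
    nonsys_parent = rng.random(n) < p_parent
    nonsys_child = rng.random(n) < p_child
    temp_low_parent = config.base_temperature * np.exp(
        config.base_temperature_sd * rng.normal(size=n)
    )
    temp_low_child = config.base_temperature * np.exp(
        config.base_temperature_sd * rng.normal(size=n)
    )
    temp_parent = np.where(nonsys_parent, config.high_temperature, temp_low_parent)
    temp_child = np.where(nonsys_child, config.high_temperature, temp_low_child)

    parent_male = rng.random(n) < config.parent_male_rate
    parent_age = np.clip(rng.normal(config.parent_age_mean, config.parent_age_sd, n), 20, 75)
    parent_height = np.where(
        parent_male, rng.normal(177.0, 8.0, n), rng.normal(163.0, 7.0, n)
    )
    parent_bmi = np.clip(
        rng.normal(config.parent_bmi_mean, config.parent_bmi_sd, n),
        config.parent_bmi_min,
        70.0,
    )
    parent_weight = parent_bmi * (parent_height / 100.0) ** 2

    child_male = rng.random(n) < config.child_male_rate
    child_height = 110.0 + 6.2 * (child_age - 6.0) + rng.normal(0, 5.0, n)
    child_zbmi = np.clip(
        rng.normal(config.child_zbmi_mean, config.child_zbmi_sd, n),
        config.child_zbmi_min,
        4.0,
    )
    child_bmi = _child_bmi_from_z(child_zbmi, child_age * 12.0, child_male, reference)
    child_weight = child_bmi * (child_height / 100.0) ** 2

    race, ethnicity = _race_ethnicity(minority, rng)
    insurance = np.where(medicaid == 1, "Medicaid", "Private").astype(object)
    other_ins = (medicaid == 0) & (rng.random(n) < 0.08)
    insurance[other_ins] = rng.choice(
        ["Medicare", "Veterans", "Supplementary", "Other"], size=int(other_ins.sum())
    )

    family_id = np.array([f"F{i + 1:04d}" for i in range(n)], dtype=object)
    shared = {
        "family_id": family_id,
        "race": race,
        "ethnicity": ethnicity,
        "insurance": insurance,
        "income": income,
        "education_years": education,
        "family_size": family_size,
        "true_scarcity_z": scarcity,
    }
    parents = pd.DataFrame(
        {
            "participant_id": family_id + "-P",
            "member": "parent",
            "sex": np.where(parent_male, "male", "female"),
            "age": parent_age,
            **shared,
            "height_cm": parent_height,
            "weight_kg": parent_weight,
            "true_log_k": logk_parent,
            "true_temperature": temp_parent,
            "true_nonsystematic": nonsys_parent,
            "_order": np.arange(n) * 2,
        }
    )
    children = pd.DataFrame(
        {
            "participant_id": family_id + "-C",
            "member": "child",
            "sex": np.where(child_male, "male", "female"),
            "age": child_age,
            **shared,
            "height_cm": child_height,
            "weight_kg": child_weight,
            "true_log_k": logk_child,
            "true_temperature": temp_child,
            "true_nonsystematic": nonsys_child,
            "_order": np.arange(n) * 2 + 1,
        }
    )
    cohort = (
        pd.concat([parents, children], ignore_index=True)
        .sort_values("_order", kind="stable")
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    cols = [
        "participant_id", "family_id", "member", "sex", "age", "race", "ethnicity",
        "insurance", "income", "education_years", "family_size", "height_cm",
        "weight_kg", "true_scarcity_z", "true_log_k", "true_temperature",
        "true_nonsystematic",
    ]
    return cohort[cols]


def _child_bmi_from_z(
    z: np.ndarray, age_months: np.ndarray, male: np.ndarray, reference
) -> np.ndarray:
    """Vectorized inverse-LMS child BMI (nearest-month row, as lookup_reference)."""
    out = np.empty(z.size)
    for sex, mask in (("male", male), ("female", ~male)):
        if not mask.any():
            continue
        rows = sorted(
            (r for r in reference if r.sex == sex), key=lambda r: r.age_months
        )
        ages = np.array([r.age_months for r in rows])
        L = np.array([r.L for r in rows])
        M = np.array([r.M for r in rows])
        S = np.array([r.S for r in rows])
        idx = np.abs(ages[None, :] - age_months[mask, None]).argmin(axis=1)
        out[mask] = M[idx] * (1.0 + L[idx] * S[idx] * z[mask]) ** (1.0 / L[idx])
    return out


def _batch_staircase(
    values: np.ndarray,
    temps: np.ndarray,
    config: TaskConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized staircase: one delay, many responders.

    Returns (offers[n, T], chose_immediate[n, T], indifference[n]).
    Matches the scalar engine trial for trial: deterministic threshold
    comparison at temperature 0 (ties per config.tie_rule), logistic
    choice otherwise.
    """
    n = values.size
    offer = np.full(n, config.start_fraction * config.llr_amount)
    step = config.start_fraction * config.llr_amount / 2.0
    offers = np.empty((n, config.trials_per_delay))
    choices = np.empty((n, config.trials_per_delay), dtype=bool)
    noisy = temps > 0
    for t in range(config.trials_per_delay):
        offers[:, t] = offer
        diff = offer - values
        u = rng.random(n)  # drawn for every responder to keep streams aligned
        with np.errstate(over="ignore"):
            p_imm = expit(diff / np.where(noisy, temps, 1.0))
        if config.tie_rule == "prefer_immediate":
            det_choice = diff >= 0
        else:
            det_choice = diff > 0
        chose = np.where(noisy, u < p_imm, det_choice)
        choices[:, t] = chose
        offer = np.where(chose, offer - step, offer + step)
        step /= 2.0
    return offers, choices, offer


def simulate_profiles(
    cohort: pd.DataFrame,
    task_config: Optional[TaskConfig] = None,
    seed: int = 0,
    *,
    return_trials: bool = False,
):
    """Run the adjusting-amount task for every cohort member (vectorized).

    Returns a wide DataFrame (participant_id, member, ip_<delay>...); with
    ``return_trials=True`` also returns the long per-trial choice log in
    the standard CSV dialect.
    """
    task_config = task_config or TaskConfig()
    rng = np.random.default_rng([seed, 1])
    k = np.exp(cohort["true_log_k"].to_numpy(dtype=float))
    temps = cohort["true_temperature"].to_numpy(dtype=float)
    n = len(cohort)

    profile = {"participant_id": cohort["participant_id"].to_numpy(),
               "member": cohort["member"].to_numpy()}
    trial_frames = []
    for delay in task_config.ordered_delays():
        values = task_config.llr_amount / (1.0 + k * delay)
        offers, choices, ip = _batch_staircase(values, temps, task_config, rng)
        profile[f"ip_{delay}"] = ip
        if return_trials:
            t_count = task_config.trials_per_delay
            trial_frames.append(
                pd.DataFrame(
                    {
                        "participant_id": np.repeat(
                            cohort["participant_id"].to_numpy(), t_count
                        ),
                        "member_role": np.repeat(cohort["member"].to_numpy(), t_count),
                        "delay_days": delay,
                        "trial_index": np.tile(np.arange(1, t_count + 1), n),
                        "immediate_amount": offers.ravel(),
                        "chose_immediate": choices.ravel().astype(int),
                    }
                )
            )
    profiles = pd.DataFrame(profile)
    if return_trials:
        trials = pd.concat(trial_frames, ignore_index=True)
        trials = trials.sort_values(
            ["participant_id", "delay_days", "trial_index"], kind="stable"
        ).reset_index(drop=True)
        return profiles, trials
    return profiles


def generate_raw_choices(
    cohort: pd.DataFrame,
    task_config: Optional[TaskConfig] = None,
    config: Optional[SyntheticConfig] = None,
) -> pd.DataFrame:
    """Emit the complete per-trial choice log for a generated cohort."""
    seed = config.seed if config is not None else 0
    _, trials = simulate_profiles(cohort, task_config, seed=seed, return_trials=True)
    return trials


def profiles_to_objects(
    profiles: pd.DataFrame, task_config: Optional[TaskConfig] = None
) -> Dict[str, IndifferenceProfile]:
    """Convert a wide profile frame into IndifferenceProfile objects."""
    task_config = task_config or TaskConfig()
    ip_cols = {int(c[3:]): c for c in profiles.columns if c.startswith("ip_")}
    out = {}
    for row in profiles.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(profiles.columns, row))
        out[d["participant_id"]] = IndifferenceProfile(
            participant_id=d["participant_id"],
            points={delay: d[col] for delay, col in ip_cols.items()},
            llr_amount=task_config.llr_amount,
        )
    return out


def auc_ordinal_matrix(points: np.ndarray, llr: float) -> np.ndarray:
    """Ordinal AUC for a (participants x delays) matrix of delay-ordered
    indifference points; agrees with the scalar :func:`auc_ordinal` and is
    cross-checked against it in the test suite."""
    y = np.asarray(points, dtype=float) / llr
    n = y.shape[1]
    weights = np.full(n, 1.0 / (n - 1))
    weights[0] = weights[-1] = 0.5 / (n - 1)
    return y @ weights


def systematic_matrix(points: np.ndarray, llr: float,
                      c1_frac: float = 0.20, c2_frac: float = 0.10) -> np.ndarray:
    """Vectorized systematic-responding classification (both criteria)."""
    pts = np.asarray(points, dtype=float)
    no_rise = ~(np.diff(pts, axis=1) > c1_frac * llr).any(axis=1)
    drop_ok = pts[:, 0] - pts[:, -1] >= c2_frac * llr
    return no_rise & drop_ok


def simulate_analysis_dataset(
    config: SyntheticConfig,
    task_config: Optional[TaskConfig] = None,
) -> pd.DataFrame:
    """Cohort -> task -> QC -> ordinal AUC, as one stacked analysis frame.

    Fast path for calibration and power studies: the task runs vectorized,
    then QC and AUC use the standard scalar components per participant.
    Columns: family_id, member, auc_ord, systematic, true_* and the
    family-level predictors.
    """
    task_config = task_config or TaskConfig()
    cohort = generate_cohort(config)
    profiles = simulate_profiles(cohort, task_config, seed=config.seed)
    points = profiles[
        [f"ip_{d}" for d in sorted(task_config.delays)]
    ].to_numpy(dtype=float)
    auc = auc_ordinal_matrix(points, task_config.llr_amount)
    systematic = systematic_matrix(points, task_config.llr_amount)
    out = cohort.copy()
    out["auc_ord"] = auc
    out["systematic"] = systematic
    out["sex_code"] = np.where(out["sex"] == "male", 1, 2)
    out["minority"] = (
        (out["race"] != "White") | (out["ethnicity"] == "Hispanic/Latino")
    ).astype(int)
    out["medicaid"] = (out["insurance"] == "Medicaid").astype(int)
    return out


def recover_parameters(
    analysis: pd.DataFrame,
    truth: pd.DataFrame,
    config: SyntheticConfig,
    *,
    alpha: float = 0.05,
    systematic_only: bool = False,
) -> dict:
    """Assess recovery of the parent-child scarcity-slope difference.

    Fits the stacked model with the latent scarcity z-score as predictor
    and compares the interaction estimate against the generating truth.
    With the child dummy coded 1 and AUC decreasing in log-k, the expected
    interaction sign equals sign(gamma1_parent - gamma1_child).
    """
    missing = [c for c in ("true_scarcity_z",) if c not in truth.columns]
    if missing:
        raise ValidationError(f"latent truth columns absent: {missing}")
    merged = analysis.merge(
        truth[["participant_id", "true_scarcity_z"]], on="participant_id", how="inner"
    ) if "true_scarcity_z" not in analysis.columns else analysis
    if systematic_only:
        merged = merged[merged["systematic"].astype(bool)]
    res = fit_stacked_hlm(merged, "true_scarcity_z")
    inter = res.interaction
    truth_diff = config.gamma1_parent - config.gamma1_child
    expected_sign = int(np.sign(truth_diff))
    observed_sign = int(np.sign(inter.estimate))
    return {
        "interaction_estimate": inter.estimate,
        "interaction_se": inter.se,
        "interaction_p": inter.pvalue,
        "truth_gamma_diff": truth_diff,
        "expected_sign": expected_sign,
        "sign_recovered": expected_sign == 0 or observed_sign == expected_sign,
        "significant": inter.pvalue < alpha,
        "n_families": res.n_families,
    }


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["child_age_range"] = list(d["child_age_range"])
    d["scarcity_weights"] = list(d["scarcity_weights"])
    return d
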