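"""End-to-end orchestration: scoring -> QC -> AUC -> covariates -> models.

A run consumes either a generated synthetic cohort or user-supplied CSVs
(choice log + demographics + LMS reference) and writes, under one output
directory: the scored indifference profiles, the QC report, discounting
metrics, anthropometrics, the merged analysis table, a descriptives table
split by systematic status, the correlation/interaction results tables
(all-data and systematic-only are both inside the battery), full model
dumps, and a manifest tying every output to the config, seed and input
digests.  Runs are deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import yaml
from statsmodels.stats.proportion import proportions_ztest

from . import __version__
from .anthropometrics import (
    compute_bmi,
    lms_z,
    lookup_reference,
    make_synthetic_reference,
    percent_over_median_bmi,
    reference_from_frame,
    reference_to_frame,
)
from .association_models import ResultsTables, build_results_tables
from .discounting_metrics import auc_ordinal
from .exceptions import ValidationError
from .response_qc import classify_systematic
from .scarcity_covariates import categorize_income, encode_covariates
from .synthetic_cohort import (
    SyntheticConfig,
    TRUTH_COLUMNS,
    config_to_dict,
    generate_cohort,
    generate_raw_choices,
)
from .task_engine import ChoiceTrial, IndifferenceProfile, TaskConfig, score_choice_log

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = (
    "bmi",
    "pct_over_median",
    "medicaid",
    "education_years",
    "income",
    "minority",
    "family_size",
    "age",
    "sex_code",
)

DEMOGRAPHIC_COLUMNS = (
    "participant_id",
    "family_id",
    "member",
    "sex",
    "age",
    "race",
    "ethnicity",
    "insurance",
    "income",
    "education_years",
    "family_size",
    "height_cm",
    "weight_kg",
)


@dataclass
class PipelineConfig:
    """Full run configuration (plain-text YAML on disk)."""

    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    predictors: Sequence[str] = DEFAULT_PREDICTORS
    fdr_q: float = 0.10
    with_covariates_variant: bool = True
    # data-mode inputs
    choices_csv: Optional[str] = None
    demographics_csv: Optional[str] = None
    reference_csv: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path, seed: Optional[int] = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        task = TaskConfig(**{k: tuple(v) if k == "delays" else v
                             for k, v in (raw.get("task") or {}).items()})
        syn_raw = dict(raw.get("synthetic") or {})
        for key in ("child_age_range", "scarcity_weights"):
            if key in syn_raw:
                syn_raw[key] = tuple(syn_raw[key])
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            task=task,
            synthetic=SyntheticConfig(**syn_raw),
            predictors=tuple(raw.get("predictors", DEFAULT_PREDICTORS)),
            fdr_q=float(raw.get("fdr_q", 0.10)),
            with_covariates_variant=bool(raw.get("with_covariates_variant", True)),
            choices_csv=raw.get("choices_csv"),
            demographics_csv=raw.get("demographics_csv"),
            reference_csv=raw.get("reference_csv"),
        )
        if seed is not None:
            cfg = cfg.with_seed(seed)
        return cfg

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            synthetic=dataclasses.replace(self.synthetic, seed=seed),
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "task": dataclasses.asdict(self.task),
            "synthetic": config_to_dict(self.synthetic),
            "predictors": list(self.predictors),
            "fdr_q": self.fdr_q,
            "with_covariates_variant": self.with_covariates_variant,
            "choices_csv": self.choices_csv,
            "demographics_csv": self.demographics_csv,
            "reference_csv": self.reference_csv,
        }


def _require_columns(frame: pd.DataFrame, columns: Sequence[str], name: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValidationError(f"{name}: missing columns {missing}")


def validate_demographics(frame: pd.DataFrame, name: str = "demographics") -> None:
    """Schema-check the demographics table, naming the first offending row."""
    _require_columns(frame, DEMOGRAPHIC_COLUMNS, name)
    if frame["participant_id"].duplicated().any():
        dup = frame.loc[frame["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValidationError(f"{name}: duplicate participant_id {dup!r}")
    for idx, row in frame.iterrows():
        try:
            if row["member"] not in ("parent", "child"):
                raise ValidationError(
                    f"member must be 'parent' or 'child', got {row['member']!r}"
                )
            encode_covariates(row.to_dict())
        except (ValidationError, KeyError, ValueError) as exc:
            raise ValidationError(
                f"{name} row {idx} (participant {row.get('participant_id')!r}): {exc}"
            ) from exc


def score_choices_frame(choices: pd.DataFrame, task: TaskConfig) -> Dict[str, IndifferenceProfile]:
    """Score a long choice-log frame into per-participant profiles."""
    _require_columns(
        choices,
        ("participant_id", "delay_days", "trial_index", "immediate_amount", "chose_immediate"),
        "choice log",
    )
    profiles: Dict[str, IndifferenceProfile] = {}
    for pid, block in choices.groupby("participant_id", sort=True):
        trials = [
            ChoiceTrial(
                participant_id=str(pid),
                delay_days=int(r.delay_days),
                immediate_amount=float(r.immediate_amount),
                chose_immediate=bool(r.chose_immediate),
                trial_index=int(r.trial_index),
            )
            for r in block.itertuples()
        ]
        profiles[str(pid)] = score_choice_log(trials, task)
    return profiles


def _profiles_long(profiles: Dict[str, IndifferenceProfile]) -> pd.DataFrame:
    rows = [
        {"participant_id": pid, "delay_days": d, "indifference_point": prof.points[d]}
        for pid, prof in profiles.items()
        for d in prof.delays
    ]
    return pd.DataFrame(rows)


def build_analysis_table(
    demographics: pd.DataFrame,
    profiles: Dict[str, IndifferenceProfile],
    reference,
) -> pd.DataFrame:
    """Merge QC, AUC, anthropometrics and coded covariates per participant."""
    parent_incomes = demographics.loc[
        demographics["member"] == "parent", "income"
    ].tolist()
    categories = dict(
        zip(
            demographics.loc[demographics["member"] == "parent", "family_id"],
            categorize_income(parent_incomes),
        )
    )
    records = []
    for _, row in demographics.iterrows():
        pid = row["participant_id"]
        prof = profiles.get(pid)
        coded = encode_covariates(
            row.to_dict(), income_category=categories.get(row["family_id"])
        )
        rec = {
            "participant_id": pid,
            "family_id": row["family_id"],
            "member": row["member"],
            "income": coded.income,
            "income_category": coded.income_category,
            "education_years": coded.education_years,
            "medicaid": coded.medicaid,
            "minority": coded.minority,
            "sex_code": coded.sex_code,
            "family_size": coded.family_size,
            "age": coded.age,
        }
        bmi = compute_bmi(float(row["weight_kg"]), float(row["height_cm"]))
        ref_row = lookup_reference(
            str(row["sex"]).lower(), float(row["age"]) * 12.0, row["member"], reference
        )
        rec["bmi"] = bmi
        rec["pct_over_median"] = percent_over_median_bmi(bmi, ref_row.M)
        rec["zbmi"] = lms_z(bmi, ref_row)
        if prof is not None:
            qc = classify_systematic(prof)
            rec["auc_ord"] = auc_ordinal(prof).auc_ord
            rec["systematic"] = qc.systematic
            rec["criterion1_violations"] = qc.violation_labels()
            rec["criterion2_violation"] = int(qc.criterion2_violation)
            rec["task_completed"] = True
        else:
            rec.update(
                auc_ord=np.nan, systematic=False, criterion1_violations="",
                criterion2_violation=0, task_completed=False,
            )
        records.append(rec)
    return pd.DataFrame(records)


def _prop_test(x1: pd.Series, x2: pd.Series) -> float:
    x1, x2 = x1.dropna(), x2.dropna()
    if len(x1) == 0 or len(x2) == 0:
        return np.nan
    count = np.array([x1.sum(), x2.sum()])
    nobs = np.array([len(x1), len(x2)])
    if np.all(count == 0) or np.all(count == nobs):
        return 1.0
    return float(proportions_ztest(count, nobs)[1])


def _mean_test(x1: pd.Series, x2: pd.Series) -> float:
    x1, x2 = x1.dropna(), x2.dropna()
    if len(x1) < 2 or len(x2) < 2:
        return np.nan
    return float(sps.ttest_ind(x1, x2, equal_var=False).pvalue)


def build_descriptives_table(analysis: pd.DataFrame) -> pd.DataFrame:
    """Table-1-shaped descriptives: all vs systematic vs non-systematic.

    Member-level variables are summarized per role; family-level variables
    are summarized once from the parent rows.  The p-value compares
    systematic against non-systematic responders (Welch t-test for means,
    two-proportion z-test for rates).
    """
    completed = analysis[analysis["task_completed"]].copy()
    member_vars = [
        ("n", None, "count"),
        ("sex_male", lambda d: (d["sex_code"] == 1).astype(float), "prop"),
        ("minority", lambda d: d["minority"].astype(float), "prop"),
        ("pct_over_median", lambda d: d["pct_over_median"], "mean"),
        ("age", lambda d: d["age"], "mean"),
        ("auc_ord", lambda d: d["auc_ord"], "mean"),
        ("zbmi", lambda d: d["zbmi"], "mean"),
        ("bmi", lambda d: d["bmi"], "mean"),
    ]
    family_vars = [
        ("medicaid", lambda d: d["medicaid"].astype(float), "prop"),
        ("education_years", lambda d: d["education_years"], "mean"),
        ("income", lambda d: d["income"], "mean"),
        ("family_size", lambda d: d["family_size"].astype(float), "mean"),
    ]
    rows = []
    for member in ("parent", "child"):
        sub = completed[completed["member"] == member]
        sys_ = sub[sub["systematic"]]
        non = sub[~sub["systematic"]]
        for name, getter, kind in member_vars:
            rows.append(_descriptive_row(name, member, sub, sys_, non, getter, kind))
    parents = completed[completed["member"] == "parent"]
    psys = parents[parents["systematic"]]
    pnon = parents[~parents["systematic"]]
    for name, getter, kind in family_vars:
        rows.append(_descriptive_row(name, "family", parents, psys, pnon, getter, kind))
    return pd.DataFrame(rows)


def _descriptive_row(name, member, allr, sysr, nonr, getter, kind):
    if kind == "count":
        return {
            "variable": "n", "member": member,
            "all": len(allr), "systematic": len(sysr), "non_systematic": len(nonr),
            "all_sd": np.nan, "systematic_sd": np.nan, "non_systematic_sd": np.nan,
            "p_sys_vs_nonsys": np.nan,
        }
    va, vs, vn = getter(allr), getter(sysr), getter(nonr)
    if kind == "prop":
        return {
            "variable": name, "member": member,
            "all": va.mean(), "systematic": vs.mean(), "non_systematic": vn.mean(),
            "all_sd": np.nan, "systematic_sd": np.nan, "non_systematic_sd": np.nan,
            "p_sys_vs_nonsys": _prop_test(vs, vn),
        }
    return {
        "variable": name, "member": member,
        "all": va.mean(), "systematic": vs.mean(), "non_systematic": vn.mean(),
        "all_sd": va.std(ddof=1), "systematic_sd": vs.std(ddof=1),
        "non_systematic_sd": vn.std(ddof=1),
        "p_sys_vs_nonsys": _mean_test(vs, vn),
    }


def _model_dump(results: ResultsTables, title: str) -> str:
    lines = [f"== {title} ==", f"tests in battery: {results.n_tests} (q={results.fdr_q})"]
    for res in results.model_results:
        lines.append(
            f"\n-- predictor={res.predictor} covariates={res.with_covariates} "
            f"families={res.n_families} rows={res.n_rows} "
            f"tau2={res.random_intercept_var:.6g} converged={res.converged}"
        )
        for term, coef in res.coefficients.items():
            lines.append(
                f"   {term:<28s} est={coef.estimate: .6f} se={coef.se:.6f} "
                f"p={coef.pvalue:.4g}"
            )
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(
    config: PipelineConfig,
    mode: str = "synthetic",
    out_dir: str | Path = "out",
) -> Path:
    """Execute the full analysis and write every artifact under ``out_dir``."""
    if mode not in ("synthetic", "data"):
        raise ValidationError("mode must be 'synthetic' or 'data'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: Dict[str, str] = {}

    if mode == "synthetic":
        logger.info("generating synthetic cohort (n_families=%d, seed=%d)",
                    config.synthetic.n_families, config.synthetic.seed)
        reference = make_synthetic_reference()
        cohort = generate_cohort(config.synthetic, reference)
        choices = generate_raw_choices(cohort, config.task, config.synthetic)
        demographics = cohort.drop(columns=list(TRUTH_COLUMNS))
        truth = cohort[["participant_id", *TRUTH_COLUMNS]]
        _write_csv(demographics, out / "demographics.csv")
        _write_csv(truth, out / "truth.csv")
        _write_csv(choices, out / "choices.csv")
        _write_csv(reference_to_frame(reference), out / "reference.csv")
    else:
        for name, path in (
            ("choices_csv", config.choices_csv),
            ("demographics_csv", config.demographics_csv),
        ):
            if not path:
                raise ValidationError(f"data mode requires {name} in the config")
            if not Path(path).exists():
                raise ValidationError(f"{name} file not found: {path}")
        choices = pd.read_csv(config.choices_csv)
        demographics = pd.read_csv(config.demographics_csv)
        inputs["choices_csv"] = _sha256(Path(config.choices_csv))
        inputs["demographics_csv"] = _sha256(Path(config.demographics_csv))
        if config.reference_csv:
            reference = reference_from_frame(pd.read_csv(config.reference_csv))
            inputs["reference_csv"] = _sha256(Path(config.reference_csv))
        else:
            reference = make_synthetic_reference()

    validate_demographics(demographics)

    profiles = score_choices_frame(choices, config.task)
    unknown = set(profiles) - set(demographics["participant_id"].astype(str))
    if unknown:
        raise ValidationError(
            f"choice log references unknown participants {sorted(unknown)[:5]}"
        )
    _write_csv(_profiles_long(profiles), out / "profiles.csv")

    analysis = build_analysis_table(demographics, profiles, reference)
    _write_csv(analysis, out / "analysis.csv")

    qc_report = analysis[analysis["task_completed"]][
        ["participant_id", "member", "systematic",
         "criterion1_violations", "criterion2_violation"]
    ].rename(columns={"member": "member_role"})
    qc_report = qc_report.assign(systematic=qc_report["systematic"].astype(int))
    _write_csv(qc_report, out / "qc_report.csv")

    metrics = analysis[analysis["task_completed"]][
        ["participant_id", "member", "auc_ord", "systematic"]
    ].rename(columns={"member": "member_role"})
    _write_csv(metrics, out / "metrics.csv")

    anthro = analysis[["participant_id", "bmi", "pct_over_median", "zbmi"]]
    _write_csv(anthro, out / "anthro.csv")

    descriptives = build_descriptives_table(analysis)
    _write_csv(descriptives, out / "table1_descriptives.csv")

    completed = analysis[analysis["task_completed"]]
    logger.info("running association battery on %d predictors", len(config.predictors))
    results = build_results_tables(completed, config.predictors, q=config.fdr_q)
    _write_csv(results.correlations, out / "table2_correlations.csv")
    _write_csv(results.interactions, out / "table2_interactions.csv")

    dump = _model_dump(results, "stacked models, no covariates")
    if config.with_covariates_variant:
        cov_results = build_results_tables(
            completed, config.predictors, q=config.fdr_q, with_covariates=True
        )
        _write_csv(cov_results.interactions, out / "table2_interactions_covariates.csv")
        dump += "\n" + _model_dump(cov_results, "stacked models, with covariates")
    (out / "model_dumps.txt").write_text(dump)

    manifest = {
        "package_version": __version__,
        "mode": mode,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": inputs,
        "outputs": sorted(
            p.name for p in out.iterdir() if p.name != "manifest.json"
        ),
        "n_tests": results.n_tests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
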