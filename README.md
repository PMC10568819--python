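# famdelay

Measurement and analysis toolkit for adjusting-amount delay-discounting
studies of parent–child dyads: task simulation and scoring, response
quality control, ordinal area-under-the-curve, anthropometric and
economic-scarcity covariate coding, and stacked family mixed models with
false-discovery-rate control — plus a synthetic cohort generator so the
entire path runs and tests without any external data.

## Modules

| module | what it does |
| --- | --- |
| `famdelay.task_engine` | Halving-staircase adjusting-amount task: simulate hyperbolic agents (optional logistic choice noise), administer staircases, score recorded choice logs into indifference points with consistency checking. |
| `famdelay.response_qc` | Systematic vs non-systematic classification: no adjacent rise > 20% of the larger-later reward; last point below the first by ≥ 10% of it. Both criteria toggleable. |
| `famdelay.discounting_metrics` | Ordinal (rank-spaced) AUC in [0, 1]; delay-weighted AUC provided for contrast. |
| `famdelay.anthropometrics` | BMI, percent over reference-median BMI (age-20 proxy row for adults), LMS z-scores; generic over a user-supplied sex/age LMS table. |
| `famdelay.scarcity_covariates` | Income banding at median ± 1 SD, Medicaid dichotomy, minority indicator, male=1/female=2 sex coding, closed-vocabulary validation. |
| `famdelay.association_models` | Pearson / point-biserial screens, stacked parent–child random-intercept models with predictor×member interaction (fast profiled-REML solver, cross-validated against statsmodels `MixedLM`), Benjamini–Hochberg FDR. |
| `famdelay.synthetic_cohort` | Parent–child dyad generator with latent discount rates linked to a scarcity composite for parents (not children by default), mechanistic non-systematic responding via high choice noise, and retained latent truth for parameter recovery. |
| `famdelay.pipeline` / `famdelay.cli` | End-to-end orchestration and the `famdelay` command. |

## CLI

```bash
# full synthetic run: cohort -> choice log -> scoring -> QC -> AUC ->
# covariates -> descriptives + correlation/interaction tables + model dumps
famdelay run-all --seed 1 --out out/

# stage by stage
famdelay simulate --seed 1 --out sim/
famdelay score --choices sim/choices.csv --out profiles.csv
famdelay qc --profiles profiles.csv --out qc.csv
famdelay analyze --analysis out/analysis.csv --out tables/

# supplied data instead of the generator
famdelay run-all --mode data --config config.yaml --out out/
```

`config.yaml` is a plain key/value file; any subset of keys may be given:

```yaml
seed: 1
task: {llr_amount: 100.0, delays: [1, 7, 30, 182, 365], trials_per_delay: 6}
synthetic: {n_families: 452, gamma1_parent: 0.5, gamma1_child: 0.0}
predictors: [bmi, pct_over_median, medicaid, education_years, income,
             minority, family_size, age, sex_code]
fdr_q: 0.10
choices_csv: data/choices.csv        # data mode only
demographics_csv: data/demo.csv      # data mode only
reference_csv: data/lms.csv          # optional LMS reference table
```

Every run writes a `manifest.json` binding outputs to the config, seed and
input digests; identical config + seed reproduces the output tree
byte-for-byte.

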