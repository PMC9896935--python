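# bioage

Biological age (BA) is an indicator of accumulated physiological
deterioration, expressed in years on the chronological-age (CA) scale and
computed from a panel of biomarkers. `bioage` implements five BA
estimators and the mortality models used to judge them, for
epidemiologists and demographers working with cohort data (baseline age,
biomarkers, follow-up duration, death indicator):

* **MLR** — fitted values of an OLS regression of CA on the markers;
* **PCA** — first principal component of the z-scored markers, mapped to
  age units by matching the mean and SD of CA;
* **KD** — the Klemera–Doubal two-step estimator: per-marker regressions
  `x_j = q_j + k_j·CA`, combined as
  `BA = [Σ_j (x_j − q_j)k_j/s_j² + CA/s²_BA] / [Σ_j (k_j/s_j)² + 1/s²_BA]`;
* **OF** (outcome-free) — a one-factor structural equation model
  `x_j = ν_j + λ_j·BA + ε_j`, `BA = b·g(CA) + ζ` with `g` the identity or
  the log, whose factor scores FS(BA) are regressed against CA (or ln CA)
  to put them on the age scale;
* **OD** (outcome-dependent) — BA anchored on mortality: the age at which
  a null Gompertz hazard equals the augmented hazard at the subject's
  actual age and factor score,
  `BA = [ln(k_a/k_n) + β_a·CA + γ·FS]/β_n`.

Around the estimators sit a constrained Gompertz proportional-hazards
engine (`μ(t) = k·exp(β·CA_t0)·exp(β·t)·exp(φ·ΔBA_t0)`, maximum
likelihood with right censoring), mortality-rate doubling times
`ln(2)/β`, life expectancy at 65 under ΔBA scenarios, AUC by specificity
band, ΔBA disparity regressions, and a synthetic-cohort simulator with a
known latent-factor truth so every stage is testable without external
data.

## Worked example

```python
import bioage as ba

cfg = ba.RunConfig(outdir="demo", truth=ba.default_truth(seed=20220726),
                   seed=20220726)
arts = ba.run_pipeline(cfg)   # simulate -> filter -> SEM -> BA -> hazards

null = arts["hazard_fits"]["null"]
aug = arts["hazard_fits"]["augmented-linear"]
print(null.beta, ba.doubling_time(null.beta))   # 0.0998, 6.9
print(aug.beta, ba.doubling_time(aug.beta))     # 0.0780, 8.9
for est in arts["estimates"]:
    print(est.method, ba.ba_ca_regression(est, arts["cohort"]).slope)
```

On the 5,000-subject reference simulation this prints a null Gompertz
slope of 0.0998 (doubling time 6.9 y) that drops to 0.0780 (8.9 y) once
factor scores enter the hazard — the share of mortality acceleration
attributable to the latent deterioration the markers measure. The
BA-on-CA slopes line up as the methods' structure dictates: MLR 0.46,
PCA 0.68, OF 0.56 (all < 1, attenuated by marker noise), KD exactly 1.00
(an in-sample identity of the estimator), and OD 1.57 — the only
estimator exceeding 1, because it also absorbs the age gradient of
mortality risk. The ΔBA hazard models rank the same way the estimators'
information content suggests: the OD model attains the lowest AIC
(18,710 vs 21,318 for MLR) and the largest ΔBA effect (φ = 0.108, a
hazard ratio of exp(0.108) ≈ 1.11 per year of excess biological age).

The same workflow runs from the shell:

```bash
bioage run --outdir demo --seed 20220726
bioage simulate --out cohort.csv --seed 1
bioage estimate-ba cohort.csv --config cols.yaml --method kd --out ba.csv
```

Real cohort files (CSV/TSV or Stata DTA) are read through a
`ColumnConfig` mapping file columns onto roles; eligibility filtering
(age window 30–75, complete cases, recoding of deaths from causes
unrelated to aging as censored) is applied before any estimation.

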