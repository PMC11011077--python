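# gbmsize

Tumour size and overall survival in glioblastoma: synthetic cohorts,
Cox proportional-hazards models, and bootstrap resampling power studies.

## The problem

Glioblastoma (GBM) studies disagree about whether pre-operative tumour
size — maximum core diameter (cm), core volume (CV, enhancing +
necrotic tumour, cm³), or whole volume (WV, core + peritumoural
oedema, cm³) — predicts overall survival (OS). Much of the
disagreement plausibly comes from methodology rather than biology:
cohort sizes ranging from a few dozen to tens of thousands, and raw
versus log-transformed entry of skewed volume measures into Cox models.

`gbmsize` is a toolkit for studying exactly that question. It provides:

- **A synthetic-cohort generator** whose packaged `paper_like`
  configuration reproduces the summary statistics of a published
  279-patient institutional GBM cohort (median OS 12 months, 236/279
  deaths, median diameter 4.4 cm, CV 28.1 cm³, WV 103.3 cm³, 39%
  female, four-level surgery and three-level adjuvant-oncology mixes,
  MGMT methylation with 21/279 unknown), with correlated size variables
  (Gaussian copula), a Weibull proportional-hazards outcome model and
  uniform censoring. Patient-level data of this kind are confidential,
  so the generator is the reproducible stand-in with a known truth.
- **Cox modelling** of one size variable at a time — univariable or
  adjusted for age, sex, surgery, oncology protocol and MGMT status,
  raw or log-transformed, with hazard ratios, Wald tests, Harrell's C,
  and penalised-spline (P-spline) checks for non-linearity.
- **The resampling experiment**: bootstrap the cohort at sample sizes
  50–279, refit the chosen Cox model in each of R repetitions, and
  report the percentage of resamples in which tumour size is
  significant — an empirical picture of how sample size and
  transformation change the chance of "finding" a prognostic effect —
  plus Kolmogorov–Smirnov comparisons of the p-value distributions.

The core model throughout is the Cox proportional-hazards model
`h(t | x) = h0(t) · exp(x'β)` fitted by maximising the Efron partial
likelihood; the generator simulates from the same model family
(`T = scale · (−ln U / e^lp)^{1/shape}`), so every analysis can be
validated against known parameters. See `docs/methods.md` for the full
model description, calibration and caveats.

## Worked example

```python
import gbmsize as g

cohort = g.generate_cohort(g.paper_like_config(seed=1))
s = g.summarize_cohort(cohort)
# events: 234   KM median OS: 11.3 months (95% CI 9.0-13.3)

res = g.SizeCoxModel(cohort, size="wv", transform="log",
                     adjust=["surgery"]).fit()
print(res.summary())
```

```text
                          coef      se      hr  hr_ci_lo  hr_ci_hi       p
term
log(wv)                 0.2291  0.0750  1.2575    1.0856    1.4566  0.0023
surgery_resection_100  -0.3393  0.1980  0.7123    0.4832    1.0500  0.0866
surgery_resection_ge90  0.1269  0.1763  1.1353    0.8036    1.6039  0.4715
surgery_resection_lt90 -0.0128  0.1798  0.9873    0.6940    1.4046  0.9434
```

Doubling of whole volume multiplies the hazard by `1.26^(ln2/1) ≈ 1.17`
(HR 1.26 per ln-cm³; Wald p = 0.0023, C = 0.57, n = 279) after
adjusting for extent of resection — the generator's true log-WV effect
is 0.226 per ln-cm³, so the fit recovers it within one standard error.

The resampling study on the same cohort:

```python
study = g.ResamplingStudy(cohort, sample_sizes=(50, 100, 200, 279),
                          repetitions=2000, master_seed=0,
                          model_specs=(g.ModelSpec("wv"),
                                       g.ModelSpec("wv", "log")))
print(study.fit().percent_table(0.05))
```

```text
               wv  log(wv)
sample_size
50           35.2     26.6
100          59.0     49.6
200          87.4     80.1
279          95.1     91.5
```

Each cell is the percentage of bootstrap resamples of that size in
which the size coefficient's Wald p < 0.05: a study of 50 patients
drawn from this population would have detected the whole-volume effect
in only a quarter to a third of realisations. The p-value distributions
at n = 50 vs n = 279 differ strongly (two-sided KS D = 0.688,
p < 1e-100). Note these percentages condition on the realised cohort;
`gbmsize.resampling.run_unconditional_power` and
`run_null_calibration` give the procedure-level power and type-I-error
counterparts (see `docs/methods.md`).

## Command line

```sh
gbmsize simulate --seed 1 --out cohort.csv           # cohort + summary JSON
gbmsize fit cohort.csv --out-dir fits/               # 42-model suite + splines
gbmsize resample cohort.csv -R 10000 --seed 1 --out-dir resampling/
gbmsize report resampling/                           # render a run report
```

Every command writes a `manifest.json` with the seed, a config snapshot
and SHA-256 checksums of all outputs. Cohort CSVs use the fixed column
schema `age,sex,surgery,oncology,mgmt,diameter_cm,cv_cm3,wv_cm3,
time_months,event` (`mgmt` uses the literal `unknown`); any
user-supplied survival table in that schema can be fed to `fit` and
`resample`.

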