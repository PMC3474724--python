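# rpsurv

Flexible parametric survival modelling versus Cox proportional hazards for
short-horizon prognosis, built around the hospice setting: predicting how
long a patient admitted to hospice care will survive from their Palliative
Performance Scale (PPS) stratum at admission.

It is aimed at biostatisticians and clinical researchers validating
prognostic survival models on cohorts with heavily tied, right-skewed,
fully observed survival times — the regime where the Cox model's
nonparametric "choppy" baseline and its proportional-hazards assumption
both become liabilities.

## The models

The Cox proportional hazards (CPH) model writes `S(t; x) = S0(t)^exp(xβ)`,
estimating `β` by partial likelihood (Breslow tie handling here) and the
baseline `S0` by the Breslow step estimator.

The flexible parametric (Royston–Parmar, RP) alternative models a link
transform of survival as a restricted cubic spline in log time plus a
linear predictor:

```
g(S(t; x)) = s(ln t; γ) + xβ
```

with `g` from one of three families — `g(s) = ln(−ln s)` (proportional
hazards), `g(s) = ln(1/s − 1)` (proportional odds), `g(s) = −Φ⁻¹(s)`
(probit) — and `s(·; γ)` a restricted cubic spline with `m` interior knots
at equally spaced centiles of the log event times. With `m = 0` these
collapse to the Weibull, log-logistic and log-normal models, which the test
suite uses as exact oracles. Scale and knot count are chosen by the joint
ranking of AIC, BIC and the explained-variation statistic `R²_D`
(prognostic-index rankits scaled by `κ = √(8/π)`, refitted as a single
regressor; `R² = (D²/κ²)/(σ² + D²/κ²)`).

Model performance is compared by Brier score, scaled Brier score
(`100·(1 − BS/Brier_max)`, `Brier_max = p̄(1−p̄)`), discrimination (Yates)
slope, and `R²_D`, both naively (fit and evaluate on the whole cohort) and
by stratified 10-fold cross-validation repeated 20 times, with calibration
against Kaplan–Meier over the first 15 days.

Because the motivating patient records are not public, the package ships a
synthetic-cohort generator emulating their structure: five PPS strata with
weights 188/125/123/96/44 out of 576, log-normal integer-day survival with
stratum medians 3/5/7/14/18 days (overall ≈ 6), no censoring, and unequal
log-scales across strata so the proportional-hazards assumption genuinely
fails.

## Worked example

```python
import rpsurv as rs

report = rs.run_full_analysis(generator_seed=1, cv_seed=2, k=10, repeats=20)
print(report.summary_text())
```

prints

```
subjects: 576, events: 576
log-rank: chi2=139.80 df=4 p=3.11e-29
Schoenfeld PH test: chi2=79.74 df=4 p=1.98e-16
selected scale/knots: family=probit, m=1
naive R2: RP=0.289 Cox=0.153
cross-validated R2: RP=0.173 Cox=0.086
fraction of horizons with RP scaled Brier above Cox (CV): 0.52
```

Reading this: the five PPS strata have clearly separated survival curves
(log-rank), the proportional-hazards assumption is violated (Schoenfeld
global test), the selection grid picks the probit scale with one interior
knot, and the flexible model explains roughly twice the variation the Cox
model does, both naively and under cross-validation, while its scaled Brier
score beats Cox on a (slim) majority of the first 100 days.

The same pipeline is scriptable from the shell:

```
rpsurv simulate --seed 1 --out cohort.csv
rpsurv fit --model rp --family probit --knots 1 --cohort cohort.csv --out fit.json
rpsurv validate --cohort cohort.csv --k 10 --repeats 20 --seed 7 --out run/
```

`validate` writes the selection grid, Kaplan–Meier curves, Cox baseline,
calibration table, difference curves, fit JSONs and a YAML manifest into
`run/`.

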