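# specocc — one-class screening of adulterated powder spectra

`specocc` implements non-targeted adulteration screening for FT-IR / FT-NIR
spectra of powdered foods: instead of training a classifier on known
adulterants, it models the *authentic* class only (here: pure almond powder
from two varieties) and flags any sample that leaves the class acceptance
region — so unknown adulterants are detectable by construction.  It is
written for chemometricians and food-authentication labs who want the two
standard one-class classifiers behind a common data model, plus a synthetic
study generator that makes every stage testable without instrument data.

## Methods at a glance

**DD-SIMCA** (data-driven SIMCA).  PCA with k components on the centered
calibration matrix reduces each sample to a score distance
h = Σₐ t²ₐ/λₐ and an orthogonal distance v = ‖x − x̂‖².  Both are modeled
as scaled chi-squares with data-estimated degrees of freedom
(N = 2·mean²/var), so the total distance

    c = N_h·h/h0 + N_v·v/v0   ~   χ²(N_h + N_v)

yields an acceptance boundary at significance α and, with the per-dataset
adjustment γ_adj = 1 − (1−γ)^(1/n), an outlier boundary at γ.  Training
samples between the boundaries are *extreme*; the extreme plot compares
their observed counts with n·α across significance levels.

**OCPLS** (one-class PLS).  PLS1 regresses a constant unit response y ≡ 1
on the calibration spectra (uncentered columns — centering would annihilate
X′y).  A sample is judged by Hotelling's T² of its mean-centered scores,
bounded by A(n²−1)/(n(n−A))·F₁₋α(A, n−A), and by the absolute centered
residual ACR = |ŷ − mean(ŷ_train)|, bounded by z₁₋α/₂·sd(residuals).  The
two limits split the diagnostic plane into regular / good-leverage /
response-outlier / bad-leverage quadrants; only regular samples are
accepted.

Preprocessing (SNV, MSC, normalization, Savitzky–Golay smoothing and
derivatives), confusion metrics (sensitivity / specificity / total
accuracy with two naming conventions), Monte-Carlo cross-validation for
latent-variable selection, and CSV/JSON/YAML interchange round out the
package.  See `docs/methods.md` for the full model description and design
rationale.

## Worked example

```python
from specocc import (RunConfig, run_study)

report = run_study(RunConfig(classifier="ddsimca", preset="separable",
                             n_components=4, outdir="results/demo", seed=1))
print(report.metrics_frame().to_string(index=False))
```

prints

```
              group  sensitivity_pct sensitivity_counts  specificity_pct specificity_counts  accuracy_pct
validation1_apricot             95.0             95/100            100.0              10/10         95.45
validation2_apricot            100.0              40/40             90.0               9/10         98.00
 validation1_peanut             93.0             93/100            100.0              10/10         93.63
 validation2_peanut            100.0              40/40             90.0               9/10         98.00
```

One row per validation set: `sensitivity` is the fraction of adulterated
samples rejected (e.g. 95/100 — the five misses are all 5%-adulteration
replicates; every level ≥ 10% is rejected completely), `specificity` the
fraction of pure samples accepted, and `accuracy` the overall correct
fraction.  The run directory receives the fitted model (`model.json`),
per-sample distance tables, per-level detection rates, acceptance-plot
data and a JSON report.  The same run with `classifier="ocpls"` or
`preset="hard"` reproduces the other study arms; the numbered scripts in
`analysis/` execute the whole study (data generation → component selection
→ both screening runs → summary table) and write their tables under
`results/`.

A CLI mirrors the library:

```bash
specocc generate --preset separable --seed 1 --outdir data
specocc fit --train data/calibration_apricot_separable.csv --classifier ddsimca --model-out model.json
specocc classify --model model.json --data data/validation1_apricot_separable.csv --out cls.csv
specocc report --data data/validation1_apricot_separable.csv --classification cls.csv
specocc run --preset hard --classifier ocpls --seed 1 --outdir results/run
```

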