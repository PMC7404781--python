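# Methods

This note documents the models implemented in `specocc`, the reasoning
behind the open design choices, what the synthetic study generator does and
does not emulate, and the numerical conventions that make the test suite
exact.

## One-class screening

Non-targeted adulteration screening asks a one-class question: does a new
spectrum belong to the authentic class, yes or no?  Only the authentic
class is modeled; anything outside its acceptance region — including
adulterants never seen during calibration — is flagged.  Both classifiers
here follow that scheme and differ only in how they compress a spectrum
into decision statistics.

### DD-SIMCA

PCA on the column-centered calibration matrix X (n samples × p
wavenumbers) with k components gives scores t and loadings P.  Each sample
is reduced to

* score distance `h_i = Σ_{a≤k} t_ia² / λ_a`, with `λ_a` the training score
  variance (n−1 denominator).  This makes `Σ_i h_i = k(n−1)` an exact
  identity (mean h = k(n−1)/n), which the tests assert to 1e−8.
* orthogonal distance `v_i = ‖x_i − x̂_i‖²`, the squared residual outside
  the model plane.

Both distances are treated as scaled chi-squares.  The scaling centers are
the training means (`h0`, `v0`) and the degrees of freedom come from the
classical method of moments, `N = 2·mean²/var` (sample variance, n−1
denominator).  A quantile-matching alternative (`dof_method="robust"`,
solving q75/q50 of χ²(N) for N and rescaling by the median) is provided for
contaminated calibrations.  An optional integer-rounding mode clips the
estimated DoF to [1, 250]; the default keeps positive reals, since
chi-square quantiles accept them.

The total distance `c = N_h·h/h0 + N_v·v/v0 ~ χ²(N_h+N_v)` defines

* the acceptance boundary `c_crit = χ²₁₋α(N_h+N_v)`;
* the outlier boundary `c_out = χ²₁₋γadj(N_h+N_v)` with
  `γ_adj = 1 − (1−γ)^{1/n}`, reading γ as a per-dataset outlier error.

Training samples with `c ≤ c_crit` are regular, up to `c_out` extreme,
beyond it outliers.  New samples are judged by acceptance only (`c ≤
c_crit`, ties accepted — the region is closed); the extreme/outlier split
is diagnostic.  The extreme plot evaluates, over a log-spaced grid of
significance levels, the observed count of training samples beyond each
chi-square threshold against the expectation n·α with a 95% binomial
envelope.

Degenerate inputs: if the centered calibration matrix has numerical rank
below the requested k, the fit proceeds at the effective rank and records
the request (`k_requested`).  If every training residual is zero (data lie
exactly in the model plane), the fit flags `degenerate_v` and drops the
v-term from c — the orthogonal distance carries no information there.
Zero *variance* with nonzero mean of either distance makes the moments
estimator undefined and raises an error pointing at the robust method.

Finite-sample behaviour worth knowing: with k equal to the data rank the
score distance is the exact sample Mahalanobis distance, whose
new-observation law is `k(n²−1)/(n(n−k))·F(k, n−k)` — heavier-tailed than
any chi-square.  At n = 200, k = 5, α = 0.05 this alone puts the true
type-I error near 0.061, and moment-estimation noise adds roughly another
0.01; the calibration tests in `tests/test_acceptance.py` measure exactly
this (≈ 0.070 over 20 replicates).  The effect shrinks like 1/n and is an
inherent property of judging an F-distributed statistic against a
chi-square boundary, not an implementation artifact.

PC-count selection cross-validates the target-class acceptance rate over a
candidate grid and picks the smallest k within one binomial standard error
of the maximum.  On well-specified data this curve is flat — the
chi-square machinery self-calibrates at every k, because for k below the
true rank the omitted directions enter v, whose scale and DoF are estimated
from the same distribution the held-out samples follow — so the rule
deliberately prefers small k; the curve itself is the diagnostic worth
inspecting, and the study runs fix k = 4 for comparability.

### OCPLS

PLS1 regresses the constant unit response y ≡ 1 on the calibration
spectra.  The spectra are **not** column-centered for this regression:
with centered columns the first weight vector X′y would be exactly zero.
(The mixture-closure argument explains why the regression is informative at
all: for spectra that are mass-fraction mixtures, component fractions sum
to one, so a coefficient vector with unit projection on every authentic
component reproduces y = 1 exactly, and foreign components break the
prediction in proportion to their fraction.)  Centering instead enters
through the decision statistics, both referenced to the training center:

* `T²_i = Σ_a ((t_ia − t̄_a)/s_a)²` on the A latent scores, with limit
  `A(n²−1)/(n(n−A))·F₁₋α(A, n−A)` — the standard new-observation Hotelling
  bound;
* `ACR_i = |ŷ_i − mean(ŷ_train)|` with the two-sided normal-theory limit
  `z₁₋α/₂·sd(train residuals)`.

Acceptance requires both statistics within their limits (ties accepted);
the limits partition the plane into the four classical quadrants.  Note
the combined nominal type-I level of two α-level tests is ≈ 1−(1−α)², so
OCPLS rejects pure samples at roughly twice the per-statistic α; the
calibration tests therefore compare the observed rejection with the
empirical combined level rather than with α itself.

Latent-variable count: Monte-Carlo cross-validation (default 100 random
splits, 20% holdout) refits the model per split and pools held-out
prediction residuals; the reported curve is the residual standard deviation
per LV count and the chosen A is the smallest within 5% (relative) of the
minimum.  MCCV curves are flat-bottomed, so a pure argmin is noise-driven;
the tolerance is the parsimony rule, and `chosen_A` is overridable
everywhere.  PLS extraction stops early if X is deflated to numerical zero
(exact low rank); requested counts beyond that reuse the final model, which
makes the residual curve exactly flat beyond the rank.

An optional one-pass outlier refit (fit → drop samples outside the limits →
refit once) mirrors the usual calibration-cleaning practice; it is ON in
the reproduction pipeline and OFF in the library API defaults.

## Preprocessing

SNV standardizes each spectrum to mean 0, sd 1 (n−1 denominator — the
dominant chemometrics convention, and the one that makes the unit tests
exact).  MSC regresses each spectrum on a reference (calibration mean by
default) and inverts the fitted affine map.  Normalization divides by the
row maximum or total absolute area.  Savitzky–Golay fits a local
polynomial of degree `polyorder` over a centered odd `window`; derivatives
are scaled by the physical axis step (units per cm⁻¹) with the sign
following the axis direction, so results are grid- and
direction-independent.  Edges use one-sided truncated-window fits,
minimally widened inward when fewer than `polyorder+1` points remain, so
the output keeps the full axis length.  "Smoothing" is Savitzky–Golay with
derivative order 0.  The default pipeline pretreatment is SNV — the one
pretreatment explicitly tied to the modeling workflow — with all others
available via `PreprocessConfig`.

## Metrics

Sensitivity and specificity are group-wise correct-classification rates;
accuracy is the overall correct fraction and is convention-invariant.  The
default naming convention scores adulterated samples as the positive class
(what screening results tables usually print); the formula-sheet
convention with pure as positive is available and simply swaps the two
names.  Reported percentages are truncated — not rounded — at two
decimals (90.9090…% prints as 90.90), matching the convention of the
results tables this package's report layer mirrors; raw float rates are
always available on `ConfusionSummary`.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes,
not the physics of diffuse reflectance:

* **Endmembers**: Gaussian bands on a uniform grid (MIR 650–4000 cm⁻¹ step
  4, 838 points; NIR 4000–10000 cm⁻¹ step 8, 751 points).  Band placement
  follows the usual organic-powder landscape (carbohydrate C–O ≈ 1045,
  CH bends 1230–1460, amides 1530–1650, ester carbonyl ≈ 1745, CH
  stretches 2855/2925, broad O–H ≈ 3300 cm⁻¹).  The two adulterants share
  one band table and differ by small amplitude shifts, while almond
  differs in the fingerprint region — the similarity structure the
  screening problem needs.
* **Two varieties**: a fixed multiplicative perturbation of the almond
  band amplitudes, so one pooled calibration must cover both.
* **Within-class variability**: each sample draws one multiplicative
  factor per constituent group (lipid, protein, carbohydrate, moisture),
  giving the authentic class a few strong, stable directions — the
  low-rank structure PCA/PLS models expect of real powder lots, and the
  reason k ≈ 4 is a sensible model size.
* **Artifacts**: multiplicative scatter `b ~ 1+N(0,σ_b)`, additive offset
  and linear drift, a white-noise floor, and a spectrally smooth noise
  component (white noise convolved with a unit-L2 Gaussian kernel,
  correlation length ≈ 120 cm⁻¹).  The smooth component is deliberate:
  residual variation in scan-averaged FT spectra is correlated baseline
  wiggle with few effective dimensions, and with i.i.d. channel noise
  instead, the orthogonal distance would have hundreds of effective DoF
  and the unavoidable O(k/n) train-vs-test residual inflation would
  swamp the chi-square acceptance at n = 100.  Scalar artifact and
  composition factors are drawn from normals truncated at ±2.2 sd —
  controlled processes have bounded variation, and unbounded tails would
  place arbitrarily extreme samples inside the "pure" class.
* **Study design**: 100 pure calibration samples (50 per variety);
  validation set 1 with 10 pure + 5–50% in 5% steps × 10 replicates
  (variety 1); validation set 2 with 10 pure + 7/15/22/30% × 10 (variety
  2); each generated for apricot and for peanut over a shared calibration.
  The pure count per validation set is a parameter (`n_pure_val`).

Two presets fix the conditions once: `separable` (full adulterant
contrast; every level ≥ 15% — in practice ≥ 10% — is rejected completely)
and `hard` (the adulterant endmember pulled 30% of the way toward almond,
placing 5–7% adulteration on the detection transition while ≥ 15% stays
fully detected).  Contrast, not noise, realizes the hard preset because
detection difficulty and type-I calibration would otherwise be coupled.

What passing tests on this generator do **not** show: robustness to
particle-size radiative-transfer effects, water-vapor/CO₂ interference
bands, wavelength miscalibration, nonlinear detector response, or
between-session drift — none of which are modeled.  Mixtures are exactly
linear in mass fraction; real reflectance mixing is only approximately so.

## Numerical conventions

* Variances use the n−1 denominator throughout (SNV, eigenvalues, score
  variances, residual sd, moments estimator).
* Ties at any decision limit count as accepted (closed regions).
* Axis direction (ascending or descending cm⁻¹) is preserved on load and
  all numeric code is direction-agnostic; region selection is closed on
  both ends.
* CSV round trips are exact: floats are written with 17 significant
  digits and parsed with round-trip precision.
* Classification requires an exact axis match with the training grid — no
  silent interpolation.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical config + seed reproduces
  byte-identical outputs.

## Known limitations

* The chi-square acceptance is asymptotic; at calibration sizes around
  100–200 the true type-I error exceeds α by a factor ≈ 1.4–2 at α = 0.01
  (F-tail versus chi-square, plus moment-estimation noise).  The tests
  quantify this rather than hide it.
* OCPLS acceptance combines two tests, so its nominal level is
  ≈ 1−(1−α)², and the normal-theory ACR limit is approximate when the
  class has cluster structure (two varieties).
* The MCCV and PC-selection parsimony rules are documented choices, not
  canonical; both expose their full curves and accept overrides.
* One classifier per run; the pipeline compares runs rather than fusing
  decisions.
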