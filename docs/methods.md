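# Methods

## Model

For one foliar trait `y` (n samples) and a reflectance matrix `X`
(n × p wavebands, 1-nm grid trimmed to 450–2,400 nm by default), the
package fits partial least squares regression with de Jong's SIMPLS
algorithm. `X` and `y` are mean-centered and deliberately *not* variance
scaled or otherwise transformed: reflectance is already on a common [0, 1]
scale, and leaving the data untransformed keeps the regression vector
interpretable in reflectance units. Each component is obtained from the
deflated cross-product `s = X'y`: the weight is `s` normalized through its
score `t = Xs`, the X/y loadings are `p = X't`, `q = y't`, and `s` is then
projected onto the orthogonal complement of the accumulated loading basis.
Scores are orthonormal by construction; the regression vector is `B = Rq`
and the per-component explained response sum of squares is `SS_a = q_a²`
(unit-norm scores). One fit at `A` components yields every sub-model
`1..A`, which the cross-validation harness exploits (`predict_components`).

Assumptions: a single response per model (traits are modeled
independently); linearity between reflectance and trait; no missing values
inside a fitted matrix (missing trait cells drop the sample for that trait
only, maximizing usable n per model).

## Cross-validation protocol and metrics

Each of `n_iterations` (default 1,000; reduced in examples and tests)
iterations draws a random calibration set (`calibration_fraction`, default
0.8) and a validation holdout. Within the calibration set, k-fold
cross-validation (default fivefold) produces out-of-fold predictions per
component count — these define the *calibration* PRESS/RMSE/R²/RPD. A model
fit on the whole calibration set and evaluated on the holdout defines the
*validation* metrics. The published protocol states both the 80/20 holdout
and an inner fivefold step without saying which feeds which statistic; this
assignment (inner CV → calibration columns, holdout → validation columns)
is the reading that keeps both sets of metrics honestly out-of-sample.
Metrics are averaged over iterations into one curve per trait, and
selection operates on the iteration-mean validation PRESS (not on
per-iteration selections with voting).

Conventions:

- `PRESS = Σ(obs − pred)²`, `RMSE = sqrt(PRESS/n)`;
- normalized PRESS divides by the maximum mean PRESS within the same set
  (calibration or validation), so the worst component count scores 1;
- `RMSE%` divides RMSE by the *full-dataset* trait mean;
- `RPD = SD(obs)/RMSE` uses the sample SD (ddof = 1) of the evaluated
  subset. Under the matched convention (same set, n-denominator SD
  consistent with the total sum of squares) the identity
  `RPD = 1/sqrt(1 − R²)` holds exactly and is exercised in the tests;
  the curve-level values use the sample-SD convention, so the identity is
  approximate there.
- RPD reliability classes: excellent above 2.0, fair within [1.40, 2.00],
  non-reliable below 1.40.

## Component selection

- **press_min**: argmin of mean validation PRESS, ties toward fewer
  components. A minimum sitting at `max_components` triggers an overfit
  warning (the informative region may not have been explored).
- **press_adj** (backward penalty): threshold τ = `penalty_percent`/100
  (default 1.5%) of the *maximum* mean validation PRESS, computed on the
  raw (unnormalized) curve — the choice is invariant to the shared
  normalizer. Starting from the press_min choice, components are removed
  one at a time while each removal's PRESS increase stays ≤ τ; the walk
  stops at the first removal that would cost more, or at one component.
  The alternative reading of "until the difference falls below a
  threshold" (stop when steps become cheap) would always walk past the
  informative region, so the cost-bounded reading is used.
- **voet**: the press_min model is the reference. For each smaller count,
  per-sample validation squared residuals (retained across all iterations)
  are paired with the reference's and the mean difference is tested with a
  two-sided sign-flip randomization test (default 1,999 permutations,
  add-one correction). Scanning upward from one component, the first
  candidate with p ≥ α (default 0.01) — i.e. not significantly worse — is
  chosen; otherwise the reference stands. The mean paired difference with
  sign-flip randomization is the two-sided equivalent of the squared
  standardized (T²) form of the statistic; the permutation count is a
  package choice since only the significance level is standard.

Both reduced rules can never exceed the press_min choice; this ordering is
asserted property-style in the tests.

## VIP scores and coefficient profiles

`VIP_j = sqrt(p · Σ_a SS_a (r_ja/‖r_a‖)² / Σ_a SS_a)` over the SIMPLS
weight vectors; mean squared VIP is exactly 1, threshold 1 by convention.
The weight-based variant is used (the rotated-weight variant differs only
when weights are far from orthogonal). Top-peak extraction takes strict
local maxima above the threshold, merges peaks closer than the reporting
window (default ±25 nm, clipped to the grid) keeping the higher, and
returns up to k (default 3) windows ordered by score. Standardized
coefficient profiles rescale `B` over wavebands to mean 0, SD 1
(population SD) for cross-trait display; signs and peak locations are
preserved.

## Synthetic data generator

The generator emulates what matters statistically about fresh-leaf VSWIR
datasets: a smooth base spectrum with the canonical green-foliage features
(green maximum near 550 nm, chlorophyll red absorption, red edge near
700–750 nm, NIR plateau, water-band depressions near 1,350–1,420 and
1,680–1,700 nm plus the deep ~1,930 nm band, clipped to [0.01, 0.95]);
`latent_rank` independent standard-normal chemical factors, each modulating
a Gaussian absorption feature `depth·exp(−(λ−c)²/2w²)` (smooth, local, and
rank-controllable, in the spirit of pigment/water bands); traits that are
exact affine functions of the factors plus Gaussian noise expressed as a
fraction of the trait's noiseless SD (default 0.05); and iid spectral noise
(default 0.002 reflectance units) with final clipping to [0, 1].

Defaults: 360 samples on a 350–2,500 nm, 1-nm grid (the instrument-like
sweep; tests and the acceptance runs use a 10-nm step as a desk-scale
choice — the latent structure is unaffected); three factors at 560, 1,200,
and 2,100 nm, placed away from the deepest base-spectrum troughs so the
physical clip essentially never binds; five traits with wheat-like offsets
and mixed-sign loadings giving CVs of roughly 5–25%, the lower portion of
the ~5–60% CV range reported for field wheat — Gaussian factor scores
cannot push CVs much higher while keeping concentrations strictly
positive. Three traits load on exactly one factor each, which is what the
planted-correlation and planted-VIP tests key on.

`planted_rank_config` builds rank-recovery scenarios: one trait loading
equally on k factors whose absorption features are spread over 800–2,200 nm
with *geometrically spaced* depths (ratio 1.45, deepest at the
highest-reflectance center). The spacing is essential, not cosmetic: with
equal depths and equal loadings the response collapses onto a single
informative spectral direction (the Krylov space of `(X'X, X'y)` is
one-dimensional) and one component predicts perfectly, so "the planted
rank" would be ill-defined. Distinct factor variances make the informative
dimension genuinely k.

What the generator does **not** emulate: radiative-transfer physics
(no PROSPECT-style leaf model), per-detector instrument noise, splice
artifacts, genotype/stage covariate structure, or skewed/heteroscedastic
trait distributions. Passing tests therefore demonstrate that the
algorithms recover known low-rank linear structure under realistic
collinearity and noise — not that any particular field dataset will reach a
given R².

## Numerical choices

- Deflation uses modified Gram–Schmidt with one re-orthogonalization pass
  against the accumulated loading basis; stable at ~30 components on
  ~2,000 collinear wavebands.
- If a component's cross-product norm falls below 1e-12 of its initial
  value (response exhausted), fitting stops early, warns, and reports the
  achieved component count; the CV harness pads sub-model predictions by
  repeating the last achieved column (additional components add nothing).
- The component cap is lowered (with a warning) to
  `min(max_components, smallest fold training size − 1, p)`.
- Pearson significance uses the exact t transform with n − 2 degrees of
  freedom; |r| = 1 maps to p = 0. No multiple-testing correction is applied
  across wavebands or trait pairs — masks are at the raw α (default 0.01),
  matching standard practice for these displays.
- Descriptive SD is the sample (n − 1) SD; CV = SD/mean × 100. For the
  published wheat reference table both SD conventions reproduce the listed
  CVs at two decimals for most traits, so the table cannot arbitrate; the
  sample SD is standard for descriptive statistics.
- PRESS-minimum ties break toward fewer components. Trimming uses a closed
  interval (450 and 2,400 nm retained).
- Seeding: a master seed spawns one independent substream per CV iteration
  (`numpy` SeedSequence), so results are reproducible and invariant to
  iteration order; the CSV readers parse floats in round-trip mode so
  fixtures survive write/read byte-exactly.
- Trait positivity: file ingestion rejects non-positive trait values;
  in-memory construction only warns, because the generator's Gaussian
  noise could in principle produce one and a hard failure would break the
  exact-affine ground-truth contract.

## Known limitations

- Single-response PLS1 only; no PLS2, kernel, or sparse variants, and no
  nonlinear learners.
- The RPD convention question (which subset's SD the published tables use)
  cannot be resolved from conventions alone; the evaluated-subset sample SD
  is used throughout and documented above.
- Correlation spectra on ~2,000 wavebands at raw α will contain false
  positives by construction; the masks are descriptive, not inferential.
- The randomization test retains per-sample squared residuals across all
  iterations (memory grows as components × iterations × holdout size);
  at the default 1,000 iterations this is ~tens of MB per trait.
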