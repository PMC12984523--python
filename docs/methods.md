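# Methods

## The simulated cohort

The generator emulates a population-based breast-screening sample in
which age drives both of two correlated, imaging-derived surrogates.
Ages follow a normal distribution truncated to the screening range,
sampled by exact inversion: u ~ Uniform(Φ(α), Φ(β)), age = μ + σ·Φ⁻¹(u),
with α = (25−μ)/σ and β = (85−μ)/σ. Inversion is preferred to rejection
sampling because it is exact, vectorizable, and consumes a fixed number
of random draws per patient, which keeps runs bit-reproducible.

Density is a concave quadratic in age whose vertex sits at age 25
(−b/2c = 0.10/0.004), so simulated density declines monotonically over
the screening range — the familiar post-midlife decline. Risk combines a
weak logarithmic age effect with a linear density effect and uses the
*realized* (noisy) density, so the two targets are correlated through
both the age trend and the shared ε₁ noise. `log` is the natural
logarithm, the regression-modelling default. Ages are kept continuous;
nothing in the design requires integer years.

One master seed spawns three independent `numpy` SeedSequence sub-streams
(ages, ε₁, ε₂). Changing one noise SD therefore never perturbs the other
draws — a property the tests assert and the noise-sensitivity analysis
depends on.

Default parameters (all configurable through `SimulationConfig`):

| parameter | default | units | role |
|---|---|---|---|
| n_patients | 1000 | – | cohort size |
| age_mu / age_sigma | 52 / 12 | years | screening-age distribution |
| age_min / age_max | 25 / 85 | years | truncation range |
| dens_intercept, dens_age_coef, dens_age2_coef | 1.8, 0.10, −0.002 | density units | quadratic age trend |
| dens_noise_sd | 0.35 | density units | physiological heterogeneity |
| risk_intercept, risk_logage_coef, risk_density_coef | 12, 0.25, 0.20 | risk units | risk equation |
| risk_noise_sd | 0.25 | risk units | residual risk variation |

What the generator does *not* emulate: imaging noise, acquisition
artifacts, inter-reader variability, confounding (hormonal, genetic,
lifestyle), institutional heterogeneity, or any mapping to clinical
scales. Passing tests therefore demonstrate internal consistency of the
method under a known generative law, not clinical performance.

## Linear baselines and parameter recovery

Model A (density ~ age + risk) and Model B (risk ~ age + density) are
descriptive baselines; the generative-form regressions — density on
(age, age²) and risk on (ln age, density) — are the identification
check: their coefficients and unbiased residual SDs estimate the
configured generative values. Estimation uses ordinary least squares
with an intercept always included; standard errors come from the
unbiased residual variance; p-values are two-sided from the t
distribution with n−p degrees of freedom; the overall F-test is against
the intercept-only model. No multiple-testing correction is applied —
the protocol reports a handful of pre-specified coefficients, not a
screen. Rank-deficient designs raise a dedicated error rather than
falling back to a pseudoinverse, because a silently regularized fit
would invalidate the inference fields.

## Network architectures and training

Both networks consume two standardized features, age and age², and
predict in natural target units so that MAE/MSE read directly on the
density and risk scales. The scaler is fitted on the 80% training split
only; the held-out 20% test split is transformed with training
statistics.

* MLP: Dense(64, ReLU) → Dense(32, ReLU) → linear output.
* Bifurcated: Dense(32, ReLU, L2 λ = 10⁻³) → BatchNorm → Dropout(0.4) →
  Dense(8) shared trunk; density head Dense(8) → linear; risk head
  Dropout(0.3) → linear. Only the trunk Dense(32) carries an activation.

Training: Adam (lr 0.001, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷), batch size
32, per-epoch reshuffling, at most 300 epochs, early stopping on
validation loss with patience 10 and restoration of the best-validation
weights. The validation set is a 20% carve-out of the training split,
disjoint from the test set. The monitored loss is the training objective
(weighted per-output MSE plus the L2 penalty) evaluated in inference
mode. The two heads are weighted equally. Glorot-uniform initialization;
batch-norm momentum 0.99, ε = 10⁻³; inverted dropout. All stochastic
elements (initialization, shuffling, dropout masks, validation carve)
derive from one model seed, kept separate from the data seed.

Two design choices deserve justification:

* **Linear Dense(8) layers.** Dropout ahead of a linear head acts, in
  expectation, as a ridge penalty proportional to Σⱼ wⱼ²·E[zⱼ²]. A
  small-variance target (risk, deviations of SD ≈ 0.22) can only defeat
  that penalty if its signal is spread redundantly across the bottleneck
  units, which divides the penalty by their number. A ReLU bottleneck
  leaves roughly half the units inactive per input and measurably caps
  the achievable noiseless risk accuracy (R² ≈ 0.93–0.98 even with the
  epoch budget tripled); with linear Dense(8) layers the architecture
  reaches R² > 0.99 on both outputs when the noise is switched off. The
  trunk's ReLU layer supplies all the nonlinearity the targets need.
  Even so, the noiseless risk check sits near the dropout-ridge ceiling
  (~0.99–0.997 at best), and is the most delicate property in the suite.
* **Output-bias warm start.** Each linear output's bias is initialized
  at its training-target mean. Adam's per-step displacement is bounded
  by roughly the learning rate, so from a zero bias the risk head
  (target mean ≈ 13) cannot reach its operating point within 300 epochs
  at lr 0.001 — training would end far from convergence with errors the
  size of the target mean offset. The warm start removes that artifact
  while leaving targets in natural units.

## Evaluation protocol

Metrics are per-output MSE, MAE and R², with R² on test data using the
test-set mean in SS_tot (out-of-sample convention). Every metrics report
asserts Jensen's inequality (MAE² ≤ MSE).

The Wilcoxon signed-rank test on paired absolute risk errors drops zero
differences (Wilcoxon's original rule; Pratt's method is not used, and
the report says so), assigns average ranks to ties, and is two-sided.
For up to 12 effective pairs the null distribution is enumerated exactly
by dynamic programming over doubled ranks (integers even with
midranks); larger samples use the normal approximation with the tie
correction Σ(t³−t)/48 and a continuity correction. A non-significant
result is always reported as *absence of evidence for a difference*,
never as evidence of equivalence.

Seed stability retrains the bifurcated network once per model seed on
one fixed cohort and split and reports both the max−min spread and the
SD of test MAE per output — a "±" bound on run-to-run variation can be
read either way, and the spread is the conservative reading.

Noise sensitivity scales both noise *variances* by a factor (SDs by its
square root), regenerates the cohort under the same seeds, retrains and
reports metrics beside the base run; a factor of 1.0 reproduces the base
run exactly.

The response-surface sampler tabulates predictions over an age grid for
inspection and plotting only; grid points outside the training age range
are flagged as extrapolation with a warning. It fits nothing.

Known reference values from the published study this design follows
(performance tables, a Wilcoxon p-value, an external clinical
regression) are embedded in `densrisk.reference` as inert metadata
flagged non-reproducible: their error scale is incompatible with the
stated generative equations, whose irreducible MAE floors are
σ·√(2/π) ≈ 0.279 (density) and 0.199 (risk).

## Problem sizes and numerical choices

Parameter-recovery checks use n = 100,000 cohorts, where coefficient
standard errors are small enough for 3-SE acceptance bands and residual
SDs estimate the noise SDs within 2%. Stability and sensitivity analyses
use the default n = 1000 cohort; the error-floor check evaluates a
trained model on an independent n = 10,000 cohort to shrink the
estimation error of the measured MAE. The monotone noise-degradation
property is averaged over 20 replicate cohorts per variance factor.
CSV output uses 17 significant digits and round-trip float parsing, so
write/read cycles are bit-exact. Degenerate inputs fail loudly:
zero-variance scaler columns, rank-deficient designs, all-zero Wilcoxon
differences and non-finite training losses each raise a dedicated error.

## Limitations

Everything rests on a single, fully specified generative law with
homoscedastic Gaussian noise and one predictor (age); conclusions about
architecture behaviour do not transfer to real imaging cohorts, which is
the point of a feasibility testbed, not a flaw in one. The bifurcated
network's risk head operates at the edge of what its own dropout
regularization permits on a low-variance target; small protocol changes
(dropout rate, bottleneck width) move its accuracy noticeably. Early
stopping with patience 10 on a noisy validation loss can halt before
full convergence on noiseless data; the capacity checks account for this
but real use may warrant a larger patience.
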