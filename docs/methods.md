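# Methods

## Scope and model

The package estimates a scalar soil property (Ni concentration, mg/kg) from
laboratory Vis-NIR reflectance via a fixed four-stage workflow: spectral
preprocessing, a fractional-order derivative (FOD) sweep, an exhaustive
two-band index search against the response, and PLS1 regression on the
selected band combinations. The pipeline proper is deterministic; all
randomness lives in the synthetic data generator and flows from one master
seed.

## Preprocessing

Working grid: 1-nm integer wavelengths, trimmed to 401–2400 nm (2000 bands);
the trimmed edges of the 350–2500 nm instrument range have poor
signal-to-noise. Detector-splice correction at 1000 nm is additive by
default: the ≥1000 nm segment is shifted so its first band matches the value
linearly extrapolated from the two bands below the junction (a
multiplicative variant is available; the additive form is idempotent and
preserves derivative structure above the junction). Smoothing is
Savitzky–Golay, window 11 / polynomial order 2, mirror-padded — wide enough
to suppress band-to-band noise, short enough to leave ~15-nm absorption
features intact. Replicate averaging drops scans whose Pearson correlation
with the pointwise median scan falls below 0.98 (abnormal-scan rule; the
threshold is configurable and deliberately conservative). The default
pipeline order is splice correction before smoothing; both orders are
supported because the choice is not forced by anything in the data model.

## Grünwald–Letnikov differentiation

Weights follow the product recursion w₀ = 1, wₖ = wₖ₋₁(k−1−v)/k, which is
numerically stable, truncates to the classical stencils exactly at integer
v, and agrees with the Γ closed form wₖ = Γ(k−v)/(Γ(−v)Γ(k+1)) to better
than 1e−10 relative error out to k = 200 (tested). The transform uses full
memory back to the first retained band: out[x] = Σₖ wₖ R[x−k]. The band step
is one grid step (1 nm) with no h^v rescaling — the derivative is defined on
the band index, which keeps orders comparable across configurations. The
first ⌈v⌉ bands see a truncated history; they are flagged in the
preprocessing log rather than dropped, so downstream band bookkeeping stays
aligned. Implementation detail: the convolution is expressed as one
triangular-Toeplitz matrix product (a single BLAS call per order), which is
exact for integer orders because the truncated weights are exact zeros. A
windowed-memory mode truncates the weight sequence for speed; the default is
full memory.

## Index search

All six two-band indices are computed for every ordered pair on a strided
band grid (default stride 5 nm; stride 1 is the full-fidelity path — 2000²
pairs × 21 orders × 6 indices — at roughly 25× the cost). Correlations are
Pearson r, computed per-column with NaN masking in row chunks so peak memory
stays O(n_samples × n_bands). Index values with zero denominators (possible
after differentiation for RI and NDI) propagate as NaN; a pair is undefined
when fewer than 80% of samples have finite values or when either side has
zero variance. Undefined entries never enter the ranking.

Selection takes the k = 4 strongest |r| combinations per index across all
orders jointly; only the canonical λ₁ < λ₂ orientation competes (the swap is
redundant for symmetric/antisymmetric indices and is suppressed for RI as
well, for comparability); the same pair may recur at different orders. Ties
break toward lower order, then lower λ₁, then lower λ₂, making the search
fully deterministic. Correlation maps are computed on the calibration subset
only (configurable to all samples), so validation data never influence
feature selection.

## Partitioning and statistics

Kennard–Stone seeds with the two most distant samples (Euclidean) and
repeatedly adds the candidate maximising its minimum distance to the
selected set, stopping at round(0.7·n); ties break toward the lowest sample
position, so duplicate rows cannot make the split nondeterministic. The
distance space is per-band z-scored preprocessed reflectance by default
(options: raw reflectance, the response itself). A consequence used in the
tests: the feature-space extremes always land in the calibration set, so
validation interpolates. The outlier screen is an iterative mean ± 3·SD rule
on the response, applied until stable — an explicit, pluggable stand-in for
whatever screening a given survey used. Descriptive statistics use the n−1
SD and CV% = 100·SD/mean.

## PLS modelling and evaluation

PLS1 with mean centering and no scaling (scikit-learn's solver behind the
module interface); coefficients are stored in original predictor units. With
as many components as predictors the fit equals ordinary least squares
(tested to 1e−8 against the normal equations). The component count (≤ 4,
one per selected combination) minimises leave-one-out RMSE, ties toward
fewer components.

Evaluation reports RCV²/RMSEC from leave-one-out predictions on the
calibration set, RP²/RMSEP on the validation set (R² = 1 − SSE/SST, not a
squared correlation), and RPD = SD/RMSEP. The RPD denominator is the
calibration-set SD by default — that convention is the one whose arithmetic
reproduces the published evaluation tables this workflow format mirrors
(dividing the calibration SD by each tabulated RMSE recovers each tabulated
RPD within 1%, which the validation SD does not) — with the standard
validation-SD definition available by configuration. Class bands: RPD ≤ 1.4
poor, 1.4–2.0 average, > 2.0 good, boundaries to the lower class. An RMSEP
of exactly zero flags the report "perfect" instead of producing an infinite
RPD.

## Synthetic data generator

The generator produces the study conditions: n = 108 samples on the
350–2500 nm grid, with Ni from a lognormal targeting mean 28.83 / SD
8.33 mg/kg truncated to [12, 75] (the truncation clips well under 1% of the
mass, so no moment correction is applied). Each spectrum is

R(λ) = gain·C(λ) + offset + drift(λ) − Σ depthⱼ·G(λ; cⱼ, sⱼ)
       − amp·Ni·G(λ; 1930, 14) + jump·1[λ ≥ 1000] + ε(λ)

with C a sigmoid continuum rising over 400–800 nm, G unit-height Gaussians
for the water (1400/1900/2200 nm) and iron-oxide (490 valley / 550 peak)
features, and clipping into (0, 1).

Three design choices matter and are deliberate:

- **Baseline drift is a smooth random curve**, not just a per-sample gain
  and offset: a sum of broad cosine/sine modes (default 10 modes, 1/m
  amplitude decay, amplitude 0.05). A constant offset or pure gain is
  *exactly* cancelled by any two-band difference or ratio at order 0, which
  would make derivative preprocessing pointless by construction; smooth
  curved drift is what derivative preprocessing exists to remove, and with
  it the order-0 search ceiling sits measurably below the derivative-grid
  ceiling in every seed.
- **Noise is band-limited** (white noise smoothed over 3 nm, variance
  restored): spectrometers interpolate 1-nm output from coarser optical
  resolution, so their noise is spectrally smooth. Grid-scale white noise
  would be amplified ~2^v by the GL filter and would wipe out all orders
  above ~1 regardless of any signal.
- **Feature-depth jitter is mostly common-mode** (one ±25% factor per
  sample across all features, ±5% independent per feature), mimicking
  moisture/organic-matter co-variation. Ratio-type indices cancel
  common-mode factors; fully independent jitter would be an unrealistically
  adversarial nuisance for them.

The planted Ni effect (amplitude 3·10⁻³ reflectance units per mg/kg at
1930 nm, width 14 nm) was calibrated once so that the maximum raw
single-band |r| lands around 0.3–0.4 at the default nuisance levels — a
weak-signal regime — while the derivative-grid index search recovers
|r| ≈ 0.95–0.98 at orders 0.8–1.5 and the top combinations bracket the
planted band.

What the generator does **not** emulate: radiative-transfer physics,
particle-size and moisture confounders, nonlinear signal-matrix
interactions, wavelength-dependent noise floors, or any mechanistic link
between Ni and reflectance (the co-absorption is phenomenological).
Consequently, passing tests demonstrate that the pipeline recovers a weak
additive narrow-band signal under realistic smooth nuisance — not that the
method will attain any particular accuracy on real soils.

## Numerical conventions and degenerate inputs

- Undefined values are NaN throughout; they propagate, are reported, and are
  excluded from ranking; they abort a model fit with an explicit error.
- A constant response yields an all-undefined correlation map with a
  warning, not an exception.
- Pearson columns are computed with two-pass (explicitly centered) sums;
  exact-constant columns give exact zero variance and are marked undefined.
- Splice correction requires two bands below the junction; resampling is the
  identity on an already-integer 1-nm grid; order-0 differentiation is the
  identity.
- round(fraction·n) uses floor(x + 0.5) (not banker's rounding) so a 70%
  split of 108 is always 76.

## Problem sizes in the test suite

Unit tests run on 5×20 to 5×40 instances with brute-force oracles
(per-pair `scipy.stats.pearsonr`, normal-equations least squares, Γ-function
weights, hand enumeration for Kennard–Stone). The seed-swept recovery suite
uses the full study conditions — n = 108, 21 orders, 5-nm stride — across 20
seeds for the search-stage properties and a single default-seed run for the
end-to-end model check; the pipeline smoke tests use n = 40 with three
orders and a 50-nm stride. These sizes keep the default suite's cost
dominated by the one seed sweep while every scientific claim is still
exercised at the sizes stated.

## Known limitations

- The FOD is defined on the band index; spectra on a non-1-nm grid must be
  resampled first, and orders are not comparable across different grid
  steps.
- The exhaustive pair search applies no multiple-comparison control; with
  160k pairs × 21 orders the selected |r| values are optimistically biased,
  which is why models are judged on a held-out validation set.
- NDI and RI degrade at high derivative orders when denominators approach
  zero; this is a property of ratio indices on oscillating derivative
  spectra, and the NaN policy makes it visible rather than hiding it.
- Kennard–Stone guarantees coverage, not unbiasedness: calibration and
  validation moments differ systematically (validation is interior).
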