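# Methods

## Ground-truth kernels

Three duration-modulated "proto-response" families are built from a
raised-cosine (Hanning) window of support `round(duration * sfreq)` samples.
All three coincide at a reference duration (default 0.5 s, peak amplitude
1):

- **hanning** — the whole window stretches along the time axis; peak fixed.
- **scaled_hanning** — stretches along both axes; the peak scales as
  `duration / ref_duration`.
- **half_hanning** — the rising half is frozen at its reference shape; the
  falling half stretches (a cosine phase grid linearly stretched so that at
  the reference duration the samples equal the plain window exactly).

Sampling caveats: the analytic peak is only sampled exactly when the support
has an odd number of samples, and `half_hanning` needs at least the frozen
rising half plus two falling samples, i.e. a minimum duration of
`(round(ref·sfreq/2) + 2) / sfreq` (0.27 s at the defaults). The event
generator floors sampled durations at each shape's minimum renderable
duration; for `half_hanning` this puts a point mass at 0.27 s in the
half-normal condition (≈ 21 % of events). Spline quantile knots falling into
such a point mass are deduplicated (see below).

## Data-generating process

Inter-event distances are drawn i.i.d. from `uniform(0, 3.5)` s or a
half-normal (`|N(0, 1)|`) distribution — the former mimics experimentally
set stimulus durations, the latter fixation durations. Each event's
*duration equals the distance to the next onset*, so the duration effect
and the temporal overlap are perfectly collinear by construction; the final
event of each block receives an independent draw. 500 events are grouped
into blocks of 25 separated by 5 s silent gaps. Kernels are superimposed
linearly; with `duration_effect=False` every event is rendered at the
reference duration while the durations still drive the onsets.

Noise is added to the continuous signal, then the data are high-pass
filtered: a windowed-sinc FIR (Hamming window, 0.5 Hz transition width)
constructed by spectral inversion of a DC-normalized lowpass, giving an
exact null at DC and a −6 dB point at the 0.5 Hz cutoff. The filter is
applied once and its group delay compensated, so the applied magnitude
response equals the designed one (forward–backward application would square
it to −12 dB and double the kernel distortion).

### Noise model and its calibration

Real resting-state EEG noise is replaced by synthetic generators: white,
AR(1) (an Ornstein–Uhlenbeck-like 1/f² spectrum above a knee at
`(1−a)·sfreq/2π` Hz), and pink (1/f power). The study conditions do not pin
a numeric SNR, so the default (white, SD 0.3 against kernel peak 1) was
calibrated once to the published qualitative regime: the classical-average
error in the null scenario must remain dominated by the systematic
filter-induced distortion that all models share (measured floor
≈ 0.015 signal-units²), which is what keeps the overfit of needless
duration models "negligible" (normalized MSE ≲ 1.15 rather than the ~2×
that estimation variance alone would give). The model orderings are
insensitive to the noise level and color (checked with white, 1/f, and
AR(1) noise at several amplitudes).

## Designs and estimation

- **Epoch (mass-univariate)**: one row per event; the same design is fit
  independently at every peri-event lag by dense least squares (minimum-norm
  for rank-deficient designs). Events whose epochs leave the recording are
  dropped with a logged count.
- **FIR time expansion (deconvolution)**: one row per continuous sample;
  every predictor column is expanded into one column per lag, event types
  are concatenated horizontally, and out-of-bounds lag rows are truncated.
  The sparse system is solved through the normal equations with a dense
  Cholesky factorization (designs here have at most a few thousand
  columns), falling back to the minimum-norm solution when the Gram matrix
  is singular. On noise-free full-rank problems this is exact to machine
  precision, which the recovery tests rely on.

Duration encodings: raw value (linear); equal-count bins with rank-based
tie-breaking, treatment-coded against the lowest bin (categorical, n−1
columns, transform edges right-closed at each training bin's maximum);
B-splines of `df` basis functions (cubic for df ≥ 4) with interior knots at
covariate quantiles, the first basis function dropped and absorbed into the
intercept (df−1 columns). Because the prediction space of a
partition-of-unity basis plus intercept does not depend on *which* basis
function is dropped, this convention affects coefficient readouts but not
fits. Interior knots tied to each other or to the span boundary are
deduplicated with a warning, reducing the effective flexibility. Evaluation
outside the knot span clamps to the boundary. Covariates enter raw; the
fMRI-style preprocessing path (winsorize at the 5th/95th percentiles, then
center and scale) is available separately.

Default peri-event window: `[−0.1 s, max simulated duration + ref_duration)`
— a short pre-onset baseline plus full coverage of every renderable kernel.
No baseline correction is applied anywhere by default.

## Evaluation

Marginal-effect curves are the fitted linear predictor evaluated over a
duration grid (default: the 15 interior quantiles, probabilities k/16) with
other numeric covariates held at their training means and categorical terms
at the reference level. Raw MSE is the mean over grid durations and lags of
the squared difference from the true kernel (the fixed reference kernel
when no duration effect was simulated), zero-padded to the window.
Normalized MSE divides by the intercept-only fit of the same dataset and
overlap-correction setting; the median across repetitions (not the mean) is
used for all comparisons.

### What the filter does to the comparison

With kernel support equal to the event duration, long events produce
kernels whose spectral content lies largely below 1 Hz; the 0.5 Hz
high-pass removes much of it. Since predictions are made from filtered data
but scored against unfiltered kernels, all models share a large attenuation
error that compresses normalized MSEs toward 1 and is the dominant term in
the duration-effect scenarios. This biases the comparison in favor of
classical averaging and blurs the margin between the 5-spline and
10-bin-categorical encodings (the 10-spline encoding remains clearly best
in the epoch setting, the 5-spline in the deconvolution setting). The
qualitative conclusions — duration models beat averaging, splines are the
best encoding family, duration terms cannot substitute for overlap
correction — are robust to this.

## Block structure and the duration–FIR collinearity

When duration is both a predictor and, implicitly, the inter-event distance
in the FIR expansion, a continuous unbroken event stream leaves smooth
wave-like directions of the design weakly identified (smallest Gram
eigenvalues 2–4× lower than with block gaps). These directions are excited
almost exclusively by the low-frequency content of the noise: under
EEG-like drift noise the estimated duration effect on *pure-noise* data
fans out visibly without block gaps, while white noise of any amplitude
barely shows the effect. The packaged diagnostic (`block_artifact_rms`)
therefore fits the most flexible spline model to pure noise with an AR(1)
drift generator and reports the RMS of the marginal-effect spread around
its across-duration mean; silent gaps every 25 events reliably shrink it.
The instability here is mild compared to a truly break-free design because
the recording's own quiet lead-in and tail already anchor two block
boundaries.

## Group statistics

For real multi-subject data, per-subject spline coefficient vectors at each
(channel/ROI, lag) cell are tested against zero with a one-sample Hotelling
T² (`F = T²(n−p)/(p(n−1))` on `(p, n−p)` degrees of freedom; a zero mean
vector returns T² = 0 regardless of covariance). P-values are corrected
with the Benjamini–Yekutieli step-up procedure (`c(m) = Σ 1/i`), valid
under arbitrary dependence. Tests run on coefficients, not on the
always-positive maximal-marginal-effect display quantity; a one-sample
t-test companion is provided for differences of that display quantity.

## Problem sizes

The packaged study conditions are 500 events per simulation at 100 Hz with
20 repetitions per scenario for the sweep summaries — enough for stable
medians while keeping a full evaluation run to a couple of minutes on one
CPU. The repetition default for user sweeps is 50.

## Known limitations

- The synthetic noise generators are stationary and Gaussian; real EEG
  noise is neither, and its non-stationary slow components would further
  inflate the shared error floor of all models (and likely strengthen the
  block-structure artifact).
- Simulations are single-channel / single-subject; multi-channel fitting
  loops channels independently.
- Penalized (automatically smoothed) splines, ridge regularization,
  condition × duration interactions, and HRF basis functions are out of
  scope; the FIR basis is the only response model.
- The duration floor required to render kernels introduces a point mass
  into the duration distribution that the original distributions do not
  have; its main consequence (tied quantile knots) is handled by knot
  deduplication.
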