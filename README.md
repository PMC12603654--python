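# durerp — duration-aware regression ERPs with overlap correction

Event-related brain responses (EEG ERPs, fixation-related potentials, fMRI
BOLD, pupil dilation) are usually estimated as if every event evoked the
same response. In practice the response shape depends on the event's
**duration** — reaction time, fixation duration, stimulus duration — and
varying durations also change how strongly the responses to *successive*
events **overlap** in the recording. The two problems are entangled: the
inter-event distance drives both the overlap and (often) the duration
covariate, making them perfectly collinear.

`durerp` is a simulation and analysis toolkit for studying and solving this
jointly. It provides:

- a ground-truth simulator of duration-modulated response kernels
  (raised-cosine families that stretch in time, in time and amplitude, or in
  their falling half only), superimposed into a continuous noisy signal with
  block structure and an EEG-style high-pass filter;
- mass-univariate regression per peri-event time point
  (`y ~ 1 + f(duration)` at every lag) and **FIR-deconvolution** overlap
  correction, which solves one sparse least-squares problem over the
  continuous signal with one free coefficient per (predictor, lag);
- duration encodings: linear, equal-count categorical bins, and regression
  **B-splines** with knots at covariate quantiles
  (`y ~ 1 + spl(duration, 5)` in Wilkinson notation);
- evaluation against ground truth: marginal-effect time courses over the 15
  interior duration quantiles, and MSE normalized to the intercept-only
  (classical average) fit — values below 1 mean the duration model beats
  plain averaging;
- group-level inference for real data: one-sample Hotelling T² on spline
  coefficient vectors across subjects, with Benjamini–Yekutieli FDR
  correction across channels × time.

## The model

For a continuous signal $y(t)$ and events $i$ with onsets $o_i$ and
durations $d_i$, the deconvolution model is

$$y(t) = \sum_i \sum_{\ell} \beta_\ell(d_i)\, \mathbb{1}[t = o_i + \ell] + \varepsilon(t),$$

where $\ell$ ranges over peri-event lags (an FIR basis) and the
lag-coefficients depend on duration through an encoding
$\beta_\ell(d) = b_{0\ell} + \sum_j B_j(d)\, b_{j\ell}$ — $B_j$ a linear,
indicator, or B-spline basis. Without overlap correction the same linear
predictor is fit independently per epoch time point. Model quality is the
mean squared error between predicted marginal-effect curves and the true
kernels at the 15 duration quantiles, normalized by the intercept-only fit.

## Worked example

Simulate one noisy session (500 events, half-normal inter-event distances,
duration ≡ distance so overlap and duration are perfectly collinear), then
fit duration models with and without overlap correction:

```python
import numpy as np
from durerp import (SweepConfig, fit_model, marginal_effects, mse_vs_truth,
                    simulate_dataset)
from durerp.evaluate import _sweep_window

cfg = SweepConfig(global_seed=42)
signal, events, kernel = simulate_dataset(
    cfg, shape="scaled_hanning", duration_effect=True, overlap=True,
    dist="halfnormal", event_seed=42, noise_seed=43)
window = _sweep_window(cfg, events)
grid = np.quantile(events["duration"], np.arange(1, 16) / 16)

reference = fit_model(signal, events, "y ~ 1", overlap_correction=True,
                      window=window)
ref_mse = mse_vs_truth(marginal_effects(reference, grid), kernel)

for formula in ("y ~ 1 + duration", "y ~ 1 + spl(duration, 5)"):
    for correction in (False, True):
        fit = fit_model(signal, events, formula, correction, window)
        mse = mse_vs_truth(marginal_effects(fit, grid), kernel)
        print(f"{formula:28s} overlap_correction={correction!s:5s} "
              f"normalized MSE = {mse / ref_mse:.3f}")
```

Output:

```
y ~ 1 + duration             overlap_correction=False normalized MSE = 0.927
y ~ 1 + duration             overlap_correction=True  normalized MSE = 0.865
y ~ 1 + spl(duration, 5)     overlap_correction=False normalized MSE = 0.817
y ~ 1 + spl(duration, 5)     overlap_correction=True  normalized MSE = 0.664
```

Reading: every duration model beats the classical average (ratio < 1), the
non-linear spline encoding beats the linear one, and combining it with
overlap correction gives the best reconstruction of the true
duration-modulated kernels — duration modeling and overlap correction are
compatible despite their built-in collinearity.

## Command line

```bash
durerp simulate --config config.yaml --out-prefix run1
durerp fit --signal run1_signal.bin --events run1_events.tsv \
       --formula "y ~ 1 + spl(duration, 5)" --overlap-correction \
       --out run1_coef.tsv
durerp effects --fit run1_coef.tsv --grid quantiles:15 --out run1_effects.tsv
durerp evaluate --effects run1_effects.tsv --shape scaled_hanning
durerp sweep --config config.yaml --out sweep.tsv --figure sweep.png
```

Events travel as BIDS-style `events.tsv` (onset / duration / trial_type plus
covariates, seconds); signals as raw float64 with a JSON sidecar; every
output carries the config hash and seed that produced it.

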