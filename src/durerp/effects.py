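"""Marginal-effect time courses over a covariate grid.

A fitted model is summarized by evaluating its linear predictor over a grid
of durations (or any other modeled covariate) at every peri-event lag,
holding all other covariates fixed — numeric covariates at their training
means, categorical terms at the reference level. The spread between grid
curves per (channel, lag), the *maximal marginal effect*, is the scalar
display summary used for topographies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .design import BSplineEncoder, CategoricalEncoder, InterceptEncoder, LinearEncoder
from .fit import FitResult, TypeFit

logger = logging.getLogger(__name__)


@dataclass
class EffectGrid:
    """Predicted curves: ``curves`` is (n_grid, n_channels, n_lags)."""

    durations: np.ndarray
    curves: np.ndarray
    lag_times: np.ndarray
    held: dict
    covariate: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.curves)):
            raise ValueError("marginal-effect curves contain non-finite values")


def _resolve_grid(grid, tf: TypeFit, covariate: str) -> np.ndarray:
    if isinstance(grid, str):
        if not grid.startswith("quantiles:"):
            raise ValueError(f"unknown grid spec {grid!r}")
        k = int(grid.split(":", 1)[1])
        values = None
        for enc in tf.encoders:
            if getattr(enc, "name", None) == covariate:
                values = enc.values_
        if values is None:
            raise ValueError(
                f"grid {grid!r} needs a fitted {covariate!r} term; "
                "pass an explicit duration grid instead"
            )
        # k interior quantiles at probabilities i/(k+1), i = 1..k
        probs = np.arange(1, k + 1) / (k + 1)
        return np.quantile(values, probs)
    return np.asarray(grid, float)


def marginal_effects(fit: FitResult, grid="quantiles:15",
                     trial_type: str | None = None,
                     covariate: str = "duration",
                     held: str | dict = "means") -> EffectGrid:
    """Evaluate the fitted linear predictor over a grid of covariate values.

    ``grid`` is a vector of durations or ``"quantiles:k"`` (the k interior
    quantiles, probabilities i/(k+1), of the fitted covariate values).
    ``held`` fixes the remaining covariates: ``"means"`` holds numeric
    covariates at their training means and categorical terms at the
    reference level; a dict overrides individual covariates by name.
    Grid values outside a spline's knot span are clamped (with a warning).
    """
    tf = fit.types[trial_type] if trial_type is not None else fit.single()
    grid_vals = _resolve_grid(grid, tf, covariate)
    if grid_vals.ndim != 1 or len(grid_vals) == 0:
        raise ValueError("grid must be a nonempty 1-D vector")
    overrides = held if isinstance(held, dict) else {}

    n_grid = len(grid_vals)
    x = np.zeros((n_grid, tf.coef.shape[1]))
    col = 0
    held_used: dict = {}
    for enc in tf.encoders:
        w = enc.n_cols
        name = getattr(enc, "name", None)
        if isinstance(enc, InterceptEncoder):
            x[:, col:col + w] = 1.0
        elif name == covariate:
            x[:, col:col + w] = enc.transform(grid_vals)
        elif name in overrides:
            x[:, col:col + w] = enc.transform([overrides[name]])[0]
            held_used[name] = overrides[name]
        else:
            row = enc.held_row()
            x[:, col:col + w] = row
            held_used[name] = (enc.mean_ if isinstance(enc, LinearEncoder)
                               else "reference" if isinstance(enc, CategoricalEncoder)
                               else enc.mean_)
        col += w
    # curves[g, ch, lag] = sum_j x[g, j] * coef[ch, j, lag]
    curves = np.einsum("gj,cjl->gcl", x, tf.coef)
    return EffectGrid(grid_vals, curves, tf.window.lag_times, held_used, covariate)


def max_marginal_effect(effects: EffectGrid) -> np.ndarray:
    """Maximal pairwise spread of the grid curves per (channel, lag).

    Equals ``max_g curve − min_g curve`` elementwise, which is the maximum
    over all grid pairs of the absolute curve difference; always >= 0.
    """
    if len(effects.durations) < 2:
        raise ValueError("need at least 2 grid curves")
    return effects.curves.max(axis=0) - effects.curves.min(axis=0)
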