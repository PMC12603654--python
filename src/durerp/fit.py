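"""Least-squares estimation for mass-univariate and deconvolution models.

The deconvolution (overlap-corrected) path solves one large sparse
least-squares problem over the continuous signal per channel; the
mass-univariate path solves one small dense regression per peri-event time
point. Both return coefficients shaped (channels, term columns, lags) so
that downstream prediction code is mode-agnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import sparse

from .design import (BasisSpec, EpochDesign, FIRDesign, TermSpec,
                     build_epoch_design, parse_formula, time_expand_fir)
from .simulate import Signal, validate_events

logger = logging.getLogger(__name__)


@dataclass
class TypeFit:
    """Fitted coefficients for one event type: coef is (channels, p, lags)."""

    coef: np.ndarray
    terms: list[TermSpec]
    encoders: list
    window: BasisSpec
    column_labels: list[str]


@dataclass
class FitResult:
    """Estimated model: per-event-type coefficient blocks plus diagnostics."""

    types: dict[str, TypeFit]
    model_tag: str
    sfreq: float
    overlap_correction: bool
    diagnostics: dict = field(default_factory=dict)

    def single(self) -> TypeFit:
        """The only event type's fit (errors if several types were modeled)."""
        if len(self.types) != 1:
            raise ValueError("fit contains multiple event types; select one explicitly")
        return next(iter(self.types.values()))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (channel, event_type, term, basis_index, lag_seconds, estimate)."""
        rows = []
        for etype, tf in self.types.items():
            lags = tf.window.lag_times
            n_ch, p, L = tf.coef.shape
            for ch in range(n_ch):
                for j in range(p):
                    for l in range(L):
                        rows.append((ch, etype, tf.column_labels[j], j,
                                     lags[l], tf.coef[ch, j, l]))
        return pd.DataFrame(rows, columns=["channel", "event_type", "term",
                                           "basis_index", "lag_seconds", "estimate"])

    def save(self, path, meta: dict | None = None) -> None:
        """Write the tidy coefficient TSV plus a JSON sidecar.

        The sidecar carries the fitted encoder states and windows so the
        result can be reloaded for marginal-effect prediction.
        """
        from . import io as _io
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")
        sidecar = {"model_tag": self.model_tag, "sfreq": self.sfreq,
                   "overlap_correction": self.overlap_correction,
                   "diagnostics": self.diagnostics,
                   "types": {
                       etype: {
                           "terms": [{"covariate": t.covariate, "encoding": t.encoding,
                                      "param": t.param} for t in tf.terms],
                           "encoders": [enc.state() for enc in tf.encoders],
                           "window": {"tmin": tf.window.tmin, "tmax": tf.window.tmax,
                                      "sfreq": tf.window.sfreq},
                           "column_labels": tf.column_labels,
                           "coef_shape": list(tf.coef.shape),
                       } for etype, tf in self.types.items()}}
        if meta:
            sidecar.update(meta)
        _io.write_sidecar(path, sidecar)

    @classmethod
    def load(cls, path) -> "FitResult":
        import json
        from pathlib import Path

        from .design import encoder_from_state

        sidecar = json.loads(Path(str(path) + ".json").read_text())
        table = pd.read_csv(path, sep="\t", comment="#")
        types = {}
        for etype, tinfo in sidecar["types"].items():
            win = BasisSpec(**tinfo["window"])
            n_ch, p, L = tinfo["coef_shape"]
            coef = np.zeros((n_ch, p, L))
            sub = table[table["event_type"] == etype]
            coef[sub["channel"].to_numpy(int),
                 sub["basis_index"].to_numpy(int),
                 np.round((sub["lag_seconds"].to_numpy(float) - win.tmin)
                          * win.sfreq).astype(int)] = sub["estimate"].to_numpy(float)
            terms = [TermSpec(**t) for t in tinfo["terms"]]
            encoders = [encoder_from_state(s) for s in tinfo["encoders"]]
            types[etype] = TypeFit(coef, terms, encoders, win,
                                   tinfo["column_labels"])
        return cls(types, sidecar["model_tag"], sidecar["sfreq"],
                   sidecar["overlap_correction"], sidecar.get("diagnostics", {}))


def _solve_gram(X: sparse.csr_matrix, Y: np.ndarray) -> tuple[np.ndarray, int | None]:
    """Least squares through the normal equations.

    Returns (coefficients, rank). Cholesky first; on failure (rank
    deficiency) the minimum-norm solution of the Gram system, which equals
    the pseudoinverse solution of the original problem.
    """
    ncol = X.shape[1]
    nnz_per_col = np.diff(X.tocsc().indptr)
    zero_cols = nnz_per_col == 0
    if zero_cols.any():
        warnings.warn(f"{int(zero_cols.sum())} all-zero design columns; "
                      "their coefficients are forced to 0")
        keep = ~zero_cols
        Xr = X[:, np.flatnonzero(keep)]
    else:
        keep = np.ones(ncol, bool)
        Xr = X
    G = np.asarray((Xr.T @ Xr).todense())
    B = Xr.T @ Y.T  # (p, n_channels)
    if B.ndim == 1:
        B = B[:, None]
    rank: int | None = None
    try:
        c, low = sla.cho_factor(G, check_finite=False)
        sol = sla.cho_solve((c, low), B, check_finite=False)
    except (sla.LinAlgError, np.linalg.LinAlgError):
        logger.warning("rank-deficient design; returning the minimum-norm solution")
        sol, _, rank, _ = np.linalg.lstsq(G, B, rcond=None)
    out = np.zeros((ncol, B.shape[1]))
    out[np.flatnonzero(keep)] = sol
    return out, rank if rank is not None else int(keep.sum())


def solve_least_squares(design, response) -> FitResult:
    """Solve a prepared design against a response.

    ``design`` is an :class:`~durerp.design.FIRDesign` with a continuous
    :class:`~durerp.simulate.Signal` response, or an
    :class:`~durerp.design.EpochDesign` with an (events, channels, lags)
    epoch array.
    """
    if isinstance(design, FIRDesign):
        return _solve_fir(design, response)
    return _solve_epoch(design, response)


def _solve_fir(design: FIRDesign, signal: Signal) -> FitResult:
    X = design.matrix
    Y = signal.data  # (n_channels, n_samples)
    if X.shape[0] != Y.shape[1]:
        raise ValueError("design rows do not match the signal length")
    beta, rank = _solve_gram(X, Y)  # (total_cols, n_channels)
    resid = Y - (X @ beta).T
    types = {}
    for etype, (start, p, window) in design.type_slices.items():
        L = window.n_lags
        block = beta[start:start + p * L]                  # (p*L, n_ch)
        coef = block.T.reshape(Y.shape[0], p, L)
        meta_t = design.column_meta[design.column_meta["event_type"] == etype]
        labels = meta_t.drop_duplicates("basis_index")["column"].tolist()
        types[etype] = TypeFit(coef, design.type_terms[etype],
                               design.type_encoders[etype], window, labels)
    diags = {"residual_ss": (resid ** 2).sum(axis=1).tolist(),
             "rank": rank, "n_truncated": design.n_truncated}
    return FitResult(types, "fir", signal.sfreq, True, diags)


def _solve_epoch(design: EpochDesign, epochs: np.ndarray) -> FitResult:
    X = design.matrix                     # (n_events, p)
    if epochs.shape[0] != X.shape[0]:
        raise ValueError("design rows do not match the number of epochs")
    n_ev, n_ch, L = epochs.shape
    Y2 = epochs.transpose(1, 2, 0).reshape(n_ch * L, n_ev).T  # (n_ev, n_ch*L)
    beta, _, rank, _ = np.linalg.lstsq(X, Y2, rcond=None)
    coef = beta.reshape(X.shape[1], n_ch, L).transpose(1, 0, 2)
    resid = Y2 - X @ beta
    labels = design.column_meta["column"].tolist()
    tf = TypeFit(coef, design.terms, design.encoders, design.window, labels)
    diags = {"residual_ss": float((resid ** 2).sum()),
             "rank": int(rank), "n_dropped": design.n_dropped}
    return FitResult({design.event_type: tf}, "epoch", design.window.sfreq,
                     False, diags)


def _as_type_specs(events: pd.DataFrame, formulas, window) -> dict:
    """Normalize formula/window arguments into {trial_type: (terms, window)}."""
    types = list(pd.unique(events["trial_type"]))
    if isinstance(formulas, str):
        fdict = {t: formulas for t in types}
    else:
        fdict = dict(formulas)
        missing = set(types) - set(fdict)
        if missing:
            raise ValueError(f"no formula for trial_type(s) {sorted(missing)}")
    if isinstance(window, BasisSpec):
        wdict = {t: window for t in types}
    else:
        wdict = dict(window)
    return {t: (parse_formula(fdict[t]), wdict[t]) for t in fdict}


def default_window(events: pd.DataFrame, sfreq: float, tmin: float = -0.1,
                   tail: float = 0.5) -> BasisSpec:
    """Default peri-event window: [tmin, max duration + tail)."""
    return BasisSpec(tmin, float(events["duration"].max()) + tail, sfreq)


def fit_model(signal: Signal, events: pd.DataFrame, formulas,
              overlap_correction: bool, window=None,
              baseline_correction: bool = False) -> FitResult:
    """Fit a duration/overlap model to a continuous signal.

    ``formulas`` is a Wilkinson-style string (applied to every trial type)
    or a mapping ``trial_type -> formula``. With ``overlap_correction=True``
    the FIR time-expanded deconvolution model is solved on the continuous
    signal; otherwise epochs are cut and a mass-univariate regression is run
    per time point. Coefficients are indexable by (term column, lag) in both
    modes.

    ``baseline_correction`` optionally subtracts the mean pre-onset
    (lag < 0) estimate per coefficient curve; off by default.

    Row order of the event table is irrelevant: events are sorted by onset
    before the design is built.
    """
    events = events.sort_values("onset", kind="stable").reset_index(drop=True)
    validate_events(events)
    if window is None:
        window = default_window(events, signal.sfreq)
    specs = _as_type_specs(events, formulas, window)
    if overlap_correction:
        design = time_expand_fir(events, specs, signal.sfreq, signal.n_samples)
        result = solve_least_squares(design, signal)
    else:
        types = {}
        diags = {}
        for etype, (terms, win) in specs.items():
            sub = events[events["trial_type"] == etype]
            ed = build_epoch_design(sub, terms, win, signal.n_samples, etype)
            epochs = ed.extract_epochs(signal)
            part = solve_least_squares(ed, epochs)
            types[etype] = part.types[etype]
            diags[etype] = part.diagnostics
        result = FitResult(types, "epoch", signal.sfreq, False, diags)
    result.model_tag = _model_tag(formulas, overlap_correction)
    if baseline_correction:
        for tf in result.types.values():
            pre = tf.window.lag_times < 0
            if pre.any():
                tf.coef = tf.coef - tf.coef[:, :, pre].mean(axis=2, keepdims=True)
    return result


def _model_tag(formulas, overlap_correction: bool) -> str:
    f = formulas if isinstance(formulas, str) else ";".join(
        f"{k}:{v}" for k, v in sorted(dict(formulas).items()))
    return f"{f} | overlap_correction={overlap_correction}"
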