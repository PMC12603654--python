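"""Predictor encodings and design-matrix assembly.

Two design layouts are supported:

* **epoch (mass-univariate)** — one row per event; the same small design is
  used for an independent regression at every peri-event time point.
* **FIR time expansion (deconvolution)** — one row per continuous-time
  sample; every predictor column is expanded into one column per time lag,
  so that overlapping responses are unmixed by the least-squares fit.

Duration (or any numeric covariate) can enter as a linear term, as
equal-count categorical bins (treatment-coded against the lowest bin), or
as a regression B-spline basis with knots at covariate quantiles (the first
basis function is dropped and absorbed into the intercept).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.interpolate import BSpline

from .simulate import validate_events

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# term specification and formula parsing

@dataclass(frozen=True)
class TermSpec:
    """One model term: an intercept or an encoded numeric covariate."""

    covariate: str            # "1" for the intercept
    encoding: str             # intercept | linear | categorical | bspline
    param: int | None = None  # n_bins for categorical, df for bspline

    def __post_init__(self) -> None:
        if self.encoding not in ("intercept", "linear", "categorical", "bspline"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.encoding == "categorical" and (self.param is None or self.param < 2):
            raise ValueError("categorical encoding needs n_bins >= 2")
        if self.encoding == "bspline" and (self.param is None or self.param < 3):
            raise ValueError("bspline encoding needs df >= 3")

    @property
    def label(self) -> str:
        if self.encoding == "intercept":
            return "(Intercept)"
        if self.encoding == "linear":
            return self.covariate
        if self.encoding == "categorical":
            return f"bin({self.covariate},{self.param})"
        return f"spl({self.covariate},{self.param})"


_FUNC_RE = re.compile(r"^(spl|bin)\(\s*(\w+)\s*,\s*(\d+)\s*\)$")


def parse_formula(formula: str) -> list[TermSpec]:
    """Parse a Wilkinson-style formula such as ``y ~ 1 + spl(duration, 5)``.

    Supported right-hand-side terms: ``1`` (intercept), a bare covariate
    name (linear), ``bin(name, k)`` (equal-count categorical bins) and
    ``spl(name, k)`` (B-spline with k basis functions).
    """
    if "~" in formula:
        _, rhs = formula.split("~", 1)
    else:
        rhs = formula
    terms: list[TermSpec] = []
    for raw in rhs.split("+"):
        tok = raw.strip()
        if not tok:
            raise ValueError(f"empty term in formula {formula!r}")
        if tok == "1":
            terms.append(TermSpec("1", "intercept"))
            continue
        m = _FUNC_RE.match(tok)
        if m:
            func, name, num = m.groups()
            enc = "bspline" if func == "spl" else "categorical"
            terms.append(TermSpec(name, enc, int(num)))
        elif re.fullmatch(r"\w+", tok):
            terms.append(TermSpec(tok, "linear"))
        else:
            raise ValueError(f"cannot parse term {tok!r} in formula {formula!r}")
    if not terms:
        raise ValueError(f"formula {formula!r} has no terms")
    return terms


# ---------------------------------------------------------------------------
# encoders

class InterceptEncoder:
    n_cols = 1

    def fit(self, values: np.ndarray) -> "InterceptEncoder":
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        return np.ones((len(np.atleast_1d(values)), 1))

    def held_row(self) -> np.ndarray:
        return np.ones(1)

    def state(self) -> dict:
        return {"kind": "intercept"}

    @classmethod
    def from_state(cls, state: dict) -> "InterceptEncoder":
        return cls()


class LinearEncoder:
    n_cols = 1

    def __init__(self, name: str):
        self.name = name

    def fit(self, values: np.ndarray) -> "LinearEncoder":
        values = np.asarray(values, float)
        self.mean_ = float(values.mean())
        self.values_ = values.copy()
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        return np.atleast_1d(np.asarray(values, float))[:, np.newaxis]

    def held_row(self) -> np.ndarray:
        return np.array([self.mean_])

    def state(self) -> dict:
        return {"kind": "linear", "name": self.name, "mean": self.mean_,
                "values": self.values_.tolist()}

    @classmethod
    def from_state(cls, state: dict) -> "LinearEncoder":
        enc = cls(state["name"])
        enc.mean_ = state["mean"]
        enc.values_ = np.asarray(state["values"], float)
        return enc


class CategoricalEncoder:
    """Equal-count (quantile) bins, treatment-coded against the lowest bin."""

    def __init__(self, name: str, n_bins: int):
        self.name = name
        self.n_bins = n_bins
        self.n_cols = n_bins - 1

    def fit(self, values: np.ndarray) -> "CategoricalEncoder":
        values = np.asarray(values, float)
        if len(np.unique(values)) < self.n_bins:
            raise ValueError(
                f"covariate {self.name!r}: fewer distinct values than bins "
                f"({len(np.unique(values))} < {self.n_bins})"
            )
        # equal-count bins on ranks (stable sort breaks ties), so heavy ties
        # cannot produce empty bins; transform edges are right-closed at the
        # largest value of each training bin
        n = len(values)
        ranks = np.empty(n, dtype=int)
        ranks[np.argsort(values, kind="stable")] = np.arange(n)
        self.train_bins_ = (ranks * self.n_bins) // n
        edges = np.array([values[self.train_bins_ == b].max()
                          for b in range(self.n_bins - 1)])
        self.edges_ = edges
        self.mean_ = float(values.mean())
        self.values_ = values.copy()
        return self

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Right-closed bin index in 0..n_bins-1 (out-of-range values clamped)."""
        v = np.atleast_1d(np.asarray(values, float))
        return np.digitize(v, self.edges_, right=True)

    def transform(self, values: np.ndarray) -> np.ndarray:
        idx = self.assign(values)
        out = np.zeros((len(idx), self.n_cols))
        for b in range(1, self.n_bins):
            out[idx == b, b - 1] = 1.0
        return out

    def transform_training(self) -> np.ndarray:
        """Indicator columns using the rank-based training assignment."""
        out = np.zeros((len(self.train_bins_), self.n_cols))
        for b in range(1, self.n_bins):
            out[self.train_bins_ == b, b - 1] = 1.0
        return out

    def held_row(self) -> np.ndarray:
        # held at the reference (lowest) bin
        return np.zeros(self.n_cols)

    def state(self) -> dict:
        return {"kind": "categorical", "name": self.name, "n_bins": self.n_bins,
                "edges": self.edges_.tolist(), "mean": self.mean_,
                "values": self.values_.tolist()}

    @classmethod
    def from_state(cls, state: dict) -> "CategoricalEncoder":
        enc = cls(state["name"], state["n_bins"])
        enc.edges_ = np.asarray(state["edges"], float)
        enc.mean_ = state["mean"]
        enc.values_ = np.asarray(state["values"], float)
        return enc


class BSplineEncoder:
    """Regression B-spline basis with knots at covariate quantiles.

    ``df`` basis functions are constructed (cubic when df >= 4, degree
    df−1 otherwise); the first one is dropped for identifiability, leaving
    ``df − 1`` design columns. Evaluation outside the knot span is clamped
    to the span boundary.
    """

    def __init__(self, name: str, df: int):
        self.name = name
        self.df = df
        self.n_cols = df - 1

    def fit(self, values: np.ndarray) -> "BSplineEncoder":
        values = np.asarray(values, float)
        self.degree_ = k = min(3, self.df - 1)
        n_interior = self.df - (k + 1)
        lo, hi = values.min(), values.max()
        if hi <= lo:
            raise ValueError(f"covariate {self.name!r}: constant values, cannot place knots")
        interior = np.quantile(values, np.linspace(0, 1, n_interior + 2)[1:-1])
        # heavy ties (e.g. a point mass at a clipped minimum) can pull
        # quantile knots onto each other or the boundary; deduplicate and
        # accept the reduced flexibility rather than a singular basis
        interior = np.unique(interior[(interior > lo) & (interior < hi)])
        if len(interior) < n_interior:
            logger.warning(
                "covariate %r: ties collapsed %d interior spline knot(s); "
                "effective basis size reduced to %d",
                self.name, n_interior - len(interior), len(interior) + k + 1,
            )
        knots = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
        self.knots_ = knots
        self.n_cols = len(interior) + k  # basis size minus the dropped column
        self.mean_ = float(values.mean())
        self.values_ = values.copy()
        return self

    def basis(self, values: np.ndarray) -> np.ndarray:
        """Full (pre-drop) basis matrix, rows summing to one inside the span."""
        v = np.atleast_1d(np.asarray(values, float))
        lo, hi = self.knots_[0], self.knots_[-1]
        if np.any(v < lo) or np.any(v > hi):
            logger.warning(
                "covariate %r: %d values outside the spline knot span clamped",
                self.name, int(np.sum((v < lo) | (v > hi))),
            )
        v = np.clip(v, lo, hi)
        dm = BSpline.design_matrix(v, self.knots_, self.degree_, extrapolate=False)
        return np.asarray(dm.todense())

    def transform(self, values: np.ndarray) -> np.ndarray:
        return self.basis(values)[:, 1:]

    def held_row(self) -> np.ndarray:
        return self.transform([self.mean_])[0]

    def state(self) -> dict:
        return {"kind": "bspline", "name": self.name, "df": self.df,
                "knots": self.knots_.tolist(), "degree": self.degree_,
                "mean": self.mean_, "values": self.values_.tolist()}

    @classmethod
    def from_state(cls, state: dict) -> "BSplineEncoder":
        enc = cls(state["name"], state["df"])
        enc.knots_ = np.asarray(state["knots"], float)
        enc.degree_ = state["degree"]
        enc.mean_ = state["mean"]
        enc.values_ = np.asarray(state["values"], float)
        return enc


def encoder_from_state(state: dict):
    """Rebuild a fitted encoder from its serialized state."""
    kinds = {"intercept": InterceptEncoder, "linear": LinearEncoder,
             "categorical": CategoricalEncoder, "bspline": BSplineEncoder}
    return kinds[state["kind"]].from_state(state)


def make_encoder(term: TermSpec):
    if term.encoding == "intercept":
        return InterceptEncoder()
    if term.encoding == "linear":
        return LinearEncoder(term.covariate)
    if term.encoding == "categorical":
        return CategoricalEncoder(term.covariate, term.param)
    return BSplineEncoder(term.covariate, term.param)


def encode_duration(term: TermSpec, values: np.ndarray):
    """Fit an encoder for one term and return (columns, column labels, encoder)."""
    enc = make_encoder(term).fit(np.asarray(values, float))
    cols = enc.transform(values) if term.encoding != "intercept" else enc.transform(values)
    labels = [f"{term.label}[{i}]" if enc.n_cols > 1 else term.label
              for i in range(enc.n_cols)]
    return cols, labels, enc


def winsorize(values: np.ndarray, lower_pct: float = 5.0,
              upper_pct: float = 95.0) -> np.ndarray:
    """Clip values to the [lower, upper] empirical percentiles.

    A 90% winsorization (lower=5, upper=95) maps values above the 95th
    percentile onto the 95th percentile and values below the 5th percentile
    onto the 5th percentile.
    """
    if not 0 <= lower_pct < upper_pct <= 100:
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    values = np.asarray(values, float)
    lo, hi = np.percentile(values, [lower_pct, upper_pct])
    return np.clip(values, lo, hi)


# ---------------------------------------------------------------------------
# windows and design matrices

@dataclass(frozen=True)
class BasisSpec:
    """Peri-event FIR window [tmin, tmax) in seconds relative to onset."""

    tmin: float
    tmax: float
    sfreq: float

    def __post_init__(self) -> None:
        if self.tmax <= self.tmin:
            raise ValueError("tmax must exceed tmin")
        if self.n_lags < 1:
            raise ValueError("window shorter than one sample")

    @property
    def n_lags(self) -> int:
        return int(round((self.tmax - self.tmin) * self.sfreq))

    @property
    def tmin_samples(self) -> int:
        return int(round(self.tmin * self.sfreq))

    @property
    def lag_times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_lags) / self.sfreq


def _fit_term_columns(events: pd.DataFrame, terms: list[TermSpec]):
    """Fit all encoders on one event subset; returns (V, labels, term_of_col, encoders)."""
    blocks, labels, term_of_col, encoders = [], [], [], []
    n = len(events)
    for term in terms:
        if term.encoding == "intercept":
            enc = InterceptEncoder()
            cols = np.ones((n, 1))
        else:
            if term.covariate not in events.columns:
                raise ValueError(f"covariate {term.covariate!r} not in event table")
            vals = events[term.covariate].to_numpy(float)
            enc = make_encoder(term).fit(vals)
            # rank-based assignment for categorical training columns keeps
            # bins equal-count even with tied values
            cols = (enc.transform_training()
                    if isinstance(enc, CategoricalEncoder) else enc.transform(vals))
        blocks.append(cols)
        for i in range(cols.shape[1]):
            labels.append(f"{term.label}[{i}]" if cols.shape[1] > 1 else term.label)
            term_of_col.append(term)
        encoders.append(enc)
    return np.hstack(blocks), labels, term_of_col, encoders


def _column_meta(event_type: str, labels, term_of_col, n_lags: int | None) -> pd.DataFrame:
    rows = []
    for j, (lab, term) in enumerate(zip(labels, term_of_col)):
        if n_lags is None:
            rows.append({"event_type": event_type, "term": term.label,
                         "column": lab, "basis_index": j, "lag": -1})
        else:
            for lag in range(n_lags):
                rows.append({"event_type": event_type, "term": term.label,
                             "column": lab, "basis_index": j, "lag": lag})
    return pd.DataFrame(rows)


@dataclass
class EpochDesign:
    """Mass-univariate design: one row per kept event, plus an epoch extractor."""

    matrix: np.ndarray
    column_meta: pd.DataFrame
    terms: list[TermSpec]
    encoders: list
    window: BasisSpec
    event_type: str
    kept: np.ndarray          # boolean mask into the original event subset
    onset_samples: np.ndarray  # onset samples of kept events
    n_dropped: int = 0
    kind: str = "epoch"

    def extract_epochs(self, signal) -> np.ndarray:
        """Cut epochs [onset+tmin, onset+tmax) -> (n_events, n_channels, n_lags)."""
        L = self.window.n_lags
        out = np.empty((len(self.onset_samples), signal.n_channels, L))
        for i, o in enumerate(self.onset_samples):
            start = o + self.window.tmin_samples
            out[i] = signal.data[:, start:start + L]
        return out


def build_epoch_design(events: pd.DataFrame, terms: list[TermSpec],
                       window: BasisSpec, n_samples: int | None = None,
                       event_type: str | None = None) -> EpochDesign:
    """Build the (n_events × p) mass-univariate design for one event type.

    Events whose epoch window extends beyond ``[0, n_samples)`` are dropped
    (count logged); encoders are fit on the kept events.
    """
    onset_samples = np.round(events["onset"].to_numpy(float) * window.sfreq).astype(int)
    start = onset_samples + window.tmin_samples
    if n_samples is None:
        kept = np.ones(len(events), bool)
    else:
        kept = (start >= 0) & (start + window.n_lags <= n_samples)
    n_dropped = int(np.sum(~kept))
    if n_dropped:
        logger.info("dropped %d events with epochs outside the signal", n_dropped)
    sub = events.loc[kept]
    if len(sub) == 0:
        raise ValueError("no events left after dropping out-of-bounds epochs")
    V, labels, term_of_col, encoders = _fit_term_columns(sub, terms)
    if event_type is None:
        etype = str(sub["trial_type"].iloc[0]) if "trial_type" in sub.columns else "event"
    else:
        etype = event_type
    meta = _column_meta(etype, labels, term_of_col, None)
    return EpochDesign(V, meta, terms, encoders, window, etype, kept,
                       onset_samples[kept], n_dropped)


@dataclass
class FIRDesign:
    """Time-expanded deconvolution design over the continuous signal."""

    matrix: sparse.csr_matrix
    column_meta: pd.DataFrame
    type_slices: dict        # event_type -> (col_start, n_term_cols, window)
    type_terms: dict         # event_type -> list[TermSpec]
    type_encoders: dict      # event_type -> list of fitted encoders
    n_truncated: int = 0
    kind: str = "fir"


def time_expand_fir(events: pd.DataFrame,
                    type_specs: dict[str, tuple[list[TermSpec], BasisSpec]],
                    sfreq: float, n_samples: int) -> FIRDesign:
    """Build the sparse FIR time-expanded design matrix.

    For each event, each term-column value ``v`` and each lag ``l`` the
    entry at row ``onset_sample + tmin_samples + l`` of the column
    ``(term column, l)`` is incremented by ``v``. Columns of different
    event types are concatenated horizontally. Lag rows falling outside
    ``[0, n_samples)`` are truncated (count logged).
    """
    validate_events(events)
    rows_all, cols_all, data_all = [], [], []
    metas = []
    type_slices, type_terms, type_encoders = {}, {}, {}
    col_offset = 0
    n_truncated = 0
    for etype, (terms, window) in type_specs.items():
        sub = events[events["trial_type"] == etype]
        if len(sub) == 0:
            raise ValueError(f"no events of trial_type {etype!r}")
        V, labels, term_of_col, encoders = _fit_term_columns(sub, terms)
        L = window.n_lags
        onset_samples = np.round(sub["onset"].to_numpy(float) * sfreq).astype(int)
        row_base = onset_samples + window.tmin_samples      # (n_ev,)
        rows = row_base[:, None] + np.arange(L)[None, :]    # (n_ev, L)
        valid = (rows >= 0) & (rows < n_samples)
        n_truncated += int(np.sum(~valid)) * V.shape[1]
        lag_cols = np.tile(np.arange(L), (len(sub), 1))
        for j in range(V.shape[1]):
            vj = V[:, j]
            nz_ev = vj != 0
            mask = valid & nz_ev[:, None]
            rows_all.append(rows[mask])
            cols_all.append(col_offset + j * L + lag_cols[mask])
            data_all.append(np.repeat(vj, L).reshape(len(sub), L)[mask])
        metas.append(_column_meta(etype, labels, term_of_col, L))
        type_slices[etype] = (col_offset, V.shape[1], window)
        type_terms[etype] = terms
        type_encoders[etype] = encoders
        col_offset += V.shape[1] * L
    if n_truncated:
        logger.info("truncated %d design entries outside the signal", n_truncated)
    mat = sparse.coo_matrix(
        (np.concatenate(data_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n_samples, col_offset),
    ).tocsr()
    mat.sum_duplicates()
    return FIRDesign(mat, pd.concat(metas, ignore_index=True),
                     type_slices, type_terms, type_encoders, n_truncated)
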