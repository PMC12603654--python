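"""Generate event sequences and continuous signals with duration/overlap structure.

The data-generating process mimics a continuous single-channel recording in
which each event evokes a duration-modulated kernel, subsequent responses
superimpose linearly, and the inter-event distance doubles as the event's
duration — making the duration effect and the temporal overlap perfectly
collinear, which is the crux of the modeling problem.

Events come in blocks (default 25 events per block) separated by silent
inter-block intervals, mirroring block-structured experiments; the block
gaps are what keeps the time-expanded design matrix identifiable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .kernels import KernelSpec, make_kernel

logger = logging.getLogger(__name__)

DISTRIBUTIONS = ("uniform", "halfnormal")


@dataclass
class Signal:
    """A continuous multi-channel signal: ``data`` is (n_channels, n_samples)."""

    data: np.ndarray
    sfreq: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class NoiseSpec:
    """Additive noise generator settings.

    ``kind`` is one of none/white/ar1/pink; ``amplitude`` is the target
    standard deviation in signal units; ``ar_coefficient`` applies to the
    AR(1) kind only.
    """

    kind: str = "white"
    amplitude: float = 1.0
    ar_coefficient: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "white", "ar1", "pink"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")
        if self.kind == "ar1" and not -1 < self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in (-1, 1)")


def _draw_distances(rng: np.random.Generator, dist: str, size: int,
                    uniform_high: float, halfnormal_sd: float) -> np.ndarray:
    if dist == "uniform":
        return rng.uniform(0.0, uniform_high, size)
    if dist == "halfnormal":
        return np.abs(rng.normal(0.0, halfnormal_sd, size))
    raise ValueError(f"unknown distribution {dist!r}; expected one of {DISTRIBUTIONS}")


def sample_event_sequence(
    dist: str,
    n_events: int = 500,
    block_size: int | None = 25,
    inter_block_interval: float = 5.0,
    seed: int = 0,
    *,
    sfreq: float = 100.0,
    overlap: bool = True,
    start_time: float = 2.0,
    min_distance: float | None = None,
    uniform_high: float = 3.5,
    halfnormal_sd: float = 1.0,
    no_overlap_margin: float = 1.0,
    trial_type: str = "stim",
) -> pd.DataFrame:
    """Sample an event table with collinear duration/overlap structure.

    Inter-event distances are drawn i.i.d. from ``uniform(0, 3.5)`` or a
    half-normal (|N(0, 1)|) distribution and floored at ``min_distance``
    (default ``3 / sfreq``, the shortest renderable kernel). With
    ``overlap=True`` each event's duration *is* the distance to the next
    onset; the last event of each block has no successor and receives an
    independent draw. With ``overlap=False`` durations are still drawn from
    the same distribution but onsets are spaced by the maximum duration plus
    ``no_overlap_margin`` so responses never superimpose.

    ``block_size=None`` disables the block structure (no silent gaps).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if block_size is not None and block_size < 1:
        raise ValueError("block_size must be >= 1 (or None)")
    if dist not in DISTRIBUTIONS:
        raise ValueError(f"unknown distribution {dist!r}; expected one of {DISTRIBUTIONS}")
    if (block_size is not None and block_size < n_events
            and inter_block_interval <= 0):
        raise ValueError("inter_block_interval must be positive when blocks are used")

    rng = np.random.default_rng(seed)
    if min_distance is None:
        min_distance = 3.0 / sfreq
    durations = _draw_distances(rng, dist, n_events, uniform_high, halfnormal_sd)
    durations = np.maximum(durations, min_distance)

    onsets = np.empty(n_events)
    onsets[0] = start_time
    if overlap:
        for i in range(1, n_events):
            block_end = block_size is not None and i % block_size == 0
            gap = inter_block_interval if block_end else 0.0
            onsets[i] = onsets[i - 1] + durations[i - 1] + gap
    else:
        spacing = durations.max() + no_overlap_margin
        for i in range(1, n_events):
            block_end = block_size is not None and i % block_size == 0
            gap = inter_block_interval if block_end else 0.0
            onsets[i] = onsets[i - 1] + spacing + gap

    return pd.DataFrame(
        {"onset": onsets, "duration": durations, "trial_type": trial_type}
    )


def validate_events(events: pd.DataFrame) -> None:
    """Check the event-table invariants (required columns, increasing onsets)."""
    for col in ("onset", "duration", "trial_type"):
        if col not in events.columns:
            raise ValueError(f"event table is missing required column {col!r}")
    onsets = events["onset"].to_numpy(float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets must be strictly increasing")
    if np.any(events["duration"].to_numpy(float) <= 0):
        raise ValueError("event durations must be positive")


def render_continuous(
    events: pd.DataFrame,
    spec: KernelSpec | dict[str, KernelSpec],
    total_padding: float = 1.0,
    *,
    duration_effect: bool = True,
    n_samples: int | None = None,
) -> Signal:
    """Superimpose one kernel per event into a continuous single-channel signal.

    Each event contributes ``make_kernel(spec, duration)`` starting at
    ``round(onset * sfreq)``; overlapping supports are summed. When
    ``duration_effect`` is False every event is rendered at the reference
    duration (durations then only drive the onsets). ``spec`` may be a dict
    mapping ``trial_type`` to a spec when several event types coexist.
    """
    if len(events) == 0:
        raise ValueError("event table is empty")
    validate_events(events)
    specs = spec if isinstance(spec, dict) else {t: spec for t in events["trial_type"].unique()}
    sfreq = next(iter(specs.values())).sfreq

    kernel_dur = []
    for _, row in events.iterrows():
        s = specs[row["trial_type"]]
        kernel_dur.append(row["duration"] if duration_effect else s.ref_duration)
    last_end = max(
        row["onset"] + d for (_, row), d in zip(events.iterrows(), kernel_dur)
    )
    needed = int(round((last_end + total_padding) * sfreq))
    if n_samples is None:
        n_samples = needed
    data = np.zeros(n_samples)
    for (_, row), d in zip(events.iterrows(), kernel_dur):
        s = specs[row["trial_type"]]
        k = make_kernel(s, d)
        start = int(round(row["onset"] * sfreq))
        if start < 0 or start + len(k) > n_samples:
            raise RuntimeError(
                "kernel extends beyond the allocated signal; allocation must "
                "account for the maximum duration"
            )
        data[start:start + len(k)] += k
    return Signal(data[np.newaxis, :], sfreq)


def add_noise(signal: Signal, noise: NoiseSpec) -> Signal:
    """Return ``signal`` plus generated noise (deterministic given the seed)."""
    if noise.kind == "none" or noise.amplitude == 0:
        return Signal(signal.data.copy(), signal.sfreq)
    rng = np.random.default_rng(noise.seed)
    shape = signal.data.shape
    if noise.kind == "white":
        eps = rng.normal(0.0, noise.amplitude, shape)
    elif noise.kind == "ar1":
        a = noise.ar_coefficient
        # innovations scaled so the stationary SD equals `amplitude`
        innov = rng.normal(0.0, noise.amplitude * np.sqrt(1 - a * a), shape)
        eps = sps.lfilter([1.0], [1.0, -a], innov, axis=-1)
    else:  # pink: 1/f spectral shaping of white noise, renormalized
        white = rng.normal(0.0, 1.0, shape)
        spec = np.fft.rfft(white, axis=-1)
        freqs = np.fft.rfftfreq(shape[-1])
        scale = np.zeros_like(freqs)
        scale[1:] = 1.0 / np.sqrt(freqs[1:])
        spec = spec * scale
        eps = np.fft.irfft(spec, n=shape[-1], axis=-1)
        sd = eps.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        eps = eps / sd * noise.amplitude
    return Signal(signal.data + eps, signal.sfreq)


def design_highpass(sfreq: float, cutoff_minus6db: float = 0.5,
                    transition_width: float = 0.5) -> np.ndarray:
    """Design the windowed-sinc FIR high-pass used to remove slow drifts.

    The returned taps have a magnitude response of 0.5 (−6 dB) at the cutoff
    frequency. Odd length, Hamming window.
    """
    if not 0 < cutoff_minus6db < sfreq / 2:
        raise ValueError("cutoff must lie strictly between 0 and the Nyquist frequency")
    numtaps = int(np.ceil(3.3 * sfreq / transition_width))
    numtaps += 1 - numtaps % 2  # force odd
    # spectral inversion of a DC-normalized lowpass: exact null at DC,
    # amplitude 1 - H_lp(f) elsewhere (both linear phase, same delay)
    lowpass = sps.firwin(numtaps, cutoff_minus6db, window="hamming",
                         pass_zero=True, fs=sfreq)
    lowpass /= lowpass.sum()
    taps = -lowpass
    taps[(numtaps - 1) // 2] += 1.0
    return taps


def highpass_filter(signal: Signal, cutoff_minus6db: float = 0.5,
                    transition_width: float = 0.5) -> Signal:
    """Zero-phase high-pass filter with a −6 dB response at the cutoff.

    The linear-phase windowed-sinc FIR is applied once and its group delay
    compensated (standard EEG practice), so the applied magnitude response
    equals the designed one — 0.5 at the cutoff — rather than its square.
    """
    taps = design_highpass(signal.sfreq, cutoff_minus6db, transition_width)
    shift = (len(taps) - 1) // 2
    ext = np.pad(signal.data, [(0, 0), (0, shift)], mode="edge")
    filtered = sps.lfilter(taps, [1.0], ext, axis=-1)[:, shift:]
    return Signal(filtered, signal.sfreq)
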