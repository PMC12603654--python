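"""Duration-modulated ground-truth response kernels.

The simulation study uses a family of "proto" event-related responses built
from a raised-cosine (Hanning) window, all of which coincide at a reference
duration and diverge as the event duration changes:

``hanning``
    The whole response is stretched along the time axis; the peak amplitude
    stays fixed.
``scaled_hanning``
    The response is stretched along both axes: support grows with duration
    and the peak amplitude scales linearly with ``duration / ref_duration``.
``half_hanning``
    The rising half is frozen at its reference-duration shape; only the
    falling half is stretched to fill the remaining support.

All kernels are nonnegative, start and end at (numerically) zero, and have a
support of ``round(duration * sfreq)`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SHAPES = ("hanning", "scaled_hanning", "half_hanning")


@dataclass(frozen=True)
class KernelSpec:
    """Parameters of the ground-truth kernel family.

    Parameters
    ----------
    shape:
        One of :data:`SHAPES`.
    ref_duration:
        Duration (s) at which the three shapes produce identical kernels.
    sfreq:
        Sampling frequency in Hz.
    base_amplitude:
        Peak amplitude of the kernel at the reference duration.
    """

    shape: str = "hanning"
    ref_duration: float = 0.5
    sfreq: float = 100.0
    base_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown kernel shape {self.shape!r}; expected one of {SHAPES}")
        if self.ref_duration <= 0:
            raise ValueError("ref_duration must be positive")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")


def _n_support(duration: float, sfreq: float) -> int:
    return int(round(duration * sfreq))


def _fixed_half_len(spec: KernelSpec) -> int:
    # rising half of the reference-duration kernel, frozen for half_hanning
    return int(round(spec.ref_duration * spec.sfreq / 2))


def min_duration(spec: KernelSpec) -> float:
    """Shortest duration (s) for which :func:`make_kernel` is defined."""
    if spec.shape == "half_hanning":
        return (_fixed_half_len(spec) + 2) / spec.sfreq
    return 3.0 / spec.sfreq


def make_kernel(spec: KernelSpec, duration: float) -> np.ndarray:
    """Sample the ground-truth kernel for one event of the given duration.

    Returns a 1-D array of ``round(duration * sfreq)`` samples.

    Raises
    ------
    ValueError
        If ``duration`` is not positive, the support would be shorter than
        3 samples, or (for ``half_hanning``) shorter than the frozen rising
        half plus two falling samples.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = _n_support(duration, spec.sfreq)
    if n < 3:
        raise ValueError(
            f"duration {duration} gives a {n}-sample kernel at sfreq={spec.sfreq}; "
            "at least 3 samples are required"
        )
    amp = spec.base_amplitude
    if spec.shape == "hanning":
        return amp * np.hanning(n)
    if spec.shape == "scaled_hanning":
        return amp * (duration / spec.ref_duration) * np.hanning(n)
    # half_hanning
    n_ref = _n_support(spec.ref_duration, spec.sfreq)
    n_half = _fixed_half_len(spec)
    m = n - n_half
    if m < 2:
        raise ValueError(
            f"half_hanning support ({n} samples) shorter than the fixed rising half "
            f"({n_half} samples) plus 2"
        )
    rising = np.hanning(n_ref)[:n_half]
    # falling raised-cosine half, evaluated on a phase grid stretched so that
    # m samples cover what indices n_half .. n_ref-1 cover at the reference
    t = np.linspace(n_half, n_ref - 1, m)
    falling = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / (n_ref - 1)))
    return amp * np.concatenate([rising, falling])
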