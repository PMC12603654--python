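import numpy as np
import pandas as pd
import pytest

from durerp import BasisSpec, KernelSpec, render_continuous


@pytest.fixture
def sfreq():
    return 100.0


@pytest.fixture
def scaled_spec(sfreq):
    return KernelSpec("scaled_hanning", ref_duration=0.5, sfreq=sfreq)


def make_events(durations, spacing=None, start=2.0, trial_type="stim"):
    """Event table with given durations; non-overlapping unless spacing given."""
    durations = np.asarray(durations, float)
    if spacing is None:
        spacing = durations.max() + 1.0
    onsets = start + np.arange(len(durations)) * spacing
    return pd.DataFrame({"onset": onsets, "duration": durations,
                         "trial_type": trial_type})


@pytest.fixture
def distinct_duration_sim(scaled_spec):
    """Noise-free non-overlapping simulation with 15 distinct durations x 4."""
    durs = np.linspace(0.3, 2.0, 15)
    vals = np.tile(durs, 4)
    rng = np.random.default_rng(0)
    rng.shuffle(vals)
    events = make_events(vals)
    window = BasisSpec(-0.1, 2.5, scaled_spec.sfreq)
    signal = render_continuous(events, scaled_spec, total_padding=3.0)
    return signal, events, durs, window
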