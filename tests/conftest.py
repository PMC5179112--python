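import numpy as np
import pandas as pd
import pytest

from respigate.receptive_field_mapping import STIM_COLUMNS, Session
from respigate.respiration_phase import PhaseMap


@pytest.fixture
def simple_phase_map():
    """Regular 500 ms cycles with the trough at 200 ms (asymmetric halves)."""
    peaks = np.arange(0.0, 10_001.0, 500.0)
    troughs = peaks[:-1] + 200.0
    return PhaseMap(peaks, troughs)


def make_session(spikes, stimuli_rows, phase_map, field_size=(600.0, 600.0),
                 pixel=4.0):
    stim = pd.DataFrame(stimuli_rows, columns=STIM_COLUMNS)
    return Session(np.asarray(spikes, dtype=float), stim, phase_map,
                   field_size, pixel)


@pytest.fixture
def tiny_session(simple_phase_map):
    """Two non-overlapping stimuli with a handful of known spikes."""
    rows = [
        # x, y, side, onset, duration, onset_phase (filled by Session)
        (100.0, 100.0, 100.0, 1000.0, 200.0, np.nan),
        (400.0, 400.0, 100.0, 1400.0, 200.0, np.nan),
    ]
    spikes = [1010.0, 1030.0, 1100.0, 1450.0, 1500.0]
    return make_session(spikes, rows, simple_phase_map)
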