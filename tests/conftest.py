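import numpy as np
import pytest

from dubscreen.imquant import WellTimeSeries


@pytest.fixture
def make_series():
    """Factory for hand-built per-construct time series."""

    def _make(construct_id, times, values_by_time):
        times = np.asarray(times, dtype=float)
        values = {float(t): np.asarray(v, dtype=float)
                  for t, v in values_by_time.items()}
        return WellTimeSeries(construct_id, times, values)

    return _make
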