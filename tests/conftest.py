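import numpy as np
import pytest

from meanet import BurstParams, SyntheticNetworkSpec, WellRecording


@pytest.fixture
def params():
    return BurstParams()


@pytest.fixture
def small_spec():
    """A short, well-separated synthetic well used across tests."""
    return SyntheticNetworkSpec(
        n_channels=8,
        duration_s=120.0,
        tonic_rate_hz=0.3,
        nb_rate_per_min=6.0,
        nb_duration_ms=500.0,
        nb_duration_cv=0.2,
        in_burst_rate_hz=120.0,
        participation_frac=1.0,
        onset_jitter_ms=5.0,
        seed=7,
    )


def make_well(trains: dict, duration_s: float = 600.0, well_id: str = "w0", **meta):
    """Construct a WellRecording from raw time lists (seconds)."""
    return WellRecording(
        well_id=well_id,
        duration_s=duration_s,
        trains={ch: np.asarray(t, dtype=float) for ch, t in trains.items()},
        metadata=meta,
    )


@pytest.fixture
def well_factory():
    return make_well
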