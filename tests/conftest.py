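import numpy as np
import pytest

from vstenergetics.synthetic_data import generate_cohort, generate_session, preset
from vstenergetics.telemetry_io import ExerciseSession, Role, SubjectMetadata


@pytest.fixture
def metadata():
    return SubjectMetadata(
        subject_id="PH1", role=Role.PH,
        horse_mass_kg=428.0, rider_mass_kg=75.0, tack_mass_kg=10.0,
    )


def make_session(hr, speed, metadata=None, t=None):
    """Build a valid session from raw channel values."""
    hr = np.asarray(hr, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if metadata is None:
        metadata = SubjectMetadata("S1", Role.PH, 428.0, 75.0, 10.0)
    if t is None:
        t = np.arange(hr.size)
    return ExerciseSession(
        metadata=metadata,
        t_s=np.asarray(t),
        hr_bpm=hr,
        speed_mps=speed,
        cum_dist_m=np.cumsum(speed),
    )


@pytest.fixture(scope="session")
def preset_config():
    return preset("coelho2021", seed=1)


@pytest.fixture(scope="session")
def vst_session(preset_config):
    """One synthetic PH session from the named preset, seed 1."""
    return generate_session(preset_config, Role.PH, 0)


@pytest.fixture(scope="session")
def cohort(preset_config):
    return generate_cohort(preset_config)
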