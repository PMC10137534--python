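import numpy as np
import pytest
from hypothesis import settings

from comaqeeg.recording import Recording, Stage, StageSchedule
from comaqeeg.segmentation import Segment
from comaqeeg.synthetic import SyntheticCohortConfig

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mini_schedule() -> StageSchedule:
    """The five-stage protocol scaled 1:10 (3.5 min) for fast unit tests."""
    return StageSchedule(
        stages=(
            Stage("first_rest", 0.5, "rest"),
            Stage("nurse", 0.5, "interaction"),
            Stage("second_rest", 1.0, "rest", split=True),
            Stage("family", 0.5, "interaction"),
            Stage("last_rest", 1.0, "rest", split=True),
        )
    )


@pytest.fixture(scope="session")
def mini_config(mini_schedule) -> SyntheticCohortConfig:
    """A small, fast cohort configuration (1:10 schedule, fs 128)."""
    return SyntheticCohortConfig(
        patients_per_level={lv: 1 for lv in range(3, 9)},
        fs=128.0,
        schedule=mini_schedule,
        truncation_rate=0.0,
        master_seed=7,
        patient_sigma=0.1,
    )


@pytest.fixture()
def toy_segment() -> Segment:
    """A 2-second random 4-channel segment at the native 500 Hz rate."""
    rng = np.random.default_rng(42)
    return Segment(
        patient_id="T01",
        gcs=5,
        stage_name="first_rest",
        window_label="FULL",
        samples=rng.normal(0, 10, (4, 1000)),
        fs=500.0,
    )


def full_protocol_recording(fs: float = 10.0, seed: int = 0) -> Recording:
    """A 35-minute annotated recording (low rate: segmentation tests only)."""
    rng = np.random.default_rng(seed)
    n = int(35 * 60 * fs)
    ann = [
        ("first_rest", 0.0, 300.0),
        ("nurse", 300.0, 300.0),
        ("second_rest", 600.0, 600.0),
        ("family", 1200.0, 300.0),
        ("last_rest", 1500.0, 600.0),
    ]
    return Recording(
        channels=rng.normal(0, 1, (4, n)),
        fs=fs,
        stage_annotations=ann,
        patient_id="FULL01",
        gcs=6,
    )
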