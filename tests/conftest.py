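import numpy as np
import pytest

from fearsig.io import ChannelSignal, SelfReport, Sensor, Session, Trial
from fearsig.synthetic import ConditionEffect, SubjectProfile, synth_trial

FS = 256.0


def make_trial(
    duration_s: float = 120.0,
    fs: float = FS,
    report=(5, 5, 5),
    trial_id: str = "T01",
    pre_s: float = 30.0,
    post_s: float = 30.0,
    seed: int = 0,
) -> Trial:
    """Light synthetic trial (noise signals, no physiology) for structural tests."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    channels = {
        Sensor.ECG: ChannelSignal(Sensor.ECG, fs, rng.standard_normal(n) * 0.1),
        Sensor.GSR: ChannelSignal(Sensor.GSR, fs, 5.0 + 0.1 * rng.standard_normal(n)),
        Sensor.SKT: ChannelSignal(Sensor.SKT, fs, 33.0 + 0.05 * rng.standard_normal(n)),
    }
    return Trial(trial_id, channels, SelfReport(*report), pre_s, post_s)


@pytest.fixture(scope="session")
def physio_trial():
    """One physiologically plausible fear trial with ground truth (session-scoped:
    generation is the expensive part)."""
    rng = np.random.default_rng(42)
    trial, truth = synth_trial(SubjectProfile(), ConditionEffect(), True, "T01", rng)
    return trial, truth


@pytest.fixture(scope="session")
def feature_window(physio_trial):
    """First 20 s window of the trimmed physiological trial."""
    from fearsig.io import trim_recovery
    from fearsig.segmentation import segment_trial

    trial, _ = physio_trial
    windows = segment_trial(trim_recovery(trial, 30, 30), 20, 10, subject_id="V01", fear_label=1)
    return windows[0]


@pytest.fixture()
def small_session():
    return Session("S01", [make_trial(trial_id=f"T{i:02d}", seed=i) for i in range(2)])
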