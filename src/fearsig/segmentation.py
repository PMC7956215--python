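"""Fixed-length overlapping windowing of trimmed trials.

A trimmed trial is cut into windows of ``window_s`` seconds advancing by
``window_s - overlap_s`` seconds.  All timing is computed in integer
samples so segmentation is bit-exact; trailing samples that do not fill a
final window are discarded.  Every window inherits its trial's fear label.

With the reference protocol (60 s stimulus at 256 Hz, 20 s windows, 10 s
overlap) each trial yields exactly five windows, and a full-window spectral
estimate has a 0.05 Hz/bin resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Sensor, Trial, ValidationError


@dataclass
class Window:
    """One fixed-length tri-channel segment; the unit of feature extraction."""

    subject_id: str
    trial_id: str
    window_index: int
    sampling_rate: float
    segments: dict[Sensor, np.ndarray]
    fear_label: int
    start_s: float

    @property
    def n_samples(self) -> int:
        return int(next(iter(self.segments.values())).size)


def segment_trial(
    trial: Trial,
    window_s: float,
    overlap_s: float,
    subject_id: str = "",
    fear_label: int = 0,
) -> list[Window]:
    """Cut a (trimmed) trial into overlapping fixed-length windows.

    Window count is ``floor((N - L) / S) + 1`` with ``N`` samples per
    channel, ``L = window_s * fs`` and step ``S = (window_s - overlap_s) * fs``.
    """
    if not (0 <= overlap_s < window_s):
        raise ValidationError(f"need 0 <= overlap_s < window_s, got {overlap_s}, {window_s}")
    fs = trial.sampling_rate
    L = int(round(window_s * fs))
    S = int(round((window_s - overlap_s) * fs))
    N = trial.n_samples
    if N < L:
        raise ValidationError(
            f"trial {trial.trial_id!r} duration {trial.duration_s:.2f}s shorter than "
            f"window {window_s}s"
        )
    n_windows = (N - L) // S + 1
    windows = []
    for i in range(n_windows):
        start = i * S
        segments = {
            sensor: ch.values[start : start + L] for sensor, ch in trial.channels.items()
        }
        windows.append(
            Window(
                subject_id=subject_id,
                trial_id=trial.trial_id,
                window_index=i,
                sampling_rate=fs,
                segments=segments,
                fear_label=fear_label,
                start_s=start / fs,
            )
        )
    return windows


def frequency_resolution(window_s: float) -> float:
    """Hz/bin of a full-window spectral estimate: ``1 / window_s``."""
    if window_s <= 0:
        raise ValidationError(f"window_s must be positive, got {window_s}")
    return 1.0 / window_s


def storage_bytes(fs: float, window_s: float, n_sensors: int, bits_per_sample: int) -> float:
    """Raw storage needed to buffer one window on an embedded target."""
    if min(fs, window_s, n_sensors, bits_per_sample) <= 0:
        raise ValidationError("all storage parameters must be positive")
    return fs * window_s * n_sensors * bits_per_sample / 8
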