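"""Domain types and session / feature-table I/O.

A recording corpus is organized subject -> trial -> channel.  Each trial
holds exactly one channel per sensor (ECG, GSR, SKT), all sampled at the
same rate, plus a SAM self-report (valence, arousal, dominance on 1-9
scales) and the neutral recovery padding recorded before and after the
stimulus.

Native interchange is a pair of long-format CSVs:

* samples CSV: ``subject_id,trial_id,sensor,sample_index,value``
* trials CSV: ``subject_id,trial_id,sampling_rate,valence,arousal,
  dominance,pre_recovery_s,post_recovery_s``

Sample indices are 0-based; time ``t = index / sampling_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd


class StructuralError(ValueError):
    """A file or object violates the structural contract (missing channel, ...)."""


class ValidationError(ValueError):
    """A value is out of its documented range or non-finite."""


class SchemaError(ValueError):
    """A table carries unknown or missing columns."""


class Sensor(str, Enum):
    ECG = "ECG"  # electrocardiogram, mV
    GSR = "GSR"  # galvanic skin response, microsiemens
    SKT = "SKT"  # skin temperature, degrees Celsius


@dataclass
class ChannelSignal:
    """A single-sensor sample sequence at a fixed sampling rate."""

    sensor: Sensor
    sampling_rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sensor = Sensor(self.sensor)
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValidationError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"non-finite samples in {self.sensor.value} channel")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class SelfReport:
    """SAM self-report: integer 1-9 ratings of valence, arousal and dominance."""

    valence: int
    arousal: int
    dominance: int

    def __post_init__(self) -> None:
        for name in ("valence", "arousal", "dominance"):
            v = getattr(self, name)
            if not (1 <= int(v) <= 9) or int(v) != v:
                raise ValidationError(f"{name} must be an integer in [1, 9], got {v!r}")


@dataclass
class Trial:
    """One stimulus presentation: tri-channel signal block + self-report."""

    trial_id: str
    channels: dict[Sensor, ChannelSignal]
    report: SelfReport
    pre_recovery_s: float = 0.0
    post_recovery_s: float = 0.0

    def __post_init__(self) -> None:
        self.channels = {Sensor(k): v for k, v in self.channels.items()}
        missing = set(Sensor) - set(self.channels)
        if missing:
            names = ", ".join(sorted(s.value for s in missing))
            raise StructuralError(f"trial {self.trial_id!r} missing channel(s): {names}")
        if len(self.channels) != len(Sensor):
            raise StructuralError(f"trial {self.trial_id!r} must have exactly one channel per sensor")
        rates = {c.sampling_rate for c in self.channels.values()}
        lengths = {c.n_samples for c in self.channels.values()}
        if len(rates) != 1 or len(lengths) != 1:
            raise StructuralError(f"trial {self.trial_id!r}: channels differ in rate or length")
        if self.pre_recovery_s < 0 or self.post_recovery_s < 0:
            raise ValidationError("recovery durations must be non-negative")
        if self.duration_s < self.pre_recovery_s + self.post_recovery_s:
            raise ValidationError(
                f"trial {self.trial_id!r}: duration {self.duration_s:.2f}s shorter than "
                f"recovery padding {self.pre_recovery_s + self.post_recovery_s:.2f}s"
            )

    @property
    def sampling_rate(self) -> float:
        return next(iter(self.channels.values())).sampling_rate

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).n_samples

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Session:
    """One subject's ordered set of trials."""

    subject_id: str
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trials:
            raise StructuralError(f"session {self.subject_id!r} has no trials")
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise StructuralError(f"session {self.subject_id!r} has duplicate trial ids")


def trim_recovery(trial: Trial, pre_s: float, post_s: float) -> Trial:
    """Drop the neutral recovery padding from both ends of a trial.

    Removes ``round(pre_s * fs)`` leading and ``round(post_s * fs)`` trailing
    samples from every channel; the self-report is unchanged.  The trimmed
    trial records zero remaining recovery.
    """
    if pre_s < 0 or post_s < 0:
        raise ValidationError("trim durations must be non-negative")
    fs = trial.sampling_rate
    head = int(round(pre_s * fs))
    tail = int(round(post_s * fs))
    n = trial.n_samples
    if head + tail >= n:
        raise ValidationError(
            f"trimming {pre_s}+{post_s}s leaves no stimulus segment in a "
            f"{trial.duration_s:.2f}s trial"
        )
    stop = n - tail
    channels = {
        s: ChannelSignal(s, fs, c.values[head:stop]) for s, c in trial.channels.items()
    }
    return Trial(trial.trial_id, channels, trial.report, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Session CSV I/O

_SAMPLE_COLS = ["subject_id", "trial_id", "sensor", "sample_index", "value"]
_TRIAL_COLS = [
    "subject_id",
    "trial_id",
    "sampling_rate",
    "valence",
    "arousal",
    "dominance",
    "pre_recovery_s",
    "post_recovery_s",
]


def load_session_csv(samples_source, trials_source) -> list[Session]:
    """Read sessions from the documented long-format CSV pair.

    Parameters are anything :func:`pandas.read_csv` accepts (path or open
    text handle).  Returns one :class:`Session` per subject, in order of
    first appearance; sample order within each channel follows
    ``sample_index``.
    """
    samples = pd.read_csv(samples_source, float_precision="round_trip")
    trials = pd.read_csv(trials_source)
    for col in _SAMPLE_COLS:
        if col not in samples.columns:
            raise SchemaError(f"samples CSV missing column {col!r}")
    for col in _TRIAL_COLS:
        if col not in trials.columns:
            raise SchemaError(f"trials CSV missing column {col!r}")

    sessions: list[Session] = []
    sample_groups = {k: g for k, g in samples.groupby(["subject_id", "trial_id"], sort=False)}
    for subject_id, tmeta in trials.groupby("subject_id", sort=False):
        trial_objs = []
        for row in tmeta.itertuples(index=False):
            key = (row.subject_id, row.trial_id)
            if key not in sample_groups:
                raise StructuralError(f"no samples for trial {row.trial_id!r} of {subject_id!r}")
            g = sample_groups[key]
            channels = {}
            for sensor_name, ch in g.groupby("sensor", sort=False):
                ch = ch.sort_values("sample_index")
                idx = ch["sample_index"].to_numpy()
                if not np.array_equal(idx, np.arange(len(idx))):
                    raise StructuralError(
                        f"trial {row.trial_id!r} sensor {sensor_name}: sample indices "
                        "are not consecutive from 0"
                    )
                channels[Sensor(sensor_name)] = ChannelSignal(
                    Sensor(sensor_name), float(row.sampling_rate), ch["value"].to_numpy()
                )
            report = SelfReport(int(row.valence), int(row.arousal), int(row.dominance))
            trial_objs.append(
                Trial(
                    str(row.trial_id),
                    channels,
                    report,
                    float(row.pre_recovery_s),
                    float(row.post_recovery_s),
                )
            )
        sessions.append(Session(str(subject_id), trial_objs))
    return sessions


def write_session_csv(sessions: Sequence[Session], samples_sink, trials_sink) -> None:
    """Write sessions to the long-format CSV pair (lossless round trip)."""
    sample_frames = []
    trial_rows = []
    for session in sessions:
        for trial in session.trials:
            for sensor in Sensor:
                ch = trial.channels[sensor]
                sample_frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": session.subject_id,
                            "trial_id": trial.trial_id,
                            "sensor": sensor.value,
                            "sample_index": np.arange(ch.n_samples),
                            "value": ch.values,
                        }
                    )
                )
            trial_rows.append(
                {
                    "subject_id": session.subject_id,
                    "trial_id": trial.trial_id,
                    "sampling_rate": trial.sampling_rate,
                    "valence": trial.report.valence,
                    "arousal": trial.report.arousal,
                    "dominance": trial.report.dominance,
                    "pre_recovery_s": trial.pre_recovery_s,
                    "post_recovery_s": trial.post_recovery_s,
                }
            )
    pd.concat(sample_frames, ignore_index=True).to_csv(
        samples_sink, index=False, float_format="%.17g"
    )
    pd.DataFrame(trial_rows, columns=_TRIAL_COLS).to_csv(trials_sink, index=False)


# ---------------------------------------------------------------------------
# Feature-table I/O

_META_COLS = ["subject_id", "trial_id", "window_index"]
_LABEL_COL = "fear_label"


def feature_table_columns(feature_names: Sequence[str]) -> list[str]:
    return [*_META_COLS, *feature_names, _LABEL_COL]


def write_feature_table(table: pd.DataFrame, sink, feature_names: Sequence[str] | None = None) -> None:
    """Write a feature table CSV with stable column order and full precision."""
    if feature_names is None:
        from .features import FEATURE_NAMES

        feature_names = FEATURE_NAMES
    cols = feature_table_columns(feature_names)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    table[cols].to_csv(sink, index=False, float_format="%.17g")


def read_feature_table(source, feature_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a feature table CSV, validating the column schema."""
    if feature_names is None:
        from .features import FEATURE_NAMES

        feature_names = FEATURE_NAMES
    df = pd.read_csv(source, float_precision="round_trip")
    expected = feature_table_columns(feature_names)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SchemaError(f"unknown feature table columns: {unknown}")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    return df[expected]
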