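"""Synthetic multi-subject physiological sessions with ground truth.

Emulates the structure of a lab emotion-elicitation corpus: each subject
watches 20 one-minute stimuli, every recording padded with 30 s of neutral
recovery before and after, all channels at 256 Hz, with PAD self-reports
coupled to the imposed fear/neutral condition of each trial.

* ECG: Gaussian-template PQRST beats at inter-beat intervals from a
  positive-truncated AR(1) process (stationary mean ``60/hr``, SD
  ``sdnn``), plus band-limited additive noise at a configurable SNR.
* GSR: tonic level + slow drift + Poisson-timed skin conductance
  responses shaped by a Bateman kernel ``A(exp(-t/tau_d) - exp(-t/tau_r))``
  with ``tau_r = 0.75 s`` and per-event ``tau_d`` in 2-10 s.
* SKT: baseline + slow drift + low-pass (<0.2 Hz) noise.

Fear trials apply the condition effect — the standard sympathetic
activation pattern: heart rate up, HRV down, SCR rate up, skin temperature
down — to the 60 s stimulus span only.  Every generator is deterministic
under its seed and returns the ground truth (beat times, SCR onsets and
amplitudes, imposed condition) needed to score the pipeline's detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .io import ChannelSignal, SelfReport, Sensor, Session, Trial, ValidationError

FS_DEFAULT = 256.0
STIMULUS_S = 60.0
RECOVERY_S = 30.0


@dataclass(frozen=True)
class SubjectProfile:
    """Baseline physiology of one simulated subject."""

    baseline_hr: float = 70.0  # bpm
    sdnn_base: float = 0.05  # s
    tonic_gsr: float = 6.0  # microsiemens
    scr_rate_base: float = 2.0  # events/min
    skt_base: float = 33.0  # degrees C
    report_noise_sd: float = 1.0  # SAM scale units

    def __post_init__(self) -> None:
        if not (45 <= self.baseline_hr <= 120):
            raise ValidationError(f"baseline_hr {self.baseline_hr} outside [45, 120] bpm")
        if self.tonic_gsr < 0 or self.scr_rate_base < 0:
            raise ValidationError("tonic level and SCR rate must be non-negative")


#: Default profile sampling ranges (physiologically typical adults).
PROFILE_RANGES = {
    "baseline_hr": (55.0, 85.0),
    "sdnn_base": (0.02, 0.08),
    "tonic_gsr": (2.0, 12.0),
    "scr_rate_base": (1.0, 4.0),
    "skt_base": (31.0, 35.0),
}


@dataclass(frozen=True)
class ConditionEffect:
    """What the fear condition does to the stimulus span of a trial."""

    hr_delta: float = 8.0  # bpm
    sdnn_factor: float = 0.7
    scr_rate_factor: float = 2.0
    skt_delta: float = -0.3  # degrees C
    pad_fear: tuple[int, int, int] = (2, 8, 2)  # valence, arousal, dominance means
    pad_neutral: tuple[int, int, int] = (7, 3, 7)

    def __post_init__(self) -> None:
        if self.sdnn_factor <= 0 or self.scr_rate_factor <= 0:
            raise ValidationError("condition factors must be positive")


def strong_effect() -> ConditionEffect:
    """A deliberately strong sympathetic response, for effect-recovery checks."""
    return ConditionEffect(hr_delta=15.0, sdnn_factor=0.6, scr_rate_factor=3.0, skt_delta=-0.5)


def null_effect() -> ConditionEffect:
    """No physiological effect: labels still track condition, signals do not."""
    return ConditionEffect(hr_delta=0.0, sdnn_factor=1.0, scr_rate_factor=1.0, skt_delta=0.0)


# ---------------------------------------------------------------------------
# ECG

# PQRST template: (center offset s relative to R, amplitude mV, width s)
_ECG_TEMPLATE = (
    (-0.20, 0.12, 0.025),  # P
    (-0.025, -0.15, 0.010),  # Q
    (0.0, 1.00, 0.012),  # R
    (0.025, -0.20, 0.010),  # S
    (0.25, 0.30, 0.050),  # T
)


def _ar1_beat_times(
    duration_s: float,
    rr_mean_fn: Callable[[float], float],
    rr_sd_fn: Callable[[float], float],
    rng: np.random.Generator,
    phi: float = 0.8,
    start_s: float = 0.2,
) -> np.ndarray:
    """Beat times with AR(1) RR dynamics; instantaneous mean/SD may vary in time."""
    times = []
    t = start_s
    dev = 0.0  # AR(1) deviation from the local mean
    innov_scale = np.sqrt(max(1.0 - phi**2, 1e-12))
    while t < duration_s:
        times.append(t)
        sd = rr_sd_fn(t)
        dev = phi * dev + (innov_scale * sd * rng.standard_normal() if sd > 0 else 0.0)
        rr = max(rr_mean_fn(t) + dev, 0.3)
        t += rr
    return np.array(times)


def _ecg_waveform(beat_times: np.ndarray, fs: float, n_samples: int) -> np.ndarray:
    """Place the Gaussian PQRST template at each beat (nearest-sample alignment)."""
    half_s = 0.45
    tt = np.arange(-half_s, half_s, 1.0 / fs)
    template = np.zeros_like(tt)
    for center, amp, width in _ECG_TEMPLATE:
        template += amp * np.exp(-0.5 * ((tt - center) / width) ** 2)
    x = np.zeros(n_samples)
    half_n = int(round(half_s * fs))
    for bt in beat_times:
        i = int(round(bt * fs))
        lo, hi = i - half_n, i - half_n + len(template)
        s_lo, s_hi = max(lo, 0), min(hi, n_samples)
        if s_lo < s_hi:
            x[s_lo:s_hi] += template[s_lo - lo : s_hi - lo]
    return x


def _band_limited_noise(n: int, fs: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    w = rng.standard_normal(n)
    cutoff_hz = min(cutoff_hz, 0.45 * fs)  # stay below Nyquist at low test rates
    b, a = _signal.butter(4, cutoff_hz / (fs / 2), btype="low")
    y = _signal.filtfilt(b, a, w)
    sd = y.std()
    return y / sd if sd > 0 else y


def synth_ecg(
    fs: float,
    duration_s: float,
    hr_mean: float,
    sdnn: float,
    seed: int | np.random.Generator = 0,
    snr_db: float | None = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic ECG; returns (samples in mV, ground-truth R times in s)."""
    if not (45 <= hr_mean <= 120) or sdnn < 0:
        raise ValidationError(f"hr_mean {hr_mean} or sdnn {sdnn} out of range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beats = _ar1_beat_times(duration_s, lambda t: 60.0 / hr_mean, lambda t: sdnn, rng)
    n = int(round(duration_s * fs))
    x = _ecg_waveform(beats, fs, n)
    if snr_db is not None:
        p_signal = np.var(x)
        noise = _band_limited_noise(n, fs, 45.0, rng)
        x = x + noise * np.sqrt(p_signal / 10 ** (snr_db / 10))
    return x, beats


# ---------------------------------------------------------------------------
# GSR

TAU_RISE_S = 0.75


def _bateman(t: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    t_peak = np.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)
    peak = np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r)
    return k / peak  # unit peak amplitude


def _poisson_times(
    duration_s: float,
    rate_fn: Callable[[float], float],
    rate_max_per_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous Poisson event times by thinning."""
    if rate_max_per_s <= 0:
        return np.array([])
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_max_per_s)
        if t >= duration_s:
            break
        if rng.random() < rate_fn(t) / rate_max_per_s:
            times.append(t)
    return np.array(times)


def synth_gsr(
    fs: float,
    duration_s: float,
    tonic: float,
    drift_per_min: float,
    scr_rate_per_min: float,
    amp_range: tuple[float, float] = (0.2, 1.0),
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.0,
    rate_fn: Callable[[float], float] | None = None,
    rate_max_per_min: float | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Synthetic GSR; returns (samples in microsiemens, ground-truth SCR events).

    Each event dict holds ``onset_s``, ``peak_s``, ``amplitude`` and
    ``tau_decay``.  ``rate_fn`` (events/min as a function of time) overrides
    the constant ``scr_rate_per_min`` for condition-modulated trials.
    """
    if scr_rate_per_min < 0 or tonic < 0:
        raise ValidationError("rates and tonic level must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    x = tonic + drift_per_min * t / 60.0 + 0.02 * tonic * np.sin(2 * np.pi * t / 90.0 + phase)

    if rate_fn is None:
        rate_fn = lambda _t: scr_rate_per_min  # noqa: E731
        rate_max_per_min = scr_rate_per_min
    onsets = _poisson_times(duration_s, lambda s: rate_fn(s) / 60.0, rate_max_per_min / 60.0, rng)
    events = []
    for onset in onsets:
        if onset > duration_s - 5.0:
            continue  # an event must fit its rise and early decay
        amp = rng.uniform(*amp_range)
        tau_d = rng.uniform(2.0, 10.0)
        i0 = int(round(onset * fs))
        span = min(n - i0, int(round(8 * tau_d * fs)))
        if span <= 1:
            continue
        tk = np.arange(span) / fs
        x[i0 : i0 + span] += amp * _bateman(tk, TAU_RISE_S, tau_d)
        t_peak = np.log(tau_d / TAU_RISE_S) * TAU_RISE_S * tau_d / (tau_d - TAU_RISE_S)
        events.append(
            {"onset_s": float(onset), "peak_s": float(onset + t_peak), "amplitude": float(amp), "tau_decay": float(tau_d)}
        )
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return x, events


# ---------------------------------------------------------------------------
# SKT


def synth_skt(
    fs: float,
    duration_s: float,
    base: float,
    drift_per_min: float = 0.0,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.02,
    delta_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Synthetic skin temperature: baseline + drift + low-pass (<0.2 Hz) noise."""
    if not (25 <= base <= 40):
        raise ValidationError(f"skt base {base} outside [25, 40] degrees C")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = base + drift_per_min * t / 60.0
    if delta_fn is not None:
        x = x + delta_fn(t)
    if noise_sd > 0:
        x = x + noise_sd * _band_limited_noise(n, fs, 0.15, rng)
    return x


# ---------------------------------------------------------------------------
# Sessions and datasets


def _stimulus_gate(t: float | np.ndarray, ramp_s: float = 10.0):
    """0 -> 1 -> 0 gate over the stimulus span with linear ramps."""
    start, stop = RECOVERY_S, RECOVERY_S + STIMULUS_S
    up = np.clip((np.asarray(t, dtype=float) - start) / ramp_s, 0.0, 1.0)
    down = np.clip((stop - np.asarray(t, dtype=float)) / ramp_s, 0.0, 1.0)
    return np.minimum(up, down)


def synth_trial(
    profile: SubjectProfile,
    effect: ConditionEffect,
    is_fear: bool,
    trial_id: str,
    rng: np.random.Generator,
    fs: float = FS_DEFAULT,
    ecg_snr_db: float | None = 20.0,
    gsr_noise_sd: float = 0.01,
) -> tuple[Trial, dict]:
    """One 30 s + 60 s + 30 s trial; fear effects apply to the stimulus span only."""
    duration = 2 * RECOVERY_S + STIMULUS_S
    gate = _stimulus_gate

    hr_delta = effect.hr_delta if is_fear else 0.0
    sdnn_factor = effect.sdnn_factor if is_fear else 1.0
    rr_mean = lambda t: 60.0 / (profile.baseline_hr + hr_delta * float(gate(t)))  # noqa: E731
    rr_sd = lambda t: profile.sdnn_base * (1 + (sdnn_factor - 1) * float(gate(t)))  # noqa: E731
    beats = _ar1_beat_times(duration, rr_mean, rr_sd, rng)
    n = int(round(duration * fs))
    ecg = _ecg_waveform(beats, fs, n)
    if ecg_snr_db is not None:
        noise = _band_limited_noise(n, fs, 45.0, rng)
        ecg = ecg + noise * np.sqrt(np.var(ecg) / 10 ** (ecg_snr_db / 10))

    rate_factor = effect.scr_rate_factor if is_fear else 1.0
    base_rate = profile.scr_rate_base
    rate_fn = lambda t: base_rate * (1 + (rate_factor - 1) * float(gate(t)))  # noqa: E731
    gsr, scr_events = synth_gsr(
        fs,
        duration,
        tonic=profile.tonic_gsr,
        drift_per_min=rng.uniform(-0.05, 0.05) * profile.tonic_gsr,
        scr_rate_per_min=base_rate,
        seed=rng,
        noise_sd=gsr_noise_sd,
        rate_fn=rate_fn,
        rate_max_per_min=base_rate * max(rate_factor, 1.0),
    )

    skt_delta = effect.skt_delta if is_fear else 0.0
    skt = synth_skt(
        fs,
        duration,
        base=profile.skt_base,
        drift_per_min=rng.uniform(-0.05, 0.05),
        seed=rng,
        delta_fn=lambda t: skt_delta * gate(t),
    )

    targets = effect.pad_fear if is_fear else effect.pad_neutral
    vals = [
        int(np.clip(round(m + profile.report_noise_sd * rng.standard_normal()), 1, 9))
        for m in targets
    ]
    report = SelfReport(*vals)

    trial = Trial(
        trial_id=trial_id,
        channels={
            Sensor.ECG: ChannelSignal(Sensor.ECG, fs, ecg),
            Sensor.GSR: ChannelSignal(Sensor.GSR, fs, gsr),
            Sensor.SKT: ChannelSignal(Sensor.SKT, fs, skt),
        },
        report=report,
        pre_recovery_s=RECOVERY_S,
        post_recovery_s=RECOVERY_S,
    )
    truth = {
        "condition": "fear" if is_fear else "neutral",
        "r_times_s": beats,
        "scr_events": scr_events,
        "report": (report.valence, report.arousal, report.dominance),
    }
    return trial, truth


def synth_session(
    profile: SubjectProfile,
    effect: ConditionEffect,
    n_trials: int = 20,
    fear_fraction: float = 0.2,
    seed: int | np.random.Generator = 0,
    subject_id: str = "S01",
    fs: float = FS_DEFAULT,
) -> tuple[Session, dict]:
    """A full session: ``n_trials`` trials with the given fear fraction.

    Returns the :class:`Session` and a ground-truth dict keyed by trial id.
    """
    if not (0 <= fear_fraction <= 1):
        raise ValidationError(f"fear_fraction {fear_fraction} outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_fear = int(round(fear_fraction * n_trials))
    conditions = np.array([True] * n_fear + [False] * (n_trials - n_fear))
    rng.shuffle(conditions)
    trials, truth = [], {}
    for i, is_fear in enumerate(conditions):
        trial_id = f"T{i + 1:02d}"
        trial, t_truth = synth_trial(profile, effect, bool(is_fear), trial_id, rng, fs=fs)
        trials.append(trial)
        truth[trial_id] = t_truth
    return Session(subject_id, trials), truth


@dataclass
class SynthDataset:
    sessions: list[Session]
    manifest: pd.DataFrame  # one row per trial: subject, trial, condition, report
    ground_truth: dict  # (subject_id, trial_id) -> per-trial truth dict
    profiles: dict[str, SubjectProfile] = field(default_factory=dict)


def synth_dataset(
    n_subjects: int = 12,
    n_trials: int = 20,
    effect: ConditionEffect | None = None,
    fear_fraction: float = 0.2,
    seed: int = 0,
    fs: float = FS_DEFAULT,
) -> SynthDataset:
    """Reproducible multi-subject corpus with per-subject profile heterogeneity."""
    if n_subjects < 2:
        raise ValidationError("need at least 2 subjects")
    effect = effect or ConditionEffect()
    root = np.random.SeedSequence(seed)
    sessions, truth, profiles, rows = [], {}, {}, []
    for k, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        subject_id = f"V{k + 1:02d}"
        profile = SubjectProfile(
            **{name: rng.uniform(*rng_range) for name, rng_range in PROFILE_RANGES.items()}
        )
        profiles[subject_id] = profile
        session, s_truth = synth_session(
            profile, effect, n_trials, fear_fraction, seed=rng, subject_id=subject_id, fs=fs
        )
        sessions.append(session)
        for trial_id, t_truth in s_truth.items():
            truth[(subject_id, trial_id)] = t_truth
            v, a, d = t_truth["report"]
            rows.append(
                {
                    "subject_id": subject_id,
                    "trial_id": trial_id,
                    "condition": t_truth["condition"],
                    "valence": v,
                    "arousal": a,
                    "dominance": d,
                    "n_scr_truth": len(t_truth["scr_events"]),
                    "n_beats_truth": len(t_truth["r_times_s"]),
                }
            )
    manifest = pd.DataFrame(rows)
    return SynthDataset(sessions=sessions, manifest=manifest, ground_truth=truth, profiles=profiles)
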