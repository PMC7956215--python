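"""Per-sensor denoising applied to each window before feature extraction.

ECG passes through a linear-phase FIR band-pass realized as a high-pass /
low-pass cascade, followed by automatic gain control (AGC) that equalizes
beat amplitudes ahead of R-peak detection.  GSR and SKT pass through
linear-phase FIR low-passes.  All filters are zero-phase by group-delay
compensation (centered convolution on reflect-padded input), so filtered
output is sample-aligned with the input and has the same length.

Defaults (declared here, not dictated by any reference protocol):

* ECG band 0.5-40 Hz, Hamming-windowed (1023-tap high-pass, 255-tap
  low-pass at 256 Hz);
* GSR low-pass 2 Hz, SKT low-pass 1 Hz, 129 taps;
* AGC: moving maximum of ``|x|`` over 2 s smoothed by a 0.5 s moving
  average, floored at 5% of the global maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .io import ValidationError


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR filter description (odd tap count, Hamming window)."""

    kind: str  # "lowpass" | "highpass"
    cutoff_hz: float
    taps: int

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ValidationError(f"unknown filter kind {self.kind!r}")
        if self.taps < 3 or self.taps % 2 == 0:
            raise ValidationError("tap count must be odd and >= 3")

    def design(self, fs: float) -> np.ndarray:
        if not (0 < self.cutoff_hz < fs / 2):
            raise ValidationError(
                f"cutoff {self.cutoff_hz} Hz outside (0, {fs / 2}) at fs={fs}"
            )
        return signal.firwin(
            self.taps, self.cutoff_hz, pass_zero=(self.kind == "lowpass"), fs=fs
        )


@dataclass(frozen=True)
class PreprocConfig:
    # a 0.5 Hz high-pass needs its transition band to fit below 0.5 Hz,
    # hence far more taps than the low-passes
    ecg_highpass: FilterSpec = FilterSpec("highpass", 0.5, 1023)
    ecg_lowpass: FilterSpec = FilterSpec("lowpass", 40.0, 255)
    gsr_lowpass: FilterSpec = FilterSpec("lowpass", 2.0, 129)
    skt_lowpass: FilterSpec = FilterSpec("lowpass", 1.0, 129)
    agc_window_s: float = 2.0
    agc_smooth_s: float = 0.5
    agc_floor_frac: float = 0.05


DEFAULT_CONFIG = PreprocConfig()


def _fir_apply(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase FIR: reflect-pad, centered convolution, same length out."""
    pad = len(taps)
    if len(x) <= pad:
        raise ValidationError(f"input of {len(x)} samples too short for {len(taps)}-tap filter")
    xp = np.pad(x, pad, mode="reflect")
    y = np.convolve(xp, taps, mode="same")
    return y[pad : pad + len(x)]


def filter_ecg(x: np.ndarray, fs: float, config: PreprocConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Band-pass the raw ECG via a high-pass then low-pass FIR cascade."""
    x = np.asarray(x, dtype=float)
    longest = max(config.ecg_highpass.taps, config.ecg_lowpass.taps)
    if len(x) <= 3 * longest:
        raise ValidationError(
            f"ECG window of {len(x)} samples too short for {longest}-tap filtering"
        )
    y = _fir_apply(x, config.ecg_highpass.design(fs))
    return _fir_apply(y, config.ecg_lowpass.design(fs))


def filter_lowpass(
    x: np.ndarray, fs: float, spec: FilterSpec
) -> np.ndarray:
    """Low-pass a GSR or SKT window with a linear-phase FIR."""
    x = np.asarray(x, dtype=float)
    if len(x) <= 3 * spec.taps:
        raise ValidationError(
            f"window of {len(x)} samples too short for {spec.taps}-tap filtering"
        )
    return _fir_apply(x, spec.design(fs))


def apply_agc(x: np.ndarray, fs: float, config: PreprocConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Normalize a filtered ECG by a smoothed running amplitude envelope.

    Each sample is divided by a moving maximum of ``|x|`` (window
    ``agc_window_s``) smoothed with a short moving average, floored at
    ``agc_floor_frac`` of the global maximum so quiet stretches do not blow
    up.  Peak sample positions are unchanged; output peaks sit near 1
    regardless of the input scale (scale invariance).
    """
    x = np.asarray(x, dtype=float)
    gmax = np.max(np.abs(x))
    if gmax == 0:
        raise ValidationError("AGC input is all zero")
    if np.all(x == x[0]):
        raise ValidationError("AGC input is constant")
    env = maximum_filter1d(np.abs(x), size=max(1, int(round(config.agc_window_s * fs))), mode="reflect")
    env = uniform_filter1d(env, size=max(1, int(round(config.agc_smooth_s * fs))), mode="reflect")
    env = np.maximum(env, config.agc_floor_frac * gmax)
    return x / env


def preprocess_ecg(x: np.ndarray, fs: float, config: PreprocConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Full ECG conditioning chain: band-pass then AGC (for peak detection)."""
    return apply_agc(filter_ecg(x, fs, config), fs, config)
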