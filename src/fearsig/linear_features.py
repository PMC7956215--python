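"""Time- and frequency-domain features for ECG, GSR and SKT windows.

ECG: R-peak detection on the AGC-conditioned waveform gives the inter-beat
interval (IBI) series; mean IBI and SDNN summarize heart rate and its
variability, and spectral mass of the 4 Hz-resampled IBI tachogram in the
LF (<0.08 Hz), MF (0.08-0.15 Hz) and HF (0.15-0.5 Hz) bands captures
autonomic balance.  Four additional band powers (0-0.4 Hz in 0.1 Hz steps)
are computed on the band-passed ECG waveform itself.

GSR: a centered moving median separates the slow tonic level from the
phasic component; skin conductance responses (SCRs) are found by
trough-to-peak pairing on the phasic trace.

SKT: first four standardized moments plus two low-frequency band powers.

All spectral mass is measured with a single full-window periodogram
(mean removed, rectangular window), so a ``window_s`` second window has a
``1/window_s`` Hz/bin resolution and band powers over a partition of
[0, Nyquist) sum to the signal variance (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .io import ValidationError


class InsufficientBeatsError(ValueError):
    """Fewer than two R peaks found in a window; HRV features are imputed."""


# IBI sanity band used for ectopic rejection, seconds.
IBI_MIN_S = 0.25
IBI_MAX_S = 3.0

# Standard HRV bands on the IBI tachogram, Hz.
LF_BAND = (0.0, 0.08)
MF_BAND = (0.08, 0.15)
HF_BAND = (0.15, 0.5)


@dataclass
class IbiSeries:
    """R-peak sample positions and the seconds between successive peaks."""

    r_peak_indices: np.ndarray
    ibi_s: np.ndarray
    sampling_rate: float

    @property
    def peak_times_s(self) -> np.ndarray:
        return self.r_peak_indices / self.sampling_rate


@dataclass(frozen=True)
class ScrEvent:
    """One skin conductance response: trough onset to peak."""

    onset_index: int
    peak_index: int
    amplitude: float  # microsiemens, peak minus trough
    rise_time_s: float


def detect_r_peaks(ecg: np.ndarray, fs: float, min_height: float = 0.4) -> IbiSeries:
    """Detect R peaks on an AGC-conditioned ECG window.

    After AGC the QRS peaks sit near 1, so a fixed relative height
    threshold plus a 0.25 s refractory period suffices.  IBIs outside
    (0.25 s, 3 s) are rejected as ectopic/artifactual.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 10 * fs:
        raise ValidationError("R-peak detection needs a window of at least 10 s")
    if np.all(ecg == ecg[0]):
        raise InsufficientBeatsError("constant ECG window")
    refractory = int(round(IBI_MIN_S * fs))
    peaks, _ = signal.find_peaks(ecg, height=min_height, distance=refractory)
    if len(peaks) < 2:
        raise InsufficientBeatsError(f"only {len(peaks)} R peak(s) found")
    ibi = np.diff(peaks) / fs
    keep = (ibi > IBI_MIN_S) & (ibi < IBI_MAX_S)
    ibi = ibi[keep]
    if len(ibi) < 1:
        raise InsufficientBeatsError("no physiologically plausible inter-beat intervals")
    return IbiSeries(r_peak_indices=peaks, ibi_s=ibi, sampling_rate=fs)


def ecg_time_features(ibi: IbiSeries) -> dict[str, float]:
    """Mean IBI and SDNN (standard deviation of the IBI series), seconds."""
    if len(ibi.ibi_s) < 3:
        raise InsufficientBeatsError("need at least 3 inter-beat intervals")
    return {
        "mean_ibi": float(np.mean(ibi.ibi_s)),
        "sdnn": float(np.std(ibi.ibi_s, ddof=1)),
    }


def periodogram_power(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided mean-removed periodogram normalized so the bins sum to var(x).

    Returns (frequencies, power per bin).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValidationError("periodogram needs at least 2 samples")
    X = np.fft.rfft(x - x.mean())
    p = (np.abs(X) ** 2) / n**2
    # one-sided: double everything except DC (and Nyquist when n is even)
    scale = np.full(p.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, p * scale


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Spectral mass of ``x`` in the half-open band ``[low, high)`` Hz."""
    low, high = band
    if not (0 <= low < high):
        raise ValidationError(f"invalid band {band}")
    if high > fs / 2 + 1e-12:
        raise ValidationError(f"band {band} exceeds Nyquist frequency {fs / 2}")
    freqs, p = periodogram_power(x, fs)
    mask = (freqs >= low) & (freqs < high)
    return float(np.sum(p[mask]))


def ibi_spectral_features(ibi: IbiSeries, resample_hz: float = 4.0) -> dict[str, float]:
    """LF/MF/HF power of the IBI tachogram plus MF and LF/HF ratios.

    The irregularly-timed IBI series is cubic-interpolated onto a uniform
    ``resample_hz`` grid before the periodogram.  ``mf_ratio`` uses
    LF+MF+HF as denominator; both ratios fall back to 0 when their
    denominator is below machine tolerance.
    """
    if len(ibi.ibi_s) < 4:
        raise InsufficientBeatsError("need at least 4 inter-beat intervals for spectra")
    t = np.cumsum(ibi.ibi_s)  # time of each interval's closing beat, relative
    spline = CubicSpline(t, ibi.ibi_s)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    if len(grid) < 8:
        raise InsufficientBeatsError("IBI span too short to resample")
    u = spline(grid)
    lf = band_power(u, resample_hz, LF_BAND)
    mf = band_power(u, resample_hz, MF_BAND)
    hf = band_power(u, resample_hz, HF_BAND)
    total = lf + mf + hf
    eps = 1e-15
    return {
        "ibi_lf": lf,
        "ibi_mf": mf,
        "ibi_hf": hf,
        "ibi_mf_ratio": mf / total if total > eps else 0.0,
        "ibi_lf_hf_ratio": lf / hf if hf > eps else 0.0,
    }


def resample_ibi(ibi: IbiSeries, resample_hz: float = 4.0) -> np.ndarray:
    """Uniform ``resample_hz`` cubic interpolation of the IBI tachogram."""
    if len(ibi.ibi_s) < 4:
        raise InsufficientBeatsError("need at least 4 inter-beat intervals")
    t = np.cumsum(ibi.ibi_s)
    spline = CubicSpline(t, ibi.ibi_s)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    return spline(grid)


def gsr_decompose(
    gsr: np.ndarray, fs: float, median_window_s: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Split GSR into tonic (centered moving median) and phasic (residual).

    Edges shrink to the valid sample range; ``tonic + phasic`` reconstructs
    the input exactly by construction.
    """
    gsr = np.asarray(gsr, dtype=float)
    win = int(round(median_window_s * fs))
    if win >= len(gsr):
        raise ValidationError(
            f"median window {median_window_s}s >= signal length {len(gsr) / fs}s"
        )
    win |= 1  # force odd so the window is centered on a sample
    tonic = (
        pd.Series(gsr).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    return tonic, gsr - tonic


def detect_scrs(
    phasic: np.ndarray, fs: float, amp_threshold: float = 0.01
) -> list[ScrEvent]:
    """Trough-to-peak SCR detection on a phasic trace.

    Each local maximum is paired with the preceding trough: the last local
    minimum before it (falling back to the last occurrence of the
    inter-peak segment minimum, so a flat lead-in places the trough at the
    response onset).  Events with amplitude below ``amp_threshold``
    microsiemens are dropped.
    """
    phasic = np.asarray(phasic, dtype=float)
    peaks, _ = signal.find_peaks(phasic)
    minima, _ = signal.find_peaks(-phasic)
    events: list[ScrEvent] = []
    prev = 0
    for p in peaks:
        seg_start = prev
        candidates = minima[(minima >= seg_start) & (minima < p)]
        if len(candidates):
            trough = int(candidates[-1])
        else:
            seg = phasic[seg_start : p + 1]
            trough = seg_start + int(np.flatnonzero(seg == seg.min())[-1])
        amp = phasic[p] - phasic[trough]
        if amp >= amp_threshold and trough < p:
            events.append(
                ScrEvent(
                    onset_index=int(trough),
                    peak_index=int(p),
                    amplitude=float(amp),
                    rise_time_s=float((p - trough) / fs),
                )
            )
        prev = p
    return events


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation between order stats
    return float(q3 - q1)


# GSR band conventions, Hz.
GSR_LOW_BAND = (0.0, 0.05)
GSR_PHASIC_BAND = (0.05, 1.5)


def gsr_linear_features(
    gsr: np.ndarray,
    tonic: np.ndarray,
    phasic: np.ndarray,
    events: list[ScrEvent],
    fs: float,
) -> dict[str, float]:
    """Nine linear GSR features: six time-domain, three spectral.

    Time domain: SCR count, mean SCR amplitude and rise time (0 with no
    events), raw mean, standard deviation and interquartile range.
    Spectral: tonic-component power in [0, 0.05) Hz, phasic-component power
    in [0.05, 1.5) Hz, and the fraction of total signal power below
    0.05 Hz (0 for a flat window).
    """
    gsr = np.asarray(gsr, dtype=float)
    total = band_power(gsr, fs, (0.0, fs / 2))
    low = band_power(gsr, fs, GSR_LOW_BAND)
    eps = 1e-15
    return {
        "n_scr": float(len(events)),
        "scr_amp_mean": float(np.mean([e.amplitude for e in events])) if events else 0.0,
        "scr_rise_mean": float(np.mean([e.rise_time_s for e in events])) if events else 0.0,
        "mean": float(np.mean(gsr)),
        "sd": float(np.std(gsr, ddof=1)),
        "iqr": _iqr(gsr),
        "tonic_power_low": band_power(tonic, fs, GSR_LOW_BAND),
        "phasic_power_band": band_power(phasic, fs, GSR_PHASIC_BAND),
        "ratio_low": low / total if total > eps else 0.0,
    }


SKT_BAND1 = (0.0, 0.1)
SKT_BAND2 = (0.1, 0.2)


def skt_features(skt: np.ndarray, fs: float) -> dict[str, float]:
    """Six SKT features: four moments and two low-frequency band powers.

    Skewness is the standardized third central moment; kurtosis is the
    Pearson (non-excess) standardized fourth moment.  A zero-variance
    window gets flagged zeros for both shape moments.
    """
    skt = np.asarray(skt, dtype=float)
    if skt.size == 0:
        raise ValidationError("empty SKT window")
    sd = float(np.std(skt, ddof=1)) if skt.size > 1 else 0.0
    degenerate = sd < 1e-12
    return {
        "mean": float(np.mean(skt)),
        "sd": sd,
        "skewness": 0.0 if degenerate else float(_skew(skt, bias=True)),
        "kurtosis": 0.0 if degenerate else float(_kurtosis(skt, fisher=False, bias=True)),
        "psd_000_010": band_power(skt, fs, SKT_BAND1),
        "psd_010_020": band_power(skt, fs, SKT_BAND2),
    }
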