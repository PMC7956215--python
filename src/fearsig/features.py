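"""Per-window 48-feature extraction and full-table orchestration.

The "paper-48" layout is 25 ECG + 17 GSR + 6 SKT features with fixed,
ordered names (see :data:`FEATURE_NAMES`).  GSR first/third quartiles are
merged into a single interquartile-range dispersion value; the
``"quartiles"`` profile emits them separately (49 columns) instead.

Degenerate windows (too few beats, zero variance, collapsed phase-space
geometry) never drop a row: the affected features are imputed as 0 so the
five-windows-per-trial geometry survives, and extraction is fully
deterministic — identical window samples give an identical vector.

ECG and GSR are decimated to 32 Hz before the non-linear block (embedding,
recurrence analysis, multiscale entropy, DFA, correlation dimension): the
dynamics of interest sit well below the decimated Nyquist and the
recurrence computations are quadratic in window length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from . import linear_features as lf
from . import nonlinear_features as nl
from .io import Sensor, Session, Trial, trim_recovery
from .labeling import binarize_pad
from .preprocessing import DEFAULT_CONFIG, PreprocConfig, filter_ecg, filter_lowpass, apply_agc
from .segmentation import Window, segment_trial

ECG_FEATURES = [
    "ecg.mean_ibi",
    "ecg.sdnn",
    "ecg.psd_000_010",
    "ecg.psd_010_020",
    "ecg.psd_020_030",
    "ecg.psd_030_040",
    "ecg.ibi_lf",
    "ecg.ibi_mf",
    "ecg.ibi_hf",
    "ecg.ibi_mf_ratio",
    "ecg.ibi_lf_hf_ratio",
    "ecg.mse_1",
    "ecg.mse_2",
    "ecg.mse_3",
    "ecg.mse_4",
    "ecg.mse_5",
    "ecg.dfa_raw",
    "ecg.dfa_ibi",
    "ecg.rqa_rr",
    "ecg.rqa_det",
    "ecg.rqa_lam",
    "ecg.rqa_lmax",
    "ecg.rqa_entropy",
    "ecg.rqa_tt",
    "ecg.corr_dim",
]

GSR_FEATURES = [
    "gsr.n_scr",
    "gsr.scr_amp_mean",
    "gsr.scr_rise_mean",
    "gsr.mean",
    "gsr.sd",
    "gsr.iqr",
    "gsr.tonic_power_low",
    "gsr.phasic_power_band",
    "gsr.ratio_low",
    "gsr.dfa",
    "gsr.rqa_rr",
    "gsr.rqa_det",
    "gsr.rqa_lam",
    "gsr.rqa_lmax",
    "gsr.rqa_entropy",
    "gsr.rqa_tt",
    "gsr.corr_dim",
]

SKT_FEATURES = [
    "skt.mean",
    "skt.sd",
    "skt.skewness",
    "skt.kurtosis",
    "skt.psd_000_010",
    "skt.psd_010_020",
]

#: Ordered, versioned "paper-48" feature registry: 25 ECG, 17 GSR, 6 SKT.
FEATURE_NAMES: list[str] = [*ECG_FEATURES, *GSR_FEATURES, *SKT_FEATURES]


def feature_names(profile: str = "paper-48") -> list[str]:
    """Feature registry for a layout profile (``"paper-48"`` or ``"quartiles"``)."""
    if profile == "paper-48":
        return list(FEATURE_NAMES)
    if profile == "quartiles":
        names = list(FEATURE_NAMES)
        i = names.index("gsr.iqr")
        return names[:i] + ["gsr.q1", "gsr.q3"] + names[i + 1 :]
    raise ValueError(f"unknown feature profile {profile!r}")


# Waveform PSD bands for ECG (Hz).
ECG_BANDS = [(0.0, 0.1), (0.1, 0.2), (0.2, 0.3), (0.3, 0.4)]


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of the extractor; defaults match the documented pipeline."""

    profile: str = "paper-48"
    median_window_s: float = 4.0  # tonic/phasic moving-median window
    scr_threshold_us: float = 0.01  # minimum SCR amplitude, microsiemens
    ibi_resample_hz: float = 4.0
    decimate_hz: float = 32.0  # rate for the non-linear block
    embed_max_lag: int = 32
    embed_max_dim: int = 6
    rqa_e_frac: float = 0.10
    rqa_l_min: int = 2
    rqa_v_min: int = 2
    rqa_theiler: int = 1
    mse_scales: int = 5
    mse_m: int = 2
    mse_r_frac: float = 0.2
    preproc: PreprocConfig = field(default_factory=PreprocConfig)


DEFAULT_FEATURE_CONFIG = FeatureConfig()


def _decimate(x: np.ndarray, fs: float, target_hz: float) -> tuple[np.ndarray, float]:
    factor = int(round(fs / target_hz))
    if factor <= 1:
        return x, fs
    return _signal.decimate(x, factor, ftype="fir", zero_phase=True), fs / factor


def _nonlinear_block(x: np.ndarray, cfg: FeatureConfig) -> dict[str, float]:
    """Delay embedding + RQA + correlation dimension on one decimated series.

    Returns rqa_* and corr_dim keys; degenerate geometry yields zeros.
    """
    out = {
        "rqa_rr": 0.0,
        "rqa_det": 0.0,
        "rqa_lam": 0.0,
        "rqa_lmax": 0.0,
        "rqa_entropy": 0.0,
        "rqa_tt": 0.0,
        "corr_dim": 0.0,
    }
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            delay = nl.estimate_delay(x, max_lag=cfg.embed_max_lag)
            dim = nl.estimate_dimension(x, delay, max_dim=cfg.embed_max_dim)
        # shrink the delay if the embedding would starve for points
        while len(x) - (dim - 1) * delay < 100 and delay > 1:
            delay //= 2
        emb = nl.embed(x, max(delay, 1), dim)
        rp = nl.recurrence_matrix(emb, e_frac=cfg.rqa_e_frac)
        rqa = nl.rqa_measures(rp, l_min=cfg.rqa_l_min, v_min=cfg.rqa_v_min, theiler=cfg.rqa_theiler)
        out.update(
            rqa_rr=rqa.recurrence_rate,
            rqa_det=rqa.determinism,
            rqa_lam=rqa.laminarity,
            rqa_lmax=rqa.longest_diagonal,
            rqa_entropy=rqa.diagonal_entropy,
            rqa_tt=rqa.trapping_time,
        )
        if len(emb.points) >= 100:
            out["corr_dim"] = nl.correlation_dimension(emb)
    except (nl.DegenerateSeriesError, ValueError):
        pass
    return out


def _safe(fn, default):
    try:
        return fn()
    except (lf.InsufficientBeatsError, nl.DegenerateSeriesError, ValueError):
        return default


def extract_window_features(
    window: Window, config: FeatureConfig = DEFAULT_FEATURE_CONFIG
) -> dict[str, float]:
    """Compute the ordered feature vector for one tri-channel window."""
    fs = window.sampling_rate
    cfg = config
    feats: dict[str, float] = {}

    # --- ECG ---------------------------------------------------------------
    ecg_raw = window.segments[Sensor.ECG]
    ecg_filt = filter_ecg(ecg_raw, fs, cfg.preproc)
    ecg_agc = _safe(lambda: apply_agc(ecg_filt, fs, cfg.preproc), None)

    ibi = None
    if ecg_agc is not None:
        ibi = _safe(lambda: lf.detect_r_peaks(ecg_agc, fs), None)
    if ibi is not None:
        tf = _safe(lambda: lf.ecg_time_features(ibi), {"mean_ibi": 0.0, "sdnn": 0.0})
        feats["ecg.mean_ibi"] = tf["mean_ibi"]
        feats["ecg.sdnn"] = tf["sdnn"]
        sf = _safe(
            lambda: lf.ibi_spectral_features(ibi, resample_hz=cfg.ibi_resample_hz),
            dict.fromkeys(["ibi_lf", "ibi_mf", "ibi_hf", "ibi_mf_ratio", "ibi_lf_hf_ratio"], 0.0),
        )
        for k, v in sf.items():
            feats[f"ecg.{k}"] = v
        feats["ecg.dfa_ibi"] = _safe(
            lambda: nl.dfa_alpha(lf.resample_ibi(ibi, cfg.ibi_resample_hz)), 0.0
        )
    else:
        for name in ("mean_ibi", "sdnn", "ibi_lf", "ibi_mf", "ibi_hf", "ibi_mf_ratio", "ibi_lf_hf_ratio", "dfa_ibi"):
            feats[f"ecg.{name}"] = 0.0

    for (low, high), name in zip(
        ECG_BANDS, ("psd_000_010", "psd_010_020", "psd_020_030", "psd_030_040")
    ):
        feats[f"ecg.{name}"] = lf.band_power(ecg_filt, fs, (low, high))

    ecg_dec, _dec_fs = _decimate(ecg_filt, fs, cfg.decimate_hz)
    mse = _safe(
        lambda: nl.multiscale_entropy(ecg_dec, cfg.mse_scales, cfg.mse_m, cfg.mse_r_frac),
        np.zeros(cfg.mse_scales),
    )
    for s in range(cfg.mse_scales):
        feats[f"ecg.mse_{s + 1}"] = float(mse[s])
    feats["ecg.dfa_raw"] = _safe(lambda: nl.dfa_alpha(ecg_dec), 0.0)
    for k, v in _nonlinear_block(ecg_dec, cfg).items():
        feats[f"ecg.{k}"] = v

    # --- GSR ---------------------------------------------------------------
    gsr_raw = window.segments[Sensor.GSR]
    gsr_filt = filter_lowpass(gsr_raw, fs, cfg.preproc.gsr_lowpass)
    tonic, phasic = lf.gsr_decompose(gsr_filt, fs, cfg.median_window_s)
    events = lf.detect_scrs(phasic, fs, cfg.scr_threshold_us)
    glin = lf.gsr_linear_features(gsr_filt, tonic, phasic, events, fs)
    for k, v in glin.items():
        feats[f"gsr.{k}"] = v
    if cfg.profile == "quartiles":
        q1, q3 = np.percentile(gsr_filt, [25, 75])
        del feats["gsr.iqr"]
        feats["gsr.q1"] = float(q1)
        feats["gsr.q3"] = float(q3)

    gsr_dec, _ = _decimate(gsr_filt, fs, cfg.decimate_hz)
    feats["gsr.dfa"] = _safe(lambda: nl.dfa_alpha(gsr_dec), 0.0)
    for k, v in _nonlinear_block(gsr_dec, cfg).items():
        feats[f"gsr.{k}"] = v

    # --- SKT ---------------------------------------------------------------
    skt_raw = window.segments[Sensor.SKT]
    skt_filt = filter_lowpass(skt_raw, fs, cfg.preproc.skt_lowpass)
    for k, v in lf.skt_features(skt_filt, fs).items():
        feats[f"skt.{k}"] = v

    ordered = feature_names(cfg.profile)
    return {name: float(feats[name]) for name in ordered}


def extract_feature_table(
    sessions: Iterable[Session],
    window_s: float = 20.0,
    overlap_s: float = 10.0,
    pre_trim_s: float = 30.0,
    post_trim_s: float = 30.0,
    midpoint: int = 5,
    config: FeatureConfig = DEFAULT_FEATURE_CONFIG,
) -> pd.DataFrame:
    """Run the full extraction chain over sessions into a feature table.

    Per trial: binarize the PAD self-report into a fear label, trim the
    recovery padding, segment into overlapping windows, and extract the
    feature vector of each window.  Returns one row per window with
    ``subject_id, trial_id, window_index, <features>, fear_label``.
    """
    rows = []
    names = feature_names(config.profile)
    for session in sessions:
        for trial in session.trials:
            label = binarize_pad(trial.report, midpoint=midpoint).value
            trimmed = trim_recovery(trial, pre_trim_s, post_trim_s)
            windows = segment_trial(
                trimmed, window_s, overlap_s, subject_id=session.subject_id, fear_label=label
            )
            for w in windows:
                feats = extract_window_features(w, config)
                rows.append(
                    {
                        "subject_id": session.subject_id,
                        "trial_id": trial.trial_id,
                        "window_index": w.window_index,
                        **feats,
                        "fear_label": label,
                    }
                )
    cols = ["subject_id", "trial_id", "window_index", *names, "fear_label"]
    return pd.DataFrame(rows, columns=cols)
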