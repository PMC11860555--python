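"""Windowed per-modality feature extraction into a labeled feature table.

The canonical feature set spans six modalities:

* ECG — statistics of the instantaneous heart-rate series derived from
  detected beats (``ECG_bpm``, ``ECG_min``, ``ECG_max``, ``ECG_std``);
* RESP — breath-cycle timing and raw-amplitude statistics, including the
  inhale/exhale duration ratio;
* EDA — window mean, max and dynamic range of skin conductance;
* BVP — dominant pulse frequency (periodogram argmax over 0.5-3.5 Hz) and max;
* TEMP — window mean skin temperature;
* ACC — wrist net-acceleration mean/std, wrist x-axis mean/min, chest x-axis
  std (``w`` = wrist device, ``C`` = chest device).

Windows default to 60 s length with a 30 s shift; each emitted row carries
the label of the condition interval covering the window midpoint.  Rows for
which any extractor fails (too few beats, no breath cycles, no in-band pulse
power) are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .exceptions import InvalidParameterError
from .peaks import PeakResult, ampd_detect, qrs_select, rr_to_hr
from .preprocess import ACC_CUTOFF_HZ, EDA_CUTOFF_HZ, lowpass_butterworth
from .simulate import MultimodalRecording

__all__ = [
    "WindowSpec",
    "FEATURE_NAMES",
    "FEATURE_MODALITY",
    "META_COLUMNS",
    "RowDrop",
    "ecg_features",
    "resp_features",
    "eda_features",
    "bvp_features",
    "temp_features",
    "acc_features",
    "extract_windows",
    "preprocess_recording",
    "cohort_to_table",
]

#: feature -> modality map (the rollup key for modality-level importance)
FEATURE_MODALITY: dict[str, str] = {
    "ECG_bpm": "ECG", "ECG_min": "ECG", "ECG_max": "ECG", "ECG_std": "ECG",
    "Resp_rate": "RESP", "Resp_mean": "RESP", "Resp_min": "RESP",
    "Resp_IE": "RESP", "Resp_Inhal_mean": "RESP", "Resp_Exhal_std": "RESP",
    "EDA_mean": "EDA", "EDA_max": "EDA", "EDA_drange": "EDA",
    "BVP_peak_freq": "BVP", "BVP_max": "BVP",
    "TEMP_mean": "TEMP",
    "ACC_net_w_mean": "ACC", "ACC_net_w_std": "ACC",
    "ACC_x_mean": "ACC", "ACC_x_min": "ACC", "ACC_x_C_std": "ACC",
}

FEATURE_NAMES: tuple[str, ...] = tuple(FEATURE_MODALITY)
META_COLUMNS: tuple[str, ...] = ("subject_id", "window_start_s", "subset", "label")


class RowDrop(Exception):
    """Signal that a window cannot yield a complete feature row."""


@dataclass
class WindowSpec:
    length_s: float = 60.0
    shift_s: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.shift_s <= self.length_s):
            raise InvalidParameterError("require 0 < shift_s <= length_s")


def ecg_features(peaks: PeakResult, start_s: float, length_s: float) -> dict[str, float]:
    """Instantaneous-HR statistics within the window (population std).

    The min/max/std are computed on the HR series, not raw ECG voltage: the
    features co-occur with the mean heart rate and follow time-domain HRV
    convention.  Requires >= 3 beats in the window.
    """
    sel = (peaks.times_s >= start_s) & (peaks.times_s <= start_s + length_s)
    times = peaks.times_s[sel]
    if times.size < 3:
        raise RowDrop("fewer than 3 beats in window")
    hr = rr_to_hr(np.diff(times))
    return {
        "ECG_bpm": float(hr.mean()),
        "ECG_min": float(hr.min()),
        "ECG_max": float(hr.max()),
        "ECG_std": float(hr.std()),
    }


def _breath_segments(x: np.ndarray, fs: float):
    """Breath boundaries from the smoothed, mean-removed window.

    Cycles are delimited by rising zero-crossings; within each cycle the peak
    marks end-of-inhale and the flanking troughs mark cycle turn-points, so
    inhale = trough-to-peak and exhale = peak-to-next-trough durations.
    """
    if x.size < int(2 * fs):
        raise RowDrop("respiration window too short")
    cutoff = min(1.5, 0.45 * fs)
    sm = lowpass_butterworth(x, fs, cutoff, order=2) if fs > 4 else x.astype(float)
    sm = sm - sm.mean()
    raw = x - x.mean()
    rising = np.flatnonzero((sm[:-1] < 0) & (sm[1:] >= 0)) + 1
    if rising.size < 3:
        raise RowDrop("fewer than 2 complete breath cycles")
    # Within each cycle [r_j, r_{j+1}) the volume-like waveform rises to its
    # peak (end of inhale) then falls to its trough (end of exhale).  Cycle
    # boundaries come from the smoothed signal (robust to noise); peak and
    # trough positions are refined on the raw signal, because smoothing a
    # flat-bottomed trough with unequal flank curvatures biases its argmin.
    peaks_i, troughs_i = [], []
    for a, b in zip(rising[:-1], rising[1:]):
        pk = a + int(np.argmax(raw[a:b]))
        tr = pk + int(np.argmin(raw[pk:b])) if pk < b else pk
        peaks_i.append(pk)
        troughs_i.append(tr)
    # inhale_j = trough_{j-1} -> peak_j ; exhale_j = peak_j -> trough_j
    inhale = (np.asarray(peaks_i[1:]) - np.asarray(troughs_i[:-1])) / fs
    exhale = (np.asarray(troughs_i) - np.asarray(peaks_i)) / fs
    return rising, inhale, exhale


def resp_features(series: np.ndarray, fs: float) -> dict[str, float]:
    """Breath-cycle timing plus raw-amplitude statistics."""
    x = np.asarray(series, float)
    rising, inhale, exhale = _breath_segments(x, fs)
    span_s = (rising[-1] - rising[0]) / fs
    n_cycles = rising.size - 1
    if n_cycles < 2 or span_s <= 0:
        raise RowDrop("fewer than 2 complete breath cycles")
    inhale = inhale[(inhale > 0)]
    exhale = exhale[(exhale > 0)]
    if inhale.size == 0 or exhale.size == 0 or exhale.mean() == 0:
        raise RowDrop("degenerate breath segmentation")
    return {
        "Resp_rate": 60.0 * n_cycles / span_s,
        "Resp_mean": float(x.mean()),
        "Resp_min": float(x.min()),
        "Resp_IE": float(inhale.mean() / exhale.mean()),
        "Resp_Inhal_mean": float(inhale.mean()),
        "Resp_Exhal_std": float(exhale.std()),
    }


def eda_features(series: np.ndarray) -> dict[str, float]:
    x = np.asarray(series, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise RowDrop("empty EDA window")
    return {
        "EDA_mean": float(x.mean()),
        "EDA_max": float(x.max()),
        "EDA_drange": float(x.max() - x.min()),
    }


_BVP_BAND = (0.5, 3.5)  # plausible pulse-rate band, Hz


def bvp_features(series: np.ndarray, fs: float) -> dict[str, float]:
    """Dominant pulse frequency from the periodogram over 0.5-3.5 Hz."""
    x = np.asarray(series, float)
    if x.size < int(10 * fs):
        raise RowDrop("BVP window shorter than 10 s")
    freqs, power = _signal.periodogram(x, fs=fs, detrend="constant")
    band = (freqs >= _BVP_BAND[0]) & (freqs <= _BVP_BAND[1])
    if not band.any() or power[band].max() <= 0:
        raise RowDrop("no in-band pulse power")
    return {
        "BVP_peak_freq": float(freqs[band][np.argmax(power[band])]),
        "BVP_max": float(x.max()),
    }


def temp_features(series: np.ndarray) -> dict[str, float]:
    x = np.asarray(series, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise RowDrop("empty TEMP window")
    return {"TEMP_mean": float(x.mean())}


def acc_features(chest_xyz: np.ndarray | None, wrist_xyz: np.ndarray) -> dict[str, float]:
    """Wrist net-acceleration and axis statistics, chest x-axis std."""
    wrist_xyz = np.asarray(wrist_xyz, float)
    if wrist_xyz.ndim != 2 or wrist_xyz.shape[0] != 3 or wrist_xyz.shape[1] == 0:
        raise RowDrop("wrist accelerometer window missing")
    net = np.sqrt((wrist_xyz ** 2).sum(axis=0))
    out = {
        "ACC_net_w_mean": float(net.mean()),
        "ACC_net_w_std": float(net.std()),
        "ACC_x_mean": float(wrist_xyz[0].mean()),
        "ACC_x_min": float(wrist_xyz[0].min()),
    }
    if chest_xyz is None:
        raise RowDrop("chest accelerometer window missing")
    chest_xyz = np.asarray(chest_xyz, float)
    out["ACC_x_C_std"] = float(chest_xyz[0].std())
    return out


def preprocess_recording(rec: MultimodalRecording) -> MultimodalRecording:
    """Apply the standard per-channel conditioning before feature extraction.

    EDA gets the 5 Hz low-pass and accelerometry the 13 Hz low-pass; a filter
    whose cutoff would reach the channel's Nyquist frequency is skipped (the
    band is then already limited by sampling).  Other channels pass through.
    """
    from .simulate import Channel  # local import to avoid cycle at module load

    channels = {}
    for name, ch in rec.channels.items():
        x = ch.samples
        cutoff = None
        if name == "EDA":
            cutoff = EDA_CUTOFF_HZ
        elif name.startswith("ACC"):
            cutoff = ACC_CUTOFF_HZ
        if cutoff is not None and cutoff < ch.fs / 2:
            x = lowpass_butterworth(x, ch.fs, cutoff)
        channels[name] = Channel(np.asarray(x, float), ch.fs)
    return MultimodalRecording(channels=channels, annotations=rec.annotations,
                               true_beats_s=rec.true_beats_s,
                               subject_id=rec.subject_id,
                               device_tag=dict(rec.device_tag),
                               meta=dict(rec.meta))


def _label_at(rec: MultimodalRecording, t_mid: float) -> int | None:
    from .dataset import LabelSpec, label_from_stai

    for iv in rec.annotations:
        if iv.start_s <= t_mid < iv.end_s or (t_mid == iv.end_s == rec.duration_s):
            return label_from_stai(iv.stai_y6, LabelSpec())
    return None


def _slice(ch, start_s: float, length_s: float) -> np.ndarray:
    i0 = int(round(start_s * ch.fs))
    i1 = int(round((start_s + length_s) * ch.fs))
    return ch.samples[i0:i1]


def extract_windows(rec: MultimodalRecording, spec: WindowSpec | None = None, *,
                    peaks: PeakResult | None = None, ampd_seed: int = 0,
                    subset: str | None = None,
                    drop_log: dict | None = None) -> pd.DataFrame:
    """Slide windows over a (preprocessed) recording and emit a feature table.

    ECG beats are detected once on the full record with windowed AMPD unless
    a precomputed :class:`~wearanx.peaks.PeakResult` is supplied.  Rows with
    any failed extractor or no covering annotation are dropped; counts go to
    ``drop_log`` when given.
    """
    spec = spec or WindowSpec()
    duration = rec.duration_s
    if spec.length_s > duration:
        raise InvalidParameterError("window longer than recording")
    if peaks is None:
        ecg = rec.channels["ECG"]
        detected = ampd_detect(ecg.samples, ecg.fs, seed=ampd_seed)
        peaks = qrs_select(ecg.samples, ecg.fs, detected)
    subset = subset if subset is not None else rec.meta.get("subset", "unknown")
    n_windows = int(np.floor((duration - spec.length_s) / spec.shift_s)) + 1
    rows, dropped = [], 0
    for w in range(n_windows):
        t0 = w * spec.shift_s
        label = _label_at(rec, t0 + spec.length_s / 2.0)
        if label is None:
            dropped += 1
            continue
        try:
            feats: dict[str, float] = {}
            feats.update(ecg_features(peaks, t0, spec.length_s))
            feats.update(resp_features(_slice(rec.channels["RESP"], t0, spec.length_s),
                                       rec.channels["RESP"].fs))
            feats.update(eda_features(_slice(rec.channels["EDA"], t0, spec.length_s)))
            feats.update(bvp_features(_slice(rec.channels["BVP"], t0, spec.length_s),
                                      rec.channels["BVP"].fs))
            feats.update(temp_features(_slice(rec.channels["TEMP"], t0, spec.length_s)))
            chest = np.stack([_slice(rec.channels[f"ACC_C_{a}"], t0, spec.length_s)
                              for a in "xyz"])
            wrist = np.stack([_slice(rec.channels[f"ACC_w_{a}"], t0, spec.length_s)
                              for a in "xyz"])
            feats.update(acc_features(chest, wrist))
        except RowDrop:
            dropped += 1
            continue
        if any(not np.isfinite(v) for v in feats.values()):
            dropped += 1
            continue
        rows.append({"subject_id": rec.subject_id, "window_start_s": t0,
                     "subset": subset, "label": label, **feats})
    if drop_log is not None:
        drop_log[rec.subject_id] = dropped
    cols = list(META_COLUMNS) + list(FEATURE_NAMES)
    return pd.DataFrame(rows, columns=cols)


def cohort_to_table(recordings, spec: WindowSpec | None = None, *,
                    preprocess: bool = True, ampd_seed: int = 0,
                    drop_log: dict | None = None) -> pd.DataFrame:
    """Feature table for a whole cohort (one row per emitted window)."""
    tables = []
    for rec in recordings:
        r = preprocess_recording(rec) if preprocess else rec
        tables.append(extract_windows(r, spec, ampd_seed=ampd_seed, drop_log=drop_log))
    return pd.concat(tables, ignore_index=True)
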