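"""Signal conditioning: zero-phase Butterworth filtering, Hampel outlier
removal, min-max normalization, anti-aliased downsampling, mean imputation
with segment dropping, and SNR-calibrated Gaussian noise injection.

All operations are length-preserving except :func:`downsample`.  Missing
samples are represented as NaN throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import (
    DegenerateRangeError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "NoiseSpec",
    "CleaningReport",
    "lowpass_butterworth",
    "remove_outliers",
    "minmax_normalize",
    "downsample",
    "impute_or_drop",
    "add_gaussian_noise",
    "butterworth_gain",
]

#: cutoff used for electrodermal activity, Hz
EDA_CUTOFF_HZ = 5.0
#: cutoff used for accelerometry, Hz
ACC_CUTOFF_HZ = 13.0
#: default filter order (applied forward-backward, so effective order doubles)
DEFAULT_ORDER = 4


@dataclass
class NoiseSpec:
    """Gaussian noise at a target linear signal-to-noise (variance) ratio."""

    snr_linear: float
    seed: int = 0
    channels: tuple[str, ...] | None = None  # None = all channels

    def __post_init__(self) -> None:
        if not (self.snr_linear > 0):
            raise InvalidParameterError("snr_linear must be > 0")


@dataclass
class CleaningReport:
    n_outliers_replaced: int = 0
    n_imputed: int = 0
    dropped: bool = False
    missing_frac: float = 0.0
    notes: list[str] = field(default_factory=list)


def butterworth_gain(f: float, cutoff: float, order: int, passes: int = 2) -> float:
    """Analytic Butterworth magnitude response ``|H(f)|`` after ``passes``
    applications (2 = zero-phase forward-backward)."""
    per_pass = 1.0 / math.sqrt(1.0 + (f / cutoff) ** (2 * order))
    return per_pass ** passes


def lowpass_butterworth(series: np.ndarray, fs: float, cutoff: float,
                        order: int = DEFAULT_ORDER) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The filter is applied twice via ``filtfilt``, so the net magnitude
    response is the squared single-pass response and the phase is zero.
    """
    series = np.asarray(series, float)
    if order < 1:
        raise InvalidParameterError("order must be >= 1")
    if not (0 < cutoff < fs / 2):
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={fs / 2} Hz)")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, series)


def remove_outliers(series: np.ndarray, window: int = 0, n_mad: float = 4.0,
                    fs: float | None = None) -> tuple[np.ndarray, CleaningReport]:
    """Hampel filter: mark points farther than ``n_mad`` scaled MADs from the
    centered rolling median as missing (NaN).

    ``window`` must be odd and >= 3; if 0 it defaults to ~1 s of samples when
    ``fs`` is given, else 7.  A zero rolling MAD degenerates gracefully: any
    deviation from the local median is then flagged, exact duplicates pass.
    """
    series = np.asarray(series, float)
    if window == 0:
        window = int(fs) | 1 if fs else 7
    window = max(window, 3)
    if window % 2 == 0 or window < 3:
        raise InvalidParameterError("window must be odd and >= 3")
    s = pd.Series(series)
    med = s.rolling(window, center=True, min_periods=1).median()
    abs_dev = (s - med).abs()
    mad = abs_dev.rolling(window, center=True, min_periods=1).median()
    threshold = n_mad * 1.4826 * mad
    # NaN-safe: an already-missing point is not counted as an outlier
    is_out = (abs_dev > threshold).to_numpy() & np.isfinite(series)
    out = series.copy()
    out[is_out] = np.nan
    return out, CleaningReport(n_outliers_replaced=int(is_out.sum()),
                               missing_frac=float(np.isnan(out).mean()))


def minmax_normalize(series: np.ndarray) -> np.ndarray:
    """Scale observed values to [0, 1] as ``(x - min) / (max - min)``.

    Missing values (NaN) propagate.  A constant series has no admissible
    scaling and raises :class:`DegenerateRangeError` — the caller decides
    whether to drop the segment.
    """
    series = np.asarray(series, float)
    finite = series[np.isfinite(series)]
    if finite.size < 2 or np.unique(finite).size < 2:
        raise DegenerateRangeError("series needs >= 2 distinct finite values")
    lo, hi = finite.min(), finite.max()
    return (series - lo) / (hi - lo)


def downsample(series: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased rate reduction with exact length ``floor(n * fs_out / fs_in)``.

    Integer ratios use polyphase decimation; non-integer ratios resample by a
    rational polyphase factor.
    """
    series = np.asarray(series, float)
    if fs_out > fs_in:
        raise InvalidParameterError("fs_out must not exceed fs_in")
    if fs_out <= 0:
        raise InvalidParameterError("fs_out must be > 0")
    n_out = int(math.floor(series.size * fs_out / fs_in))
    if fs_in == fs_out:
        return series.copy()
    # rational approximation of the rate ratio
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    out = signal.resample_poly(series, frac.numerator, frac.denominator)
    return out[:n_out]


def impute_or_drop(series: np.ndarray, max_missing_frac: float = 0.2
                   ) -> tuple[np.ndarray, CleaningReport]:
    """Replace missing points with the segment mean of observed points, or
    flag the segment as dropped when too much is missing.

    The observed-sample mean of the segment is preserved exactly by mean
    imputation.
    """
    if not (0 < max_missing_frac < 1):
        raise InvalidParameterError("max_missing_frac must lie in (0, 1)")
    series = np.asarray(series, float)
    missing = ~np.isfinite(series)
    frac = float(missing.mean()) if series.size else 1.0
    if frac == 0.0:
        return series.copy(), CleaningReport(missing_frac=0.0)
    if frac > max_missing_frac or frac == 1.0:
        return series.copy(), CleaningReport(
            dropped=True, missing_frac=frac,
            notes=["missing fraction exceeds threshold" if frac < 1.0
                   else "segment fully missing"])
    out = series.copy()
    out[missing] = series[~missing].mean()
    return out, CleaningReport(n_imputed=int(missing.sum()), missing_frac=frac)


def add_gaussian_noise(series: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Add zero-mean Gaussian noise with variance ``var(series) / snr_linear``.

    The SNR is a linear power (variance) ratio; ``snr_linear=inf`` is the
    zero-noise limit and returns the series unchanged.
    """
    series = np.asarray(series, float)
    if not np.isfinite(spec.snr_linear):
        return series.copy()
    var = float(np.nanvar(series))
    if var == 0.0:
        raise InvalidInputError("series is constant; SNR is undefined")
    sigma = math.sqrt(var / spec.snr_linear)
    rng = np.random.default_rng(spec.seed)
    return series + rng.normal(0.0, sigma, series.shape)
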