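"""Bilateral structure of ongoing activity.

Decomposes paired left/right traces into symmetric ((L+R)/2) and asymmetric
((L-R)/2) components and their per-frequency power fractions, computes
seed-correlation maps, tabulates homotopic correlation against midline
distance (with a linear fit excluding designated outlier areas), and
estimates the interhemispheric cross-correlation function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import signal, stats

from .areas import AreaSet

WELCH_SEGMENT_S = 2.0  # Hann windows, 50% overlap


@dataclass(frozen=True)
class SymAsymDecomposition:
    """sym + asym reconstructs left; sym - asym reconstructs right."""

    sym: np.ndarray
    asym: np.ndarray
    freqs: np.ndarray
    rel_power_sym: np.ndarray
    rel_power_asym: np.ndarray


def decompose_sym_asym(left: np.ndarray, right: np.ndarray, fs: float = 35.0) -> SymAsymDecomposition:
    """Symmetric/asymmetric decomposition with per-frequency power fractions.

    The per-frequency total is PSD(sym) + PSD(asym), which by Parseval
    equals (PSD(L) + PSD(R))/2; the two relative powers sum to 1 at every
    frequency with nonzero total (zero-total bins are NaN).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right traces must have equal length")
    sym = (left + right) / 2.0
    asym = (left - right) / 2.0
    nperseg = min(int(WELCH_SEGMENT_S * fs), len(left))
    freqs, psd_sym = signal.welch(sym, fs=fs, window="hann", nperseg=nperseg)
    _, psd_asym = signal.welch(asym, fs=fs, window="hann", nperseg=nperseg)
    total = psd_sym + psd_asym
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_sym = np.where(total > 0, psd_sym / total, np.nan)
        rel_asym = np.where(total > 0, psd_asym / total, np.nan)
    return SymAsymDecomposition(sym, asym, freqs, rel_sym, rel_asym)


def _pearson_rows(seed_trace: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Pearson r of one trace against every row; zero-variance rows are NaN."""
    s = seed_trace - seed_trace.mean()
    s_sd = s.std()
    if s_sd == 0:
        raise ValueError("seed trace has zero variance")
    t = targets - targets.mean(axis=1, keepdims=True)
    t_sd = t.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (t @ s) / (len(s) * t_sd * s_sd)
    r[t_sd == 0] = np.nan
    return r


def seed_correlation_map(
    data: np.ndarray,
    seed: Union[int, str],
    areas: Optional[AreaSet] = None,
    image_shape: Optional[tuple[int, int]] = None,
) -> Union[pd.Series, np.ndarray]:
    """Correlation of a seed area's trace against all traces or pixels.

    ``data`` is area x frame (seed by name or row index; returns a Series)
    or pixel x frame with ``image_shape`` (seed is the mean trace of the
    named area's mask; returns an H x W map). Zero-variance targets come
    back as NaN, never silently 0; the seed's own entry is 1.
    """
    data = np.asarray(data, dtype=float)
    if image_shape is None:
        if isinstance(seed, str):
            if areas is None:
                raise ValueError("area-name seed requires an AreaSet")
            seed_idx = areas.index(seed)
        else:
            seed_idx = int(seed)
        r = _pearson_rows(data[seed_idx], data)
        index = areas.names if areas is not None else np.arange(len(data))
        return pd.Series(r, index=index, name=f"seed={seed}")
    if areas is None or not isinstance(seed, str):
        raise ValueError("pixel-level maps need an AreaSet and a seed area name")
    mask = areas[seed].mask
    if mask is None:
        raise ValueError(f"seed area {seed} has no mask")
    seed_trace = data[mask.ravel()].mean(axis=0)
    return _pearson_rows(seed_trace, data).reshape(image_shape)


def bilateral_correlation_by_area(
    roi_traces: np.ndarray,
    areas: AreaSet,
    frames: Optional[np.ndarray] = None,
    condition: Optional[str] = None,
) -> pd.DataFrame:
    """Pearson r per homotopic pair vs midline distance.

    ``frames`` optionally restricts the computation to a frame subset (e.g.
    the frames of one behavioral condition); ``condition`` only labels the
    output. Undefined correlations (zero variance) propagate as NaN.
    """
    data = np.asarray(roi_traces, dtype=float)
    if frames is not None:
        data = data[:, np.asarray(frames)]
    rows = []
    for base in areas.bases:
        left_name, right_name = f"{base}_L", f"{base}_R"
        if right_name not in areas:
            raise KeyError(f"area {left_name} has no homotopic partner")
        lt = data[areas.index(left_name)]
        rt = data[areas.index(right_name)]
        if lt.std() == 0 or rt.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(lt, rt)[0, 1])
        rows.append(dict(area=base, distance_mm=areas[left_name].distance_mm,
                         r=r, condition=condition))
    return pd.DataFrame(rows)


def fit_correlation_vs_distance(
    table: pd.DataFrame, exclude: Sequence[str] = ()
) -> tuple[float, float]:
    """OLS line of homotopic correlation on midline distance.

    ``exclude`` drops the designated outlier areas (e.g. monocular V1 and,
    in the active condition, secondary motor cortex) before fitting.
    Returns (slope, intercept).
    """
    sub = table[~table["area"].isin(exclude)].dropna(subset=["r"])
    if len(sub) < 2:
        raise ValueError("need at least 2 non-excluded areas to fit a line")
    res = stats.linregress(sub["distance_mm"].to_numpy(), sub["r"].to_numpy())
    return float(res.slope), float(res.intercept)


def interhemispheric_xcorr(
    left: np.ndarray, right: np.ndarray, max_lag_s: float, fs: float
) -> pd.DataFrame:
    """Normalized cross-correlation of homotopic traces over +/- max_lag_s.

    r(k) is the Pearson correlation of the overlapping segments at lag k
    (positive lag: right leads), so r(0) is the plain Pearson r and the
    function is symmetric when left equals right.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("traces must have equal length")
    max_lag = int(round(max_lag_s * fs))
    if max_lag < 1:
        raise ValueError("max_lag_s * fs must be >= 1")
    if len(left) <= max_lag + 1:
        raise ValueError("traces shorter than the maximum lag")
    lags = np.arange(-max_lag, max_lag + 1)
    rs = np.empty(len(lags))
    for j, k in enumerate(lags):
        if k >= 0:
            a, b = left[: len(left) - k], right[k:]
        else:
            a, b = left[-k:], right[: len(right) + k]
        rs[j] = np.corrcoef(a, b)[0, 1]
    return pd.DataFrame({"lag_s": lags / fs, "r": rs})
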