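"""Signal conditioning for dual-channel widefield movies.

The reference chain for calcium data is: SVD compression of the movie,
regression-based hemodynamic correction of the signal channel against the
artifact channel, a temporal derivative with rectification (to sharpen the
slow indicator kinetics into spiking-like transients), and a 7 Hz zero-phase
lowpass to attenuate heartbeat components.

All filters are 4th-order Butterworth applied forward-backward (zero phase);
frames are 0-based and every time window is half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
from scipy import signal

from .areas import AreaSet

logger = logging.getLogger(__name__)

DEFAULT_RANK = 500       # movie compression rank
DEFAULT_CUTOFF_HZ = 7.0  # heartbeat-attenuating lowpass
FILTER_ORDER = 4


@dataclass(frozen=True)
class CompressedMovie:
    """Truncated SVD of a pixel x frame movie.

    Reconstruction is ``spatial @ diag(singular_values) @ temporal``.
    """

    spatial_components: np.ndarray   # pixel x k
    singular_values: np.ndarray      # k
    temporal_components: np.ndarray  # k x frame
    fs: float

    def __post_init__(self) -> None:
        s = self.singular_values
        if np.any(np.diff(s) > 1e-9 * max(1.0, float(s[0]))):
            raise ValueError("singular values must be non-increasing")

    @property
    def rank(self) -> int:
        return len(self.singular_values)

    def reconstruct(self) -> np.ndarray:
        return (self.spatial_components * self.singular_values) @ self.temporal_components


def svd_compress(movie: np.ndarray, rank: int = DEFAULT_RANK, fs: float = 35.0) -> CompressedMovie:
    """Compress a pixel x frame movie to its top ``rank`` singular triplets.

    The Frobenius reconstruction error equals the root-sum-square of the
    discarded singular values. A rank above ``min(movie.shape)`` is clipped
    with a warning.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 2:
        raise ValueError("movie must be a 2-D pixel x frame array")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    max_rank = min(movie.shape)
    if rank > max_rank:
        logger.warning("rank %d exceeds min(movie dims)=%d; clipping", rank, max_rank)
        rank = max_rank
    u, s, vt = np.linalg.svd(movie, full_matrices=False)
    return CompressedMovie(
        spatial_components=np.ascontiguousarray(u[:, :rank]),
        singular_values=s[:rank].copy(),
        temporal_components=np.ascontiguousarray(vt[:rank]),
        fs=float(fs),
    )


def hemodynamic_correct(signal_trace: np.ndarray, artifact_trace: np.ndarray) -> np.ndarray:
    """Subtract the artifact channel scaled by its regression coefficient.

    beta is the least-squares slope of (mean-centered) signal on artifact;
    the returned trace is ``signal - beta * artifact`` and has zero sample
    covariance with the artifact. A constant artifact yields beta = 0 with a
    warning (nothing to regress out).
    """
    s = np.asarray(signal_trace, dtype=float)
    a = np.asarray(artifact_trace, dtype=float)
    if s.shape != a.shape or s.ndim != 1 or len(s) < 2:
        raise ValueError("signal and artifact must be equal-length 1-D traces (n >= 2)")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(a))):
        raise ValueError("traces must be finite")
    ac = a - a.mean()
    var = float(ac @ ac)
    if var == 0.0:
        logger.warning("constant artifact trace; beta set to 0, no subtraction")
        return s.copy()
    beta = float((s - s.mean()) @ ac) / var
    return s - beta * a


def derivative_rectify(trace: np.ndarray, fs: float) -> np.ndarray:
    """Forward first difference scaled by fs, negatives zeroed; length n-1."""
    t = np.asarray(trace, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("trace must be 1-D with length >= 2")
    return np.maximum(np.diff(t) * fs, 0.0)


def _sos_lowpass(cutoff: float, fs: float):
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2); got {cutoff} at fs={fs}")
    return signal.butter(FILTER_ORDER, cutoff, btype="low", fs=fs, output="sos")


def _sos_bandpass(low: float, high: float, fs: float):
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band edges must satisfy 0 < low < high < fs/2; got ({low}, {high})")
    return signal.butter(FILTER_ORDER, (low, high), btype="band", fs=fs, output="sos")


def lowpass(trace: np.ndarray, cutoff: float = DEFAULT_CUTOFF_HZ, fs: float = 35.0) -> np.ndarray:
    """Zero-phase Butterworth lowpass (DC gain 1, no phase shift)."""
    t = np.atleast_2d(np.asarray(trace, dtype=float))
    out = signal.sosfiltfilt(_sos_lowpass(cutoff, fs), t, axis=-1)
    return out[0] if np.asarray(trace).ndim == 1 else out


def bandpass(trace: np.ndarray, low: float = 2.0, high: float = 7.0, fs: float = 35.0) -> np.ndarray:
    """Zero-phase Butterworth bandpass; the 2-7 Hz band is the ongoing-activity band."""
    t = np.atleast_2d(np.asarray(trace, dtype=float))
    out = signal.sosfiltfilt(_sos_bandpass(low, high, fs), t, axis=-1)
    return out[0] if np.asarray(trace).ndim == 1 else out


def lowpass_frequency_response(cutoff: float, fs: float, freqs: np.ndarray) -> np.ndarray:
    """|H(f)|^2-effective gain of the forward-backward lowpass at ``freqs``."""
    sos = _sos_lowpass(cutoff, fs)
    w, h = signal.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs) / fs)
    return np.abs(h) ** 2  # filtfilt applies the filter twice


def extract_roi_traces(
    movie: Union[np.ndarray, CompressedMovie],
    areas: AreaSet,
    image_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-frame mean over each area mask; rows follow the AreaSet order.

    ``movie`` is either a frames x H x W stack, a pixel x frame matrix (with
    ``image_shape`` giving (H, W)), or a CompressedMovie (extraction is done
    in the compressed basis and equals extraction on the reconstruction).
    """
    if isinstance(movie, CompressedMovie):
        traces = []
        for area in areas:
            flat = _flat_mask(area, image_shape)
            u_mean = movie.spatial_components[flat].mean(axis=0)
            traces.append((u_mean * movie.singular_values) @ movie.temporal_components)
        return np.array(traces)

    arr = np.asarray(movie, dtype=float)
    if arr.ndim == 3:
        n_frames, h, w = arr.shape
        flat_movie = arr.reshape(n_frames, h * w).T  # pixel x frame
        image_shape = (h, w)
    elif arr.ndim == 2:
        if image_shape is None:
            raise ValueError("pixel x frame movie requires image_shape")
        flat_movie = arr
    else:
        raise ValueError("movie must be 2-D or 3-D")
    traces = []
    for area in areas:
        flat = _flat_mask(area, image_shape)
        traces.append(flat_movie[flat].mean(axis=0))
    return np.array(traces)


def _flat_mask(area, image_shape) -> np.ndarray:
    if area.mask is None:
        raise ValueError(f"area {area.name} has no mask")
    mask = np.asarray(area.mask, dtype=bool)
    if image_shape is not None and mask.shape != tuple(image_shape):
        raise ValueError(f"mask for {area.name} does not match image shape {image_shape}")
    flat = mask.ravel()
    if not flat.any():
        raise ValueError(f"empty mask for area {area.name}")
    return flat


CHAIN_STEPS = ("correct", "deriv", "lowpass")


def apply_chain(
    signal_trace: np.ndarray,
    artifact_trace: np.ndarray | None,
    fs: float,
    chain: Iterable[str] = CHAIN_STEPS,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> np.ndarray:
    """Run the configured conditioning chain on one trace; order is logged.

    Steps: ``correct`` (hemodynamic regression against the artifact channel),
    ``deriv`` (derivative + rectification; shortens the trace by one sample),
    ``lowpass`` (zero-phase filter at ``cutoff_hz``).
    """
    chain = list(chain)
    unknown = set(chain) - set(CHAIN_STEPS)
    if unknown:
        raise ValueError(f"unknown chain steps: {sorted(unknown)}")
    logger.info("preprocess chain: %s (fs=%g Hz, cutoff=%g Hz)", "->".join(chain), fs, cutoff_hz)
    out = np.asarray(signal_trace, dtype=float)
    art = None if artifact_trace is None else np.asarray(artifact_trace, dtype=float)
    for step in chain:
        if step == "correct":
            if art is None:
                raise ValueError("'correct' step requires an artifact trace")
            out = hemodynamic_correct(out, art[: len(out)])
        elif step == "deriv":
            out = derivative_rectify(out, fs)
        elif step == "lowpass":
            out = lowpass(out, cutoff_hz, fs)
    return out
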