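"""Seeded synthetic dual-hemisphere widefield sessions.

The generator produces the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any recorded data:

* per-area ongoing fluctuations band-limited to ~2-7 Hz, shared between the
  two hemispheres with an area-specific coupling ``rho_a`` that decreases
  with distance from the midline (designated exception areas excepted);
* unilateral, purely contralateral evoked responses rising 50-150 ms after
  stimulus onset, with window-mean amplitude following the Naka-Rushton
  contrast-response function;
* an additive combination of the two with a known mixing weight ``h_true``
  between a target area and its homotopic partner;
* a slow hemodynamic artifact mixed into the signal channel and reproduced
  in a second (artifact) channel;
* choices sampled from the 2AUC observer model, hence conditionally
  independent of the ongoing fluctuation by construction.

One ``SeedSequence`` per session is split into named substreams
(fluctuations, artifact, measurement noise, trial layout, choices, amplitude
noise, rendering), so the random draws of each component do not depend on
the others' parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .areas import AreaSet
from .evoked import NakaRushtonParams, naka_rushton
from .observer import GParams, ObserverFit, simulate_choices
from .preprocess import bandpass, lowpass

SeedLike = Union[int, np.random.SeedSequence]


@dataclass(frozen=True)
class AreaSpec:
    """Generative spec of one bilateral area pair.

    rho is the left-right coupling of the ongoing fluctuation (Pearson
    correlation of the two hemispheres' traces). rho_passive optionally
    overrides it in the passive condition (secondary motor cortex couples
    more strongly when the animal is not engaged in the task).
    """

    name: str
    distance_mm: float
    rho: float
    rho_passive: Optional[float] = None

    def coupling(self, condition: str) -> float:
        if condition == "passive" and self.rho_passive is not None:
            return self.rho_passive
        return self.rho


@dataclass
class GroundTruth:
    """All generative parameters of a synthetic session."""

    areas: list[AreaSpec] = field(default_factory=lambda: list(DEFAULT_AREAS))
    fs: float = 35.0
    nr: NakaRushtonParams = field(default_factory=lambda: NakaRushtonParams(0.0, 1.0, 0.3, 2.0))
    h_true: float = 0.8
    target_area: str = "PM"
    coupling_decay_mm: float = 2.0   # decay length (mm) of shared variance across areas
    band: tuple[float, float] = (2.0, 7.0)
    evoked_onset: float = 0.05       # s after stimulus onset
    evoked_peak: float = 0.15        # s; plateau reached here
    noise_sd: float = 0.1            # measurement noise on ROI traces (fluctuation SD is 1)
    amp_noise_sd: float = 0.0        # trial-by-trial evoked-amplitude noise (fractional)
    artifact_gain: float = 0.3       # hemodynamic contamination of the signal channel
    observer_b: float = -1.0
    observer_s: float = 4.0
    observer_g: GParams = field(default_factory=lambda: GParams(0.0, 1.0, 0.3, 2.0))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.areas:
            raise ValueError("at least one area is required")
        names = [a.name for a in self.areas]
        if len(set(names)) != len(names):
            raise ValueError("duplicate area names")
        for a in self.areas:
            if not np.isfinite(a.rho) or not 0 <= a.rho <= 1:
                raise ValueError(f"rho for {a.name} must be in [0, 1]")
            if not np.isfinite(a.distance_mm) or a.distance_mm < 0:
                raise ValueError(f"distance for {a.name} must be finite and >= 0")
        if not 0 < self.h_true <= 1:
            raise ValueError("h_true must lie in (0, 1]")
        if not (0 < self.nr.c50 <= 1 and self.nr.n > 0 and self.nr.rmax >= 0):
            raise ValueError("Naka-Rushton parameters out of range")
        if self.fs <= 0 or not np.isfinite(self.fs):
            raise ValueError("fs must be positive")
        if not 0 <= self.evoked_onset < self.evoked_peak:
            raise ValueError("need 0 <= evoked_onset < evoked_peak")
        if self.coupling_decay_mm <= 0:
            raise ValueError("coupling_decay_mm must be positive")

    @property
    def base_names(self) -> list[str]:
        return [a.name for a in self.areas]

    def area_set(self) -> AreaSet:
        return AreaSet.bilateral(self.base_names, [a.distance_mm for a in self.areas])

    def observer_fit(self) -> ObserverFit:
        return ObserverFit(b=self.observer_b, s=self.observer_s, g=self.observer_g)


# Default cortical layout: coupling decreases with midline distance, with
# V1m (monocular V1) as a standing exception and M2 coupling reduced during
# task engagement relative to the passive condition.
DEFAULT_AREAS: tuple[AreaSpec, ...] = (
    AreaSpec("M2", 0.9, 0.60, rho_passive=0.88),
    AreaSpec("PM", 1.6, 0.80),
    AreaSpec("AM", 2.0, 0.75),
    AreaSpec("V1", 2.6, 0.65),
    AreaSpec("V1m", 2.9, 0.35),
    AreaSpec("RL", 3.2, 0.55),
    AreaSpec("AL", 3.6, 0.50),
    AreaSpec("LM", 4.0, 0.45),
)


@dataclass
class ImagingSession:
    """Dual-channel movie: frames x H x W per channel, plus channel roles."""

    signal: np.ndarray
    artifact: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.signal.shape != self.artifact.shape:
            raise ValueError("channels must share a shape")


@dataclass
class SyntheticSession:
    """A generated session: ground truth plus everything an analysis reads."""

    truth: GroundTruth
    areas: AreaSet
    trials: pd.DataFrame
    roi_traces: np.ndarray          # noiseless fluctuation + evoked, area x frame
    measured: np.ndarray            # signal-channel ROI traces (noise + artifact added)
    measured_artifact: np.ndarray   # artifact-channel ROI traces
    fs: float
    movie: Optional[ImagingSession] = None

    @property
    def n_frames(self) -> int:
        return self.roi_traces.shape[1]

    def trace(self, area_name: str, which: str = "measured") -> np.ndarray:
        idx = self.areas.index(area_name)
        source = {
            "measured": self.measured,
            "truth": self.roi_traces,
            "artifact": self.measured_artifact,
        }[which]
        return source[idx]


def _seedseq(seed: SeedLike) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


def _band_limited(white: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Zero-phase bandpass then per-row z-score: unit-variance 2-7 Hz noise."""
    filtered = bandpass(white, band[0], band[1], fs)
    filtered = np.atleast_2d(filtered)
    filtered -= filtered.mean(axis=1, keepdims=True)
    sd = filtered.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return filtered / sd


def generate_bilateral_fluctuations(
    truth: GroundTruth,
    n_frames: int,
    seed: SeedLike,
    condition: str = "active",
) -> np.ndarray:
    """Ongoing bilateral fluctuations, rows ordered ``<base>_L, <base>_R`` per area.

    For each area pair, left = sqrt(rho)*common + sqrt(1-rho)*private (and
    symmetrically for right), every component being zero-mean unit-variance
    band-limited noise, so the expected Pearson correlation of the pair is
    rho. The target area instead uses the directional mix
    ``L = h*R + sqrt(1-h^2)*private`` whose regression slope (either
    direction, unit variances) and Pearson correlation both equal h_true.
    Common components of different areas are themselves correlated as
    exp(-d / (2*lambda)) in the mediolateral separation d, so shared variance
    decays with length constant ``coupling_decay_mm``.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    truth.validate()
    rng = np.random.default_rng(_seedseq(seed))
    bases = truth.areas
    n_bases = len(bases)

    # white-noise building blocks; correlations are shaped in the white
    # domain and preserved by the (linear) band-limiting filter
    commons = rng.standard_normal((n_bases, n_frames))
    privates = rng.standard_normal((2 * n_bases, n_frames))

    try:
        t_idx = truth.base_names.index(truth.target_area)
    except ValueError:
        t_idx = 0
    d_target = bases[t_idx].distance_mm
    ref = commons[t_idx].copy()
    for i, spec in enumerate(bases):
        if i == t_idx:
            continue
        gamma = float(np.exp(-abs(spec.distance_mm - d_target) / (2.0 * truth.coupling_decay_mm)))
        commons[i] = gamma * ref + np.sqrt(1.0 - gamma**2) * commons[i]

    traces = np.empty((2 * n_bases, n_frames))
    for i, spec in enumerate(bases):
        rho = spec.coupling(condition)
        if i == t_idx:
            h = truth.h_true
            right = commons[i]
            left = h * right + np.sqrt(max(0.0, 1.0 - h**2)) * privates[2 * i]
        else:
            sq_c, sq_p = np.sqrt(rho), np.sqrt(1.0 - rho)
            left = sq_c * commons[i] + sq_p * privates[2 * i]
            right = sq_c * commons[i] + sq_p * privates[2 * i + 1]
        traces[2 * i] = left
        traces[2 * i + 1] = right
    return _band_limited(traces, truth.band, truth.fs)


def evoked_time_course(
    contrast: float,
    t,
    truth: GroundTruth,
    nr: Optional[NakaRushtonParams] = None,
) -> np.ndarray:
    """Contralateral evoked waveform at time(s) ``t`` (seconds from onset).

    A piecewise-linear ramp from ``evoked_onset`` to ``evoked_peak`` followed
    by a plateau; the plateau is twice the Naka-Rushton amplitude so that the
    mean over the analysis window [onset, peak) equals R(c) exactly.
    """
    if not 0 <= contrast <= 1:
        raise ValueError(f"contrast must lie in [0, 1]; got {contrast}")
    nr = nr or truth.nr
    amp = 2.0 * naka_rushton(contrast, nr.r0, nr.rmax, nr.c50, nr.n)
    t = np.asarray(t, dtype=float)
    ramp = np.clip((t - truth.evoked_onset) / (truth.evoked_peak - truth.evoked_onset), 0.0, 1.0)
    return amp * ramp


# evoked response decays back to baseline after the plateau so consecutive
# trials do not accumulate
_PLATEAU_END_S = 0.45
_DECAY_S = 0.25


def _evoked_trial_waveform(contrast: float, n_samples: int, truth: GroundTruth) -> np.ndarray:
    t = np.arange(n_samples) / truth.fs
    wave = evoked_time_course(contrast, t, truth)
    decay = np.clip(1.0 - (t - _PLATEAU_END_S) / _DECAY_S, 0.0, 1.0)
    return wave * decay


def generate_session(
    truth: GroundTruth,
    n_trials: int,
    contrast_set: Sequence[float],
    seed: SeedLike,
    iti_s: float = 2.0,
    pre_s: float = 1.0,
    condition: str = "active",
    image_shape: Optional[tuple[int, int]] = None,
    pixel_noise_sd: float = 0.02,
) -> SyntheticSession:
    """Generate a full session; all randomness derives from ``seed``.

    Contrasts are balanced across trials (round-robin, shuffled), stimulus
    side is random, and choices are drawn from the observer model given the
    trial contrasts alone. Trial onsets are spaced ``iti_s`` apart, which
    must exceed the epoching window used downstream.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    contrast_set = sorted(set(float(c) for c in contrast_set))
    if not contrast_set or 0.0 not in contrast_set:
        raise ValueError("contrast_set must be non-empty and include 0 "
                         "(the additive-model training set needs 0% trials)")
    truth.validate()
    fs = truth.fs
    ss = _seedseq(seed)
    s_fluct, s_artifact, s_noise, s_trials, s_choices, s_amp, s_render = ss.spawn(7)

    n_frames = int(round((pre_s + n_trials * iti_s + 1.0) * fs))
    onsets = (pre_s * fs + np.arange(n_trials) * iti_s * fs).round().astype(int)

    fluct = generate_bilateral_fluctuations(truth, n_frames, s_fluct, condition)
    areas = truth.area_set()

    rng_tr = np.random.default_rng(s_trials)
    contrasts = np.resize(np.array(contrast_set), n_trials)
    rng_tr.shuffle(contrasts)
    # stimulus side balanced within each contrast level, as in the task
    sides = np.empty(n_trials, dtype=object)
    for level in contrast_set:
        idx = np.nonzero(contrasts == level)[0]
        assignment = np.resize(np.array(["L", "R"]), len(idx))
        rng_tr.shuffle(assignment)
        sides[idx] = assignment
    sides = sides.astype(str)

    trials = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "onset_frame": onsets,
            "side": sides,
            "contrast": contrasts,
            "condition": condition,
        }
    )
    trials["choice"] = simulate_choices(
        trials, truth.observer_fit(), np.random.default_rng(s_choices)
    )
    trials = trials[["trial", "onset_frame", "side", "contrast", "choice", "condition"]]

    # contralateral evoked responses, added to every visual area of the
    # hemisphere opposite the stimulated visual field
    roi = fluct.copy()
    n_ev = int(round((_PLATEAU_END_S + _DECAY_S) * fs)) + 1
    rng_amp = np.random.default_rng(s_amp)
    amp_factors = np.maximum(0.0, 1.0 + truth.amp_noise_sd * rng_amp.standard_normal(n_trials))
    hemi_rows = {
        "L": [i for i, name in enumerate(areas.names) if name.endswith("_L")],
        "R": [i for i, name in enumerate(areas.names) if name.endswith("_R")],
    }
    for i in range(n_trials):
        c = contrasts[i]
        if c <= 0:
            continue
        wave = _evoked_trial_waveform(c, n_ev, truth) * amp_factors[i]
        contra = "R" if sides[i] == "L" else "L"
        sl = slice(onsets[i], min(onsets[i] + n_ev, n_frames))
        roi[hemi_rows[contra], sl] += wave[: sl.stop - sl.start]

    rng_art = np.random.default_rng(s_artifact)
    artifact = lowpass(rng_art.standard_normal(n_frames), cutoff=0.5, fs=fs)
    sd = artifact.std()
    if sd > 0:
        artifact = (artifact - artifact.mean()) / sd

    rng_noise = np.random.default_rng(s_noise)
    measured = (
        roi
        + truth.noise_sd * rng_noise.standard_normal(roi.shape)
        + truth.artifact_gain * artifact[None, :]
    )
    measured_artifact = artifact[None, :] + 0.01 * rng_noise.standard_normal(roi.shape)

    movie = None
    if image_shape is not None:
        masks = default_masks(areas, image_shape)
        areas = areas.with_masks(masks)
        rng_px = np.random.default_rng(s_render)
        movie = ImagingSession(
            signal=render_movie(measured, areas, image_shape, pixel_noise_sd, rng_px),
            artifact=render_movie(measured_artifact, areas, image_shape, pixel_noise_sd, rng_px),
            fs=fs,
        )
    return SyntheticSession(
        truth=truth, areas=areas, trials=trials, roi_traces=roi,
        measured=measured, measured_artifact=measured_artifact, fs=fs, movie=movie,
    )


def default_masks(areas: AreaSet, image_shape: tuple[int, int]) -> dict:
    """Disjoint rectangular masks: one row per base area, mirrored columns.

    The horizontal pixel offset from the vertical midline is proportional to
    the area's midline distance, so rendered geometry matches the generative
    distances up to pixel quantization.
    """
    h, w = image_shape
    bases = areas.bases
    n = len(bases)
    row_h = h // (n + 1)
    if row_h < 1 or w < 8:
        raise ValueError(f"image shape {image_shape} too small for {n} area pairs")
    bs = max(1, min(row_h, w // 8))  # block side
    max_d = max(areas[f"{b}_L"].distance_mm for b in bases) or 1.0
    mid = w // 2
    masks = {}
    for i, base in enumerate(bases):
        d = areas[f"{base}_L"].distance_mm
        off = 1 + int(round(d / max_d * (mid - bs - 2)))
        r0 = (i + 1) * row_h - bs // 2
        for hemi, c0 in (("L", mid - off - bs), ("R", mid + off)):
            m = np.zeros(image_shape, dtype=bool)
            m[r0 : r0 + bs, c0 : c0 + bs] = True
            masks[f"{base}_{hemi}"] = m
    return masks


def render_movie(
    roi_traces: np.ndarray,
    areas: AreaSet,
    image_shape: tuple[int, int],
    pixel_noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Paint each area's trace into its mask; background carries noise only.

    Masks must be disjoint, non-empty, and inside the image; ROI-mean
    extraction inverts the rendering up to pixel noise (whose SD shrinks as
    1/sqrt(mask size) under averaging).
    """
    roi_traces = np.asarray(roi_traces, dtype=float)
    n_areas, n_frames = roi_traces.shape
    if n_areas != len(areas):
        raise ValueError("one trace per area required")
    occupancy = np.zeros(image_shape, dtype=int)
    for area in areas:
        if area.mask is None or not area.mask.any():
            raise ValueError(f"area {area.name} has an empty or missing mask")
        if area.mask.shape != tuple(image_shape):
            raise ValueError(f"mask for {area.name} does not fit image shape")
        occupancy += area.mask.astype(int)
    if occupancy.max() > 1:
        raise ValueError("area masks overlap")
    rng = rng or np.random.default_rng()
    movie = (
        pixel_noise_sd * rng.standard_normal((n_frames, *image_shape))
        if pixel_noise_sd > 0
        else np.zeros((n_frames, *image_shape))
    )
    for i, area in enumerate(areas):
        movie[:, area.mask] += roi_traces[i][:, None]
    return movie
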