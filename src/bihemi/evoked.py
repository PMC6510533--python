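"""Trial epoching, response-window statistics, ongoing-activity trial splits,
and two-stage Naka-Rushton contrast-response fitting.

The analysis window for visually evoked responses is 50-150 ms after
stimulus onset (half-open, ``[0.05, 0.15)`` s). The contrast-response
function is

    R(C) = R0 + Rmax * C^n / (C50^n + C^n)

fitted in two stages: the grand fit estimates all four parameters on pooled
trials; group fits then fix (C50, n) and re-estimate only offset R0 and
scale Rmax within each trial group — the device that dissociates an
additive effect of ongoing activity (R0 moves) from a multiplicative one
(Rmax moves).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .preprocess import bandpass

logger = logging.getLogger(__name__)

RESPONSE_WINDOW = (0.05, 0.15)   # s from stimulus onset
PRESTIM_WINDOW = (-0.5, 0.0)     # s; the task enforces >= 500 ms quiescence


@dataclass(frozen=True)
class NakaRushtonParams:
    """R(C) = r0 + rmax * C^n / (c50^n + C^n)."""

    r0: float = 0.0
    rmax: float = 1.0
    c50: float = 0.3
    n: float = 2.0


def naka_rushton(contrast, r0: float, rmax: float, c50: float, n: float):
    c = np.asarray(contrast, dtype=float)
    cn = c**n
    return r0 + rmax * cn / (c50**n + cn)


@dataclass
class EpochSet:
    """trial x time array for one ROI, with onset at t = 0."""

    data: np.ndarray
    time_s: np.ndarray
    meta: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_index(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean index of samples falling in a half-open [t0, t1) window."""
        return (self.time_s >= window[0]) & (self.time_s < window[1])


def epoch_trials(
    trace: np.ndarray,
    onsets: Sequence[int],
    window: tuple[float, float],
    fs: float,
    meta: Optional[pd.DataFrame] = None,
) -> EpochSet:
    """Cut ``[onset + ceil(t0*fs), onset + ceil(t1*fs))`` around each onset.

    Every epoch must fit inside the trace; offending trials are reported by
    index.
    """
    trace = np.asarray(trace, dtype=float)
    onsets = np.asarray(onsets, dtype=int)
    i0 = math.ceil(window[0] * fs)
    i1 = math.ceil(window[1] * fs)
    if i1 <= i0:
        raise ValueError(f"window {window} is empty after discretization")
    starts = onsets + i0
    stops = onsets + i1
    bad = np.nonzero((starts < 0) | (stops > len(trace)))[0]
    if bad.size:
        raise ValueError(f"epochs outside trace for trials {bad.tolist()}")
    data = np.stack([trace[a:b] for a, b in zip(starts, stops)])
    time_s = np.arange(i0, i1) / fs
    if meta is None:
        meta = pd.DataFrame({"trial": np.arange(len(onsets))})
    else:
        meta = meta.reset_index(drop=True)
    return EpochSet(data=data, time_s=time_s, meta=meta)


def response_amplitude(
    epochs: EpochSet, window: tuple[float, float] = RESPONSE_WINDOW
) -> np.ndarray:
    """Per-trial time-mean inside the (half-open) response window."""
    idx = epochs.time_index(window)
    if not idx.any():
        raise ValueError(f"window {window} contains no samples")
    return epochs.data[:, idx].mean(axis=1)


def trial_stats(epochs: EpochSet, by: str = "contrast") -> pd.DataFrame:
    """Across-trial mean and SD time courses per level of ``by``.

    SD uses the n-1 denominator and is reported missing (NaN) for
    single-trial groups rather than 0.
    """
    rows = []
    for level, idx in epochs.meta.groupby(by).groups.items():
        sub = epochs.data[np.asarray(idx)]
        mean_tc = sub.mean(axis=0)
        sd_tc = sub.std(axis=0, ddof=1) if len(sub) >= 2 else np.full(sub.shape[1], np.nan)
        for t, m, s in zip(epochs.time_s, mean_tc, sd_tc):
            rows.append({by: level, "time_s": t, "mean": m, "sd": s, "n": len(sub)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrialSplit:
    """Per-trial group labels under a named criterion; a full partition."""

    criterion: str
    labels: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def group_sizes(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def indices(self, label) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


def _median_split(values: np.ndarray, names: tuple[str, str], criterion: str,
                  quantile: float = 0.5) -> TrialSplit:
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 trials to split")
    if np.ptp(values) == 0:
        raise ValueError("degenerate split: all values identical")
    cut = float(np.quantile(values, quantile))
    labels = np.where(values > cut, names[1], names[0])  # ties go to the low group
    return TrialSplit(criterion=criterion, labels=labels,
                      params={"quantile": quantile, "cut": cut})


def split_by_contralateral_activity(
    amplitudes_unstim: np.ndarray, quantile: float = 0.5
) -> TrialSplit:
    """Low/high split of unstimulated-hemisphere response-window amplitudes.

    Median split by default, ties assigned to the low group; other quantile
    cuts are selectable (results are expected to be robust to the choice).
    """
    return _median_split(amplitudes_unstim, ("low", "high"),
                         "contralateral_activity", quantile)


def split_by_prestim_updown(amplitudes_prestim: np.ndarray,
                            quantile: float = 0.5) -> TrialSplit:
    """Down/up split of prestimulus activity in the stimulated hemisphere."""
    return _median_split(amplitudes_prestim, ("down", "up"), "prestim_updown", quantile)


def split_by_template_similarity(
    trial_maps: np.ndarray, template: np.ndarray
) -> TrialSplit:
    """Sign-of-correlation split against a bilateral evoked template.

    ``trial_maps`` is trial x space (area or pixel values at stimulus
    onset); ``template`` is the symmetrized (left+right mirrored) mean
    evoked map. Zero-variance trial maps cannot be correlated and are
    labelled ``excluded`` with a log entry.
    """
    template = np.asarray(template, dtype=float).ravel()
    if np.allclose(template, 0) or template.std() == 0:
        raise ValueError("template must be nonzero and non-constant")
    tm = np.asarray(trial_maps, dtype=float).reshape(len(trial_maps), -1)
    tz = template - template.mean()
    labels = np.empty(len(tm), dtype=object)
    corrs = np.full(len(tm), np.nan)
    for i, row in enumerate(tm):
        sd = row.std()
        if sd == 0:
            logger.info("trial %d excluded from template split (zero variance)", i)
            labels[i] = "excluded"
            continue
        r = float((row - row.mean()) @ tz) / (len(row) * sd * tz.std())
        corrs[i] = r
        labels[i] = "positive" if r >= 0 else "negative"
    return TrialSplit("template_similarity", np.asarray(labels),
                      params={"correlations": corrs})


def split_by_prestim_state(
    bilateral_trace: np.ndarray,
    onsets: Sequence[int],
    fs: float,
    band: tuple[float, float] = (2.0, 7.0),
    window: tuple[float, float] = PRESTIM_WINDOW,
) -> TrialSplit:
    """Synchronized/desynchronized split by prestimulus 2-7 Hz amplitude.

    Band amplitude is the SD of the band-passed symmetric (bilateral) trace
    inside the prestimulus window of each trial; trials above the median are
    'synchronized'. Combine with the instantaneous-activity split via
    :func:`combine_splits` to form the 2x2 state x activity groups.
    """
    trace = bandpass(np.asarray(bilateral_trace, dtype=float), band[0], band[1], fs)
    onsets = np.asarray(onsets, dtype=int)
    i0 = math.ceil(window[0] * fs)
    i1 = math.ceil(window[1] * fs)
    if np.any(onsets + i0 < 0):
        raise ValueError("prestimulus window extends before recording start")
    amps = np.array([trace[o + i0 : o + i1].std() for o in onsets])
    split = _median_split(amps, ("desynchronized", "synchronized"), "prestim_state")
    return TrialSplit(split.criterion, split.labels,
                      params={**split.params, "band": band, "window": window})


def combine_splits(a: TrialSplit, b: TrialSplit) -> TrialSplit:
    """Cartesian combination of two splits into 2x2 (or m x n) labels."""
    if len(a.labels) != len(b.labels):
        raise ValueError("splits label different numbers of trials")
    labels = np.array([f"{x}/{y}" for x, y in zip(a.labels, b.labels)], dtype=object)
    return TrialSplit(f"{a.criterion}x{b.criterion}", labels,
                      params={"first": a.criterion, "second": b.criterion})


@dataclass(frozen=True)
class NakaRushtonFit:
    r0: float
    rmax: float
    c50: float
    n: float
    stage: str = "grand"
    residual: float = np.nan

    def __call__(self, contrast):
        return naka_rushton(contrast, self.r0, self.rmax, self.c50, self.n)


def fit_naka_rushton(
    contrasts: np.ndarray,
    responses: np.ndarray,
    fixed: Optional[tuple[float, float]] = None,
    use_median: bool = False,
) -> NakaRushtonFit:
    """Least-squares Naka-Rushton fit of per-trial responses.

    With ``fixed=(C50, n)`` the problem is linear in (R0, Rmax) and solved
    exactly (the group stage of the two-stage procedure). Otherwise all four
    parameters are fitted by bounded nonlinear least squares (C50 in
    [0.01, 1], n in [0.5, 6]). ``use_median`` replaces trials by per-contrast
    medians before fitting.
    """
    c = np.asarray(contrasts, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise ValueError("contrasts and responses must align")
    if use_median:
        levels = np.unique(c)
        r = np.array([np.median(r[c == lv]) for lv in levels])
        c = levels
    n_levels = len(np.unique(c))
    if fixed is not None:
        c50, n = fixed
        if c50 <= 0 or n <= 0:
            raise ValueError("fixed (C50, n) must be positive")
        if n_levels < 2:
            raise ValueError("need >= 2 distinct contrasts")
        x = c**n / (c50**n + c**n)
        design = np.column_stack([np.ones_like(x), x])
        coef, res, *_ = np.linalg.lstsq(design, r, rcond=None)
        resid = float(np.sum((design @ coef - r) ** 2))
        return NakaRushtonFit(float(coef[0]), float(coef[1]), float(c50), float(n),
                              stage="group", residual=resid)

    if n_levels < 4:
        raise ValueError("the 4-parameter stage needs >= 4 distinct contrasts")

    def residuals(theta):
        return naka_rushton(c, *theta) - r

    lo = np.array([-np.inf, 0.0, 0.01, 0.5])
    hi = np.array([np.inf, np.inf, 1.0, 6.0])
    x0 = np.array([float(r.min()), float(np.ptp(r)) or 1.0, 0.25, 2.0])
    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi))
    if not sol.success:
        raise RuntimeError(f"Naka-Rushton fit did not converge (residual {sol.cost:.3g})")
    return NakaRushtonFit(*[float(v) for v in sol.x], stage="grand",
                          residual=float(np.sum(sol.fun**2)))


def fit_naka_rushton_groups(
    contrasts: np.ndarray,
    responses: np.ndarray,
    split: TrialSplit,
    use_median: bool = False,
) -> tuple[NakaRushtonFit, dict]:
    """Two-stage procedure: grand 4-parameter fit, then per-group (R0, Rmax)
    refits sharing the grand (C50, n)."""
    grand = fit_naka_rushton(contrasts, responses, use_median=use_median)
    groups = {}
    for label in pd.unique(split.labels):
        if label == "excluded":
            continue
        idx = split.indices(label)
        groups[label] = fit_naka_rushton(
            np.asarray(contrasts)[idx], np.asarray(responses)[idx],
            fixed=(grand.c50, grand.n), use_median=use_median,
        )
    return grand, groups
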