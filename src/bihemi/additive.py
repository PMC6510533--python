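"""Additive single-trial model of ongoing + evoked activity.

Single-trial activity in a predicted area is modelled as

    f_it = V(c_i, t) + F_it,

where V(c, t) is the evoked component (the across-trial mean time course at
contrast c) and F_it is the bilateral ongoing fluctuation, estimated from
the simultaneously measured homotopic contralateral trace f'_it after
removing any trial-triggered activity there:

    F_it = h * (f'_it - V'(c_i, t)).

The mixing weight h is a fixed coefficient obtained from 0%-contrast trials
by linear regression of the target on the contralateral fluorescence.
Model quality is summarized as cross-validated explained variance of
response-window (50-150 ms) trial scalars,

    EV = 100 * (1 - sum_i (r_i - f_i)^2 / sum_i (r_i - rbar)^2),

computed within each nonzero contrast and averaged across contrasts
(pooled centering is available as a flag). h is trained on 0% trials only
and evaluated on the >0% trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .evoked import RESPONSE_WINDOW, EpochSet, epoch_trials, response_amplitude

logger = logging.getLogger(__name__)

DEFAULT_EPOCH_WINDOW = (-0.2, 0.5)  # s around onset used for template estimation


@dataclass
class EvokedTemplate:
    """Per-contrast mean time courses for the target ROI (v) and the
    contralateral regressor ROI (v_contra)."""

    v: dict
    v_contra: dict
    time_s: np.ndarray
    window: tuple[float, float] = RESPONSE_WINDOW

    def lookup(self, contrast: float) -> np.ndarray:
        key = float(contrast)
        if key not in self.v:
            raise KeyError(f"no template for contrast {contrast}")
        return self.v[key]

    def lookup_contra(self, contrast: float) -> np.ndarray:
        key = float(contrast)
        if key not in self.v_contra:
            raise KeyError(f"no contralateral template for contrast {contrast}")
        return self.v_contra[key]


def estimate_templates(epochs_target: EpochSet, epochs_contra: EpochSet) -> EvokedTemplate:
    """Across-trial mean per contrast for both ROIs."""
    if epochs_target.n_trials != epochs_contra.n_trials:
        raise ValueError("target and contralateral epochs must cover the same trials")
    contrasts = epochs_target.meta["contrast"].to_numpy(dtype=float)
    v, v_contra = {}, {}
    for c in np.unique(contrasts):
        idx = contrasts == c
        v[float(c)] = epochs_target.data[idx].mean(axis=0)
        v_contra[float(c)] = epochs_contra.data[idx].mean(axis=0)
    return EvokedTemplate(v=v, v_contra=v_contra, time_s=epochs_target.time_s)


def estimate_h(target_0pct: np.ndarray, contra_0pct: np.ndarray) -> float:
    """Mixing weight h: pooled OLS slope of target on contralateral samples.

    Both trial x time arrays come from 0%-contrast trials; samples are
    pooled across trials and time and mean-centered before the regression.
    The estimate is reported unclipped; values above 1 trigger a warning
    (h <= 1 is an empirical observation, not an enforced constraint).
    """
    y = np.asarray(target_0pct, dtype=float).ravel()
    x = np.asarray(contra_0pct, dtype=float).ravel()
    if y.shape != x.shape or len(np.atleast_2d(target_0pct)) < 2:
        raise ValueError("need matching arrays from >= 2 zero-contrast trials")
    xc = x - x.mean()
    var = float(xc @ xc)
    if var == 0:
        raise ValueError("zero-variance contralateral regressor")
    h = float((y - y.mean()) @ xc) / var
    if h > 1:
        logger.warning("estimated h = %.3f exceeds 1", h)
    return h


def predict_trials(
    template: EvokedTemplate,
    contra_trials: np.ndarray,
    contrasts: Sequence[float],
    h: float,
) -> np.ndarray:
    """f_hat_it = V(c_i, t) + h * (f'_it - V'(c_i, t))."""
    contra = np.asarray(contra_trials, dtype=float)
    if contra.shape[0] != len(contrasts):
        raise ValueError("one contralateral trial per contrast entry required")
    out = np.empty_like(contra)
    for i, c in enumerate(contrasts):
        out[i] = template.lookup(c) + h * (contra[i] - template.lookup_contra(c))
    return out


def explained_variance(
    observed: np.ndarray,
    predicted: np.ndarray,
    contrasts: Sequence[float],
    pooled: bool = False,
) -> float:
    """Percent explained variance of window-mean trial scalars.

    Per nonzero contrast: ``100 * (1 - SS_res / SS_tot)`` with the trial
    mean rbar taken within that contrast; the returned value is the average
    over nonzero contrasts (may be negative). ``pooled=True`` instead
    centers on the grand mean of all >0% trials and evaluates one ratio.
    Contrast cells whose observations are identical (zero denominator) are
    undefined and excluded with a warning.
    """
    r = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    c = np.asarray(contrasts, dtype=float)
    if not (r.shape == f.shape == c.shape):
        raise ValueError("observed, predicted and contrasts must align")
    go = c > 0
    if not go.any():
        raise ValueError("no nonzero-contrast trials to evaluate")
    if pooled:
        rr, ff = r[go], f[go]
        ss_tot = float(np.sum((rr - rr.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError("identical observations: explained variance undefined")
        return 100.0 * (1.0 - float(np.sum((rr - ff) ** 2)) / ss_tot)
    evs = []
    for level in np.unique(c[go]):
        idx = c == level
        if idx.sum() < 2:
            raise ValueError(f"need >= 2 trials at contrast {level}")
        rr, ff = r[idx], f[idx]
        ss_tot = float(np.sum((rr - rr.mean()) ** 2))
        if ss_tot == 0:
            logger.warning("contrast %g: identical observations, EV undefined", level)
            continue
        evs.append(100.0 * (1.0 - float(np.sum((rr - ff) ** 2)) / ss_tot))
    if not evs:
        raise ValueError("explained variance undefined at every contrast")
    return float(np.mean(evs))


@dataclass
class AdditiveFit:
    """Cross-validated additive-model fit for one target/regressor pair."""

    h: float
    ev_additive: float
    ev_visual_only: float
    target: str
    regressor: str
    per_contrast: dict = field(default_factory=dict)
    predicted: Optional[np.ndarray] = None
    fluctuation: Optional[np.ndarray] = None

    def to_record(self) -> dict:
        return {
            "target": self.target,
            "regressor": self.regressor,
            "h": self.h,
            "ev_additive": self.ev_additive,
            "ev_visual_only": self.ev_visual_only,
            "per_contrast": {str(k): v for k, v in self.per_contrast.items()},
        }


def crossval_additive(
    session,
    target_area: str,
    regressor_area: str,
    window: tuple[float, float] = RESPONSE_WINDOW,
    epoch_window: tuple[float, float] = DEFAULT_EPOCH_WINDOW,
    pooled: bool = False,
    which: str = "measured",
    restrict_side: bool = True,
) -> AdditiveFit:
    """Fit and evaluate the additive model on one session.

    h is estimated from 0%-contrast trials only (the training set);
    templates are the per-contrast trial means; explained variance is
    reported on the >0% trials both for the additive model and for the
    visual-only model f = V(c_i, t). By default only trials whose stimulus
    is contralateral to the target area (plus the 0% blanks) enter, so the
    per-contrast template is well defined — the single-visual-field design.
    """
    trials = session.trials
    if restrict_side and hasattr(session, "areas"):
        hemi = session.areas[target_area].hemisphere
        stim_side = "L" if hemi == "R" else "R"
        keep = (trials["side"] == stim_side) | (trials["contrast"] == 0)
        trials = trials.loc[keep].reset_index(drop=True)
    contrasts = trials["contrast"].to_numpy(dtype=float)
    if not (contrasts == 0).any():
        raise ValueError("session has no zero-contrast trials (training set)")
    if not (contrasts > 0).any():
        raise ValueError("session has no nonzero-contrast trials (test set)")
    onsets = trials["onset_frame"].to_numpy(dtype=int)
    ep_t = epoch_trials(session.trace(target_area, which), onsets, epoch_window,
                        session.fs, meta=trials)
    ep_c = epoch_trials(session.trace(regressor_area, which), onsets, epoch_window,
                        session.fs, meta=trials)
    template = estimate_templates(ep_t, ep_c)

    zero = contrasts == 0
    h = estimate_h(ep_t.data[zero], ep_c.data[zero])

    predicted = predict_trials(template, ep_c.data, contrasts, h)
    fluct = predicted - np.stack([template.lookup(c) for c in contrasts])

    idx = ep_t.time_index(window)
    obs = ep_t.data[:, idx].mean(axis=1)
    pred_add = predicted[:, idx].mean(axis=1)
    pred_vis = np.stack([template.lookup(c) for c in contrasts])[:, idx].mean(axis=1)

    ev_add = explained_variance(obs, pred_add, contrasts, pooled=pooled)
    ev_vis = explained_variance(obs, pred_vis, contrasts, pooled=pooled)
    per_contrast = {}
    for level in np.unique(contrasts[contrasts > 0]):
        sel = contrasts == level
        try:
            per_contrast[float(level)] = explained_variance(
                obs[sel], pred_add[sel], np.full(sel.sum(), level), pooled=True
            )
        except ValueError:
            per_contrast[float(level)] = np.nan
    return AdditiveFit(
        h=h, ev_additive=ev_add, ev_visual_only=ev_vis,
        target=target_area, regressor=regressor_area,
        per_contrast=per_contrast, predicted=predicted, fluctuation=fluct,
    )


@dataclass
class DistanceSweep:
    """EV per candidate regressor plus an exponential fit EV(d)=a*exp(-d/lam)+c."""

    table: pd.DataFrame
    a: float = np.nan
    decay_mm: float = np.nan
    c: float = np.nan
    fit_ok: bool = False


def regressor_distance_sweep(
    session,
    target_area: str,
    candidate_areas: Optional[Sequence[str]] = None,
    which: str = "measured",
) -> DistanceSweep:
    """Sweep contralateral regressors and fit an exponential EV-vs-distance curve.

    Distance is the mediolateral separation between each candidate and the
    target's homotopic location (|midline-distance difference|; the
    homotopic partner sits at 0). Candidates default to every area in the
    hemisphere opposite the target. Exponential-fit failure returns the raw
    table with ``fit_ok=False``.
    """
    areas = session.areas
    target = areas[target_area]
    if candidate_areas is None:
        other = "L" if target.hemisphere == "R" else "R"
        candidate_areas = [a.name for a in areas.hemisphere(other)]
    if len(candidate_areas) < 3:
        raise ValueError("need >= 3 candidate regressors at distinct distances")
    rows = []
    for cand in candidate_areas:
        d = abs(areas[cand].distance_mm - target.distance_mm)
        fit = crossval_additive(session, target_area, cand, which=which)
        rows.append(dict(regressor=cand, distance_mm=d, ev=fit.ev_additive, h=fit.h))
    table = pd.DataFrame(rows).sort_values("distance_mm").reset_index(drop=True)

    d = table["distance_mm"].to_numpy()
    ev = table["ev"].to_numpy()
    try:
        p0 = [max(ev.max() - ev.min(), 1.0), max(np.ptp(d) / 2, 0.5), min(ev.min(), 0.0)]
        popt, _ = optimize.curve_fit(
            lambda x, a, lam, c: a * np.exp(-x / lam) + c,
            d, ev, p0=p0,
            bounds=([0.0, 1e-3, -100.0], [200.0, 100.0, 100.0]),
            maxfev=10000,
        )
        return DistanceSweep(table, a=float(popt[0]), decay_mm=float(popt[1]),
                             c=float(popt[2]), fit_ok=True)
    except (RuntimeError, ValueError) as err:  # fit failure: return raw table
        logger.warning("exponential fit failed: %s", err)
        return DistanceSweep(table, fit_ok=False)
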