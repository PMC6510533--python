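"""Probabilistic observer model for the 2AUC (left / right / no-go) task.

The animal's choice on each trial is modelled through two decision variables,

    z_L = b + s * g(c_L),    z_R = b + s * g(c_R),

where ``b`` is a bias toward go responses relative to no-go (log-odds units),
``s`` weights the visual evidence, and ``g`` is a contrast-sensitivity
function of Naka-Rushton form, g(c) = offset + scale * c^n / (C50^n + c^n).
The decision variables set the log odds of each go choice against no-go,

    log(p_L / p_0) = z_L,    log(p_R / p_0) = z_R,

so p_0 = 1 / (1 + e^{z_L} + e^{z_R}), p_L = e^{z_L} p_0, p_R = e^{z_R} p_0.

Fitting is two-stage: stage 1 maximizes the multinomial likelihood over
(b, g_scale, g_C50, g_n) with s fixed at 1 (s and g's scale are
multiplicatively confounded, so the scale is absorbed into g); stage 2 fixes
g and refits (b, s) within each trial group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

CHOICES = ("L", "R", "NoGo")


@dataclass(frozen=True)
class GParams:
    """Perceptual contrast-sensitivity function g(c) = offset + scale*c^n/(C50^n+c^n)."""

    offset: float = 0.0
    scale: float = 1.0
    c50: float = 0.3
    n: float = 2.0

    def __post_init__(self) -> None:
        if not (self.c50 > 0 and self.n > 0):
            raise ValueError("C50 and n must be positive")


@dataclass(frozen=True)
class ObserverFit:
    """Fitted observer parameters; stage is 'global' or 'group'."""

    b: float
    s: float
    g: GParams
    stage: str = "global"
    loglik: float = np.nan
    n_trials: int = 0


def g_value(contrast, g: GParams):
    """Evaluate the contrast-sensitivity function at one or more contrasts."""
    c = np.asarray(contrast, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("contrast must lie in [0, 1]")
    cn = c**g.n
    return g.offset + g.scale * cn / (g.c50**g.n + cn)


def decision_variables(c_left, c_right, fit: ObserverFit):
    """z_L, z_R for given left/right contrasts under a fitted observer."""
    z_left = fit.b + fit.s * g_value(c_left, fit.g)
    z_right = fit.b + fit.s * g_value(c_right, fit.g)
    return z_left, z_right


def choice_probabilities(z_left, z_right):
    """(p_L, p_R, p_0) from the log-odds link; overflow-safe, sums to 1."""
    zl = np.asarray(z_left, dtype=float)
    zr = np.asarray(z_right, dtype=float)
    if not (np.all(np.isfinite(zl)) and np.all(np.isfinite(zr))):
        raise ValueError("decision variables must be finite")
    m = np.maximum(0.0, np.maximum(zl, zr))
    e0 = np.exp(-m)
    el = np.exp(zl - m)
    er = np.exp(zr - m)
    denom = e0 + el + er
    return el / denom, er / denom, e0 / denom


def side_contrasts(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (c_L, c_R): the stimulated side carries the trial contrast."""
    c = trials["contrast"].to_numpy(dtype=float)
    side = trials["side"].to_numpy()
    c_left = np.where(side == "L", c, 0.0)
    c_right = np.where(side == "R", c, 0.0)
    return c_left, c_right


def simulate_choices(
    trials: pd.DataFrame, fit: ObserverFit, rng: np.random.Generator
) -> np.ndarray:
    """Sample a choice per trial from the model probabilities.

    Choices depend on the trial contrasts only — by construction they are
    independent of any imaging fluctuation.
    """
    cl, cr = side_contrasts(trials)
    pl, pr, p0 = choice_probabilities(*decision_variables(cl, cr, fit))
    u = rng.random(len(trials))
    out = np.where(u < pl, "L", np.where(u < pl + pr, "R", "NoGo"))
    return out.astype(object)


def _neg_loglik(b: float, s: float, g: GParams, cl, cr, choice) -> float:
    zl = b + s * g_value(cl, g)
    zr = b + s * g_value(cr, g)
    pl, pr, p0 = choice_probabilities(zl, zr)
    p = np.where(choice == "L", pl, np.where(choice == "R", pr, p0))
    return -float(np.sum(np.log(np.maximum(p, 1e-300))))


def log_likelihood(trials: pd.DataFrame, fit: ObserverFit) -> float:
    cl, cr = side_contrasts(trials)
    return -_neg_loglik(fit.b, fit.s, fit.g, cl, cr, trials["choice"].to_numpy())


def _fit_stage1(trials: pd.DataFrame, n_starts: int, seed: int) -> ObserverFit:
    cl, cr = side_contrasts(trials)
    choice = trials["choice"].to_numpy()

    def nll(theta):
        b, scale, c50, n = theta
        return _neg_loglik(b, 1.0, GParams(0.0, scale, c50, n), cl, cr, choice)

    bounds = [(-10.0, 10.0), (1e-3, 50.0), (0.01, 1.0), (0.5, 6.0)]
    rng = np.random.default_rng(seed)
    best = None
    x0s = [np.array([-1.0, 3.0, 0.25, 2.0])]
    for _ in range(max(0, n_starts - 1)):
        x0s.append(np.array([rng.uniform(-3, 1), rng.uniform(0.5, 10),
                             rng.uniform(0.05, 0.8), rng.uniform(0.8, 4)]))
    for x0 in x0s:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("stage-1 observer fit failed to converge")
    b, scale, c50, n = best.x
    return ObserverFit(
        b=float(b), s=1.0, g=GParams(0.0, float(scale), float(c50), float(n)),
        stage="global", loglik=-float(best.fun), n_trials=len(trials),
    )


def _fit_bs(trials: pd.DataFrame, g: GParams, stage: str) -> ObserverFit:
    cl, cr = side_contrasts(trials)
    choice = trials["choice"].to_numpy()

    def nll(theta):
        return _neg_loglik(theta[0], theta[1], g, cl, cr, choice)

    res = optimize.minimize(
        nll, np.array([-1.0, 1.0]), method="L-BFGS-B",
        bounds=[(-10.0, 10.0), (0.0, 20.0)],
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"(b, s) fit failed: {res.message}")
    return ObserverFit(
        b=float(res.x[0]), s=float(res.x[1]), g=g, stage=stage,
        loglik=-float(res.fun), n_trials=len(trials),
    )


@dataclass(frozen=True)
class ObserverFitResult:
    global_fit: ObserverFit
    group_fits: dict


def fit_observer(
    trials: pd.DataFrame,
    groups: Optional[np.ndarray] = None,
    fixed_g: Optional[GParams] = None,
    min_group_trials: int = 20,
    n_starts: int = 5,
    seed: int = 0,
) -> ObserverFitResult:
    """Two-stage observer fit; optional per-group stage-2 refits.

    Parameters
    ----------
    trials : trial table with columns side, contrast, choice.
    groups : optional per-trial labels; stage 2 refits (b, s) per label with
        g fixed to the stage-1 (or ``fixed_g``) sensitivity function.
    fixed_g : skip stage 1 and use this g(); (b, s) are then fitted on all
        trials, which makes both identifiable.
    """
    if trials["choice"].nunique() < 2:
        raise ValueError("need at least two choice categories to fit the observer")
    if fixed_g is not None:
        global_fit = _fit_bs(trials, fixed_g, stage="global")
    else:
        global_fit = _fit_stage1(trials, n_starts=n_starts, seed=seed)

    group_fits: dict = {}
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != len(trials):
            raise ValueError("groups must label every trial")
        for label in pd.unique(groups):
            sub = trials.loc[groups == label]
            if len(sub) == 0:
                raise ValueError(f"empty trial group {label!r}")
            if len(sub) < min_group_trials:
                raise ValueError(
                    f"group {label!r} has {len(sub)} trials; need >= {min_group_trials}"
                )
            group_fits[label] = replace(
                _fit_bs(sub, global_fit.g, stage="group")
            )
    return ObserverFitResult(global_fit=global_fit, group_fits=group_fits)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval."""
    if n == 0:
        return (np.nan, np.nan)
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def psychometric_table(
    trials: pd.DataFrame, groups: Optional[np.ndarray] = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Empirical P(correct) and P(no-go) per contrast (and group) with 95% CIs.

    'Correct' means choosing the stimulated side; at zero contrast the
    rewarded response is no-go, so P(correct) is undefined there and reported
    as missing.
    """
    df = trials.copy()
    df["group"] = "all" if groups is None else np.asarray(groups)
    rows = []
    for (grp, c), sub in df.groupby(["group", "contrast"], sort=True):
        n = len(sub)
        k_nogo = int((sub["choice"] == "NoGo").sum())
        lo_ng, hi_ng = clopper_pearson(k_nogo, n, alpha)
        if c > 0:
            k_corr = int((sub["choice"] == sub["side"]).sum())
            p_corr = k_corr / n
            lo_c, hi_c = clopper_pearson(k_corr, n, alpha)
        else:
            p_corr, lo_c, hi_c = np.nan, np.nan, np.nan
        rows.append(
            dict(
                contrast=c, group=grp, n=n,
                p_correct=p_corr, ci_correct_lo=lo_c, ci_correct_hi=hi_c,
                p_nogo=k_nogo / n, ci_nogo_lo=lo_ng, ci_nogo_hi=hi_ng,
            )
        )
    return pd.DataFrame(rows)
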