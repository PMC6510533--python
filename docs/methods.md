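# Methods

## The problem and the model

Widefield imaging of both cortical hemispheres shows that ongoing activity —
activity present without stimuli or overt behavior — is largely bilateral:
left and right homotopic areas fluctuate together, most strongly near the
midline. A lateralized visual stimulus instead drives only the contralateral
hemisphere in the first ~150 ms. The package implements the analysis that
separates, and then recombines, these two components at the single-trial
level.

**Additive model.** Activity of a predicted area on trial *i* at time *t*
from stimulus onset is modelled as

    f_it = V(c_i, t) + F_it

where `V(c, t)` is the evoked component, estimated as the across-trial mean
time course at contrast `c`, and `F_it` is the bilateral ongoing
fluctuation, estimated from the simultaneously imaged homotopic area of the
other hemisphere after removing any trial-triggered activity there:

    F_it = h · (f'_it − V'(c_i, t)).

The mixing weight `h` is a single fixed coefficient per area pair, obtained
by ordinary least squares of the target on the contralateral fluorescence
using only 0%-contrast trials (the training set). Model quality is the
explained variance of response-window trial scalars,

    EV = 100 · (1 − Σᵢ (r_i − f_i)² / Σᵢ (r_i − r̄)²),

evaluated on the >0%-contrast trials (cross-validation of `h`). `r̄` is
taken within each nonzero contrast and the EV averaged across contrasts;
this prevents differences in evoked means from inflating EV, at the price
that the visual-only reference model (`f = V(c_i, t)`) scores ~0 by
construction. Pooled centering (one grand mean across all >0% trials) is
available via `pooled=True`. Estimates of `h` are reported unclipped; a
value above 1 triggers a warning rather than truncation, because clipping
would bias recovery studies.

**Contrast responses.** Window amplitudes follow the Naka-Rushton function
`R(C) = R0 + Rmax·Cⁿ/(C50ⁿ + Cⁿ)` (`R0` offset, `Rmax` scale, `C50`
semi-saturation contrast, `n` exponent). Fitting is two-stage: all four
parameters on the pooled trials (bounded nonlinear least squares,
initialization `R0 = min`, `Rmax = range`, `C50 = 0.25`, `n = 2`, bounds
`C50 ∈ [0.01, 1]`, `n ∈ [0.5, 6]`), then `(R0, Rmax)` per trial group with
`(C50, n)` frozen — a linear problem solved exactly. The group stage is what
dissociates an additive effect of ongoing activity (moves `R0` only) from a
multiplicative one (moves `Rmax` only). Trial-level least squares is the
default objective; a median-based option reproduces the
median/median-absolute-deviation display convention.

**Trial splits.** Groups of "low/high ongoing activity" are median splits
(ties to the low group, fixed) of: the unstimulated-hemisphere amplitude in
the response window; the spatial correlation with a bilateralized evoked
template at onset (positive/negative); the prestimulus 2–7 Hz band amplitude
(SD of the band-passed symmetric trace in the prestimulus window;
synchronized/desynchronized); or the prestimulus amplitude of the stimulated
hemisphere (down/up). Splits compose into 2×2 labels, and every split
partitions the analyzed trials exactly. The median cut is a default, not an
assumption — robustness to the quantile is exercised in tests.

**Bilateral structure.** `sym = (L+R)/2`, `asym = (L−R)/2` reconstruct the
inputs exactly, and relative power is each component's PSD divided by
`PSD(sym) + PSD(asym)` (equal, by Parseval, to the mean PSD of the measured
traces). PSDs use Welch averaging with 2-s Hann windows and 50% overlap;
relative powers are ratios and are insensitive to this choice. Homotopic
Pearson correlations are tabulated against midline distance; the linear fit
excludes designated outlier areas (monocular V1, and secondary motor cortex
whose coupling drops during task engagement). Interhemispheric
cross-correlation is the per-lag Pearson correlation of the overlapping
segments, so the lag-0 value is the plain correlation coefficient.

**Observer model.** Choices in the two-alternative unforced-choice task
(left / right / no-go; no-go rewarded at zero contrast) follow decision
variables `z_L = b + s·g(c_L)`, `z_R = b + s·g(c_R)` with
`log(p_L/p_0) = z_L`, `log(p_R/p_0) = z_R`; probabilities are computed
overflow-safely and sum to one exactly. `g()` has the Naka-Rushton form.
Because `s` and `g`'s scale multiply each other, stage 1 fixes `s = 1` and
offset 0 and maximizes the multinomial likelihood over
`(b, g_scale, g_C50, g_n)` (L-BFGS-B, 5 random restarts, `|b| ≤ 10`,
`s ∈ [0, 20]`); stage 2 freezes `g` and refits `(b, s)` per trial group.
Parameter-recovery studies therefore supply the generating `g` as `fixed_g`,
the only setting in which comparing the fitted `s` to a generating value is
meaningful. A single `b` serves both sides (the psychometric curves are
symmetric); no lapse rate is modelled. Empirical psychometric tables use
exact Clopper-Pearson 95% binomial intervals.

**Preprocessing.** The reference conditioning chain for calcium signals is:
truncated SVD of the pixel×frame movie (default 500 components; the
Frobenius reconstruction error equals the root-sum-square of the discarded
singular values, and ROI extraction commutes with compression); hemodynamic
correction, subtracting the artifact channel scaled by the least-squares
regression coefficient (per trace, at whatever granularity the caller
selects — the constant-artifact case degrades to a warning and no
subtraction); forward first difference times the sampling rate with negative
values zeroed (sharpening slow indicator kinetics); and a zero-phase 4th-order
Butterworth lowpass at 7 Hz to attenuate heartbeat components. All filters
are applied forward-backward; frames are 0-based; all windows are half-open
`[t0, t1)` in seconds with stimulus onset at t = 0. Voltage-specific
ratiometric gain equalization and reflectance regression are out of scope;
the calcium chain is the reference path.

## The synthetic generator

The generator is first-class, tested code: it produces sessions with the
exact statistical structure the analyses assume, so every stage can be
validated against known ground truth.

* **Ongoing fluctuations.** White Gaussian noise is band-passed 2–7 Hz with
  the same zero-phase Butterworth family used in preprocessing, then
  z-scored to unit variance. For each area pair,
  `L = √ρ·common + √(1−ρ)·private_L` (and symmetrically for right), giving
  Pearson(L, R) = ρ. The target area instead uses the directional mix
  `L = h·R + √(1−h²)·private`, whose regression slope in either direction
  equals `h_true` (both variances are 1) — this is the sense in which the
  generative mixing weight is known exactly. Default couplings decrease
  with midline distance (0.85 at 0.9 mm down to 0.45 at 4 mm), with
  monocular V1 a standing exception (0.35) and secondary motor cortex
  coupling 0.60 during the task but 0.88 in the passive condition.
* **Cross-area coupling.** Common components of different areas correlate
  with the target's as `exp(−d/(2λ))` in the mediolateral separation `d`
  (areas are laid out along a mediolateral line, so inter-area distance is
  the difference of midline distances). Shared *variance* — and hence the
  explained variance available to a distance-swept regressor — then decays
  as `exp(−d/λ)`: `coupling_decay_mm` (default 2 mm) is defined as the decay
  length of shared variance, which is the quantity the exponential EV fit
  recovers.
* **Evoked responses.** Strictly contralateral to the stimulated visual
  field, zero before 50 ms, rising linearly to a plateau at 150 ms and
  decaying back to baseline after 450 ms. The plateau is twice the
  Naka-Rushton amplitude so that the mean over the 50–150 ms analysis window
  equals `R(c)` exactly (default curve `R0 = 0`, `Rmax = 1 ΔF/F`,
  `C50 = 0.3`, `n = 2`). Trial-by-trial evoked-amplitude noise is exposed as
  an independent fractional parameter (`amp_noise_sd`, default 0): the
  decomposition of response variability into amplitude noise versus additive
  ongoing activity is left as an explicit knob rather than asserted.
* **Trials and choices.** Contrasts are balanced round-robin and shuffled;
  stimulus side is balanced within each contrast; onsets are spaced
  `iti_s` (default 2 s) apart, exceeding the epoch window. Choices are
  sampled from the observer model (defaults `b = −1`, `s = 4`, `g`: scale 1,
  `C50 = 0.3`, `n = 2`) given the trial contrasts alone, making them
  conditionally independent of the imaging fluctuation by construction —
  the null the behavioral analysis is supposed to report.
* **Channels and rendering.** The measured signal adds white noise
  (default SD 0.1 against a unit-variance fluctuation) and
  `artifact_gain` (default 0.3) times a slow (<0.5 Hz) global artifact that
  reappears, with small sensor noise, in the artifact channel. Movies are
  rendered on demand (default 64×64 or smaller) by painting each area's
  trace into disjoint rectangular masks mirrored about the vertical midline
  at pixel offsets proportional to midline distance, plus independent pixel
  noise; sessions are generated without a movie unless a shape is requested,
  since all analyses operate on ROI traces.
* **Randomness.** One `SeedSequence` per session is split into named
  substreams (fluctuations, artifact, noise, trial layout, choices,
  amplitude noise, rendering), so the draws of one component do not depend
  on another's parameters. Note that although changing `n_trials` leaves the
  fluctuation substream untouched, the zero-phase filter makes every output
  sample depend on the trace length, so the realized fluctuation is only
  reproducible for a fixed session length.

**What the generator does not emulate:** photon/shot noise and camera
nonlinearities, eye/body movements and their artifacts, pupil-linked arousal,
retinotopic fine structure within areas, slow drift or photobleaching, and
any dependence of choices on cortical state. Passing tests therefore show
that the estimators are correct and calibrated under the assumed model —
not that real data satisfy those assumptions.

## Numerical choices and conventions

* Filters: 4th-order Butterworth, `sosfiltfilt`; band edges validated
  against Nyquist; the lowpass frequency-response helper documents the
  effective (squared) gain used in stopband tests.
* Epoching: sample `k` of a trial covers `[onset + ceil(t0·fs), onset +
  ceil(t1·fs))`; the response window is `[0.05, 0.15)` s and the prestimulus
  window `[−0.5, 0)` s (the task enforces ≥ 500 ms of quiescence).
* Degenerate inputs: zero-variance correlation targets propagate as NaN
  (never silent 0); all-equal amplitudes make a median split an error;
  single-trial groups report SD as missing; a constant artifact trace makes
  the hemodynamic β 0 with a warning; EV with a zero denominator is flagged,
  not returned as a number.
* SVD uses the exact (LAPACK) decomposition — movies in this package are
  small enough that randomized methods are unnecessary; rank above
  `min(pixels, frames)` is clipped with a warning.
* `h ≤ 1` is treated as an empirical observation, not a constraint.
* The end-to-end pipeline records a SHA-256 config hash and seed in every
  summary; identical config + seed reproduces byte-identical JSON. The demo
  configuration runs 120 trials at 35 Hz with an optional 24×24 rendered
  movie — sizes chosen so a full pipeline completes in seconds while leaving
  every per-contrast cell with enough trials for stable explained-variance
  estimates.
* The preprocessing chain for the pipeline's analysis path defaults to
  hemodynamic correction + lowpass; the derivative step is aimed at slow
  calcium indicators, whereas the generator already emits activity-like
  traces, so it is opt-in (`chain=("correct", "deriv", "lowpass")`).

## Design decisions that were genuinely open

* **EV centering** (per-contrast vs pooled): per-contrast by default, pooled
  behind a flag; see above for the trade-off.
* **Template estimation** uses all trials of each contrast, including test
  trials — only the weight `h` is cross-validated. A stricter fully-held-out
  template mode would change the visual-only baseline but not the additive
  comparison; the default matches the cross-validation described for the
  weight.
* **Which two parameters of `g()` the observer's stage 1 optimizes:** scale
  and the pair `(C50, n)` with offset 0 and `s` absorbed into the scale;
  this is an interpretive choice flagged in the code.
* **`B_it` vs `F_it`:** the contralateral-fluctuation regressor and the
  fluctuation term of the additive model are treated as the same quantity.
* **Distance metric for the regressor sweep:** mediolateral separation
  (difference of midline distances), the only geometry the synthetic layout
  defines; the homotopic partner sits at distance 0.

## Known limitations

* The exponential EV-vs-distance fit needs at least three distinct distances
  and a non-flat profile; on failure the raw table is returned with the fit
  marked failed rather than raising.
* Band-limited noise has few independent samples per epoch (~3 for a 0.7-s
  epoch of 2–7 Hz signal), so `h` estimates from small sessions carry an
  SD of ~0.05; recovery guarantees are stated at 200 zero-contrast trials.
* Observer fits can sit on the bias bound (`b = −10`) for degenerate data
  (e.g. all no-go); bounds, not priors, are the guard.
* The two-stage Naka-Rushton fit assumes the grand `(C50, n)` transfer to
  the groups; when groups genuinely differ in `C50` or `n`, offset/scale
  changes will partially absorb that difference.
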