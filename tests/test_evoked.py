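"""Epoching, response amplitudes, trial splits, and the two-stage
Naka-Rushton contrast-response fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bihemi import evoked
from bihemi.evoked import (
    PRESTIM_WINDOW,
    RESPONSE_WINDOW,
    combine_splits,
    epoch_trials,
    fit_naka_rushton,
    fit_naka_rushton_groups,
    naka_rushton,
    response_amplitude,
    split_by_contralateral_activity,
    split_by_prestim_state,
    split_by_prestim_updown,
    split_by_template_similarity,
    trial_stats,
)

FS = 35.0


def test_analysis_windows_are_reference_constants():
    assert RESPONSE_WINDOW == (0.05, 0.15)
    assert PRESTIM_WINDOW == (-0.5, 0.0)


class TestEpoching:
    def test_counting_trace_window(self):
        trace = np.arange(100, dtype=float)
        ep = epoch_trials(trace, [10, 40], (0.0, 3 / FS), FS)
        np.testing.assert_array_equal(ep.data, [[10, 11, 12], [40, 41, 42]])
        np.testing.assert_allclose(ep.time_s, [0, 1 / FS, 2 / FS])

    def test_constant_trace_epochs(self):
        ep = epoch_trials(np.full(200, 3.5), [20, 100], (-0.1, 0.2), FS)
        np.testing.assert_array_equal(ep.data, 3.5)

    def test_out_of_bounds_trials_listed(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            epoch_trials(np.zeros(50), [10, 49], (0.0, 0.2), FS)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            epoch_trials(np.zeros(50), [10], (0.0, 0.0), FS)


class TestResponseAmplitude:
    def test_constant_and_zero(self):
        ep = epoch_trials(np.full(300, 2.0), [50, 150], (-0.1, 0.3), FS)
        np.testing.assert_allclose(response_amplitude(ep), 2.0)
        ep0 = epoch_trials(np.zeros(300), [50, 150], (-0.1, 0.3), FS)
        np.testing.assert_allclose(response_amplitude(ep0), 0.0)

    def test_linear_ramp_mean_half(self):
        # ramp 0 -> 1 across the window: discrete mean is 0.5 up to half a sample
        n = 32
        onset = 10
        trace = np.zeros(100)
        trace[onset : onset + n] = np.linspace(0, 1, n)
        ep = epoch_trials(trace, [onset], (0.0, n / FS), FS)
        amp = response_amplitude(ep, (0.0, n / FS))
        assert amp[0] == pytest.approx(0.5, abs=0.5 / n)


class TestTrialStats:
    def _epochs(self, data, contrasts):
        return evoked.EpochSet(
            data=np.asarray(data, dtype=float),
            time_s=np.arange(np.shape(data)[1]) / FS,
            meta=pd.DataFrame({"contrast": contrasts}),
        )

    def test_identical_trials_zero_sd(self):
        stats = trial_stats(self._epochs([[1, 2], [1, 2]], [0.5, 0.5]))
        np.testing.assert_array_equal(stats["sd"], 0.0)

    def test_two_trial_mean_and_sd(self):
        stats = trial_stats(self._epochs([[0, 0], [2, 2]], [1.0, 1.0]))
        np.testing.assert_allclose(stats["mean"], 1.0)
        np.testing.assert_allclose(stats["sd"], np.sqrt(2.0))

    def test_single_trial_sd_missing_not_zero(self):
        stats = trial_stats(self._epochs([[1, 1], [2, 2]], [0.0, 1.0]))
        assert stats["sd"].isna().all()


class TestMedianSplits:
    def test_basic_median_split(self):
        split = split_by_contralateral_activity(np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_array_equal(split.labels, ["low", "low", "high", "high"])

    def test_ties_go_low(self):
        split = split_by_contralateral_activity(np.array([1.0, 1.0, 2.0, 2.0]))
        np.testing.assert_array_equal(split.labels, ["low", "low", "high", "high"])

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            split_by_contralateral_activity(np.full(6, 2.0))

    def test_gaussian_group_gap_matches_order_statistics(self, rng):
        # median split of a Gaussian: E[high] - E[low] = 2*sqrt(2/pi)*sigma
        x = rng.standard_normal(40_000)
        split = split_by_contralateral_activity(x)
        gap = x[split.labels == "high"].mean() - x[split.labels == "low"].mean()
        assert gap == pytest.approx(2 * np.sqrt(2 / np.pi), abs=0.05)

    def test_updown_split_and_2x2_partition(self, rng):
        updown = split_by_prestim_updown(np.array([-1.0, -1.0, 1.0, 1.0]))
        np.testing.assert_array_equal(updown.labels, ["down", "down", "up", "up"])
        pre = rng.standard_normal(400)
        post = rng.standard_normal(400)
        combo = combine_splits(split_by_prestim_updown(pre),
                               split_by_contralateral_activity(post))
        sizes = combo.group_sizes
        assert sum(sizes.values()) == 400
        assert len(sizes) == 4
        # independent criteria: each 2x2 cell near n/4
        assert all(70 <= v <= 130 for v in sizes.values())

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=60))
    def test_split_partitions_all_trials(self, values):
        values = np.asarray(values)
        if np.ptp(values) == 0:
            return
        split = split_by_contralateral_activity(values)
        assert sum(split.group_sizes.values()) == len(values)
        assert set(split.group_sizes) <= {"low", "high"}


class TestTemplateSplit:
    def test_sign_of_correlation(self, rng):
        template = rng.standard_normal(16)
        trials = np.stack([template, -template])
        split = split_by_template_similarity(trials, template)
        np.testing.assert_array_equal(split.labels, ["positive", "negative"])

    def test_random_frames_split_evenly(self, rng):
        template = rng.standard_normal(16)
        trials = rng.standard_normal((2000, 16))
        split = split_by_template_similarity(trials, template)
        frac = (split.labels == "positive").mean()
        assert 0.45 < frac < 0.55

    def test_zero_variance_trial_excluded(self, rng):
        template = rng.standard_normal(8)
        trials = np.stack([template, np.zeros(8), -template])
        split = split_by_template_similarity(trials, template)
        assert split.labels[1] == "excluded"
        with pytest.raises(ValueError):
            split_by_template_similarity(trials, np.zeros(8))


class TestPrestimStateSplit:
    def test_band_amplitude_orders_sinusoids(self):
        fs = FS
        t = np.arange(0, 120, 1 / fs)
        trace = np.sin(2 * np.pi * 5 * t)  # in-band
        trace[len(t) // 2 :] = np.sin(2 * np.pi * 13 * t[len(t) // 2 :])  # out of band
        onsets = [int(1.0 * fs), int(len(t) // 2 + 1.0 * fs),
                  int(20 * fs), int(len(t) // 2 + 20 * fs)]
        split = split_by_prestim_state(trace, onsets, fs)
        assert split.labels[0] == "synchronized"
        assert split.labels[1] == "desynchronized"

    def test_window_before_start_rejected(self):
        with pytest.raises(ValueError):
            split_by_prestim_state(np.zeros(1000), [5], FS)

    def test_sd_regimes_recovered(self, rng):
        # trials drawn from two band-amplitude regimes (SD ratio 3)
        fs = FS
        from bihemi.preprocess import bandpass

        n_trials, seg = 60, int(3.0 * fs)
        trace = []
        truth_labels = []
        for i in range(n_trials):
            sd = 3.0 if i % 2 == 0 else 1.0
            trace.append(sd * bandpass(rng.standard_normal(seg), 2, 7, fs))
            truth_labels.append("synchronized" if sd == 3.0 else "desynchronized")
        trace = np.concatenate(trace)
        onsets = [(i + 1) * seg - 1 for i in range(n_trials)]
        split = split_by_prestim_state(trace, onsets, fs)
        agreement = (split.labels == np.array(truth_labels)).mean()
        assert agreement >= 0.9


class TestNakaRushtonFit:
    CONTRASTS = np.repeat([0.0, 0.06, 0.12, 0.25, 0.5, 1.0], 20)

    def test_noiseless_recovery(self):
        r = naka_rushton(self.CONTRASTS, 0.1, 1.0, 0.25, 2.0)
        fit = fit_naka_rushton(self.CONTRASTS, r)
        assert fit.residual == pytest.approx(0.0, abs=1e-10)
        assert (fit.r0, fit.rmax, fit.c50, fit.n) == pytest.approx(
            (0.1, 1.0, 0.25, 2.0), abs=1e-4)

    def test_curve_passes_half_saturation_at_c50(self):
        r = naka_rushton(self.CONTRASTS, 0.2, 0.8, 0.3, 1.7)
        fit = fit_naka_rushton(self.CONTRASTS, r)
        assert fit(fit.c50) == pytest.approx(fit.r0 + fit.rmax / 2, abs=1e-6)

    def test_fixed_stage_is_exact_least_squares(self, rng):
        c = self.CONTRASTS
        r = naka_rushton(c, 0.3, 1.2, 0.25, 2.0) + 0.01 * rng.standard_normal(len(c))
        fit = fit_naka_rushton(c, r, fixed=(0.25, 2.0))
        x = c**2.0 / (0.25**2.0 + c**2.0)
        coef = np.polyfit(x, r, 1)
        assert fit.rmax == pytest.approx(coef[0], abs=1e-8)
        assert fit.r0 == pytest.approx(coef[1], abs=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_naka_rushton(np.array([0.0, 1.0]), np.array([0.0, 1.0]))  # < 4 levels
        with pytest.raises(ValueError):
            fit_naka_rushton(self.CONTRASTS, naka_rushton(self.CONTRASTS, 0, 1, 0.3, 2),
                             fixed=(-0.1, 2.0))

    def test_two_stage_offset_shift_moves_r0_only(self, rng):
        c = np.repeat([0.0, 0.06, 0.12, 0.25, 0.5, 1.0], 40)
        base = naka_rushton(c, 0.1, 1.0, 0.25, 2.0)
        labels = np.tile(["low", "high"], len(c) // 2)
        r = base + 0.2 * (labels == "high") + 0.05 * rng.standard_normal(len(c))
        split = evoked.TrialSplit("test", labels)
        _, groups = fit_naka_rushton_groups(c, r, split)
        assert groups["high"].r0 - groups["low"].r0 == pytest.approx(0.2, abs=0.03)
        assert groups["high"].rmax / groups["low"].rmax == pytest.approx(1.0, abs=0.05)

    def test_median_option(self, rng):
        c = self.CONTRASTS
        r = naka_rushton(c, 0.0, 1.0, 0.3, 2.0) + 0.02 * rng.standard_normal(len(c))
        r[::25] += 10.0  # gross outliers barely move the median fit
        fit = fit_naka_rushton(c, r, use_median=True)
        assert fit.rmax == pytest.approx(1.0, abs=0.1)
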