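"""Synthetic-session generator: coupling calibration, evoked waveform
contract, determinism, rendering."""

import numpy as np
import pytest
from scipy import stats

from bihemi import synth
from bihemi.areas import AreaSet
from bihemi.evoked import (
    NakaRushtonParams,
    RESPONSE_WINDOW,
    epoch_trials,
    response_amplitude,
)
from conftest import pair_truth


def _pair_corr(truth, n_frames, seed):
    fl = synth.generate_bilateral_fluctuations(truth, n_frames, seed)
    return np.corrcoef(fl[0], fl[1])[0, 1]


class TestBilateralFluctuations:
    def test_full_coupling_gives_identical_hemispheres(self):
        fl = synth.generate_bilateral_fluctuations(pair_truth(1.0), 2000, seed=0)
        np.testing.assert_allclose(fl[0], fl[1], atol=1e-12)

    def test_zero_coupling_gives_independent_hemispheres(self):
        truth = pair_truth(1e-6, h_true=1e-6)
        assert abs(_pair_corr(truth, 50_000, seed=1)) < 0.02

    def test_intermediate_coupling_calibrated(self):
        # Monte-Carlo check of the sqrt(rho) common/private mix at large n
        assert _pair_corr(pair_truth(0.8), 100_000, seed=2) == pytest.approx(0.8, abs=0.02)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synth.GroundTruth(areas=[synth.AreaSpec("PM", 1.6, 1.5)])
        with pytest.raises(ValueError):
            synth.GroundTruth(fs=-1.0)
        with pytest.raises(ValueError):
            synth.generate_bilateral_fluctuations(pair_truth(0.5), 0, seed=0)

    def test_band_limited_spectrum(self):
        from scipy.signal import welch

        truth = pair_truth(0.5)
        fl = synth.generate_bilateral_fluctuations(truth, 50_000, seed=3)
        f, psd = welch(fl[0], fs=truth.fs, nperseg=512)
        in_band = psd[(f > 2.5) & (f < 6.5)].mean()
        out_band = psd[(f > 10) & (f < 16)].mean()
        assert in_band > 50 * out_band

    def test_passive_condition_uses_passive_coupling(self):
        truth = synth.GroundTruth()
        names = truth.area_set().names
        i, j = names.index("M2_L"), names.index("M2_R")
        fl_act = synth.generate_bilateral_fluctuations(truth, 60_000, 4, "active")
        fl_pas = synth.generate_bilateral_fluctuations(truth, 60_000, 4, "passive")
        r_act = np.corrcoef(fl_act[i], fl_act[j])[0, 1]
        r_pas = np.corrcoef(fl_pas[i], fl_pas[j])[0, 1]
        assert r_pas > r_act + 0.15


class TestEvokedTimeCourse:
    def test_zero_contrast_zero_offset_is_silent(self):
        truth = pair_truth(0.8)
        t = np.linspace(-0.1, 0.5, 200)
        np.testing.assert_array_equal(synth.evoked_time_course(0.0, t, truth), 0.0)

    def test_window_mean_at_c50_is_half_saturation(self):
        # R(C50) = R0 + Rmax/2 by definition of the semi-saturation contrast
        truth = pair_truth(0.8, nr=NakaRushtonParams(0.1, 1.0, 0.3, 2.0))
        t = np.arange(0.05, 0.15, 1e-4) + 5e-5  # midpoint samples of [0.05, 0.15)
        mean = synth.evoked_time_course(0.3, t, truth).mean()
        assert mean == pytest.approx(0.1 + 0.5, abs=1e-3)

    def test_window_mean_direct_evaluation(self):
        # R(1) = 2 * 1 / (0.25^2 + 1) for R0=0, Rmax=2, C50=0.25, n=2
        truth = pair_truth(0.8, nr=NakaRushtonParams(0.0, 2.0, 0.25, 2.0))
        t = np.arange(0.05, 0.15, 1e-4) + 5e-5
        mean = synth.evoked_time_course(1.0, t, truth).mean()
        assert mean == pytest.approx(2.0 / 1.0625, abs=1e-3)

    def test_silent_before_onset_and_contrast_domain(self):
        truth = pair_truth(0.8)
        assert synth.evoked_time_course(1.0, np.array([-0.01, 0.0, 0.049]), truth).max() == 0
        with pytest.raises(ValueError):
            synth.evoked_time_course(1.2, 0.1, truth)


class TestGenerateSession:
    def test_rejects_bad_inputs(self):
        truth = pair_truth(0.8)
        with pytest.raises(ValueError):
            synth.generate_session(truth, 0, [0, 0.5], seed=0)
        with pytest.raises(ValueError):
            synth.generate_session(truth, 10, [0.5, 1.0], seed=0)  # no 0% trials

    def test_no_corruption_means_measured_equals_truth(self):
        truth = pair_truth(0.8, noise_sd=0.0)
        s = synth.generate_session(truth, 12, [0, 0.5], seed=5)
        np.testing.assert_array_equal(s.measured, s.roi_traces)

    def test_same_seed_bit_identical(self):
        truth = pair_truth(0.7, noise_sd=0.1)
        a = synth.generate_session(truth, 15, [0, 0.25, 1.0], seed=9)
        b = synth.generate_session(truth, 15, [0, 0.25, 1.0], seed=9)
        np.testing.assert_array_equal(a.measured, b.measured)
        assert a.trials.equals(b.trials)

    def test_evoked_is_contralateral_only(self):
        truth = pair_truth(1e-6, h_true=1e-6, noise_sd=0.0)
        s = synth.generate_session(truth, 300, [0, 1.0], seed=6, iti_s=1.2)
        onsets = s.trials["onset_frame"].to_numpy()
        for hemi, stim_side in (("R", "L"), ("L", "R")):
            ep = epoch_trials(s.trace(f"PM_{hemi}", "truth"), onsets, (-0.2, 0.4),
                              s.fs, meta=s.trials)
            amp = response_amplitude(ep, RESPONSE_WINDOW)
            contra = ((s.trials["side"] == stim_side) & (s.trials["contrast"] > 0)).to_numpy()
            ipsi = ((s.trials["side"] != stim_side) & (s.trials["contrast"] > 0)).to_numpy()
            # R(1) ~ 0.917 for the default curve; ongoing SD 1 leaves ~0.13 SE
            assert amp[contra].mean() - amp[ipsi].mean() == pytest.approx(0.917, abs=0.35)
            assert abs(amp[ipsi].mean()) < 0.3

    def test_unstimulated_amplitude_flat_across_contrasts(self):
        # contrast must not leak into the unstimulated hemisphere
        truth = pair_truth(0.6, noise_sd=0.05)
        s = synth.generate_session(truth, 500, [0, 0.12, 0.25, 0.5, 1.0], seed=7, iti_s=1.2)
        trials = s.trials
        left_stim = (trials["side"] == "L").to_numpy()
        ep = epoch_trials(s.trace("PM_L"), trials["onset_frame"].to_numpy(),
                          (-0.2, 0.4), s.fs, meta=trials)
        amp = response_amplitude(ep)
        res = stats.linregress(trials["contrast"].to_numpy()[left_stim], amp[left_stim])
        assert res.pvalue > 0.01

    def test_amplitude_noise_raises_stimulated_sd_only(self):
        kw = dict(n_trials=400, contrast_set=[0, 1.0], seed=8, iti_s=1.2)
        quiet = synth.generate_session(pair_truth(0.5, noise_sd=0.0), **kw)
        noisy = synth.generate_session(
            pair_truth(0.5, noise_sd=0.0, amp_noise_sd=1.0), **kw)

        def sds(s):
            trials = s.trials
            sel = ((trials["side"] == "L") & (trials["contrast"] == 1.0)).to_numpy()
            out = []
            for hemi in ("R", "L"):  # stimulated first
                ep = epoch_trials(s.trace(f"PM_{hemi}"), trials["onset_frame"].to_numpy(),
                                  (-0.2, 0.4), s.fs, meta=trials)
                out.append(response_amplitude(ep)[sel].std(ddof=1))
            return out

        sd_stim_q, sd_unstim_q = sds(quiet)
        sd_stim_n, sd_unstim_n = sds(noisy)
        assert sd_stim_q == pytest.approx(sd_unstim_q, rel=0.15)
        assert sd_stim_n > sd_unstim_n * 1.2

    def test_choices_follow_contrast_not_fluctuation(self, small_session):
        trials = small_session.trials
        high = trials["contrast"] >= 0.5
        correct = (trials["choice"] == trials["side"])[high].mean()
        nogo0 = (trials.loc[trials["contrast"] == 0, "choice"] == "NoGo").mean()
        assert correct > 0.6
        assert nogo0 > 0.3


class TestRenderMovie:
    def _single_pixel_setup(self):
        areas = AreaSet.bilateral(["PM"], [1.6])
        masks = {}
        for i, name in enumerate(areas.names):
            m = np.zeros((4, 4), dtype=bool)
            m[i, i] = True
            masks[name] = m
        return areas.with_masks(masks)

    def test_single_pixel_zero_noise_roundtrip(self):
        from bihemi.preprocess import extract_roi_traces

        areas = self._single_pixel_setup()
        traces = np.arange(8, dtype=float).reshape(2, 4)
        movie = synth.render_movie(traces, areas, (4, 4), pixel_noise_sd=0.0)
        np.testing.assert_array_equal(extract_roi_traces(movie, areas), traces)

    def test_empty_and_overlapping_masks_rejected(self):
        areas = AreaSet.bilateral(["PM"], [1.6])
        empty = {n: np.zeros((4, 4), dtype=bool) for n in areas.names}
        with pytest.raises(ValueError, match="empty"):
            synth.render_movie(np.zeros((2, 5)), areas.with_masks(empty), (4, 4))
        full = {n: np.ones((4, 4), dtype=bool) for n in areas.names}
        with pytest.raises(ValueError, match="overlap"):
            synth.render_movie(np.zeros((2, 5)), areas.with_masks(full), (4, 4))

    def test_roi_mean_noise_shrinks_with_mask_size(self):
        # 100-pixel mask: ROI-mean noise SD ~ sigma / 10
        from bihemi.preprocess import extract_roi_traces

        areas = AreaSet.bilateral(["PM"], [1.6])
        masks = {
            "PM_L": np.zeros((10, 20), dtype=bool),
            "PM_R": np.zeros((10, 20), dtype=bool),
        }
        masks["PM_L"][:, :10] = True
        masks["PM_R"][:, 10:] = True
        areas = areas.with_masks(masks)
        traces = np.zeros((2, 4000))
        movie = synth.render_movie(traces, areas, (10, 20), pixel_noise_sd=1.0,
                                   rng=np.random.default_rng(0))
        got = extract_roi_traces(movie, areas)
        assert got[0].std() == pytest.approx(0.1, rel=0.1)

    def test_default_masks_are_disjoint_and_mirrored(self, default_truth):
        areas = default_truth.area_set()
        masks = synth.default_masks(areas, (64, 64))
        total = np.zeros((64, 64), dtype=int)
        for m in masks.values():
            total += m
        assert total.max() == 1
        for base in areas.bases:
            assert masks[f"{base}_L"].sum() == masks[f"{base}_R"].sum() > 0
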