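"""Intrinsic-signal synthesis, Fourier retinotopy, delta-R/R maps, cut-off."""

import math

import numpy as np
import pytest

from vplmouse.imaging import (
    ConditionMap,
    CortexTruth,
    FrameStack,
    StimulusSchedule,
    condition_map,
    cortex_truth,
    cutoff_sf,
    default_roi,
    fourier_map,
    load_stack,
    map_scatter,
    roi_tuning,
    save_stack,
    smooth_map,
    synth_cortex,
    trial_maps,
)


def _episodic(sf=0.2, n_trials=4):
    return StimulusSchedule(mode="episodic", sf_cpd=sf, n_trials=n_trials)


class TestFourierMap:
    def test_pure_cosine_identity(self):
        # amplitude and phase recovered to near machine precision
        fr, n = 4.0, 256
        t = (np.arange(n) + 0.5) / fr
        f = 0.125                          # exactly on the DFT grid (8 cyc)
        amp, phi = 0.7, 1.1
        frames = (1.0 + amp * np.cos(2 * math.pi * f * t - phi))[
            :, None, None] * np.ones((1, 4, 4))
        stack = FrameStack(frames=frames, frame_interval_s=1 / fr,
                           schedule=StimulusSchedule(mode="periodic",
                                                     frequency_hz=f))
        rmap = fourier_map(stack, f)
        assert np.allclose(rmap.magnitude, amp, atol=1e-10)
        assert np.allclose(np.angle(np.exp(1j * (rmap.phase + phi))), 0.0,
                           atol=1e-10)

    def test_constant_stack_has_zero_magnitude(self):
        stack = FrameStack(frames=np.full((64, 5, 5), 2.0),
                           frame_interval_s=0.2)
        assert np.allclose(fourier_map(stack, 0.5).magnitude, 0.0, atol=1e-12)

    def test_matches_naive_dft_oracle(self, rng):
        frames = rng.normal(1.0, 0.1, size=(256, 16, 16))
        stack = FrameStack(frames=frames, frame_interval_s=0.2)
        f = 0.1
        rmap = fourier_map(stack, f)
        # independent oracle: explicit per-pixel discrete Fourier sum
        t = (np.arange(256) + 0.5) * 0.2
        x = frames - frames.mean(axis=0)
        oracle = np.zeros((16, 16), dtype=complex)
        for i in range(16):
            for j in range(16):
                oracle[i, j] = (x[:, i, j]
                                * np.exp(-2j * math.pi * f * t)).sum()
        oracle *= 2.0 / 256
        assert np.max(np.abs(np.abs(oracle) - rmap.magnitude)) < 1e-8
        assert np.max(np.abs(np.angle(oracle) - rmap.phase)) < 1e-8

    def test_above_nyquist_rejected(self):
        stack = FrameStack(frames=np.ones((16, 2, 2)), frame_interval_s=0.2)
        with pytest.raises(ValueError):
            fourier_map(stack, 3.0)

    def test_periodic_synthesis_amplitude(self, rng):
        truth = CortexTruth(noise_sd=0.0, drift_amplitude=0.0,
                            amplitude=1e-3, blob_sigma=100.0)
        sched = StimulusSchedule(mode="periodic", frequency_hz=0.1,
                                 duration_s=200.0)
        stack = synth_cortex(truth, sched, rng, shape=(8, 8), frame_rate=5.0)
        rmap = fourier_map(stack, 0.1)
        center = rmap.magnitude[4, 4]
        assert center == pytest.approx(1e-3, rel=1e-3)


class TestConditionMap:
    def test_no_response_gives_zero_map(self, rng):
        truth = CortexTruth(amplitude=0.0, noise_sd=0.0, drift_amplitude=0.0)
        stack = synth_cortex(truth, _episodic(), rng, shape=(8, 8))
        assert np.allclose(condition_map(stack).data, 0.0, atol=1e-12)

    def test_fractional_response_recovered_exactly(self):
        # frames = baseline * (1 + r) inside the window -> map equals r
        sched = _episodic(n_trials=3)
        fr = 5.0
        per = int(sched.trial_s * fr)
        t_in = (np.arange(per) + 0.5) / fr
        r = -0.0042
        h = ((t_in >= sched.baseline_s + 2.0)
             & (t_in < sched.baseline_s + 6.0)).astype(float)
        frames = np.tile(2.0 * (1.0 + r * h)[:, None, None], (3, 6, 6))
        stack = FrameStack(frames=frames, frame_interval_s=1 / fr,
                           schedule=sched)
        assert np.allclose(condition_map(stack).data, r, atol=1e-12)

    def test_trial_average_matches_brute_force(self, rng):
        truth = cortex_truth("trained")
        stack = synth_cortex(truth, _episodic(n_trials=6), rng, shape=(12, 12))
        cm = condition_map(stack)
        assert np.allclose(cm.data, trial_maps(stack).mean(axis=0),
                           atol=1e-12)

    def test_zero_baseline_rejected(self):
        sched = _episodic(n_trials=1)
        frames = np.zeros((int(sched.trial_s * 5), 4, 4))
        stack = FrameStack(frames=frames, frame_interval_s=0.2,
                           schedule=sched)
        with pytest.raises(ValueError, match="zero baseline"):
            trial_maps(stack)

    def test_linear_in_embedded_response(self, rng):
        sched = _episodic(sf=0.1, n_trials=4)
        maps = []
        for amp in (1e-3, 2e-3):
            truth = CortexTruth(amplitude=amp, noise_sd=0.0,
                                drift_amplitude=0.0, cutoff_cpd=0.39)
            st = synth_cortex(truth, sched,
                              np.random.default_rng(0), shape=(10, 10))
            maps.append(condition_map(st).data)
        # frames are rendered in float32; allow that quantization only
        assert np.allclose(maps[1], 2.0 * maps[0], atol=3e-7)


class TestSmoothMap:
    def test_constant_map_unchanged(self):
        cm = ConditionMap(np.full((20, 20), 3.3))
        assert np.allclose(smooth_map(cm).data, 3.3, atol=1e-12)

    def test_impulse_spreads_over_disk(self):
        from skimage.morphology import disk
        img = np.zeros((21, 21))
        img[10, 10] = 5.0
        out = smooth_map(ConditionMap(img), radius_px=3).data
        kernel = disk(3)
        npx = kernel.sum()
        # interior: impulse contributes v / disk-count wherever the disk
        # covers the impulse
        expected = np.zeros_like(img)
        ii, jj = np.nonzero(kernel)
        expected[10 + ii - 3, 10 + jj - 3] = 5.0 / npx
        assert np.allclose(out, expected, atol=1e-12)

    def test_mean_preserved_within_border_effects(self, rng):
        img = rng.normal(0, 1, size=(100, 100))
        out = smooth_map(ConditionMap(img), radius_px=3).data
        assert abs(out.mean() - img.mean()) < 0.01 * max(1.0, abs(img.mean()))


class TestRoiTuning:
    def test_uniform_map_negated_mean(self):
        cm = ConditionMap(np.full((8, 8), -2e-3), sf_cpd=0.1)
        roi = np.ones((8, 8), dtype=bool)
        assert roi_tuning([(0.1, cm)], roi) == [(0.1, pytest.approx(2e-3))]

    def test_amplitude_ratio_preserved(self):
        a = ConditionMap(np.full((8, 8), -2e-3))
        b = ConditionMap(np.full((8, 8), -1e-3))
        roi = np.ones((8, 8), dtype=bool)
        out = roi_tuning([(0.1, a), (0.2, b)], roi)
        assert out[0][1] == pytest.approx(2 * out[1][1])

    def test_arbitrary_roi_matches_masked_mean(self, rng):
        img = rng.normal(0, 1, size=(16, 16))
        roi = rng.random((16, 16)) > 0.6
        out = roi_tuning([(0.3, ConditionMap(img))], roi)
        assert out[0][1] == pytest.approx(-img[roi].mean())

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_tuning([(0.1, ConditionMap(np.ones((4, 4))))],
                       np.zeros((4, 4), dtype=bool))

    def test_default_roi_top_decile(self, rng):
        img = -rng.random((20, 20))
        roi = default_roi(ConditionMap(img), quantile=0.9)
        assert roi.sum() == pytest.approx(40, abs=5)
        assert (-img[roi]).min() >= np.quantile(-img, 0.9) - 1e-12


class TestCutoffSf:
    def test_exact_line(self):
        fit = cutoff_sf([(0.1, 0.3), (0.2, 0.2), (0.3, 0.1)])
        assert fit.slope == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(0.4)
        assert fit.cutoff == pytest.approx(0.4)
        assert fit.valid

    def test_flat_tuning_rejected(self):
        with pytest.raises(ValueError, match="declining"):
            cutoff_sf([(0.1, 0.2), (0.2, 0.2), (0.3, 0.2)])

    def test_noiseless_linear_recovery_to_machine_precision(self):
        truth = 0.39
        sfs = np.arange(0.05, 0.36, 0.05)
        pts = [(s, 1e-3 * (1 - s / truth)) for s in sfs]
        assert cutoff_sf(pts).cutoff == pytest.approx(truth, rel=1e-12)

    def test_noise_floor_selects_declining_limb(self):
        pts = [(0.1, 0.8), (0.2, 0.6), (0.3, 0.4), (0.4, 0.2),
               (0.5, 0.01), (0.6, -0.005)]
        fit = cutoff_sf(pts, noise_floor=0.05)
        assert fit.fitted_mask.tolist() == [True] * 5 + [False]


class TestScatter:
    def test_smooth_gradient_scores_near_zero(self):
        xx = np.linspace(-math.pi / 2, math.pi / 2, 32)
        phase = np.tile(xx, (32, 1))
        from vplmouse.imaging import RetinotopyMap
        rmap = RetinotopyMap(magnitude=np.ones((32, 32)), phase=phase)
        s = map_scatter(rmap, 0.5)
        # bounded by the within-disk gradient term
        assert s < 0.2

    def test_random_phases_match_circular_uniform_expectation(self, rng):
        from skimage.morphology import disk

        from vplmouse.imaging import RetinotopyMap
        phase = rng.uniform(-math.pi, math.pi, size=(64, 64))
        rmap = RetinotopyMap(magnitude=np.ones((64, 64)), phase=phase)
        s = map_scatter(rmap, 0.5)
        # Monte-Carlo oracle of the same statistic: one pixel's absolute
        # circular deviation from the circular mean of its disk (the pixel
        # belongs to its own neighbourhood, so the value sits below pi/2)
        k = int(disk(3).sum())
        th = rng.uniform(-math.pi, math.pi, size=(20_000, k))
        local = np.angle(np.exp(1j * th).sum(axis=1))
        oracle = np.abs(np.angle(np.exp(1j * (th[:, 0] - local)))).mean()
        assert s == pytest.approx(oracle, rel=0.05)

    def test_noise_monotonically_increases_scatter(self, rng):
        from vplmouse.imaging import RetinotopyMap
        xx = np.tile(np.linspace(-1.0, 1.0, 48), (48, 1))
        scatters = []
        for sd in (0.0, 0.3, 0.9):
            phase = xx + rng.normal(0, sd, size=xx.shape)
            phase = np.angle(np.exp(1j * phase))
            rmap = RetinotopyMap(magnitude=np.ones_like(phase), phase=phase)
            scatters.append(map_scatter(rmap, 0.5))
        assert scatters[0] < scatters[1] < scatters[2]


class TestEndToEnd:
    def test_blank_amplitude_gives_blank_pipeline(self, rng):
        truth = CortexTruth(amplitude=0.0, noise_sd=0.0, drift_amplitude=0.0)
        stack = synth_cortex(truth, _episodic(), rng, shape=(8, 8))
        cm = smooth_map(condition_map(stack))
        assert np.allclose(cm.data, 0.0, atol=1e-12)

    def test_trained_truth_recovered_and_ordered(self):
        from vplmouse.imaging import simulate_cutoff_animal
        res = {}
        for prof in ("trained", "untrained"):
            vals = []
            for i in (1, 2, 3):
                rng = np.random.default_rng(
                    np.random.SeedSequence((900 + i, i)))
                out = simulate_cutoff_animal(cortex_truth(prof), rng,
                                             shape=(32, 32), n_trials=8)
                vals.append(out["fit"].cutoff)
            res[prof] = float(np.mean(vals))
        assert res["trained"] == pytest.approx(0.39, abs=0.04)
        assert res["untrained"] < res["trained"]

    def test_tiff_json_roundtrip(self, tmp_path, rng):
        truth = cortex_truth("trained")
        stack = synth_cortex(truth, _episodic(n_trials=2), rng, shape=(8, 8))
        path = tmp_path / "stack.tiff"
        save_stack(stack, path)
        back = load_stack(path)
        assert np.allclose(back.frames, stack.frames, atol=1e-7)
        assert back.schedule == stack.schedule
        assert back.frame_interval_s == stack.frame_interval_s
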