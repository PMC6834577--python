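"""Synthetic data generation: phantoms, plasma and tissue curves, rendering."""

import numpy as np
import pytest

from nanoktrans.core import PlasmaParams, spgr_signal
from nanoktrans.synth import (
    default_scene,
    render_dynamic_study,
    simulate_phantom_series,
    simulate_plasma_curve,
    simulate_tissue_curve,
)


class TestPhantom:
    def test_saturation_limit_recovers_s0(self):
        ph = simulate_phantom_series([0.0], 0.5, 4.78, [1e4], s0=2.0)
        assert ph.tube_means()[0, 0] == pytest.approx(2.0, rel=1e-12)

    def test_rejects_non_positive_tr(self):
        with pytest.raises(ValueError, match="-0.2"):
            simulate_phantom_series([0.1], 0.5, 4.78, [0.5, -0.2])

    def test_truth_table_records_t1(self):
        conc = np.array([0.25, 0.125, 0.0])
        ph = simulate_phantom_series(conc, 0.4, 4.78, [0.2, 0.5, 2.0])
        assert np.allclose(ph.truth["r1_s"], 0.4 + 4.78 * conc)
        assert np.allclose(ph.truth["t1_s"], 1.0 / (0.4 + 4.78 * conc))

    def test_noise_reproducible_by_seed(self):
        a = simulate_phantom_series([0.1], 0.5, 4.1, [0.5], noise_sigma=0.01, seed=3)
        b = simulate_phantom_series([0.1], 0.5, 4.1, [0.5], noise_sigma=0.01, seed=3)
        assert np.array_equal(a.signals, b.signals)


class TestPlasmaCurve:
    def test_initial_value_is_sum_of_amplitudes(self):
        p = PlasmaParams(a=1.0, alpha=0.2, b=0.5, beta=0.02)
        assert simulate_plasma_curve(np.array([0.0]), p)[0] == pytest.approx(1.5)

    def test_zero_before_injection(self):
        p = PlasmaParams(a=1.0, alpha=0.2, b=0.5, beta=0.02)
        cp = simulate_plasma_curve(np.array([-5.0, -0.1, 1.0]), p)
        assert cp[0] == 0.0 and cp[1] == 0.0 and cp[2] > 0

    def test_single_phase_halves_at_half_life(self):
        # elimination half-life 15.70 min as the only phase
        beta = np.log(2) / 15.70
        p = PlasmaParams(a=0.0, alpha=2 * beta, b=1.0, beta=beta)
        cp = simulate_plasma_curve(np.array([15.70]), p)
        assert cp[0] == pytest.approx(0.5, rel=1e-12)

    def test_degenerate_merge_is_single_exponential(self):
        p = PlasmaParams(a=0.7, alpha=0.1, b=0.7, beta=0.1)
        t = np.linspace(0, 30, 50)
        assert np.allclose(simulate_plasma_curve(t, p), 1.4 * np.exp(-0.1 * t))


class TestTissueCurve:
    def test_zero_ktrans_gives_zero_curve(self, plasma, frame_times_s):
        ct = simulate_tissue_curve(plasma, frame_times_s, 0.0, 0.3)
        assert np.all(ct == 0)

    def test_constant_plasma_equilibrates_at_ve_times_c(self):
        t = np.linspace(0, 36000, 400)  # 600 min: many washout time constants
        const = (np.array([0.0, 36000.0]), np.array([0.8, 0.8]))
        ct = simulate_tissue_curve(const, t, 0.2, 0.3)
        assert ct[-1] == pytest.approx(0.3 * 0.8, rel=1e-6)

    def test_matches_closed_form_biexponential_convolution(self, plasma, frame_times_s):
        kt, ve = 0.17, 0.3
        ct = simulate_tissue_curve(plasma, frame_times_s, kt, ve)
        kep = kt / ve
        tm = frame_times_s / 60.0
        want = np.zeros_like(tm)
        for amp, rate in ((plasma.a, plasma.alpha), (plasma.b, plasma.beta)):
            want += amp * (np.exp(-rate * tm) - np.exp(-kep * tm)) / (kep - rate)
        want *= kt
        assert np.max(np.abs(ct - want)) < 1e-5 * want.max()

    def test_bounded_by_ve_times_peak_plasma(self, plasma, frame_times_s):
        ct = simulate_tissue_curve(plasma, frame_times_s, 0.4, 0.25)
        assert np.all(ct >= 0)
        assert ct.max() <= 0.25 * (plasma.a + plasma.b) * (1 + 1e-9)

    def test_fine_grid_convergence(self, plasma, frame_times_s):
        a = simulate_tissue_curve(plasma, frame_times_s, 0.17, 0.3, fine_dt_s=1.0)
        b = simulate_tissue_curve(plasma, frame_times_s, 0.17, 0.3, fine_dt_s=0.5)
        assert np.max(np.abs(a - b)) < 1e-3 * a.max()

    def test_rejects_zero_ve_with_positive_ktrans(self, plasma, frame_times_s):
        with pytest.raises(ValueError, match="washout"):
            simulate_tissue_curve(plasma, frame_times_s, 0.1, 0.0)


class TestRender:
    def test_noiseless_frame_equals_analytic_spgr(self, small_noiseless):
        scene = small_noiseless["scene"]
        study = small_noiseless["study"]
        truth = small_noiseless["truth"]
        i, j, k = np.argwhere(scene.labels == 1)[0]  # a focal voxel
        want = spgr_signal(
            scene.m0, truth.r1_true[i, j, k, 0], scene.tr_s, scene.dynamic_flip_deg
        )
        assert study.series[i, j, k, 2] == pytest.approx(want, rel=1e-12)

    def test_same_seed_bit_identical(self):
        kw = dict(shape=(8, 8, 1), n_frames=12, noise_sigma=0.01, seed=5)
        a, _ = render_dynamic_study(default_scene(**kw))
        b, _ = render_dynamic_study(default_scene(**kw))
        assert np.array_equal(a.series, b.series)

    def test_seed_changes_noise_not_signal(self):
        kw = dict(shape=(8, 8, 1), n_frames=12)
        noisy1, _ = render_dynamic_study(default_scene(seed=1, noise_sigma=0.01, **kw))
        noisy2, _ = render_dynamic_study(default_scene(seed=2, noise_sigma=0.01, **kw))
        clean1, _ = render_dynamic_study(default_scene(seed=1, noise_sigma=0.0, **kw))
        clean2, _ = render_dynamic_study(default_scene(seed=2, noise_sigma=0.0, **kw))
        assert not np.array_equal(noisy1.series, noisy2.series)
        assert np.array_equal(clean1.series, clean2.series)

    def test_vessel_carries_plasma_curve(self, small_noiseless):
        scene = small_noiseless["scene"]
        truth = small_noiseless["truth"]
        v = scene.labels == 4
        cp = simulate_plasma_curve(scene.frame_times_s / 60.0, scene.plasma)
        assert np.allclose(truth.c_true[v], cp)

    def test_rician_option(self):
        study, _ = render_dynamic_study(
            default_scene(shape=(8, 8, 1), n_frames=12, noise_sigma=0.01,
                          noise_model="rician", seed=0)
        )
        assert np.all(study.series >= 0)

    def test_scene_validation(self):
        scene = default_scene(shape=(8, 8, 1), n_frames=5)
        with pytest.raises(ValueError, match="ve"):
            default_scene(shape=(8, 8, 1), n_frames=5, focal_ve=1.5)
        bad = np.array(scene.frame_times_s)
        bad[3] = bad[2]
        with pytest.raises(ValueError, match="increasing"):
            type(scene)(**{**scene.__dict__, "frame_times_s": bad})
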