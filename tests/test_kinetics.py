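"""Reference-region model: forward evaluation and voxel-wise fitting."""

import numpy as np
import pytest

from nanoktrans.kinetics import (
    ReferenceCurve,
    RRMConfig,
    build_reference_curve,
    fit_rrm_voxel,
    map_ktrans,
    rrm_forward,
)
from nanoktrans.synth import simulate_tissue_curve


@pytest.fixture(scope="module")
def reference(plasma, frame_times_s):
    cfg = RRMConfig()
    c_rr = simulate_tissue_curve(plasma, frame_times_s, cfg.ktrans_rr, cfg.ve_rr)
    t_min = np.concatenate([[0.0], frame_times_s / 60.0])
    c_rr = np.concatenate([[0.0], c_rr])
    return cfg, t_min, c_rr


class TestForward:
    def test_matched_parameters_return_reference_curve(self, reference):
        cfg, t, c = reference
        got = rrm_forward(c, t, cfg.ktrans_rr, cfg.ktrans_rr, cfg.ve_rr, cfg.ve_rr)
        assert np.allclose(got, c, atol=1e-14)

    def test_zero_ktrans_returns_zero(self, reference):
        cfg, t, c = reference
        assert np.all(rrm_forward(c, t, 0.0, cfg.ktrans_rr, 0.3, cfg.ve_rr) == 0)

    def test_against_dense_quadrature_oracle(self, reference):
        cfg, t, c = reference
        kt, ve = 0.17, 0.3
        kep = kt / ve
        got = rrm_forward(c, t, kt, cfg.ktrans_rr, ve, cfg.ve_rr)
        dense = np.linspace(t[0], t[-1], 400001)
        cd = np.interp(dense, t, c)
        for i in (20, 60, 100):
            integral = np.trapezoid(
                cd[dense <= t[i]]
                * np.exp(-kep * (t[i] - dense[dense <= t[i]])),
                dense[dense <= t[i]],
            )
            want = (kt / cfg.ktrans_rr) * (
                c[i] + (cfg.ktrans_rr / cfg.ve_rr - kep) * integral
            )
            assert got[i] == pytest.approx(want, rel=1e-3)

    def test_monotone_in_ktrans_at_fixed_washout(self, reference):
        # at fixed kep = ktrans/ve the model is linear in ktrans, so the
        # predicted curve grows pointwise with ktrans
        cfg, t, c = reference
        kep = 0.6
        curves = [
            rrm_forward(c, t, kt, cfg.ktrans_rr, kt / kep, cfg.ve_rr)
            for kt in np.linspace(0.01, 0.5, 8)
        ]
        for lo, hi in zip(curves[:-1], curves[1:]):
            assert np.all(hi[1:] > lo[1:])

    def test_rejects_bad_time_grid(self, reference):
        cfg, t, c = reference
        bad = t.copy()
        bad[5] = bad[4]
        with pytest.raises(ValueError, match="increasing"):
            rrm_forward(c, bad, 0.1, cfg.ktrans_rr, 0.3, cfg.ve_rr)


class TestVoxelFit:
    def test_noiseless_focal_voxel_recovered(self, plasma, frame_times_s, reference):
        cfg, t, c = reference
        ref = ReferenceCurve.from_samples(t, c, cfg)
        ct = simulate_tissue_curve(plasma, frame_times_s, 0.170, 0.3)
        fit = fit_rrm_voxel(ct, ref, config=cfg)
        assert fit.converged and fit.flag == ""
        assert fit.ktrans == pytest.approx(0.170, rel=0.02)
        assert fit.ve == pytest.approx(0.3, rel=0.05)

    def test_reference_parameters_give_unit_ratio(self, plasma, frame_times_s, reference):
        cfg, t, c = reference
        fit = fit_rrm_voxel(c, c_rr=c, times_min=t, config=cfg)
        assert fit.ratio == pytest.approx(1.0, rel=0.01)

    def test_ratio_identity_holds_exactly(self, plasma, frame_times_s, reference):
        cfg, t, c = reference
        ct = simulate_tissue_curve(plasma, frame_times_s, 0.05, 0.2)
        fit = fit_rrm_voxel(ct, c_rr=c, times_min=t, config=cfg)
        assert fit.ratio * cfg.ktrans_rr == pytest.approx(fit.ktrans, abs=1e-15)

    def test_scale_invariance_of_ktrans(self, plasma, frame_times_s, reference):
        # multiplying both curves by a constant leaves ktrans unchanged:
        # mg/mL and mM tracers are comparable through K^trans
        cfg, t, c = reference
        ct = np.concatenate(
            [[0.0], simulate_tissue_curve(plasma, frame_times_s, 0.17, 0.3)]
        )
        a = fit_rrm_voxel(ct, c_rr=c, times_min=t, config=cfg)
        b = fit_rrm_voxel(37.0 * ct, c_rr=37.0 * c, times_min=t, config=cfg)
        assert b.ktrans == pytest.approx(a.ktrans, rel=1e-6)

    def test_all_zero_curve_degenerate(self, reference):
        cfg, t, c = reference
        fit = fit_rrm_voxel(np.zeros_like(c), c_rr=c, times_min=t, config=cfg)
        assert fit.ktrans == 0.0 and fit.flag == "degenerate"

    def test_noiseless_recovery_grid(self, plasma, frame_times_s, reference):
        cfg, t, c = reference
        ref = ReferenceCurve.from_samples(t, c, cfg)
        for kt in (0.01, 0.17):
            for ve in (0.05, 0.5):
                ct = simulate_tissue_curve(plasma, frame_times_s, kt, ve)
                fit = fit_rrm_voxel(ct, ref, config=cfg)
                assert fit.ktrans == pytest.approx(kt, rel=0.02), (kt, ve)

    def test_halving_integration_step_is_stable(self, plasma, frame_times_s):
        ct = simulate_tissue_curve(plasma, frame_times_s, 0.17, 0.3)
        c_rr = simulate_tissue_curve(plasma, frame_times_s, 0.1, 0.1)
        t = frame_times_s / 60.0
        fits = [
            fit_rrm_voxel(ct, c_rr=c_rr, times_min=t, config=RRMConfig(refine_substeps=n))
            for n in (34, 68)
        ]
        assert fits[1].ktrans == pytest.approx(fits[0].ktrans, rel=0.005)

    def test_zero_reference_rejected(self, reference):
        cfg, t, c = reference
        with pytest.raises(ValueError, match="reference"):
            fit_rrm_voxel(c, c_rr=np.zeros_like(c), times_min=t, config=cfg)


class TestMap:
    def test_reference_curve_mean_of_two_voxels(self, small_noiseless):
        conc = small_noiseless["conc"]
        scene = small_noiseless["scene"]
        mask = np.zeros(scene.shape, dtype=bool)
        vox = np.argwhere(scene.labels == 3)[:2]
        mask[tuple(vox[0])] = mask[tuple(vox[1])] = True
        got = build_reference_curve(conc, mask)
        want = 0.5 * (conc.c[tuple(vox[0])] + conc.c[tuple(vox[1])])
        assert np.allclose(got, want, atol=1e-14)

    def test_reference_matches_scene_truth(self, small_noiseless):
        conc = small_noiseless["conc"]
        scene = small_noiseless["scene"]
        truth = small_noiseless["truth"]
        got = build_reference_curve(conc, scene.labels == 3)
        want = truth.c_true[scene.labels == 3].mean(axis=0)
        assert np.max(np.abs(got - want)) < 1e-8

    def test_fold_ratio_on_noiseless_scene(self, small_noiseless):
        conc = small_noiseless["conc"]
        scene = small_noiseless["scene"]
        res = map_ktrans(conc, scene.labels)
        fold = res.summary.set_index("roi")["fold_vs_contralateral"]["focal"]
        assert fold == pytest.approx(0.170 / 0.00135, rel=0.03)
        assert res.n_excluded == 0

    def test_empty_reference_errors(self, small_noiseless):
        conc = small_noiseless["conc"]
        scene = small_noiseless["scene"]
        rois = np.where(scene.labels == 3, 0, scene.labels)
        with pytest.raises(ValueError, match="empty"):
            map_ktrans(conc, rois)
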