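"""PSF pipeline: focus metric, wavelet detection, Gaussian fit cascade."""

import math

import numpy as np
import pytest
from scipy import ndimage

from opmcal import psf, scene
from conftest import match_to_truth


def gaussian_image(ny, nx, x0, y0, sx, sy, amp=100.0, bg=10.0):
    yy, xx = np.mgrid[0:ny, 0:nx]
    return amp * np.exp(-0.5 * (((xx - x0) / sx) ** 2 + ((yy - y0) / sy) ** 2)) + bg


class TestFocusMetric:
    def test_constant_image_scores_zero(self):
        assert psf.focus_metric(np.full((32, 32), 7.0)) == 0.0

    def test_offset_invariant(self):
        img = gaussian_image(32, 32, 16, 16, 2, 2)
        assert psf.focus_metric(img) == pytest.approx(psf.focus_metric(img + 55.0))

    def test_focal_plane_sharper_than_defocus(self):
        img = gaussian_image(48, 48, 24, 24, 1.2, 1.2)
        blurred = ndimage.gaussian_filter(img, 2.0)
        assert psf.focus_metric(img) > psf.focus_metric(blurred)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            psf.focus_metric(np.ones(5))


class TestBestFocusFrame:
    def test_symmetric_stack_picks_centre(self):
        t = scene.SceneTruth(
            positions=np.array([[0.0, 0.0, 0.0]]), fov=(4, 4, 1), seed=0
        )
        g = scene.StackGeometry(nx=48, ny=48, n_planes=21)
        s = scene.render_stack(t, g, noise=None)
        assert psf.best_focus_frame(s) == 10

    def test_monotonically_blurred_sequence_picks_first(self):
        base = gaussian_image(40, 40, 20, 20, 1.5, 1.5)
        frames = np.stack(
            [ndimage.gaussian_filter(base, 0.5 * k) for k in range(8)]
        )
        s = scene.BeadStack(voxels=frames, pixel_xy=0.1, step_z=0.1)
        assert psf.best_focus_frame(s) == 0

    def test_recovers_simulator_focal_plane(self):
        # beads at z = +0.6 µm put best focus 4 planes above centre
        t = scene.SceneTruth(
            positions=np.array([[1.0, -1.0, 0.6], [-1.5, 1.0, 0.6]]),
            fov=(8, 8, 1.5),
            seed=0,
        )
        g = scene.StackGeometry(nx=80, ny=80, n_planes=21)
        s = scene.render_stack(t, g, noise=None)
        assert psf.best_focus_frame(s) == 10 + round(0.6 / g.step_z)


class TestWaveletDetection:
    def test_blank_noise_yields_no_candidates(self):
        # false-positive rate under pure camera noise below 1% of seeds
        hits = 0
        for s in range(60):
            rng = np.random.default_rng(s)
            img = np.clip(rng.normal(100.0, 1.6, (300, 300)), 0, None)
            hits += len(psf.detect_beads(img)) > 0
        assert hits == 0

    def test_dense_scene_detection_complete_and_clean(self, default_scene):
        truth, geometry, stack = default_scene
        k = psf.best_focus_frame(stack)
        cands = psf.detect_beads(stack.voxels[k].astype(float))
        cx, cy = stack.centre_px
        true_px = np.column_stack(
            [
                cx + truth.positions[:, 0] / geometry.pixel_xy,
                cy + truth.positions[:, 1] / geometry.pixel_xy,
            ]
        )
        d = np.linalg.norm(cands[:, None, :] - true_px[None, :, :], axis=-1)
        nearest = d.min(axis=1)
        assert np.all(nearest <= 1.0)  # no spurious detections
        matched = np.unique(d.argmin(axis=1)[nearest <= 1.0]).size
        assert matched >= 0.95 * truth.n_beads

    def test_close_pair_merges_to_one_candidate(self):
        img = gaussian_image(64, 64, 30, 32, 1.1, 1.1) + gaussian_image(
            64, 64, 33, 32, 1.1, 1.1, bg=0.0
        )
        rng = np.random.default_rng(0)
        img = img + rng.normal(0, 0.5, img.shape)
        assert len(psf.detect_beads(img)) == 1

    def test_wavelet_planes_sum_back_to_image(self):
        rng = np.random.default_rng(1)
        img = rng.normal(50, 5, (64, 64))
        planes = psf.atrous_b3_planes(img, n_levels=3)
        # residual smooth array = image - sum of planes; reconstruction is exact
        smooth = img - sum(planes)
        assert np.allclose(sum(planes) + smooth, img)
        assert smooth.std() < img.std()


class TestGaussianFits:
    def test_noiseless_lateral_fit_recovers_width(self):
        img = gaussian_image(32, 32, 15.3, 16.7, 1.2, 1.6)
        fit = psf.fit_bead_2d(img, (15.0, 17.0))
        assert fit.ok
        assert fit.sigma_x == pytest.approx(1.2, rel=0.005)
        assert fit.sigma_y == pytest.approx(1.6, rel=0.005)
        assert (fit.x, fit.y) == pytest.approx((15.3, 16.7), abs=0.01)

    def test_border_roi_flagged(self):
        img = gaussian_image(32, 32, 2.0, 16.0, 1.2, 1.2)
        assert not psf.fit_bead_2d(img, (2.0, 16.0)).ok

    def test_axial_profile_recovers_injected_width(self, small_noisefree_scene):
        truth, stack = small_noisefree_scene
        recs = [r for r in psf.measure_psfs(stack) if r.fit_ok]
        assert recs
        for r in recs:
            i, d = match_to_truth(r, truth)
            x, y, z = truth.positions[i]
            _, ax_true = truth.psf_model.fwhms_at(math.hypot(x, y), z)
            assert r.fwhm_z == pytest.approx(ax_true, rel=0.01)

    def test_axial_peak_at_boundary_flagged(self):
        t = scene.SceneTruth(
            positions=np.array([[0.0, 0.0, 1.5]]), fov=(4, 4, 3.2), seed=0
        )
        g = scene.StackGeometry(nx=48, ny=48, n_planes=11)  # z range ±0.75 µm
        s = scene.render_stack(t, g, noise=None)
        fit = psf.fit_axial_profile(s, *[c for c in s.centre_px])
        assert not fit.ok

    def test_well_sampled_axial_profile(self):
        # 54 planes at 150 nm leave >= 4 samples above half max for ~700 nm FWHM
        t = scene.SceneTruth(positions=np.array([[0.0, 0.0, 0.0]]), fov=(4, 4, 1), seed=0)
        s = scene.render_stack(t, scene.StackGeometry(nx=48, ny=48), noise=None)
        prof = psf.axial_profile(s, *s.centre_px)
        above = prof - prof.min() > 0.5 * (prof.max() - prof.min())
        assert above.sum() >= 4


class TestMeasurePsfs:
    def test_single_centred_bead(self):
        t = scene.SceneTruth(positions=np.array([[0.0, 0.0, 0.0]]), fov=(4, 4, 1), seed=0)
        s = scene.render_stack(t, scene.StackGeometry(nx=48, ny=48), noise=None)
        recs = psf.measure_psfs(s)
        assert len(recs) == 1
        assert recs[0].r == pytest.approx(0.0, abs=0.02)

    def test_recovers_injected_radial_trend(self):
        # strong injected growth so the trend dominates fit scatter
        model = scene.PsfFieldModel(radial_growth=4e-3)
        truth = scene.generate_bead_field(
            (44.0, 44.0, 0.6), 150, 2.5, seed=55, psf_model=model
        )
        stack = scene.render_stack(
            truth, scene.StackGeometry(nx=420, ny=420, n_planes=30), seed=56
        )
        df = psf.records_to_frame([r for r in psf.measure_psfs(stack) if r.fit_ok])
        slope = np.polyfit(df["r"], df["fwhm_lat"], 1)[0]
        assert slope == pytest.approx(model.fwhm_lat0 * model.radial_growth, rel=0.05)

    def test_oblique_modality_rejected(self):
        s = scene.BeadStack(
            voxels=np.zeros((5, 8, 8)), pixel_xy=0.1, step_z=0.1,
            modality="oblique", tilt_deg=28.0,
        )
        with pytest.raises(ValueError):
            psf.measure_psfs(s)


class TestSummaries:
    def test_identical_records_have_zero_spread(self):
        rec = psf.BeadRecord(
            x=1.0, y=0.0, z_best=0.0, fwhm_x=260.0, fwhm_y=260.0, fwhm_z=700.0,
            amplitude=100.0, background=5.0, r=1.0, theta=0.0, fit_ok=True,
        )
        df = psf.summarize_by_radius([rec] * 5, np.array([0.0, 5.0]))
        assert len(df) == 1
        assert df["fwhm_lat_sd"].iloc[0] == 0.0
        assert df["n"].iloc[0] == 5

    def test_sparse_bins_omitted_and_failures_excluded(self):
        good = psf.BeadRecord(1, 0, 0, 260, 260, 700, 100, 5, 1.0, 0.0, True)
        bad = psf.BeadRecord(8, 0, 0, 999, 999, 999, 100, 5, 8.0, 0.0, False)
        df = psf.summarize_by_radius([good] * 4 + [bad] * 4, np.array([0.0, 5.0, 10.0]))
        assert df["r_lo"].tolist() == [0.0]

    def test_radial_bin_means_reproduce_injected_line(self, default_scene, default_scene_records):
        truth, _, _ = default_scene
        ok = [r for r in default_scene_records if r.fit_ok]
        df = psf.summarize_by_radius(ok, np.arange(0.0, 50.0, 10.0))
        model = truth.psf_model
        for _, row in df.iterrows():
            expected = model.fwhm_lat0 * (1 + model.radial_growth * row["r_mid"])
            assert row["fwhm_lat_mean"] == pytest.approx(expected, rel=0.03)

    def test_percent_increase_arithmetic(self):
        assert psf.percent_increase(300.0, 250.0) == pytest.approx(20.0)
        with pytest.raises(ValueError):
            psf.percent_increase(1.0, 0.0)
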