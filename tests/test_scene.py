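"""Simulator contracts: determinism, geometry, flux, injected models."""

import math

import numpy as np
import pytest

from opmcal import psf, scene
from opmcal.scene import (
    DensityError,
    NoiseModel,
    PsfFieldModel,
    RenderError,
    SceneTruth,
    StackGeometry,
    generate_bead_field,
    render_scan_series,
    render_stack,
)


class TestBeadField:
    def test_deterministic_and_separated(self):
        a = generate_bead_field((40, 40, 4), 120, 2.0, seed=1)
        b = generate_bead_field((40, 40, 4), 120, 2.0, seed=1)
        assert np.array_equal(a.positions, b.positions)
        assert a.n_beads == 120
        d = np.linalg.norm(
            a.positions[:, None, :] - a.positions[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2.0

    def test_positions_inside_fov(self):
        t = generate_bead_field((10, 20, 2), 50, 0.5, seed=2)
        assert np.all(np.abs(t.positions) <= np.array([5, 10, 1]))

    def test_single_bead_skips_separation(self):
        t = generate_bead_field((5, 5, 1), 1, 100.0, seed=3)
        assert t.n_beads == 1

    def test_infeasible_density_raises(self):
        with pytest.raises(DensityError):
            generate_bead_field((5, 5, 1), 2, 100.0, seed=4, max_tries_per_bead=50)

    def test_positions_outside_fov_rejected(self):
        with pytest.raises(ValueError):
            SceneTruth(positions=np.array([[10.0, 0, 0]]), fov=(4, 4, 1))


class TestRenderStack:
    def test_bit_identical_under_fixed_seed(self):
        t = generate_bead_field((10, 10, 0.5), 8, 1.5, seed=5)
        g = StackGeometry(nx=100, ny=100, n_planes=20)
        a = render_stack(t, g, seed=9)
        b = render_stack(t, g, seed=9)
        assert np.array_equal(a.voxels, b.voxels)

    def test_noisefree_flux_conserved(self):
        # interior beads integrate to flux within truncation error
        t = generate_bead_field((8, 8, 0.2), 4, 2.0, seed=6)
        g = StackGeometry(nx=160, ny=160, n_planes=54)
        s = render_stack(t, g, noise=None)
        total = float(s.voxels.sum())
        assert total == pytest.approx(t.n_beads * t.flux, rel=2e-3)

    def test_centred_bead_fwhm_matches_model(self):
        # noise-free render of one centred bead fits back to < 1%
        t = SceneTruth(positions=np.array([[0.0, 0.0, 0.0]]), fov=(4, 4, 1), seed=0)
        g = StackGeometry(nx=48, ny=48, n_planes=54)
        s = render_stack(t, g, noise=None)
        rec = psf.measure_psfs(s)[0]
        assert rec.fit_ok
        assert rec.fwhm_lat == pytest.approx(t.psf_model.fwhm_lat0, rel=0.01)
        assert rec.fwhm_z == pytest.approx(t.psf_model.fwhm_ax0, rel=0.01)

    def test_distortion_shifts_beads_radially(self):
        # a bead at r with rate k and depth d moves outward by r*k*d
        pos = np.array([[15.0, 0.0, 0.0]])
        base = SceneTruth(positions=pos, fov=(36, 36, 1), seed=0)
        g = StackGeometry(nx=360, ny=360, n_planes=11, depth=10.0)
        rate = 5e-4
        undist = render_stack(base, g, noise=None)
        dist = render_stack(base.with_(distortion_rate=rate), g, noise=None)
        r0 = psf.measure_psfs(undist)[0]
        r1 = psf.measure_psfs(dist)[0]
        assert r1.x - r0.x == pytest.approx(15.0 * rate * 10.0, abs=0.01)

    def test_zero_distortion_position_depth_invariant(self):
        pos = np.array([[12.0, -6.0, 0.0]])
        t = SceneTruth(positions=pos, fov=(30, 30, 1), seed=0)
        g0 = StackGeometry(nx=300, ny=300, n_planes=11, depth=0.0)
        g1 = StackGeometry(nx=300, ny=300, n_planes=11, depth=20.0)
        a = psf.measure_psfs(render_stack(t, g0, noise=None))[0]
        b = psf.measure_psfs(render_stack(t, g1, noise=None))[0]
        assert (a.x, a.y) == pytest.approx((b.x, b.y), abs=0.01)

    def test_window_smaller_than_fov_rejected(self):
        t = generate_bead_field((50, 50, 1), 3, 5.0, seed=7)
        with pytest.raises(RenderError):
            render_stack(t, StackGeometry(nx=100, ny=100), noise=None)


class TestPsfFieldModel:
    def test_growth_with_radius_and_depth(self):
        m = PsfFieldModel(radial_growth=1e-3, depth_growth_lat=2e-3, depth_growth_ax=3e-3)
        lat0, ax0 = m.fwhms_at(0, 0)
        lat, ax = m.fwhms_at(100, 20)
        assert lat == pytest.approx(lat0 * 1.1 * 1.04)
        assert ax == pytest.approx(ax0 * 1.1 * 1.06)

    def test_axial_must_dominate_lateral(self):
        with pytest.raises(ValueError):
            PsfFieldModel(fwhm_lat0=700.0, fwhm_ax0=300.0)


class TestScanSeries:
    def test_scan_extent_and_shape(self):
        t = generate_bead_field((12, 8, 1), 20, 1.0, seed=8)
        s = render_scan_series(t, 1.02, n_steps=100, step_x=1.4, frame_shape=(80, 120))
        assert s.n_planes == 100
        assert s.modality == "oblique"
        # 100 steps of 1.4 µm cover a 140 µm scan
        assert s.n_planes * s.step_z == pytest.approx(140.0)

    def test_too_short_series_rejected(self):
        t = generate_bead_field((12, 8, 1), 5, 1.0, seed=9)
        with pytest.raises(RenderError):
            render_scan_series(t, 1.02, n_steps=2)

    def test_matched_ratio_gives_flat_series(self):
        t = generate_bead_field((12, 8, 1), 20, 1.0, seed=10)
        s = render_scan_series(
            t, t.ratio_opt(0.0), 0.0, n_steps=30, frame_shape=(80, 120), noise=None
        )
        totals = s.voxels.reshape(30, -1).sum(axis=1)
        assert np.ptp(totals) <= 1e-6 * totals.mean()

    def test_noise_values_non_negative_with_offset(self):
        t = generate_bead_field((12, 8, 1), 10, 1.0, seed=11)
        s = render_scan_series(
            t, 1.03, n_steps=10, frame_shape=(60, 80), noise=NoiseModel()
        )
        assert s.voxels.min() >= 0.0
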