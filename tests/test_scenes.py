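"""Synthetic scene generator: sampling statistics, optics, ground truth."""

import math

import numpy as np
import pytest

from spimpiv.scenes import (SceneConfig, TracerEnsemble, default_heart_waveform,
                            make_gradient_scene, make_heart_phantom,
                            make_oopm_dataset, make_tube_dataset,
                            poiseuille_velocity, render_frame, sample_tracers,
                            sheet_weight)
from spimpiv.units import TWO_PI, UM3_PER_MS_TO_NL_PER_S


class TestSampleTracers:
    def test_expected_count_matches_density(self):
        # 0.2 per 32x12 IW over a 320x120 image => 20 expected in the slab
        cfg = SceneConfig(image_shape=(120, 320), seeding_density=0.2)
        region = ((0, 320 * cfg.pixel_size), (0, 120 * cfg.pixel_size),
                  (-cfg.slab_halfdepth, cfg.slab_halfdepth))
        counts = [sample_tracers(cfg, region, s).n for s in range(4000)]
        assert np.mean(counts) == pytest.approx(20.0, rel=0.02)

    def test_zero_density_gives_empty_ensemble(self, small_scene):
        cfg = SceneConfig(image_shape=(64, 96), seeding_density=0.0)
        ens = sample_tracers(cfg, ((0, 10), (0, 10), (0, 10)), 1)
        assert ens.n == 0

    def test_same_seed_identical_positions(self, small_scene):
        region = ((0, 30), (0, 30), (-5, 5))
        e1 = sample_tracers(small_scene, region, 7)
        e2 = sample_tracers(small_scene, region, 7)
        np.testing.assert_array_equal(e1.positions, e2.positions)

    def test_degenerate_region_rejected(self, small_scene):
        with pytest.raises(ValueError):
            sample_tracers(small_scene, ((0, 0), (0, 10), (0, 10)), 1)

    def test_positions_stay_inside_region(self, small_scene):
        region = ((-3, 12), (2, 9), (-4, 4))
        ens = sample_tracers(small_scene, region, 3)
        for axis, (lo, hi) in enumerate(region):
            assert np.all(ens.positions[:, axis] >= lo)
            assert np.all(ens.positions[:, axis] <= hi)


class TestPoiseuilleVelocity:
    @pytest.mark.parametrize("r_frac,expected", [(0.0, 1.0), (1.0, 0.0),
                                                 (0.5, 0.75)])
    def test_profile_values(self, r_frac, expected):
        v = poiseuille_velocity((0.0, 10.0 * r_frac, 0.0), v_max=8.0,
                                radius=10.0)
        assert v[0] == pytest.approx(8.0 * expected)
        assert v[1] == 0.0 and v[2] == 0.0

    def test_zero_outside_tube(self):
        v = poiseuille_velocity((0.0, 15.0, 0.0), v_max=8.0, radius=10.0)
        assert v[0] == 0.0

    def test_vectorized_matches_scalar(self, rng):
        pos = rng.uniform(-12, 12, size=(50, 3))
        batch = poiseuille_velocity(pos, 5.0, 10.0, center=(1.0, -2.0))
        single = np.array([poiseuille_velocity(p, 5.0, 10.0, (1.0, -2.0))
                           for p in pos])
        np.testing.assert_allclose(batch, single)


class TestRenderFrame:
    def test_sheet_weight_normalisation(self):
        assert sheet_weight(0.0, 0.0, 2.0) == 1.0
        assert sheet_weight(1.0, 0.0, 2.0) == pytest.approx(0.5)
        assert sheet_weight(-1.0, 0.0, 2.0) == pytest.approx(0.5)

    def test_half_amplitude_at_half_axial_fwhm(self):
        cfg = SceneConfig(image_shape=(32, 32), pixel_size=0.5,
                          tracer_diameter=2.0, noise_sd=0.0)
        in_plane = TracerEnsemble([[8.0, 8.0, 0.0]], [1.0], 2.0)
        off = TracerEnsemble([[8.0, 8.0, cfg.axial_fwhm / 2.0]], [1.0], 2.0)
        img0 = render_frame(in_plane, cfg, focal_z=0.0)
        img1 = render_frame(off, cfg, focal_z=0.0)
        assert img1.max() == pytest.approx(img0.max() / 2.0, rel=1e-12)

    def test_distant_tracer_invisible(self):
        cfg = SceneConfig(image_shape=(32, 32), pixel_size=0.5, noise_sd=0.0,
                          tracer_diameter=0.1, psf_sigma0=1.0, sheet_fwhm=2.0)
        far = TracerEnsemble([[8.0, 8.0, 10.0 * cfg.axial_fwhm]], [1.0], 0.1)
        img = render_frame(far, cfg, focal_z=0.0)
        assert img.max() < 1e-3 * cfg.amplitude

    def test_empty_ensemble_is_noise_only(self):
        cfg = SceneConfig(image_shape=(32, 32), noise_sd=2.0)
        empty = TracerEnsemble(np.empty((0, 3)), np.empty(0), 1.0)
        img = render_frame(empty, cfg, focal_z=0.0,
                           rng=np.random.default_rng(0))
        # clipped Gaussian noise: small positive mean, nothing structured
        assert 0.0 < img.mean() < 2.0

    def test_volume_mode_spot_broader_when_defocused(self):
        cfg = SceneConfig(image_shape=(64, 64), pixel_size=0.5,
                          illumination_mode="volume", tracer_diameter=2.0,
                          defocus_rate=0.5, noise_sd=0.0)
        focused = TracerEnsemble([[16.0, 16.0, 0.0]], [1.0], 2.0)
        blurred = TracerEnsemble([[16.0, 16.0, 8.0]], [1.0], 2.0)
        i0 = render_frame(focused, cfg, 0.0)
        i1 = render_frame(blurred, cfg, 0.0)
        assert i1.max() < i0.max()                    # dimmer
        assert (i1 > i1.max() / 2).sum() > (i0 > i0.max() / 2).sum()  # wider


class TestTubeDataset:
    def test_zero_flow_frames_identical(self):
        cfg = SceneConfig(image_shape=(48, 64), v_max=0.0, noise_sd=0.0)
        pairs, _ = make_tube_dataset(cfg, 2, [0.0], seed=5)
        for p in pairs:
            np.testing.assert_array_equal(p.frame_a, p.frame_b)

    def test_advection_fidelity_before_rasterisation(self):
        cfg = SceneConfig(image_shape=(48, 64), flow_rate=0.5)
        from spimpiv.scenes import _sample_tube_slab
        rng = np.random.default_rng(0)
        ens = _sample_tube_slab(cfg, -3, 3, rng)
        vel = poiseuille_velocity(ens.positions, cfg.v_max, cfg.tube_radius,
                                  center=((48 / 2) * cfg.pixel_size, 0.0))
        moved = ens.advected(vel * cfg.dt)
        err = np.abs((moved.positions - ens.positions) - vel * cfg.dt)
        assert err.max() < 1e-9

    def test_determinism_bit_identical(self):
        cfg = SceneConfig(image_shape=(48, 64), noise_sd=1.0)
        p1, _ = make_tube_dataset(cfg, 2, [0.0, 2.0], seed=9)
        p2, _ = make_tube_dataset(cfg, 2, [0.0, 2.0], seed=9)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.frame_a, b.frame_a)
            np.testing.assert_array_equal(a.frame_b, b.frame_b)

    def test_volume_and_sheet_share_tracers_only_through_seed(self):
        sheet = SceneConfig(image_shape=(48, 64), illumination_mode="sheet")
        vol = SceneConfig(image_shape=(48, 64), illumination_mode="volume")
        ps, _ = make_tube_dataset(sheet, 1, [0.0], seed=3)
        pv, _ = make_tube_dataset(vol, 1, [0.0], seed=3)
        assert not np.array_equal(ps[0].frame_a, pv[0].frame_a)

    def test_ground_truth_flow_rate_closed_form(self):
        cfg = SceneConfig(image_shape=(48, 64), flow_rate=0.5)
        _, truth = make_tube_dataset(cfg, 1, [0.0], seed=1)
        q_closed = (math.pi * cfg.tube_radius ** 2 * cfg.v_max / 2.0
                    * UM3_PER_MS_TO_NL_PER_S)
        assert truth.params["q_nl_s"] == pytest.approx(q_closed, rel=1e-6)
        # and the nominal flow rate is recovered: 0.5 uL/min = 8.333 nL/s
        assert truth.params["q_nl_s"] == pytest.approx(0.5 * 1e3 / 60.0,
                                                       rel=1e-9)


class TestOOPMDataset:
    def test_zero_dz_is_exact_roll(self):
        cfg = SceneConfig(image_shape=(96, 96), sheet_fwhm=2.5,
                          tracer_diameter=7.32, noise_sd=0.0)
        ds = make_oopm_dataset([0.0], 24, 2, cfg, seed=1, n_visible=30)
        for p in ds[0.0]:
            np.testing.assert_array_equal(p.frame_b,
                                          np.roll(p.frame_a, 24, axis=1))

    def test_visible_tracer_count_near_target(self):
        cfg = SceneConfig(image_shape=(256, 256), sheet_fwhm=2.5,
                          tracer_diameter=7.32)
        ds = make_oopm_dataset([0.0, 2.0], 10, 6, cfg, seed=2, n_visible=100)
        counts = [p.meta["n_visible"] for dz in ds for p in ds[dz]]
        assert np.mean(counts) == pytest.approx(100, rel=0.2)

    def test_dz_of_one_fwhm_halves_most_brightnesses(self):
        # at dz = axial FWHM a tracer in the sheet centre for frame A keeps
        # w(dz)/w(0) = 1/16; one near the midpoint keeps ~exactly 1; shared
        # visibility drops but is not yet zero
        cfg = SceneConfig(image_shape=(96, 96), sheet_fwhm=2.0,
                          tracer_diameter=0.5, noise_sd=0.0)
        dz = cfg.axial_fwhm
        ds = make_oopm_dataset([0.0, dz], 0, 4, cfg, seed=3, n_visible=40)
        shared0 = np.mean([p.meta["n_shared_visible"] for p in ds[0.0]])
        shared1 = np.mean([p.meta["n_shared_visible"] for p in ds[dz]])
        assert shared1 < shared0
        assert shared1 > 0

    def test_large_dz_shares_no_visible_tracers(self):
        cfg = SceneConfig(image_shape=(96, 96), sheet_fwhm=2.0,
                          tracer_diameter=0.5, noise_sd=0.0)
        dz = 8.0 * cfg.axial_fwhm
        ds = make_oopm_dataset([dz], 0, 3, cfg, seed=3, n_visible=40)
        assert all(p.meta["n_shared_visible"] == 0 for p in ds[dz])

    def test_shift_wider_than_image_rejected(self):
        cfg = SceneConfig(image_shape=(32, 32))
        with pytest.raises(ValueError):
            make_oopm_dataset([0.0], 40, 1, cfg, seed=1)


class TestHeartPhantom:
    def test_waveform_regurgitant_fraction(self):
        w = default_heart_waveform(v_peak=2.5, regurg_amplitude=0.6)
        phi = np.linspace(0, TWO_PI, 200001)
        v = w(phi)
        fwd = np.trapezoid(np.clip(v, 0, None), phi)
        reg = -np.trapezoid(np.clip(v, None, 0), phi)
        assert reg / fwd == pytest.approx(0.3, abs=1e-4)

    def test_constant_waveform_volumes(self):
        cfg = SceneConfig(image_shape=(48, 48), seeding_density=0.1)
        pairs, anchors, truth = make_heart_phantom(
            lambda phi: np.full_like(np.asarray(phi, float), 2.0),
            n_beats=1, frames_per_beat=4, config=cfg, seed=1,
            period_ms=400.0)
        q = math.pi * cfg.tube_radius ** 2 * 2.0 / 2.0 * UM3_PER_MS_TO_NL_PER_S
        assert truth.regurgitant_volume == pytest.approx(0.0, abs=1e-12)
        assert truth.net_volume == pytest.approx(q * 0.4, rel=1e-6)

    def test_zero_mean_sinusoid_nets_zero(self):
        cfg = SceneConfig(image_shape=(48, 48), seeding_density=0.1)
        _, _, truth = make_heart_phantom(np.sin, 1, 4, cfg, seed=1)
        assert truth.net_volume == pytest.approx(0.0, abs=1e-9)
        assert truth.forward_volume == pytest.approx(truth.regurgitant_volume,
                                                     rel=1e-9)

    def test_anchor_series_spans_acquisition(self):
        cfg = SceneConfig(image_shape=(48, 48), seeding_density=0.1)
        pairs, (t, phi), _ = make_heart_phantom(
            default_heart_waveform(), n_beats=3, frames_per_beat=5,
            config=cfg, seed=2, period_ms=100.0)
        assert t[0] <= min(p.timestamp for p in pairs)
        assert t[-1] >= max(p.timestamp + p.dt for p in pairs)
        assert np.all(phi >= 0) and np.all(phi < TWO_PI)


class TestGradientScene:
    def test_zero_slope_uniform_brightness(self, small_scene):
        pair = make_gradient_scene(small_scene, 0.0, seed=4)
        assert pair.meta["true_shift_px"] == (6.0, 0.0)

    def test_same_seed_same_geometry_different_intensity(self, small_scene):
        p1 = make_gradient_scene(small_scene, 0.0, seed=4)
        p2 = make_gradient_scene(small_scene, 5.0, seed=4)
        assert p1.meta["n_tracers"] == p2.meta["n_tracers"]
        assert not np.array_equal(p1.frame_a, p2.frame_a)

    def test_known_shift_is_recoverable(self, small_scene):
        from spimpiv.engine import PIVConfig, analyze_plane
        cfg = SceneConfig(image_shape=(64, 96), seeding_density=1.0,
                          tracer_diameter=2.0, pixel_size=0.5, dt=1.0)
        pairs = [make_gradient_scene(cfg, 0.0, seed=s, shift_px=(6.0, 0.0))
                 for s in range(8)]
        pc = PIVConfig(small_iw=(16, 16), large_iw=(32, 32), dt=1.0,
                       pixel_size=0.5)
        f = analyze_plane(pairs, pc)
        ok = f.valid
        assert ok.sum() > 0
        np.testing.assert_allclose(f.u_px[ok], 6.0, atol=0.1)
        np.testing.assert_allclose(f.v_px[ok], 0.0, atol=0.1)
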