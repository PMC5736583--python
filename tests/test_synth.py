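"""Phantom generators: analytic forms, determinism, parity."""

import numpy as np
import pandas as pd
import pytest

from rtdic import (SynthSpec, filopodium_phantom, helical_blob_movie,
                   radial_grating, synth_dic, walker_movie_2d, walker_tracks)
from rtdic.synth import _helix_path


class TestRadialGrating:
    def test_bright_spokes_and_range(self):
        g = radial_grating(shape=(512, 512), n_spokes=16).data
        assert g.min() >= 0 and g.max() <= 1
        # pixels just right of center lie on the φ=0 spoke (cos = 1)
        assert g[255, 280] > 0.95

    def test_symmetric_under_180_rotation(self):
        g = radial_grating(shape=(256, 256), n_spokes=16).data
        np.testing.assert_allclose(g, np.rot90(g, 2), atol=1e-12)

    def test_annulus_mean_half(self):
        g = radial_grating(shape=(256, 256), n_spokes=16).data
        yy, xx = np.mgrid[:256, :256].astype(float)
        r = np.hypot(xx - 127.5, yy - 127.5)
        ann = (r > 60) & (r < 100)
        assert abs(g[ann].mean() - 0.5) < 0.01

    def test_odd_spokes_rejected(self):
        with pytest.raises(ValueError):
            radial_grating(shape=(64, 64), n_spokes=15)


class TestSynthDic:
    def test_constant_plane(self):
        out = synth_dic(np.full((32, 32), 0.7), 45.0).data
        np.testing.assert_allclose(out, -0.7, atol=1e-12)

    def test_ramp_along_shear(self):
        yy, xx = np.mgrid[:32, :32].astype(float)
        t = np.deg2rad(30.0)
        ramp = 0.1 * (xx * np.cos(t) + yy * np.sin(t))
        out = synth_dic(ramp, 30.0).data
        # −I + constant slope 0.1 (interior; np.gradient is one-sided at edges)
        np.testing.assert_allclose(out[1:-1, 1:-1],
                                   (-ramp + 0.1)[1:-1, 1:-1], atol=1e-12)

    def test_matches_pixel_loop_oracle(self):
        g = radial_grating(shape=(32, 32), n_spokes=8).data
        theta = 45.0
        out = synth_dic(g, theta).data
        t = np.deg2rad(theta)
        ref = np.empty_like(g)
        for i in range(32):
            for j in range(32):
                gy = (g[min(i + 1, 31), j] - g[max(i - 1, 0), j]) / (
                    min(i + 1, 31) - max(i - 1, 0))
                gx = (g[i, min(j + 1, 31)] - g[i, max(j - 1, 0)]) / (
                    min(j + 1, 31) - max(j - 1, 0))
                ref[i, j] = -g[i, j] + np.cos(t) * gx + np.sin(t) * gy
        np.testing.assert_allclose(out, ref, atol=1e-12)


class TestHelix:
    def test_planar_circle_closed_form(self):
        spec = SynthSpec(helix_pitch=1e-12, helix_radius=2.0,
                         helix_omega=0.05, n_frames=7)
        t = np.arange(7) * spec.dt
        _, v, a, _ = _helix_path(spec, t)
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), 0.1, rtol=1e-9)
        w = np.cross(v, a) / np.sum(v * v, axis=1)[:, None]
        np.testing.assert_allclose(np.linalg.norm(w, axis=1), 0.05,
                                   rtol=1e-6)

    def test_rest_when_omega_zero(self):
        spec = SynthSpec(helix_omega=0.0, n_frames=7)
        mv, truth = helical_blob_movie(spec)
        assert np.abs(truth.velocity).max() == 0
        assert np.abs(truth.jerk).max() == 0
        np.testing.assert_allclose(mv.data[0], mv.data[-1], atol=1e-12)

    def test_truth_matches_finite_differences(self):
        spec = SynthSpec(helix_radius=2.0, helix_pitch=1.0,
                         helix_omega=0.05, n_frames=7)
        t = np.arange(7) * spec.dt
        p, v, a, j = _helix_path(spec, t)
        h = spec.dt / 100
        pp = _helix_path(spec, t + h)[0]
        pm = _helix_path(spec, t - h)[0]
        vfd = (pp - pm) / (2 * h)
        assert np.abs(vfd - v).max() / np.abs(v).max() < 1e-3
        vp = _helix_path(spec, t + h)[1]
        vm = _helix_path(spec, t - h)[1]
        afd = (vp - vm) / (2 * h)
        assert np.abs(afd - a).max() / np.abs(a).max() < 1e-3
        ap = _helix_path(spec, t + h)[2]
        am = _helix_path(spec, t - h)[2]
        jfd = (ap - am) / (2 * h)
        assert np.abs(jfd - j).max() / np.abs(j).max() < 1e-3

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            helical_blob_movie(SynthSpec(n_frames=5))

    def test_determinism(self):
        a = helical_blob_movie(SynthSpec(n_frames=7, noise_sigma=0.01))[0]
        b = helical_blob_movie(SynthSpec(n_frames=7, noise_sigma=0.01))[0]
        np.testing.assert_array_equal(a.data, b.data)


class TestFilopodium:
    SPEC = dict(shape=(56, 40, 40), pitch=0.05, dt=4.0, n_frames=5,
                filo_length=2.0, filo_radius=0.25)

    def test_ground_truth_by_construction(self):
        mv, truth = filopodium_phantom(SynthSpec(
            retraction_speed=0.02, axial_spin=0.03, **self.SPEC))
        assert truth.axial_velocity == -0.02
        assert truth.axial_angular_velocity == 0.03

    def test_zero_spin(self):
        _, truth = filopodium_phantom(SynthSpec(
            retraction_speed=0.02, axial_spin=0.0, **self.SPEC))
        assert truth.axial_angular_velocity == 0.0

    def test_mirror_parity_of_movie(self):
        """x → −x mirroring equals reversing the spin sign.

        Mirroring maps the azimuth φ → π − φ, so the mirror image is the
        phantom with negated spin and texture phase π − φ0.
        """
        mv_pos, _ = filopodium_phantom(SynthSpec(
            retraction_speed=0.02, axial_spin=0.03, **self.SPEC))
        mv_neg, _ = filopodium_phantom(SynthSpec(
            retraction_speed=0.02, axial_spin=-0.03, azim_phase=np.pi,
            **self.SPEC))
        np.testing.assert_allclose(mv_pos.data[:, :, :, ::-1],
                                   mv_neg.data, atol=1e-9)

    def test_length_underflow_rejected(self):
        with pytest.raises(ValueError):
            filopodium_phantom(SynthSpec(
                retraction_speed=0.2, axial_spin=0.0, **self.SPEC))


class TestWalkers:
    def test_straight_when_unbiased_and_noiseless(self):
        spec = SynthSpec(shape=(512, 512), pitch=2.58, dt=30.0, n_frames=20,
                         n_walkers=5, angular_bias=0.0, heading_noise=0.0,
                         walker_sigma=5.0, seed=3)
        gt = walker_tracks(spec, (512 * 2.58, 512 * 2.58))
        for _, sub in gt.groupby("track"):
            if sub.reflected.any() or sub.contact.any():
                continue
            steps = np.diff(sub[["x", "y"]].to_numpy(), axis=0)
            h = np.arctan2(steps[:, 1], steps[:, 0])
            assert np.ptp(h) < 1e-9

    def test_constant_bias_gives_circle_radius(self):
        """ω0 = +0.8°/min, no noise → circle of radius speed/ω0."""
        spec = SynthSpec(shape=(1024, 1024), pitch=2.58, dt=30.0,
                         n_frames=120, n_walkers=1, walker_speed=10.0,
                         angular_bias=0.8, heading_noise=0.0, seed=5)
        gt = walker_tracks(spec, (1024 * 2.58, 1024 * 2.58))
        xy = gt[["x", "y"]].to_numpy()
        # fit circle (Kasa): radius should be speed/ω0 in consistent units
        A = np.c_[2 * xy, np.ones(len(xy))]
        b = (xy**2).sum(axis=1)
        cx, cy, c0 = np.linalg.lstsq(A, b, rcond=None)[0]
        r_fit = np.sqrt(c0 + cx**2 + cy**2)
        r_true = 10.0 / np.deg2rad(0.8)        # µm (speed/|ω0|)
        assert abs(r_fit - r_true) / r_true < 0.02

    def test_bias_recovery_from_ground_truth(self):
        """Empirical mean heading increment = ω0 within 3 s.e."""
        spec = SynthSpec(shape=(800, 800), pitch=2.58, dt=30.0, n_frames=60,
                         n_walkers=50, walker_speed=10.0, angular_bias=0.8,
                         heading_noise=10.0, walker_sigma=5.0, seed=7)
        gt = walker_tracks(spec, (800 * 2.58, 800 * 2.58))
        incs = []
        for _, sub in gt.groupby("track"):
            h = np.deg2rad(sub.heading.to_numpy())
            d = np.rad2deg((np.diff(h) + np.pi) % (2 * np.pi) - np.pi)
            keep = ~(sub.reflected.to_numpy()[:-1]
                     | sub.contact.to_numpy()[:-1])
            incs.extend(d[keep] / 0.5)           # deg per min
        incs = np.asarray(incs)
        se = incs.std(ddof=1) / np.sqrt(len(incs))
        assert abs(incs.mean() - 0.8) < 3 * se

    def test_rendered_movie_deterministic(self):
        spec = SynthSpec(shape=(128, 128), pitch=2.58, dt=30.0, n_frames=4,
                         n_walkers=3, walker_sigma=5.0, seed=11)
        a, ta = walker_movie_2d(spec)
        b, tb = walker_movie_2d(spec)
        np.testing.assert_array_equal(a.data, b.data)
        pd.testing.assert_frame_equal(ta, tb)

    def test_mirrored_movie_flips_bias(self):
        """Mirroring the arena about x negates the heading bias."""
        kw = dict(shape=(256, 256), pitch=2.58, dt=30.0, n_frames=30,
                  n_walkers=1, walker_speed=10.0, heading_noise=0.0,
                  walker_sigma=5.0, seed=2)
        gt_cw = walker_tracks(SynthSpec(angular_bias=3.0, **kw),
                              (256 * 2.58,) * 2)
        xy = gt_cw[["x", "y"]].to_numpy()
        steps = np.diff(xy, axis=0)
        h = np.unwrap(np.arctan2(steps[:, 1], steps[:, 0]))
        # mirror x: headings negate, so cumulative turn negates
        xy_m = xy * np.array([-1.0, 1.0])
        steps_m = np.diff(xy_m, axis=0)
        hm = np.unwrap(np.arctan2(steps_m[:, 1], steps_m[:, 0]))
        np.testing.assert_allclose(np.diff(hm), -np.diff(h), atol=1e-9)
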