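"""Kinematic stencil, Frenet frame, axis projections, parity.

Most tests drive :func:`derive_kinematics` with *synthetic* displacement
fields built from analytic paths, so the stencil and sign conventions are
checked independently of the optical-flow estimator.
"""

import numpy as np
import pytest

from rtdic import (chordal_orbital_axes, derive_kinematics,
                   local_axis_projection, path_kinematics,
                   pixelwise_2d_motility, radial_axis_projection)
from rtdic.flow import FlowSet
from rtdic.kinematics import KinField


def flowset_from_path(offsets, shape=(6, 6, 6)):
    """Uniform FlowSet whose displacements mimic a point path p(t+k)−p(t).

    ``offsets`` maps k ∈ {−2,−1,1,2} to 3-vectors in voxel units.
    """
    def field(vec):
        return np.broadcast_to(np.asarray(vec, float),
                               shape + (len(vec),)).copy()

    return FlowSet(d_sf_fwd=field(offsets[1]), d_sf_bwd=field(offsets[-1]),
                   d_df_fwd=field(offsets[2]), d_df_bwd=field(offsets[-2]),
                   alpha=0.1, n_iter=0, levels=1, residuals={})


def cubic_path_offsets(coeffs, dt):
    """Displacements of the cubic path p(t) = Σ c_n t^n around t = 0."""
    def p(t):
        return sum(c * t**n for n, c in enumerate(coeffs))

    return {k: p(k * dt) - p(0.0) for k in (-2, -1, 1, 2)}


class TestStencilExactness:
    DT = 0.5
    # cubic vector path with distinct coefficients per component
    COEFFS = [np.array([0.0, 0.0, 0.0]),
              np.array([1.0, -2.0, 0.5]),      # velocity
              np.array([0.3, 0.8, -0.4]),      # accel/2
              np.array([-0.2, 0.1, 0.6])]      # jerk/6

    def test_cubic_path_derivatives_exact(self):
        """v, a, j reproduce the cubic's analytic derivatives exactly."""
        fs = flowset_from_path(cubic_path_offsets(self.COEFFS, self.DT))
        kin = derive_kinematics(fs, self.DT, 1.0)
        v_true = self.COEFFS[1]
        a_true = 2 * self.COEFFS[2]
        j_true = 6 * self.COEFFS[3]
        np.testing.assert_allclose(kin.velocity[0, 0, 0], v_true,
                                   atol=1e-12)
        np.testing.assert_allclose(kin.acceleration[0, 0, 0], a_true,
                                   atol=1e-12)
        np.testing.assert_allclose(kin.jerk[0, 0, 0], j_true, atol=1e-12)

    def test_path_kinematics_cubic_exact_at_every_frame(self):
        t = (np.arange(9) - 4) * self.DT
        path = np.stack([sum(c[i] * t**n
                             for n, c in enumerate(self.COEFFS))
                         for i in range(3)], axis=-1)
        v, a, j, _ = path_kinematics(path, self.DT)
        ti = t[2:-2][:, None]
        c1, c2, c3 = (np.asarray(self.COEFFS[n]) for n in (1, 2, 3))
        np.testing.assert_allclose(v, c1 + 2 * c2 * ti + 3 * c3 * ti**2,
                                   atol=1e-12)
        np.testing.assert_allclose(a, 2 * c2 + 6 * c3 * ti, atol=1e-12)
        np.testing.assert_allclose(j, np.tile(6 * c3, (5, 1)), atol=1e-12)

    def test_units_scale_with_dt(self):
        """Same displacement fields at dt/2 double the velocity."""
        offs = cubic_path_offsets(self.COEFFS, self.DT)
        fs = flowset_from_path(offs)
        v1 = derive_kinematics(fs, self.DT, 1.0).velocity[0, 0, 0]
        v2 = derive_kinematics(fs, self.DT / 2, 1.0).velocity[0, 0, 0]
        np.testing.assert_allclose(v2, 2 * v1, atol=1e-12)

    def test_pitch_scales_displacements(self):
        offs = cubic_path_offsets(self.COEFFS, self.DT)
        fs = flowset_from_path(offs)
        v1 = derive_kinematics(fs, self.DT, 1.0).velocity[0, 0, 0]
        v2 = derive_kinematics(fs, self.DT, 0.5).velocity[0, 0, 0]
        np.testing.assert_allclose(v2, 0.5 * v1, atol=1e-12)


def circle_flowset(omega, r, dt, shape=(5, 5, 5)):
    """FlowSet of a point moving on a circle of radius r (µm, xy-plane)."""
    def p(t):
        return np.array([r * np.cos(omega * t), r * np.sin(omega * t), 0.0])

    offsets = {k: p(k * dt) - p(0.0) for k in (-2, -1, 1, 2)}
    return flowset_from_path(offsets, shape)


class TestFrenetAndOmega:
    def test_circle_angular_velocity(self):
        """ω = v×a/|v|² recovers the circular rate and its +z sense."""
        kin = derive_kinematics(circle_flowset(0.05, 2.0, 1.0), 1.0, 1.0)
        w = kin.angular_velocity[0, 0, 0]
        # small finite-difference bias only (O((Ωdt)²))
        assert abs(np.linalg.norm(w) - 0.05) / 0.05 < 0.01
        assert w[2] > 0        # x→y rotation = +z in the right-handed frame

    def test_frenet_orthonormality(self):
        kin = derive_kinematics(circle_flowset(0.1, 1.0, 1.0), 1.0, 1.0)
        T, N, B = (f[0, 0, 0] for f in (kin.tangent, kin.normal,
                                        kin.binormal))
        for pair in ((T, N), (T, B), (N, B)):
            assert abs(np.dot(*pair)) < 1e-6
        for vec in (T, N, B):
            assert abs(np.linalg.norm(vec) - 1) < 1e-6

    def test_uniform_translation_masks_omega(self):
        offs = {k: np.array([0.7 * k, 0.0, 0.0]) for k in (-2, -1, 1, 2)}
        kin = derive_kinematics(flowset_from_path(offs), 1.0, 1.0)
        assert not kin.defined.any()
        assert np.abs(kin.acceleration).max() < 1e-12
        assert np.abs(kin.angular_velocity).max() == 0

    def test_mirror_parity_exact(self):
        """x → −x negates ω_z exactly on analytic displacement fields."""
        fs = circle_flowset(0.05, 2.0, 1.0)
        mirrored = FlowSet(
            d_sf_fwd=fs.d_sf_fwd * np.array([-1, 1, 1]),
            d_sf_bwd=fs.d_sf_bwd * np.array([-1, 1, 1]),
            d_df_fwd=fs.d_df_fwd * np.array([-1, 1, 1]),
            d_df_bwd=fs.d_df_bwd * np.array([-1, 1, 1]),
            alpha=0.1, n_iter=0, levels=1, residuals={})
        w = derive_kinematics(fs, 1.0, 1.0).angular_velocity[0, 0, 0]
        wm = derive_kinematics(mirrored, 1.0, 1.0).angular_velocity[0, 0, 0]
        assert abs(w[2] + wm[2]) < 1e-12
        assert abs(np.linalg.norm(w) - np.linalg.norm(wm)) < 1e-12


class TestProjections:
    def _kin_with_velocity(self, v, shape=(4, 4, 4)):
        offs = {k: np.asarray(v) * k for k in (-2, -1, 1, 2)}
        return derive_kinematics(flowset_from_path(offs, shape), 1.0, 1.0)

    def test_local_axis_velocity_sign(self):
        """Retraction along −z on a +z-oriented fiber is negative."""
        kin = self._kin_with_velocity([0.0, 0.0, -0.02])
        e = np.broadcast_to([0.0, 0.0, 1.0], (4, 4, 4, 3))
        proj = local_axis_projection(kin, e)
        assert np.allclose(proj.axial_velocity[proj.valid], -0.02)

    def test_local_axis_requires_direction(self):
        kin = self._kin_with_velocity([0.0, 0.0, -0.02])
        e = np.zeros((4, 4, 4, 3))
        proj = local_axis_projection(kin, e)
        assert not proj.valid.any()

    def test_chordal_equals_local_for_straight_filopodium(self):
        """Point receding from base along +z: chordal axis ≈ +z."""
        t = (np.arange(9) - 4) * 1.0
        path = np.stack([np.zeros_like(t), np.zeros_like(t), 5.0 + 0.1 * t],
                        axis=-1)
        chordal, orbital = chordal_orbital_axes(
            path, np.zeros(3), np.array([0.0, 0.0, 1.0]), 1.0)
        np.testing.assert_allclose(chordal.axis, orbital.axis, atol=1e-9)
        np.testing.assert_allclose(chordal.axial_velocity, 0.1, atol=1e-9)

    def test_chordal_masked_at_base(self):
        path = np.zeros((9, 3))
        chordal, _ = chordal_orbital_axes(path, np.zeros(3),
                                          np.array([0.0, 0.0, 1.0]), 1.0)
        assert not chordal.valid.any()

    def test_rigid_rotation_about_base(self):
        """Rotation about the base: chordal velocity ≈ 0, ang vel ≈ spin."""
        om, r = 0.05, 3.0
        t = (np.arange(9) - 4) * 1.0
        path = np.stack([r * np.cos(om * t), r * np.sin(om * t),
                         np.zeros_like(t)], axis=-1)
        # fiber direction at base along +z = the rotation axis
        chordal, orbital = chordal_orbital_axes(
            path, np.zeros(3), np.array([0.0, 0.0, 1.0]), 1.0)
        assert np.abs(chordal.axial_velocity).max() < 1e-3
        np.testing.assert_allclose(orbital.axial_angular_velocity, om,
                                   rtol=0.01)

    def test_radial_projection_exploding_phantom(self):
        """Radial outflow: radial axial velocity > 0, angular ≈ 0."""
        shape = (9, 9, 9)
        z, y, x = np.mgrid[:9, :9, :9].astype(float)
        vol = np.exp(-((x - 4) ** 2 + (y - 4) ** 2 + (z - 4) ** 2) / 8)
        pos = np.stack([x - 4, y - 4, z - 4], axis=-1)
        rn = np.linalg.norm(pos, axis=-1)
        rhat = pos / np.where(rn > 0, rn, 1)[..., None]
        rate = 0.1
        fs = FlowSet(d_sf_fwd=rhat * rate, d_sf_bwd=-rhat * rate,
                     d_df_fwd=rhat * 2 * rate, d_df_bwd=-rhat * 2 * rate,
                     alpha=0.1, n_iter=0, levels=1, residuals={})
        kin = derive_kinematics(fs, 1.0, 1.0, intensity=vol,
                                tau_intensity_frac=0.01)
        proj = radial_axis_projection(kin, vol)
        sel = proj.valid & (rn > 1)
        assert proj.axial_velocity[sel].min() > 0
        assert np.abs(proj.axial_angular_velocity[sel]).max() < 1e-9

    def test_radial_centroid_of_symmetric_phantom(self):
        z, y, x = np.mgrid[:9, :9, :9].astype(float)
        vol = np.exp(-((x - 4) ** 2 + (y - 4) ** 2 + (z - 4) ** 2) / 8)
        kin = derive_kinematics(circle_flowset(0.05, 1.0, 1.0, (9, 9, 9)),
                                1.0, 1.0)
        proj = radial_axis_projection(kin, vol)
        np.testing.assert_allclose(proj.meta["centroid_xyz"], [4, 4, 4],
                                   atol=0.1)

    def test_zero_intensity_rejected(self):
        kin = derive_kinematics(circle_flowset(0.05, 1.0, 1.0), 1.0, 1.0)
        with pytest.raises(ValueError):
            radial_axis_projection(kin, np.zeros((5, 5, 5)))


class TestPixelwise2D:
    def test_clockwise_circle_positive_rate(self):
        """A blob on a clockwise circular path gives positive angular rate
        and curvature 1/R, pinned to the display convention."""
        from scipy import ndimage as ndi
        R, pitch, dt = 100.0, 2.5, 10.0     # µm, µm/px, s
        Rpx = R / pitch
        n = 96
        rng = np.random.default_rng(3)
        tex = ndi.gaussian_filter(rng.normal(size=(n, n)), 2.0)
        yy, xx = np.mgrid[:n, :n].astype(float)
        ccx, ccy = n / 2, n / 2 + Rpx
        sp = 6.0                            # px per frame
        om = sp / Rpx
        frames = []
        for k in range(5):
            ang = -np.pi / 2 + om * (k - 2)
            bx, by = ccx + Rpx * np.cos(ang), ccy + Rpx * np.sin(ang)
            env = np.exp(-(((xx - bx) ** 2 + (yy - by) ** 2)) / (2 * 10**2))
            texk = ndi.shift(tex, (by - ccy + Rpx, bx - ccx), order=3,
                             mode="wrap")
            frames.append(env * (1 + 0.5 * texk))
        from rtdic.containers import Movie2D
        movie = Movie2D(np.stack(frames), pitch=pitch, dt=dt)
        kin, rate, curv, mask = pixelwise_2d_motility(
            movie, alpha=0.05, n_iter=300, tau_intensity_frac=0.3)
        mean_curv = curv[mask].mean() * 1e3            # rad/mm
        assert mean_curv > 0
        assert abs(mean_curv - 1e3 / R) / (1e3 / R) < 0.10

    def test_too_few_frames(self):
        from rtdic.containers import Movie2D
        movie = Movie2D(np.zeros((3, 16, 16)), pitch=1.0, dt=1.0)
        with pytest.raises(ValueError):
            pixelwise_2d_motility(movie)
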