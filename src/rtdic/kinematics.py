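"""Voxel-wise kinematics from five-frame displacement sets.

With the four displacement fields d± (single-frame) and D± (double-frame)
of :class:`~rtdic.flow.FlowSet`, the symmetric five-point stencil gives

    v = [8(d⁺ − d⁻) − (D⁺ − D⁻)] / (12Δt)         velocity, µm/s
    a = (d⁺ + d⁻) / Δt²                           acceleration, µm/s²
    j = (D⁺ − 2d⁺ + 2d⁻ − D⁻) / (2Δt³)            jerk, µm/s³
    ω = (v × a) / |v|²                            Frenet angular velocity

(each exact for cubic polynomial paths; the velocity stencil is the
five-point first derivative, which cancels the O(Δt²) curvature bias of
the plain central difference).  The Frenet triad is T = v/|v|,
B = v×a/|v×a|, N = B×T.  Voxels where |v| or |v×a| fall below numeric
floors are masked rather than NaN-propagated, and all chirality-signed
projections inherit the package's display conventions: positive axial
velocity = extension along base→tip, positive axial angular velocity =
right-screw rotation about the reference axis, positive 2D angular
velocity = clockwise on screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import FlowSet, five_frame_flowset

__all__ = [
    "KinField",
    "AxisProjection",
    "derive_kinematics",
    "local_axis_projection",
    "chordal_orbital_axes",
    "radial_axis_projection",
    "pixelwise_2d_motility",
    "path_kinematics",
]


@dataclass
class KinField:
    """Per-voxel kinematic vector fields (components (x, y[, z]))."""

    velocity: np.ndarray          # µm/s
    acceleration: np.ndarray      # µm/s²
    jerk: np.ndarray              # µm/s³
    angular_velocity: np.ndarray  # rad/s (3D) or scalar rate (2D helper)
    tangent: np.ndarray
    normal: np.ndarray
    binormal: np.ndarray
    visible: np.ndarray           # intensity >= τI
    motile: np.ndarray            # |v| >= τv (and visible)
    defined: np.ndarray           # |v×a| above floor: triad/ω valid
    dt: float
    pitch: tuple


@dataclass
class AxisProjection:
    """Signed projections of v and ω onto a per-voxel reference axis."""

    kind: str                     # local | chordal | orbital | radial
    axis: np.ndarray              # unit vectors, (..., d)
    axial_velocity: np.ndarray    # µm/s; > 0 extension, < 0 retraction
    axial_angular_velocity: np.ndarray  # rad/s; > 0 right-screw
    valid: np.ndarray
    meta: dict = field(default_factory=dict)


def _cross(v, a):
    return np.cross(v, a)


def derive_kinematics(flowset: FlowSet, dt: float, pitch,
                      intensity: np.ndarray | None = None,
                      tau_intensity_frac: float = 0.1,
                      tau_speed_vox: float = 0.2,
                      floor: float = 1e-12) -> KinField:
    """Physical kinematic fields from a :class:`FlowSet`.

    ``pitch`` is the voxel pitch in µm, scalar or per (x, y[, z]) axis;
    anisotropic pitch is honoured by scaling each displacement component.
    ``intensity`` (the center frame) feeds the visibility mask at
    ``tau_intensity_frac`` of its maximum; the motility mask uses
    ``tau_speed_vox`` voxels/frame.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    d = flowset.d_sf_fwd.shape[-1]
    pitch = np.broadcast_to(np.asarray(pitch, float), (d,))
    if not np.allclose(pitch, pitch[0]):
        import warnings
        warnings.warn("anisotropic pitch: proceeding in physical units; "
                      "consider resample_isotropic first")
    sf_f = flowset.d_sf_fwd * pitch
    sf_b = flowset.d_sf_bwd * pitch
    df_f = flowset.d_df_fwd * pitch
    df_b = flowset.d_df_bwd * pitch
    v = (8 * (sf_f - sf_b) - (df_f - df_b)) / (12 * dt)
    a = (sf_f + sf_b) / dt**2
    j = (df_f - 2 * sf_f + 2 * sf_b - df_b) / (2 * dt**3)
    speed = np.linalg.norm(v, axis=-1)
    if d == 3:
        cross = _cross(v, a)
        cross_mag = np.linalg.norm(cross, axis=-1)
    else:
        cross = v[..., 0] * a[..., 1] - v[..., 1] * a[..., 0]
        cross_mag = np.abs(cross)
    v2 = speed**2
    defined = (speed > floor) & (cross_mag > floor)
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = np.where(
            defined[..., None] if d == 3 else defined,
            cross / np.where(v2 > 0, v2, 1.0)[..., None] if d == 3
            else cross / np.where(v2 > 0, v2, 1.0),
            0.0)
        T = np.where((speed > floor)[..., None],
                     v / np.where(speed > 0, speed, 1.0)[..., None], 0.0)
        if d == 3:
            B = np.where(defined[..., None],
                         cross / np.where(cross_mag > 0, cross_mag, 1.0
                                          )[..., None], 0.0)
            N = _cross(B, T)
        else:
            B = np.zeros_like(T)
            N = np.stack([-T[..., 1], T[..., 0]], axis=-1)
    if intensity is not None:
        visible = np.asarray(intensity, float) >= \
            tau_intensity_frac * float(np.max(intensity))
    else:
        visible = np.ones(speed.shape, dtype=bool)
    motile = visible & (speed * dt >= tau_speed_vox * pitch.min())
    return KinField(velocity=v, acceleration=a, jerk=j,
                    angular_velocity=omega, tangent=T, normal=N, binormal=B,
                    visible=visible, motile=motile, defined=defined,
                    dt=dt, pitch=tuple(pitch))


def local_axis_projection(kin: KinField, direction_field: np.ndarray,
                          tractable: np.ndarray | None = None
                          ) -> AxisProjection:
    """Project v and ω onto the tip-oriented local fiber axis.

    Velocity projections are evaluated on visible∧tractable voxels;
    angular-velocity projections additionally require the motile mask and
    a defined Frenet system.
    """
    e = np.asarray(direction_field, float)
    norm = np.linalg.norm(e, axis=-1)
    has_dir = norm > 0.5
    tract = np.ones_like(has_dir) if tractable is None else \
        np.asarray(tractable, bool)
    valid_v = kin.visible & tract & has_dir
    valid_w = valid_v & kin.motile & kin.defined
    av = np.where(valid_v, np.sum(kin.velocity * e, axis=-1), 0.0)
    aw = np.where(valid_w, np.sum(kin.angular_velocity * e, axis=-1), 0.0)
    return AxisProjection(kind="local", axis=e, axial_velocity=av,
                          axial_angular_velocity=aw, valid=valid_v,
                          meta={"valid_omega": valid_w})


def path_kinematics(path: np.ndarray, dt: float):
    """Five-point-stencil kinematics of a tracked point path (T, d) µm.

    Returns (v, a, j, ω) arrays over the interior frames (two trimmed at
    each end), using the same stencil as the voxel-wise analysis.
    """
    p = np.asarray(path, float)
    sf_f = p[3:-1] - p[2:-2]
    sf_b = p[1:-3] - p[2:-2]
    df_f = p[4:] - p[2:-2]
    df_b = p[:-4] - p[2:-2]
    v = (8 * (sf_f - sf_b) - (df_f - df_b)) / (12 * dt)
    a = (sf_f + sf_b) / dt**2
    j = (df_f - 2 * sf_f + 2 * sf_b - df_b) / (2 * dt**3)
    v2 = np.sum(v * v, axis=-1, keepdims=True)
    if p.shape[-1] == 3:
        omega = np.where(v2 > 0, np.cross(v, a) / np.where(v2 > 0, v2, 1.0),
                         0.0)
    else:
        omega = (v[..., 0] * a[..., 1] - v[..., 1] * a[..., 0]) / v2[..., 0]
    return v, a, j, omega


def chordal_orbital_axes(point_path: np.ndarray, base_path: np.ndarray,
                         fiber_dir_at_base: np.ndarray, dt: float
                         ) -> tuple[AxisProjection, AxisProjection]:
    """Chordal- and orbital-axis projections for a tracked point.

    The chordal axis is the unit chord from the tracked basal point to the
    point of interest; the orbital axis is the fiber direction at the
    basal point.  Kinematics of the point path use the five-point stencil;
    outputs cover the interior frames.  Coincident point and base mask the
    chordal projection.
    """
    p = np.asarray(point_path, float)
    b = np.broadcast_to(np.asarray(base_path, float), p.shape)
    v, a, j, omega = path_kinematics(p, dt)
    chord = (p - b)[2:-2]
    cn = np.linalg.norm(chord, axis=-1)
    ok = cn > 1e-9
    chord_axis = np.where(ok[..., None], chord / np.where(ok, cn, 1.0)[..., None], 0.0)
    orb = np.asarray(fiber_dir_at_base, float)
    orb = orb / np.linalg.norm(orb)
    orb_axis = np.broadcast_to(orb, chord_axis.shape)
    chordal = AxisProjection(
        kind="chordal", axis=chord_axis,
        axial_velocity=np.where(ok, np.sum(v * chord_axis, axis=-1), 0.0),
        axial_angular_velocity=np.where(ok, np.sum(omega * chord_axis,
                                                   axis=-1), 0.0),
        valid=ok)
    orbital = AxisProjection(
        kind="orbital", axis=orb_axis,
        axial_velocity=np.sum(v * orb_axis, axis=-1),
        axial_angular_velocity=np.sum(omega * orb_axis, axis=-1),
        valid=np.ones_like(ok))
    return chordal, orbital


def radial_axis_projection(kin: KinField, volume: np.ndarray,
                           tip_certainty: np.ndarray | None = None,
                           ct_threshold: float = 0.15) -> AxisProjection:
    """Project v and ω onto the radial axis from the intensity-weighted
    centroid of the cell.

    Restricted to voxels whose tip certainty exceeds ``ct_threshold``
    (when provided) intersected with the kinematic validity masks.
    """
    vol = np.asarray(volume, float)
    total = vol.sum()
    if total <= 0:
        raise ValueError("zero total intensity")
    d = vol.ndim
    grids = np.meshgrid(*[np.arange(n) for n in vol.shape], indexing="ij")
    centroid = np.array([(vol * g).sum() / total for g in grids])  # array order
    pos = np.stack(grids[::-1], axis=-1).astype(float)  # (x, y[, z])
    radial = pos - centroid[::-1]
    rn = np.linalg.norm(radial, axis=-1)
    ok = rn > 1e-9
    axis = np.where(ok[..., None], radial / np.where(ok, rn, 1.0)[..., None],
                    0.0)
    valid = ok & kin.visible
    if tip_certainty is not None:
        valid &= np.asarray(tip_certainty) >= ct_threshold
    valid_w = valid & kin.motile & kin.defined
    av = np.where(valid, np.sum(kin.velocity * axis, axis=-1), 0.0)
    aw = np.where(valid_w, np.sum(kin.angular_velocity * axis, axis=-1), 0.0)
    return AxisProjection(kind="radial", axis=axis, axial_velocity=av,
                          axial_angular_velocity=aw, valid=valid,
                          meta={"centroid_xyz": centroid[::-1],
                                "valid_omega": valid_w})


def pixelwise_2d_motility(movie2d, t_index: int | None = None,
                          alpha: float = 0.1, n_iter: int = 200,
                          levels: int | None = None,
                          tau_intensity_frac: float = 0.1,
                          tau_speed_vox: float = 0.2):
    """Pixel-wise 2D kinematics of a movie at one center frame.

    Runs the five-frame flow scheme in 2D and returns
    ``(kin, angular_rate, signed_curvature, mask)`` where ``angular_rate``
    is the scalar rotation rate ``(v_x a_y − v_y a_x)/|v|²`` in rad/s
    (positive = clockwise on screen) and ``signed_curvature`` is the path
    curvature ``angular_rate/|v|`` in rad/µm.
    """
    data = movie2d.data if hasattr(movie2d, "data") else np.asarray(movie2d)
    pitch = getattr(movie2d, "pitch", 1.0)
    dt = getattr(movie2d, "dt", 1.0)
    if data.shape[0] < 5:
        raise ValueError("need >= 5 frames")
    if t_index is None:
        t_index = data.shape[0] // 2
    if not 2 <= t_index <= data.shape[0] - 3:
        raise ValueError("t_index must have two frames on each side")
    frames = data[t_index - 2:t_index + 3]
    fs = five_frame_flowset(frames, alpha=alpha, n_iter=n_iter,
                            levels=levels)
    kin = derive_kinematics(fs, dt, pitch, intensity=frames[2],
                            tau_intensity_frac=tau_intensity_frac,
                            tau_speed_vox=tau_speed_vox)
    v, a = kin.velocity, kin.acceleration
    speed = np.linalg.norm(v, axis=-1)
    v2 = speed**2
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(v2 > 0, (v[..., 0] * a[..., 1] -
                                 v[..., 1] * a[..., 0]) / np.where(v2 > 0, v2, 1.0), 0.0)
        curv = np.where(speed > 0, rate / np.where(speed > 0, speed, 1.0),
                        0.0)
    mask = kin.visible & kin.motile
    return kin, np.where(mask, rate, 0.0), np.where(mask, curv, 0.0), mask
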