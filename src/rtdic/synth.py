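"""Synthetic phantoms with analytic ground truth.

Every downstream stage of the pipeline (filtering, optical flow, kinematics,
tracking, statistics) is validated against these generators, which emulate
the study conditions without any microscope data:

* a radial grating and its synthetic shadow-cast DIC rendering,
* a Gaussian blob moving on a 3D helix (closed-form kinematics),
* a retracting, axially spinning filopodium-like cylinder,
* 2D migrating cell blobs with a constant clockwise angular-velocity bias.

All phantoms are deterministic given the spec (including the seed), and
mirroring a phantom flips the sign of every chirality-signed ground-truth
quantity while preserving magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import Movie2D, Movie3D, Plane

__all__ = [
    "SynthSpec",
    "radial_grating",
    "synth_dic",
    "helical_blob_movie",
    "filopodium_phantom",
    "walker_movie_2d",
    "HelixTruth",
    "FilopodiumTruth",
]


@dataclass
class SynthSpec:
    """Parameters of the synthetic phantoms (µm, s, deg unless noted).

    Defaults are the study conditions the validation suite runs under:
    near-isotropic 100 nm voxels at 1 s (3D phantoms, matching the scale of
    growth-cone imaging), a 2 µm-radius helix at 0.05 rad/s, a filopodium
    retracting at 0.02 µm/s while spinning at +0.03 rad/s, and amoeboid
    walkers at 10 µm/min with a +0.8°/min clockwise heading bias.
    """

    # image geometry
    shape: tuple[int, ...] = (64, 64, 64)       # (z, y, x) or (y, x)
    pitch: float = 0.1                          # µm per voxel (isotropic)
    dt: float = 1.0                             # s between frames
    n_frames: int = 9
    # DIC rendering
    theta: float = 45.0                         # shear angle, deg
    # radial grating
    n_spokes: int = 16
    # blob
    blob_sigma: float = 0.3                     # µm
    # helix
    helix_radius: float = 2.0                   # µm
    helix_pitch: float = 1.0                    # axial advance per turn, µm
    helix_omega: float = 0.05                   # rad/s
    helix_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    # filopodium
    filo_length: float = 4.0                    # µm
    filo_radius: float = 0.25                   # µm
    retraction_speed: float = 0.02              # µm/s (positive = shrinking)
    axial_spin: float = 0.03                    # rad/s, + = right-screw
    azim_phase: float = 0.0                     # surface texture start, rad
    # 2D walkers
    n_walkers: int = 50
    walker_speed: float = 10.0                  # µm/min
    angular_bias: float = 0.8                   # deg/min, + = clockwise
    heading_noise: float = 10.0                 # deg per step (s.d.)
    walker_sigma: float = 4.0                   # rendered cell radius, µm
    noise_sigma: float = 0.0                    # additive image noise, off
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pitch", "dt", "blob_sigma", "helix_radius",
                     "filo_length", "filo_radius", "walker_speed",
                     "walker_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_walkers < 1:
            raise ValueError("n_walkers must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# radial grating and synthetic DIC
# ---------------------------------------------------------------------------

def radial_grating(spec: SynthSpec | None = None, *, shape=(512, 512),
                   n_spokes: int | None = None, pitch: float = 0.1) -> Plane:
    """Radial grating test pattern, ``I(φ) = 0.5·(1 + cos(N·φ))``.

    ``N`` must be even (the pattern is then symmetric under 180° rotation)
    and at least 4.  Intensity lies in [0, 1] with bright spokes at angles
    where ``cos(Nφ) = 1``.
    """
    if spec is not None:
        shape = spec.shape if len(spec.shape) == 2 else shape
        n_spokes = spec.n_spokes
        pitch = spec.pitch
    if n_spokes is None:
        n_spokes = 16
    if n_spokes % 2 != 0 or n_spokes < 4:
        raise ValueError("spoke count must be even and >= 4")
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    phi = np.arctan2(y - cy, x - cx)
    img = 0.5 * (1.0 + np.cos(n_spokes * phi))
    return Plane(img, pitch=pitch, meta={"n_spokes": n_spokes})


def synth_dic(ground_truth: Plane | np.ndarray, theta: float = 45.0,
              pitch: float | None = None) -> Plane:
    """Render a synthetic shadow-cast DIC image from a ground-truth image.

    The DIC image is the sum of the inverted image and its directional
    gradient along the shear axis: ``−I + ∂I/∂d`` with ``d = (cosθ, sinθ)``
    (θ in degrees, display frame, gradient by central differences in pixel
    units).
    """
    if isinstance(ground_truth, Plane):
        img = ground_truth.data
        pitch = ground_truth.pitch if pitch is None else pitch
    else:
        img = np.asarray(ground_truth, dtype=float)
        pitch = 1.0 if pitch is None else pitch
    if not np.all(np.isfinite(img)):
        raise ValueError("ground truth must be finite")
    t = np.deg2rad(theta)
    gy, gx = np.gradient(img)          # central differences, per pixel
    out = -img + np.cos(t) * gx + np.sin(t) * gy
    return Plane(out, pitch=pitch, meta={"theta": theta})


# ---------------------------------------------------------------------------
# Gaussian blob on a 3D helix
# ---------------------------------------------------------------------------

def _rotation_to_axis(axis) -> np.ndarray:
    """Rotation matrix taking ẑ to ``axis`` (identity when already ẑ)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, a)
    c = float(np.dot(z, a))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


@dataclass
class HelixTruth:
    """Closed-form kinematics of the helical blob at each frame time."""

    t: np.ndarray              # (T,) s
    position: np.ndarray       # (T, 3) µm, components (x, y, z)
    velocity: np.ndarray       # (T, 3) µm/s
    acceleration: np.ndarray   # (T, 3) µm/s²
    jerk: np.ndarray           # (T, 3) µm/s³
    angular_velocity: np.ndarray  # (T, 3) rad/s, Frenet ω = v×a/|v|²


def _helix_path(spec: SynthSpec, t: np.ndarray):
    r, h, w = spec.helix_radius, spec.helix_pitch, spec.helix_omega
    R = _rotation_to_axis(spec.helix_axis)
    c, s = np.cos(w * t), np.sin(w * t)
    p = np.stack([r * c, r * s, h * w * t / (2 * np.pi)], axis=-1)
    v = np.stack([-r * w * s, r * w * c,
                  np.full_like(t, h * w / (2 * np.pi))], axis=-1)
    a = np.stack([-r * w**2 * c, -r * w**2 * s, np.zeros_like(t)], axis=-1)
    j = np.stack([r * w**3 * s, -r * w**3 * c, np.zeros_like(t)], axis=-1)
    return p @ R.T, v @ R.T, a @ R.T, j @ R.T


def _frenet_omega(v: np.ndarray, a: np.ndarray) -> np.ndarray:
    cross = np.cross(v, a)
    v2 = np.sum(v * v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(v2 > 0, cross / v2, 0.0)
    return w


def render_blob(shape, centers_um, sigma_um, pitch) -> np.ndarray:
    """Render isotropic Gaussian blobs sampled at voxel centers."""
    nz, ny, nx = shape
    z, y, x = np.mgrid[0:nz, 0:ny, 0:nx].astype(float) * pitch
    vol = np.zeros(shape, dtype=float)
    for cx, cy, cz in np.atleast_2d(centers_um):
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        vol += np.exp(-d2 / (2.0 * sigma_um**2))
    return vol


def helical_blob_movie(spec: SynthSpec) -> tuple[Movie3D, HelixTruth]:
    """Gaussian blob travelling on a helix, with closed-form ground truth.

    The path is ``p(t) = (r cos Ωt, r sin Ωt, h·Ωt/2π)`` rotated into the
    requested axis and centred in the volume.  Raises if the blob would
    leave the volume (3σ margin).
    """
    if spec.n_frames < 7:
        raise ValueError("need >= 7 frames for five-frame kinematics on "
                         ">= 3 interior frames")
    t = np.arange(spec.n_frames) * spec.dt
    p, v, a, j = _helix_path(spec, t)
    extent = np.array(spec.shape[::-1]) * spec.pitch   # (x, y, z) µm
    center = extent / 2.0
    # centre the path's bounding box in the volume
    offset = center - (p.min(axis=0) + p.max(axis=0)) / 2.0
    pc = p + offset
    margin = 3.0 * spec.blob_sigma
    if np.any(pc - margin < 0) or np.any(pc + margin > extent):
        raise ValueError("helical path leaves the volume (3σ margin)")
    frames = np.stack([render_blob(spec.shape, pc[k], spec.blob_sigma,
                                   spec.pitch) for k in range(spec.n_frames)])
    if spec.noise_sigma > 0:
        frames = frames + spec.rng().normal(0, spec.noise_sigma, frames.shape)
    truth = HelixTruth(t=t, position=pc, velocity=v, acceleration=a, jerk=j,
                       angular_velocity=_frenet_omega(v, a))
    movie = Movie3D(frames, pitch=(spec.pitch,) * 3, dt=spec.dt,
                    meta={"seed": spec.seed, "phantom": "helical_blob"})
    return movie, truth


# ---------------------------------------------------------------------------
# filopodium phantom
# ---------------------------------------------------------------------------

@dataclass
class FilopodiumTruth:
    t: np.ndarray
    base: np.ndarray                # (3,) µm
    axis: np.ndarray                # unit base→tip
    length: np.ndarray              # (T,) µm
    axial_velocity: float           # µm/s, negative = retraction
    axial_angular_velocity: float   # rad/s, positive = right-screw


def filopodium_phantom(spec: SynthSpec) -> tuple[Movie3D, FilopodiumTruth]:
    """Retracting, axially spinning cylinder with surface texture.

    The cylinder is anchored at a base point on the lower-z face and
    aligned with +z (base→tip).  Its length shrinks at
    ``retraction_speed`` while an axial surface texture treadmills toward
    the base at the same speed (the retrograde-flow appearance of real
    filopodia) and an azimuthal texture rotates about the axis at
    ``axial_spin`` (positive = right-screw about base→tip).  Ground truth
    carries the two signed axial quantities directly.
    """
    if spec.filo_radius < 2 * spec.pitch:
        raise ValueError("cylinder radius must be >= 2 voxels")
    t = np.arange(spec.n_frames) * spec.dt
    length = spec.filo_length - spec.retraction_speed * t
    if np.any(length <= 0):
        raise ValueError("filopodium length underflows before movie ends")
    nz, ny, nx = spec.shape
    extent = np.array([nx, ny, nz]) * spec.pitch
    # base on the voxel-grid symmetry center so x-mirroring is exact
    base = np.array([(nx - 1) / 2 * spec.pitch,
                     (ny - 1) / 2 * spec.pitch, 3 * spec.pitch])
    axis = np.array([0.0, 0.0, 1.0])
    z, y, x = np.mgrid[0:nz, 0:ny, 0:nx].astype(float) * spec.pitch
    s = z - base[2]                       # axial coordinate (µm)
    rx, ry = x - base[0], y - base[1]
    rho2 = rx**2 + ry**2
    phi = np.arctan2(ry, rx)
    sig = spec.filo_radius
    lam_s = 1.0                           # axial texture wavelength, µm
    frames = np.empty((spec.n_frames, nz, ny, nx), dtype=float)
    for k in range(spec.n_frames):
        envelope = np.exp(-rho2 / (2 * sig**2)) \
            / (1.0 + np.exp(-s / (0.5 * sig))) \
            / (1.0 + np.exp((s - length[k]) / (0.5 * sig)))
        # texture crests drift toward the base at the retraction speed and
        # rotate right-screw about +z at the axial spin rate
        axial_tex = 1.0 + 0.4 * np.cos(
            2 * np.pi * (s + spec.retraction_speed * t[k]) / lam_s)
        azim_tex = 1.0 + 0.4 * np.cos(phi - spec.azim_phase
                                      - spec.axial_spin * t[k])
        frames[k] = envelope * axial_tex * azim_tex
    if spec.noise_sigma > 0:
        frames = frames + spec.rng().normal(0, spec.noise_sigma, frames.shape)
    truth = FilopodiumTruth(
        t=t, base=base, axis=axis, length=length,
        axial_velocity=-spec.retraction_speed,
        axial_angular_velocity=spec.axial_spin)
    movie = Movie3D(frames, pitch=(spec.pitch,) * 3, dt=spec.dt,
                    meta={"seed": spec.seed, "phantom": "filopodium"})
    return movie, truth


# ---------------------------------------------------------------------------
# 2D walkers with clockwise heading bias
# ---------------------------------------------------------------------------

def walker_tracks(spec: SynthSpec, arena_um: tuple[float, float]) -> pd.DataFrame:
    """Ground-truth random-walk tracks (no rendering).

    Headings evolve ``φ(t+dt) = φ(t) + ω0·dt + ε`` with ε ~ N(0, noise²)
    per step; positions advance at constant speed and reflect at the arena
    border (reflection frames are flagged).  Positive ω0 turns the walker
    clockwise on screen.  Walkers are impenetrable: pairs closer than
    4·``walker_sigma`` are pushed apart along the line of centers and both
    frames flagged as contacts (the ground-truth encounter schedule).
    """
    rng = spec.rng()
    dt_min = spec.dt / 60.0                       # spec.dt is seconds
    step_len = spec.walker_speed * dt_min         # µm per step
    bias = np.deg2rad(spec.angular_bias) * dt_min
    noise = np.deg2rad(spec.heading_noise)
    w, h = arena_um
    margin = 3 * spec.walker_sigma
    # low-density seeding: rejection-sample a minimum separation so cells
    # start as distinct particles
    min_sep = 4 * spec.walker_sigma
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(placed) < spec.n_walkers:
        cand = (rng.uniform(margin, w - margin),
                rng.uniform(margin, h - margin))
        if all((cand[0] - p[0])**2 + (cand[1] - p[1])**2 >= min_sep**2
               for p in placed):
            placed.append(cand)
        attempts += 1
        if attempts > 10000 * spec.n_walkers:
            raise ValueError("arena too small for the requested walkers")
    pos = np.asarray(placed)
    phi = rng.uniform(-np.pi, np.pi, spec.n_walkers)
    d_min = 4.0 * spec.walker_sigma
    contact = np.zeros(spec.n_walkers, dtype=bool)
    rows = []
    for k in range(spec.n_frames):
        for i in range(spec.n_walkers):
            rows.append((i, k, k * spec.dt, pos[i, 0], pos[i, 1],
                         np.rad2deg(phi[i]), False, bool(contact[i])))
        if k == spec.n_frames - 1:
            break
        phi = phi + bias + rng.normal(0.0, noise, spec.n_walkers)
        step = step_len * np.column_stack([np.cos(phi), np.sin(phi)])
        new = pos + step
        # excluded volume: push overlapping pairs apart symmetrically
        contact = np.zeros(spec.n_walkers, dtype=bool)
        for _ in range(5):
            diff = new[None, :, :] - new[:, None, :]
            dist = np.linalg.norm(diff, axis=-1)
            iu, ju = np.triu_indices(spec.n_walkers, k=1)
            close = dist[iu, ju] < d_min
            if not close.any():
                break
            for i, jj in zip(iu[close], ju[close]):
                dvec = new[jj] - new[i]
                d = np.hypot(*dvec)
                if d < 1e-9:
                    dvec, d = np.array([1.0, 0.0]), 1.0
                push = (d_min - d) / 2.0 * dvec / d
                new[i] -= push
                new[jj] += push
                contact[i] = contact[jj] = True
        reflected = np.zeros(spec.n_walkers, dtype=bool)
        for ax, lim in ((0, w), (1, h)):
            low = new[:, ax] < margin
            high = new[:, ax] > lim - margin
            new[low, ax] = 2 * margin - new[low, ax]
            new[high, ax] = 2 * (lim - margin) - new[high, ax]
            reflected |= low | high
        # heading follows the realized step after reflection/contact
        real_step = new - pos
        bumped = reflected | contact
        phi = np.where(bumped, np.arctan2(real_step[:, 1], real_step[:, 0]),
                       phi)
        for idx in np.nonzero(reflected)[0]:
            r = rows[-spec.n_walkers + idx]
            rows[-spec.n_walkers + idx] = r[:6] + (True, r[7])
        pos = new
    df = pd.DataFrame(rows, columns=["track", "frame", "t", "x", "y",
                                     "heading", "reflected", "contact"])
    return df


def walker_movie_2d(spec: SynthSpec, *, as_dic: bool = False
                    ) -> tuple[Movie2D, pd.DataFrame]:
    """Render the 2D walker phantom and return it with ground-truth tracks.

    Cells are isotropic Gaussian blobs; with ``as_dic`` the frames are
    passed through :func:`synth_dic` to emulate shadow-cast DIC contrast.
    """
    if len(spec.shape) != 2:
        raise ValueError("walker_movie_2d needs a 2D spec.shape")
    ny, nx = spec.shape
    arena = (nx * spec.pitch, ny * spec.pitch)
    tracks = walker_tracks(spec, arena)
    sig_px = spec.walker_sigma / spec.pitch
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    frames = np.zeros((spec.n_frames, ny, nx), dtype=float)
    for k in range(spec.n_frames):
        sub = tracks[tracks.frame == k]
        for _, row in sub.iterrows():
            cx, cy = row.x / spec.pitch, row.y / spec.pitch
            x0, x1 = int(max(0, cx - 4 * sig_px)), int(min(nx, cx + 4 * sig_px + 1))
            y0, y1 = int(max(0, cy - 4 * sig_px)), int(min(ny, cy + 4 * sig_px + 1))
            d2 = (xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2
            frames[k, y0:y1, x0:x1] += np.exp(-d2 / (2 * sig_px**2))
    if spec.noise_sigma > 0:
        frames = frames + spec.rng().normal(0, spec.noise_sigma, frames.shape)
    if as_dic:
        frames = np.stack([synth_dic(f, spec.theta).data for f in frames])
    movie = Movie2D(frames, pitch=spec.pitch, dt=spec.dt,
                    meta={"seed": spec.seed, "phantom": "walkers"})
    return movie, tracks


def mirrored(spec: SynthSpec) -> SynthSpec:
    """Spec of the mirror-image phantom (x → −x): flips every chiral sign."""
    ax = spec.helix_axis
    return replace(spec, helix_axis=(-ax[0], ax[1], ax[2]),
                   helix_omega=spec.helix_omega,
                   axial_spin=-spec.axial_spin,
                   angular_bias=-spec.angular_bias)
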