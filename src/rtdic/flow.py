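"""Dense Horn–Schunck optical flow in 2D and 3D with Gaussian pyramids.

The Horn–Schunck estimator minimizes brightness-constancy violation plus a
smoothness penalty; its Jacobi iteration is

    u ← ū − I_x (I_x ū_x + I_y ū_y [+ I_z ū_z] + I_t) / (α² + |∇I|²)

per component, where ū is the neighbour mean of the current field
(6-neighbour mean in 3D, 4-neighbour in 2D), derivatives are central
differences averaged over the two frames, and boundaries are Neumann
(replicated edges).  Large displacements are handled coarse-to-fine: the
image pyramid is built with Gaussian pre-smoothing (σ = 1 voxel) and
decimation by 2, the coarse flow is upsampled, used to warp frame 0 toward
frame 1, and the residual flow estimated at the finer level.

For the five-frame kinematic scheme, :func:`five_frame_flowset` computes
the four displacement fields from the center frame to t±1 and t±2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FlowSet", "horn_schunck", "pyramid_flow", "five_frame_flowset"]


@dataclass
class FlowSet:
    """The four displacement fields of the five-frame scheme (voxel units).

    All fields live on the grid of the center frame; components are in
    (x, y[, z]) order on the last axis.
    """

    d_sf_fwd: np.ndarray    # t → t+1
    d_sf_bwd: np.ndarray    # t → t−1
    d_df_fwd: np.ndarray    # t → t+2
    d_df_bwd: np.ndarray    # t → t−2
    alpha: float
    n_iter: int
    levels: int
    residuals: dict


def _neighbor_mean(u: np.ndarray) -> np.ndarray:
    """Mean over the 2·d axis neighbours with replicated edges."""
    d = u.ndim
    acc = np.zeros_like(u)
    for ax in range(d):
        for shift in (1, -1):
            acc += _roll_replicate(u, shift, ax)
    return acc / (2 * d)


def _roll_replicate(u: np.ndarray, shift: int, axis: int) -> np.ndarray:
    out = np.roll(u, shift, axis=axis)
    sl = [slice(None)] * u.ndim
    src = [slice(None)] * u.ndim
    if shift == 1:
        sl[axis] = slice(0, 1)
        src[axis] = slice(0, 1)
    else:
        sl[axis] = slice(-1, None)
        src[axis] = slice(-1, None)
    out[tuple(sl)] = u[tuple(src)]
    return out


def _central_diff(f: np.ndarray, axis: int) -> np.ndarray:
    return (_roll_replicate(f, -1, axis) - _roll_replicate(f, 1, axis)) / 2.0


def horn_schunck(frame0: np.ndarray, frame1: np.ndarray, alpha: float = 0.1,
                 n_iter: int = 200, tol: float = 1e-6,
                 init: np.ndarray | None = None):
    """Single-level Horn–Schunck flow from ``frame0`` to ``frame1``.

    Returns ``(flow, residual)``; ``flow[..., i]`` is the displacement
    component in (x, y[, z]) voxels.  Identical frames give exactly zero
    flow.  The residual is the RMS update of the last iteration.
    """
    f0 = np.asarray(frame0, float)
    f1 = np.asarray(frame1, float)
    if f0.shape != f1.shape:
        raise ValueError("frames must share a shape")
    if not (np.all(np.isfinite(f0)) and np.all(np.isfinite(f1))):
        raise ValueError("non-finite frames")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    d = f0.ndim
    favg = (f0 + f1) / 2.0
    # spatial derivatives averaged over the two frames; array axis for
    # component i (x first) is d-1-i
    I = [_central_diff(favg, d - 1 - i) for i in range(d)]
    It = f1 - f0
    denom_base = sum(g * g for g in I)
    u = (np.zeros(f0.shape + (d,)) if init is None
         else np.array(init, float, copy=True))
    residual = 0.0
    for _ in range(n_iter):
        ubar = np.stack([_neighbor_mean(u[..., i]) for i in range(d)],
                        axis=-1)
        proj = sum(I[i] * ubar[..., i] for i in range(d)) + It
        denom = alpha**2 + denom_base
        new = np.stack([ubar[..., i] - I[i] * proj / denom for i in range(d)],
                       axis=-1)
        residual = float(np.sqrt(np.mean((new - u) ** 2)))
        u = new
        if residual < tol:
            break
    return u, residual


def _decimate(f: np.ndarray) -> np.ndarray:
    """Gaussian pre-smooth then 2× block mean.

    Block averaging (not strided sampling) keeps decimation equivariant
    under mirroring for even sizes — chirality-signed outputs must not
    depend on image handedness through grid alignment.
    """
    sm = ndimage.gaussian_filter(f, 1.0, mode="nearest")
    for ax in range(f.ndim):
        n = sm.shape[ax]
        if n % 2 == 1:                      # replicate last slice to even
            pad = [(0, 0)] * sm.ndim
            pad[ax] = (0, 1)
            sm = np.pad(sm, pad, mode="edge")
            n += 1
        shape = list(sm.shape)
        shape[ax] = n // 2
        shape.insert(ax + 1, 2)
        sm = sm.reshape(shape).mean(axis=ax + 1)
    return sm


def _warp(frame: np.ndarray, flow: np.ndarray) -> np.ndarray:
    """Warp ``frame`` forward by ``flow`` (sampling at x + d(x))."""
    d = frame.ndim
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in frame.shape],
                        indexing="ij")
    coords = [grids[ax] + flow[..., d - 1 - ax] for ax in range(d)]
    return ndimage.map_coordinates(frame, coords, order=1, mode="nearest")


def pyramid_flow(frame0: np.ndarray, frame1: np.ndarray, levels: int | None
                 = None, alpha: float = 0.1, n_iter: int = 200,
                 tol: float = 1e-6, warps: int = 3):
    """Coarse-to-fine Horn–Schunck flow.

    ``levels=None`` chooses ``1 + floor(log2(min_dim/16))`` so the coarsest
    level keeps at least 8 voxels per axis; ``levels=1`` with ``warps=1``
    reduces to plain :func:`horn_schunck`.  At each level the target frame
    is warped backward by the current estimate and the residual flow
    re-estimated ``warps`` times.  Returns ``(flow, residuals)`` with one
    residual per level (coarse first).
    """
    f0 = np.asarray(frame0, float)
    f1 = np.asarray(frame1, float)
    min_dim = min(f0.shape)
    if levels is None:
        levels = max(1, 1 + int(np.floor(np.log2(min_dim / 16))))
    if min_dim / 2 ** (levels - 1) < 8:
        raise ValueError("coarsest level below 8 voxels per axis")
    pyr0, pyr1 = [f0], [f1]
    for _ in range(levels - 1):
        pyr0.append(_decimate(pyr0[-1]))
        pyr1.append(_decimate(pyr1[-1]))
    flow = None
    residuals = []
    for lev in range(levels - 1, -1, -1):
        a, b = pyr0[lev], pyr1[lev]
        if flow is None:
            flow = np.zeros(a.shape + (a.ndim,))
        else:
            zoom = [b1 / b0 for b0, b1 in zip(flow.shape[:-1], a.shape)]
            # grid_mode=True: voxels are blocks, so upsampling stays
            # aligned with the block-mean decimation (mirror-equivariant)
            comp = [ndimage.zoom(flow[..., i], zoom, order=1,
                                 mode="nearest", grid_mode=True)
                    for i in range(a.ndim)]
            flow = np.stack(comp, axis=-1) * 2.0
        res = 0.0
        for _ in range(max(1, warps)):
            # f0(x) ≈ f1(x + w): warp the target back by w, estimate the
            # residual displacement, accumulate
            warped = _warp(b, flow)
            inc, res = horn_schunck(a, warped, alpha=alpha, n_iter=n_iter,
                                    tol=tol)
            flow = flow + inc
        residuals.append(res)
    return flow, residuals


def five_frame_flowset(frames, alpha: float = 0.1, n_iter: int = 200,
                       levels: int | None = None) -> FlowSet:
    """Four displacement fields from five sequential frames.

    ``frames`` are the five frames ``t−2 … t+2``; flows are estimated from
    the center frame to each of the other four (single-frame forward and
    backward, double-frame forward and backward).
    """
    frames = [np.asarray(f, float) for f in frames]
    if len(frames) != 5:
        raise ValueError(
            "exactly 5 frames required (t−2…t+2); the first and last two "
            "time points of a movie yield no kinematics")
    center = frames[2]
    flows, residuals = {}, {}
    for name, target in (("sf_fwd", frames[3]), ("sf_bwd", frames[1]),
                         ("df_fwd", frames[4]), ("df_bwd", frames[0])):
        fl, res = pyramid_flow(center, target, levels=levels, alpha=alpha,
                               n_iter=n_iter)
        flows[name] = fl
        residuals[name] = res
    lev = len(residuals["sf_fwd"])
    return FlowSet(d_sf_fwd=flows["sf_fwd"], d_sf_bwd=flows["sf_bwd"],
                   d_df_fwd=flows["df_fwd"], d_df_bwd=flows["df_bwd"],
                   alpha=alpha, n_iter=n_iter, levels=lev,
                   residuals=residuals)
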