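"""Segmentation, flow-assisted centroid linking and chirality statistics
for 2D cell-migration movies.

Cells in spatiotemporally smoothed self-luminous (RT-DIC) frames are
segmented by watershed seeded from h-maxima, linked across frames by
greedy nearest-neighbour assignment of flow-predicted centroids, and each
track is reduced to heading increments Δφ (degrees, clockwise on screen
positive), a mean angular velocity (deg/min) and a signed trajectory
curvature (rad/mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

__all__ = [
    "CellTrack",
    "segment_cells",
    "link_tracks",
    "chirality_stats",
    "contact_state",
    "tracks_to_frame",
]


@dataclass
class CellTrack:
    """Per-cell time series of centroids (µm) and derived chirality."""

    track_id: int
    frames: list = field(default_factory=list)       # frame indices
    times: list = field(default_factory=list)        # s
    centroids: list = field(default_factory=list)    # (x, y) µm
    areas: list = field(default_factory=list)        # µm²
    labels: list = field(default_factory=list)       # watershed label/frame
    contact: list = field(default_factory=list)      # bool per frame

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray(self.centroids, float)


def segment_cells(plane: np.ndarray, smooth_sigma: float = 2.0,
                  h_frac: float = 0.10, pitch: float = 1.0):
    """Watershed segmentation of a self-luminous intensity plane.

    The plane is Gaussian-smoothed, background is set by Otsu, markers are
    the h-maxima of the smoothed image at ``h = h_frac × dynamic range``,
    and watershed runs on the inverted intensity.  Returns
    ``(labels, centroids_df)`` with intensity-weighted centroids in µm.
    """
    img = np.asarray(plane, float)
    sm = ndimage.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 \
        else img
    rng = float(sm.max() - sm.min())
    if rng == 0:
        return np.zeros(img.shape, int), _centroid_frame([], [], [])
    fg = sm > threshold_otsu(sm)
    if not fg.any():
        return np.zeros(img.shape, int), _centroid_frame([], [], [])
    maxima = h_maxima(sm, h_frac * rng)
    markers, n = ndimage.label(maxima)
    if n == 0:
        return np.zeros(img.shape, int), _centroid_frame([], [], [])
    labels = watershed(-sm, markers, mask=fg)
    ids, cxs, cys, areas = [], [], [], []
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        if not m.any():
            continue
        w = sm * m
        tot = w.sum()
        yy, xx = np.nonzero(m)
        cx = (w[yy, xx] * xx).sum() / tot
        cy = (w[yy, xx] * yy).sum() / tot
        ids.append(lab)
        cxs.append(cx * pitch)
        cys.append(cy * pitch)
        areas.append(m.sum() * pitch**2)
    return labels, _centroid_frame(ids, list(zip(cxs, cys)), areas)


def _centroid_frame(ids, xy, areas) -> pd.DataFrame:
    xy = np.asarray(xy, float).reshape(-1, 2)
    return pd.DataFrame({"label": ids, "x": xy[:, 0], "y": xy[:, 1],
                         "area": areas})


def link_tracks(label_movie, centroid_frames, flow_fields=None,
                pitch: float = 1.0, dt: float = 1.0,
                gate: float | None = None) -> list[CellTrack]:
    """Link per-frame particles into tracks, flow-assisted.

    Each live track's next centroid is predicted by adding the mean
    optical-flow displacement inside its particle mask (when flow is
    given); assignment is greedy nearest-neighbour under a distance gate
    (default: 2× the median per-step displacement, estimated from the
    predictions themselves).  Unmatched detections start tracks;
    unmatched tracks terminate.
    """
    n_frames = len(centroid_frames)
    tracks: list[CellTrack] = []
    live: dict[int, CellTrack] = {}
    next_id = 0

    def _new_track(frame, row):
        nonlocal next_id
        tr = CellTrack(next_id)
        next_id += 1
        _append(tr, frame, row)
        tracks.append(tr)
        return tr

    def _append(tr, frame, row):
        tr.frames.append(frame)
        tr.times.append(frame * dt)
        tr.centroids.append((row.x, row.y))
        tr.areas.append(row.area)
        tr.labels.append(int(row.label))

    first = centroid_frames[0]
    for _, row in first.iterrows():
        tr = _new_track(0, row)
        live[tr.track_id] = tr

    for k in range(1, n_frames):
        det = centroid_frames[k]
        det_xy = det[["x", "y"]].to_numpy()
        preds, pred_tracks = [], []
        for tid, tr in live.items():
            cx, cy = tr.centroids[-1]
            if flow_fields is not None:
                lab_img = label_movie[k - 1]
                m = lab_img == tr.labels[-1]
                if m.any():
                    fl = flow_fields[k - 1]
                    dx = float(fl[..., 0][m].mean()) * pitch
                    dy = float(fl[..., 1][m].mean()) * pitch
                    cx, cy = cx + dx, cy + dy
            preds.append((cx, cy))
            pred_tracks.append(tr)
        preds = np.asarray(preds, float).reshape(-1, 2)
        if gate is None:
            if len(preds) and len(det_xy):
                d0 = np.linalg.norm(
                    preds[:, None, :] - det_xy[None, :, :], axis=-1)
                med = np.median(d0.min(axis=1)) if d0.size else 1.0
                gate_k = max(2.0 * med, 2.0 * pitch)
            else:
                gate_k = np.inf
        else:
            gate_k = gate
        assigned_det = set()
        new_live = {}
        if len(preds) and len(det_xy):
            dist = np.linalg.norm(preds[:, None, :] - det_xy[None, :, :],
                                  axis=-1)
            order = np.dstack(np.unravel_index(np.argsort(dist, axis=None),
                                               dist.shape))[0]
            used_tr = set()
            for ti, di in order:
                if ti in used_tr or di in assigned_det:
                    continue
                if dist[ti, di] > gate_k:
                    break
                tr = pred_tracks[ti]
                _append(tr, k, det.iloc[di])
                new_live[tr.track_id] = tr
                used_tr.add(ti)
                assigned_det.add(di)
        for di, (_, row) in enumerate(det.iterrows()):
            if di not in assigned_det:
                tr = _new_track(k, row)
                new_live[tr.track_id] = tr
        live = new_live
    return tracks


def _wrap_deg(a):
    return (a + 180.0) % 360.0 - 180.0


def chirality_stats(tracks, min_step: float = 0.5, dt: float | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Per-track and per-culture chirality summary.

    Heading φ = atan2(Δy, Δx) in display coordinates; the angular
    displacement Δφ between successive steps is wrapped to (−180°, 180°],
    positive clockwise.  Steps shorter than ``min_step`` (µm) contribute
    no heading.  Per track: mean angular velocity (deg/min) and signed
    curvature (rad/mm, mean of Δφ_rad/step length).  Tracks with fewer
    than 3 gated steps are excluded but counted.
    """
    rows, excluded = [], 0
    for tr in tracks:
        p = tr.positions
        t = np.asarray(tr.times, float)
        if len(p) < 4:
            excluded += 1
            continue
        steps = np.diff(p, axis=0)
        lens = np.linalg.norm(steps, axis=1)
        step_dt = np.diff(t)
        keep = lens >= min_step
        if keep.sum() < 3:
            excluded += 1
            continue
        idx = np.nonzero(keep)[0]
        headings = np.degrees(np.arctan2(steps[idx, 1], steps[idx, 0]))
        dphi = _wrap_deg(np.diff(headings))
        span_min = (t[idx[-1] + 1] - t[idx[0] + 1]) / 60.0
        if span_min <= 0 or len(dphi) == 0:
            excluded += 1
            continue
        ang_vel = dphi.sum() / span_min                     # deg/min
        seg_len = np.array([lens[idx[i + 1]] for i in range(len(dphi))])
        curv = np.mean(np.deg2rad(dphi) / seg_len) * 1e3    # rad/mm
        rows.append({"track": tr.track_id, "n_steps": int(keep.sum()),
                     "mean_angular_velocity": ang_vel,
                     "signed_curvature": curv,
                     "cumulative_angle": float(dphi.sum()),
                     "mean_speed": float(lens[keep].mean() /
                                         step_dt[keep].mean() * 60.0)})
    per_track = pd.DataFrame(rows)
    if len(per_track):
        summary = {
            "n_tracks": int(len(per_track)),
            "n_excluded": excluded,
            "mean_angular_velocity": float(
                per_track.mean_angular_velocity.mean()),
            "sd_angular_velocity": float(
                per_track.mean_angular_velocity.std(ddof=1))
            if len(per_track) > 1 else 0.0,
            "mean_signed_curvature": float(
                per_track.signed_curvature.mean()),
        }
        summary["sem_angular_velocity"] = (
            summary["sd_angular_velocity"] / np.sqrt(len(per_track))
            if len(per_track) > 1 else 0.0)
    else:
        summary = {"n_tracks": 0, "n_excluded": excluded}
    return per_track, summary


def contact_state(label_movie, dilate_px: int = 2) -> list[dict[int, bool]]:
    """Per-frame contact flags: a particle's dilated mask touches another.

    Returns one ``{label: bool}`` dict per frame.
    """
    out = []
    struct = ndimage.generate_binary_structure(2, 1)
    for labels in label_movie:
        flags: dict[int, bool] = {}
        present = [lab for lab in np.unique(labels) if lab != 0]
        for lab in present:
            m = labels == lab
            dil = ndimage.binary_dilation(m, struct, iterations=dilate_px)
            others = (labels != 0) & (labels != lab)
            flags[int(lab)] = bool((dil & others).any())
        out.append(flags)
    return out


def tracks_to_frame(tracks) -> pd.DataFrame:
    """Flatten tracks to one row per particle per frame."""
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            rows.append({"track": tr.track_id, "frame": tr.frames[i],
                         "t": tr.times[i], "x": tr.centroids[i][0],
                         "y": tr.centroids[i][1], "area": tr.areas[i],
                         "contact": tr.contact[i] if tr.contact else None})
    return pd.DataFrame(rows)
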