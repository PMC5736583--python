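"""Pipeline configuration and the two workflow presets.

``PipelineConfig`` is a schema-validated bundle of every stage parameter
(unknown keys are rejected); ``run_pipeline`` composes the stages in the
canonical order — expand → drift/Z correction → RT-DIC conversion →
(deconvolution) → smoothing → isotropic resampling → structure tensor →
optical flow → kinematics → projections — for the 3D workflow, or the
segment/link/chirality variant for 2D migration movies.  Every output
directory carries a provenance record (full config + hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import kinematics as kin_mod
from . import preprocess, riesz, tensor, tracking
from .containers import Movie2D, Movie3D
from .flow import five_frame_flowset
from .io import write_sidecar

log = logging.getLogger("rtdic")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage toggles and parameters of the two workflow presets."""

    layout: str = "3d"                 # "2d" | "3d"
    # metadata
    pitch: tuple = (0.0645, 0.0645, 0.25)   # µm
    dt: float = 1.0                    # s
    seed: int = 0
    out_dir: str = "rtdic_out"
    # preprocessing
    expand: bool = True
    drift_correct: bool = True
    z_correct: bool = False
    smooth_sigma: tuple = (1.0, 1.0, 0.5)    # (sx, sy, st) voxels/frames
    z_upsample: int = 4
    # conversion
    shear_theta: float = 45.0
    hp_sigma: float = riesz.DEFAULT_HP_SIGMA
    threshold_at_zero: bool = True
    pad: str = "mirror"
    # tensor
    sigma_out_um: float = 0.6 / 2.0    # tensor outer scale (radius ~ d/2)
    # flow
    alpha: float = 0.1
    n_iter: int = 200
    levels: int | None = None
    # masks
    tau_intensity_frac: float = 0.1
    tau_speed_vox: float = 0.2
    # tracking (2D preset)
    seg_smooth_sigma: float = 2.0
    h_frac: float = 0.10
    min_step_um: float = 0.5
    contact_dilate_px: int = 2

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.layout not in ("2d", "3d"):
            raise ValueError("layout must be '2d' or '3d'")
        if cfg.dt <= 0 or min(np.atleast_1d(cfg.pitch)) <= 0:
            raise ValueError("pitch and dt must be positive")
        return cfg

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, movie, out_dir=None) -> dict:
    """Run the configured preset on a movie; returns the result dict.

    Numeric artifacts are written under ``out_dir`` with a provenance
    sidecar; the returned dict also carries the in-memory fields.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timing = {}
    results: dict = {"config_hash": config.hash()}

    def _stage(name, fn, *a, **kw):
        s = time.time()
        r = fn(*a, **kw)
        timing[name] = time.time() - s
        log.info("stage %s: %.2fs", name, timing[name])
        return r

    if config.layout == "3d":
        assert isinstance(movie, Movie3D)
        if config.expand:
            movie = _stage("expand", preprocess.expand_range, movie)
        if config.drift_correct and movie.n_frames >= 2:
            movie = _stage("drift", preprocess.correct_xy_drift, movie)
        if config.z_correct:
            def _zc(mv):
                data = np.stack([preprocess.correct_z_positions(f)[0]
                                 for f in mv.data])
                return Movie3D(data, pitch=mv.pitch, dt=mv.dt,
                               meta=dict(mv.meta))
            movie = _stage("zcorrect", _zc, movie)
        movie = _stage("convert", riesz.rtdic_convert, movie,
                       config.shear_theta, config.hp_sigma,
                       config.threshold_at_zero, config.pad)
        sx, sy, st = config.smooth_sigma
        movie = _stage("smooth", preprocess.smooth_spatiotemporal, movie,
                       sx, sy, st)
        if config.z_upsample > 1 and not movie.isotropic:
            movie = _stage("isotropic", preprocess.resample_isotropic,
                           movie, config.z_upsample)
        t_center = movie.n_frames // 2
        t_center = min(max(t_center, 2), movie.n_frames - 3)
        center = movie.data[t_center]
        sig_out_vox = config.sigma_out_um / movie.pitch[0]
        tf = _stage("tensor", lambda: tensor.certainties(
            tensor.compute_tensor(center, max(1.0, sig_out_vox / 3),
                                  max(2.0, sig_out_vox))))
        fs = _stage("flow", five_frame_flowset,
                    movie.data[t_center - 2:t_center + 3],
                    config.alpha, config.n_iter, config.levels)
        kin = _stage("kinematics", kin_mod.derive_kinematics, fs, movie.dt,
                     movie.pitch, center, config.tau_intensity_frac,
                     config.tau_speed_vox)
        proj = _stage("radial", kin_mod.radial_axis_projection, kin, center,
                      tf.ct)
        results.update({"movie": movie, "tensor": tf, "flow": fs,
                        "kinematics": kin, "radial": proj,
                        "t_center": t_center})
        np.save(out / "axial_angular_velocity.npy",
                proj.axial_angular_velocity)
    else:
        assert isinstance(movie, Movie2D)
        if config.expand:
            movie = _stage("expand", preprocess.expand_range, movie)
        conv = _stage("convert", riesz.rtdic_convert, movie,
                      config.shear_theta, config.hp_sigma,
                      config.threshold_at_zero, config.pad)
        sx, sy, st = config.smooth_sigma
        conv = _stage("smooth", preprocess.smooth_spatiotemporal, conv,
                      sx, sy, st)
        labels, cents = [], []
        for k in range(conv.n_frames):
            lab, cen = tracking.segment_cells(conv.data[k],
                                              config.seg_smooth_sigma,
                                              config.h_frac, conv.pitch)
            labels.append(lab)
            cents.append(cen)
        tracks = _stage("link", tracking.link_tracks, labels, cents, None,
                        conv.pitch, conv.dt)
        per_track, summary = _stage("chirality", tracking.chirality_stats,
                                    tracks, config.min_step_um)
        contacts = _stage("contact", tracking.contact_state, labels,
                          config.contact_dilate_px)
        results.update({"movie": conv, "labels": labels, "tracks": tracks,
                        "per_track": per_track, "summary": summary,
                        "contacts": contacts})
        per_track.to_csv(out / "tracks_summary.csv", index=False)
        tracking.tracks_to_frame(tracks).to_csv(out / "tracks.csv",
                                                index=False)
    timing["total"] = time.time() - t0
    prov = {"config": asdict(config), "config_hash": config.hash(),
            "timing": timing,
            "conventions": {"display": "y down", "positive_rotation":
                            "clockwise on screen / right-screw about axis",
                            "z": "away from objective"}}
    write_sidecar(out / "provenance", prov)
    results["timing"] = timing
    return results
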