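"""TIFF / CSV / JSON input and output with provenance sidecars.

Movies are multi-page TIFF: a single multi-page file for 2D movies, one
file per time point for 3D stacks (serially numbered).  Pixel pitch and
frame interval travel in a JSON sidecar (``<stem>.json``) when not given
as flags; arrays of 8/12/16-bit integers or float are promoted to float.
"""

from __future__ import annotations

import glob as _glob
import json
from pathlib import Path

import numpy as np
import tifffile

from .containers import Movie2D, Movie3D

__all__ = ["read_movie", "write_movie", "write_sidecar", "read_sidecar"]


def _np_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def write_sidecar(path, payload: dict) -> Path:
    p = Path(path).with_suffix(".json")
    p.write_text(json.dumps(payload, indent=2, default=_np_default))
    return p


def read_sidecar(path) -> dict:
    p = Path(path).with_suffix(".json")
    return json.loads(p.read_text()) if p.exists() else {}


def read_movie(path_or_glob, layout: str = "2d", pitch=None, dt=None):
    """Read a movie from TIFF.

    ``layout='2d'``: one multi-page file, pages are time frames.
    ``layout='3d'``: a glob of serially numbered multi-page files, one
    Z-stack per file, sorted lexically.  Missing pitch/dt must come from
    the sidecar or the keyword arguments, otherwise an explicit error
    names the flag to set.
    """
    if layout not in ("2d", "3d"):
        raise ValueError("layout must be '2d' or '3d'")
    if layout == "2d":
        path = Path(path_or_glob)
        data = tifffile.imread(path).astype(float)
        if data.ndim == 2:
            data = data[None]
        side = read_sidecar(path)
        pitch = pitch if pitch is not None else side.get("pitch")
        dt = dt if dt is not None else side.get("dt")
        if pitch is None:
            raise ValueError("pixel pitch missing: set --pitch or sidecar")
        if dt is None:
            raise ValueError("frame interval missing: set --dt or sidecar")
        return Movie2D(data, pitch=float(pitch), dt=float(dt), meta=side)
    files = sorted(_glob.glob(str(path_or_glob)))
    if not files:
        raise FileNotFoundError(f"no files match {path_or_glob}")
    stacks = [tifffile.imread(f).astype(float) for f in files]
    shapes = {s.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent stack shapes: {shapes}")
    side = read_sidecar(files[0])
    pitch = pitch if pitch is not None else side.get("pitch")
    dt = dt if dt is not None else side.get("dt")
    if pitch is None:
        raise ValueError("voxel pitch missing: set --pitch x,y,z or sidecar")
    if dt is None:
        raise ValueError("frame interval missing: set --dt or sidecar")
    pitch = tuple(np.atleast_1d(np.asarray(pitch, float)).tolist())
    if len(pitch) == 1:
        pitch = pitch * 3
    return Movie3D(np.stack(stacks), pitch=pitch, dt=float(dt), meta=side)


def write_movie(movie, path, sidecar: dict | None = None):
    """Write a movie to float32 TIFF with a JSON sidecar.

    2D movies become one multi-page file; 3D movies one file per time
    point (``<stem>_t0000.tif`` …) plus the sidecar on the stem.
    """
    path = Path(path)
    payload = {"pitch": movie.pitch, "dt": movie.dt}
    payload.update({k: v for k, v in movie.meta.items()
                    if _json_ok(v)})
    if sidecar:
        payload.update(sidecar)
    if isinstance(movie, Movie2D):
        tifffile.imwrite(path, movie.data.astype(np.float32),
                         photometric="minisblack")
        write_sidecar(path, payload)
        return [path]
    paths = []
    for k in range(movie.n_frames):
        p = path.with_name(f"{path.stem}_t{k:04d}{path.suffix or '.tif'}")
        tifffile.imwrite(p, movie.data[k].astype(np.float32),
                         photometric="minisblack")
        paths.append(p)
    write_sidecar(path, payload)
    return paths


def _json_ok(v) -> bool:
    try:
        json.dumps(v, default=_np_default)
        return True
    except TypeError:
        return False
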