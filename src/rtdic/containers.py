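"""Lightweight in-memory containers shared across the pipeline.

Conventions used throughout the package (chirality signs depend on them):

* Array axes are ``(y, x)`` for planes, ``(z, y, x)`` for volumes, with a
  leading time axis for movies.  The row index ``y`` increases *downward* on
  screen (display convention), ``x`` increases to the right and ``z``
  increases away from the objective.  This frame is right-handed.
* Vector *components* are ordered ``(x, y)`` / ``(x, y, z)``.
* A positive in-plane rotation (from +x toward +y) is **clockwise on
  screen**; a positive axial angular velocity about a reference axis is a
  **right-screw** rotation about that axis.
* Physical units are µm, seconds, radians and degrees; voxel units appear
  only internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Plane", "Movie2D", "Movie3D"]


def _check_finite(a: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")


@dataclass
class Plane:
    """A single 2D intensity image with physical pixel pitch.

    Parameters
    ----------
    data:
        2D array, shape ``(y, x)``, at least 8×8.
    pitch:
        Pixel pitch in µm (isotropic in-plane).
    bit_depth:
        Bit depth of the acquisition the values originate from (metadata
        only; the array itself is floating point).
    """

    data: np.ndarray
    pitch: float = 1.0
    bit_depth: int = 12
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or min(self.data.shape) < 8:
            raise ValueError("Plane requires a 2D array of at least 8×8")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        _check_finite(self.data, "Plane.data")


@dataclass
class Movie2D:
    """Time-lapse of 2D frames, shape ``(t, y, x)``."""

    data: np.ndarray
    pitch: float = 1.0
    dt: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Movie2D requires a (t, y, x) array")
        if self.pitch <= 0 or self.dt <= 0:
            raise ValueError("pitch and dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class Movie3D:
    """Time-lapse of Z-stacks, shape ``(t, z, y, x)``.

    ``pitch`` is ``(x, y, z)`` voxel pitch in µm; the stage-offset record
    filled in by drift correction lives in ``meta['drift']``.
    """

    data: np.ndarray
    pitch: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dt: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("Movie3D requires a (t, z, y, x) array")
        if min(self.pitch) <= 0 or self.dt <= 0:
            raise ValueError("pitch and dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def isotropic(self) -> bool:
        return np.allclose(self.pitch, self.pitch[0])
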