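"""Shared containers for image time series and rigid transforms.

Coordinate conventions used across the package (stated once, used everywhere):

* images are ``(row, col)`` numpy arrays; the origin is the top-left corner,
  rows (``y``) increase downward — the direction of gravity on the plate;
* point coordinates are written ``(x, y) = (col, row)`` in pixel units, with
  pixel centres at integer coordinates;
* observation times are 1-based indices ``1..N_t``; continuous times appear
  after interpolation (a node at ``t = 3.5`` appeared midway between the
  third and fourth observation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = ["RigidTransform", "ImageTimeSeries"]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about the image centre followed by a translation.

    Maps moving-image coordinates onto fixed-image coordinates:
    ``p' = R(theta) @ (p - c) + c + (dx, dy)`` with ``p = (x, y)`` and ``c``
    the rotation centre (normally the image centre).
    """

    theta: float = 0.0  # radians, counter-clockwise in (x, y)
    dx: float = 0.0
    dy: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an ``(n, 2)`` array of ``(x, y)`` points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center, dtype=float)
        ct, st = math.cos(self.theta), math.sin(self.theta)
        rot = np.array([[ct, -st], [st, ct]])
        out = (pts - c) @ rot.T + c + np.array([self.dx, self.dy])
        return out.reshape(np.asarray(points, dtype=float).shape)

    def inverse(self) -> "RigidTransform":
        ct, st = math.cos(self.theta), math.sin(self.theta)
        # Solve p = R^-1 (p' - t - c) + c for the same centre convention.
        tx, ty = self.dx, self.dy
        inv_dx = -(ct * tx + st * ty)
        inv_dy = -(-st * tx + ct * ty)
        return RigidTransform(-self.theta, inv_dx, inv_dy, self.center)

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to ``self ∘ inner``.

        Both operands must share the same rotation centre.
        """
        if not np.allclose(self.center, inner.center):
            raise ValueError("composition requires a common rotation centre")
        theta = self.theta + inner.theta
        ct, st = math.cos(self.theta), math.sin(self.theta)
        dx = ct * inner.dx - st * inner.dy + self.dx
        dy = st * inner.dx + ct * inner.dy + self.dy
        return RigidTransform(theta, dx, dy, self.center)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return abs(self.theta) < tol and abs(self.dx) < tol and abs(self.dy) < tol

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "dx": self.dx,
            "dy": self.dy,
            "center": list(self.center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(d["theta"], d["dx"], d["dy"], tuple(d["center"]))

    @classmethod
    def identity(cls, shape: tuple[int, int] | None = None) -> "RigidTransform":
        center = (0.0, 0.0)
        if shape is not None:
            center = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
        return cls(0.0, 0.0, 0.0, center)


@dataclass
class ImageTimeSeries:
    """A registered or raw 2D+t grayscale stack with acquisition metadata."""

    frames: np.ndarray  # (n_t, rows, cols), float32 or integer grayscale
    timestep_h: float
    px_size_um: float
    transforms: list | None = None  # per-frame transforms onto the last frame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_t, rows, cols) array")

    @property
    def n_t(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_t

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    # -- disk I/O ---------------------------------------------------------

    def write_tiffs(self, directory: str | Path, plate_id: str = "0") -> list[Path]:
        """Write frames as ``plate_<id>_t<k>.tif`` (k = 1..n_t) plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for k in range(self.n_t):
            frame = self.frames[k]
            if frame.dtype.kind == "f":
                frame = np.clip(np.round(frame), 0, 255).astype(np.uint8)
            p = directory / f"plate_{plate_id}_t{k + 1}.tif"
            tifffile.imwrite(p, frame)
            paths.append(p)
        manifest = {
            "plate_id": plate_id,
            "n_t": self.n_t,
            "timestep_h": self.timestep_h,
            "px_size_um": self.px_size_um,
            "transforms": [t.to_dict() if t is not None else None
                           for t in self.transforms] if self.transforms else None,
        }
        (directory / f"plate_{plate_id}_manifest.json").write_text(
            json.dumps(manifest, indent=2))
        return paths

    @classmethod
    def read_tiffs(cls, paths: Sequence[str | Path], timestep_h: float,
                   px_size_um: float) -> "ImageTimeSeries":
        frames = np.stack([tifffile.imread(p) for p in paths])
        if frames.dtype == np.uint16:
            # thresholds are calibrated on 8-bit gray levels
            frames = (frames / 257.0).astype(np.float32)
        return cls(frames.astype(np.float32), timestep_h, px_size_um)
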