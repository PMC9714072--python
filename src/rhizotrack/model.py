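"""Root system architecture model: per-plant forests of timed polylines.

An :class:`Organ` is an ordered polyline of ``(x, y, t)`` nodes — pixel
coordinates plus a continuous observation time.  First-order organs
(primaries) root the per-plant trees; second-order organs (laterals) carry a
reference to their parent and the index of the parent node nearest to their
attachment point.  Nodes flagged ``extrapolated`` were inferred rather than
observed (seed extrapolation upstream, hidden growth downstream) and are
excluded from growth statistics by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Organ", "Plant", "RootSystemModel"]


@dataclass
class Organ:
    points: np.ndarray                 # (n, 3) columns x, y, t
    order: int = 1                     # 1 = primary, 2 = lateral
    extrapolated: np.ndarray | None = None  # (n,) bool
    parent: int | None = None          # organ index within the plant
    attachment_index: int | None = None  # node index on the parent polyline
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.extrapolated is None:
            self.extrapolated = np.zeros(len(self.points), dtype=bool)
        else:
            self.extrapolated = np.asarray(self.extrapolated, dtype=bool)
        if len(self.extrapolated) != len(self.points):
            raise ValueError("extrapolated flag length mismatch")

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def t_first(self) -> float:
        return float(self.points[0, 2])

    @property
    def t_last(self) -> float:
        return float(self.points[-1, 2])

    def segment_lengths(self) -> np.ndarray:
        """Euclidean length of each polyline segment, px."""
        d = np.diff(self.points[:, :2], axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    def length_px(self, t: float | None = None,
                  include_extrapolated: bool = False) -> float:
        """Arc length of segments whose apparition time (later node) is <= t."""
        if self.n_nodes < 2:
            return 0.0
        seg = self.segment_lengths()
        keep = np.ones(len(seg), dtype=bool)
        if t is not None:
            keep &= self.points[1:, 2] <= t + 1e-9
        if not include_extrapolated:
            keep &= ~(self.extrapolated[1:] | self.extrapolated[:-1])
        return float(seg[keep].sum())

    def position_at(self, t: float) -> np.ndarray:
        """Interpolated (x, y) tip position at continuous time t."""
        ts = self.points[:, 2]
        t = float(np.clip(t, ts[0], ts[-1]))
        i = int(np.searchsorted(ts, t, side="right")) - 1
        i = min(max(i, 0), self.n_nodes - 2) if self.n_nodes > 1 else 0
        if self.n_nodes == 1 or ts[i + 1] <= ts[i]:
            return self.points[i, :2].copy()
        w = (t - ts[i]) / (ts[i + 1] - ts[i])
        return (1 - w) * self.points[i, :2] + w * self.points[i + 1, :2]


@dataclass
class Plant:
    organs: list[Organ] = field(default_factory=list)
    seed_xy: tuple[float, float] = (0.0, 0.0)

    @property
    def primary(self) -> Organ | None:
        for o in self.organs:
            if o.order == 1:
                return o
        return None

    @property
    def laterals(self) -> list[Organ]:
        return [o for o in self.organs if o.order == 2]


@dataclass
class RootSystemModel:
    plants: list[Plant]
    px_size_um: float
    timestep_h: float
    n_timesteps: int
    meta: dict = field(default_factory=dict)

    @property
    def px_mm(self) -> float:
        return self.px_size_um / 1000.0

    def all_organs(self):
        for ip, plant in enumerate(self.plants):
            for io, organ in enumerate(plant.organs):
                yield ip, io, organ

    def validate(self) -> None:
        """Raise on invariant violations, naming the offending organ."""
        for ip, io, organ in self.all_organs():
            name = f"plant {ip} organ {io}"
            if organ.n_nodes < 2:
                raise ValueError(f"{name}: fewer than 2 nodes")
            ts = organ.points[:, 2]
            if np.any(np.diff(ts) < -1e-6):
                raise ValueError(f"{name}: node times decrease")
            if organ.order == 2 and organ.parent is None:
                continue  # orphan laterals are allowed but unattached
            if organ.order == 2:
                parent = self.plants[ip].organs[organ.parent]
                if parent.order != 1:
                    raise ValueError(f"{name}: lateral attached to a lateral")
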