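"""Pipeline configuration.

Defaults reproduce the acquisition regime and thresholds of the reference
setup: 5 plants per plate, 19 µm/px, one observation every 8 h, mean-shift
thresholds s1 = 25 and s2 = 10 gray levels, 2000-px minimum component size
(equivalent to 38 mm of 1-px-wide organ at 19 µm/px), and a 25x MADe outlier
bound for artefact roots.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RegistrationConfig:
    block_half: int = 8           # blocks are (2*block_half+1)^2 px
    stride: int = 10              # grid spacing between block centres
    search_radius: int = 40       # px search window around each block (rigid)
    dense_search_radius: int = 10  # px search window for the dense stage
    dense_block_half: int = 15    # larger blocks for the dense stage: small
    # blocks slide along straight roots (aperture problem)
    dense_stride: int = 16
    variance_percentile: float = 85.0  # blocks below this intensity-variance
    # percentile are discarded (flat background carries no signal)
    min_variance: float = 30.0    # absolute variance floor, gray^2 — well
    # above sensor noise (sd ~3), far below root-bearing blocks
    min_correspondences: int = 3
    n_iterations: int = 3         # estimate/warp/re-estimate refinement loops
    trim_factor: float = 3.0      # residual > trim_factor * median -> outlier
    dense_sigma_px: float = 24.0  # Gaussian regularisation of the dense field
    dense_cap_px: float = 8.0     # displacement magnitude cap for the field
    use_dense: bool = False       # rigid-only by default; dense is a refinement


@dataclass
class SegmentationConfig:
    s1: float = 25.0              # min max-mean-shift, 8-bit gray levels
    s2: float = 10.0              # min max successive drop, 8-bit gray levels
    min_component_px: int = 2000  # 4-connected component filter
    suppress_transients: bool = False  # reset pixels that brighten back up

    def equivalent_length_mm(self, px_size_um: float) -> float:
        """Physical length of a 1-px-wide curve holding ``min_component_px``."""
        return self.min_component_px * px_size_um / 1000.0


@dataclass
class TrackConfig:
    max_connection_cost: float = 0.6   # admissibility bound for splices
    feature_weights: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)  # f1 virtual
    # edge weight, f2 direction angle, f3 speeds, f4 topological score,
    # f5 gross jump misalignment (dead zone below 60 degrees)
    weight_cap: float = 4.0            # f1 rescaling: p(e) in [-1, cap] -> [0, 1]
    topo_norm: float = 6.0             # f4 normalisation (hops + temporal gap)
    search_hops: int = 8               # max RAG hops explored for f4
    min_support_px: float = 6.0        # trajectory support below which a
    # feature is replaced by its majoring value (1)
    speed_window: int = 3              # timesteps used for speed estimates
    max_gap_px: float = 60.0           # centroid distance cutoff for splices
    suspicious_gap_primary: int = 3    # a lateral chain head hanging from a
    # primary vertex across >= this many timesteps is a reconnection
    # candidate (genuine emergences have smaller delays)
    suspicious_gap_lateral: int = 1    # same for heads hanging from a
    # lateral vertex (continuations are gap-free; a gap hints at an
    # artefact or crossing interrupting the chain)
    made_factor: float = 25.0          # outlier bound = median +/- factor*MADe
    made_epsilon: float = 1e-6         # MADe floor against zero spread
    min_population: int = 5            # below this many laterals, skip rejection


@dataclass
class GeometryConfig:
    dp_tol_px: float = 1.5             # Douglas-Peucker tolerance
    seed_row: int | None = None        # target row for upstream extrapolation
    min_growth_timesteps: int = 3      # isolated early-stopping roots shorter
    # than this many observation intervals are rejected
    include_extrapolated: bool = False  # count extrapolated segments in lengths


@dataclass
class PipelineConfig:
    n_plants: int = 5
    px_size_um: float = 19.0
    timestep_h: float = 8.0
    register: bool = True
    seed: int = 0
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    track: TrackConfig = field(default_factory=TrackConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        data = {**data.get("defaults", {}), **{k: v for k, v in data.items()
                                               if k != "defaults"}}
        sub = {
            "registration": RegistrationConfig,
            "segmentation": SegmentationConfig,
            "track": TrackConfig,
            "geometry": GeometryConfig,
        }
        kwargs = {}
        for key, val in data.items():
            if key in sub:
                kwargs[key] = sub[key](**{k: tuple(v) if isinstance(v, list) else v
                                          for k, v in val.items()})
            else:
                kwargs[key] = val
        return cls(**kwargs)
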