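"""End-to-end orchestration: registration -> segmentation -> tracking ->
reconstruction -> RSML + phene tables, with per-stage logging.

Fully deterministic given the configuration and inputs: rerunning the same
plate produces byte-identical RSML.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry, phenes, register, rsml_io, segment, track
from .config import PipelineConfig
from .core import ImageTimeSeries
from .model import RootSystemModel

logger = logging.getLogger("rhizotrack")

__all__ = ["PipelineResult", "run_pipeline", "load_series"]


@dataclass
class PipelineResult:
    model: RootSystemModel
    S: segment.ApparitionLabelImage
    forest: track.OrganForest
    registered: ImageTimeSeries
    log: list[dict] = field(default_factory=list)
    rsml_path: Path | None = None
    phene_path: Path | None = None


def load_series(input_dir: str | Path, pattern: str = "*.tif",
                cfg: PipelineConfig | None = None) -> ImageTimeSeries:
    """Load a TIFF series; a JSON manifest beside the frames overrides the
    configured pixel size and timestep, and the component filter is
    rescaled through its physical-length equivalence so thresholds keep
    their meaning at any sampling."""
    cfg = cfg or PipelineConfig()
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob(pattern))
    if len(paths) < 2:
        raise ValueError(
            f"needs >=2 observations, found {len(paths)} in {input_dir}")
    manifests = sorted(input_dir.glob("*manifest.json"))
    if manifests:
        meta = json.loads(manifests[0].read_text())
        px = float(meta.get("px_size_um", cfg.px_size_um))
        if px != cfg.px_size_um:
            equiv_mm = cfg.segmentation.equivalent_length_mm(cfg.px_size_um)
            cfg.segmentation.min_component_px = int(
                round(equiv_mm / (px / 1000.0)))
            cfg.px_size_um = px
        cfg.timestep_h = float(meta.get("timestep_h", cfg.timestep_h))
    return ImageTimeSeries.read_tiffs(paths, cfg.timestep_h, cfg.px_size_um)


def run_pipeline(stack: ImageTimeSeries,
                 cfg: PipelineConfig | None = None,
                 out_dir: str | Path | None = None,
                 plate_id: str = "0") -> PipelineResult:
    """Run every stage on a loaded series; optionally persist artifacts."""
    cfg = cfg or PipelineConfig()
    if stack.n_t < 2:
        raise ValueError("needs >=2 observations")
    log: list[dict] = []

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        rec = {"stage": name, "seconds": round(time.perf_counter() - t0, 3)}
        log.append(rec)
        return out, rec

    if cfg.register:
        registered, _ = stage(
            "register", lambda: register.register_series(stack,
                                                         cfg.registration))
    else:
        registered = stack
        log.append({"stage": "register", "skipped": True})

    S, rec = stage("segment",
                   lambda: segment.segment(registered, cfg.segmentation))
    rec["root_px"] = int((S.labels > 0).sum())
    rec["equivalent_length_mm"] = cfg.segmentation.equivalent_length_mm(
        cfg.px_size_um)

    def _track():
        rag = track.build_rag(S)
        track.extract_primaries(rag, cfg.n_plants)
        forest = track.prune_to_forest(rag)
        n_starts0 = len(forest.v_start())
        track.resolve_crossings(forest, cfg.track)
        n_starts1 = len(forest.v_start())
        n_before = len([c for c in forest.extract_chains() if c.order == 2])
        track.reject_artefact_roots(forest, cfg.track)
        n_after = len([c for c in forest.extract_chains() if c.order == 2])
        return forest, {"vertices": rag.number_of_vertices(),
                        "edges": rag.graph.number_of_edges(),
                        "starts_before": n_starts0,
                        "starts_after": n_starts1,
                        "laterals_rejected": n_before - n_after}

    (forest, counts), rec = stage("track", _track)
    rec.update(counts)

    def _geometry():
        model = geometry.build_model(forest, S, cfg.geometry)
        if cfg.geometry.seed_row is not None:
            geometry.extrapolate_to_seed(model, registered.frames[-1],
                                         cfg.geometry.seed_row, cfg.geometry)
        geometry.handle_stopped_laterals(model, forest, cfg.geometry)
        return model

    model, rec = stage("reconstruct", _geometry)
    rec["organs"] = sum(1 for _ in model.all_organs())

    result = PipelineResult(model, S, forest, registered, log)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.rsml_path = rsml_io.write_rsml(
            model, out_dir / f"plate_{plate_id}.rsml")
        table = phenes.phene_table([model], [plate_id])
        result.phene_path = out_dir / f"plate_{plate_id}_phenes.csv"
        table.to_csv(result.phene_path, index=False)
        S.write(out_dir / f"plate_{plate_id}_labels.tif")
        (out_dir / f"plate_{plate_id}_log.json").write_text(
            json.dumps({"config": cfg.resolved(), "stages": log}, indent=2,
                       default=str))
    return result
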