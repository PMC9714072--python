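"""Static and dynamic phene extraction from root system models.

Lengths are obtained by summing centerline segments whose apparition time
(the time of the later node) does not exceed the query time, converted to mm
through the configured pixel size; growth between observations is the
difference of such lengths, hence non-negative and telescoping.  Population
analyses follow the study design: per-timestep two-group comparisons with
the Mann-Whitney U test and the lateral elongation-rate heatmap as a
function of insertion depth on the primary root.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model import Organ, RootSystemModel

__all__ = [
    "root_length_at", "growth_between", "count_laterals", "insertion_depth",
    "phene_table", "elongation_heatmap", "per_timestep_group_test",
    "mann_whitney_u",
]


def _resolve(model: RootSystemModel, organ) -> Organ:
    if isinstance(organ, Organ):
        return organ
    try:
        ip, io = organ
        return model.plants[ip].organs[io]
    except (TypeError, IndexError) as exc:
        raise KeyError(f"unknown organ {organ!r}") from exc


def root_length_at(model: RootSystemModel, organ, t: float,
                   include_extrapolated: bool = False) -> float:
    """Organ centerline length in mm at observation time ``t``.

    Sums the segments whose apparition time (time of their later node) is
    <= t.  Extrapolated segments are excluded unless requested.
    """
    o = _resolve(model, organ)
    return o.length_px(t, include_extrapolated) * model.px_mm


def growth_between(model: RootSystemModel, organ, t1: float, t2: float,
                   include_extrapolated: bool = False) -> float:
    """Additional length (mm) gained between observations t1 < t2."""
    if t1 > t2:
        raise ValueError("t1 must not exceed t2")
    return (root_length_at(model, organ, t2, include_extrapolated)
            - root_length_at(model, organ, t1, include_extrapolated))


def count_laterals(model: RootSystemModel, t: float) -> int:
    """Number of second-order organs that have emerged by time ``t``."""
    return sum(1 for _ip, _io, o in model.all_organs()
               if o.order == 2 and o.t_first <= t + 1e-9)


def insertion_depth(model: RootSystemModel, organ,
                    seed_y: float | None = None) -> float:
    """Depth (mm) of a lateral's insertion below the plate's seed line."""
    o = _resolve(model, organ)
    if o.order != 2:
        raise ValueError("insertion depth is defined for laterals")
    if seed_y is None:
        ip = next(ip for ip, _io, oo in model.all_organs() if oo is o)
        seed_y = model.plants[ip].seed_xy[1]
    return (o.points[0, 1] - seed_y) * model.px_mm


def phene_table(models, plate_ids=None,
                include_extrapolated: bool = False) -> pd.DataFrame:
    """One row per organ x observation time, lengths and growth in mm."""
    if isinstance(models, RootSystemModel):
        models = [models]
    plate_ids = plate_ids or list(range(len(models)))
    rows = []
    for plate, model in zip(plate_ids, models):
        times = np.arange(1, model.n_timesteps + 1)
        for ip, io, organ in model.all_organs():
            seed_y = model.plants[ip].seed_xy[1]
            prev = 0.0
            for t in times:
                length = root_length_at(model, (ip, io), t,
                                        include_extrapolated)
                rows.append({
                    "plate": plate, "plant": ip, "organ": io,
                    "order": organ.order, "time": int(t),
                    "length_mm": length, "growth_mm": length - prev,
                    "tip_depth_mm": (organ.position_at(t)[1] - seed_y)
                    * model.px_mm,
                    "insertion_depth_mm": insertion_depth(model, (ip, io),
                                                          seed_y)
                    if organ.order == 2 else np.nan,
                })
                prev = length
    return pd.DataFrame(rows)


def elongation_heatmap(models, depth_bins_mm, times=None):
    """Mean lateral elongation rate (mm/interval) per insertion-depth bin.

    Returns ``(matrix, counts, tip_depth_mean, tip_depth_sd)``: the matrix is
    (n_bins x n_times) with NaN marking empty cells (no lateral in the bin —
    distinct from an observed zero rate); counts give the populated sample
    sizes; the last two arrays summarise primary tip depth per time.
    """
    if isinstance(models, RootSystemModel):
        models = [models]
    model0 = models[0]
    if times is None:
        times = np.arange(2, model0.n_timesteps + 1)
    times = np.asarray(times)
    bins = np.asarray(depth_bins_mm, dtype=float)
    n_bins = len(bins) - 1
    total = np.zeros((n_bins, len(times)))
    counts = np.zeros((n_bins, len(times)), dtype=int)
    tip_depths = [[] for _ in times]
    for model in models:
        for ip, io, organ in model.all_organs():
            seed_y = model.plants[ip].seed_xy[1]
            if organ.order == 1:
                for j, t in enumerate(times):
                    if organ.t_first <= t:
                        tip_depths[j].append(
                            (organ.position_at(t)[1] - seed_y) * model.px_mm)
                continue
            depth = insertion_depth(model, (ip, io), seed_y)
            b = int(np.searchsorted(bins, depth, side="right")) - 1
            if b < 0 or b >= n_bins:
                continue
            for j, t in enumerate(times):
                if organ.t_first > t:
                    continue
                g = growth_between(model, (ip, io), t - 1, t)
                total[b, j] += g
                counts[b, j] += 1
    matrix = np.full_like(total, np.nan)
    nz = counts > 0
    matrix[nz] = total[nz] / counts[nz]
    tip_mean = np.array([np.mean(d) if d else np.nan for d in tip_depths])
    tip_sd = np.array([np.std(d) if d else np.nan for d in tip_depths])
    return matrix, counts, tip_mean, tip_sd


def mann_whitney_u(a, b) -> float:
    """Two-sided Mann-Whitney U statistic (pairs where a beats b + half ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def per_timestep_group_test(group_a, group_b) -> np.ndarray:
    """Two-sided Mann-Whitney p-value per timestep.

    ``group_a``/``group_b`` are (n_samples, n_times) arrays of per-interval
    growth.  Uses the exact null for small tie-free samples, the
    tie-corrected normal approximation otherwise; timesteps with fewer than
    3 samples in either group yield NaN.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    n_times = a.shape[1]
    out = np.full(n_times, np.nan)
    for j in range(n_times):
        xa = a[:, j][~np.isnan(a[:, j])]
        xb = b[:, j][~np.isnan(b[:, j])]
        if len(xa) < 3 or len(xb) < 3:
            continue
        has_ties = len(np.unique(np.concatenate([xa, xb]))) < len(xa) + len(xb)
        if not has_ties and max(len(xa), len(xb)) <= 20:
            method = "exact"
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                 method=method, use_continuity=False)
        out[j] = res.pvalue
    return out
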