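"""Time-lapse rendering of the reconstructed growing root system.

The reconstructed architecture is rasterized back into pixel space: every
pixel of the segmented root system receives the apparition time of the
nearest centerline pixel (itself interpolated along the model's nodes).
Thresholding this time function yields a nested family of masks used to
composite intermediate frames between the observed keyframes — the grown
part is sampled from the next keyframe, the background from the previous
one — with a linear crossfade near each keyframe, and root tips overlaid as
markers colored by elongation rate.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import binary_dilation, disk as disk_se

from .core import ImageTimeSeries
from .model import RootSystemModel
from .segment import ApparitionLabelImage

__all__ = ["apparition_time_map", "render_timelapse", "timelapse_times"]


def apparition_time_map(model: RootSystemModel, shape: tuple[int, int],
                        S: ApparitionLabelImage | None = None,
                        include_extrapolated: bool = True) -> np.ndarray:
    """Per-pixel apparition time of the segmented RSA (inf = not root).

    Centerline pixels take their interpolated node time; every other pixel
    of the segmentation mask takes the time of the nearest centerline pixel.
    """
    times = np.full(shape, np.inf, dtype=np.float64)
    for _ip, _io, organ in model.all_organs():
        pts = organ.points
        for k in range(len(pts) - 1):
            if not include_extrapolated and (organ.extrapolated[k]
                                             or organ.extrapolated[k + 1]):
                continue
            r0, c0 = int(round(pts[k, 1])), int(round(pts[k, 0]))
            r1, c1 = int(round(pts[k + 1, 1])), int(round(pts[k + 1, 0]))
            rr, cc = draw_line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            rr, cc = rr[ok], cc[ok]
            if len(rr) == 0:
                continue
            frac = np.linspace(0.0, 1.0, len(rr))
            tvals = pts[k, 2] + frac * (pts[k + 1, 2] - pts[k, 2])
            times[rr, cc] = np.minimum(times[rr, cc], tvals)
    centerline = np.isfinite(times)
    if not centerline.any():
        return times
    if S is not None:
        segmask = S.labels > 0
    else:
        segmask = binary_dilation(centerline, disk_se(2))
    _dist, (ir, ic) = ndimage.distance_transform_edt(
        ~centerline, return_indices=True)
    out = np.full(shape, np.inf)
    out[segmask] = times[ir[segmask], ic[segmask]]
    return out


def timelapse_times(n_t: int, timestep_h: float,
                    step_minutes: float = 15.0) -> np.ndarray:
    """Continuous observation times of the rendered frames."""
    total_min = (n_t - 1) * timestep_h * 60.0
    n_frames = int(round(total_min / step_minutes)) + 1
    return 1.0 + np.arange(n_frames) * step_minutes / (timestep_h * 60.0)


def _composite(frames: np.ndarray, tmap: np.ndarray, t: float) -> np.ndarray:
    """mask(t) . frame(i+1) + complement . frame(i) for t in [i, i+1]."""
    n_t = frames.shape[0]
    i = int(np.clip(np.floor(t - 1e-9), 1, n_t - 1))
    mask = tmap <= t
    lo = frames[i - 1]
    hi = frames[min(i, n_t - 1)]
    return np.where(mask, hi, lo)


def render_timelapse(model: RootSystemModel, stack: ImageTimeSeries,
                     step_minutes: float = 15.0,
                     fade_minutes: float = 30.0,
                     S: ApparitionLabelImage | None = None,
                     with_tips: bool = True,
                     out_dir: str | Path | None = None,
                     cmap: str = "viridis") -> list[np.ndarray]:
    """Render interpolated growth frames; returns RGB uint8 arrays.

    With the study defaults (21 keyframes every 8 h, one frame per 15 min)
    this produces 641 frames.  When ``out_dir`` is given the frames are also
    written as numbered PNGs.
    """
    if stack.n_t != model.n_timesteps:
        raise ValueError("model and stack disagree on observation count")
    tmap = apparition_time_map(model, stack.shape, S)
    ts = timelapse_times(stack.n_t, stack.timestep_h, step_minutes)
    fade_obs = fade_minutes / (stack.timestep_h * 60.0)
    frames_out = []
    colormap = colormaps[cmap]
    rates = _tip_rates(model)
    vmax = max(rates.max(initial=0.0), 1e-9)
    for t in ts:
        base = _composite(stack.frames, tmap, t)
        near = round(t) if abs(t - round(t)) * stack.timestep_h * 60.0 \
            <= fade_minutes else None
        if near is not None and 1 < near < stack.n_t and fade_obs > 0:
            # linear crossfade with the next keyframe pair
            w = 0.5 * (1.0 - abs(t - near) / fade_obs)
            other = _composite(stack.frames, tmap, t + (1 if t >= near else -1))
            base = (1 - w) * base + w * other
        rgb = np.repeat(np.clip(base, 0, 255).astype(np.uint8)[..., None],
                        3, axis=2)
        if with_tips:
            for _ip, _io, organ in model.all_organs():
                if organ.t_first > t:
                    continue
                xy = organ.position_at(t)
                rate = _organ_rate(model, organ, t)
                color = (np.array(colormap(rate / vmax)[:3]) * 255).astype(
                    np.uint8)
                rr, cc = draw_disk((xy[1], xy[0]), 3, shape=stack.shape)
                rgb[rr, cc] = color
        frames_out.append(rgb)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames_out):
            iio.imwrite(out_dir / f"frame_{i:05d}.png", frame)
    return frames_out


def _organ_rate(model: RootSystemModel, organ, t: float) -> float:
    t0 = max(organ.t_first, t - 1.0)
    return organ.length_px(t) - organ.length_px(t0)


def _tip_rates(model: RootSystemModel) -> np.ndarray:
    rates = []
    for _ip, _io, organ in model.all_organs():
        for t in range(2, model.n_timesteps + 1):
            rates.append(_organ_rate(model, organ, float(t)))
    return np.asarray(rates) if rates else np.zeros(1)
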