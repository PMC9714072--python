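"""Temporal segmentation: per-pixel apparition times.

A registered stack is reduced to a single 2D label image ``S``: ``S(p) = 0``
for background and ``S(p) = t`` when a root first covers pixel ``p`` at
observation ``t``.  Root detection is per-pixel change-point detection on
the intensity time series: the series of a traversed pixel starts at
background level, drops sharply when the root arrives and stays low.  Two
thresholds control the detector (in 8-bit gray levels): ``s1`` on the
maximum mean shift between the head and tail of the series, and ``s2`` on
the maximum successive drop; the label is the observation following the
maximal drop.  Small 4-connected components (condensation, dirt) are then
removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from skimage.measure import label as cc_label

from .config import SegmentationConfig
from .core import ImageTimeSeries

__all__ = ["ApparitionLabelImage", "pixel_apparition_time", "segment_stack",
           "filter_components", "segment"]


@dataclass
class ApparitionLabelImage:
    """2D integer image of first-coverage observation indices."""

    labels: np.ndarray           # int16, 0 = background, 1..n_t = apparition
    n_t: int
    px_size_um: float
    timestep_h: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask_at(self, t: int) -> np.ndarray:
        """Binary root mask M_t = {p : 0 < S(p) <= t}; nested in t."""
        return (self.labels > 0) & (self.labels <= t)

    def write(self, path) -> None:
        tifffile.imwrite(path, self.labels.astype(np.uint16))


def _rescale_8bit(frames: np.ndarray) -> np.ndarray:
    """Thresholds are calibrated on 8-bit gray levels; map 16-bit inputs."""
    if frames.dtype == np.uint16:
        return frames.astype(np.float32) / 257.0
    return frames.astype(np.float32)


def pixel_apparition_time(series, s1: float = 25.0, s2: float = 10.0) -> int:
    """Apparition label of a single pixel's intensity time series.

    Returns 0 (background) unless the maximum mean shift
    ``mean(series[:k]) - mean(series[k:])`` reaches ``s1`` and the maximum
    successive drop reaches ``s2``; otherwise returns the index (1-based)
    of the observation following the maximal drop.  Ties on the maximal
    drop resolve to the earliest index.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have at least 2 observations")
    n = x.size
    prefix = np.cumsum(x)
    k = np.arange(1, n)
    shift = prefix[:-1] / k - (prefix[-1] - prefix[:-1]) / (n - k)
    if shift.max() < s1:
        return 0
    drops = x[:-1] - x[1:]
    if drops.max() < s2:
        return 0
    return int(np.argmax(drops)) + 2


def segment_stack(stack: ImageTimeSeries,
                  s1: float = 25.0, s2: float = 10.0,
                  exclusion_mask: np.ndarray | None = None,
                  suppress_transients: bool = False,
                  initial_background: bool = True) -> ApparitionLabelImage:
    """Apply the change-point detector independently to every pixel.

    The first observation has no earlier reference, so structures already
    present in it (seeds, pre-germinated roots) would show no intensity
    drop; with ``initial_background`` a virtual background observation (the
    median intensity of the first frame) is prepended so such pixels are
    labeled 1.  ``exclusion_mask`` marks pixels (e.g. fallen leaves, plate
    frame) to force to background.  With ``suppress_transients``, pixels
    whose intensity recovers above background after the detected drop —
    large moving artefacts rather than roots, which only darken — are reset
    to 0.
    """
    if stack.transforms is None:
        warnings.warn("stack carries no registration transforms; assuming "
                      "frames are already aligned", stacklevel=2)
    x = _rescale_8bit(stack.frames)
    n_obs = x.shape[0]
    if n_obs < 2:
        raise ValueError("segmentation needs at least 2 observations")
    if initial_background:
        bg = np.float32(np.median(x[0]))
        x = np.concatenate([np.full((1,) + x.shape[1:], bg,
                                    dtype=np.float32), x])
    n = x.shape[0]
    prefix = np.cumsum(x, axis=0)
    k = np.arange(1, n, dtype=np.float32).reshape(-1, 1, 1)
    shift = prefix[:-1] / k - (prefix[-1] - prefix[:-1]) / (n - k)
    max_shift = shift.max(axis=0)
    drops = x[:-1] - x[1:]
    max_drop = drops.max(axis=0)
    arg_drop = drops.argmax(axis=0)           # first maximum wins
    labels = (arg_drop + 2).astype(np.int16)
    labels[(max_shift < s1) | (max_drop < s2)] = 0
    if suppress_transients:
        # roots only darken pixels: if the intensity later rises back near
        # its pre-apparition mean, the drop was a moving artefact
        idx = np.clip(labels.astype(np.int64), 1, n) - 1
        later_max = np.maximum.accumulate(x[::-1], axis=0)[::-1]
        gi, gj = np.indices(idx.shape)
        post = later_max[idx, gi, gj]
        pre = prefix[np.maximum(idx - 1, 0), gi, gj] / np.maximum(idx, 1)
        labels[(labels > 0) & (post > pre - s2)] = 0
    if initial_background:
        labels[labels > 0] -= 1  # virtual observation shifted indices by one
    if exclusion_mask is not None:
        labels[exclusion_mask.astype(bool)] = 0
    return ApparitionLabelImage(labels, n_obs, stack.px_size_um,
                                stack.timestep_h, meta={"s1": s1, "s2": s2})


def filter_components(S: ApparitionLabelImage,
                      min_component_px: int = 2000) -> ApparitionLabelImage:
    """Remove 4-connected nonzero components smaller than the threshold.

    Idempotent; labels of surviving components are untouched.
    """
    mask = S.labels > 0
    comps = cc_label(mask, connectivity=1)
    if comps.max() == 0:
        return ApparitionLabelImage(S.labels.copy(), S.n_t, S.px_size_um,
                                    S.timestep_h, dict(S.meta))
    sizes = np.bincount(comps.ravel())
    small = sizes < min_component_px
    small[0] = False
    labels = S.labels.copy()
    labels[small[comps]] = 0
    meta = dict(S.meta)
    meta["min_component_px"] = min_component_px
    meta["equivalent_length_mm"] = min_component_px * S.px_size_um / 1000.0
    return ApparitionLabelImage(labels, S.n_t, S.px_size_um, S.timestep_h,
                                meta)


def segment(stack: ImageTimeSeries,
            cfg: SegmentationConfig | None = None,
            exclusion_mask: np.ndarray | None = None) -> ApparitionLabelImage:
    """Full segmentation stage: change-point detection + component filter."""
    cfg = cfg or SegmentationConfig()
    S = segment_stack(stack, cfg.s1, cfg.s2, exclusion_mask,
                      cfg.suppress_transients)
    return filter_components(S, cfg.min_component_px)
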