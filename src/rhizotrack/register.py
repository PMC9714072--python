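"""Time-series registration by block matching.

All frames are aligned onto the geometry of the last frame, which contains
every structure present in the earlier ones.  Each pair of consecutive
frames is registered (moving = earlier frame, fixed = next frame) with a
rigid transform estimated from local block correspondences — normalized
cross-correlation peaks with parabolic sub-pixel refinement, fit by
least squares with iterative outlier trimming — optionally followed by a
smoothed dense displacement field for residual deformations of the medium.
The pairwise transforms are then composed along the chain and applied to
each frame in a single resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .config import RegistrationConfig
from .core import ImageTimeSeries, RigidTransform

__all__ = [
    "RegistrationError", "DenseField", "ComposedTransform",
    "estimate_rigid_blockmatching", "estimate_dense_field",
    "compose_daisychain", "resample", "register_series",
]


class RegistrationError(RuntimeError):
    """Estimation failed (too few valid correspondences)."""


@dataclass
class DenseField:
    """Per-pixel displacement field sampled on a regular grid.

    ``du``/``dv`` hold (dx, dy) displacements in px at grid nodes spaced
    ``spacing`` px apart; values between nodes are bilinearly interpolated.
    """

    du: np.ndarray
    dv: np.ndarray
    spacing: float
    shape: tuple[int, int]

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Displacement (dx, dy) at ``(n, 2)`` points in (x, y)."""
        pts = np.atleast_2d(points)
        gy = pts[:, 1] / self.spacing
        gx = pts[:, 0] / self.spacing
        dx = ndimage.map_coordinates(self.du, [gy, gx], order=1,
                                     mode="nearest")
        dy = ndimage.map_coordinates(self.dv, [gy, gx], order=1,
                                     mode="nearest")
        return np.column_stack([dx, dy])

    def max_magnitude(self) -> float:
        return float(np.hypot(self.du, self.dv).max()) if self.du.size else 0.0

    @classmethod
    def zero(cls, shape: tuple[int, int], spacing: float = 16.0) -> "DenseField":
        g = (int(shape[0] // spacing) + 2, int(shape[1] // spacing) + 2)
        return cls(np.zeros(g), np.zeros(g), spacing, shape)


# ---------------------------------------------------------------------------
# block correspondences
# ---------------------------------------------------------------------------

def _block_grid(shape, cfg: RegistrationConfig):
    bh, stride = cfg.block_half, cfg.stride
    pad = bh + cfg.search_radius + 2
    rows = np.arange(pad, shape[0] - pad, stride)
    cols = np.arange(pad, shape[1] - pad, stride)
    return [(r, c) for r in rows for c in cols]


def _find_correspondences(moving, fixed, cfg: RegistrationConfig,
                          search_radius: int):
    """NCC peak per high-variance block; returns (src, dst) point arrays."""
    bh = cfg.block_half
    centers = _block_grid(moving.shape, cfg)
    if not centers:
        return np.empty((0, 2)), np.empty((0, 2))
    variances = np.array([
        moving[r - bh:r + bh + 1, c - bh:c + bh + 1].var()
        for r, c in centers])
    thresh = max(np.percentile(variances, cfg.variance_percentile),
                 cfg.min_variance)
    src, dst = [], []
    for (r, c), var in zip(centers, variances):
        if var < thresh:
            continue
        block = moving[r - bh:r + bh + 1, c - bh:c + bh + 1]
        r0, r1 = r - bh - search_radius, r + bh + search_radius + 1
        c0, c1 = c - bh - search_radius, c + bh + search_radius + 1
        window = fixed[max(r0, 0):r1, max(c0, 0):c1]
        if window.shape[0] < block.shape[0] + 2 or \
           window.shape[1] < block.shape[1] + 2:
            continue
        ncc = match_template(window, block)
        peak = np.unravel_index(np.argmax(ncc), ncc.shape)
        if ncc[peak] < 0.3:
            continue
        pr, pc = _subpixel_peak(ncc, peak)
        dst_r = max(r0, 0) + pr + bh
        dst_c = max(c0, 0) + pc + bh
        src.append((c, r))      # (x, y)
        dst.append((dst_c, dst_r))
    return np.asarray(src, dtype=float), np.asarray(dst, dtype=float)


def _subpixel_peak(ncc, peak):
    """1D parabola fit through the peak along each axis."""
    pr, pc = peak
    out = [float(pr), float(pc)]
    for axis, p in enumerate(peak):
        if 0 < p < ncc.shape[axis] - 1:
            idx = list(peak)
            idx[axis] = p - 1
            ym = ncc[tuple(idx)]
            idx[axis] = p + 1
            yp = ncc[tuple(idx)]
            y0 = ncc[peak]
            denom = ym - 2 * y0 + yp
            if abs(denom) > 1e-12:
                out[axis] = p + 0.5 * (ym - yp) / denom
    return out[0], out[1]


def _fit_rigid(src, dst, center, trim_factor, min_pts):
    """Least-squares rigid fit (Kabsch in 2D) with iterative trimming."""
    keep = np.ones(len(src), dtype=bool)
    transform = RigidTransform(0, 0, 0, center)
    for _ in range(4):
        s, d = src[keep], dst[keep]
        if len(s) < min_pts:
            raise RegistrationError(
                f"only {len(s)} valid correspondences (need {min_pts})")
        sc, dc = s.mean(axis=0), d.mean(axis=0)
        h = (s - sc).T @ (d - dc)
        theta = math.atan2(h[0, 1] - h[1, 0], h[0, 0] + h[1, 1])
        ct, st = math.cos(theta), math.sin(theta)
        rot = np.array([[ct, -st], [st, ct]])
        c = np.asarray(center)
        t = dc - (rot @ (sc - c)) - c
        transform = RigidTransform(theta, t[0], t[1], center)
        residuals = np.linalg.norm(transform.apply(src) - dst, axis=1)
        med = max(np.median(residuals[keep]), 0.1)
        new_keep = residuals <= trim_factor * med
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    rms = float(np.sqrt(np.mean(
        np.linalg.norm(transform.apply(src[keep]) - dst[keep], axis=1) ** 2)))
    report = {"n_used": int(keep.sum()), "n_total": len(src), "rms_px": rms}
    return transform, report


def estimate_rigid_blockmatching(moving: np.ndarray, fixed: np.ndarray,
                                 cfg: RegistrationConfig | None = None
                                 ) -> tuple[RigidTransform, dict]:
    """Rigid transform mapping ``moving`` onto ``fixed``.

    Iterates estimate / warp / re-estimate with a shrinking search radius so
    large motions converge to sub-pixel accuracy.  Raises
    :class:`RegistrationError` when fewer than ``cfg.min_correspondences``
    blocks match — a failure distinct from finding the identity.
    """
    cfg = cfg or RegistrationConfig()
    if moving.shape != fixed.shape:
        raise ValueError("images must share a shape")
    moving = np.asarray(moving, dtype=np.float32)
    fixed = np.asarray(fixed, dtype=np.float32)
    center = ((moving.shape[1] - 1) / 2.0, (moving.shape[0] - 1) / 2.0)
    total = RigidTransform(0.0, 0.0, 0.0, center)
    report: dict = {}
    radius = cfg.search_radius
    warped = moving
    for it in range(cfg.n_iterations):
        src, dst = _find_correspondences(warped, fixed, cfg, radius)
        if len(src) < cfg.min_correspondences:
            if it == 0:
                raise RegistrationError(
                    f"only {len(src)} valid correspondences "
                    f"(need {cfg.min_correspondences})")
            break
        delta, report = _fit_rigid(src, dst, center, cfg.trim_factor,
                                   cfg.min_correspondences)
        total = delta.compose(total)
        warped = resample(moving, total, fill=float(np.median(moving)))
        radius = max(6, radius // 3)
    return total, report


def estimate_dense_field(moving: np.ndarray, fixed: np.ndarray,
                         cfg: RegistrationConfig | None = None) -> DenseField:
    """Residual displacement field after rigid alignment.

    Scattered block displacements are spread onto a coarse grid by
    Gaussian-weighted normalized convolution; where no confident block
    supports the estimate the field is zero.  Degenerate inputs (uniform
    images) yield a zero field rather than an error.
    """
    import dataclasses

    cfg = cfg or RegistrationConfig()
    cfg = dataclasses.replace(cfg, block_half=cfg.dense_block_half,
                              stride=cfg.dense_stride)
    moving = np.asarray(moving, dtype=np.float32)
    fixed = np.asarray(fixed, dtype=np.float32)
    spacing = float(cfg.stride)
    field = DenseField.zero(moving.shape, spacing)
    try:
        src, dst = _find_correspondences(moving, fixed, cfg,
                                         cfg.dense_search_radius)
    except ValueError:
        return field
    if len(src) == 0:
        return field
    disp = dst - src
    mag = np.linalg.norm(disp, axis=1)
    ok = mag <= cfg.dense_cap_px
    src, disp = src[ok], disp[ok]
    if len(src) == 0:
        return field
    gshape = field.du.shape
    num_u = np.zeros(gshape)
    num_v = np.zeros(gshape)
    den = np.zeros(gshape)
    gi = np.clip(np.round(src[:, 1] / spacing).astype(int), 0, gshape[0] - 1)
    gj = np.clip(np.round(src[:, 0] / spacing).astype(int), 0, gshape[1] - 1)
    np.add.at(num_u, (gi, gj), disp[:, 0])
    np.add.at(num_v, (gi, gj), disp[:, 1])
    np.add.at(den, (gi, gj), 1.0)
    sigma = cfg.dense_sigma_px / spacing
    num_u = ndimage.gaussian_filter(num_u, sigma)
    num_v = ndimage.gaussian_filter(num_v, sigma)
    den = ndimage.gaussian_filter(den, sigma)
    support = den > 1e-3
    field.du[support] = num_u[support] / den[support]
    field.dv[support] = num_v[support] / den[support]
    np.clip(field.du, -cfg.dense_cap_px, cfg.dense_cap_px, out=field.du)
    np.clip(field.dv, -cfg.dense_cap_px, cfg.dense_cap_px, out=field.dv)
    return field


# ---------------------------------------------------------------------------
# composition and resampling
# ---------------------------------------------------------------------------

@dataclass
class ComposedTransform:
    """An ordered chain of (rigid, optional dense) steps, applied left first.

    Maps coordinates of an early frame onto the reference (last) frame.  The
    chain is evaluated functionally so each frame is resampled exactly once.
    """

    steps: list  # list of (RigidTransform, DenseField | None)

    def map_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        for rigid, dense in self.steps:
            pts = rigid.apply(pts)
            if dense is not None:
                pts = pts + dense.sample(pts)
        return pts

    def inverse_map_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        for rigid, dense in reversed(self.steps):
            if dense is not None:
                # small smooth field: fixed-point inversion
                q = pts.copy()
                for _ in range(3):
                    q = pts - dense.sample(q)
                pts = q
            pts = rigid.inverse().apply(pts)
        return pts

    def net_rigid(self) -> RigidTransform:
        """Composition of the rigid parts only (exact if no dense steps)."""
        total = None
        for rigid, _ in self.steps:
            total = rigid if total is None else rigid.compose(total)
        return total if total is not None else RigidTransform()


def compose_daisychain(pairwise, n_t: int | None = None
                       ) -> list[ComposedTransform]:
    """Compose pairwise frame->next transforms onto the last frame.

    ``pairwise[i]`` maps frame i onto frame i+1 (i = 0..n_t-2); entry t of
    the result maps frame t onto frame n_t-1.  Accepts plain
    :class:`RigidTransform` items or (rigid, dense) tuples.
    """
    if n_t is not None and len(pairwise) != n_t - 1:
        raise ValueError(
            f"expected {n_t - 1} pairwise transforms, got {len(pairwise)}")
    norm = []
    for item in pairwise:
        if isinstance(item, RigidTransform):
            norm.append((item, None))
        else:
            norm.append(tuple(item))
    composed = []
    for t in range(len(norm)):
        composed.append(ComposedTransform(list(norm[t:])))
    return composed


def resample(image: np.ndarray,
             transform: "RigidTransform | ComposedTransform",
             fill: float | None = None, order: int = 1) -> np.ndarray:
    """Warp ``image`` into the reference geometry in one interpolation.

    ``output(x) = image(T^-1(x))`` with bilinear interpolation; out-of-field
    pixels are set to ``fill`` (default: the median of the frame, a robust
    background estimate).
    """
    image = np.asarray(image, dtype=np.float32)
    if fill is None:
        fill = float(np.median(image))
    rows, cols = image.shape
    if isinstance(transform, RigidTransform) and transform.is_identity():
        return image.copy()
    yy, xx = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    if isinstance(transform, RigidTransform):
        srcs = transform.inverse().apply(pts)
    else:
        srcs = transform.inverse_map_points(pts)
    out = ndimage.map_coordinates(
        image, [srcs[:, 1].reshape(rows, cols), srcs[:, 0].reshape(rows, cols)],
        order=order, mode="constant", cval=fill)
    return out.astype(np.float32)


def register_series(stack: ImageTimeSeries,
                    cfg: RegistrationConfig | None = None
                    ) -> ImageTimeSeries:
    """Register all frames onto the last one; returns a new series.

    The returned series carries the composed per-frame transforms (the last
    frame gets an identity) so downstream stages can audit the alignment.
    """
    cfg = cfg or RegistrationConfig()
    n_t = stack.n_t
    pairwise = []
    for t in range(n_t - 1):
        rigid, _ = estimate_rigid_blockmatching(stack.frames[t],
                                                stack.frames[t + 1], cfg)
        dense = None
        if cfg.use_dense:
            aligned = resample(stack.frames[t], rigid)
            dense = estimate_dense_field(aligned, stack.frames[t + 1], cfg)
        pairwise.append((rigid, dense))
    composed = compose_daisychain(pairwise, n_t)
    if not cfg.use_dense:
        # the daisy chain accumulates small pairwise errors; a direct
        # refinement of each composed transform against the reference frame
        # removes the accumulation
        import dataclasses
        fine = dataclasses.replace(cfg, search_radius=8, n_iterations=2)
        for t in range(n_t - 1):
            net = composed[t].net_rigid()
            warped = resample(stack.frames[t], net)
            try:
                delta, _ = estimate_rigid_blockmatching(
                    warped, stack.frames[n_t - 1], fine)
            except RegistrationError:
                continue
            composed[t] = ComposedTransform([(delta.compose(net), None)])
    frames = np.empty_like(stack.frames, dtype=np.float32)
    for t in range(n_t - 1):
        frames[t] = resample(stack.frames[t], composed[t])
    frames[n_t - 1] = stack.frames[n_t - 1]
    transforms = list(composed) + [ComposedTransform(
        [(RigidTransform.identity(stack.shape), None)])]
    return ImageTimeSeries(frames, stack.timestep_h, stack.px_size_um,
                           transforms=transforms, meta=dict(stack.meta))
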