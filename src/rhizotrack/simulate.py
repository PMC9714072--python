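"""Synthetic root-growth plates with ground truth.

Generates Arabidopsis-like seedling root systems — one primary per plant
growing predominantly downward with second-order laterals — and rasterizes
them into a grayscale time series that emulates backlit plate imaging: dark
roots on a lighter background (~100 gray levels of contrast at the
centerline), nested monotone growth, optional rigid plate jitter between
frames, sensor noise, and persistent condensation/dirt blobs.

The spatial sampling is coarser than the reference instrument (default
100 µm/px instead of 19 µm/px) so that a full plate fits in a
960 x 960 frame; physical quantities (growth rates in mm/h, 8 h timestep,
21 observations, 5 plants, contrast) are kept at study scale.  Time is
continuous inside the model; rasterization snapshots it at integer
observation indices 1..n_timesteps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .core import ImageTimeSeries, RigidTransform
from .model import Organ, Plant, RootSystemModel

__all__ = [
    "SimParams", "CrossingEvent", "GroundTruthModel", "SimulatedPlate",
    "SizingError", "simulate_architecture", "rasterize_timeseries",
    "inject_artifacts", "simulate_plate",
]


class SizingError(ValueError):
    """The image is too small to contain the requested growth."""


@dataclass(frozen=True)
class SimParams:
    n_plants: int = 5
    n_timesteps: int = 21
    timestep_h: float = 8.0
    px_size_um: float = 100.0
    image_shape: tuple[int, int] = (960, 960)
    primary_rate: tuple[float, float] = (0.42, 0.05)   # mm/h (mean, sd)
    lateral_rate: tuple[float, float] = (0.12, 0.05)   # mm/h (mean, sd)
    lateral_density: float = 0.18       # emergences per mm of primary
    lateral_delay_h: tuple[float, float] = (20.0, 6.0)  # emergence lag after
    # the primary tip passes the insertion point (mean, sd)
    tortuosity: float = 0.06            # heading noise, rad per growth substep
    crossing_bias: float = 0.4          # probability a lateral is steered to
    # cross an already-grown neighbouring organ
    background_level: float = 180.0
    root_contrast: float = 100.0        # gray drop at the centerline
    noise_sd: float = 3.0
    jitter: tuple[float, float] = (0.0, 0.0)  # max |translation| px, |rot| deg
    artifact_rate: float = 0.5          # condensation blobs per frame
    artifact_area_px: tuple[int, int] = (60, 250)  # below the component
    # filter threshold, as observed condensation/dirt is
    tube_width_px: float = 3.0          # full root width at medium intensity
    seed_radius_px: float = 4.0         # seed visible from the first frame
    seed_row_px: float = 55.0
    margin_px: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timesteps < 2:
            raise ValueError("n_timesteps must be >= 2")
        if min(self.primary_rate[0], self.lateral_rate[0],
               self.lateral_density) < 0:
            raise ValueError("rates must be >= 0")
        if self.root_contrast <= 0:
            raise ValueError("root_contrast must be > 0")

    @property
    def px_mm(self) -> float:
        return self.px_size_um / 1000.0


@dataclass(frozen=True)
class CrossingEvent:
    """A 2D intersection of two organs with a temporal offset >= 1 timestep."""
    first: tuple[int, int]    # (plant, organ) index of the earlier organ
    second: tuple[int, int]   # the organ that crosses at least 1 step later
    x: float
    y: float
    t_first: float
    t_second: float


class GroundTruthModel(RootSystemModel):
    """Simulated architecture plus the crossing-event ledger."""

    def __init__(self, plants, px_size_um, timestep_h, n_timesteps,
                 crossings=None, meta=None):
        super().__init__(plants, px_size_um, timestep_h, n_timesteps,
                         meta or {})
        self.crossings: list[CrossingEvent] = crossings or []


@dataclass
class SimulatedPlate:
    params: SimParams
    model: GroundTruthModel
    stack: ImageTimeSeries
    gt_transforms: list[RigidTransform]
    coverage_labels: np.ndarray          # first observation covering each px
    artifact_ledger: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# architecture generation
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, lo, hi):
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _grow_polyline(rng, start_xy, t_start, rate_mm_h, params, *,
                   phi0=0.0, relax=0.06, target=None, overshoot_mm=3.0):
    """Integrate a root trajectory with gravitropic mean reversion.

    ``phi`` is the heading measured from the downward vertical.  If ``target``
    is given, the heading is locked onto the target point until the tip has
    passed it by ``overshoot_mm``; afterwards the usual relaxed random walk
    resumes.  Returns an (n, 3) array of (x, y, t) nodes; growth stops at the
    image margins or at the last observation.
    """
    px_mm = params.px_mm
    step_px = 2.0
    step_mm = step_px * px_mm
    total_h = (params.n_timesteps - t_start) * params.timestep_h
    if total_h <= 0 or rate_mm_h <= 0:
        return np.array([[start_xy[0], start_xy[1], t_start]])
    n_steps = max(1, int(math.ceil(rate_mm_h * total_h / step_mm)))
    rows, cols = params.image_shape
    margin = params.margin_px
    x, y = float(start_xy[0]), float(start_xy[1])
    phi = phi0
    pts = [(x, y, t_start)]
    chasing = target is not None
    passed_mm = 0.0
    for k in range(n_steps):
        if chasing:
            dxt, dyt = target[0] - x, target[1] - y
            dist = math.hypot(dxt, dyt)
            if dist < step_px:
                chasing = False
                passed_mm = 0.0
                # keep heading through the crossing
            else:
                phi = math.atan2(dxt, dyt)
        elif target is not None and passed_mm < overshoot_mm:
            passed_mm += step_mm  # straight continuation beyond the crossing
        else:
            phi = phi * (1.0 - relax) + rng.normal(0.0, params.tortuosity)
        # steer back toward the plate interior
        if x < margin + 10 and math.sin(phi) < 0:
            phi = abs(phi) * 0.5
        elif x > cols - margin - 10 and math.sin(phi) > 0:
            phi = -abs(phi) * 0.5
        x += step_px * math.sin(phi)
        y += step_px * math.cos(phi)
        if y >= rows - margin or x <= margin or x >= cols - margin or y <= margin:
            break
        t = t_start + (k + 1) * step_mm / (rate_mm_h * params.timestep_h)
        pts.append((x, y, min(t, float(params.n_timesteps))))
        if t >= params.n_timesteps:
            break
    return np.asarray(pts)


def _arc_interp(points, s_px):
    """Point and time at arc-length position ``s_px`` along a polyline."""
    seg = np.hypot(*np.diff(points[:, :2], axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = float(np.clip(s_px, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(i, len(seg) - 1)
    w = 0.0 if seg[i] == 0 else (s - cum[i]) / seg[i]
    xy = (1 - w) * points[i, :2] + w * points[i + 1, :2]
    t = (1 - w) * points[i, 2] + w * points[i + 1, 2]
    return xy, t


def detect_crossings(model: GroundTruthModel,
                     min_margin_mm: float = 1.5) -> list[CrossingEvent]:
    """Find 2D organ intersections with a temporal offset >= 1 timestep.

    Events too close (< ``min_margin_mm`` of arc) to either end of the later
    organ are not listed: without observed growth on both sides of the
    crossing there is no identity to preserve.  Attachment points of laterals
    on their own parent are excluded.
    """
    px_mm = model.px_mm
    organs = [(ip, io, o) for ip, io, o in model.all_organs()
              if o.n_nodes >= 2]
    lines = {(ip, io): LineString(o.points[:, :2]) for ip, io, o in organs}
    events = []
    for a in range(len(organs)):
        for b in range(a + 1, len(organs)):
            ipa, ioa, oa = organs[a]
            ipb, iob, ob = organs[b]
            la, lb = lines[(ipa, ioa)], lines[(ipb, iob)]
            if not la.intersects(lb):
                continue
            inter = la.intersection(lb)
            geoms = getattr(inter, "geoms", [inter])
            for g in geoms:
                pt = g.centroid if g.geom_type != "Point" else g
                sa, sb = la.project(pt), lb.project(pt)
                parent_child = (
                    (oa.order == 2 and ipa == ipb and oa.parent == iob and
                     sa < 2 * min_margin_mm / px_mm) or
                    (ob.order == 2 and ipa == ipb and ob.parent == ioa and
                     sb < 2 * min_margin_mm / px_mm))
                if parent_child:
                    continue
                _, ta = _arc_interp(oa.points, sa)
                _, tb = _arc_interp(ob.points, sb)
                if abs(ta - tb) < 1.0:
                    continue
                if ta <= tb:
                    (first, s_first) = ((ipa, ioa), sa)
                    (second, s_second) = ((ipb, iob), sb)
                    later, s_l, t1, t2 = ob, sb, ta, tb
                else:
                    (first, s_first) = ((ipb, iob), sb)
                    (second, s_second) = ((ipa, ioa), sa)
                    later, s_l, t1, t2 = oa, sa, tb, ta
                margin_px = min_margin_mm / px_mm
                length_l = LineString(later.points[:, :2]).length
                if s_l < margin_px or length_l - s_l < margin_px:
                    continue
                if t2 > model.n_timesteps - 0.5:
                    continue  # crossing happens after the last useful frame
                events.append(CrossingEvent(first, second, pt.x, pt.y, t1, t2))
    return events


def simulate_architecture(params: SimParams) -> GroundTruthModel:
    """Grow a plate of ``n_plants`` seedlings; deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    rows, cols = params.image_shape
    px_mm = params.px_mm
    usable = cols - 2 * params.margin_px
    spacing = usable / params.n_plants
    if spacing < 6 * params.tube_width_px:
        raise SizingError("image too narrow for the requested plant count")
    total_h = (params.n_timesteps - 1) * params.timestep_h
    max_depth_px = (params.primary_rate[0] + 2 * params.primary_rate[1]) \
        * total_h / px_mm + params.seed_row_px
    if max_depth_px > 1.35 * rows:
        raise SizingError(
            "image too shallow for the requested primary growth: "
            f"expected up to {max_depth_px:.0f} px of depth for {rows} rows")

    plants = []
    for i in range(params.n_plants):
        x0 = params.margin_px + (i + 0.5) * spacing + rng.normal(0, spacing * 0.05)
        seed_xy = (float(x0), float(params.seed_row_px))
        rate = _trunc_normal(rng, *params.primary_rate,
                             max(0.05, params.primary_rate[0] - 2 * params.primary_rate[1]),
                             params.primary_rate[0] + 2 * params.primary_rate[1])
        pts = _grow_polyline(rng, seed_xy, 1.0, rate, params,
                             phi0=rng.normal(0.0, 0.05))
        primary = Organ(pts, order=1, label=f"primary_{i}")
        plants.append(Plant([primary], seed_xy))

    # lateral emergence: homogeneous Poisson along each primary with a
    # refractory zone near the tip and the seed
    pending = []  # (t_emerge, plant, s_px, side, rate)
    for ip, plant in enumerate(plants):
        primary = plant.organs[0]
        seg = np.hypot(*np.diff(primary.points[:, :2], axis=0).T)
        length_mm = float(seg.sum()) * px_mm
        lo_mm, hi_mm = 3.0, length_mm - 8.0
        if hi_mm <= lo_mm or params.lateral_density <= 0:
            continue
        n_lat = rng.poisson(params.lateral_density * (hi_mm - lo_mm))
        for _ in range(n_lat):
            s_mm = rng.uniform(lo_mm, hi_mm)
            _, t_pass = _arc_interp(primary.points, s_mm / px_mm)
            delay = _trunc_normal(rng, *params.lateral_delay_h, 8.0,
                                  params.lateral_delay_h[0] + 3 * params.lateral_delay_h[1])
            t_emerge = t_pass + delay / params.timestep_h
            if t_emerge > params.n_timesteps - 1.0:
                continue  # would not produce an observable component
            rate = _trunc_normal(rng, *params.lateral_rate, 0.03,
                                 params.lateral_rate[0] + 2 * params.lateral_rate[1])
            side = 1 if rng.random() < 0.5 else -1
            pending.append((t_emerge, ip, s_mm / px_mm, side, rate))

    pending.sort(key=lambda e: e[0])
    for t_emerge, ip, s_px, side, rate in pending:
        plant = plants[ip]
        primary = plant.organs[0]
        start_xy, _ = _arc_interp(primary.points, s_px)
        target = None
        if rng.random() < params.crossing_bias:
            target = _pick_crossing_target(
                rng, plants, ip, start_xy, t_emerge, rate, params)
        phi0 = side * math.radians(rng.uniform(55.0, 85.0))
        pts = _grow_polyline(rng, start_xy, t_emerge, rate, params,
                             phi0=phi0, relax=0.03, target=target)
        if len(pts) < 2:
            continue
        # attachment node: nearest node on the parent polyline
        d = np.hypot(primary.points[:, 0] - start_xy[0],
                     primary.points[:, 1] - start_xy[1])
        lat = Organ(pts, order=2, parent=0, attachment_index=int(np.argmin(d)),
                    label=f"lateral_{ip}_{len(plant.organs)}")
        plant.organs.append(lat)

    model = GroundTruthModel(plants, params.px_size_um, params.timestep_h,
                             params.n_timesteps,
                             meta={"seed": params.seed})
    model.crossings = detect_crossings(model)
    return model


def _pick_crossing_target(rng, plants, ip, start_xy, t_emerge, rate, params):
    """Choose a point on an existing organ that the new lateral can cross
    with a temporal offset >= 1 timestep, or None."""
    px_mm = params.px_mm
    candidates = []
    for jp, plant in enumerate(plants):
        for jo, organ in enumerate(plant.organs):
            if jp == ip and jo == 0:
                continue  # own primary near the insertion is not a crossing
            if organ.n_nodes < 2:
                continue
            candidates.append(organ)
    rng.shuffle(candidates)
    for organ in candidates[:6]:
        seg = np.hypot(*np.diff(organ.points[:, :2], axis=0).T)
        total = float(seg.sum())
        for _ in range(4):
            s = rng.uniform(0.25, 0.8) * total
            xy, t_cover = _arc_interp(organ.points, s)
            d_px = math.hypot(xy[0] - start_xy[0], xy[1] - start_xy[1])
            if d_px < 8.0:
                continue  # too close to the insertion to be a crossing
            if d_px * px_mm > 25.0:
                continue  # too far to reach plausibly
            heading = math.atan2(xy[0] - start_xy[0], xy[1] - start_xy[1])
            if abs(heading) > math.radians(100):
                continue  # would require growing upward
            # a crossing must be transversal: a shallow approach relative to
            # the target's local tangent makes the roots follow each other
            # instead of crossing
            xy2, _ = _arc_interp(organ.points, s + 3.0)
            tangent = math.atan2(xy2[0] - xy[0], xy2[1] - xy[1])
            rel = abs((heading - tangent + math.pi) % (2 * math.pi) - math.pi)
            if not (math.radians(35) < rel < math.radians(145)):
                continue
            t_arrive = t_emerge + d_px * px_mm / (rate * params.timestep_h)
            if t_arrive < t_cover + 1.1:
                continue  # offset below one timestep: not a trackable crossing
            if t_arrive > params.n_timesteps - 0.6:
                continue  # no post-crossing growth would be observed
            return (float(xy[0]), float(xy[1]))
    return None


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _active_points(organ: Organ, t: float) -> np.ndarray | None:
    """Polyline portion grown by continuous time ``t`` (partial last segment)."""
    ts = organ.points[:, 2]
    if ts[0] > t:
        return None
    n = int(np.searchsorted(ts, t, side="right"))
    pts = organ.points[:n, :2]
    if n < organ.n_nodes and n >= 1 and ts[n] > ts[n - 1]:
        w = (t - ts[n - 1]) / (ts[n] - ts[n - 1])
        tip = (1 - w) * organ.points[n - 1, :2] + w * organ.points[n, :2]
        pts = np.vstack([pts, tip])
    return pts if len(pts) >= 1 else None


def _draw_centerlines(model: RootSystemModel, params: SimParams,
                      t: float) -> np.ndarray:
    canvas = np.zeros(params.image_shape, dtype=bool)
    rows, cols = params.image_shape
    for plant in model.plants:
        # the visible seed hangs just below the hypocotyl point where the
        # primary polyline starts, so the mask's topmost pixel marks it
        rr, cc = draw_disk((plant.seed_xy[1] + params.seed_radius_px - 1,
                            plant.seed_xy[0]),
                           params.seed_radius_px, shape=params.image_shape)
        canvas[rr, cc] = True
        for organ in plant.organs:
            pts = _active_points(organ, t)
            if pts is None or len(pts) < 2:
                continue
            ij = np.round(pts[:, ::-1]).astype(int)  # (row, col)
            for k in range(len(ij) - 1):
                rr, cc = draw_line(*ij[k], *ij[k + 1])
                ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
                canvas[rr[ok], cc[ok]] = True
    return canvas


def rasterize_timeseries(model: GroundTruthModel, params: SimParams,
                         rng: np.random.Generator | None = None
                         ) -> SimulatedPlate:
    """Render the model into frames 1..n_timesteps with jitter and noise.

    Roots are drawn as tubes with a transverse Gaussian intensity profile —
    darkest at the centerline (``background_level - root_contrast``), medium
    at the border.  Before jitter, pixel coverage is nested across frames.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    n_t = params.n_timesteps
    sigma_r = params.tube_width_px / 2.0 / 1.1774  # half profile at half width
    cutoff = 3.0 * sigma_r
    cover_radius = 1.6  # px; centerline distance safely above detectability
    frames = np.empty((n_t,) + params.image_shape, dtype=np.float32)
    coverage = np.zeros(params.image_shape, dtype=np.uint8)
    gt_transforms: list[RigidTransform] = []
    trans_max, rot_max_deg = params.jitter
    center = ((params.image_shape[1] - 1) / 2.0,
              (params.image_shape[0] - 1) / 2.0)

    canvas = np.zeros(params.image_shape, dtype=bool)
    for k in range(1, n_t + 1):
        # accumulate the drawn set so pixel coverage is exactly nested even
        # where the rounded partial-tip of frame k strays off the final line
        canvas |= _draw_centerlines(model, params, float(k))
        d = ndimage.distance_transform_edt(~canvas)
        frame = np.full(params.image_shape, params.background_level,
                        dtype=np.float32)
        near = d <= cutoff
        frame[near] -= (params.root_contrast *
                        np.exp(-0.5 * (d[near] / sigma_r) ** 2)).astype(np.float32)
        new = (d <= cover_radius) & (coverage == 0)
        coverage[new] = k
        # plate jitter: rigid motion of the whole frame; the last frame
        # defines the reference geometry and is left untouched
        if k < n_t and (trans_max > 0 or rot_max_deg > 0):
            ang = math.radians(rng.uniform(-rot_max_deg, rot_max_deg))
            jx = rng.uniform(-trans_max, trans_max)
            jy = rng.uniform(-trans_max, trans_max)
            gt = RigidTransform(ang, jx, jy, center)  # jittered -> reference
            from .register import resample
            frame = resample(frame, gt.inverse(),
                             fill=params.background_level)
            gt_transforms.append(gt)
        else:
            gt_transforms.append(RigidTransform(0.0, 0.0, 0.0, center))
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd,
                                       params.image_shape).astype(np.float32)
        frames[k - 1] = np.clip(frame, 0.0, 255.0)

    stack = ImageTimeSeries(frames, params.timestep_h, params.px_size_um,
                            meta={"seed": params.seed})
    return SimulatedPlate(params, model, stack, gt_transforms, coverage)


def inject_artifacts(plate: SimulatedPlate, params: SimParams | None = None,
                     rng: np.random.Generator | None = None) -> SimulatedPlate:
    """Add small persistent dark blobs (condensation, dirt) to the stack.

    Blobs appear at a random frame and persist in all later frames; each is
    recorded in the artifact ledger so downstream filtering can be audited.
    """
    params = params or plate.params
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    if params.artifact_rate <= 0:
        return plate
    frames = plate.stack.frames
    n_t, rows, cols = frames.shape
    ledger = list(plate.artifact_ledger)
    # condensation and dirt fall on the dish during the experiment; the
    # first observation is clean (lids are wiped before plates are loaded)
    for k in range(1, n_t):
        for _ in range(rng.poisson(params.artifact_rate)):
            area = rng.uniform(*params.artifact_area_px)
            aspect = rng.uniform(1.0, 2.5)
            b = math.sqrt(area / (math.pi * aspect))
            a = aspect * b
            r0 = rng.uniform(params.margin_px, rows - params.margin_px)
            c0 = rng.uniform(params.margin_px, cols - params.margin_px)
            rot = rng.uniform(0, math.pi)
            rr, cc = draw_ellipse(r0, c0, a, b, shape=(rows, cols),
                                  rotation=rot)
            depth = rng.uniform(0.5, 0.9) * params.root_contrast
            dark = np.float32(params.background_level - depth)
            for j in range(k, n_t):
                frames[j, rr, cc] = np.minimum(frames[j, rr, cc], dark)
            ledger.append({"frame": k + 1, "rows": rr, "cols": cc,
                           "area": int(len(rr))})
    plate.artifact_ledger = ledger
    return plate


def simulate_plate(params: SimParams) -> SimulatedPlate:
    """Architecture + rasterization + artifacts in one call."""
    model = simulate_architecture(params)
    plate = rasterize_timeseries(model, params)
    return inject_artifacts(plate)
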