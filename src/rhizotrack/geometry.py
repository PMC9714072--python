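"""Geometric reconstruction: from the organ forest to timed centerlines.

Each forest edge is a transition between two consecutive growth regions of a
root, so it pins the root tip to a known place at a known observation time:
the dual-graph vertex sits at the central-most element of the pixel frontier
between the two components.  A per-organ tip is added at the pixel of the
last component geodesically farthest from the previous vertex.  Consecutive
vertices are joined by a Dijkstra shortest path through the component's
pixels, weighted by the distance map to the component contour so the path
hugs the medial axis; the pixel path is decimated (Douglas-Peucker) and
interior node times are linearly interpolated between the bounding vertices.
Two post-processes complete the model: upstream extrapolation of primaries
to the seed line, and handling of laterals that stop growing early (either
rejected, or extrapolated along the earlier root hiding them).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as sparse_dijkstra
from scipy.spatial import cKDTree

from .config import GeometryConfig
from .model import Organ, Plant, RootSystemModel
from .segment import ApparitionLabelImage
from .track import OrganForest

__all__ = [
    "NotAdjacentError", "locate_frontier_point", "locate_tip",
    "trace_centerline", "decimate_polyline", "build_model",
    "extrapolate_to_seed", "handle_stopped_laterals",
]

SQRT2 = math.sqrt(2.0)


class NotAdjacentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pixel-graph machinery
# ---------------------------------------------------------------------------

def _pixel_graph(mask: np.ndarray, node_vals: np.ndarray | None = None,
                 combine: str = "none") -> tuple[csr_matrix, np.ndarray]:
    """8-connected weighted graph over the True pixels of ``mask``.

    Step weight is the Euclidean inter-pixel distance (1 or sqrt(2)),
    multiplied by ``min`` or ``mean`` of the two pixels' ``node_vals``.
    Returns the sparse matrix and the ``idx`` image (-1 off the mask).
    """
    H, W = mask.shape
    idx = np.full((H, W), -1, dtype=np.int64)
    n = int(mask.sum())
    idx[mask] = np.arange(n)
    vals = node_vals[mask] if node_vals is not None else None
    rows, cols, data = [], [], []
    for dr, dc, dist in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, SQRT2),
                         (1, -1, SQRT2)):
        r0, r1 = max(0, -dr), H - max(0, dr)
        c0, c1 = max(0, -dc), W - max(0, dc)
        a = idx[r0:r1, c0:c1]
        b = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (a >= 0) & (b >= 0)
        ia, ib = a[ok], b[ok]
        if combine == "min":
            w = dist / (1.0 + np.minimum(vals[ia], vals[ib]))
        elif combine == "mean":
            w = dist * 0.5 * (vals[ia] + vals[ib])
        else:
            w = np.full(len(ia), dist)
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        data.extend([w, w])
    if not rows:
        return csr_matrix((n, n)), idx
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    return csr_matrix((data, (rows, cols)), shape=(n, n)), idx


def _as_pixels(comp) -> tuple[np.ndarray, np.ndarray]:
    """Accept a boolean mask or (rows, cols) arrays."""
    if isinstance(comp, np.ndarray) and comp.dtype == bool:
        return np.nonzero(comp)
    rr, cc = comp
    return np.asarray(rr, dtype=int), np.asarray(cc, dtype=int)


class _Comp:
    """A component's pixels in a local bounding-box window."""

    def __init__(self, comp):
        rr, cc = _as_pixels(comp)
        if len(rr) == 0:
            raise ValueError("empty component")
        self.r0, self.c0 = int(rr.min()) - 1, int(cc.min()) - 1
        h = int(rr.max()) - self.r0 + 2
        w = int(cc.max()) - self.c0 + 2
        self.mask = np.zeros((h, w), dtype=bool)
        self.mask[rr - self.r0, cc - self.c0] = True
        self.rr, self.cc = rr, cc

    def to_local(self, xy) -> tuple[int, int]:
        """Nearest component pixel (local row, col) to an (x, y) point."""
        d2 = (self.rr - xy[1]) ** 2 + (self.cc - xy[0]) ** 2
        i = int(np.argmin(d2))
        return self.rr[i] - self.r0, self.cc[i] - self.c0

    def to_xy(self, local_rc: np.ndarray) -> np.ndarray:
        """(n, 2) local (row, col) -> global (x, y)."""
        rc = np.atleast_2d(local_rc)
        return np.column_stack([rc[:, 1] + self.c0, rc[:, 0] + self.r0])


# ---------------------------------------------------------------------------
# dual-graph vertices
# ---------------------------------------------------------------------------

def locate_frontier_point(comp1, comp2) -> tuple[float, float]:
    """Central-most shared pixel edge between two 4-adjacent components.

    Enumerates the shared pixel edges, orders them along the frontier chain
    (greedy nearest-neighbour walk from the lexicographically smallest
    element) and returns the midpoint of the median element; even-length
    frontiers resolve to the lower-index median.
    """
    r1, c1 = _as_pixels(comp1)
    r2, c2 = _as_pixels(comp2)
    set2 = set(zip(r2.tolist(), c2.tolist()))
    elements = []  # midpoints (x, y) of shared pixel edges
    for r, c in zip(r1.tolist(), c1.tolist()):
        if (r, c + 1) in set2:
            elements.append((c + 0.5, float(r)))
        if (r, c - 1) in set2:
            elements.append((c - 0.5, float(r)))
        if (r + 1, c) in set2:
            elements.append((float(c), r + 0.5))
        if (r - 1, c) in set2:
            elements.append((float(c), r - 0.5))
    if not elements:
        raise NotAdjacentError("components share no pixel edge")
    pts = np.unique(np.asarray(elements), axis=0)
    order_start = np.lexsort((pts[:, 0], pts[:, 1]))[0]
    chain = [order_start]
    remaining = set(range(len(pts))) - {order_start}
    while remaining:
        last = pts[chain[-1]]
        nxt = min(remaining,
                  key=lambda i: ((pts[i][0] - last[0]) ** 2
                                 + (pts[i][1] - last[1]) ** 2, i))
        chain.append(nxt)
        remaining.discard(nxt)
    med = pts[chain[(len(chain) - 1) // 2]]
    return float(med[0]), float(med[1])


def _gap_midpoint(comp1, comp2) -> tuple[float, float]:
    """Midpoint of the closest pixel pair — junction for non-adjacent
    components (chains spliced across a crossing)."""
    r1, c1 = _as_pixels(comp1)
    r2, c2 = _as_pixels(comp2)
    tree = cKDTree(np.column_stack([r2, c2]))
    d, j = tree.query(np.column_stack([r1, c1]))
    i = int(np.argmin(d))
    p1 = np.array([c1[i], r1[i]], dtype=float)
    p2 = np.array([c2[j[i]], r2[j[i]]], dtype=float)
    mid = 0.5 * (p1 + p2)
    return float(mid[0]), float(mid[1])


def junction_point(comp1, comp2) -> tuple[float, float]:
    """Frontier point when adjacent, closest-pair midpoint otherwise."""
    try:
        return locate_frontier_point(comp1, comp2)
    except NotAdjacentError:
        return _gap_midpoint(comp1, comp2)


def locate_tip(comp, anchor) -> tuple[float, float]:
    """Pixel of the component geodesically farthest from the anchor.

    Geodesic distance is measured within the mask over 8-connected steps
    with Euclidean costs; ties resolve to the smaller row, then column.
    """
    c = _Comp(comp)
    graph, idx = _pixel_graph(c.mask)
    src_rc = c.to_local(anchor)
    src = idx[src_rc]
    dist = sparse_dijkstra(graph, indices=src, directed=False)
    dist[~np.isfinite(dist)] = -1.0
    nodes = np.argwhere(c.mask)
    order = np.lexsort((nodes[:, 1], nodes[:, 0]))
    nodes = nodes[order]
    dvals = dist[idx[nodes[:, 0], nodes[:, 1]]]
    best = nodes[int(np.argmax(dvals))]
    xy = c.to_xy(best)[0]
    return float(xy[0]), float(xy[1])


def trace_centerline(p1, p2, comp, cfg: GeometryConfig | None = None
                     ) -> np.ndarray:
    """Medial-axis-weighted shortest pixel path from p1 to p2 in a component.

    Dijkstra over the component's pixels with step cost
    ``euclidean_step * 1 / (1 + min(D(a), D(b)))`` where ``D`` is the
    distance transform to the component contour: deeper pixels are cheaper,
    pulling the path onto the medial axis.  Returns the full (n, 2) pixel
    path in (x, y), endpoints included.
    """
    c = _Comp(comp)
    D = ndimage.distance_transform_edt(c.mask)
    graph, idx = _pixel_graph(c.mask, D, combine="min")
    src = idx[c.to_local(p1)]
    dst = idx[c.to_local(p2)]
    if src == dst:
        return c.to_xy(np.array([c.to_local(p1)]))
    dist, pred = sparse_dijkstra(graph, indices=src, directed=False,
                                 return_predecessors=True)
    if not np.isfinite(dist[dst]):
        raise ValueError("endpoints lie in different connected parts")
    path = [dst]
    while path[-1] != src:
        path.append(pred[path[-1]])
    nodes = np.argwhere(c.mask)  # ordered like idx numbering (row-major)
    flat = np.full(graph.shape[0], -1, dtype=int)
    flat[idx[c.mask]] = np.arange(len(nodes))
    rc = nodes[flat[np.asarray(path[::-1])]]
    return c.to_xy(rc)


def decimate_polyline(path: np.ndarray, tol_px: float = 1.5) -> np.ndarray:
    """Douglas-Peucker simplification; endpoints always kept."""
    pts = np.asarray(path, dtype=float)
    if len(pts) < 3:
        return pts.copy()
    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, len(pts) - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        seg = pts[j] - pts[i]
        norm = np.hypot(*seg)
        rel = pts[i + 1:j] - pts[i]
        if norm == 0:
            d = np.hypot(rel[:, 0], rel[:, 1])
        else:
            d = np.abs(rel[:, 0] * seg[1] - rel[:, 1] * seg[0]) / norm
        k = int(np.argmax(d))
        if d[k] > tol_px:
            keep[i + 1 + k] = True
            stack.extend([(i, i + 1 + k), (i + 1 + k, j)])
    return pts[keep]


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def _interp_times(points: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Times along a polyline, linear in arc length from t0 to t1."""
    if len(points) == 1:
        return np.array([t1])
    seg = np.hypot(*np.diff(points, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return np.full(len(points), t1)
    return t0 + (t1 - t0) * cum / total


def build_model(forest: OrganForest, S: ApparitionLabelImage,
                cfg: GeometryConfig | None = None) -> RootSystemModel:
    """Convert the organ forest into a RootSystemModel of timed polylines."""
    cfg = cfg or GeometryConfig()
    rag = forest.rag
    chains = forest.extract_chains()
    organs: list[Organ | None] = [None] * len(chains)
    base_pts: list = [None] * len(chains)

    for ci, chain in enumerate(chains):
        verts = chain.vertices
        comps = [rag.pixels(v) for v in verts]
        junctions = []
        for i in range(len(verts) - 1):
            xy = junction_point(comps[i], comps[i + 1])
            junctions.append((xy, float(rag.t(verts[i + 1]) - 1)))
        # organ base vertex
        if chain.order == 1:
            rr, cc = comps[0]
            k = int(np.lexsort((cc, rr))[0])  # topmost pixel: the seed end
            base = ((float(cc[k]), float(rr[k])), 1.0)
        elif chain.parent_vertex is not None:
            pxy = junction_point(rag.pixels(chain.parent_vertex), comps[0])
            base = (pxy, max(float(rag.t(verts[0]) - 1), 1.0))
        elif junctions:
            base = (locate_tip(comps[0], junctions[0][0]),
                    max(float(rag.t(verts[0]) - 1), 1.0))
        else:
            rr, cc = comps[0]
            k = int(np.lexsort((cc, rr))[0])
            base = ((float(cc[k]), float(rr[k])),
                    max(float(rag.t(verts[0]) - 1), 1.0))
        anchor = junctions[-1][0] if junctions else base[0]
        tip = (locate_tip(comps[-1], anchor), float(rag.t(verts[-1])))

        nodes = []  # (x, y, t)
        entry = base
        for i, comp in enumerate(comps):
            exit_ = junctions[i] if i < len(junctions) else tip
            path = trace_centerline(entry[0], exit_[0], comp, cfg)
            path = decimate_polyline(path, cfg.dp_tol_px)
            pts = np.vstack([[entry[0]], path[1:-1] if len(path) > 2 else
                             np.empty((0, 2)), [exit_[0]]])
            ts = _interp_times(pts, entry[1], exit_[1])
            start = 1 if nodes else 0  # entry already emitted by previous comp
            for p, t in list(zip(pts, ts))[start:]:
                nodes.append((float(p[0]), float(p[1]), float(t)))
            entry = exit_
        pts = np.asarray(nodes)
        ts = np.maximum.accumulate(pts[:, 2])
        pts[:, 2] = ts
        organs[ci] = Organ(pts, order=chain.order,
                           label=f"{chain.kind}_{ci}")
        base_pts[ci] = base[0]

    # plants: one per primary chain, left to right (sources are pre-sorted)
    plants: list[Plant] = []
    chain_to_plant: dict[int, tuple[int, int]] = {}
    for ci, chain in enumerate(chains):
        if chain.order != 1:
            continue
        organ = organs[ci]
        plants.append(Plant([organ], (organ.points[0, 0], organ.points[0, 1])))
        chain_to_plant[ci] = (len(plants) - 1, 0)
    for ci, chain in enumerate(chains):
        if chain.order != 2:
            continue
        organ = organs[ci]
        if chain.parent is not None and chain.parent in chain_to_plant:
            ip, _ = chain_to_plant[chain.parent]
        else:
            # orphan: attach to the plant whose primary is closest to the base
            b = np.asarray(base_pts[ci])
            dists = [np.min(np.linalg.norm(
                p.organs[0].points[:, :2] - b, axis=1)) for p in plants]
            ip = int(np.argmin(dists)) if dists else 0
        if chain.parent is not None and chain.parent in chain_to_plant:
            parent_organ = plants[ip].organs[0]
            organ.parent = 0
            organ.attachment_index = int(np.argmin(np.linalg.norm(
                parent_organ.points[:, :2] - np.asarray(base_pts[ci]),
                axis=1)))
        plants[ip].organs.append(organ)
        chain_to_plant[ci] = (ip, len(plants[ip].organs) - 1)

    model = RootSystemModel(plants, S.px_size_um, S.timestep_h, S.n_t)
    model.meta["chain_map"] = {ci: pv for ci, pv in chain_to_plant.items()}
    model.meta["chain_vertices"] = {ci: list(c.vertices)
                                    for ci, c in enumerate(chains)}
    return model


# ---------------------------------------------------------------------------
# post-processes
# ---------------------------------------------------------------------------

def extrapolate_to_seed(model: RootSystemModel, last_frame: np.ndarray,
                        target_row: int,
                        cfg: GeometryConfig | None = None,
                        corridor_halfwidth: int = 80) -> RootSystemModel:
    """Extend each primary upstream to the seed line along dark pixels.

    Minimum-cost pixel path (Dijkstra) from the organ's first node up to
    ``target_row``; the step cost is the inter-pixel distance times the mean
    intensity of the two pixels, so the path follows the dark root remnant
    when one exists and goes straight up over uniform background.  The path
    is prepended with the first node's time and flagged extrapolated.
    """
    cfg = cfg or GeometryConfig()
    frame = np.asarray(last_frame, dtype=float)
    rows, cols = frame.shape
    for plant in model.plants:
        primary = plant.primary
        if primary is None:
            continue
        x0, y0 = primary.points[0, 0], primary.points[0, 1]
        if y0 <= target_row:
            continue
        r0 = int(max(0, target_row))
        r1 = int(min(rows, math.ceil(y0) + 3))
        c0 = int(max(0, math.floor(x0) - corridor_halfwidth))
        c1 = int(min(cols, math.ceil(x0) + corridor_halfwidth + 1))
        window = frame[r0:r1, c0:c1]
        mask = np.ones_like(window, dtype=bool)
        graph, idx = _pixel_graph(mask, window, combine="mean")
        dst = idx[int(round(y0)) - r0, int(round(x0)) - c0]
        srcs = idx[0, :]
        dist, pred, _ = sparse_dijkstra(graph, indices=srcs, directed=False,
                                        return_predecessors=True,
                                        min_only=True)
        if not np.isfinite(dist[dst]):
            continue
        sources_pred = pred
        path = [dst]
        while sources_pred[path[-1]] >= 0:
            path.append(sources_pred[path[-1]])
        nodes = np.argwhere(mask)
        rc = nodes[np.asarray(path)]          # dst -> seed row
        xy = np.column_stack([rc[:, 1] + c0, rc[:, 0] + r0]).astype(float)
        xy = decimate_polyline(xy[::-1], cfg.dp_tol_px)  # seed row -> dst
        if len(xy) < 2 and np.allclose(xy[-1], primary.points[0, :2]):
            continue
        t0 = primary.points[0, 2]
        new_pts = np.column_stack([xy[:-1], np.full(len(xy) - 1, t0)])
        primary.points = np.vstack([new_pts, primary.points])
        primary.extrapolated = np.concatenate([
            np.ones(len(new_pts), dtype=bool), primary.extrapolated])
        # shift attachment indices of laterals on this primary
        for organ in plant.organs:
            if organ.order == 2 and organ.attachment_index is not None:
                organ.attachment_index += len(new_pts)
    return model


def handle_stopped_laterals(model: RootSystemModel, forest: OrganForest,
                            cfg: GeometryConfig | None = None
                            ) -> RootSystemModel:
    """Process organs that stop growing before the last observation.

    Early stops are suspect: an isolated one is kept only if it grew over at
    least ``min_growth_timesteps`` observation times, while one incident to
    an earlier root is assumed to keep growing hidden below it — its path is
    extrapolated along the host centerline at the stopped root's median
    speed, all added nodes flagged.
    """
    cfg = cfg or GeometryConfig()
    n_t = model.n_timesteps
    rag = forest.rag
    chain_map = model.meta.get("chain_map", {})
    chain_vertices = model.meta.get("chain_vertices", {})
    vertex_owner = {}
    for ci, verts in chain_vertices.items():
        for v in verts:
            vertex_owner[v] = ci
    to_remove: list[tuple[int, int]] = []
    for ci, (ip, io) in list(chain_map.items()):
        organ = model.plants[ip].organs[io]
        if organ.order != 2 or organ.t_last >= n_t - 1e-6:
            continue
        verts = chain_vertices.get(ci, [])
        if not verts:
            continue
        last_v = verts[-1]
        host_ci = None
        if last_v in rag.graph.nodes:
            for u in set(rag.graph.predecessors(last_v)) | \
                    set(rag.graph.successors(last_v)):
                owner = vertex_owner.get(u)
                if owner is not None and owner != ci and \
                        rag.t(u) <= rag.t(last_v):
                    host_ci = owner
                    break
        if host_ci is None:
            n_times = len({rag.t(v) for v in verts if v in rag.graph.nodes})
            if n_times < cfg.min_growth_timesteps:
                to_remove.append((ip, io))
            continue
        host_ip, host_io = chain_map.get(host_ci, (None, None))
        if host_ip is None:
            continue
        host = model.plants[host_ip].organs[host_io]
        # median observed speed, px per timestep
        ts = organ.points[:, 2]
        span = max(organ.t_last - organ.t_first, 1.0)
        speed = organ.length_px() / span
        tip = organ.points[-1, :2]
        hseg = host.points[:, :2]
        s0_idx = int(np.argmin(np.linalg.norm(hseg - tip, axis=1)))
        cum = np.concatenate([[0.0], np.cumsum(
            np.hypot(*np.diff(hseg, axis=0).T))])
        s = cum[s0_idx]
        t = math.floor(organ.t_last) + 1.0
        new_nodes = []
        t_host_end = host.t_last
        while t <= min(n_t, t_host_end) + 1e-9:
            s_t = s + speed * (t - organ.t_last)
            if s_t > cum[-1]:
                break
            k = int(np.searchsorted(cum, s_t, side="right")) - 1
            k = min(k, len(hseg) - 2)
            w = 0.0 if cum[k + 1] == cum[k] else \
                (s_t - cum[k]) / (cum[k + 1] - cum[k])
            xy = (1 - w) * hseg[k] + w * hseg[k + 1]
            new_nodes.append((float(xy[0]), float(xy[1]), float(t)))
            t += 1.0
        if new_nodes:
            organ.points = np.vstack([organ.points, np.asarray(new_nodes)])
            organ.extrapolated = np.concatenate([
                organ.extrapolated, np.ones(len(new_nodes), dtype=bool)])
    for ip, io in sorted(to_remove, key=lambda x: (x[0], -x[1])):
        del model.plants[ip].organs[io]
        model.meta["chain_map"] = {
            ci: (p, o - 1 if p == ip and o > io else o)
            for ci, (p, o) in model.meta["chain_map"].items()
            if (p, o) != (ip, io)}
    return model
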