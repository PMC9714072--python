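"""Topological tracking of growing roots on the region adjacency graph.

The apparition-label image is converted into a weighted directed region
adjacency graph (RAG): every 8-connected component of same-label pixels is a
vertex; 4-adjacent components are joined by an edge directed forward in time
(the graph is therefore acyclic).  Edge weights favour links between regions
of comparable surface, consecutive apparition times and downward direction.
Primary roots are extracted as greedy min-cost walks from the largest
first-frame components; the remainder is pruned to a minimum-weight spanning
forest (Edmonds); lateral branching is suppressed by keeping each lateral
vertex's min-cost outgoing arc.  Root crossings disconnect chains — they are
reconnected by iterated optimal assignment (Hungarian) over a connection
cost built from geometric and topological continuity features, and spurious
lateral roots are rejected by a robust 25x MADe outlier rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.measure import label as cc_label

from .config import TrackConfig
from .segment import ApparitionLabelImage

__all__ = [
    "TrackError", "RegionGraph", "OrganForest", "OrganChain",
    "build_rag", "edge_weight", "extract_primaries", "prune_to_forest",
    "connection_cost", "resolve_crossings", "reject_artefact_roots",
    "solve_assignment", "made", "track",
]

UP = np.array([0.0, -1.0])  # unit vector opposite to gravity (y grows down)


class TrackError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# region adjacency graph
# ---------------------------------------------------------------------------

class RegionGraph:
    """Weighted directed RAG over same-label 8-connected components of S."""

    def __init__(self, graph: nx.DiGraph, vertex_map: np.ndarray,
                 S: ApparitionLabelImage):
        self.graph = graph
        #: pristine adjacency as built, before primary extraction edits
        #: edges away — the topological score of the connection cost is
        #: defined on the original RAG
        self.original = graph.copy()
        self.vertex_map = vertex_map
        self.S = S
        self._objects = ndimage.find_objects(vertex_map)

    def t(self, v: int) -> int:
        return self.graph.nodes[v]["t"]

    def area(self, v: int) -> int:
        return self.graph.nodes[v]["area"]

    def centroid(self, v: int) -> np.ndarray:
        return np.asarray(self.graph.nodes[v]["centroid"])

    def pixels(self, v: int) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of the component's pixels."""
        sl = self._objects[v - 1]
        rr, cc = np.nonzero(self.vertex_map[sl] == v)
        return rr + sl[0].start, cc + sl[1].start

    def component_mask(self, v: int):
        """Boolean mask of the component inside its bounding box, plus offset."""
        sl = self._objects[v - 1]
        return self.vertex_map[sl] == v, (sl[0].start, sl[1].start)

    def number_of_vertices(self) -> int:
        return self.graph.number_of_nodes()


def edge_weight(area1: float, area2: float, t1: int, t2: int,
                c1, c2) -> float:
    """Weight of a forward-time RAG edge (v1 -> v2).

    ``|#v1 - #v2| / (#v1 + #v2) + (t(v2) - t(v1) - 1) + u . y_up`` where
    ``u`` is the unit vector from v1's centroid to v2's centroid and
    ``y_up`` points opposite to gravity, so straight-down growth contributes
    -1.  A zero-length centroid vector contributes 0.
    """
    size = abs(area1 - area2) / (area1 + area2)
    dt = (t2 - t1 - 1)
    d = np.asarray(c2, dtype=float) - np.asarray(c1, dtype=float)
    norm = float(np.hypot(*d))
    direction = 0.0 if norm == 0 else float(d @ UP) / norm
    return size + dt + direction


def build_rag(S: ApparitionLabelImage) -> RegionGraph:
    """Vertices from same-label 8-connected components, edges between
    4-adjacent components directed forward in time."""
    labels = S.labels
    vertex_map = np.zeros_like(labels, dtype=np.int32)
    graph = nx.DiGraph()
    next_id = 1
    for t in range(1, int(labels.max()) + 1 if labels.size else 1):
        mask = labels == t
        if not mask.any():
            continue
        comps, n = cc_label(mask, connectivity=2, return_num=True)
        vertex_map[mask] = comps[mask] + (next_id - 1)
        idx = np.arange(1, n + 1)
        areas = ndimage.sum_labels(np.ones_like(comps), comps, idx)
        rows = ndimage.sum_labels(np.indices(mask.shape)[0], comps, idx) / areas
        cols = ndimage.sum_labels(np.indices(mask.shape)[1], comps, idx) / areas
        for i in range(n):
            graph.add_node(next_id + i, t=t, area=int(areas[i]),
                           centroid=(float(cols[i]), float(rows[i])),
                           role="unassigned")
        next_id += n

    pairs = set()
    for axis in (0, 1):
        a = vertex_map[:-1, :] if axis == 0 else vertex_map[:, :-1]
        b = vertex_map[1:, :] if axis == 0 else vertex_map[:, 1:]
        sel = (a > 0) & (b > 0) & (a != b)
        if sel.any():
            stacked = np.unique(np.stack([a[sel], b[sel]]), axis=1)
            pairs.update(map(tuple, stacked.T))
    for u, v in pairs:
        tu, tv = graph.nodes[u]["t"], graph.nodes[v]["t"]
        if tu == tv:
            continue  # cannot happen for 4-adjacency of distinct 8-components
        if tu > tv:
            u, v = v, u
        if graph.has_edge(u, v):
            continue
        w = edge_weight(graph.nodes[u]["area"], graph.nodes[v]["area"],
                        graph.nodes[u]["t"], graph.nodes[v]["t"],
                        graph.nodes[u]["centroid"], graph.nodes[v]["centroid"])
        graph.add_edge(u, v, weight=w)
    return RegionGraph(graph, vertex_map, S)


# ---------------------------------------------------------------------------
# primary extraction and spanning forest
# ---------------------------------------------------------------------------

def _edge_key(g: nx.DiGraph, u: int, v: int):
    """Deterministic ordering of candidate arcs: weight, then earlier
    target time, then larger target area, then ids."""
    return (g[u][v]["weight"], g.nodes[v]["t"], -g.nodes[v]["area"], u, v)


def extract_primaries(rag: RegionGraph, n_plants: int) -> RegionGraph:
    """Mark the primary paths and drop outlier vertices, in place.

    Sources are the ``n_plants`` largest label-1 components; from each, the
    longest greedy min-cost walk (follow the minimum-weight outgoing edge
    until none remains) is marked primary.  Lateral arcs pointing into
    primary vertices are eliminated, and vertices unreachable from any
    primary vertex are dropped as outliers.
    """
    g = rag.graph
    first = [v for v in g.nodes if g.nodes[v]["t"] == 1]
    if len(first) < n_plants:
        raise TrackError(
            f"found {len(first)} first-frame components but n_plants="
            f"{n_plants}: {n_plants - len(first)} seed(s) missing")
    # candidate sources: label-1 vertices inside the largest whole-plant
    # 4-connected components of the segmentation, ranked by vertex area —
    # debris that was present from the start cannot outrank a seedling
    plant_comps = cc_label(rag.S.labels > 0, connectivity=1)
    comp_sizes = np.bincount(plant_comps.ravel())
    comp_sizes[0] = 0
    big_comps = set(np.argsort(comp_sizes)[::-1][:n_plants])
    candidates = []
    for v in first:
        rr, cc = rag.pixels(v)
        if plant_comps[rr[0], cc[0]] in big_comps:
            candidates.append(v)
    if len(candidates) < n_plants:
        candidates = first
    candidates.sort(key=lambda v: (-g.nodes[v]["area"], v))
    sources = candidates[:n_plants]
    primary_edges = set()
    for src in sources:
        g.nodes[src]["role"] = "primary"
        g.nodes[src]["source"] = True
        v = src
        walked = [src]
        while True:
            out = [(u2, v2) for u2, v2 in g.out_edges(v)
                   if g.nodes[v2]["role"] != "primary"]
            if not out:
                break
            # min-cost edge, with an angular-continuity penalty: where a
            # lateral's fresh growth is adjacent to the primary's path, only
            # collinearity with the recent trajectory tells the primary's
            # own continuation apart
            tail = [np.asarray(g.nodes[u]["centroid"]) for u in walked[-4:]]
            d_in = _direction(tail, 4.0)
            c_v = np.asarray(g.nodes[v]["centroid"])

            def walk_cost(e):
                w = g[e[0]][e[1]]["weight"]
                if d_in is not None:
                    d_out = np.asarray(g.nodes[e[1]]["centroid"]) - c_v
                    n = float(np.hypot(*d_out))
                    if n > 0:
                        ang = math.acos(float(np.clip(d_in @ d_out / n,
                                                      -1, 1)))
                        w += 2.0 * ang / math.pi
                return (w,) + _edge_key(g, *e)[1:]

            u2, v2 = min(out, key=walk_cost)
            if g.nodes[v2]["t"] - g.nodes[v]["t"] - 1 >= 2:
                # a primary grows continuously: a multi-step temporal gap
                # means the path is interrupted (crossing, artefact) and the
                # continuation is better recovered by the global matching
                break
            recent = [g.nodes[u]["area"] for u in walked[-5:]]
            if len(walked) >= 3 and \
                    g.nodes[v2]["area"] < 0.25 * float(np.median(recent)):
                # growth area per interval is roughly constant for a
                # primary; a collapse means the walk is about to crawl onto
                # slivers along a blocking root.  Stopping here is safe:
                # a premature stop is reconnected by the matching, while an
                # overrun poisons it (the true continuation turns
                # temporally backward)
                break
            primary_edges.add((u2, v2))
            g.nodes[v2]["role"] = "primary"
            v = v2
            walked.append(v)
    for v in g.nodes:
        if g.nodes[v]["role"] != "primary":
            g.nodes[v]["role"] = "lateral"
    # outlier removal: keep only the connected components (undirected, on
    # the full adjacency) that contain a primary vertex; floating debris
    # (condensation, dirt not touching any root) is rejected
    und = g.to_undirected(as_view=True)
    keep: set = set()
    for comp in nx.connected_components(und):
        if any(g.nodes[v]["role"] == "primary" for v in comp):
            keep |= comp
    g.remove_nodes_from([v for v in list(g.nodes) if v not in keep])
    # lateral arcs incident INTO a primary vertex violate the root hierarchy
    drop = [(u, v) for u, v in g.edges
            if g.nodes[v]["role"] == "primary" and (u, v) not in primary_edges]
    g.remove_edges_from(drop)
    for u, v in primary_edges:
        g[u][v]["primary_path"] = True
    return rag


def minimum_in_forest(g: nx.DiGraph,
                      fixed_in: dict[int, int] | None = None
                      ) -> dict[int, int]:
    """Minimum-weight spanning arborescence forest of a DAG.

    On a DAG any choice of one incoming arc per non-root vertex is acyclic,
    so the general algorithm's cycle-contraction phase never triggers and
    the optimum is the independent minimum incoming arc of each vertex.
    ``fixed_in`` pins chosen parents (the primary path).  Returns a map
    ``vertex -> chosen parent``.
    """
    fixed_in = fixed_in or {}
    choice: dict[int, int] = {}
    for v in g.nodes:
        if v in fixed_in:
            choice[v] = fixed_in[v]
            continue
        preds = list(g.pred[v])
        if not preds:
            continue
        choice[v] = min(preds, key=lambda u: _edge_key(g, u, v))
    return choice


def _continuity_in_forest(g: nx.DiGraph,
                          fixed_in: dict[int, int]) -> dict[int, int]:
    """Per-vertex parent choice with an angular-continuity penalty.

    Processing vertices forward in time (valid on a DAG) means every
    candidate parent's own chain is already resolved, so the arc weight can
    be augmented with the angle between the parent chain's direction and
    the parent->child step.  Where roots grow entangled, this keeps each
    chain on its own trajectory where the raw weight alone would hop
    between parallel organs.
    """
    choice: dict[int, int] = dict(fixed_in)
    for v in sorted(g.nodes, key=lambda v: (g.nodes[v]["t"], v)):
        if v in choice:
            continue
        preds = list(g.pred[v])
        if not preds:
            continue
        if len(preds) == 1:
            choice[v] = preds[0]
            continue
        c_vs = {}

        def arc_cost(u):
            w = g[u][v]["weight"]
            chain = [u]
            while len(chain) < 4 and chain[-1] in choice:
                chain.append(choice[chain[-1]])
            pts = [np.asarray(g.nodes[x]["centroid"])
                   for x in reversed(chain)]
            d_in = _direction(pts, 4.0)
            if d_in is not None:
                d_out = (np.asarray(g.nodes[v]["centroid"])
                         - np.asarray(g.nodes[u]["centroid"]))
                n = float(np.hypot(*d_out))
                if n > 0:
                    ang = math.acos(float(np.clip(d_in @ d_out / n, -1, 1)))
                    w += 2.0 * ang / math.pi
            return (w,) + _edge_key(g, u, v)[1:]

        choice[v] = min(preds, key=arc_cost)
    return choice


class OrganForest:
    """Pruned spanning forest over the RAG, with organ chain extraction."""

    def __init__(self, forest: nx.DiGraph, rag: RegionGraph,
                 sources: list[int]):
        self.forest = forest
        self.rag = rag
        self.sources = sources

    def role(self, v: int) -> str:
        return self.forest.nodes[v]["role"]

    def v_start(self, cfg: TrackConfig | None = None) -> list[int]:
        """Lateral vertices with no incoming arc, plus suspicious chain
        heads: lateral vertices whose single incoming arc spans a temporal
        gap implausible for what it claims to be (an emergence from a
        primary, or a continuation after a lateral vertex), hinting at a
        crossing or artefact interrupting the true chain.  Such heads are
        reconnection candidates; they only lose their arc if the optimal
        matching finds a cheaper continuation."""
        f = self.forest
        starts = [v for v in f.nodes
                  if f.nodes[v]["role"] == "lateral" and f.in_degree(v) == 0]
        if cfg is not None:
            for v in f.nodes:
                if f.nodes[v]["role"] != "lateral" or f.in_degree(v) != 1:
                    continue
                u = next(iter(f.pred[v]))
                if f[u][v].get("kind") == "splice":
                    continue
                gap = f.nodes[v]["t"] - f.nodes[u]["t"] - 1
                bound = (cfg.suspicious_gap_primary
                         if f.nodes[u]["role"] == "primary"
                         else cfg.suspicious_gap_lateral)
                if gap >= bound:
                    starts.append(v)
        return sorted(starts)

    def v_stop(self) -> list[int]:
        """Vertices with no outgoing continuation arc.

        For lateral vertices this is out-degree 0; a primary-path end
        remains a stop even when lateral emergences hang from it, since
        those arcs do not continue the primary's own trajectory."""
        f = self.forest
        stops = []
        for v in f.nodes:
            succ = list(f.succ[v])
            if f.nodes[v]["role"] == "primary":
                cont = [w for w in succ
                        if f.nodes[w]["role"] == "primary"
                        or f[v][w].get("kind") == "splice"]
                if not cont:
                    stops.append(v)
            elif not succ:
                stops.append(v)
        return sorted(stops)

    # -- chain context helpers -------------------------------------------

    def chain_tail(self, v: int, k: int) -> list[int]:
        """Up to k vertices of the chain ending at v (oldest first)."""
        f = self.forest
        chain = [v]
        while len(chain) < k:
            preds = list(f.pred[chain[-1]])
            if not preds:
                break
            u = preds[0]
            # do not walk past an organ boundary (emergence from a primary)
            if f.nodes[u]["role"] == "primary" and \
               f.nodes[chain[-1]]["role"] == "lateral":
                break
            chain.append(u)
        return chain[::-1]

    def chain_head(self, v: int, k: int) -> list[int]:
        """Up to k vertices of the chain starting at v (oldest first)."""
        f = self.forest
        chain = [v]
        while len(chain) < k:
            succs = [w for w in f.succ[chain[-1]]
                     if not (f.nodes[chain[-1]]["role"] == "primary"
                             and f.nodes[w]["role"] == "lateral")] \
                if f.nodes[chain[-1]]["role"] == "primary" else \
                list(f.succ[chain[-1]])
            if not succs:
                break
            chain.append(succs[0])
        return chain

    def extract_chains(self) -> list["OrganChain"]:
        """Decompose the forest into per-organ vertex chains."""
        f = self.forest
        chains: list[OrganChain] = []
        consumed: set[int] = set()

        def follow(start: int) -> list[int]:
            chain = [start]
            consumed.add(start)
            while True:
                v = chain[-1]
                nxt = None
                if f.nodes[v]["role"] == "primary":
                    cand = [w for w in f.succ[v]
                            if f.nodes[w]["role"] == "primary"]
                    if not cand:
                        cand = [w for w in f.succ[v]
                                if f[v][w].get("kind") == "splice"]
                    nxt = cand[0] if cand else None
                else:
                    succ = [w for w in f.succ[v]]
                    nxt = succ[0] if succ else None
                if nxt is None or nxt in consumed:
                    break
                chain.append(nxt)
                consumed.add(nxt)
            return chain

        for src in self.sources:
            if src not in f.nodes:
                continue
            chains.append(OrganChain(follow(src), order=1, parent=None,
                                     parent_vertex=None, kind="primary"))
        vertex_chain = {v: i for i, ch in enumerate(chains)
                        for v in ch.vertices}
        # laterals: heads attached to a primary vertex by a non-splice arc
        heads = []
        for u, v in f.edges:
            if f.nodes[v]["role"] == "lateral" and v not in consumed \
               and f.nodes[u]["role"] == "primary" \
               and f[u][v].get("kind") != "splice" and u in vertex_chain:
                heads.append((v, u))
        for v, u in sorted(heads):
            ch = OrganChain(follow(v), order=2, parent=vertex_chain[u],
                            parent_vertex=u, kind="lateral")
            chains.append(ch)
            for w in ch.vertices:
                vertex_chain[w] = len(chains) - 1
        # orphans: unconnected lateral chain heads
        for v in sorted(f.nodes):
            if v not in consumed and f.in_degree(v) == 0 \
               and f.nodes[v]["role"] == "lateral":
                ch = OrganChain(follow(v), order=2, parent=None,
                                parent_vertex=None, kind="orphan")
                chains.append(ch)
        return chains

    def remove_chain(self, chain: "OrganChain") -> None:
        self.forest.remove_nodes_from(chain.vertices)

    # -- debugging I/O ----------------------------------------------------

    def dump_jsonl(self, path) -> None:
        """Write vertices and edges as JSON lines (debugging, fixtures)."""
        with open(path, "w") as fh:
            for v in sorted(self.forest.nodes):
                d = {"kind": "vertex", "id": int(v),
                     **{k: val for k, val in self.forest.nodes[v].items()}}
                fh.write(json.dumps(d) + "\n")
            for u, v in sorted(self.forest.edges):
                d = {"kind": "edge", "source": int(u), "target": int(v),
                     **{k: val for k, val in self.forest[u][v].items()}}
                fh.write(json.dumps(d) + "\n")

    @staticmethod
    def load_jsonl(path) -> nx.DiGraph:
        """Restore a dumped forest as a bare graph (no pixel data)."""
        g = nx.DiGraph()
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                kind = d.pop("kind")
                if kind == "vertex":
                    vid = d.pop("id")
                    if "centroid" in d:
                        d["centroid"] = tuple(d["centroid"])
                    g.add_node(vid, **d)
                else:
                    g.add_edge(d.pop("source"), d.pop("target"), **d)
        return g


@dataclass
class OrganChain:
    vertices: list[int]
    order: int
    parent: int | None
    parent_vertex: int | None
    kind: str = "lateral"
    meta: dict = field(default_factory=dict)


def prune_to_forest(rag: RegionGraph) -> OrganForest:
    """Minimum spanning forest rooted at the primary sources, then lateral
    out-arc pruning so lateral chains cannot branch."""
    g = rag.graph
    sources = sorted((v for v in g.nodes if g.nodes[v].get("source")),
                     key=lambda v: g.nodes[v]["centroid"][0])
    fixed = {}
    for u, v in g.edges:
        if g[u][v].get("primary_path"):
            fixed[v] = u
    choice = _continuity_in_forest(g, fixed)
    forest = nx.DiGraph()
    for v in g.nodes:
        forest.add_node(v, **g.nodes[v])
    for v, u in choice.items():
        forest.add_edge(u, v, **g[u][v])
    # suppress lateral branching: each lateral vertex keeps only its
    # min-cost outgoing arc.  The arc cost is augmented with an angular
    # continuity penalty: at a root crossing the crossed vertex sees both
    # its own continuation and the crossing root's outgoing region with
    # near-equal weights, and only collinearity with the incoming chain
    # tells them apart.
    result = OrganForest(forest, rag, sources)
    for v in list(forest.nodes):
        if forest.nodes[v]["role"] != "lateral":
            continue
        out = list(forest.out_edges(v))
        if len(out) <= 1:
            continue
        tail = result.chain_tail(v, 4)
        c_v = np.asarray(forest.nodes[v]["centroid"])
        d_in = _direction([np.asarray(forest.nodes[u]["centroid"])
                           for u in tail], 4.0)

        def arc_cost(e):
            w = forest[e[0]][e[1]]["weight"]
            if d_in is not None:
                d_out = np.asarray(forest.nodes[e[1]]["centroid"]) - c_v
                n = float(np.hypot(*d_out))
                if n > 0:
                    ang = math.acos(float(np.clip(d_in @ d_out / n, -1, 1)))
                    w += 2.0 * ang / math.pi
            return (w,) + _edge_key(forest, *e)[1:]

        keep = min(out, key=arc_cost)
        forest.remove_edges_from([e for e in out if e != keep])
    return result


# ---------------------------------------------------------------------------
# crossing resolution
# ---------------------------------------------------------------------------

def solve_assignment(cost: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Optimal one-to-one assignment (Hungarian); rectangular matrices are
    padded internally.  Returns matched (row, col) pairs and their total."""
    cost = np.asarray(cost, dtype=float)
    big = 1e9
    n = max(cost.shape)
    padded = np.full((n, n), big)
    finite = np.where(np.isfinite(cost), cost, big)
    padded[:cost.shape[0], :cost.shape[1]] = finite
    rows, cols = linear_sum_assignment(padded)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols)
             if r < cost.shape[0] and c < cost.shape[1]
             and np.isfinite(cost[r, c])]
    total = float(sum(cost[r, c] for r, c in pairs))
    return pairs, total


def _pixel_gap(rag: RegionGraph, v1: int, v2: int) -> float:
    """Minimum pixel-to-pixel distance between two components."""
    from scipy.spatial import cKDTree

    r1, c1 = rag.pixels(v1)
    r2, c2 = rag.pixels(v2)
    tree = cKDTree(np.column_stack([r1, c1]))
    d, _ = tree.query(np.column_stack([r2, c2]))
    return float(d.min())


def _direction(points: list[np.ndarray], min_support: float):
    """Unit direction of a centroid sequence, or None if too short."""
    if len(points) < 2:
        return None
    d = np.asarray(points[-1], dtype=float) - np.asarray(points[0], dtype=float)
    n = float(np.hypot(*d))
    if n < min_support:
        return None
    return d / n


def _speed(forest: OrganForest, chain: list[int]):
    """Centroid path length per timestep over a chain window, or None."""
    if len(chain) < 2:
        return None
    g = forest.forest
    cents = [np.asarray(g.nodes[v]["centroid"]) for v in chain]
    dist = sum(float(np.hypot(*(b - a))) for a, b in zip(cents, cents[1:]))
    dt = g.nodes[chain[-1]]["t"] - g.nodes[chain[0]]["t"]
    if dt <= 0:
        return None
    return dist / dt


def connection_cost(v_stop: int, v_start: int, rag: RegionGraph,
                    forest: OrganForest,
                    cfg: TrackConfig | None = None) -> float:
    """Likelihood cost in [0, 1] of reconnecting a root stop to a root start.

    Weighted mean of four continuity features, each normalized to [0, 1]
    and replaced by the majoring value 1 when the chains are too short to
    support the estimate: the virtual RAG edge weight, the angle between the
    stop's terminal and the start's initial directions, the relative speed
    difference, and a topological score from the min-hop undirected RAG path
    (wrong-direction edges + temporal gap).  Temporally backward or
    spatially distant pairs are inadmissible (infinite cost).
    """
    cfg = cfg or TrackConfig()
    g = forest.forest
    t_stop, t_start = g.nodes[v_stop]["t"], g.nodes[v_start]["t"]
    # one step of temporal overlap is tolerated for primary stops: a
    # primary is wide and fast, and merged growth at its crossings can give
    # the continuation an apparition label preceding the stop's
    overlap = 1 if g.nodes[v_stop]["role"] == "primary" else 0
    if t_start < t_stop - overlap:
        return math.inf
    c_stop = np.asarray(g.nodes[v_stop]["centroid"])
    c_start = np.asarray(g.nodes[v_start]["centroid"])
    gap = float(np.hypot(*(c_start - c_stop)))
    pixel_gap = _pixel_gap(rag, v_stop, v_start)
    if pixel_gap > cfg.max_gap_px:
        return math.inf

    # f1: virtual edge weight, affinely rescaled from [-1, cap] to [0, 1]
    p = edge_weight(g.nodes[v_stop]["area"], g.nodes[v_start]["area"],
                    t_stop, t_start, c_stop, c_start)
    f1 = float(np.clip((p + 1.0) / (cfg.weight_cap + 1.0), 0.0, 1.0))

    # f2: angle between the stop's terminal and the start's initial
    # directions, theta / pi
    tail = forest.chain_tail(v_stop, cfg.speed_window + 1)
    head = forest.chain_head(v_start, cfg.speed_window + 1)
    d_stop = _direction([np.asarray(g.nodes[v]["centroid"]) for v in tail],
                        cfg.min_support_px)
    d_start = _direction([np.asarray(g.nodes[v]["centroid"]) for v in head],
                         cfg.min_support_px)
    if d_stop is None or d_start is None:
        f2 = 1.0
    else:
        f2 = math.acos(float(np.clip(d_stop @ d_start, -1.0, 1.0))) / math.pi

    # f5: gross misalignment of the stop->start jump with the stop's
    # heading.  Centroid jumps are noisy for small regions, so angles up to
    # 60 degrees are not penalized at all; beyond that the feature ramps to
    # 1 — a connection that requires the root to double back is no
    # continuation even when the two directions agree.
    if d_stop is None or gap < 2.0:
        f5 = 0.0
    else:
        d_gap = (c_start - c_stop) / gap
        ang = math.acos(float(np.clip(d_stop @ d_gap, -1.0, 1.0)))
        f5 = max(0.0, (ang - math.pi / 3) / (math.pi - math.pi / 3))

    # f3: relative speed difference, including the speed implied by the
    # hidden stretch (the root must have grown across the gap during the
    # temporal gap — a long jump in little time is no continuation)
    s_stop = _speed(forest, tail)
    s_start = _speed(forest, head)
    if s_stop is None or s_start is None or s_stop + s_start == 0:
        f3 = 1.0
    else:
        f3 = abs(s_stop - s_start) / (s_stop + s_start)
        jump_speed = pixel_gap / max(t_start - t_stop, 1)
        mean_speed = 0.5 * (s_stop + s_start)
        if jump_speed > mean_speed:
            f3 = max(f3, (jump_speed - mean_speed)
                     / (jump_speed + mean_speed))

    # f4: topological score on the original RAG
    und = rag.original.to_undirected(as_view=True)
    try:
        path = nx.shortest_path(und, v_stop, v_start)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        path = None
    if path is None or len(path) - 1 > cfg.search_hops:
        f4 = 1.0
    else:
        wrong = sum(1 for a, b in zip(path, path[1:])
                    if not rag.original.has_edge(a, b))
        tgap = max(t_start - t_stop - 1, 0)
        f4 = min((wrong + tgap) / cfg.topo_norm, 1.0)

    w = np.asarray(cfg.feature_weights, dtype=float)
    return float(np.clip((w @ [f1, f2, f3, f4, f5]) / w.sum(), 0.0, 1.0))


def resolve_crossings(forest: OrganForest,
                      cfg: TrackConfig | None = None) -> OrganForest:
    """Iteratively reconnect disconnected chains across root crossings.

    Loop: build the stop x start cost matrix, solve the optimal assignment,
    apply only the matched pair of minimal cost (if admissible), then
    recompute — each new connection informs the next.  Terminates because
    every splice removes one start.
    """
    cfg = cfg or TrackConfig()
    rag = forest.rag
    f = forest.forest

    def _apply(v_stop, v_start):
        for u in list(f.pred[v_start]):  # suspicious head loses its arc
            f.remove_edge(u, v_start)
        p = edge_weight(f.nodes[v_stop]["area"], f.nodes[v_start]["area"],
                        f.nodes[v_stop]["t"], f.nodes[v_start]["t"],
                        f.nodes[v_stop]["centroid"],
                        f.nodes[v_start]["centroid"])
        f.add_edge(v_stop, v_start, weight=p, kind="splice")

    # phase 1: continuations of interrupted primaries, cheapest first.
    # A primary's continuation is distinctive (large, fast, collinear), so
    # committing these connections before the ambiguous lateral matching
    # injects certain knowledge into the system.
    while True:
        prim_stops = [v for v in forest.v_stop()
                      if f.nodes[v]["role"] == "primary"]
        starts = forest.v_start(cfg)
        best: tuple = (math.inf, None)
        for vo in prim_stops:
            for vs in starts:
                if vo == vs or nx.has_path(f, vs, vo):
                    continue
                c = connection_cost(vo, vs, rag, forest, cfg)
                if c < best[0]:
                    best = (c, (vo, vs))
        if best[1] is None or best[0] > cfg.max_connection_cost:
            break
        _apply(*best[1])

    # phase 2: iterated optimal assignment over all remaining stops/starts
    while True:
        starts = forest.v_start(cfg)
        stops = forest.v_stop()
        if not starts or not stops:
            break
        cost = np.full((len(stops), len(starts)), math.inf)
        for i, vo in enumerate(stops):
            for j, vs in enumerate(starts):
                if vo == vs:
                    continue
                if nx.has_path(f, vs, vo):
                    continue  # splicing would close a cycle in the forest
                cost[i, j] = connection_cost(vo, vs, rag, forest, cfg)
        if not np.isfinite(cost).any():
            break
        pairs, _ = solve_assignment(cost)
        if not pairs:
            break
        i, j = min(pairs, key=lambda rc: cost[rc])
        if cost[i, j] > cfg.max_connection_cost:
            break
        v_stop, v_start = stops[i], starts[j]
        for u in list(f.pred[v_start]):  # suspicious emergence loses its arc
            f.remove_edge(u, v_start)
        p = edge_weight(f.nodes[v_stop]["area"], f.nodes[v_start]["area"],
                        f.nodes[v_stop]["t"], f.nodes[v_start]["t"],
                        f.nodes[v_stop]["centroid"],
                        f.nodes[v_start]["centroid"])
        f.add_edge(v_stop, v_start, weight=p, kind="splice")
    return forest


# ---------------------------------------------------------------------------
# artefact rejection
# ---------------------------------------------------------------------------

def made(values) -> float:
    """Scaled median absolute deviation, MADe = 1.483 * MAD."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    return 1.483 * float(np.median(np.abs(values - med)))


def reject_artefact_roots(forest: OrganForest,
                          cfg: TrackConfig | None = None) -> OrganForest:
    """Reject lateral roots whose per-age statistics are extreme outliers.

    For every lateral, cumulative length, step speed and component surface
    are collected per timestep of age (temporal distance from emergence);
    within each age bin the population median and MADe are computed, and any
    root carrying a value outside median +/- made_factor * MADe in any bin
    is removed.  Skipped when fewer than ``min_population`` laterals exist.
    """
    cfg = cfg or TrackConfig()
    g = forest.forest
    chains = [c for c in forest.extract_chains() if c.order == 2]
    if len(chains) < cfg.min_population:
        return forest
    records = []  # (chain_idx, bin, stat_name, value)
    for ci, chain in enumerate(chains):
        verts = chain.vertices
        cents = [np.asarray(g.nodes[v]["centroid"]) for v in verts]
        t0 = g.nodes[verts[0]]["t"]
        cum = 0.0
        for k, v in enumerate(verts):
            age = g.nodes[v]["t"] - t0
            if k > 0:
                step = float(np.hypot(*(cents[k] - cents[k - 1])))
                dt = g.nodes[v]["t"] - g.nodes[verts[k - 1]]["t"]
                cum += step
                records.append((ci, age, "length", cum))
                records.append((ci, age, "speed", step / max(dt, 1)))
            records.append((ci, age, "surface", float(g.nodes[v]["area"])))
    bins: dict[tuple[int, str], list[tuple[int, float]]] = {}
    for ci, age, name, value in records:
        bins.setdefault((age, name), []).append((ci, value))
    rejected: set[int] = set()
    for (_age, _name), entries in bins.items():
        vals = np.array([v for _, v in entries])
        med = float(np.median(vals))
        spread = max(made(vals), cfg.made_epsilon)
        bound = cfg.made_factor * spread
        for ci, v in entries:
            if abs(v - med) > bound:
                rejected.add(ci)
    for ci in rejected:
        forest.remove_chain(chains[ci])
    return forest


def track(S: ApparitionLabelImage, n_plants: int,
          cfg: TrackConfig | None = None) -> OrganForest:
    """Full tracking stage: RAG, primaries, forest, crossings, artefacts."""
    cfg = cfg or TrackConfig()
    rag = build_rag(S)
    extract_primaries(rag, n_plants)
    forest = prune_to_forest(rag)
    resolve_crossings(forest, cfg)
    reject_artefact_roots(forest, cfg)
    return forest
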