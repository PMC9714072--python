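"""Region adjacency graph, spanning forest, crossing resolution, artefacts."""

import math

import networkx as nx
import numpy as np
import pytest

from rhizotrack.config import TrackConfig
from rhizotrack.segment import ApparitionLabelImage
from rhizotrack.track import (OrganForest, TrackError, build_rag,
                              connection_cost, edge_weight,
                              extract_primaries, made, minimum_in_forest,
                              prune_to_forest, reject_artefact_roots,
                              resolve_crossings, solve_assignment, track)
from rhizotrack.validate import (brute_force_assignment,
                                 brute_force_min_forest,
                                 edmonds_oracle_agreement,
                                 hungarian_oracle_agreement, random_dag)


def _label_image(arr):
    return ApparitionLabelImage(np.asarray(arr, dtype=np.int16),
                                int(np.max(arr)), 100.0, 8.0)


class TestEdgeWeight:
    def test_all_terms_vanish(self):
        # equal surfaces, consecutive times, horizontal step
        assert edge_weight(100, 100, 3, 4, (0, 0), (10, 0)) == 0.0

    def test_size_and_downward_terms(self):
        # |100-300|/400 + 0 - 1 for a straight-down step
        assert edge_weight(100, 300, 3, 4, (5, 0), (5, 20)) == \
            pytest.approx(-0.5)

    def test_time_gap_and_upward_terms(self):
        # 0 + (4-1-1... ) t1=1,t2=4 -> 2; straight up -> +1
        assert edge_weight(50, 50, 1, 4, (5, 30), (5, 10)) == pytest.approx(3.0)

    def test_zero_length_vector_drops_direction_term(self):
        assert edge_weight(10, 10, 1, 2, (5, 5), (5, 5)) == 0.0


class TestBuildRag:
    def test_single_component(self):
        img = np.zeros((10, 10))
        img[2:5, 2:5] = 1
        rag = build_rag(_label_image(img))
        assert rag.number_of_vertices() == 1
        assert rag.graph.number_of_edges() == 0

    def test_vertical_chain_is_forward_path(self):
        img = np.zeros((12, 6))
        img[0:4, 2:4] = 1
        img[4:8, 2:4] = 2
        img[8:12, 2:4] = 3
        rag = build_rag(_label_image(img))
        g = rag.graph
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        for u, v in g.edges:
            assert g.nodes[u]["t"] < g.nodes[v]["t"]

    def test_diagonal_touch_makes_no_edge(self):
        img = np.zeros((6, 6))
        img[0:3, 0:3] = 1
        img[3:6, 3:6] = 2   # shares only the corner at (3, 3)
        rag = build_rag(_label_image(img))
        assert rag.graph.number_of_edges() == 0

    def test_acyclic_with_topological_time_order(self, clean_plate,
                                                  plate_config):
        from rhizotrack.segment import segment
        S = segment(clean_plate.stack, plate_config.segmentation)
        rag = build_rag(S)
        assert nx.is_directed_acyclic_graph(rag.graph)


def _chain_image(n_plants=1):
    """One seed + three growth components per plant, vertically stacked."""
    img = np.zeros((40, 12 * n_plants), dtype=np.int16)
    for p in range(n_plants):
        c = 12 * p + 4
        img[0:10, c:c + 3] = 1
        img[10:20, c:c + 3] = 2
        img[20:30, c:c + 3] = 3
        img[30:40, c:c + 3] = 4
    return img


class TestExtractPrimaries:
    def test_linear_chain_fully_primary(self):
        rag = build_rag(_label_image(_chain_image()))
        extract_primaries(rag, 1)
        assert all(rag.graph.nodes[v]["role"] == "primary"
                   for v in rag.graph.nodes)

    def test_floating_component_dropped(self):
        img = _chain_image(2)
        img[2:6, 0:2] = 3   # floating blob touching nothing
        rag = build_rag(_label_image(img))
        extract_primaries(rag, 2)
        cents = [rag.graph.nodes[v]["centroid"] for v in rag.graph.nodes]
        assert all(c[0] > 2 for c in cents), "floating blob survived"

    def test_missing_seed_raises(self):
        rag = build_rag(_label_image(_chain_image(1)))
        with pytest.raises(TrackError, match="seed"):
            extract_primaries(rag, 3)


class TestForestOracles:
    def test_min_forest_matches_exhaustive_enumeration(self, rng):
        for _ in range(60):
            n, edges = random_dag(rng)
            g = nx.DiGraph()
            g.add_nodes_from(range(n), t=0, area=1)
            for u, v, w in edges:
                g.add_edge(u, v, weight=w)
            for v in g.nodes:
                g.nodes[v]["t"] = v
            choice = minimum_in_forest(g)
            total = sum(g[u][v]["weight"] for v, u in choice.items())
            assert total == pytest.approx(brute_force_min_forest(n, edges))

    def test_forest_in_degree_at_most_one(self):
        res = edmonds_oracle_agreement(n_instances=30, seed=5)
        assert res["agreement"] == 1.0


class TestHungarian:
    def test_worked_example(self):
        pairs, total = solve_assignment([[4, 1, 3], [2, 0, 5], [3, 2, 2]])
        assert total == 5

    def test_matches_brute_force(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 6))
            cost = rng.uniform(0, 10, size=(n, n))
            _, total = solve_assignment(cost)
            assert total == pytest.approx(brute_force_assignment(cost))

    def test_rectangular_matrices(self):
        pairs, total = solve_assignment([[1.0, 9.0, 2.0]])
        assert pairs == [(0, 0)] and total == 1.0

    def test_agreement_helper(self):
        res = hungarian_oracle_agreement(n_instances=30, seed=2)
        assert res["agreement"] == 1.0


def _crossed_chain_image(second_labels=(7, 8, 9), reversed_=False):
    """X-cross fixture: root B (vertical, labels 1..4 then 7..9) is crossed
    by root A (horizontal, rooted at a second seed, covering at t=3), which
    splits B's chain during pruning."""
    img = np.zeros((80, 24), dtype=np.int16)
    img[0:8, 12:15] = 1
    img[8:16, 12:15] = 2
    img[16:24, 12:15] = 3
    img[24:32, 12:15] = 4
    img[30:36, 0:3] = 1     # root A's seed at the left edge
    img[32:36, 3:24] = 3    # root A's covered region across B's path
    labels = list(second_labels)
    if reversed_:
        labels = labels[::-1]
    for i, lab in enumerate(labels):
        img[36 + 8 * i:36 + 8 * (i + 1), 12:15] = lab
    return img


def _prepare_forest(img, n_plants=1):
    rag = build_rag(_label_image(img))
    extract_primaries(rag, n_plants)
    return prune_to_forest(rag)


def _stop_start(forest):
    """The primary-path stop and the continuation head of the fixture."""
    g = forest.forest
    stop = next(v for v in forest.v_stop() if g.nodes[v]["t"] == 4
                and g.nodes[v]["role"] == "primary")
    cfg = TrackConfig()
    start = next(v for v in forest.v_start(cfg)
                 if g.nodes[v]["t"] >= 7
                 and g.nodes[v]["centroid"][1] < 50)
    return stop, start


class TestConnectionCost:
    def test_collinear_equal_speed_pair_is_cheap(self):
        forest = _prepare_forest(_crossed_chain_image(), n_plants=2)
        stop, start = _stop_start(forest)
        cost = connection_cost(stop, start, forest.rag, forest,
                               TrackConfig())
        assert cost < 0.25

    def test_antiparallel_directions_cost_more(self):
        forward = _prepare_forest(_crossed_chain_image(), n_plants=2)
        backward = _prepare_forest(_crossed_chain_image(reversed_=True), n_plants=2)
        cfg = TrackConfig()
        c_fwd = connection_cost(*_stop_start(forward), forward.rag,
                                forward, cfg)
        g = backward.forest
        stop = next(v for v in backward.v_stop()
                    if g.nodes[v]["t"] == 4
                    and g.nodes[v]["role"] == "primary")
        # reversed chain grows upward: its head is the bottom component
        start = next(v for v in backward.v_start(cfg)
                     if g.nodes[v]["t"] == 7)
        c_bwd = connection_cost(stop, start, backward.rag, backward, cfg)
        assert c_bwd > c_fwd

    def test_short_support_majors_the_angle_feature(self):
        # a single detached component gives no direction estimate: the
        # angular and speed features take the majoring value 1
        forest = _prepare_forest(_crossed_chain_image(second_labels=(7,)), n_plants=2)
        stop, start = _stop_start(forest)
        cost = connection_cost(stop, start, forest.rag, forest,
                               TrackConfig())
        assert cost > 0.5

    def test_backward_in_time_is_inadmissible(self):
        forest = _prepare_forest(_crossed_chain_image(), n_plants=2)
        stop, start = _stop_start(forest)
        assert connection_cost(start, stop, forest.rag, forest,
                               TrackConfig()) == math.inf


class TestResolveCrossings:
    def test_interrupted_chain_is_spliced_back(self):
        forest = _prepare_forest(_crossed_chain_image(), n_plants=2)
        cfg = TrackConfig()
        resolve_crossings(forest, cfg)
        primaries = [c for c in forest.extract_chains() if c.order == 1]
        assert len(primaries) == 2
        b = max(primaries, key=lambda c: len(c.vertices))
        assert [forest.rag.t(v) for v in b.vertices] == \
            [1, 2, 3, 4, 7, 8, 9]

    def test_fragmented_hidden_root_chained_into_one_organ(self):
        # a root hidden below a primary surfaces as short fragments beside
        # it, each contributing a stop and a start across large temporal
        # gaps; the iterated matching must chain them into one organ
        img = np.zeros((80, 9), dtype=np.int16)
        img[0:20, 2:5] = 1
        img[20:40, 2:5] = 2
        img[40:60, 2:5] = 3
        img[60:80, 2:5] = 4
        img[18:26, 5:8] = 8
        img[26:34, 5:8] = 9
        img[38:46, 5:8] = 11
        img[46:54, 5:8] = 12
        img[58:66, 5:8] = 14
        img[66:74, 5:8] = 15
        forest = _prepare_forest(img)
        resolve_crossings(forest, TrackConfig())
        laterals = [c for c in forest.extract_chains() if c.order == 2]
        assert len(laterals) == 1
        assert [forest.rag.t(v) for v in laterals[0].vertices] == \
            [8, 9, 11, 12, 14, 15]

    def test_forest_invariants_after_resolution(self, clean_plate,
                                                plate_config):
        from rhizotrack.segment import segment
        S = segment(clean_plate.stack, plate_config.segmentation)
        forest = track(S, plate_config.n_plants, plate_config.track)
        f = forest.forest
        assert all(f.in_degree(v) <= 1 for v in f.nodes)
        for v in f.nodes:
            if f.nodes[v]["role"] == "lateral":
                assert f.out_degree(v) <= 1
        assert nx.is_directed_acyclic_graph(f)


class TestArtefactRejection:
    def test_made_chain_on_worked_sample(self):
        sample = list(range(1, 10)) + [100]
        assert np.median(sample) == 5.5
        assert made(sample) == pytest.approx(3.7075)
        bound = 25 * made(sample)
        assert bound == pytest.approx(92.6875)
        assert abs(100 - 5.5) > bound          # the extreme value rejected
        assert abs(60 - 5.5) < bound           # a milder value kept

    def _fake_forest(self, surfaces):
        """Primary of 3 vertices plus one 3-vertex lateral per surface."""
        g = nx.DiGraph()
        vid = 0
        prim = []
        for t in range(1, 4):
            g.add_node(vid, t=t, area=50, centroid=(5.0, 10.0 * t),
                       role="primary", source=(t == 1))
            if prim:
                g.add_edge(prim[-1], vid, weight=0.0, primary_path=True)
            prim.append(vid)
            vid += 1
        for k, surf in enumerate(surfaces):
            prev = None
            for j in range(3):
                g.add_node(vid, t=4 + j, area=surf,
                           centroid=(10.0 + 5 * k + 3 * j, 30.0 + 4 * j),
                           role="lateral")
                if prev is None:
                    g.add_edge(prim[-1], vid, weight=0.5)
                else:
                    g.add_edge(prev, vid, weight=0.1)
                prev = vid
                vid += 1
        return OrganForest(g, rag=None, sources=[prim[0]])

    def test_identical_laterals_none_rejected(self):
        forest = self._fake_forest([20] * 6)
        reject_artefact_roots(forest, TrackConfig())
        assert len([c for c in forest.extract_chains()
                    if c.order == 2]) == 6

    def test_extreme_surface_outlier_rejected(self):
        forest = self._fake_forest([20, 21, 19, 20, 22, 5000])
        reject_artefact_roots(forest, TrackConfig())
        chains = [c for c in forest.extract_chains() if c.order == 2]
        assert len(chains) == 5

    def test_small_population_skips_rejection(self):
        forest = self._fake_forest([20, 5000])
        reject_artefact_roots(forest, TrackConfig())
        assert len([c for c in forest.extract_chains()
                    if c.order == 2]) == 2


def test_forest_dump_restore_round_trip(tmp_path):
    forest = _prepare_forest(_crossed_chain_image(), n_plants=2)
    path = tmp_path / "forest.jsonl"
    forest.dump_jsonl(path)
    g = OrganForest.load_jsonl(path)
    assert set(g.nodes) == set(forest.forest.nodes)
    assert set(g.edges) == set(forest.forest.edges)
    for v in g.nodes:
        assert g.nodes[v]["t"] == forest.forest.nodes[v]["t"]
        assert g.nodes[v]["role"] == forest.forest.nodes[v]["role"]
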