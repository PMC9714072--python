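"""Length/growth phenes, heatmaps and group tests."""

import numpy as np
import pytest
from scipy import stats

from rhizotrack.model import Organ, Plant, RootSystemModel
from rhizotrack.phenes import (count_laterals, elongation_heatmap,
                               growth_between, insertion_depth,
                               mann_whitney_u, per_timestep_group_test,
                               phene_table, root_length_at)


def _model(px_size_um=1000.0):
    """Primary with two laterals; 1000 um/px makes 1 px = 1 mm."""
    primary = Organ(np.array([[10.0, 0.0, 1.0], [10.0, 30.0, 2.0],
                              [10.0, 70.0, 3.0]]), order=1)
    # two segments: 3 mm appearing at t=2, then 4 mm at t=3
    lat = Organ(np.array([[10.0, 20.0, 1.0], [13.0, 20.0, 2.0],
                          [17.0, 20.0, 3.0]]), order=2, parent=0,
                attachment_index=0)
    late = Organ(np.array([[10.0, 50.0, 4.0], [12.0, 50.0, 5.0]]),
                 order=2, parent=0, attachment_index=1)
    return RootSystemModel([Plant([primary, lat, late], (10.0, 0.0))],
                           px_size_um, 8.0, 5)


class TestLength:
    def test_before_first_node_is_zero(self):
        assert root_length_at(_model(), (0, 1), 0.5) == 0.0

    def test_segment_apparition_sums(self):
        m = _model()
        assert root_length_at(m, (0, 1), 2) == pytest.approx(3.0)
        assert root_length_at(m, (0, 1), 3) == pytest.approx(7.0)

    def test_last_observation_gives_total_length(self):
        m = _model()
        organ = m.plants[0].organs[1]
        assert root_length_at(m, (0, 1), m.n_timesteps) == \
            pytest.approx(organ.length_px() * m.px_mm)

    def test_lengths_scale_with_pixel_size(self):
        a = root_length_at(_model(1000.0), (0, 1), 5)
        b = root_length_at(_model(500.0), (0, 1), 5)
        assert a == pytest.approx(2 * b)

    def test_extrapolated_segments_excluded_by_default(self):
        organ = Organ(np.array([[0, 0, 1], [0, 10, 2], [0, 20, 3]]),
                      extrapolated=np.array([False, False, True]))
        m = RootSystemModel([Plant([organ], (0, 0))], 1000.0, 8.0, 3)
        assert root_length_at(m, (0, 0), 3) == pytest.approx(10.0)
        assert root_length_at(m, (0, 0), 3, include_extrapolated=True) == \
            pytest.approx(20.0)

    def test_unknown_organ_raises(self):
        with pytest.raises(KeyError):
            root_length_at(_model(), (0, 9), 2)


class TestGrowth:
    def test_no_new_segments_zero_growth(self):
        assert growth_between(_model(), (0, 1), 3, 5) == pytest.approx(0.0)

    def test_telescoping_sums_to_total(self):
        m = _model()
        for organ in [(0, 0), (0, 1), (0, 2)]:
            total = sum(growth_between(m, organ, t, t + 1)
                        for t in range(1, m.n_timesteps))
            expected = root_length_at(m, organ, m.n_timesteps) \
                - root_length_at(m, organ, 1)
            assert total == pytest.approx(expected)

    def test_growth_non_negative_on_simulated_plate(self, clean_plate):
        m = clean_plate.model
        for ip, io, _o in m.all_organs():
            for t in range(1, m.n_timesteps):
                assert growth_between(m, (ip, io), t, t + 1) >= -1e-9


class TestCounts:
    def test_before_first_emergence(self):
        assert count_laterals(_model(), 1) == 1  # first lateral at t=1
        assert count_laterals(_model(), 0.5) == 0

    def test_total_at_last_observation(self):
        assert count_laterals(_model(), 5) == 2

    def test_simulated_emergence_schedule(self, clean_plate):
        m = clean_plate.model
        for t in range(1, m.n_timesteps + 1):
            expected = sum(1 for _, _, o in m.all_organs()
                           if o.order == 2 and o.t_first <= t)
            assert count_laterals(m, t) == expected


class TestHeatmap:
    def test_single_lateral_constant_rate(self):
        m = _model()
        depth = insertion_depth(m, (0, 1))
        matrix, counts, tip_mean, _sd = elongation_heatmap(
            m, depth_bins_mm=[0, 30, 60], times=[2, 3])
        row = 0 if depth < 30 else 1
        assert counts[row].sum() > 0
        assert np.isnan(matrix[1 - row, 0])    # empty bin flagged, not zero
        assert matrix[row, 0] == pytest.approx(3.0)
        assert matrix[row, 1] == pytest.approx(4.0)
        assert np.all(np.isfinite(tip_mean))

    def test_deterministic(self, clean_plate):
        a = elongation_heatmap(clean_plate.model, [0, 15, 30, 50])
        b = elongation_heatmap(clean_plate.model, [0, 15, 30, 50])
        np.testing.assert_array_equal(a[0], b[0])


class TestGroupTest:
    def test_identical_groups_give_p_one(self):
        g = np.tile([1.0, 2.0, 3.0, 4.0], (1, 1)).T @ np.ones((1, 3))
        p = per_timestep_group_test(g.T, g.T)
        assert np.allclose(p[~np.isnan(p)], 1.0)

    def test_disjoint_support_highly_significant(self, rng):
        a = rng.normal(0.0, 0.5, size=(30, 4))
        b = rng.normal(10.0, 0.5, size=(30, 4))
        p = per_timestep_group_test(a, b)
        assert (p < 0.001).all()

    def test_insufficient_samples_give_nan(self):
        a = np.ones((2, 3))
        b = np.ones((5, 3))
        assert np.isnan(per_timestep_group_test(a, b)).all()

    def test_u_statistic_matches_scipy(self, rng):
        for _ in range(40):
            n1, n2 = rng.integers(2, 9, size=2)
            a = rng.integers(0, 6, size=n1).astype(float)
            b = rng.integers(0, 6, size=n2).astype(float)
            u = mann_whitney_u(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic").statistic
            assert u == pytest.approx(ref)


def test_phene_table_shape_and_monotonicity(clean_plate):
    table = phene_table(clean_plate.model, plate_ids=["p0"])
    n_organs = sum(1 for _ in clean_plate.model.all_organs())
    assert len(table) == n_organs * clean_plate.model.n_timesteps
    for _key, grp in table.groupby(["plant", "organ"]):
        lengths = grp.sort_values("time")["length_mm"].to_numpy()
        assert (np.diff(lengths) >= -1e-9).all()
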