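import math

import numpy as np
import pytest
import shapely
from shapely.geometry import Point, Polygon

import territoria as tt
from territoria.simulate import (
    DEFAULT_TRUE_AREAS,
    DIVISORS_OF_360,
    enumerate_equiangular_subsets,
    generate_fixture_individuals,
    make_virtual_territory,
    pair_trials,
    place_edge_points,
    sample_central_points,
)


class TestVirtualTerritories:
    @pytest.mark.parametrize("shape", sorted(DEFAULT_TRUE_AREAS))
    def test_outer_area_matches_true_area(self, shape):
        t = make_virtual_territory(shape)
        assert t.outer.area == pytest.approx(DEFAULT_TRUE_AREAS[shape], rel=1e-6)
        assert t.true_area == DEFAULT_TRUE_AREAS[shape]
        assert t.outer.contains(t.central)

    def test_circle_radius(self):
        t = make_virtual_territory("circle", 200.04, 0.3)
        r = math.sqrt(200.04 / math.pi)
        minx, miny, maxx, maxy = t.outer.bounds
        assert (maxx - minx) / 2 == pytest.approx(r, rel=1e-3)

    def test_custom_polygon_and_errors(self):
        t = make_virtual_territory(Polygon([(0, 0), (4, 0), (4, 2), (0, 2)]), 10.0)
        assert t.outer.area == pytest.approx(10.0)
        with pytest.raises(Exception):
            make_virtual_territory([(0, 0), (1, 1), (1, 0), (0, 1)], 1.0)  # bowtie
        with pytest.raises(ValueError):
            make_virtual_territory("circle", central_scale=1.5)


class TestCentralPoints:
    def test_containment_and_reproducibility(self):
        t = make_virtual_territory("circle")
        pts = sample_central_points(t, 360, np.random.default_rng(1))
        assert pts.shape == (360, 2)
        assert shapely.contains_xy(t.central, pts[:, 0], pts[:, 1]).all()
        again = sample_central_points(t, 360, np.random.default_rng(1))
        assert np.array_equal(pts, again)

    def test_zero_points(self):
        t = make_virtual_territory("circle")
        assert sample_central_points(t, 0, np.random.default_rng(1)).shape == (0, 2)

    def test_empirical_centroid_converges(self):
        t = make_virtual_territory("circle")
        pts = sample_central_points(t, 10000, np.random.default_rng(1))
        c = t.central.centroid
        r = math.sqrt(t.central.area / math.pi)
        assert np.hypot(*(pts.mean(axis=0) - [c.x, c.y])) < 0.05 * r


class TestEdgePoints:
    def test_circle_one_degree_spacing(self):
        t = make_virtual_territory("circle")
        pts = place_edge_points(t, 360)
        c = t.central.centroid
        bearings = np.degrees(
            np.arctan2(pts[:, 0] - c.x, pts[:, 1] - c.y)
        ) % 360
        spacing = np.diff(np.sort(bearings))
        assert np.allclose(spacing, 1.0, atol=1e-6)

    def test_four_cardinal_points(self):
        t = make_virtual_territory("circle", 200.04)
        pts = place_edge_points(t, 4)
        r = math.sqrt(200.04 / math.pi)
        c = t.central.centroid
        rel = pts - [c.x, c.y]
        # bearings 0/90/180/270 -> +y, +x, -y, -x
        assert np.allclose(rel[0], [0, r], atol=1e-3 * r)
        assert np.allclose(rel[1], [r, 0], atol=1e-3 * r)

    def test_star_points_on_exterior_ring(self):
        t = make_virtual_territory("star")
        pts = place_edge_points(t, 360)
        for p in pts[::20]:
            assert t.outer.exterior.distance(Point(*p)) < 1e-9

    def test_non_divisor_rejected(self):
        t = make_virtual_territory("circle")
        with pytest.raises(ValueError):
            place_edge_points(t, 7)


class TestPairing:
    def test_bijection(self):
        t = make_virtual_territory("circle")
        rng = np.random.default_rng(7)
        centrals = sample_central_points(t, 360, rng)
        edges = place_edge_points(t, 360)
        ts = pair_trials(centrals, edges, rng)
        assert len(ts) == 360
        ends = ts.end_points()
        assert np.unique(ends, axis=0).shape[0] == 360  # each edge used once
        starts = ts.start_points()
        assert np.unique(starts, axis=0).shape[0] == 360
        assert shapely.contains_xy(t.central, starts[:, 0], starts[:, 1]).all()

    def test_single_pair_and_mismatch(self):
        ts = pair_trials([(0.0, 0.0)], [(1.0, 1.0)], np.random.default_rng(0))
        assert len(ts) == 1 and ts.trials[0].end == (1.0, 1.0)
        with pytest.raises(ValueError):
            pair_trials([(0, 0)], [(1, 1), (2, 2)], np.random.default_rng(0))

    def test_different_seeds_differ(self):
        t = make_virtual_territory("circle")
        edges = place_edge_points(t, 360)
        centrals = sample_central_points(t, 360, np.random.default_rng(0))
        a = pair_trials(centrals, edges, np.random.default_rng(1)).start_points()
        b = pair_trials(centrals, edges, np.random.default_rng(2)).start_points()
        assert not np.array_equal(a, b)


class TestEquiangularSubsets:
    def test_single_and_twelve(self):
        assert enumerate_equiangular_subsets(360, 360) == [tuple(range(360))]
        subs = enumerate_equiangular_subsets(360, 12)
        assert len(subs) == 30
        assert all(np.diff(s).tolist() == [30] * 11 for s in subs)

    def test_total_is_810(self):
        assert len(enumerate_equiangular_subsets()) == 810

    def test_partition_per_k(self):
        for k in (2, 12, 90):
            subs = enumerate_equiangular_subsets(360, k)
            flat = sorted(d for s in subs for d in s)
            assert flat == list(range(360))

    def test_nesting_when_k_divides_kprime(self):
        small = set(enumerate_equiangular_subsets(360, 12)[3])
        big = set(enumerate_equiangular_subsets(360, 36)[3])
        assert small <= big

    def test_non_divisor_rejected(self):
        with pytest.raises(ValueError):
            enumerate_equiangular_subsets(360, 7)


class TestFixtureCohort:
    def test_single_individual_directions(self):
        arena = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
        (fi,) = generate_fixture_individuals(1, arena, np.random.default_rng(3))
        dirs = sorted(t.direction for t in fi.trials.trials)
        assert dirs == [float(d) for d in range(0, 360, 30)]

    def test_territories_do_not_overlap(self, fixture_cohort):
        outers = [fi.territory.outer for fi in fixture_cohort]
        assert len(outers) == 15
        for i in range(len(outers)):
            for j in range(i + 1, len(outers)):
                assert outers[i].intersection(outers[j]).area == 0.0

    def test_trial_geometry(self, fixture_cohort):
        for fi in fixture_cohort:
            for t in fi.trials.trials:
                assert fi.territory.central.covers(Point(*t.start))
                if t.responded:
                    assert fi.territory.outer.exterior.distance(Point(*t.end)) < 1e-9

    def test_full_nonresponse(self):
        arena = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
        (fi,) = generate_fixture_individuals(
            1, arena, np.random.default_rng(3), nonresponse_prob=1.0
        )
        assert all(not t.responded and t.end is None for t in fi.trials.trials)

    def test_impossible_placement_raises(self):
        tiny = Polygon([(0, 0), (5, 0), (5, 5), (0, 5)])
        with pytest.raises(RuntimeError):
            generate_fixture_individuals(
                10, tiny, np.random.default_rng(0), max_tries=50
            )
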