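import itertools
import math

import numpy as np
import pytest

from strack.masks import extract_regions
from strack.simulate import ColonyParams, simulate_colony
from strack.tracking import (
    DegenerateDivisionAxisError,
    TrackingConfig,
    candidate_pairs,
    division_angle,
    link_frames,
    track_series,
)

from _instances import random_two_frame_instance
from _oracles import brute_force_angle, oracle_link_frames
from conftest import make_mask, regions_of


def _rod_regions(specs, shape=(100, 100), frame_index=0):
    """Build regions from (label, row_slice, col_slice) rectangle specs."""
    grid = np.zeros(shape, dtype=np.int32)
    for label, rows, cols in specs:
        grid[rows, cols] = label
    return regions_of(grid, frame_index)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [{"max_dist": 0}, {"max_dist": -1},
                                        {"max_angle": 0}, {"max_angle": 91}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrackingConfig(**kwargs)


class TestCandidatePairs:
    def test_distance_cutoff(self):
        mothers = _rod_regions([(1, slice(9, 12), slice(9, 12))])
        daughters = _rod_regions(
            [(1, slice(9, 12), slice(11, 14)), (2, slice(79, 82), slice(79, 82))],
            frame_index=1,
        )
        pairs = candidate_pairs(mothers, daughters, TrackingConfig(max_dist=50))
        assert [p.daughter.label for p in pairs] == [1]

    def test_identical_pixel_sets(self):
        mothers = _rod_regions([(1, slice(5, 10), slice(5, 15))])
        daughters = _rod_regions([(1, slice(5, 10), slice(5, 15))], frame_index=1)
        (pair,) = candidate_pairs(mothers, daughters, TrackingConfig())
        assert pair.overlap_px == mothers[0].area
        assert pair.center_dist == 0.0

    def test_matches_all_pairs_brute_force(self):
        """20 mothers / 25 daughters at random: the pair list equals the
        distance-filtered cross product with independently computed overlaps."""
        rng = np.random.default_rng(7)
        g0 = np.zeros((200, 200), dtype=np.int32)
        g1 = np.zeros((200, 200), dtype=np.int32)
        for grid, n in ((g0, 20), (g1, 25)):
            for label in range(1, n + 1):
                r, c = rng.integers(3, 193, size=2)
                grid[r : r + 4, c : c + 4] = label
        mothers = regions_of(g0)
        daughters = regions_of(g1, 1)
        config = TrackingConfig(max_dist=30)
        got = {
            (p.mother.label, p.daughter.label): (p.overlap_px, p.center_dist)
            for p in candidate_pairs(mothers, daughters, config)
        }
        expected = {}
        for m, d in itertools.product(mothers, daughters):
            dist = math.hypot(m.centroid[0] - d.centroid[0], m.centroid[1] - d.centroid[1])
            if dist <= 30:
                expected[(m.label, d.label)] = (len(m.pixel_set & d.pixel_set), dist)
        assert got.keys() == expected.keys()
        for key in got:
            assert got[key][0] == expected[key][0]
            assert got[key][1] == pytest.approx(expected[key][1])


def _point_region(label, cx, cy, frame_index, orientation=0.0):
    from strack.masks import CellRegion

    return CellRegion(
        frame_index=frame_index,
        label=label,
        pixel_set=frozenset({(int(cy), int(cx))}),
        centroid=(cx, cy),
        area=1,
        orientation_deg=orientation,
    )


class TestDivisionAngle:
    def test_collinear_is_zero(self):
        m = _point_region(1, 15, 10, 0, orientation=0.0)
        a = _point_region(1, 5, 10, 1)
        b = _point_region(2, 25, 10, 1)
        assert division_angle(m, a, b) == pytest.approx(0.0)

    def test_perpendicular_is_ninety(self):
        m = _point_region(1, 10, 15, 0, orientation=0.0)
        a = _point_region(1, 10, 5, 1)
        b = _point_region(2, 10, 25, 1)
        assert division_angle(m, a, b) == pytest.approx(90.0)

    def test_acute_angle_between_undirected_lines(self):
        """Mother at 30 deg vs daughter line at 150 deg -> 60, not 120, and
        the result is symmetric in daughter order and matches a direct
        vector computation."""
        m = _point_region(1, 0, 0, 0, orientation=30.0)
        rad = math.radians(150.0)
        a = _point_region(1, 10 * math.cos(rad), 10 * math.sin(rad), 1)
        b = _point_region(2, -10 * math.cos(rad), -10 * math.sin(rad), 1)
        assert division_angle(m, a, b) == pytest.approx(60.0, abs=1e-9)
        assert division_angle(m, b, a) == pytest.approx(60.0, abs=1e-9)
        assert division_angle(m, a, b) == pytest.approx(
            brute_force_angle(30.0, a.centroid, b.centroid)
        )

    def test_coincident_daughters_degenerate(self):
        m = _point_region(1, 0, 0, 0)
        a = _point_region(1, 3, 3, 1)
        b = _point_region(2, 3, 3, 1)
        with pytest.raises(DegenerateDivisionAxisError, match="degenerate division axis"):
            division_angle(m, a, b)


class TestLinkFrames:
    def test_canonical_division_two_overlap_links(self):
        """A rod splitting along its axis into two abutting halves yields two
        overlap links to the same mother at any max_angle."""
        mothers = _rod_regions([(1, slice(10, 15), slice(10, 40))])
        daughters = _rod_regions(
            [(1, slice(10, 15), slice(10, 24)), (2, slice(10, 15), slice(26, 40))],
            frame_index=1,
        )
        links = link_frames(mothers, daughters, TrackingConfig(max_angle=5))
        assert [l.method for l in links] == ["overlap", "overlap"]
        assert {l.mother for l in links} == {(0, 1)}
        assert {l.daughter for l in links} == {(1, 1), (1, 2)}

    def test_second_daughter_rejected_by_angle(self):
        """With one daughter linked, a third overlapping cell whose division
        axis makes ~90 deg with the mother axis is not linked under
        max_angle=45 and becomes a new track."""
        mothers = _rod_regions([(1, slice(20, 25), slice(10, 40))])  # horizontal
        # daughter 1 re-occupies the mother; daughter 2 overlaps from above so
        # the d1-d2 centroid line makes ~54 deg with the mother axis
        grid = np.zeros((100, 100), dtype=np.int32)
        grid[20:25, 10:40] = 1
        grid[17:22, 22:32] = 2
        daughters = regions_of(grid, 1)
        links = link_frames(mothers, daughters, TrackingConfig(max_angle=45))
        by_daughter = {l.daughter[1]: l for l in links}
        assert by_daughter[1].mother == (0, 1)
        assert by_daughter[2].method == "new-track"
        # a permissive angle accepts the division instead
        links_wide = link_frames(mothers, daughters, TrackingConfig(max_angle=90))
        assert {l.method for l in links_wide} == {"overlap"}

    def test_zero_overlap_goes_to_distance_pass(self):
        mothers = _rod_regions([(1, slice(10, 14), slice(10, 20))])
        daughters = _rod_regions([(1, slice(30, 34), slice(10, 20))], frame_index=1)
        (link,) = link_frames(mothers, daughters, TrackingConfig(max_dist=50))
        assert link.method == "distance"
        assert link.center_dist <= 50

    def test_out_of_range_daughter_is_new_track(self):
        mothers = _rod_regions([(1, slice(10, 14), slice(10, 20))])
        daughters = _rod_regions([(1, slice(80, 84), slice(80, 90))], frame_index=1)
        (link,) = link_frames(mothers, daughters, TrackingConfig(max_dist=30))
        assert link.method == "new-track" and link.mother is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed, default_config):
        """On small random two-frame instances the greedy result equals the
        exhaustive enumeration under the documented priority order."""
        rng = np.random.default_rng(1000 + seed)
        mothers, daughters = random_two_frame_instance(rng)
        config = TrackingConfig(max_dist=30, max_angle=float(rng.choice([30, 45, 60, 90])))
        links = link_frames(mothers, daughters, config)
        got = {l.edge_key for l in links if not l.is_new_track}
        assert got == oracle_link_frames(mothers, daughters, config)


class TestTrackSeries:
    def test_static_scene_all_continuations(self, static_masks, default_config):
        forest = track_series(static_masks, default_config)
        assert all(l.method == "overlap" for l in forest.links if l.daughter[0] > 0)
        assert sum(1 for l in forest.links if l.is_new_track) == 0
        assert len(forest.roots) == 2

    def test_track_ends_when_cell_leaves(self, default_config):
        grids = []
        for t in range(4):
            g = np.zeros((40, 40), dtype=np.int32)
            g[5:8, 5:15] = 1
            if t < 2:
                g[30:33, 20:30] = 2  # disappears after frame 1
            grids.append(g)
        masks = [make_mask(g, t) for t, g in enumerate(grids)]
        forest = track_series(masks, default_config)
        cell2_nodes = [c for c in forest.nodes if forest.nodes[c].area and c[1] == 2]
        assert max(f for f, _ in cell2_nodes) == 1
        assert forest.children((1, 2)) == []

    def test_requires_two_frames(self, static_masks, default_config):
        with pytest.raises(ValueError, match="insufficient frames"):
            track_series(static_masks[:1], default_config)

    def test_recovers_simulated_ground_truth(self, colony_seed1, tracked_seed1):
        assert tracked_seed1.edge_keys == {l.edge_key for l in colony_seed1.links}

    def test_determinism_identical_link_sets(self, colony_seed1, default_config):
        a = track_series(colony_seed1.masks, default_config)
        b = track_series(colony_seed1.masks, default_config)
        assert a.links == b.links
        assert a.track_id == b.track_id

    def test_constraints_hold_on_simulator_output(self, colony_seed1, tracked_seed1, default_config):
        regions = {r.cell: r for m in colony_seed1.masks
                   for r in extract_regions(m, warn_disconnected=False)}
        in_deg = {}
        out_deg = {}
        for link in tracked_seed1.edges:
            in_deg[link.daughter] = in_deg.get(link.daughter, 0) + 1
            out_deg[link.mother] = out_deg.get(link.mother, 0) + 1
            assert link.center_dist <= default_config.max_dist
        assert all(v == 1 for v in in_deg.values())
        assert all(v <= 2 for v in out_deg.values())
        for mother, deg in out_deg.items():
            if deg == 2:
                a, b = tracked_seed1.children(mother)
                ang = division_angle(regions[mother], regions[a], regions[b])
                assert ang < default_config.max_angle

    def test_raising_max_angle_never_loses_divisions(self):
        """On simulator scenes, widening the angle gate cannot reduce the
        number of two-daughter mothers."""
        gt = simulate_colony(ColonyParams(seed=3))
        counts = []
        for max_angle in (20.0, 45.0, 90.0):
            forest = track_series(gt.masks, TrackingConfig(max_angle=max_angle))
            counts.append(forest.n_divisions)
        assert counts == sorted(counts)
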