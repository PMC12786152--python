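import math

import numpy as np
import pytest
from scipy import ndimage

import vesseltort as vt
from vesseltort import tracing as tr
from vesseltort.optic_disc import OpticDisc

from conftest import dijkstra_pixel_count, grid_from_pixels


class TestPixelExtraction:
    def test_line_pixel_count(self):
        skel = grid_from_pixels([(i, 3) for i in range(10)], (8, 15))
        assert len(tr.extract_skeleton_pixels(skel)) == 10

    def test_empty_grid_empty_set(self):
        skel = vt.Skeleton(grid=np.zeros((5, 5), bool))
        assert tr.extract_skeleton_pixels(skel) == set()

    def test_count_conserves_grid_sum(self, radial_phantom):
        skel = vt.skeletonize(radial_phantom.mask)
        assert len(tr.extract_skeleton_pixels(skel)) == int(skel.grid.sum())


class TestDistance:
    def test_three_four_five(self):
        od = OpticDisc(center_xy=(0.0, 0.0), radius_px=1.0)
        assert tr.distance_to_od((3, 4), od) == 5.0

    def test_center_is_zero(self):
        od = OpticDisc(center_xy=(7.0, 9.0), radius_px=1.0)
        assert tr.distance_to_od((7, 9), od) == 0.0

    def test_reflection_symmetry(self):
        od = OpticDisc(center_xy=(10.0, 10.0), radius_px=1.0)
        assert tr.distance_to_od((13, 14), od) == tr.distance_to_od((7, 6), od)


class TestCandidateStarts:
    @pytest.mark.parametrize("dist,kept", [(12, True), (9, False), (16, False), (10, False), (15, True)])
    def test_band_bounds(self, dist, kept):
        od = OpticDisc(center_xy=(0.0, 0.0), radius_px=10.0)
        p = (dist, 0)
        got = tr.candidate_starts({p}, od, delta=5.0)
        assert (p in got) == kept  # strict lower bound, inclusive upper

    def test_negative_delta_rejected(self):
        od = OpticDisc(center_xy=(0.0, 0.0), radius_px=10.0)
        with pytest.raises(ValueError):
            tr.candidate_starts(set(), od, delta=-1.0)


class TestEndpoints:
    def test_straight_chain_has_two(self):
        skel = grid_from_pixels([(i, 5) for i in range(2, 12)], (10, 15))
        assert tr.detect_endpoints(skel) == {(2, 5), (11, 5)}

    def test_y_shape_has_three(self):
        stem = [(5, y) for y in range(0, 5)]
        left = [(5 - i, 4 + i) for i in range(1, 4)]
        right = [(5 + i, 4 + i) for i in range(1, 4)]
        skel = grid_from_pixels(stem + left + right, (10, 12))
        assert tr.detect_endpoints(skel) == {(5, 0), (2, 7), (8, 7)}

    def test_isolated_pixel_is_not_endpoint(self):
        skel = grid_from_pixels([(3, 3)], (6, 6))
        assert tr.detect_endpoints(skel) == set()


class TestValidatePairs:
    def od(self, r=10.0):
        return OpticDisc(center_xy=(0.0, 0.0), radius_px=r)

    def test_single_line_yields_one_pair(self):
        pixels = [(x, 0) for x in range(12, 40)]
        skel = grid_from_pixels(pixels, (50, 50))
        od = self.od()
        starts = tr.candidate_starts(set(pixels), od, 5.0)
        ends = tr.detect_endpoints(skel)
        pairs = tr.validate_pairs(skel, starts, ends, od)
        assert len(pairs) == 1
        assert pairs[0].end_xy == (39, 0)
        assert pairs[0].start_xy in starts

    def test_disconnected_component_yields_none(self):
        pixels = [(x, 30) for x in range(25, 45)]  # never touches the band
        skel = grid_from_pixels(pixels, (50, 50))
        od = self.od()
        starts = tr.candidate_starts(set(pixels), od, 5.0)
        pairs = tr.validate_pairs(skel, starts, tr.detect_endpoints(skel), od)
        assert pairs == []

    def test_path_through_od_interior_is_blocked(self):
        """The only route from the endpoint to the band crosses the disc."""
        od = OpticDisc(center_xy=(25.0, 25.0), radius_px=10.0)
        # a diameter chord: enters the band on the left, crosses the center,
        # exits right and continues to a distal endpoint
        pixels = [(x, 25) for x in range(12, 48)]
        skel = grid_from_pixels(pixels, (50, 60))
        starts = {p for p in tr.candidate_starts(set(pixels), od, 5.0) if p[0] < 25}
        ends = {p for p in tr.detect_endpoints(skel) if p[0] > 25}
        assert starts and ends
        pairs = tr.validate_pairs(skel, starts, ends, od)
        assert pairs == []

    def test_empty_starts_drop_all(self):
        pixels = [(x, 0) for x in range(12, 40)]
        skel = grid_from_pixels(pixels, (50, 50))
        assert tr.validate_pairs(skel, set(), tr.detect_endpoints(skel), self.od()) == []

    def test_retained_endpoints_outside_od(self, radial_phantom):
        od = radial_phantom.od
        skel = vt.skeletonize(
            vt.VesselMask(radial_phantom.class_masks["artery"]), "artery"
        )
        pixels = tr.extract_skeleton_pixels(skel)
        starts = tr.candidate_starts(pixels, od, 5.0)
        pairs = tr.validate_pairs(skel, starts, tr.detect_endpoints(skel), od)
        assert pairs
        for pair in pairs:
            assert tr.distance_to_od(pair.end_xy, od) > od.radius_px
            d = tr.distance_to_od(pair.start_xy, od)
            assert od.radius_px < d <= od.radius_px + 5.0


class TestCurveLength:
    def test_diagonal_chain_counts_pixels(self):
        pixels = [(i, i) for i in range(10)]
        skel = grid_from_pixels(pixels, (12, 12))
        tp = tr.curve_length(skel, tr.PathPair((0, 0), (9, 9)))
        assert tp.l_curve == 10
        assert tp.pixels[0] == (0, 0) and tp.pixels[-1] == (9, 9)

    def test_l_shape_cuts_the_corner(self):
        # two 5-px arms sharing the corner pixel (4,0); the 8-connected
        # shortest path steps (3,0) -> (4,1) diagonally, skipping the
        # corner, as the Dijkstra oracle confirms
        arm1 = [(x, 0) for x in range(5)]
        arm2 = [(4, y) for y in range(1, 5)]
        skel = grid_from_pixels(arm1 + arm2, (8, 8))
        tp = tr.curve_length(skel, tr.PathPair((0, 0), (4, 4)))
        assert tp.l_curve == dijkstra_pixel_count(skel.grid, (0, 0), (4, 4)) == 8
        assert (4, 0) not in tp.pixels

    def test_off_skeleton_pair_rejected(self):
        skel = grid_from_pixels([(1, 1)], (4, 4))
        with pytest.raises(ValueError):
            tr.curve_length(skel, tr.PathPair((1, 1), (3, 3)))

    def test_unreachable_pair_flagged_missing(self):
        skel = grid_from_pixels([(0, 0), (5, 5)], (8, 8))
        tp = tr.curve_length(skel, tr.PathPair((0, 0), (5, 5)))
        assert tp.l_curve is None and tp.pixels == []

    def test_matches_dijkstra_oracle_on_random_skeletons(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 50:
            m = ndimage.gaussian_filter(rng.standard_normal((40, 40)), 2.5) > 0.15
            skel = vt.skeletonize(vt.VesselMask(m))
            if skel.grid.sum() == 0 or skel.grid.sum() > 500:
                continue
            lbl, n = ndimage.label(skel.grid, np.ones((3, 3)))
            comp = lbl == (1 + np.argmax(ndimage.sum_labels(skel.grid, lbl, range(1, n + 1))))
            coords = np.argwhere(comp)
            if len(coords) < 5:
                continue
            (r1, c1), (r2, c2) = coords[0], coords[-1]
            tp = tr.curve_length(vt.Skeleton(grid=skel.grid), tr.PathPair((c1, r1), (c2, r2)))
            assert tp.l_curve == dijkstra_pixel_count(skel.grid, (c1, r1), (c2, r2))
            checked += 1

    def test_deterministic_paths(self):
        from conftest import skeleton_of

        spec = vt.VesselSpec(
            "vein", "sinusoid",
            {"p0": (20, 150), "angle_deg": 10, "length": 180,
             "amplitude": 4, "wavelength": 70},
        )
        skel = skeleton_of(spec)
        ends = sorted(tr.detect_endpoints(skel))
        pair = tr.PathPair(ends[0], ends[-1])
        p1 = tr.curve_length(skel, pair)
        p2 = tr.curve_length(skel, pair)
        assert p1.pixels == p2.pixels and p1.l_curve == p2.l_curve

    def test_traced_path_invariants(self, radial_phantom):
        """8-adjacency of consecutive pixels, endpoint match, step bound."""
        od = radial_phantom.od
        for cls in ("artery", "vein"):
            skel = vt.skeletonize(vt.VesselMask(radial_phantom.class_masks[cls]), cls)
            pixels = tr.extract_skeleton_pixels(skel)
            starts = tr.candidate_starts(pixels, od, 5.0)
            pairs = tr.validate_pairs(skel, starts, tr.detect_endpoints(skel), od)
            assert pairs
            for pair in pairs:
                tp = tr.curve_length(skel, pair)
                assert tp.pixels[0] == pair.start_xy and tp.pixels[-1] == pair.end_xy
                for (x1, y1), (x2, y2) in zip(tp.pixels, tp.pixels[1:]):
                    assert max(abs(x1 - x2), abs(y1 - y2)) == 1
                assert tp.l_straight <= math.ceil(math.sqrt(2) * (tp.l_curve - 1))


class TestStraightLength:
    @pytest.mark.parametrize(
        "a,b,expected", [((0, 0), (3, 4), 5), ((0, 0), (9, 0), 9), ((0, 0), (1, 1), 1)]
    )
    def test_rounded_euclidean(self, a, b, expected):
        assert tr.straight_length(tr.PathPair(a, b)) == expected

    def test_coincident_points_zero(self):
        assert tr.straight_length(tr.PathPair((2, 2), (2, 2))) == 0


class TestPairTables:
    def test_round_trip_csv_and_xlsx(self, tmp_path):
        pairs = [
            tr.PathPair((3, 4), (50, 61), "artery"),
            tr.PathPair((7, 8), (90, 12), "vein"),
        ]
        for name in ("pairs.csv", "pairs.xlsx"):
            path = tmp_path / name
            tr.write_pair_table(pairs, path)
            assert tr.read_pair_table(path) == pairs

    def test_parse_rejects_garbage(self):
        from vesseltort.tracing import _parse_point

        with pytest.raises(ValueError):
            _parse_point("not a point")
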