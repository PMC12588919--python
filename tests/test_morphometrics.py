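import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampelqtl.exceptions import (
    FormatError,
    GeometryError,
    InconsistentGeometryError,
    InvalidCoordinateError,
    UndefinedRatioError,
)
from ampelqtl.morphometrics import (
    LandmarkSet,
    PolygonConfig,
    TRAIT_NAMES,
    compute_traits,
    euclidean_distance,
    leaf_areas,
    qc_landmarks,
    read_landmarks,
    shape_ratios,
    shoelace_area,
    traits_table,
    vein_lengths,
    write_landmarks,
)

from conftest import LEAF_A_EXPECTED, LEAF_A_POINTS, make_leaf


class TestEuclideanDistance:
    @pytest.mark.parametrize(
        "p,q,expected",
        [
            ((0, 0), (3, 4), 5.0),
            ((2.5, -1), (2.5, -1), 0.0),
            ((1, 1), (4, 5), 5.0),
        ],
    )
    def test_known_distances(self, p, q, expected):
        assert euclidean_distance(p, q) == pytest.approx(expected)
        assert euclidean_distance(q, p) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidCoordinateError):
            euclidean_distance((np.nan, 0), (1, 1))
        with pytest.raises(InvalidCoordinateError):
            euclidean_distance((0, 0), (np.inf, 1))


class TestShoelace:
    @pytest.mark.parametrize(
        "vertices,expected",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
            ([(0, 0), (4, 0), (0, 3)], 6.0),
            ([(0, 0), (1, 1), (2, 2)], 0.0),
        ],
    )
    def test_known_areas(self, vertices, expected):
        assert shoelace_area(vertices) == pytest.approx(expected)

    def test_too_few_vertices(self):
        with pytest.raises(GeometryError):
            shoelace_area([(0, 0), (1, 1)])

    @given(
        st.integers(min_value=0, max_value=10_000),
        st.integers(min_value=3, max_value=12),
    )
    @settings(max_examples=60, deadline=None)
    def test_rotation_and_reversal_invariance(self, seed, n):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n, 2))
        base = shoelace_area(v)
        k = int(rng.integers(0, n))
        assert shoelace_area(np.roll(v, k, axis=0)) == pytest.approx(base, rel=1e-12, abs=1e-12)
        assert shoelace_area(v[::-1]) == pytest.approx(base, rel=1e-12, abs=1e-12)

    def test_matches_triangulation_oracle_on_star_polygons(self):
        """Fan triangulation from the star centre is an independent oracle."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(5, 30))
            # angular gaps < pi so the centre is inside the polygon and
            # the fan triangles tile it without overlap
            gaps = rng.uniform(0.5, 1.0, size=n)
            ang = np.cumsum(gaps) / gaps.sum() * 2 * np.pi
            rad = rng.uniform(0.5, 3.0, size=n)
            v = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
            fan = 0.0
            for i in range(n):
                a, b = v[i], v[(i + 1) % n]
                fan += 0.5 * abs(a[0] * b[1] - b[0] * a[1])
            assert shoelace_area(v) == pytest.approx(fan, rel=1e-9)


class TestVeinLengths:
    def test_leaf_a_frozen_values(self, leaf_a):
        lengths = vein_lengths(leaf_a)
        for key in ("L1", "L2", "L3", "L4", "L5"):
            assert lengths[key] == pytest.approx(LEAF_A_EXPECTED[key], rel=1e-12)

    def test_midvein_length_from_constructed_midpoint(self):
        pts = LEAF_A_POINTS.copy()
        pts[2] = (-1.0, 0.0)  # P3
        pts[3] = (1.0, 0.0)   # P4 -> midpoint (0, 0)
        pts[20] = (0.0, 10.0)  # P21
        leaf = make_leaf(pts)
        assert vein_lengths(leaf)["L1"] == pytest.approx(10.0)

    def test_xvii_length_three_four_five(self):
        pts = LEAF_A_POINTS.copy()
        pts[1] = (0.0, 0.0)   # P2
        pts[16] = (6.0, 8.0)  # P17
        leaf = make_leaf(pts)
        assert vein_lengths(leaf)["L3"] == pytest.approx(10.0)

    def test_degenerate_leaf_rejected(self):
        leaf = make_leaf(np.zeros((21, 2)) + 1.0)
        with pytest.raises(GeometryError):
            vein_lengths(leaf)


def _rectangle_config_leaf():
    """10x10 boundary square with three 1 x 0.1 vein rectangles inside."""
    pts = np.zeros((21, 2))
    pts[13] = (0, 0)
    pts[14] = (10, 0)
    pts[15] = (10, 10)
    pts[16] = (0, 10)  # boundary corners at landmarks 14..17
    rects = {
        (1, 2, 3, 4): [(1, 1), (2, 1), (2, 1.1), (1, 1.1)],
        (5, 6, 7, 8): [(3, 1), (4, 1), (4, 1.1), (3, 1.1)],
        (9, 10, 11, 12): [(5, 1), (6, 1), (6, 1.1), (5, 1.1)],
    }
    for cyc, corners in rects.items():
        for idx, xy in zip(cyc, corners):
            pts[idx - 1] = xy
    # remaining landmarks: distinct filler points inside the square
    pts[12] = (7, 7)
    pts[17] = (8, 7)
    pts[18] = (7, 8)
    pts[19] = (8, 8)
    pts[20] = (9, 9)
    cfg = PolygonConfig(
        boundary_cycle=(14, 15, 16, 17),
        mid_vein_cycle=(1, 2, 3, 4),
        prox_vein_cycle=(5, 6, 7, 8),
        dist_vein_cycle=(9, 10, 11, 12),
        sinus_pair=(14, 15),
    )
    return make_leaf(pts), cfg


class TestLeafAreas:
    def test_constructed_rectangles(self):
        leaf, cfg = _rectangle_config_leaf()
        areas = leaf_areas(leaf, cfg)
        assert areas["total_area"] == pytest.approx(100.0)
        assert areas["vein_area"] == pytest.approx(0.3)
        assert areas["blade_area"] == pytest.approx(99.7)

    def test_scaling_homogeneity(self, leaf_a):
        base = leaf_areas(leaf_a)
        k = 2.7
        scaled = leaf_areas(make_leaf(LEAF_A_POINTS * k))
        for key, value in base.items():
            assert scaled[key] == pytest.approx(value * k**2, rel=1e-12)

    def test_leaf_a_matches_polygon_library_oracle(self, leaf_a):
        from shapely.geometry import Polygon

        cfg = PolygonConfig()
        areas = leaf_areas(leaf_a, cfg)
        for key, cycle in [
            ("total_area", cfg.boundary_cycle),
            ("mid_vein_area", cfg.mid_vein_cycle),
            ("prox_vein_area", cfg.prox_vein_cycle),
            ("dist_vein_area", cfg.dist_vein_cycle),
        ]:
            oracle = Polygon([leaf_a.point(i) for i in cycle]).area
            assert areas[key] == pytest.approx(oracle, rel=1e-12)
            assert areas[key] == pytest.approx(LEAF_A_EXPECTED[key], rel=1e-12)

    def test_vein_exceeding_boundary_rejected(self, leaf_a):
        pts = LEAF_A_POINTS.copy()
        # blow the midvein polygon up far beyond the blade
        for idx in (2, 3, 10, 11, 12):
            pts[idx] = pts[idx] * 40
        with pytest.raises(InconsistentGeometryError):
            leaf_areas(make_leaf(pts))


class TestShapeRatios:
    def test_log_of_equal_areas_is_zero(self):
        lengths = {"L1": 2.0, "L2": 1.0, "L3": 1.0, "L4": 1.0, "L5": 1.0}
        areas = {"vein_area": 5.0, "blade_area": 5.0, "total_area": 10.0}
        assert shape_ratios(lengths, areas)["veins_to_blade"] == pytest.approx(0.0)

    def test_equal_lengths_unit_ratio(self):
        lengths = {"L1": 2.0, "L2": 3.0, "L3": 1.0, "L4": 3.0, "L5": 2.0}
        areas = {"vein_area": 1.0, "blade_area": 9.0, "total_area": 100.0}
        r = shape_ratios(lengths, areas)
        assert r["prox_to_dist"] == pytest.approx(1.0)
        assert r["petiolar_sinus_to_area"] == pytest.approx(0.02)

    def test_zero_denominator_names_trait(self):
        lengths = {"L1": 0.0, "L2": 1.0, "L3": 1.0, "L4": 1.0, "L5": 1.0}
        areas = {"vein_area": 1.0, "blade_area": 1.0, "total_area": 1.0}
        with pytest.raises(UndefinedRatioError, match="prox_to_mid|dist_to_mid|xvii_to_mid"):
            shape_ratios(lengths, areas)


def _rigid_transform(points, angle, translation):
    c, s = math.cos(angle), math.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return points @ R.T + np.asarray(translation)


class TestComputeTraits:
    def test_sixteen_named_traits(self, leaf_a):
        traits = compute_traits(leaf_a)
        series = traits.as_series()
        assert tuple(series.index) == TRAIT_NAMES
        assert len(series) == 16
        assert np.isfinite(series.to_numpy()).all()

    def test_leaf_a_full_vector_matches_oracle(self, leaf_a):
        t = compute_traits(leaf_a).as_dict()
        expected = {
            "mid_vein_length": LEAF_A_EXPECTED["L1"],
            "prox_vein_length": LEAF_A_EXPECTED["L4"],
            "dist_vein_length": LEAF_A_EXPECTED["L2"],
            "xvii_vein_length": LEAF_A_EXPECTED["L3"],
            **{k: LEAF_A_EXPECTED[k] for k in (
                "total_area", "blade_area", "vein_area", "mid_vein_area",
                "prox_vein_area", "dist_vein_area", "veins_to_blade",
                "prox_to_dist", "prox_to_mid", "dist_to_mid", "xvii_to_mid",
                "petiolar_sinus_to_area",
            )},
        }
        for key, value in expected.items():
            assert t[key] == pytest.approx(value, rel=1e-10), key

    def test_additivity_identities_exact(self, leaf_a):
        t = compute_traits(leaf_a)
        assert t.vein_area == t.mid_vein_area + t.prox_vein_area + t.dist_vein_area
        assert t.blade_area == t.total_area - t.vein_area

    def test_dimensional_analysis_under_scaling(self, leaf_a):
        k = 3.0
        base = compute_traits(leaf_a).as_dict()
        scaled = compute_traits(make_leaf(LEAF_A_POINTS * k)).as_dict()
        lengths = ["mid_vein_length", "prox_vein_length", "dist_vein_length", "xvii_vein_length"]
        areas = ["total_area", "blade_area", "vein_area", "mid_vein_area",
                 "prox_vein_area", "dist_vein_area"]
        invariant = ["veins_to_blade", "prox_to_dist", "prox_to_mid", "dist_to_mid", "xvii_to_mid"]
        for key in lengths:
            assert scaled[key] == pytest.approx(base[key] * k, rel=1e-12)
        for key in areas:
            assert scaled[key] == pytest.approx(base[key] * k**2, rel=1e-12)
        for key in invariant:
            assert scaled[key] == pytest.approx(base[key], rel=1e-12)
        assert scaled["petiolar_sinus_to_area"] == pytest.approx(
            base["petiolar_sinus_to_area"] / k, rel=1e-12
        )

    @pytest.mark.parametrize("angle,shift", [(0.3, (2, -1)), (2.1, (-10, 4)), (-1.2, (0, 0))])
    def test_rigid_motion_invariance(self, leaf_a, angle, shift):
        base = compute_traits(leaf_a).as_series()
        moved = make_leaf(_rigid_transform(LEAF_A_POINTS, angle, shift))
        got = compute_traits(moved).as_series()
        np.testing.assert_allclose(got.to_numpy(), base.to_numpy(), rtol=1e-9, atol=1e-9)

    def test_reflection_invariance(self, leaf_a):
        base = compute_traits(leaf_a).as_series()
        mirrored = make_leaf(LEAF_A_POINTS * np.array([-1.0, 1.0]))
        got = compute_traits(mirrored).as_series()
        np.testing.assert_allclose(got.to_numpy(), base.to_numpy(), rtol=1e-9, atol=1e-9)

    def test_error_carries_leaf_id(self):
        with pytest.raises(GeometryError, match="bad_leaf"):
            compute_traits(make_leaf(np.ones((21, 2)), leaf_id="bad_leaf"))


class TestQcLandmarks:
    def test_clean_fixture_has_no_flags(self, leaf_a):
        assert qc_landmarks(leaf_a) == []

    def test_tip_moved_inside_flags(self):
        pts = LEAF_A_POINTS.copy()
        pts[20] = (-1.0, 3.0)  # P21 pulled into the blade
        flags = qc_landmarks(make_leaf(pts))
        assert "tip-not-distal" in flags

    def test_duplicate_coordinates_flagged(self):
        pts = LEAF_A_POINTS.copy()
        pts[4] = pts[5]
        assert "duplicate-coordinate" in qc_landmarks(make_leaf(pts))

    def test_boundary_self_intersection_flagged(self):
        pts = LEAF_A_POINTS.copy()
        pts[14], pts[16] = pts[16].copy(), pts[14].copy()  # swap P15 and P17
        assert "boundary-self-intersection" in qc_landmarks(make_leaf(pts))

    def test_overlong_vein_flagged(self, leaf_a):
        flags = qc_landmarks(leaf_a, max_vein_to_diameter=0.3)
        assert any(f.startswith("vein-too-long") for f in flags)


class TestLandmarkIO:
    def test_roundtrip(self, tmp_path, leaf_a):
        path = tmp_path / "landmarks.csv"
        write_landmarks([leaf_a], path, header_comment="fixture")
        back = read_landmarks(path)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].points, leaf_a.points)
        assert back[0].leaf_id == "leaf_A"

    def test_missing_landmark_columns_rejected(self, tmp_path, leaf_a):
        path = tmp_path / "landmarks.csv"
        write_landmarks([leaf_a], path)
        text = path.read_text().splitlines()
        header = text[0].split(",")
        drop = header.index("x21")
        truncated = "\n".join(
            ",".join(v for i, v in enumerate(line.split(",")) if i not in (drop, drop + 1))
            for line in text
        )
        bad = tmp_path / "bad.csv"
        bad.write_text(truncated)
        with pytest.raises(FormatError, match="x21"):
            read_landmarks(bad)

    def test_collect_mode_reports_bad_rows(self, tmp_path, leaf_a):
        path = tmp_path / "landmarks.csv"
        write_landmarks([leaf_a, leaf_a], path)
        lines = path.read_text().splitlines()
        parts = lines[2].split(",")
        parts[6] = "not-a-number"
        lines[2] = ",".join(parts)
        path.write_text("\n".join(lines))
        leaves, failures = read_landmarks(path, on_bad="collect")
        assert len(leaves) == 1
        assert len(failures) == 1

    def test_scale_applied(self, tmp_path, leaf_a):
        path = tmp_path / "landmarks.csv"
        write_landmarks([leaf_a], path)
        back = read_landmarks(path, scale=2.0)
        np.testing.assert_allclose(back[0].points, leaf_a.points * 2.0)


def test_traits_table_shape(leaf_a):
    table = traits_table([leaf_a, make_leaf(LEAF_A_POINTS * 1.1, leaf_id="b")], qc=True)
    assert len(table) == 2
    assert set(TRAIT_NAMES).issubset(table.columns)
    assert (table["qc_flags"] == "").all()
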