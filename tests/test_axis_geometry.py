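import numpy as np
import pandas as pd
import pytest
import scipy.stats

from embryoaxis import (
    EmbryoAxis,
    EmbryoGeometry,
    SyntheticGeometryParams,
    align_profiles,
    angular_profile,
    bias_test,
    cell_angle,
    exhaustive_bias_test,
    fit_axis,
    marker_domain_distance,
    marker_fraction,
    reference_direction,
    simulate_geometry,
)
from embryoaxis.axis_geometry import (
    BIN_EDGES,
    DegenerateGeometryError,
    InsufficientCellsError,
)


def make_geometry(epi_points, hyp_points, cer1=None, psmad=None):
    pts = np.vstack([epi_points, hyp_points])
    n_epi = len(epi_points)
    n = len(pts)
    cer1_col = np.zeros(n, dtype=bool)
    if cer1 is not None:
        cer1_col[n_epi:] = cer1
    psmad_col = np.zeros(n, dtype=bool)
    if psmad is not None:
        psmad_col[:n_epi] = psmad
    return EmbryoGeometry(
        pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "x_um": pts[:, 0],
                "y_um": pts[:, 1],
                "z_um": pts[:, 2],
                "lineage": ["EPI"] * n_epi + ["HYP"] * (n - n_epi),
                "CER1": cer1_col,
                "GATA6": [False] * n_epi + [True] * (n - n_epi),
                "OCT4": [True] * n_epi + [False] * (n - n_epi),
                "LEFTY1": False,
                "pSMAD15": psmad_col,
                "embryo_id": "E1",
                "stage_dpf": 9,
            }
        )
    )


def tetra(centre):
    """Four points whose centroid is exactly `centre`."""
    offsets = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    return np.asarray(centre) + offsets


class TestFitAxis:
    def test_closed_form_centroids(self):
        g = make_geometry(tetra([0, 0, 0]), tetra([0, 0, 10]))
        axis = fit_axis(g)
        np.testing.assert_allclose(axis.origin, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(axis.distal, [0, 0, 1], atol=1e-12)

    def test_translation_equivariance(self):
        g = make_geometry(tetra([0, 0, 0]), tetra([0, 0, 10]))
        t = np.array([5.0, -3.0, 2.0])
        shifted = g.transformed(np.eye(3), t)
        axis = fit_axis(shifted)
        np.testing.assert_allclose(axis.origin, t, atol=1e-12)
        np.testing.assert_allclose(axis.distal, [0, 0, 1], atol=1e-12)

    def test_coincident_centroids_are_degenerate(self):
        g = make_geometry(tetra([0, 0, 0]), tetra([0, 0, 0]))
        with pytest.raises(DegenerateGeometryError):
            fit_axis(g)

    def test_requires_three_cells_per_lineage(self):
        g = make_geometry(tetra([0, 0, 0])[:2], tetra([0, 0, 10]))
        with pytest.raises(InsufficientCellsError):
            fit_axis(g)


class TestReferenceDirection:
    def test_majority_side_sets_lateral(self):
        hyp = np.array([[10, 0, 5], [10, 0, 6], [10, 0, 7], [-10, 0, 5]], dtype=float)
        g = make_geometry(tetra([0, 0, -5]), hyp, cer1=[True, True, True, False])
        axis = EmbryoAxis(origin=[0, 0, 0], distal=[0, 0, 1])
        axis = reference_direction(g, axis)
        assert axis.lateral is not None
        np.testing.assert_allclose(axis.lateral, [1, 0, 0], atol=1e-12)

    def test_opposed_markers_are_degenerate(self):
        hyp = np.array([[10, 0, 5], [-10, 0, 5], [0, 10, 5], [0, -10, 5]], dtype=float)
        g = make_geometry(tetra([0, 0, -5]), hyp, cer1=[True, True, False, False])
        axis = EmbryoAxis(origin=[0, 0, 0], distal=[0, 0, 1])
        with pytest.raises(DegenerateGeometryError, match="degenerate reference"):
            reference_direction(g, axis)

    def test_no_marker_cells_is_an_error(self):
        g = make_geometry(tetra([0, 0, -5]), tetra([0, 0, 5]), cer1=[False] * 4)
        with pytest.raises(DegenerateGeometryError, match="reference undefined"):
            reference_direction(g, fit_axis(g))

    def test_recovers_planted_anterior_direction(self):
        """With strong concentration the data-driven 0-degree side lands close
        to the planted anterior direction in most simulations."""
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            g = simulate_geometry(
                SyntheticGeometryParams(
                    seed=5000 + i,
                    n_hypoblast=60,
                    marker_fraction=0.3,
                    concentration_kappa=4.0,
                )
            )
            axis = reference_direction(g, fit_axis(g))
            lateral_true = np.array([1.0, 0.0, 0.0])
            planted = lateral_true - (lateral_true @ axis.distal) * axis.distal
            planted /= np.linalg.norm(planted)
            ang = np.degrees(np.arccos(np.clip(axis.lateral @ planted, -1, 1)))
            hits += ang < 30
        assert hits / n_rep >= 0.9


class TestCellAngle:
    @pytest.fixture
    def axis(self):
        return EmbryoAxis(origin=[0, 0, 0], distal=[0, 0, 1], lateral=[1, 0, 0])

    @pytest.mark.parametrize(
        "point, expected",
        [((5, 0, 0), 0.0), ((0, 0, 7), 90.0), ((0, 3, 0), 90.0), ((-2, 0, 0), 180.0)],
    )
    def test_landmarks(self, axis, point, expected):
        assert cell_angle(np.array(point, dtype=float), axis) == pytest.approx(expected)

    def test_origin_is_undefined(self, axis):
        with pytest.raises(DegenerateGeometryError):
            cell_angle(np.zeros(3), axis)

    def test_rigid_motion_invariance(self, axis):
        rng = np.random.default_rng(4)
        rot = scipy.stats.special_ortho_group.rvs(3, random_state=rng)
        t = rng.normal(size=3)
        for _ in range(50):
            p = rng.normal(size=3) * 20
            moved_axis = EmbryoAxis(
                origin=rot @ axis.origin + t,
                distal=rot @ axis.distal,
                lateral=rot @ axis.lateral,
            )
            assert cell_angle(rot @ p + t, moved_axis) == pytest.approx(
                cell_angle(p, axis), abs=1e-9
            )

    def test_mirror_symmetry_through_axis_plane(self, axis):
        """Reflecting through the plane spanned by distal and lateral leaves
        every angle unchanged."""
        rng = np.random.default_rng(9)
        mirror = np.diag([1.0, -1.0, 1.0])
        for _ in range(50):
            p = rng.normal(size=3) * 10
            assert cell_angle(mirror @ p, axis) == pytest.approx(cell_angle(p, axis))


class TestAngularProfile:
    def test_three_landmark_cells(self):
        hyp = np.array([[10, 0, 0], [0, 0, 10], [-10, 0, 0]], dtype=float)
        g = make_geometry(tetra([0, 0, -5]) * 0.001, hyp, cer1=[True] * 3)
        axis = EmbryoAxis(origin=[0, 0, 0], distal=[0, 0, 1], lateral=[1, 0, 0])
        prof = angular_profile(g, axis, n_perm=10, seed=0)
        assert prof.mean_angle == pytest.approx(90.0)
        expected = np.zeros(18, dtype=int)
        expected[0] = expected[9] = expected[17] = 1
        assert prof.bin_counts.tolist() == expected.tolist()

    def test_histogram_matches_bruteforce_binning(self):
        g = simulate_geometry(
            SyntheticGeometryParams(seed=6, n_hypoblast=500, marker_fraction=0.5)
        )
        axis = reference_direction(g, fit_axis(g))
        prof = angular_profile(g, axis, n_perm=10, seed=0)
        brute = np.zeros(18, dtype=int)
        for a in prof.angles:
            idx = min(int(a // 10), 17)
            brute[idx] += 1
        assert prof.bin_counts.tolist() == brute.tolist()
        assert prof.bin_counts.sum() == prof.n_marker_pos
        assert np.array_equal(prof.bin_edges, BIN_EDGES)


class TestBiasTest:
    def test_extreme_separation_is_significant(self):
        rng = np.random.default_rng(1)
        angles = rng.uniform(0, 2 * np.pi, size=20)
        spread = np.column_stack(
            [10 * np.cos(angles), 10 * np.sin(angles), rng.uniform(2, 8, 20)]
        )
        clustered = np.tile([10.0, 0.0, 5.0], (20, 1)) + rng.normal(0, 0.1, (20, 3))
        g = make_geometry(
            tetra([0, 0, -5]), np.vstack([clustered, spread]),
            cer1=[True] * 20 + [False] * 20,
        )
        p = bias_test(g, fit_axis(g), n_perm=2000, seed=0)
        assert p <= 0.01

    def test_all_positive_cells_give_p_one(self):
        g = make_geometry(tetra([0, 0, -5]), tetra([0, 0, 5]) + [0, 0, 3], cer1=[True] * 4)
        assert bias_test(g, fit_axis(g), n_perm=100, seed=0) == 1.0

    def test_too_few_cells_is_undefined(self):
        g = make_geometry(
            tetra([0, 0, -5]), tetra([0, 0, 5]) + [0, 0, 3], cer1=[True, True, False, False]
        )
        with pytest.raises(InsufficientCellsError):
            bias_test(g, fit_axis(g), n_perm=100, seed=0)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        for i in range(5):
            g = simulate_geometry(
                SyntheticGeometryParams(
                    seed=40 + i, n_hypoblast=8, marker_fraction=0.5, concentration_kappa=1.0
                )
            )
            axis = fit_axis(g)
            p_exact = exhaustive_bias_test(g, axis)
            p_mc = bias_test(g, axis, n_perm=10_000, seed=i)
            assert abs(p_mc - p_exact) < 0.02


class TestAlignProfiles:
    def test_pooling_is_additive_and_conserving(self):
        profs = []
        for i in range(2):
            g = simulate_geometry(
                SyntheticGeometryParams(seed=60 + i, n_hypoblast=40, marker_fraction=0.4,
                                        embryo_id=f"E{i}")
            )
            axis = reference_direction(g, fit_axis(g))
            profs.append(angular_profile(g, axis, n_perm=50, seed=i))
        pooled, table = align_profiles(profs)
        assert pooled.tolist() == (profs[0].bin_counts + profs[1].bin_counts).tolist()
        assert pooled.sum() == table["n_marker_pos"].sum()
        assert list(table["embryo_id"]) == ["E0", "E1"]


class TestMarkerFraction:
    def test_simple_ratio(self):
        g = simulate_geometry(
            SyntheticGeometryParams(seed=3, n_hypoblast=20, marker_fraction=0.25)
        )
        assert marker_fraction(g) == pytest.approx(5 / 20)

    def test_empty_denominator_is_undefined(self):
        g = make_geometry(tetra([0, 0, -5]), tetra([0, 0, 5]))
        with pytest.raises(InsufficientCellsError):
            marker_fraction(g, lineage="STB")


class TestMarkerDomainDistance:
    def test_single_pair_distance(self):
        g = make_geometry(
            np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], dtype=float),
            np.array([[10, 0, 0], [11, 0, 0], [12, 0, 0]], dtype=float),
            cer1=[True, False, False],
            psmad=[True, False, False],
        )
        res = marker_domain_distance(g)
        assert res["distances_pos"][0] == pytest.approx(10.0)

    def test_rigid_rotation_invariance(self):
        g = simulate_geometry(
            SyntheticGeometryParams(seed=12, n_hypoblast=30, marker_fraction=0.4)
        )
        df = g.data.copy()
        df.loc[df["lineage"] == "EPI", "pSMAD15"] = (
            np.arange((df["lineage"] == "EPI").sum()) % 2 == 0
        )
        g = EmbryoGeometry(df)
        rot = scipy.stats.special_ortho_group.rvs(3, random_state=1)
        moved = g.transformed(rot, np.array([3.0, 4.0, 5.0]))
        a, b = marker_domain_distance(g), marker_domain_distance(moved)
        np.testing.assert_allclose(
            np.sort(a["distances_pos"]), np.sort(b["distances_pos"]), atol=1e-9
        )

    def test_planted_anticorrelated_geometry(self):
        """BMP-active epiblast cells placed opposite the CER1 domain sit
        significantly farther from it than inactive cells."""
        rng = np.random.default_rng(5)
        n = 30
        epi = np.column_stack(
            [rng.uniform(-10, 10, n), rng.uniform(-10, 10, n), rng.uniform(-20, -10, n)]
        )
        psmad = epi[:, 0] < -3  # active cells on the -x side
        hyp = np.column_stack(
            [rng.uniform(5, 15, n), rng.uniform(-5, 5, n), rng.uniform(5, 15, n)]
        )
        g = make_geometry(epi, hyp, cer1=[True] * n, psmad=psmad)
        res = marker_domain_distance(g)
        assert res["median_pos"] > res["median_neg"]
        assert res["p_ranksum"] < 0.05
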