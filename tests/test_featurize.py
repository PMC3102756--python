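"""Tests for the reaction-coordinate geometry against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import msmbind as mb
from msmbind.featurize import (
    DegenerateGeometryError, FeatureTrajectory, hinge_dihedral, superpose, wrap_angle,
)


def dihedral_oracle(a, h1, h2, b):
    """Independent reference: angle between plane normals with triple-product sign."""
    n1 = np.cross(np.asarray(a) - h1, np.asarray(h2) - h1)
    n2 = np.cross(np.asarray(b) - h1, np.asarray(h2) - h1)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    sign = np.sign(np.dot(np.cross(n1, n2), np.asarray(h2) - h1))
    return ang if sign >= 0 else -ang


class TestHingeDihedral:
    def test_coplanar_same_side_is_zero(self):
        assert hinge_dihedral([1, 0, 0], [0, 0, 0], [0, 0, 1], [2, 0, 0.5]) == 0.0

    def test_right_hand_quarter_turn_is_plus_ninety(self):
        # rotate the B half-plane +90 deg (right-handed) about the z hinge axis
        assert hinge_dihedral([1, 0, 0], [0, 0, 0], [0, 0, 1],
                              [0, 1, 0.3]) == pytest.approx(90.0, abs=1e-9)

    def test_matches_normal_vector_oracle_on_random_quadruples(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            a, h1, h2, b = rng.standard_normal((4, 3)) * 5
            try:
                got = hinge_dihedral(a, h1, h2, b)
            except DegenerateGeometryError:
                continue
            want = dihedral_oracle(a, h1, h2, b)
            # compare on the circle (180 vs -180 are the same configuration)
            assert abs(wrap_angle(got - want)) < 1e-9
            checked += 1

    def test_degenerate_geometry_raises(self):
        with pytest.raises(DegenerateGeometryError):
            hinge_dihedral([1, 0, 0], [0, 0, 0], [0, 0, 0], [0, 1, 0])
        with pytest.raises(DegenerateGeometryError):
            hinge_dihedral([0, 0, 5], [0, 0, 0], [0, 0, 1], [0, 1, 0])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_swapping_outer_points_negates_the_angle(self, seed):
        rng = np.random.default_rng(seed)
        a, h1, h2, b = rng.standard_normal((4, 3)) * 3
        try:
            fwd = hinge_dihedral(a, h1, h2, b)
            rev = hinge_dihedral(b, h1, h2, a)
        except DegenerateGeometryError:
            return
        assert abs(wrap_angle(fwd + rev)) < 1e-9


class TestOpeningTwisting:
    def test_reference_scores_exactly_zero(self):
        ref, groups = mb.build_toy_structure(12.0, -7.0)
        assert mb.opening_twisting(ref, groups, ref) == (0.0, 0.0)

    def test_missing_residues_listed_in_error(self):
        s, groups = mb.build_toy_structure(0.0, 0.0)
        s.res_id = np.where(s.res_id == 3, 77, s.res_id)
        with pytest.raises(ValueError, match=r"\[3\]"):
            mb.opening_twisting(s, groups, s)

    def test_rigid_motion_invariance(self):
        # one rotation+translation applied to all atoms leaves angles unchanged
        from scipy.spatial.transform import Rotation
        ref, groups = mb.build_toy_structure(0.0, 0.0)
        s, _ = mb.build_toy_structure(33.0, -21.0)
        rot = Rotation.from_euler("zyx", [31.0, -14.0, 77.0], degrees=True)
        moved, _ = mb.build_toy_structure(33.0, -21.0)
        moved.coord = rot.apply(s.coord) + np.array([5.0, -3.0, 11.0])
        o1, t1 = mb.opening_twisting(s, groups, ref)
        o2, t2 = mb.opening_twisting(moved, groups, ref)
        assert abs(o1 - o2) < 1e-9 and abs(t1 - t2) < 1e-9


class TestDistances:
    def test_site_distance_zero_when_coincident(self):
        site_com = np.array([1.0, 2.0, 3.0])
        lig = np.array([[0.0, 2.0, 3.0], [2.0, 2.0, 3.0]])  # COM at site COM
        assert mb.ligand_site_distance(site_com, lig) == 0.0

    def test_site_distance_three_four_five(self):
        site_com = np.zeros(3)
        lig = np.array([[3.0, 4.0, 0.0]])
        assert mb.ligand_site_distance(site_com, lig) == pytest.approx(5.0)

    def test_site_distance_matches_two_centroid_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            site_com = rng.standard_normal(3) * 10
            lig = rng.standard_normal((7, 3)) * 5
            want = float(np.linalg.norm(lig.mean(axis=0) - site_com))
            assert abs(mb.ligand_site_distance(site_com, lig) - want) < 1e-9

    def test_empty_ligand_rejected(self):
        with pytest.raises(ValueError):
            mb.ligand_site_distance(np.zeros(3), np.empty((0, 3)))

    def test_min_heavy_distance_trivial_cases(self):
        assert mb.min_heavy_distance([[0, 0, 0], [9, 9, 9]], [[0, 0, 0]]) == 0.0
        assert mb.min_heavy_distance([[0, 0, 0]], [[7.25, 0, 0]]) == pytest.approx(7.25)

    def test_min_heavy_distance_matches_pair_loop_oracle(self):
        rng = np.random.default_rng(2)
        p = rng.standard_normal((15, 3)) * 8
        l = rng.standard_normal((6, 3)) * 8
        want = min(np.linalg.norm(pi - li) for pi in p for li in l)
        assert mb.min_heavy_distance(p, l) == pytest.approx(want, abs=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            mb.min_heavy_distance(np.empty((0, 3)), [[0, 0, 0]])


class TestRotationalACF:
    def test_constant_vector_fully_correlated(self):
        u = np.tile([0.0, 0.0, 1.0], (50, 1))
        acf = mb.rotational_acf(u, 10)
        assert np.allclose(acf, 1.0)

    def test_lag_zero_is_exactly_one(self):
        rng = np.random.default_rng(3)
        u = rng.standard_normal((100, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        assert mb.rotational_acf(u, 5)[0] == pytest.approx(1.0)

    def test_isotropic_vectors_decorrelate(self):
        rng = np.random.default_rng(4)
        u = rng.standard_normal((10_000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        acf = mb.rotational_acf(u, 5)
        assert np.all(np.abs(acf[1:]) < 0.05)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            mb.rotational_acf(np.array([[0.0, 0.0, 1.0]]), 0)

    def test_unnormalized_vectors_rejected(self):
        with pytest.raises(ValueError):
            mb.rotational_acf(np.array([[0, 0, 2.0], [0, 0, 2.0]]), 1)


class TestRMSD:
    def test_identical_structures_zero(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((10, 3))
        assert mb.ca_rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_removed_by_superposition(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(6)
        x = rng.standard_normal((20, 3)) * 4
        y = Rotation.from_euler("xyz", [10, 60, -30], degrees=True).apply(x) + 7.0
        assert mb.ca_rmsd(x, y) < 1e-9

    def test_matches_rotation_grid_oracle_on_three_points(self):
        # brute-force search over a fine rotation grid about the z axis for a
        # planar 3-point problem with a hand-checkable optimum
        a = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0]])
        b = np.array([[0.9, 0.1, 0], [-1.1, 0.1, 0], [0.1, 1.2, 0]])
        best = np.inf
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        for th in np.linspace(-np.pi, np.pi, 200_001):
            c, s = np.cos(th), np.sin(th)
            rot = ac @ np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]]).T
            best = min(best, np.sqrt(np.mean(np.sum((rot - bc) ** 2, axis=1))))
        assert mb.ca_rmsd(a, b) == pytest.approx(best, abs=1e-3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mb.ca_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_superpose_never_reflects(self):
        # a mirrored structure cannot be matched by a proper rotation
        rng = np.random.default_rng(7)
        x = rng.standard_normal((12, 3))
        mirrored = x * np.array([-1.0, 1.0, 1.0])
        _, rmsd = superpose(mirrored, x)
        assert rmsd > 0.1


class TestFeatureTrajectoryInvariants:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            FeatureTrajectory(np.zeros(3), np.zeros(2), np.zeros(3),
                              np.zeros(3), np.zeros((3, 3)))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            FeatureTrajectory(np.zeros(1), np.zeros(1), np.array([-1.0]),
                              np.zeros(1), np.zeros((1, 3)))

    def test_angle_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            FeatureTrajectory(np.array([181.0]), np.zeros(1), np.zeros(1),
                              np.zeros(1), np.zeros((1, 3)))
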