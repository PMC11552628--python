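"""Kinematics: Rodrigues rotation, pose expansion, RMSD, pose sampling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from microdock.conformation import (DockingBox, PoseVector, apply_flex_chis,
                                    heavy_atom_rmsd, pose_to_cartesian,
                                    random_pose_in_box, rodrigues_rotate,
                                    so3_left_jacobian)
from microdock.fixtures import make_toy_ligand
from microdock.pdbqt import parse_pdbqt_receptor


class TestRodrigues:
    def test_zero_angle_is_identity(self):
        v = np.array([0.3, -1.2, 2.5])
        assert np.allclose(rodrigues_rotate(v, [0, 0, 1], 0.0), v)

    def test_quarter_turn_about_z(self):
        out = rodrigues_rotate(np.array([1.0, 0, 0]), [0, 0, 1], np.pi / 2)
        assert np.allclose(out, [0, 1, 0], atol=1e-12)

    def test_matches_rotation_matrix_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            v = rng.normal(size=3) * 3
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            theta = rng.uniform(-np.pi, np.pi)
            oracle = Rotation.from_rotvec(axis * theta).as_matrix() @ v
            out = rodrigues_rotate(v, axis, theta)
            assert np.allclose(out, oracle, atol=1e-12)
            assert abs(np.linalg.norm(out) - np.linalg.norm(v)) < 1e-12

    def test_zero_axis_with_angle_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            rodrigues_rotate(np.ones(3), np.zeros(3), 0.3)

    def test_non_unit_axis_is_an_error(self):
        with pytest.raises(ValueError, match="unit"):
            rodrigues_rotate(np.ones(3), [2.0, 0, 0], 0.3)


def _frame_index_sets(top):
    tree = top.torsion_tree
    yield tree.root_atoms
    for b in range(tree.k):
        yield tree.frame_atoms(b)


class TestPoseToCartesian:
    def test_zero_pose_returns_reference_exactly(self, toy_ligand):
        _, top = toy_ligand
        pose = PoseVector.identity(top.k)
        assert np.array_equal(pose_to_cartesian(pose, top),
                              top.reference_coords)

    def test_pure_translation_shifts_every_atom(self, toy_ligand):
        _, top = toy_ligand
        pose = PoseVector(np.array([1.0, 2.0, 3.0]), np.zeros(3),
                          np.zeros(top.k))
        out = pose_to_cartesian(pose, top)
        assert np.allclose(out, top.reference_coords + [1, 2, 3], atol=1e-12)

    def test_single_torsion_moves_only_the_moved_set(self):
        _, top = make_toy_ligand(n_atoms=7, k=1, seed=8)
        br = top.torsion_tree.branches[0]
        angle = np.deg2rad(60.0)
        pose = PoseVector(np.zeros(3), np.zeros(3), np.array([angle]))
        out = pose_to_cartesian(pose, top)
        ref = top.reference_coords
        fixed = sorted(set(range(top.n_atoms)) - set(br.moved.tolist()))
        assert np.allclose(out[fixed], ref[fixed], atol=1e-12)
        # per-atom Rodrigues oracle about the bond axis
        axis = ref[br.child_atom] - ref[br.parent_atom]
        axis /= np.linalg.norm(axis)
        for i in br.moved:
            expect = ref[br.parent_atom] + Rotation.from_rotvec(
                axis * angle).as_matrix() @ (ref[i] - ref[br.parent_atom])
            assert np.allclose(out[i], expect, atol=1e-9)
        # bond lengths preserved
        for i, j in top.bonds:
            d0 = np.linalg.norm(ref[i] - ref[j])
            d1 = np.linalg.norm(out[i] - out[j])
            assert abs(d0 - d1) < 1e-9

    def test_intra_frame_distances_preserved_for_random_poses(self, toy_ligand):
        _, top = toy_ligand
        rng = np.random.default_rng(1)
        box = DockingBox(center=np.zeros(3), size=np.full(3, 10.0))
        for _ in range(25):
            pose = random_pose_in_box(box, top.k, rng)
            out = pose_to_cartesian(pose, top)
            for frame in _frame_index_sets(top):
                idx = np.array(frame)
                d_ref = np.linalg.norm(
                    top.reference_coords[idx][:, None]
                    - top.reference_coords[idx][None], axis=-1)
                d_new = np.linalg.norm(out[idx][:, None] - out[idx][None],
                                       axis=-1)
                assert np.allclose(d_ref, d_new, atol=1e-9)

    def test_orientation_composed_with_inverse_returns_reference(self,
                                                                 toy_ligand):
        _, top = toy_ligand
        rng = np.random.default_rng(2)
        w = rng.normal(size=3)
        pose_fwd = PoseVector(np.zeros(3), w, np.zeros(top.k))
        rotated = pose_to_cartesian(pose_fwd, top)
        # treat the rotated structure as a new reference, rotate back
        import dataclasses
        top_back = dataclasses.replace(top, reference_coords=rotated,
                                       _graph_dist=None)
        pose_back = PoseVector(np.zeros(3), -w, np.zeros(top.k))
        back = pose_to_cartesian(pose_back, top_back)
        assert np.allclose(back, top.reference_coords, atol=1e-9)

    def test_dimension_mismatch_is_an_error(self, toy_ligand):
        _, top = toy_ligand
        pose = PoseVector(np.zeros(3), np.zeros(3), np.zeros(top.k + 1))
        with pytest.raises(ValueError, match="torsion"):
            pose_to_cartesian(pose, top)


class TestFlexChis:
    def test_zero_deltas_leave_receptor_unchanged(self, serine_receptor_text,
                                                  serine_flex_text):
        rec = parse_pdbqt_receptor(serine_receptor_text, serine_flex_text)
        out = apply_flex_chis(rec, [np.zeros(1)])
        assert np.allclose(out, rec.coords)

    def test_chi1_rotation_matches_rodrigues_oracle(self, serine_receptor_text,
                                                    serine_flex_text):
        rec = parse_pdbqt_receptor(serine_receptor_text, serine_flex_text)
        out = apply_flex_chis(rec, [np.array([np.pi])])
        a, b, moved = rec.flexible_residues[0].chi_axes[0]
        coords = rec.coords
        axis = coords[b] - coords[a]
        axis /= np.linalg.norm(axis)
        og = next(i for i in moved if rec.atoms[i].name == "OG")
        expect = coords[a] + Rotation.from_rotvec(axis * np.pi).as_matrix() @ (
            coords[og] - coords[a])
        assert np.allclose(out[og], expect, atol=1e-9)
        # backbone fixed
        backbone = [i for i, at in enumerate(rec.atoms)
                    if at.name in ("N", "C", "O", "CA")]
        assert np.allclose(out[backbone], coords[backbone])

    def test_rigid_receptor_with_empty_chi_is_fine(self, serine_receptor_text):
        rec = parse_pdbqt_receptor(serine_receptor_text)
        assert np.allclose(apply_flex_chis(rec, []), rec.coords)

    def test_chi_length_mismatch_is_an_error(self, serine_receptor_text,
                                             serine_flex_text):
        rec = parse_pdbqt_receptor(serine_receptor_text, serine_flex_text)
        with pytest.raises(ValueError, match="chi"):
            apply_flex_chis(rec, [np.zeros(2)])


class TestHeavyAtomRmsd:
    def test_identical_coordinates_give_zero(self):
        c = np.random.default_rng(0).normal(size=(10, 3))
        assert heavy_atom_rmsd(c, c) == 0.0

    def test_uniform_translation_gives_its_magnitude(self):
        c = np.random.default_rng(1).normal(size=(12, 3))
        shift = np.array([2.0, 0.0, 0.0])
        assert np.isclose(heavy_atom_rmsd(c, c + shift), 2.0)

    def test_matches_direct_formula_and_is_symmetric(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3))
        direct = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert np.isclose(heavy_atom_rmsd(a, b), direct)
        assert heavy_atom_rmsd(a, b) == heavy_atom_rmsd(b, a) > 0

    def test_zero_heavy_atoms_is_an_error(self):
        c = np.zeros((3, 3))
        with pytest.raises(ValueError, match="heavy"):
            heavy_atom_rmsd(c, c, np.zeros(3, dtype=bool))


class TestRandomPoseInBox:
    def test_reference_point_always_inside_box(self):
        rng = np.random.default_rng(0)
        box = DockingBox(center=[1.0, -2.0, 3.0], size=[8.0, 6.0, 10.0])
        ref = np.array([0.5, 0.5, 0.5])
        for _ in range(10_000):
            pose = random_pose_in_box(box, 2, rng, ref_point=ref)
            assert box.contains(ref + pose.translation).all()

    def test_k_zero_has_empty_torsions(self):
        rng = np.random.default_rng(1)
        box = DockingBox(center=np.zeros(3), size=np.ones(3))
        pose = random_pose_in_box(box, 0, rng)
        assert pose.torsions.size == 0
        assert pose.dim == 6

    def test_orientation_angles_match_uniform_rotation_distribution(self):
        # mean rotation angle of a uniform rotation is pi/2 + 2/pi
        rng = np.random.default_rng(2)
        box = DockingBox(center=np.zeros(3), size=np.ones(3))
        n = 4000
        angles = np.array([
            np.linalg.norm(random_pose_in_box(box, 0, rng).orientation)
            for _ in range(n)])
        expected = np.pi / 2 + 2 / np.pi
        sem = angles.std(ddof=1) / np.sqrt(n)
        assert abs(angles.mean() - expected) < 3 * sem


def test_left_jacobian_matches_finite_differences():
    # dR(w)v/dw = [J_l(w) dw]x R v : probe with small parameter steps
    rng = np.random.default_rng(3)
    for _ in range(20):
        w = rng.normal(size=3)
        v = rng.normal(size=3)
        R = Rotation.from_rotvec(w).as_matrix()
        J = so3_left_jacobian(w)
        h = 1e-6
        for i in range(3):
            dw = np.zeros(3)
            dw[i] = h
            num = (Rotation.from_rotvec(w + dw).as_matrix() @ v
                   - Rotation.from_rotvec(w - dw).as_matrix() @ v) / (2 * h)
            delta = J @ dw / h
            ana = np.cross(delta, R @ v)
            assert np.allclose(num, ana, atol=1e-5)
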