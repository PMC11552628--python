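"""The docking system: one ligand + one receptor + one search box.

Bundles the kinematic map (pose vector -> Cartesian coordinates for both the
ligand and any flexible side-chains) with scoring, and chains coordinate
gradients back onto the pose vector:

* translation: the gradient is the sum of per-atom gradients;
* orientation (axis-angle): the torque about the rotation center, mapped
  through the transposed left Jacobian of SO(3) onto the axis-angle parameters;
* each torsion / chi angle: the projection of the moved atoms' gradients onto
  their instantaneous circular velocity about the bond axis.
"""

from __future__ import annotations

import numpy as np

from ._kernels import HAVE_NUMBA, chain_ligand_gradient, expand_pose
from .conformation import (DockingBox, PoseVector, apply_flex_chis,
                           pose_to_cartesian, random_pose_in_box,
                           root_reference_point, so3_left_jacobian)
from .pdbqt import LigandTopology, ReceptorModel
from .scoring import ScoreBreakdown, ScoringFunction

__all__ = ["DockingSystem"]


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise 3-vector cross product (avoids np.cross overhead)."""
    out = np.empty_like(b)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


class DockingSystem:
    """Holds the structures and the box, converts poses to coordinates and
    evaluates scores/gradients in pose space."""

    def __init__(self, ligand: LigandTopology, receptor: ReceptorModel,
                 box: DockingBox):
        self.ligand = ligand
        self.receptor = receptor
        self.box = box
        self.root_center = root_reference_point(ligand)
        self.chi_sizes = tuple(len(fr.chi_axes)
                               for fr in receptor.flexible_residues)
        self._rigid_rec_coords = receptor.coords  # valid when no flex residues
        # flat torsion-tree arrays for the compiled kinematics kernels
        branches = ligand.torsion_tree.branches
        self._branch_parent = np.array([b.parent_atom for b in branches],
                                       dtype=np.int64)
        self._branch_child = np.array([b.child_atom for b in branches],
                                      dtype=np.int64)
        if branches:
            self._moved_flat = np.concatenate([b.moved for b in branches]
                                              ).astype(np.int64)
        else:
            self._moved_flat = np.zeros(0, dtype=np.int64)
        self._moved_start = np.concatenate(
            [[0], np.cumsum([len(b.moved) for b in branches])]
        ).astype(np.int64)

    # -- dimensions --------------------------------------------------------

    @property
    def k(self) -> int:
        return self.ligand.k

    @property
    def dim(self) -> int:
        return 6 + self.k + sum(self.chi_sizes)

    def identity_pose(self) -> PoseVector:
        return PoseVector.identity(self.k, self.chi_sizes)

    def random_pose(self, rng: np.random.Generator) -> PoseVector:
        return random_pose_in_box(self.box, self.k, rng,
                                  ref_point=self.root_center,
                                  chi_sizes=self.chi_sizes)

    def pose_from_array(self, arr: np.ndarray) -> PoseVector:
        return PoseVector.from_array(arr, self.k, self.chi_sizes)

    def clamp_to_box(self, pose: PoseVector) -> PoseVector:
        """Clamp the root reference point back into the docking box."""
        point = self.root_center + pose.translation
        clamped = self.box.clamp(point)
        out = pose.copy()
        out.translation = clamped - self.root_center
        return out

    # -- coordinates -------------------------------------------------------

    def ligand_coords(self, pose: PoseVector) -> np.ndarray:
        if HAVE_NUMBA:
            if len(pose.torsions) != self.k:
                raise ValueError(
                    f"pose has {len(pose.torsions)} torsions but the topology "
                    f"has {self.k}")
            return expand_pose(self.ligand.reference_coords, self.root_center,
                               pose.translation, pose.orientation,
                               pose.torsions, self._branch_parent,
                               self._branch_child, self._moved_flat,
                               self._moved_start)
        return pose_to_cartesian(pose, self.ligand)

    def receptor_coords(self, pose: PoseVector | None = None) -> np.ndarray:
        if pose is None or not self.chi_sizes:
            return self._rigid_rec_coords.copy()
        return apply_flex_chis(self.receptor, pose.chi)

    # -- scoring -----------------------------------------------------------

    def score(self, pose: PoseVector, sf: ScoringFunction) -> ScoreBreakdown:
        return sf.evaluate(self.ligand_coords(pose), self.receptor_coords(pose))

    def score_array(self, x: np.ndarray, sf: ScoringFunction) -> float:
        return self.score(self.pose_from_array(x), sf).total

    def pose_gradient(self, pose: PoseVector, sf: ScoringFunction) -> np.ndarray:
        """d(score)/d(pose vector) via the analytic chain rule."""
        lig = self.ligand_coords(pose)
        rec = self.receptor_coords(pose)
        g_lig, g_rec = sf.gradient(lig, rec)
        return self._chain_gradient(pose, lig, rec, g_lig, g_rec)

    def value_and_pose_grad(self, pose: PoseVector,
                            sf: ScoringFunction) -> tuple[float, np.ndarray]:
        """Fused score + pose-space gradient (one kinematic expansion)."""
        lig = self.ligand_coords(pose)
        rec = self.receptor_coords(pose)
        val, g_lig, g_rec = sf.value_and_gradient(lig, rec)
        return val, self._chain_gradient(pose, lig, rec, g_lig, g_rec)

    def _chain_gradient(self, pose, lig, rec, g_lig, g_rec) -> np.ndarray:
        grad = np.zeros(self.dim)
        if HAVE_NUMBA:
            core = chain_ligand_gradient(
                lig, g_lig, self.root_center + pose.translation, self.k,
                self._branch_parent, self._branch_child, self._moved_flat,
                self._moved_start)
            core[3:6] = so3_left_jacobian(pose.orientation).T @ core[3:6]
            grad[:6 + self.k] = core
            off = 6 + self.k
            if self.chi_sizes and g_rec is not None:
                for fr in self.receptor.flexible_residues:
                    for a, b, moved in fr.chi_axes:
                        axis = rec[b] - rec[a]
                        u = axis / np.linalg.norm(axis)
                        rel = rec[moved] - rec[a]
                        grad[off] = np.sum(
                            _cross(np.broadcast_to(u, rel.shape), rel)
                            * g_rec[moved])
                        off += 1
            return grad

        # translation
        grad[0:3] = g_lig.sum(axis=0)

        # orientation: torque about the (translated) rotation center, pulled
        # back through the left Jacobian of the axis-angle parameterisation
        center = self.root_center + pose.translation
        r = lig - center
        torque = _cross(r, g_lig).sum(axis=0)
        grad[3:6] = so3_left_jacobian(pose.orientation).T @ torque

        # torsions: dE/dtheta = sum_moved g_i . (u x (x_i - x_axis))
        for t, br in enumerate(self.ligand.torsion_tree.branches):
            axis = lig[br.child_atom] - lig[br.parent_atom]
            u = axis / np.linalg.norm(axis)
            rel = lig[br.moved] - lig[br.parent_atom]
            grad[6 + t] = np.sum(_cross(np.broadcast_to(u, rel.shape), rel)
                                 * g_lig[br.moved])

        # receptor chi angles
        off = 6 + self.k
        if self.chi_sizes and g_rec is not None:
            for fr in self.receptor.flexible_residues:
                for a, b, moved in fr.chi_axes:
                    axis = rec[b] - rec[a]
                    u = axis / np.linalg.norm(axis)
                    rel = rec[moved] - rec[a]
                    grad[off] = np.sum(_cross(np.broadcast_to(u, rel.shape),
                                              rel) * g_rec[moved])
                    off += 1
        return grad

    def gradient_array(self, x: np.ndarray, sf: ScoringFunction) -> np.ndarray:
        return self.pose_gradient(self.pose_from_array(x), sf)

    def value_and_grad_array(self, x: np.ndarray, sf: ScoringFunction
                             ) -> tuple[float, np.ndarray]:
        return self.value_and_pose_grad(self.pose_from_array(x), sf)

    # -- geometry ----------------------------------------------------------

    def rmsd_to(self, pose: PoseVector, reference_coords: np.ndarray) -> float:
        from .conformation import heavy_atom_rmsd
        return heavy_atom_rmsd(self.ligand_coords(pose), reference_coords,
                               self.ligand.heavy_mask)
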