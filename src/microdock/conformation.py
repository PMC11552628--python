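"""Reduced-coordinate kinematics: the (6+k)-dimensional pose vector and its
expansion to Cartesian coordinates.

A flexible ligand is treated as a tree of rigid frames connected by rotatable
bonds. Its state is six rigid-body degrees of freedom — a translation of the
root frame and an axis-angle orientation about the root reference point (the
centroid of the root frame's heavy atoms) — plus one torsion angle per
rotatable bond, applied root-outward about the bond axis with Rodrigues'
rotation formula. Receptor side-chain flexibility adds up to four chi angles
per flexible residue, rotated proximal-to-distal about the chi bond axes while
the backbone stays fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .pdbqt import LigandTopology, ReceptorModel

__all__ = [
    "PoseVector",
    "DockingBox",
    "rodrigues_rotate",
    "pose_to_cartesian",
    "apply_flex_chis",
    "heavy_atom_rmsd",
    "random_pose_in_box",
    "root_reference_point",
    "so3_left_jacobian",
    "wrap_angle",
]

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angles into [-pi, pi)."""
    return (np.asarray(theta) + np.pi) % TWO_PI - np.pi


@dataclass
class PoseVector:
    """Ligand state: translation (3, Angstrom), orientation (3, axis-angle,
    radians), k torsions (radians) and optional per-flex-residue chi vectors."""

    translation: np.ndarray
    orientation: np.ndarray
    torsions: np.ndarray
    chi: tuple[np.ndarray, ...] = ()

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3)
        self.torsions = np.asarray(self.torsions, dtype=float).reshape(-1)
        self.chi = tuple(np.asarray(c, dtype=float).reshape(-1) for c in self.chi)

    @property
    def k(self) -> int:
        return len(self.torsions)

    @property
    def dim(self) -> int:
        return 6 + self.k + sum(len(c) for c in self.chi)

    @property
    def chi_sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.chi)

    def to_array(self) -> np.ndarray:
        parts = [self.translation, self.orientation, self.torsions, *self.chi]
        return np.concatenate(parts) if parts else np.zeros(0)

    @classmethod
    def from_array(cls, arr: np.ndarray, k: int,
                   chi_sizes: tuple[int, ...] = ()) -> "PoseVector":
        arr = np.asarray(arr, dtype=float)
        expected = 6 + k + sum(chi_sizes)
        if arr.shape != (expected,):
            raise ValueError(f"expected a {expected}-vector, got shape {arr.shape}")
        chi = []
        off = 6 + k
        for n in chi_sizes:
            chi.append(arr[off:off + n].copy())
            off += n
        return cls(arr[:3].copy(), arr[3:6].copy(), arr[6:6 + k].copy(), tuple(chi))

    @classmethod
    def identity(cls, k: int, chi_sizes: tuple[int, ...] = ()) -> "PoseVector":
        return cls(np.zeros(3), np.zeros(3), np.zeros(k),
                   tuple(np.zeros(n) for n in chi_sizes))

    def copy(self) -> "PoseVector":
        return PoseVector(self.translation.copy(), self.orientation.copy(),
                          self.torsions.copy(), tuple(c.copy() for c in self.chi))


@dataclass
class DockingBox:
    """Axis-aligned search region: center and edge lengths in Angstrom."""

    center: np.ndarray
    size: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.size = np.asarray(self.size, dtype=float).reshape(3)
        if np.any(self.size <= 0):
            raise ValueError("docking box edge lengths must be positive")

    @property
    def lower(self) -> np.ndarray:
        return self.center - 0.5 * self.size

    @property
    def upper(self) -> np.ndarray:
        return self.center + 0.5 * self.size

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.lower) & (p <= self.upper), axis=-1)

    def clamp(self, points: np.ndarray) -> np.ndarray:
        return np.clip(points, self.lower, self.upper)


def rodrigues_rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate vector(s) ``v`` about unit ``axis`` by ``angle`` (radians):
    v cos(t) + (axis x v) sin(t) + axis (axis . v) (1 - cos(t))."""
    v = np.asarray(v, dtype=float)
    axis = np.asarray(axis, dtype=float).reshape(3)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if angle != 0.0:
            raise ValueError("zero rotation axis with a nonzero angle")
        return v.copy()
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"rotation axis must be a unit vector (|axis|={n:.3g})")
    axis = axis / n
    c, s = np.cos(angle), np.sin(angle)
    cross = np.empty_like(v)
    a0, a1, a2 = axis
    cross[..., 0] = a1 * v[..., 2] - a2 * v[..., 1]
    cross[..., 1] = a2 * v[..., 0] - a0 * v[..., 2]
    cross[..., 2] = a0 * v[..., 1] - a1 * v[..., 0]
    dot = v @ axis
    return v * c + cross * s + np.multiply.outer(dot, axis) * (1.0 - c)


def root_reference_point(topology: LigandTopology) -> np.ndarray:
    """Rotation/translation reference: centroid of the root frame's heavy
    atoms (all root atoms if the root has no heavy atom)."""
    root = topology.torsion_tree.root_atoms
    heavy = [i for i in root if topology.atoms[i].is_heavy]
    idx = heavy if heavy else list(root)
    return topology.reference_coords[idx].mean(axis=0)


def pose_to_cartesian(pose: PoseVector, topology: LigandTopology) -> np.ndarray:
    """Expand a pose vector to N x 3 Cartesian coordinates.

    Torsions are applied root-outward (file order of the BRANCH records) about
    the current bond axes; then the whole ligand is rotated about the root
    reference point by the axis-angle orientation and translated.
    """
    tree = topology.torsion_tree
    if len(pose.torsions) != tree.k:
        raise ValueError(
            f"pose has {len(pose.torsions)} torsions but the topology has {tree.k}")
    coords = topology.reference_coords.copy()
    for angle, br in zip(pose.torsions, tree.branches):
        if angle == 0.0:
            continue
        origin = coords[br.parent_atom]
        axis = coords[br.child_atom] - origin
        axis = axis / np.linalg.norm(axis)
        coords[br.moved] = origin + rodrigues_rotate(coords[br.moved] - origin,
                                                     axis, float(angle))
    center = root_reference_point(topology)
    theta = np.linalg.norm(pose.orientation)
    if theta > 1e-12:
        axis = pose.orientation / theta
        return (center + pose.translation
                + rodrigues_rotate(coords - center, axis, theta))
    return coords + pose.translation


def apply_flex_chis(receptor: ReceptorModel,
                    chi: tuple[np.ndarray, ...] | list[np.ndarray]) -> np.ndarray:
    """Apply chi-angle deltas to flexible side-chains; backbone atoms never
    move. ``chi`` holds one angle vector per flexible residue (proximal to
    distal). Returns the full receptor coordinate array."""
    coords = receptor.coords
    if len(chi) != len(receptor.flexible_residues):
        raise ValueError(
            f"got {len(chi)} chi vectors for {len(receptor.flexible_residues)} "
            f"flexible residues")
    for angles, fr in zip(chi, receptor.flexible_residues):
        angles = np.asarray(angles, dtype=float).reshape(-1)
        if len(angles) != len(fr.chi_axes):
            raise ValueError(
                f"residue {fr.residue_id} expects {len(fr.chi_axes)} chi angles, "
                f"got {len(angles)}")
        for angle, (a, b, moved) in zip(angles, fr.chi_axes):
            if angle == 0.0:
                continue
            origin = coords[a]
            axis = coords[b] - origin
            axis = axis / np.linalg.norm(axis)
            coords[moved] = origin + rodrigues_rotate(coords[moved] - origin,
                                                      axis, float(angle))
    return coords


def heavy_atom_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                    heavy_mask: np.ndarray | None = None) -> float:
    """Docking RMSD: root-mean-square deviation over heavy atoms with identity
    atom correspondence and no superposition (both poses live in the receptor
    frame)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must have equal shapes")
    if heavy_mask is not None:
        a, b = a[heavy_mask], b[heavy_mask]
    if len(a) == 0:
        raise ValueError("no heavy atoms to compare")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def random_pose_in_box(box: DockingBox, k: int, rng: np.random.Generator,
                       ref_point: np.ndarray | None = None,
                       chi_sizes: tuple[int, ...] = ()) -> PoseVector:
    """Draw a pose with the root reference point uniform in the box, an
    orientation uniform over SO(3), and torsions/chis uniform in [-pi, pi)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    point = box.lower + rng.random(3) * box.size
    ref = np.zeros(3) if ref_point is None else np.asarray(ref_point, dtype=float)
    orientation = Rotation.random(rng=rng).as_rotvec()
    torsions = rng.uniform(-np.pi, np.pi, size=k)
    chi = tuple(rng.uniform(-np.pi, np.pi, size=n) for n in chi_sizes)
    return PoseVector(point - ref, orientation, torsions, chi)


def so3_left_jacobian(w: np.ndarray) -> np.ndarray:
    """Left Jacobian of SO(3) at rotation vector ``w``: maps a perturbation of
    the axis-angle parameters to the equivalent world-frame infinitesimal
    rotation. Used to chain score gradients through the orientation DOFs."""
    w = np.asarray(w, dtype=float).reshape(3)
    theta = np.linalg.norm(w)
    W = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    if theta < 1e-6:
        return np.eye(3) + 0.5 * W + (1.0 / 6.0) * (W @ W)
    a = (1.0 - np.cos(theta)) / theta**2
    b = (theta - np.sin(theta)) / theta**3
    return np.eye(3) + a * W + b * (W @ W)
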