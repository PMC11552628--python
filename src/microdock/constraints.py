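"""Distance restraints expressed as scoring-function terms.

Restraints steer the pose search with prior structural knowledge — a covalent
attachment distance, a catalytic contact, or a full ligand-receptor distance
matrix from a reference complex. Each restraint is a non-negative penalty that
is zero on its feasible set and grows quadratically with the violation:

    harmonic:    k (d - d0)^2
    upper_wall:  k max(0, d - upper)^2
    lower_wall:  k max(0, lower - d)^2
    wall:        both one-sided terms (lower < upper)
    matrix:      sum_ij (d_ij - native_ij)^2 over a ligand x receptor atom grid

All penalties are differentiable in the coordinates (C1 at the wall bounds),
so a constraint scoring function can participate in gradient-based local
refinement and can be mixed with the empirical score through a hybrid scoring
function (equal 0.5/0.5 weights being the usual choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scoring import ScoreBreakdown, ScoringFunction

__all__ = [
    "ConstraintError",
    "AtomSelector",
    "DistanceConstraint",
    "MatrixConstraint",
    "harmonic_penalty",
    "wall_penalty",
    "matrix_penalty",
    "constraint_as_sf",
    "ConstraintScoringFunction",
    "read_matrix_constraint",
    "write_matrix_constraint",
]


class ConstraintError(ValueError):
    """Unresolvable selector or inconsistent restraint definition."""


@dataclass(frozen=True)
class AtomSelector:
    """Names exactly one atom on either side of the complex, by atom name
    within an (optional) chain/residue, or directly by index."""

    side: str  # "receptor" | "ligand"
    chain: str | None = None
    residue_number: int | None = None
    atom_name: str | None = None
    index: int | None = None

    def __post_init__(self) -> None:
        if self.side not in ("receptor", "ligand"):
            raise ConstraintError(f"selector side must be receptor|ligand, "
                                  f"got {self.side!r}")
        if self.atom_name is None and self.index is None:
            raise ConstraintError("selector needs an atom_name or an index")

    def resolve(self, system) -> int:
        atoms = (system.ligand.atoms if self.side == "ligand"
                 else system.receptor.atoms)
        if self.index is not None:
            if not 0 <= self.index < len(atoms):
                raise ConstraintError(f"selector {self} index out of range")
            return self.index
        hits = [
            i for i, a in enumerate(atoms)
            if a.name == self.atom_name
            and (self.chain is None or a.chain == self.chain)
            and (self.residue_number is None
                 or a.residue_number == self.residue_number)
        ]
        if len(hits) != 1:
            raise ConstraintError(
                f"selector {self} resolves to {len(hits)} atoms (need exactly 1)")
        return hits[0]


def harmonic_penalty(d, d0, k=1.0):
    """Harmonic restraint k (d - d0)^2."""
    return k * (np.asarray(d, dtype=float) - d0) ** 2


def wall_penalty(d, lower=None, upper=None, k=1.0):
    """One- or two-sided quadratic wall; zero inside the feasible region."""
    if lower is None and upper is None:
        raise ConstraintError("wall needs at least one bound")
    if lower is not None and upper is not None and lower >= upper:
        raise ConstraintError(f"wall requires lower < upper, got [{lower}, {upper}]")
    d = np.asarray(d, dtype=float)
    pen = np.zeros_like(d)
    if upper is not None:
        pen = pen + k * np.maximum(0.0, d - upper) ** 2
    if lower is not None:
        pen = pen + k * np.maximum(0.0, lower - d) ** 2
    return pen


@dataclass
class DistanceConstraint:
    """A single atom-pair distance restraint."""

    a: AtomSelector
    b: AtomSelector
    kind: str = "harmonic"  # harmonic | upper_wall | lower_wall | wall
    target: float | None = None
    lower: float | None = None
    upper: float | None = None
    force_constant: float = 1.0  # score-units / Angstrom^2

    def __post_init__(self) -> None:
        if self.kind not in ("harmonic", "upper_wall", "lower_wall", "wall"):
            raise ConstraintError(f"unknown constraint kind {self.kind!r}")
        if self.force_constant < 0:
            raise ConstraintError("force constant must be >= 0")
        if self.kind == "harmonic" and self.target is None:
            raise ConstraintError("harmonic constraint needs a target distance")
        if self.kind == "upper_wall" and self.upper is None:
            raise ConstraintError("upper_wall needs an upper bound")
        if self.kind == "lower_wall" and self.lower is None:
            raise ConstraintError("lower_wall needs a lower bound")
        if self.kind == "wall":
            if self.lower is None or self.upper is None:
                raise ConstraintError("wall needs both bounds")
            if self.lower >= self.upper:
                raise ConstraintError("wall requires lower < upper")

    def penalty(self, d: float) -> float:
        k = self.force_constant
        if self.kind == "harmonic":
            return float(harmonic_penalty(d, self.target, k))
        if self.kind == "upper_wall":
            return float(wall_penalty(d, upper=self.upper, k=k))
        if self.kind == "lower_wall":
            return float(wall_penalty(d, lower=self.lower, k=k))
        return float(wall_penalty(d, lower=self.lower, upper=self.upper, k=k))

    def dpenalty(self, d: float) -> float:
        k = self.force_constant
        if self.kind == "harmonic":
            return 2.0 * k * (d - self.target)
        g = 0.0
        if self.kind in ("upper_wall", "wall") and d > self.upper:
            g += 2.0 * k * (d - self.upper)
        if self.kind in ("lower_wall", "wall") and d < self.lower:
            g -= 2.0 * k * (self.lower - d)
        return g


@dataclass
class MatrixConstraint:
    """Native distance-matrix restraint: the summed squared difference between
    the current ligand-receptor distance matrix and a reference matrix."""

    ligand_atoms: np.ndarray
    receptor_atoms: np.ndarray
    native_matrix: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.ligand_atoms = np.asarray(self.ligand_atoms, dtype=int)
        self.receptor_atoms = np.asarray(self.receptor_atoms, dtype=int)
        self.native_matrix = np.asarray(self.native_matrix, dtype=float)
        shape = (len(self.ligand_atoms), len(self.receptor_atoms))
        if self.native_matrix.shape != shape:
            raise ConstraintError(
                f"native matrix shape {self.native_matrix.shape} does not match "
                f"atom lists {shape}")
        if np.any(self.native_matrix <= 0):
            raise ConstraintError("native matrix entries must be positive")


def matrix_penalty(lig_coords: np.ndarray, rec_coords: np.ndarray,
                   mc: MatrixConstraint) -> float:
    """sum_ij (d_ij - native_ij)^2, scaled by the constraint weight."""
    xl = lig_coords[mc.ligand_atoms]
    xr = rec_coords[mc.receptor_atoms]
    diff = xl[:, None, :] - xr[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    return float(mc.weight * np.sum((d - mc.native_matrix) ** 2))


def _matrix_gradient(lig_coords, rec_coords, mc: MatrixConstraint):
    xl = lig_coords[mc.ligand_atoms]
    xr = rec_coords[mc.receptor_atoms]
    diff = xl[:, None, :] - xr[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    safe = np.where(d > 1e-9, d, 1.0)
    coeff = mc.weight * 2.0 * (d - mc.native_matrix) / safe
    gv = coeff[:, :, None] * diff
    g_lig = np.zeros_like(lig_coords)
    g_rec = np.zeros_like(rec_coords)
    np.add.at(g_lig, mc.ligand_atoms, gv.sum(axis=1))
    np.add.at(g_rec, mc.receptor_atoms, -gv.sum(axis=0))
    return g_lig, g_rec


class ConstraintScoringFunction(ScoringFunction):
    """All restraint penalties summed into one differentiable score term.

    Selectors are resolved against the system at construction so that a typo
    fails fast, naming the offending selector.
    """

    supports_gradient = True

    def __init__(self, constraints, system, weight: float = 1.0,
                 name: str = "constraints"):
        if not constraints:
            raise ConstraintError("constraint scoring function needs >= 1 restraint")
        self.name = name
        self.weight = weight
        self.pair_constraints: list[tuple[DistanceConstraint, str, int, str, int]] = []
        self.matrix_constraints: list[MatrixConstraint] = []
        for c in constraints:
            if isinstance(c, MatrixConstraint):
                self.matrix_constraints.append(c)
            elif isinstance(c, DistanceConstraint):
                ia = c.a.resolve(system)
                ib = c.b.resolve(system)
                self.pair_constraints.append((c, c.a.side, ia, c.b.side, ib))
            else:
                raise ConstraintError(f"unsupported constraint object {c!r}")

    @staticmethod
    def _pick(side, idx, lig, rec):
        return (lig if side == "ligand" else rec)[idx]

    def evaluate(self, lig_coords, rec_coords=None) -> ScoreBreakdown:
        total = 0.0
        for c, sa, ia, sb, ib in self.pair_constraints:
            pa = self._pick(sa, ia, lig_coords, rec_coords)
            pb = self._pick(sb, ib, lig_coords, rec_coords)
            total += c.penalty(float(np.linalg.norm(pa - pb)))
        for mc in self.matrix_constraints:
            total += matrix_penalty(lig_coords, rec_coords, mc)
        total *= self.weight
        return ScoreBreakdown(total=total, per_term={self.name: total},
                              term_weights={self.name: 1.0}, inter=total,
                              intra=0.0, predicted_free_energy=0.0)

    def gradient(self, lig_coords, rec_coords=None):
        g_lig = np.zeros_like(lig_coords)
        g_rec = np.zeros_like(rec_coords) if rec_coords is not None else None
        for c, sa, ia, sb, ib in self.pair_constraints:
            pa = self._pick(sa, ia, lig_coords, rec_coords)
            pb = self._pick(sb, ib, lig_coords, rec_coords)
            delta = pa - pb
            d = float(np.linalg.norm(delta))
            u = delta / d if d > 1e-9 else np.zeros(3)
            g = c.dpenalty(d) * u
            for sign, side, idx in ((+1.0, sa, ia), (-1.0, sb, ib)):
                if side == "ligand":
                    g_lig[idx] += sign * g
                elif g_rec is not None:
                    g_rec[idx] += sign * g
        for mc in self.matrix_constraints:
            gl, gr = _matrix_gradient(lig_coords, rec_coords, mc)
            g_lig += gl
            if g_rec is not None:
                g_rec += gr
        g_lig *= self.weight
        if g_rec is not None:
            g_rec *= self.weight
        return g_lig, g_rec


def constraint_as_sf(constraints, system, weight: float = 1.0,
                     name: str = "constraints") -> ConstraintScoringFunction:
    """Bundle restraints into a ScoringFunction, composable via a hybrid."""
    return ConstraintScoringFunction(constraints, system, weight=weight, name=name)


# ---------------------------------------------------------------------------
# plain-text matrix constraint files
# ---------------------------------------------------------------------------

def write_matrix_constraint(mc: MatrixConstraint, path) -> None:
    with open(path, "w") as fh:
        fh.write("# ligand_atoms: " + " ".join(map(str, mc.ligand_atoms)) + "\n")
        fh.write("# receptor_atoms: " + " ".join(map(str, mc.receptor_atoms)) + "\n")
        fh.write(f"# weight: {mc.weight}\n")
        for row in mc.native_matrix:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_matrix_constraint(path) -> MatrixConstraint:
    """Read a whitespace-delimited native distance matrix with header rows
    naming the ligand/receptor atom selections (0-based indices)."""
    lig = rec = None
    weight = 1.0
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("ligand_atoms:"):
                    lig = [int(x) for x in body.split(":", 1)[1].split()]
                elif body.startswith("receptor_atoms:"):
                    rec = [int(x) for x in body.split(":", 1)[1].split()]
                elif body.startswith("weight:"):
                    weight = float(body.split(":", 1)[1])
                continue
            rows.append([float(x) for x in line.split()])
    if lig is None or rec is None:
        raise ConstraintError(
            "matrix file must carry '# ligand_atoms:' and '# receptor_atoms:' headers")
    return MatrixConstraint(np.array(lig), np.array(rec), np.array(rows),
                            weight=weight)
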