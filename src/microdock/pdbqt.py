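"""Reading and writing the PDBQT dialect used by AutoDock-family docking tools.

PDBQT extends fixed-column PDB ATOM records with a partial charge and an
AutoDock atom type, and (for ligands) wraps them in torsion-tree records::

    ROOT / ENDROOT            -- the rigid root frame
    BRANCH a b / ENDBRANCH    -- a rotatable bond between atom serials a and b;
                                 atoms listed inside the block move with it
    TORSDOF n                 -- number of "active" torsions for the entropy term

Flexible receptor side-chains use ``BEGIN_RES``/``END_RES`` blocks with the same
ROOT/BRANCH grammar, each branch being one chi angle (at most four per residue).

Atoms are 0-indexed internally; serials in files are whatever the file says
(1-based when we write). Coordinates are in Angstrom throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Branch",
    "TorsionTree",
    "LigandTopology",
    "FlexResidue",
    "ReceptorModel",
    "PdbqtParseError",
    "AtomTypingError",
    "assign_interaction_flags",
    "parse_pdbqt_ligand",
    "parse_pdbqt_receptor",
    "write_docked_poses",
    "ligand_to_pdbqt",
    "receptor_to_pdbqt",
]


class PdbqtParseError(ValueError):
    """Malformed PDBQT content (bad nesting, truncated records, ...)."""


class AtomTypingError(ValueError):
    """An AutoDock atom type outside the supported table."""


# AutoDock atom types we understand. Values: (vdW "surface" radius used by the
# Vina-style terms, hydrophobic, acceptor). Donor-hood is a property of a heavy
# atom carrying an HD hydrogen, assigned after bond inference.
_ADTYPE_TABLE: dict[str, tuple[float, bool, bool]] = {
    "H": (1.0, False, False),
    "HD": (1.0, False, False),   # polar hydrogen; marks its heavy neighbour a donor
    "C": (1.9, True, False),     # aliphatic carbon
    "A": (1.9, True, False),     # aromatic carbon
    "N": (1.8, False, False),
    "NA": (1.8, False, True),
    "OA": (1.7, False, True),
    "S": (2.0, False, False),
    "SA": (2.0, False, True),
    "P": (2.1, False, False),
    "F": (1.5, True, False),
    "Cl": (1.8, True, False),
    "Br": (2.0, True, False),
    "I": (2.2, True, False),
}

SUPPORTED_ADTYPES = frozenset(_ADTYPE_TABLE)

#: per-adtype van der Waals radii (Angstrom) for the surface-distance convention
XS_RADII: dict[str, float] = {t: v[0] for t, v in _ADTYPE_TABLE.items()}

# covalent radii (Angstrom) for distance-based bond inference
_COVALENT_RADII = {
    "H": 0.31, "HD": 0.31, "C": 0.76, "A": 0.76, "N": 0.71, "NA": 0.71,
    "OA": 0.66, "S": 1.05, "SA": 1.05, "P": 1.07, "F": 0.57, "Cl": 1.02,
    "Br": 1.20, "I": 1.39,
}
_BOND_TOLERANCE = 1.3  # bond iff d < tol * (r_cov_i + r_cov_j)

_HYDROGEN_TYPES = frozenset({"H", "HD"})
_CARBON_TYPES = frozenset({"C", "A"})


def assign_interaction_flags(adtype: str) -> tuple[bool, bool, bool]:
    """Base interaction flags ``(hydrophobic, donor, acceptor)`` for an adtype.

    This is the pure per-type mapping: carbons are tentatively hydrophobic
    (revoked if bonded to a heteroatom), OA/NA/SA are acceptors, halogens are
    hydrophobic, and nothing is a donor until an HD hydrogen is attached to it.
    """
    try:
        _, hydrophobic, acceptor = _ADTYPE_TABLE[adtype]
    except KeyError:
        raise AtomTypingError(
            f"unsupported AutoDock atom type {adtype!r}; supported types: "
            f"{', '.join(sorted(SUPPORTED_ADTYPES))}"
        ) from None
    return hydrophobic, False, acceptor


@dataclass(eq=False)
class AtomRecord:
    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    coords: np.ndarray
    partial_charge: float
    adtype: str
    is_hydrophobic: bool = False
    is_hbond_donor: bool = False
    is_hbond_acceptor: bool = False

    @property
    def is_heavy(self) -> bool:
        return self.adtype not in _HYDROGEN_TYPES


@dataclass(eq=False)
class Branch:
    """One rotatable bond: the bond axis runs parent_atom -> child_atom and the
    atoms in ``moved`` (which include the child and everything distal to it,
    nested branches included) rotate about it."""

    parent_atom: int
    child_atom: int
    moved: np.ndarray  # sorted atom indices
    parent_branch: int = -1  # index of enclosing branch, -1 = root


@dataclass(eq=False)
class TorsionTree:
    root_atoms: list[int]
    branches: list[Branch]

    @property
    def k(self) -> int:
        return len(self.branches)

    def frame_atoms(self, branch_index: int) -> list[int]:
        """Atoms that belong to a branch's own rigid frame (its moved set minus
        every nested branch's moved set); ``branch_index=-1`` gives the root."""
        if branch_index == -1:
            return list(self.root_atoms)
        own = set(self.branches[branch_index].moved.tolist())
        for j, br in enumerate(self.branches):
            if br.parent_branch == branch_index:
                own -= set(br.moved.tolist())
        return sorted(own)


@dataclass(eq=False)
class LigandTopology:
    atoms: list[AtomRecord]
    torsion_tree: TorsionTree
    reference_coords: np.ndarray
    n_rot_torsdof: int
    bonds: list[tuple[int, int]] = field(default_factory=list)
    _graph_dist: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.atoms) != len(self.reference_coords):
            raise ValueError("reference_coords row count must equal atom count")
        if self.n_rot_torsdof < 0:
            raise ValueError("TORSDOF must be >= 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def k(self) -> int:
        return self.torsion_tree.k

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def fragment_ids(self) -> np.ndarray:
        """Rigid-fragment id per atom: 0 for the root frame, 1+i for branch i."""
        frag = np.zeros(self.n_atoms, dtype=int)
        for i, br in enumerate(self.torsion_tree.branches):
            frag[br.moved] = i + 1  # later (deeper/outer) branches overwrite
        return frag

    def bond_graph_distances(self) -> np.ndarray:
        """All-pairs bond-count separation (inf if disconnected)."""
        if self._graph_dist is None:
            n = self.n_atoms
            if self.bonds:
                ii, jj = np.array(self.bonds).T
                data = np.ones(len(self.bonds))
                adj = csr_matrix((data, (ii, jj)), shape=(n, n))
                adj = adj + adj.T
            else:
                adj = csr_matrix((n, n))
            self._graph_dist = shortest_path(adj, method="D", unweighted=True)
        return self._graph_dist


@dataclass(eq=False)
class FlexResidue:
    """A flexible receptor side-chain: up to four chi torsions off a rigid
    backbone. Axis/moved indices point into the receptor's atom list."""

    residue_id: tuple[str, int, str]  # (chain, residue_number, residue_name)
    chi_axes: list[tuple[int, int, np.ndarray]]  # (axis_a, axis_b, moved indices)
    chi_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 1 <= len(self.chi_axes) <= 4:
            raise ValueError(
                f"flexible residue {self.residue_id} must have 1..4 chi angles, "
                f"got {len(self.chi_axes)}"
            )
        if self.chi_values is None:
            self.chi_values = np.zeros(len(self.chi_axes))

    @property
    def mobile_atoms(self) -> np.ndarray:
        out: set[int] = set()
        for _, _, moved in self.chi_axes:
            out |= set(moved.tolist())
        return np.array(sorted(out), dtype=int)


@dataclass(eq=False)
class ReceptorModel:
    atoms: list[AtomRecord]
    flexible_residues: list[FlexResidue] = field(default_factory=list)

    def __post_init__(self) -> None:
        mobile: set[int] = set()
        for fr in self.flexible_residues:
            s = set(fr.mobile_atoms.tolist())
            if mobile & s:
                raise ValueError("flexible residues share mobile atoms")
            mobile |= s

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def mobile_mask(self) -> np.ndarray:
        m = np.zeros(self.n_atoms, dtype=bool)
        for fr in self.flexible_residues:
            m[fr.mobile_atoms] = True
        return m

    @property
    def rigid_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.mobile_mask)


# ---------------------------------------------------------------------------
# bond inference and flag refinement
# ---------------------------------------------------------------------------

def infer_bonds(coords: np.ndarray, adtypes: list[str]) -> list[tuple[int, int]]:
    """Distance-based covalent bond inference (PDBQT carries no CONECT)."""
    n = len(adtypes)
    if n < 2:
        return []
    radii = np.array([_COVALENT_RADII[t] for t in adtypes])
    tree = cKDTree(coords)
    bonds = []
    for i, j in sorted(tree.query_pairs(r=_BOND_TOLERANCE * 2 * radii.max())):
        cut = _BOND_TOLERANCE * (radii[i] + radii[j])
        if np.linalg.norm(coords[i] - coords[j]) < cut:
            # never bond two hydrogens
            if adtypes[i] in _HYDROGEN_TYPES and adtypes[j] in _HYDROGEN_TYPES:
                continue
            bonds.append((i, j))
    return bonds


def refine_interaction_flags(atoms: list[AtomRecord],
                             bonds: list[tuple[int, int]]) -> None:
    """Context-dependent typing: a carbon bonded to a heteroatom loses its
    hydrophobic flag; a heavy atom bonded to an HD hydrogen becomes a donor."""
    neighbours: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for i, j in bonds:
        neighbours[i].append(j)
        neighbours[j].append(i)
    for i, atom in enumerate(atoms):
        if atom.adtype in _CARBON_TYPES:
            for j in neighbours[i]:
                t = atoms[j].adtype
                if t not in _CARBON_TYPES and t not in _HYDROGEN_TYPES:
                    atom.is_hydrophobic = False
                    break
        if atom.is_heavy and any(atoms[j].adtype == "HD" for j in neighbours[i]):
            atom.is_hbond_donor = True


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:21].strip()
        chain = line[21:22].strip() or " "
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PdbqtParseError(f"line {lineno}: malformed ATOM record: {exc}") from exc
    tail = line[66:].split()
    if len(tail) < 2:
        raise PdbqtParseError(f"line {lineno}: missing partial charge / atom type")
    charge = float(tail[-2])
    adtype = tail[-1]
    hydrophobic, donor, acceptor = assign_interaction_flags(adtype)
    return AtomRecord(
        serial=serial, name=name, residue_name=residue_name, chain=chain,
        residue_number=residue_number, coords=np.array([x, y, z]),
        partial_charge=charge, adtype=adtype, is_hydrophobic=hydrophobic,
        is_hbond_donor=donor, is_hbond_acceptor=acceptor,
    )


def parse_pdbqt_ligand(text: str) -> LigandTopology:
    """Parse a ligand PDBQT with AutoDock torsion-tree records.

    ``k`` equals the number of BRANCH records; each branch's moved set is the
    set of atoms parsed inside its BRANCH/ENDBRANCH block (nesting included).
    """
    atoms: list[AtomRecord] = []
    serial_to_index: dict[int, int] = {}
    root_atoms: list[int] = []
    # stack entries: (parent_serial, child_serial, moved_index_list, parent_branch_slot)
    stack: list[list] = []
    branches_raw: list[tuple[int, int, list[int], int]] = []
    in_root = False
    seen_root = False
    root_closed = False
    torsdof = None
    open_branch_slots: list[int] = []  # indices into branches_raw, innermost last

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line:
            continue
        rec = line.split()[0]
        if rec == "ROOT":
            if seen_root:
                raise PdbqtParseError(f"line {lineno}: duplicate ROOT")
            in_root = seen_root = True
        elif rec == "ENDROOT":
            if not in_root:
                raise PdbqtParseError(f"line {lineno}: ENDROOT without ROOT")
            in_root = False
            root_closed = True
        elif rec == "BRANCH":
            parts = line.split()
            if len(parts) != 3:
                raise PdbqtParseError(f"line {lineno}: BRANCH needs two serials")
            parent_s, child_s = int(parts[1]), int(parts[2])
            parent_slot = open_branch_slots[-1] if open_branch_slots else -1
            branches_raw.append((parent_s, child_s, [], parent_slot))
            open_branch_slots.append(len(branches_raw) - 1)
        elif rec == "ENDBRANCH":
            if not open_branch_slots:
                raise PdbqtParseError(f"line {lineno}: ENDBRANCH without BRANCH")
            parts = line.split()
            slot = open_branch_slots.pop()
            if len(parts) == 3:
                p, c = int(parts[1]), int(parts[2])
                if (p, c) != branches_raw[slot][:2]:
                    raise PdbqtParseError(
                        f"line {lineno}: ENDBRANCH {p} {c} does not match "
                        f"open BRANCH {branches_raw[slot][0]} {branches_raw[slot][1]}"
                    )
        elif rec == "TORSDOF":
            torsdof = int(line.split()[1])
        elif rec in ("ATOM", "HETATM"):
            atom = _parse_atom_line(line, lineno)
            idx = len(atoms)
            atoms.append(atom)
            serial_to_index[atom.serial] = idx
            if in_root:
                root_atoms.append(idx)
            elif open_branch_slots:
                for slot in open_branch_slots:
                    branches_raw[slot][2].append(idx)
            elif root_closed:
                raise PdbqtParseError(
                    f"line {lineno}: atom outside ROOT and any BRANCH block")
            else:
                raise PdbqtParseError(f"line {lineno}: atom before ROOT")
        # REMARK / MODEL / ENDMDL / USER lines are ignored

    if not seen_root:
        raise PdbqtParseError("no ROOT record found")
    if in_root:
        raise PdbqtParseError("ROOT not closed by ENDROOT")
    if open_branch_slots:
        raise PdbqtParseError("unclosed BRANCH block(s) at end of file")
    if not atoms:
        raise PdbqtParseError("no atoms found")

    branches = []
    for parent_s, child_s, moved, parent_slot in branches_raw:
        try:
            parent_idx = serial_to_index[parent_s]
            child_idx = serial_to_index[child_s]
        except KeyError as exc:
            raise PdbqtParseError(f"BRANCH references unknown serial {exc}") from None
        branches.append(Branch(
            parent_atom=parent_idx, child_atom=child_idx,
            moved=np.array(sorted(moved), dtype=int), parent_branch=parent_slot,
        ))

    coords = np.array([a.coords for a in atoms], dtype=float)
    bonds = infer_bonds(coords, [a.adtype for a in atoms])
    refine_interaction_flags(atoms, bonds)
    tree = TorsionTree(root_atoms=root_atoms, branches=branches)
    return LigandTopology(
        atoms=atoms, torsion_tree=tree, reference_coords=coords,
        n_rot_torsdof=torsdof if torsdof is not None else len(branches),
        bonds=bonds,
    )


def parse_pdbqt_receptor(text: str, flex_text: str | None = None) -> ReceptorModel:
    """Parse a rigid receptor PDBQT, optionally with flexible-residue records.

    The rigid file must contain every atom (including flexible side-chains);
    ``flex_text`` only designates which residues are flexible and how their chi
    branches nest. Unknown residues/HETATM entries are kept as rigid atoms.
    """
    atoms: list[AtomRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line:
            continue
        if line.split()[0] in ("ATOM", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno))
    if not atoms:
        raise PdbqtParseError("receptor contains no atoms")
    coords = np.array([a.coords for a in atoms], dtype=float)
    bonds = infer_bonds(coords, [a.adtype for a in atoms])
    refine_interaction_flags(atoms, bonds)

    flex_residues: list[FlexResidue] = []
    if flex_text is not None:
        locate = {
            (a.chain, a.residue_number, a.name): i for i, a in enumerate(atoms)
        }
        residue_keys = {(a.chain, a.residue_number) for a in atoms}
        flex_residues = _parse_flex_with_axes(flex_text, locate, residue_keys)
    return ReceptorModel(atoms=atoms, flexible_residues=flex_residues)


def _parse_flex_with_axes(flex_text: str, locate, residue_keys) -> list[FlexResidue]:
    residues: list[FlexResidue] = []
    current = None
    serial_to_idx: dict[int, int] = {}
    open_branches: list[list] = []
    pending: list[list] = []  # [parent_serial, child_serial, moved_idx_list]

    def close_residue(lineno: int) -> None:
        nonlocal current, serial_to_idx, pending
        if open_branches:
            raise PdbqtParseError(f"line {lineno}: unclosed BRANCH in residue")
        if len(pending) > 4:
            raise PdbqtParseError(
                f"residue {current['chain']}:{current['resnum']} has "
                f"{len(pending)} chi branches (max 4)")
        chi_axes = []
        for ps, cs, moved in pending:
            try:
                a_idx, b_idx = serial_to_idx[ps], serial_to_idx[cs]
            except KeyError:
                raise PdbqtParseError(
                    f"BRANCH serial in residue {current['chain']}:"
                    f"{current['resnum']} not among its atoms") from None
            chi_axes.append((a_idx, b_idx, np.array(sorted(moved), dtype=int)))
        residues.append(FlexResidue(
            residue_id=(current["chain"], current["resnum"], current["resname"]),
            chi_axes=chi_axes))
        current, serial_to_idx, pending = None, {}, []

    for lineno, raw in enumerate(flex_text.splitlines(), start=1):
        line = raw.rstrip()
        if not line:
            continue
        rec = line.split()[0]
        if rec == "BEGIN_RES":
            parts = line.split()
            if len(parts) < 4:
                raise PdbqtParseError(f"line {lineno}: malformed BEGIN_RES")
            chain, resnum = parts[2], int(parts[3])
            if (chain, resnum) not in residue_keys:
                raise PdbqtParseError(
                    f"line {lineno}: flexible residue {chain}:{resnum} absent "
                    f"from the rigid receptor file")
            current = {"resname": parts[1], "chain": chain, "resnum": resnum}
        elif rec == "END_RES":
            if current is None:
                raise PdbqtParseError(f"line {lineno}: END_RES without BEGIN_RES")
            close_residue(lineno)
        elif rec == "BRANCH":
            parts = line.split()
            pending.append([int(parts[1]), int(parts[2]), []])
            open_branches.append(pending[-1])
        elif rec == "ENDBRANCH":
            if not open_branches:
                raise PdbqtParseError(f"line {lineno}: ENDBRANCH without BRANCH")
            open_branches.pop()
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                raise PdbqtParseError(f"line {lineno}: atom outside BEGIN_RES")
            atom = _parse_atom_line(line, lineno)
            key = (current["chain"], current["resnum"], atom.name)
            if key not in locate:
                raise PdbqtParseError(
                    f"line {lineno}: flexible atom {atom.name} of residue "
                    f"{current['chain']}:{current['resnum']} not in rigid file")
            idx = locate[key]
            serial_to_idx[atom.serial] = idx
            for br in open_branches:
                br[2].append(idx)
    if current is not None:
        raise PdbqtParseError("BEGIN_RES not closed by END_RES")
    return residues


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_atom_line(atom: AtomRecord, coords: np.ndarray) -> str:
    name = atom.name if len(atom.name) == 4 else f"{atom.name:<3}"
    return (
        f"ATOM  {atom.serial:>5} {name:<4} {atom.residue_name:<3.3s} "
        f"{atom.chain:1}{atom.residue_number:>4}    "
        f"{coords[0]:>8.3f}{coords[1]:>8.3f}{coords[2]:>8.3f}"
        f"{1.00:>6.2f}{0.00:>6.2f}    {atom.partial_charge:>6.3f} {atom.adtype:<2}"
    )


def ligand_to_pdbqt(topology: LigandTopology,
                    coords: np.ndarray | None = None,
                    remarks: tuple[str, ...] = ()) -> str:
    """Serialize a ligand topology (optionally with replacement coordinates)
    back to torsion-tree PDBQT; the tree nesting is reconstructed exactly."""
    if coords is None:
        coords = topology.reference_coords
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError("coordinate array does not match the ligand topology")
    tree = topology.torsion_tree
    lines = [f"REMARK {r}" for r in remarks]
    lines.append("ROOT")
    for i in tree.root_atoms:
        lines.append(_format_atom_line(topology.atoms[i], coords[i]))
    lines.append("ENDROOT")

    children: dict[int, list[int]] = {}
    for j, br in enumerate(tree.branches):
        children.setdefault(br.parent_branch, []).append(j)

    def emit(branch_index: int) -> None:
        br = tree.branches[branch_index]
        pa = topology.atoms[br.parent_atom].serial
        ca = topology.atoms[br.child_atom].serial
        lines.append(f"BRANCH {pa:>3} {ca:>3}")
        for i in tree.frame_atoms(branch_index):
            lines.append(_format_atom_line(topology.atoms[i], coords[i]))
        for child in children.get(branch_index, []):
            emit(child)
        lines.append(f"ENDBRANCH {pa:>3} {ca:>3}")

    for top in children.get(-1, []):
        emit(top)
    lines.append(f"TORSDOF {topology.n_rot_torsdof}")
    return "\n".join(lines) + "\n"


def receptor_to_pdbqt(receptor: ReceptorModel) -> str:
    lines = [_format_atom_line(a, a.coords) for a in receptor.atoms]
    return "\n".join(lines) + "\n"


def write_docked_poses(poses, topology: LigandTopology, path) -> None:
    """Write a multi-model PDBQT of docked poses, best score first.

    ``poses`` is a sequence of ``(coords, breakdown)`` where ``breakdown`` has
    ``total`` and ``predicted_free_energy`` attributes. Each MODEL carries
    REMARK lines with its rank, predicted binding free energy (kcal/mol) and
    heavy-atom RMSD to the best pose.
    """
    from .conformation import heavy_atom_rmsd  # local import to avoid a cycle

    poses = list(poses)
    for coords, _ in poses:
        if np.asarray(coords).shape != (topology.n_atoms, 3):
            raise ValueError("pose coordinates do not match the ligand topology")
    order = sorted(range(len(poses)), key=lambda i: poses[i][1].total)
    heavy = topology.heavy_mask
    best = np.asarray(poses[order[0]][0]) if poses else None
    blocks = []
    for rank, i in enumerate(order, start=1):
        coords, bd = poses[i]
        rmsd = heavy_atom_rmsd(np.asarray(coords), best, heavy)
        remarks = (
            f"RANK {rank}",
            f"SCORE {bd.total:.4f}",
            f"PREDICTED_FREE_ENERGY {bd.predicted_free_energy:.3f} kcal/mol",
            f"RMSD_TO_BEST {rmsd:.3f}",
        )
        body = ligand_to_pdbqt(topology, np.asarray(coords), remarks=remarks)
        blocks.append(f"MODEL {rank:>8}\n{body}ENDMDL\n")
    with open(path, "w") as fh:
        fh.write("".join(blocks))
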