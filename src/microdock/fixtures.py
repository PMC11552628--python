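"""Synthetic receptors, ligands and planted-optimum benchmarks.

Every structure here is generated programmatically (deterministic in its
seed) so the whole engine is testable without downloading any real complex.

The toy ligand is a zigzag heavy-atom chain with chemically plausible bond
lengths (1.45-1.55 Angstrom), tetrahedral-like angles, a valid torsion tree
with ``k`` rotatable bonds, and mixed atom types (an HD-bearing amine donor at
one end, a carbonyl-like OA acceptor at the other, apolar carbons between).

The toy pocket is a shell of receptor atoms built around a chosen ligand pose:
each ligand heavy atom gets complementary partners placed near the optimum of
the matching interaction term (apolar carbons at slightly positive surface
distance for the hydrophobic/gauss terms, donors/acceptors at slightly
negative surface distance for the hydrogen-bond term), plus an outer cage of
carbons that blocks trivially equivalent placements. By construction the
planted pose is clash-free and strongly favoured, which gives the samplers a
funnel-shaped landscape with a known global optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conformation import DockingBox
from .pdbqt import (AtomRecord, LigandTopology, ReceptorModel, XS_RADII,
                    infer_bonds, parse_pdbqt_ligand, refine_interaction_flags)

__all__ = [
    "make_toy_ligand",
    "make_toy_pocket",
    "make_funnel_benchmark",
    "perturb_matrix",
    "native_distance_matrix",
    "FunnelTarget",
]


def _chain_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    """Zigzag chain of n atoms, bond lengths ~1.5 A, angles ~109 deg."""
    d0 = np.array([1.0, 0.45, 0.12])
    d1 = np.array([1.0, -0.45, -0.12])
    coords = [np.zeros(3)]
    for i in range(1, n):
        d = (d0 if i % 2 else d1) + rng.normal(0.0, 0.02, 3)
        d = d / np.linalg.norm(d) * (1.5 + rng.uniform(-0.05, 0.05))
        coords.append(coords[-1] + d)
    return np.array(coords)


def _atom_line(serial, name, resname, chain, resnum, xyz, charge, adtype):
    nm = name if len(name) == 4 else f"{name:<3}"
    return (f"ATOM  {serial:>5} {nm:<4} {resname:<3.3s} {chain:1}{resnum:>4}    "
            f"{xyz[0]:>8.3f}{xyz[1]:>8.3f}{xyz[2]:>8.3f}{1.00:>6.2f}{0.00:>6.2f}"
            f"    {charge:>6.3f} {adtype:<2}")


def make_toy_ligand(n_atoms: int, k: int, seed: int
                    ) -> tuple[str, LigandTopology]:
    """Generate a toy ligand as PDBQT text plus its parsed topology.

    ``n_atoms`` counts heavy atoms; one HD hydrogen is added on the terminal
    amine. The torsion tree has exactly ``k`` nested branches along the chain.
    """
    if n_atoms < k + 2:
        raise ValueError(f"need n_atoms >= k+2 (got n_atoms={n_atoms}, k={k})")
    rng = np.random.default_rng(seed)
    coords = _chain_coords(n_atoms, rng)
    coords -= coords.mean(axis=0)

    # types: amine donor at the head, acceptor at the tail, carbons between
    adtypes = ["C"] * n_atoms
    adtypes[0] = "N"
    adtypes[-1] = "OA"
    if n_atoms >= 7:
        adtypes[n_atoms // 2] = "OA"

    # split the chain: root frame then k consecutive branch segments
    if k > 0:
        n_root = n_atoms - 2 * k if n_atoms - 2 * k >= 3 else n_atoms - k
        tail = n_atoms - n_root
        seg_sizes = [tail // k + (1 if i < tail % k else 0) for i in range(k)]
        cuts = np.cumsum([n_root] + seg_sizes)[:-1]  # branch child start indices
    else:
        n_root = n_atoms
        cuts = np.array([], dtype=int)

    # the HD hydrogen on the head amine, placed off-chain
    away = coords[0] - coords[1]
    away = away / np.linalg.norm(away)
    h_pos = coords[0] + away * 1.0

    charges = np.round(rng.normal(0.0, 0.08, n_atoms + 1), 3)
    names = []
    counters: dict[str, int] = {}
    for t in adtypes:
        base = {"N": "N", "OA": "O", "C": "C", "A": "C"}[t]
        counters[base] = counters.get(base, 0) + 1
        names.append(f"{base}{counters[base]}")

    lines = ["ROOT"]
    serial_of = {}

    def emit(i):
        serial = len(serial_of) + 1
        serial_of[i] = serial
        lines.append(_atom_line(serial, names[i], "LIG", "A", 1, coords[i],
                                charges[i], adtypes[i]))

    for i in range(n_root):
        emit(i)
    # hydrogen lives in the root frame, bonded to atom 0
    serial_h = n_root + 1
    serial_of["H"] = serial_h
    lines.append(_atom_line(serial_h, "HN", "LIG", "A", 1, h_pos,
                            charges[-1], "HD"))
    lines.append("ENDROOT")
    for j, start in enumerate(cuts):
        end = cuts[j + 1] if j + 1 < len(cuts) else n_atoms
        lines.append(f"BRANCH {serial_of[start - 1]:>3} {len(serial_of) + 1:>3}")
        for i in range(start, end):
            emit(i)
    for j in range(len(cuts) - 1, -1, -1):
        start = cuts[j]
        lines.append(f"ENDBRANCH {serial_of[start - 1]:>3} {serial_of[start]:>3}")
    lines.append(f"TORSDOF {k}")
    text = "\n".join(lines) + "\n"
    return text, parse_pdbqt_ligand(text)


def _make_receptor_atoms(specs) -> ReceptorModel:
    atoms = []
    for i, (name, adtype, xyz, resnum) in enumerate(specs, start=1):
        atoms.append(AtomRecord(
            serial=i, name=name, residue_name="POC", chain="A",
            residue_number=resnum, coords=np.asarray(xyz, dtype=float),
            partial_charge=0.0, adtype=adtype,
            is_hydrophobic=adtype in ("C", "A"), is_hbond_donor=False,
            is_hbond_acceptor=adtype in ("OA", "NA", "SA")))
    coords = np.array([a.coords for a in atoms])
    bonds = infer_bonds(coords, [a.adtype for a in atoms])
    refine_interaction_flags(atoms, bonds)
    return ReceptorModel(atoms=atoms)


def make_toy_pocket(ligand: LigandTopology, seed: int,
                    partners_per_atom: int = 3,
                    cage_atoms: int = 30,
                    ) -> tuple[ReceptorModel, np.ndarray, DockingBox]:
    """Build a pocket shell around the ligand's reference pose.

    Returns ``(receptor, planted_coords, box)`` where the planted pose (the
    zero pose vector) is clash-free, richly contacted and, by construction,
    the funnel minimum of the empirical score inside the box.
    """
    rng = np.random.default_rng(seed)
    planted = ligand.reference_coords.copy()
    heavy_idx = np.flatnonzero(ligand.heavy_mask)
    centroid = planted[heavy_idx].mean(axis=0)
    lig_radii = np.array([XS_RADII[ligand.atoms[i].adtype] for i in heavy_idx])

    specs = []  # (name, adtype, xyz, resnum)
    placed: list[np.ndarray] = []
    placed_r: list[float] = []

    def clash_free(pos, r_new, min_rec_gap=2.4, exclude=None):
        d_lig = np.linalg.norm(planted[heavy_idx] - pos, axis=1)
        limit = lig_radii + r_new - 0.05
        if exclude is not None:
            limit[exclude] = 0.0  # the partner's own target sits closer on purpose
        if np.any(d_lig < limit):
            return False
        for q, rq in zip(placed, placed_r):
            if np.linalg.norm(q - pos) < min_rec_gap:
                return False
        return True

    counter = 0
    for ai, i in enumerate(heavy_idx):
        atom = ligand.atoms[i]
        if atom.is_hbond_donor:
            partner_types = ["OA", "OA"]
        elif atom.is_hbond_acceptor:
            partner_types = ["N", "N"]  # each gets an HD to become a donor
        else:
            partner_types = ["C"] * partners_per_atom
        base_dir = planted[i] - centroid
        nb = np.linalg.norm(base_dir)
        base_dir = base_dir / nb if nb > 0.3 else None
        for pt in partner_types:
            r_pair = XS_RADII[ligand.atoms[i].adtype] + XS_RADII[pt]
            s = -0.35 if pt in ("OA", "N") else 0.15
            dist = r_pair + s
            ok = False
            for _ in range(30):
                d = (base_dir if base_dir is not None
                     else rng.normal(size=3))
                d = d + rng.normal(0.0, 0.45, 3)
                d = d / np.linalg.norm(d)
                pos = planted[i] + d * dist
                if clash_free(pos, XS_RADII[pt], exclude=ai):
                    ok = True
                    break
            if not ok:
                continue
            counter += 1
            specs.append((f"{'O' if pt == 'OA' else pt}{counter}", pt, pos,
                          counter))
            placed.append(pos)
            placed_r.append(XS_RADII[pt])
            if pt == "N":
                # give the nitrogen an HD pointing at the ligand acceptor
                u = (planted[i] - pos)
                u = u / np.linalg.norm(u)
                specs.append((f"H{counter}", "HD", pos + u * 1.0, counter))

    # outer cage of carbons on a Fibonacci sphere: blocks equivalent placements
    extent = np.max(np.linalg.norm(planted[heavy_idx] - centroid, axis=1))
    cage_r = extent + 5.5
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for j in range(cage_atoms):
        z = 1.0 - 2.0 * (j + 0.5) / cage_atoms
        rad = np.sqrt(max(0.0, 1.0 - z * z))
        th = golden * j
        pos = centroid + cage_r * np.array([rad * np.cos(th),
                                            rad * np.sin(th), z])
        if clash_free(pos, XS_RADII["C"], min_rec_gap=2.2):
            counter += 1
            specs.append((f"C{counter}", "C", pos, counter))
            placed.append(pos)
            placed_r.append(XS_RADII["C"])

    receptor = _make_receptor_atoms(specs)
    box_edge = max(10.0, 2.0 * extent + 3.0)
    box = DockingBox(center=centroid, size=np.full(3, box_edge))
    return receptor, planted, box


@dataclass
class FunnelTarget:
    """One synthetic complex with known ground truth."""

    ligand_text: str
    ligand: LigandTopology
    receptor: ReceptorModel
    box: DockingBox
    planted_coords: np.ndarray
    native_matrix: np.ndarray          # heavy-ligand x heavy-receptor distances
    ligand_atoms: np.ndarray           # row indices (into ligand atoms)
    receptor_atoms: np.ndarray         # column indices (into receptor atoms)


def native_distance_matrix(lig_coords, rec_coords, lig_idx, rec_idx):
    diff = lig_coords[lig_idx][:, None, :] - rec_coords[rec_idx][None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def make_funnel_benchmark(n_targets: int, seed: int) -> list[FunnelTarget]:
    """Independent toy complexes with stored ground truth and per-target
    native ligand-receptor distance matrices."""
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    targets = []
    for t in range(n_targets):
        sub = seed + 1000 * t
        n_atoms = 6 + t % 3
        k = 1 + t % 2
        text, lig = make_toy_ligand(n_atoms=n_atoms, k=k, seed=sub)
        receptor, planted, box = make_toy_pocket(lig, seed=sub + 7)
        lig_idx = np.flatnonzero(lig.heavy_mask)
        rec_idx = np.flatnonzero(receptor.heavy_mask)
        native = native_distance_matrix(planted, receptor.coords,
                                        lig_idx, rec_idx)
        targets.append(FunnelTarget(
            ligand_text=text, ligand=lig, receptor=receptor, box=box,
            planted_coords=planted, native_matrix=native,
            ligand_atoms=lig_idx, receptor_atoms=rec_idx))
    return targets


def perturb_matrix(matrix: np.ndarray, mean_magnitude: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian noise whose absolute value has the stated mean
    (sigma = mean * sqrt(pi/2)); entries are kept positive."""
    if mean_magnitude == 0:
        return matrix.copy()
    sigma = mean_magnitude * np.sqrt(np.pi / 2.0)
    noisy = matrix + rng.normal(0.0, sigma, matrix.shape)
    return np.maximum(noisy, 0.1)
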