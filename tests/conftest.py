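"""Shared fixtures: generated toy structures, docking systems, receptors."""

from __future__ import annotations

import numpy as np
import pytest

from microdock import DockingSystem, VinaScore
from microdock.fixtures import make_funnel_benchmark, make_toy_ligand, make_toy_pocket


def atom_line(serial, name, resname, chain, resnum, xyz, charge, adtype):
    nm = name if len(name) == 4 else f"{name:<3}"
    return (f"ATOM  {serial:>5} {nm:<4} {resname:<3.3s} {chain:1}{resnum:>4}    "
            f"{xyz[0]:>8.3f}{xyz[1]:>8.3f}{xyz[2]:>8.3f}{1.00:>6.2f}{0.00:>6.2f}"
            f"    {charge:>6.3f} {adtype:<2}")


@pytest.fixture(scope="session")
def toy_ligand():
    """An 8-heavy-atom ligand with two nested rotatable bonds."""
    text, topology = make_toy_ligand(n_atoms=8, k=2, seed=1)
    return text, topology


@pytest.fixture(scope="session")
def pocket(toy_ligand):
    _, topology = toy_ligand
    receptor, planted, box = make_toy_pocket(topology, seed=3)
    return receptor, planted, box


@pytest.fixture(scope="session")
def system(toy_ligand, pocket):
    _, topology = toy_ligand
    receptor, _, box = pocket
    return DockingSystem(topology, receptor, box)


@pytest.fixture(scope="session")
def vina(system):
    return VinaScore(system)


@pytest.fixture(scope="session")
def funnel_targets():
    """The 20-complex planted-optimum benchmark used for recovery checks."""
    return make_funnel_benchmark(20, seed=11)


# --- a small serine-containing receptor for flexible-residue parsing -------

_SER_ATOMS = [
    # (name, adtype, xyz)
    ("N", "N", (0.00, 0.00, 0.00)),
    ("CA", "C", (1.46, 0.00, 0.00)),
    ("C", "C", (2.10, 1.33, 0.00)),
    ("O", "OA", (3.32, 1.42, 0.10)),
    ("CB", "C", (2.00, -0.77, 1.21)),
    ("OG", "OA", (1.55, -2.10, 1.25)),
]


@pytest.fixture(scope="session")
def serine_receptor_text():
    lines = [atom_line(i + 1, n, "SER", "A", 87, xyz, 0.0, t)
             for i, (n, t, xyz) in enumerate(_SER_ATOMS)]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def serine_flex_text():
    """One chi angle: rotate OG about the CA-CB axis."""
    lines = [
        "BEGIN_RES SER A 87",
        "ROOT",
        atom_line(1, "CA", "SER", "A", 87, _SER_ATOMS[1][2], 0.0, "C"),
        "ENDROOT",
        "BRANCH 1 2",
        atom_line(2, "CB", "SER", "A", 87, _SER_ATOMS[4][2], 0.0, "C"),
        atom_line(3, "OG", "SER", "A", 87, _SER_ATOMS[5][2], 0.0, "OA"),
        "ENDBRANCH 1 2",
        "END_RES",
    ]
    return "\n".join(lines) + "\n"


def make_chain_flex_text(n_chis: int) -> tuple[str, str]:
    """A lysine-like side chain with ``n_chis`` nested chi branches; returns
    (rigid receptor text, flex text)."""
    names = ["CA", "CB", "CG", "CD", "CE", "NZ", "CH", "CI"][: n_chis + 2]
    xyz = [(1.5 * i, 0.4 * (i % 2), 0.0) for i in range(len(names))]
    rigid = "\n".join(
        atom_line(i + 1, n, "LYS", "A", 41, p, 0.0, "C")
        for i, (n, p) in enumerate(zip(names, xyz))) + "\n"
    lines = ["BEGIN_RES LYS A 41", "ROOT",
             atom_line(1, names[0], "LYS", "A", 41, xyz[0], 0.0, "C"),
             "ENDROOT"]
    for c in range(n_chis):
        lines.append(f"BRANCH {c + 1} {c + 2}")
        lines.append(atom_line(c + 2, names[c + 1], "LYS", "A", 41,
                               xyz[c + 1], 0.0, "C"))
        if c == n_chis - 1:
            lines.append(atom_line(c + 3, names[c + 2], "LYS", "A", 41,
                                   xyz[c + 2], 0.0, "C"))
    for c in range(n_chis - 1, -1, -1):
        lines.append(f"ENDBRANCH {c + 1} {c + 2}")
    lines.append("END_RES")
    return rigid, "\n".join(lines) + "\n"
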