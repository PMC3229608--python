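"""Shared fixtures: hand-written PDB fixtures and a cached synthetic study."""

from __future__ import annotations

import logging

import numpy as np
import pytest

import tsmut

logging.getLogger("tsmut").setLevel(logging.ERROR)


def _pdb_line(serial, name, resname, chain, resnum, xyz, b=20.0, element=None,
              altloc=" ", icode=" "):
    element = element or name[0]
    pname = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {pname:<4s}{altloc}{resname:<3s} {chain:1s}"
        f"{resnum:4d}{icode}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


def make_pdb(residues) -> str:
    """Build PDB text from (resname, chain, resnum, [(atom, xyz, b)], ...) tuples."""
    lines = []
    serial = 1
    for resname, chain, resnum, atoms in residues:
        for entry in atoms:
            name, xyz, b = entry[0], entry[1], entry[2]
            altloc = entry[3] if len(entry) > 3 else " "
            lines.append(_pdb_line(serial, name, resname, chain, resnum, xyz, b,
                                   altloc=altloc))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def poly_ala_pdb() -> str:
    """Five alanines on a straight line, 3.8 Å apart, with CB side chains."""
    residues = []
    for i in range(5):
        x = 3.8 * i
        residues.append(
            ("ALA", "A", i + 1, [
                ("N", (x - 1.2, 0.0, 0.0), 18.0),
                ("CA", (x, 0.0, 0.0), 20.0),
                ("CB", (x, 1.5, 0.0), 25.0),
                ("O", (x + 1.2, 0.0, 0.0), 22.0),
            ])
        )
    return make_pdb(residues)


@pytest.fixture(scope="session")
def study():
    """A cached synthetic protein + alignments + labeled cohort."""
    structure, alignments, cohort = tsmut.generate_study(
        seed=11, spec=tsmut.SyntheticSpec(n_residues=60), n_mutations=150
    )
    return structure, alignments, cohort


@pytest.fixture(scope="session")
def compact_structure():
    structure, _ = tsmut.generate_structure(
        tsmut.SyntheticSpec(n_residues=40, seed=7)
    )
    return structure


def straight_chain(n: int, spacing: float = 3.8) -> np.ndarray:
    return np.column_stack(
        (spacing * np.arange(n), np.zeros(n), np.zeros(n))
    )


def brute_force_delaunay(points: np.ndarray, tol: float = 1e-9):
    """Empty-circumsphere enumeration over all 4-subsets (tessellation oracle)."""
    from itertools import combinations

    n = len(points)
    tets = []
    for quad in combinations(range(n), 4):
        p = points[list(quad)]
        A = 2.0 * (p[1:] - p[0])
        b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
        try:
            center = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue  # flat tetrahedron
        r2 = ((p[0] - center) ** 2).sum()
        others = [i for i in range(n) if i not in quad]
        d2 = ((points[others] - center) ** 2).sum(axis=1)
        if np.all(d2 > r2 + tol):
            tets.append(tuple(sorted(quad)))
    return sorted(tets)
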