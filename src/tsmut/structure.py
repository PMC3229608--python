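"""Single-chain protein structure model, PDB I/O and per-residue structural quantities.

The internal residue coordinate is a 0-based ``seq_index`` (rank along the
chain); all user-facing I/O uses PDB author numbering. Only the 20 canonical
amino acids with a Cα atom are retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    AA_ONE_TO_THREE,
    AA_THREE_TO_ONE,
    MAX_ASA,
    VDW_DEFAULT,
    VDW_RADII,
)

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    b_factor: float


@dataclass
class Residue:
    """One retained residue of a chain.

    ``b_residue`` is the mean thermal factor over all atoms of the residue;
    ``b_sidechain`` the mean over non-backbone atoms, and ``None`` for
    residues without side-chain atoms (Gly).
    """

    chain_id: str
    seq_index: int
    author_number: int
    insertion_code: str
    aa: str
    atoms: list[Atom]

    @property
    def ca_xyz(self) -> np.ndarray:
        for a in self.atoms:
            if a.name == "CA":
                return np.asarray(a.xyz, dtype=float)
        raise ValueError(f"residue {self.author_number} has no CA atom")

    @property
    def b_residue(self) -> float:
        return float(np.mean([a.b_factor for a in self.atoms]))

    @property
    def b_sidechain(self) -> float | None:
        side = [a.b_factor for a in self.atoms if a.name not in BACKBONE_ATOMS]
        if not side:
            return None
        return float(np.mean(side))


@dataclass
class ProteinStructure:
    residues: list[Residue]
    source_id: str = ""
    resolution: float | None = None
    ligand_atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates in seq_index order."""
        return np.array([r.ca_xyz for r in self.residues], dtype=float)

    def all_atoms(self) -> list[tuple[int, Atom]]:
        """Flat list of (seq_index, atom) over all residues."""
        return [(r.seq_index, a) for r in self.residues for a in r.atoms]

    def author_to_index(self) -> dict[int, int]:
        """Map author residue number -> seq_index (icode-free positions)."""
        return {r.author_number: r.seq_index for r in self.residues if not r.insertion_code}

    def to_pdb(self) -> str:
        """Serialize the retained residues as PDB ATOM records."""
        lines = []
        serial = 1
        for res in self.residues:
            resname = AA_ONE_TO_THREE[res.aa]
            for atom in res.atoms:
                name = atom.name
                # Standard PDB alignment: element symbols of one letter start
                # in column 14 for short names.
                if len(name) < 4:
                    name = f" {name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {res.chain_id:1s}"
                    f"{res.author_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
                    f"{1.00:6.2f}{atom.b_factor:6.2f}          "
                    f"{atom.element:>2s}"
                )
                serial += 1
        lines.append("END")
        return "\n".join(lines) + "\n"


class ChainNotFoundError(KeyError):
    pass


class EmptyChainError(ValueError):
    pass


def read_structure(pdb_text: str, chain: str, source_id: str = "") -> ProteinStructure:
    """Parse PDB text into a single-chain residue model.

    Keeps only canonical amino-acid residues that have a Cα atom; residues
    lacking Cα are dropped with a warning. For alternate locations the first
    occurrence in file order of each atom name is kept. Residues are ordered
    by author number, insertion codes after their base number, and
    ``seq_index`` is assigned 0..n-1 in that order.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise EmptyChainError("no models in PDB text")
    model = st[0]
    gchain = None
    for c in model:
        if c.name == chain:
            gchain = c
            break
    if gchain is None:
        raise ChainNotFoundError(f"chain not found: {chain!r}")

    residues: list[Residue] = []
    ligand_atoms: list[Atom] = []
    seen: set[tuple[int, str]] = set()
    for gres in gchain:
        resname = gres.name.strip().upper()
        number = gres.seqid.num
        icode = (gres.seqid.icode or "").strip()
        if resname not in AA_THREE_TO_ONE:
            if resname != "HOH":
                for ga in gres:
                    if ga.element.name != "H":
                        ligand_atoms.append(
                            Atom(ga.name, ga.element.name.upper(),
                                 (ga.pos.x, ga.pos.y, ga.pos.z), ga.b_iso)
                        )
            continue
        key = (number, icode)
        if key in seen:
            continue
        seen.add(key)
        atoms: list[Atom] = []
        names_seen: set[str] = set()
        for ga in gres:
            if ga.name in names_seen:  # later altloc of an already-kept atom
                continue
            names_seen.add(ga.name)
            atoms.append(
                Atom(ga.name, ga.element.name.upper(),
                     (ga.pos.x, ga.pos.y, ga.pos.z), ga.b_iso)
            )
        if "CA" not in names_seen:
            logger.warning(
                "dropping residue %s%s %s: no CA atom", number, icode, resname
            )
            continue
        residues.append(
            Residue(
                chain_id=chain,
                seq_index=-1,
                author_number=number,
                insertion_code=icode,
                aa=AA_THREE_TO_ONE[resname],
                atoms=atoms,
            )
        )
    if not residues:
        raise EmptyChainError(f"empty chain: no residues with CA in chain {chain!r}")
    residues.sort(key=lambda r: (r.author_number, r.insertion_code))
    for i, r in enumerate(residues):
        r.seq_index = i
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return ProteinStructure(
        residues=residues,
        source_id=source_id or f"{(st.name or 'struct').strip()}_{chain}",
        resolution=resolution,
        ligand_atoms=ligand_atoms,
    )


# ---------------------------------------------------------------------------
# Solvent accessibility
# ---------------------------------------------------------------------------

@dataclass
class AccessibilityProfile:
    """Per-residue absolute (Å²) and relative solvent accessibility."""

    sasa: np.ndarray
    rsa: np.ndarray


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), VDW_DEFAULT)


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Shrake–Rupley numerical SASA per atom.

    Test points are placed on each atom's solvent-expanded sphere; a point is
    exposed if it lies outside every other atom's expanded sphere. The result
    is deterministic for a fixed point count.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    n = coords.shape[0]
    expanded = np.asarray(radii, dtype=float) + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    out = np.empty(n)
    for i in range(n):
        r = expanded[i]
        pts = coords[i] + r * unit
        neigh = [j for j in tree.query_ball_point(coords[i], r + max_r) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        out[i] = exposed.mean() * 4.0 * math.pi * r * r
    return out


def compute_accessibility(
    structure: ProteinStructure,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> AccessibilityProfile:
    """Per-residue SASA and relative accessibility of the chain.

    RSA is the residue SASA divided by the bundled max-ASA value of its
    residue type; values slightly above 1 occur for exposed termini.
    """
    flat = structure.all_atoms()
    if not flat:
        raise ValueError("structure has no atoms")
    coords = np.array([a.xyz for _, a in flat], dtype=float)
    radii = np.array([_vdw_radius(a.element) for _, a in flat])
    per_atom = atom_sasa(coords, radii, probe_radius=probe_radius, n_points=n_points)
    n = len(structure)
    sasa = np.zeros(n)
    for (idx, _), s in zip(flat, per_atom):
        sasa[idx] += s
    rsa = np.array([sasa[r.seq_index] / MAX_ASA[r.aa] for r in structure.residues])
    return AccessibilityProfile(sasa=sasa, rsa=rsa)


# ---------------------------------------------------------------------------
# Thermal factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalFactors:
    b_residue: float
    b_sidechain: float
    z_residue: float
    z_sidechain: float


def _b_arrays(structure: ProteinStructure) -> tuple[np.ndarray, np.ndarray]:
    b_res = np.array([r.b_residue for r in structure.residues])
    # Gly falls back to the whole-residue value.
    b_side = np.array(
        [r.b_sidechain if r.b_sidechain is not None else r.b_residue
         for r in structure.residues]
    )
    return b_res, b_side


def thermal_factor_features(structure: ProteinStructure, pos: int) -> ThermalFactors:
    """Residue and side-chain thermal factors at ``pos`` with chain z-scores.

    z-scores use the population standard deviation over all residues of the
    chain; a constant-B structure yields z = 0.
    """
    if not 0 <= pos < len(structure):
        raise IndexError(f"seq_index out of range: {pos}")
    b_res, b_side = _b_arrays(structure)

    def zscore(values: np.ndarray, x: float) -> float:
        sd = float(values.std())  # population sd
        if sd == 0.0:
            return 0.0
        return (x - float(values.mean())) / sd

    return ThermalFactors(
        b_residue=float(b_res[pos]),
        b_sidechain=float(b_side[pos]),
        z_residue=zscore(b_res, b_res[pos]),
        z_sidechain=zscore(b_side, b_side[pos]),
    )
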