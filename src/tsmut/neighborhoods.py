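"""Residue neighborhoods of a mutation site.

Three definitions are supported:

* **sequence** — residues within a window of chain positions either side of
  the site;
* **euclidean** — residues whose Cα lies within a sphere around the site's
  Cα;
* **topological** — residues sharing a Delaunay tetrahedron (hence a
  Delaunay edge) with the site, capped at the same radius.

Delaunay tetrahedra are additionally classified into five types by how their
four vertices split into runs of consecutive chain positions — the classes
range from four consecutive residues (a backbone helix-like cluster, type I)
to four mutually non-consecutive residues (a purely long-range contact
cluster, type V).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import Delaunay as _SciPyDelaunay
from scipy.spatial import QhullError

DT_TYPES = ("I", "II", "III", "IV", "V")

# Run-length partition of the 4 sorted vertices -> tetrahedron type.
_PARTITION_TO_TYPE = {
    (4,): "I",
    (3, 1): "II",
    (2, 2): "III",
    (2, 1, 1): "IV",
    (1, 1, 1, 1): "V",
}


@dataclass(frozen=True)
class Neighborhood:
    kind: str  # sequence | euclidean | topological
    site: int
    cutoff: float
    members: frozenset[int]

    def __post_init__(self) -> None:
        if self.site in self.members:
            raise ValueError("site must not be a member of its own neighborhood")

    def __len__(self) -> int:
        return len(self.members)


def sequence_neighborhood(chain_length: int, site: int, window: int = 11) -> Neighborhood:
    """Residues within ``window`` chain positions of the site, truncated at termini."""
    if not 0 <= site < chain_length:
        raise IndexError(f"site {site} outside chain of length {chain_length}")
    lo = max(0, site - window)
    hi = min(chain_length - 1, site + window)
    members = frozenset(range(lo, hi + 1)) - {site}
    return Neighborhood("sequence", site, float(window), members)


@dataclass
class Tessellation:
    """Delaunay tessellation of a Cα point set, with per-tetrahedron types."""

    tetrahedra: list[tuple[int, int, int, int]]
    dt_types: list[str] = field(default_factory=list)

    @property
    def edges(self) -> frozenset[frozenset[int]]:
        out: set[frozenset[int]] = set()
        for tet in self.tetrahedra:
            for pair in combinations(tet, 2):
                out.add(frozenset(pair))
        return frozenset(out)

    def partners(self, site: int) -> frozenset[int]:
        """All vertices sharing a tetrahedron with ``site``."""
        out: set[int] = set()
        for tet in self.tetrahedra:
            if site in tet:
                out.update(tet)
        out.discard(site)
        return frozenset(out)

    def tetrahedra_at(self, site: int) -> list[tuple[int, int, int, int]]:
        return [t for t in self.tetrahedra if site in t]


class DegeneratePointSetError(ValueError):
    pass


def classify_dt_type(tetra) -> str:
    """Classify a tetrahedron's 4 chain positions by backbone connectivity.

    The sorted positions are partitioned into maximal runs of consecutive
    indices; the multiset of run lengths determines the type:
    {4}→I, {3,1}→II, {2,2}→III, {2,1,1}→IV, {1,1,1,1}→V.
    """
    idx = sorted(tetra)
    if len(set(idx)) != 4:
        raise ValueError(f"need 4 distinct indices, got {tetra}")
    runs = [1]
    for a, b in zip(idx, idx[1:]):
        if b == a + 1:
            runs[-1] += 1
        else:
            runs.append(1)
    key = tuple(sorted(runs, reverse=True))
    return _PARTITION_TO_TYPE[key]


def delaunay_tessellation(ca_coords: np.ndarray, joggle: bool = False) -> Tessellation:
    """Delaunay tessellation of a Cα point set.

    Each tetrahedron's circumsphere contains no other point of the set. With
    ``joggle=True`` cospherical ties are broken by Qhull's deterministic
    joggle (same input → same output), giving a reproducible tessellation on
    degenerate inputs at the cost of exact Delaunayhood.
    """
    pts = np.asarray(ca_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    if pts.shape[0] < 4:
        raise DegeneratePointSetError("degenerate point set: need at least 4 points")
    opts = "QJ" if joggle else None
    try:
        tri = _SciPyDelaunay(pts, qhull_options=opts)
    except QhullError as exc:
        raise DegeneratePointSetError(f"degenerate point set: {exc}") from exc
    if tri.simplices.shape[1] != 4:
        raise DegeneratePointSetError("degenerate point set: not 3-dimensional")
    tets = [tuple(sorted(int(v) for v in simplex)) for simplex in tri.simplices]
    tets.sort()
    types = [classify_dt_type(t) for t in tets]
    return Tessellation(tetrahedra=tets, dt_types=types)


def euclidean_neighborhood(structure, site: int, radius: float = 13.0) -> Neighborhood:
    """Residues whose Cα is within ``radius`` Å of the site's Cα (inclusive)."""
    coords = structure.ca_coords() if hasattr(structure, "ca_coords") else np.asarray(structure, float)
    n = coords.shape[0]
    if not 0 <= site < n:
        raise IndexError(f"site {site} outside structure of length {n}")
    d = np.linalg.norm(coords - coords[site], axis=1)
    members = frozenset(int(j) for j in np.nonzero(d <= radius)[0] if j != site)
    return Neighborhood("euclidean", site, float(radius), members)


def topological_neighborhood(
    structure, tessellation: Tessellation, site: int, radius: float = 13.0
) -> Neighborhood:
    """Delaunay partners of the site, capped at the Euclidean radius.

    A residue belongs to the topological neighborhood iff it shares a
    Delaunay tetrahedron with the site and its Cα lies within ``radius``.
    By construction it is a subset of the Euclidean neighborhood at the same
    radius.
    """
    eucl = euclidean_neighborhood(structure, site, radius)
    members = tessellation.partners(site) & eucl.members
    return Neighborhood("topological", site, float(radius), frozenset(members))


def neighborhood_to_tsv(neighborhoods) -> str:
    """Serialize neighborhoods as TSV (site, kind, cutoff, comma-joined members)."""
    lines = ["site\tkind\tcutoff\tmembers"]
    for nb in neighborhoods:
        members = ",".join(str(m) for m in sorted(nb.members))
        lines.append(f"{nb.site}\t{nb.kind}\t{nb.cutoff:g}\t{members}")
    return "\n".join(lines) + "\n"


def tessellation_to_edge_list(tess: Tessellation) -> str:
    """Serialize a tessellation as a sorted TSV edge list."""
    pairs = sorted(tuple(sorted(e)) for e in tess.edges)
    lines = ["i\tj"] + [f"{i}\t{j}" for i, j in pairs]
    return "\n".join(lines) + "\n"
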