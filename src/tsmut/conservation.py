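"""Per-column conservation from superfamily/subfamily alignments.

Entropy and relative entropy are computed in bits over the 20 canonical
amino acids, with gap characters excluded from the counts. Alignment columns
are mapped onto structure positions through an explicit ``column_map``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

from .constants import AA_ORDER

GAP_CHARS = frozenset("-.")
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


@dataclass
class Alignment:
    """Aligned rows over the 20 amino acids plus gap, with a structure map.

    ``column_map`` takes a structure ``seq_index`` to the alignment column
    holding that residue; positions absent from the map have no conservation
    values (they are masked downstream).
    """

    rows: list[str]
    level: str = "subfamily"
    ids: list[str] = field(default_factory=list)
    column_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        mapped = list(self.column_map.values())
        if len(set(mapped)) != len(mapped):
            raise ValueError("column_map is not injective")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def read_alignment(fasta_text: str, level: str = "subfamily") -> Alignment:
    """Read an aligned-FASTA alignment (column_map left empty)."""
    aln = AlignIO.read(io.StringIO(fasta_text), "fasta")
    return Alignment(
        rows=[str(rec.seq).upper() for rec in aln],
        ids=[rec.id for rec in aln],
        level=level,
    )


def map_to_structure(alignment: Alignment, structure_sequence: str,
                     max_mismatch: float = 0.05) -> Alignment:
    """Build column_map by matching the structure sequence to the first row.

    The ungapped first row must have the same length as the structure
    sequence; more than ``max_mismatch`` disagreeing positions is a hard
    error (the alignment belongs to a different protein).
    """
    first = alignment.rows[0]
    cols = [c for c, ch in enumerate(first) if ch not in GAP_CHARS]
    if len(cols) != len(structure_sequence):
        raise ValueError(
            f"ungapped first row has {len(cols)} residues, "
            f"structure has {len(structure_sequence)}"
        )
    mismatches = sum(
        1 for i, c in enumerate(cols) if first[c] != structure_sequence[i]
    )
    if structure_sequence and mismatches / len(structure_sequence) > max_mismatch:
        raise ValueError(
            f"{mismatches}/{len(structure_sequence)} mismatches between "
            "alignment row 1 and structure sequence"
        )
    alignment.column_map = {i: c for i, c in enumerate(cols)}
    return alignment


def _column_freqs(alignment: Alignment, col: int) -> np.ndarray | None:
    """Relative amino-acid frequencies of a column, or None if all-gap."""
    counts = np.zeros(20)
    for row in alignment.rows:
        ch = row[col]
        if ch in _AA_INDEX:
            counts[_AA_INDEX[ch]] += 1
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def column_entropy(alignment: Alignment, col: int) -> float:
    """Shannon entropy of a column in bits; NaN for an all-gap column."""
    p = _column_freqs(alignment, col)
    if p is None:
        return float("nan")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def pooled_composition(alignment: Alignment) -> np.ndarray:
    """Amino-acid composition pooled over all columns (the default background)."""
    counts = np.zeros(20)
    for row in alignment.rows:
        for ch in row:
            if ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("alignment contains no amino acids")
    return counts / total


def column_relative_entropy(
    alignment: Alignment, col: int, background: np.ndarray | None = None
) -> float:
    """KL divergence (bits) of a column's composition from a background.

    Default background is the composition pooled over the whole alignment,
    which is strictly positive wherever the column has mass.
    """
    p = _column_freqs(alignment, col)
    if p is None:
        return float("nan")
    q = pooled_composition(alignment) if background is None else np.asarray(background, float)
    if np.any((p > 0) & (q <= 0)):
        raise ValueError("background has zero mass where the column has support")
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / q[nz])).sum())


@dataclass
class ConservationProfile:
    """Per-structure-position conservation values (NaN where unmapped)."""

    level: str
    entropy: np.ndarray
    rel_entropy: np.ndarray
    coverage: np.ndarray


def conservation_profile(alignment: Alignment, n_positions: int) -> ConservationProfile:
    """Entropy/relative-entropy/coverage per structure position.

    Positions without a mapped column, and all-gap columns, are NaN.
    """
    if not alignment.column_map:
        raise ValueError("alignment has no column_map; call map_to_structure first")
    ent = np.full(n_positions, np.nan)
    rel = np.full(n_positions, np.nan)
    cov = np.full(n_positions, np.nan)
    q = pooled_composition(alignment)
    for pos, col in alignment.column_map.items():
        if not 0 <= pos < n_positions:
            continue
        ent[pos] = column_entropy(alignment, col)
        rel[pos] = column_relative_entropy(alignment, col, background=q)
        non_gap = sum(1 for row in alignment.rows if row[col] in _AA_INDEX)
        cov[pos] = non_gap / alignment.n_rows
    return ConservationProfile(
        level=alignment.level, entropy=ent, rel_entropy=rel, coverage=cov
    )


def neighborhood_conservation(
    profile: ConservationProfile, members: set[int] | frozenset[int]
) -> tuple[float, float]:
    """Mean (entropy, rel_entropy) over the mapped members of a neighborhood.

    Members without conservation values are ignored; if none remain, both
    means are NaN (masked downstream).
    """
    idx = [i for i in members if 0 <= i < len(profile.entropy)]
    ent = profile.entropy[idx]
    rel = profile.rel_entropy[idx]
    ok = ~np.isnan(ent)
    if not ok.any():
        return float("nan"), float("nan")
    return float(ent[ok].mean()), float(rel[~np.isnan(rel)].mean())


def profile_to_tsv(profile: ConservationProfile) -> str:
    """Serialize a profile as TSV (seq_index, entropy, rel_entropy, coverage)."""
    lines = ["seq_index\tentropy\trel_entropy\tcoverage"]
    for i in range(len(profile.entropy)):
        lines.append(
            f"{i}\t{profile.entropy[i]:.6g}\t{profile.rel_entropy[i]:.6g}"
            f"\t{profile.coverage[i]:.6g}"
        )
    return "\n".join(lines) + "\n"
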