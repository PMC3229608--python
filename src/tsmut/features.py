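"""Feature extraction for single amino-acid substitutions.

Features fall into two groups: properties of the mutation site itself
(physicochemical change, accessibility, thermal factors, conservation,
secondary structure) and properties of the site's neighborhood under the
three neighborhood definitions (sequence window, Euclidean sphere, Delaunay
topological). Every feature has a stable registry name; values that cannot
be computed for a mutation (no alignment, no annotations, empty
neighborhood) are recorded as missing in an explicit mask rather than
silently imputed.

Mutant-side structural features are approximated from the wild-type
structure: mutant SASA equals wild-type SASA, and mutant RSA renormalizes it
by the mutant residue type's max-ASA.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import conservation as cons
from . import neighborhoods as nbh
from . import structure as st
from .constants import (
    AA_ORDER,
    AA_CLASSES,
    CHARGE,
    CLASS_ORDER,
    HYDROPHOBICITY_KD,
    MAX_ASA,
    VOLUME,
    aa_class,
    grantham,
)

ALIGNMENT_LEVELS = ("superfamily", "subfamily")
NEIGHBORHOOD_KEYS = ("seq", "eucl", "topo")


@dataclass(frozen=True)
class Mutation:
    """A single amino-acid substitution in author (PDB) numbering."""

    protein_id: str
    chain: str
    author_number: int
    wt_aa: str
    mut_aa: str
    label: str = "unknown"  # TS | neutral | unknown
    permissive_T: float | None = None
    restrictive_T: float | None = None

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"wt and mutant residues identical: {self.wt_aa}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AA_ORDER:
                raise ValueError(f"nonstandard amino acid: {aa!r}")
        if self.label not in ("TS", "neutral", "unknown"):
            raise ValueError(f"bad label: {self.label!r}")

    @property
    def key(self) -> str:
        return f"{self.protein_id}:{self.chain}:{self.author_number}:{self.wt_aa}>{self.mut_aa}"


@dataclass
class AnnotationSet:
    """Optional per-residue annotations supplied alongside a structure.

    ``functional_sites`` uses author numbering. ``secondary_structure`` is an
    H/E/C string and ``disorder`` a boolean mask, both of chain length.
    ``ddg`` maps a source name to {(author_number, wt, mut): value} for
    pass-through stability-change columns.
    """

    functional_sites: set[int] = field(default_factory=set)
    secondary_structure: str | None = None
    disorder: list[bool] | None = None
    ddg: dict[str, dict[tuple[int, str, str], float]] = field(default_factory=dict)

    def validate(self, n_residues: int) -> None:
        if self.secondary_structure is not None and len(self.secondary_structure) != n_residues:
            raise ValueError("secondary-structure string length != chain length")
        if self.disorder is not None and len(self.disorder) != n_residues:
            raise ValueError("disorder mask length != chain length")


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable knobs of the feature engine (defaults follow the study setup)."""

    seq_window: int = 11
    eucl_radius: float = 13.0
    topo_radius: float = 13.0
    buried_rsa_threshold: float = 0.05
    unusual_residues: frozenset = frozenset("GPC")
    turn_breaker_residues: frozenset = frozenset("VILMFW")
    moment_angle_deg: float = 100.0
    hydrophobicity: tuple = tuple(sorted(HYDROPHOBICITY_KD.items()))
    include_site_in_aggregates: bool = False
    sasa_points: int = 960
    probe_radius: float = 1.4

    def hydrophobicity_scale(self) -> dict[str, float]:
        return dict(self.hydrophobicity)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: sorted(v) if isinstance(v, frozenset) else v
             for k, v in self.__dict__.items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def mutations_from_tsv(text: str) -> list[Mutation]:
    """Parse a mutation list TSV: protein_id chain position wt mut [label]."""
    out = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "protein_id":
            continue
        if len(parts) < 5:
            raise ValueError(f"line {ln}: expected ≥5 tab-separated fields")
        label = parts[5] if len(parts) > 5 and parts[5] else "unknown"
        out.append(Mutation(parts[0], parts[1], int(parts[2]), parts[3], parts[4], label))
    return out


def mutations_to_tsv(mutations) -> str:
    lines = ["protein_id\tchain\tposition\twt\tmut\tlabel"]
    for m in mutations:
        lines.append(f"{m.protein_id}\t{m.chain}\t{m.author_number}\t{m.wt_aa}\t{m.mut_aa}\t{m.label}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Individual feature operations
# ---------------------------------------------------------------------------

def residue_counts_by_type(structure: st.ProteinStructure, neighborhood) -> np.ndarray:
    """20-vector of residue counts by type among the neighborhood members.

    Component order is the fixed alphabetical one-letter order; the vector
    sums to the neighborhood size.
    """
    counts = np.zeros(20)
    seq = structure.sequence
    for j in neighborhood.members:
        counts[AA_ORDER.index(seq[j])] += 1
    return counts


def site_physchem(mut: Mutation, config: FeatureConfig | None = None) -> dict[str, float]:
    """Physicochemical site features of a substitution.

    Hydrophobicity (configured scale), volume, charge, their wt→mut deltas,
    Grantham dissimilarity, 3+3 class indicators, the 9 class-substitution
    indicators (exactly one is 1), and unusual-residue flags.
    """
    config = config or FeatureConfig()
    scale = config.hydrophobicity_scale()
    wt, mu = mut.wt_aa, mut.mut_aa
    out: dict[str, float] = {
        "site.wt_hydrophobicity": scale[wt],
        "site.mut_hydrophobicity": scale[mu],
        "site.delta_hydrophobicity": scale[mu] - scale[wt],
        "site.wt_volume": VOLUME[wt],
        "site.mut_volume": VOLUME[mu],
        "site.delta_volume": VOLUME[mu] - VOLUME[wt],
        "site.wt_charge": float(CHARGE[wt]),
        "site.mut_charge": float(CHARGE[mu]),
        "site.grantham": float(grantham(wt, mu)),
        "site.wt_unusual": float(wt in config.unusual_residues),
        "site.mut_unusual": float(mu in config.unusual_residues),
    }
    wt_cls, mu_cls = aa_class(wt), aa_class(mu)
    for cls in CLASS_ORDER:
        out[f"site.wt_class_{cls}"] = float(wt_cls == cls)
        out[f"site.mut_class_{cls}"] = float(mu_cls == cls)
    for c1 in CLASS_ORDER:
        for c2 in CLASS_ORDER:
            out[f"site.sub_{c1}_to_{c2}"] = float(wt_cls == c1 and mu_cls == c2)
    return out


def hydrophobic_moment(h_values, angle_deg: float = 100.0) -> float:
    """Magnitude of the hydrophobic moment of a residue window.

    μ = ‖Σ_k h_k (cos kδ, sin kδ)‖ with δ the turn angle per residue
    (100° for an α-helix).
    """
    h = np.asarray(list(h_values), dtype=float)
    if h.size == 0:
        raise ValueError("empty window")
    delta = math.radians(angle_deg)
    k = np.arange(h.size)
    return float(math.hypot((h * np.cos(k * delta)).sum(), (h * np.sin(k * delta)).sum()))


def buried_and_charged(
    rsa_wt: float, wt_aa: str, mut_aa: str, threshold: float = 0.05
) -> tuple[float, float]:
    """(wt, mut) indicators: residue buried (rsa ≤ threshold, inclusive) and charged."""
    buried = rsa_wt <= threshold
    charged = AA_CLASSES["charged"]
    return float(buried and wt_aa in charged), float(buried and mut_aa in charged)


def distance_to_functional_site(
    structure: st.ProteinStructure,
    site: int,
    functional_author_numbers,
    mode: str = "sequence",
) -> float:
    """Distance from the site to the nearest annotated functional residue.

    Sequence mode counts chain positions; Euclidean mode measures Cα–Cα
    distance in Å. An empty annotation list yields NaN (masked).
    """
    a2i = structure.author_to_index()
    idx = [a2i[a] for a in functional_author_numbers if a in a2i]
    if not idx:
        return float("nan")
    if mode == "sequence":
        return float(min(abs(j - site) for j in idx))
    if mode == "euclidean":
        coords = structure.ca_coords()
        return float(np.min(np.linalg.norm(coords[idx] - coords[site], axis=1)))
    raise ValueError(f"unknown mode {mode!r}")


_SALT_POS = frozenset("KRH")
_SALT_NEG = frozenset("DE")


def interaction_counts(structure: st.ProteinStructure, neighborhood) -> tuple[float, float]:
    """(H-bond, salt-bridge) counts among neighborhood ∪ {site} residues.

    Geometric criteria: an H-bond is an inter-residue N/O atom pair within
    3.5 Å (backbone–backbone pairs of adjacent residues are skipped as
    peptide-bond geometry); a salt bridge is a side-chain N of Lys/Arg/His
    within 4.0 Å of a side-chain O of Asp/Glu. Returns NaN for Cα-only
    structures.
    """
    group = set(neighborhood.members) | {neighborhood.site}
    atoms = [
        (i, a) for i, a in structure.all_atoms()
        if i in group and a.element in ("N", "O")
    ]
    if all(a.name == "CA" for r in structure.residues for a in r.atoms):
        return float("nan"), float("nan")
    seq = structure.sequence
    n_hbond = 0
    n_salt = 0
    for x in range(len(atoms)):
        i, ai = atoms[x]
        for y in range(x + 1, len(atoms)):
            j, aj = atoms[y]
            if i == j:
                continue
            d = math.dist(ai.xyz, aj.xyz)
            if d <= 3.5:
                adjacent_backbone = (
                    abs(i - j) == 1
                    and ai.name in st.BACKBONE_ATOMS
                    and aj.name in st.BACKBONE_ATOMS
                )
                if not adjacent_backbone and "N" in (ai.element, aj.element):
                    n_hbond += 1
            if d <= 4.0:
                for (ri, aa_i, at_i), (rj, aa_j, at_j) in (
                    ((i, seq[i], ai), (j, seq[j], aj)),
                    ((j, seq[j], aj), (i, seq[i], ai)),
                ):
                    if (
                        aa_i in _SALT_POS and at_i.element == "N" and at_i.name not in st.BACKBONE_ATOMS
                        and aa_j in _SALT_NEG and at_j.element == "O" and at_j.name not in st.BACKBONE_ATOMS
                    ):
                        n_salt += 1
                        break
    return float(n_hbond), float(n_salt)


def secondary_structure_features(
    mut: Mutation, site: int, annotations: AnnotationSet | None,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Secondary-structure context of the site (all NaN without annotations).

    ``helix_breaker`` fires when the mutant residue is Pro or Gly inside a
    helix; ``turn_breaker`` when the mutant is in the configured
    turn-breaker set and the site is in turn/coil.
    """
    config = config or FeatureConfig()
    nan = float("nan")
    out = {
        "site.in_helix": nan, "site.in_strand": nan, "site.in_coil": nan,
        "site.helix_breaker": nan, "site.turn_breaker": nan,
        "site.in_disordered": nan,
    }
    if annotations is not None and annotations.secondary_structure is not None:
        ss = annotations.secondary_structure[site]
        out["site.in_helix"] = float(ss == "H")
        out["site.in_strand"] = float(ss == "E")
        out["site.in_coil"] = float(ss == "C")
        out["site.helix_breaker"] = float(mut.mut_aa in "PG" and ss == "H")
        out["site.turn_breaker"] = float(
            mut.mut_aa in config.turn_breaker_residues and ss == "C"
        )
    if annotations is not None and annotations.disorder is not None:
        out["site.in_disordered"] = float(annotations.disorder[site])
    return out


def _mean(values) -> float:
    arr = np.asarray([v for v in values if not (isinstance(v, float) and math.isnan(v))], float)
    return float(arr.mean()) if arr.size else float("nan")


def neighborhood_aggregates(
    structure: st.ProteinStructure,
    neighborhood,
    access: st.AccessibilityProfile,
    profiles: dict[str, cons.ConservationProfile],
    config: FeatureConfig,
    tessellation: nbh.Tessellation | None = None,
    prefix: str = "nb",
    include_site: bool = False,
) -> dict[str, float]:
    """Aggregate features over the members of one neighborhood.

    Emits the member count, the 20-D count vector, mean physicochemical
    values, mean (relative) accessibility and buriedness, mean thermal
    factors and their z-forms, mean conservation per alignment level, and —
    for topological neighborhoods — Delaunay-tetrahedron counts by type.
    Empty neighborhoods yield NaN aggregates. ``include_site`` folds the
    mutated residue itself into the aggregates (off by default: the site is
    not its own neighbor).
    """
    member_set = set(neighborhood.members)
    if include_site:
        member_set.add(neighborhood.site)
    members = sorted(member_set)
    seq = structure.sequence
    scale = config.hydrophobicity_scale()
    nan = float("nan")
    out: dict[str, float] = {f"{prefix}.n_members": float(len(members))}
    counts = np.zeros(20)
    for j in members:
        counts[AA_ORDER.index(seq[j])] += 1
    for aa, c in zip(AA_ORDER, counts):
        out[f"{prefix}.count_{aa}"] = float(c)
    if members:
        out[f"{prefix}.mean_hydrophobicity"] = _mean(scale[seq[j]] for j in members)
        out[f"{prefix}.mean_volume"] = _mean(VOLUME[seq[j]] for j in members)
        out[f"{prefix}.mean_charge"] = _mean(float(CHARGE[seq[j]]) for j in members)
        mean_rsa = _mean(access.rsa[j] for j in members)
        out[f"{prefix}.mean_rsa"] = mean_rsa
        out[f"{prefix}.buriedness"] = 1.0 - mean_rsa
        out[f"{prefix}.frac_buried"] = _mean(
            float(access.rsa[j] <= config.buried_rsa_threshold) for j in members
        )
        b_res = np.array([r.b_residue for r in structure.residues])
        b_side = np.array(
            [r.b_sidechain if r.b_sidechain is not None else r.b_residue
             for r in structure.residues]
        )
        out[f"{prefix}.mean_b_residue"] = _mean(b_res[j] for j in members)
        out[f"{prefix}.mean_b_sidechain"] = _mean(b_side[j] for j in members)
        for name, arr in (("b_residue", b_res), ("b_sidechain", b_side)):
            sd = arr.std()
            z = (arr - arr.mean()) / sd if sd > 0 else np.zeros_like(arr)
            out[f"{prefix}.mean_z_{name}"] = _mean(z[j] for j in members)
    else:
        for name in (
            "mean_hydrophobicity", "mean_volume", "mean_charge", "mean_rsa",
            "buriedness", "frac_buried", "mean_b_residue", "mean_b_sidechain",
            "mean_z_b_residue", "mean_z_b_sidechain",
        ):
            out[f"{prefix}.{name}"] = nan
    for level in ALIGNMENT_LEVELS:
        if level in profiles and members:
            ent, rel = cons.neighborhood_conservation(profiles[level], set(members))
        else:
            ent, rel = nan, nan
        out[f"{prefix}.mean_entropy_{level}"] = ent
        out[f"{prefix}.mean_rel_entropy_{level}"] = rel
    if neighborhood.kind == "topological":
        if tessellation is None:
            raise ValueError("topological aggregates need a tessellation")
        tets = tessellation.tetrahedra_at(neighborhood.site)
        out[f"{prefix}.n_tetrahedra"] = float(len(tets))
        type_counts = {t: 0 for t in nbh.DT_TYPES}
        for tet in tets:
            type_counts[nbh.classify_dt_type(tet)] += 1
        for t in nbh.DT_TYPES:
            out[f"{prefix}.dt_count_{t}"] = float(type_counts[t])
    return out


# ---------------------------------------------------------------------------
# Registry and assembly
# ---------------------------------------------------------------------------

def feature_registry(ddg_sources=()) -> list[str]:
    """Stable ordered list of all feature names the engine can emit."""
    dummy = Mutation("x", "A", 1, "L", "K")
    names = list(site_physchem(dummy))
    names += [
        "site.sasa_wt", "site.rsa_wt", "site.sasa_mut", "site.rsa_mut",
        "site.buried_charged_wt", "site.buried_charged_mut",
        "site.b_residue", "site.b_sidechain", "site.z_b_residue", "site.z_b_sidechain",
    ]
    for level in ALIGNMENT_LEVELS:
        names += [f"site.entropy_{level}", f"site.rel_entropy_{level}"]
    names += [
        "site.in_helix", "site.in_strand", "site.in_coil",
        "site.helix_breaker", "site.turn_breaker", "site.in_disordered",
        "site.dist_functional_seq", "site.dist_functional_eucl",
    ]
    names += [f"site.ddg_{src}" for src in ddg_sources]
    for key in NEIGHBORHOOD_KEYS:
        p = f"{key}_nb"
        names.append(f"{p}.n_members")
        names += [f"{p}.count_{aa}" for aa in AA_ORDER]
        names += [
            f"{p}.mean_hydrophobicity", f"{p}.mean_volume", f"{p}.mean_charge",
            f"{p}.mean_rsa", f"{p}.buriedness", f"{p}.frac_buried",
            f"{p}.mean_b_residue", f"{p}.mean_b_sidechain",
            f"{p}.mean_z_b_residue", f"{p}.mean_z_b_sidechain",
        ]
        for level in ALIGNMENT_LEVELS:
            names += [f"{p}.mean_entropy_{level}", f"{p}.mean_rel_entropy_{level}"]
        if key == "seq":
            names.append(f"{p}.hydrophobic_moment")
        if key == "eucl":
            names += [f"{p}.n_hbond", f"{p}.n_saltbridge"]
        if key == "topo":
            names.append(f"{p}.n_tetrahedra")
            names += [f"{p}.dt_count_{t}" for t in nbh.DT_TYPES]
    return names


SITE_FEATURE_PREFIX = "site."
NEIGHBORHOOD_PREFIXES = tuple(f"{k}_nb." for k in NEIGHBORHOOD_KEYS)


def feature_groups(names) -> dict[str, list[str]]:
    """Partition feature names into the model-building groups of the study."""
    groups: dict[str, list[str]] = {
        "site": [], "neighborhood": [], "seq_nb": [], "eucl_nb": [], "topo_nb": [],
    }
    for n in names:
        if n.startswith(SITE_FEATURE_PREFIX):
            groups["site"].append(n)
        else:
            groups["neighborhood"].append(n)
            for key in NEIGHBORHOOD_KEYS:
                if n.startswith(f"{key}_nb."):
                    groups[f"{key}_nb"].append(n)
    groups["all"] = list(names)
    return groups


class FeaturizeError(ValueError):
    """Raised with an itemized report when mutations fail validation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("featurize failed:\n" + "\n".join(errors))


@dataclass
class FeatureMatrix:
    """Named feature values per mutation with an explicit missing-value mask."""

    values: pd.DataFrame  # float; NaN in masked cells
    mask: pd.DataFrame    # True where missing
    config: FeatureConfig

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path, sidecar_path=None) -> None:
        self.values.to_csv(path, sep="\t", index_label="mutation_id")
        sidecar = {
            "registry": self.feature_names,
            "config_hash": self.config.config_hash(),
            "mask_encoding": "NaN",
            "n_mutations": int(len(self.values)),
        }
        if sidecar_path is None:
            sidecar_path = str(path) + ".json"
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_tsv(cls, path, config: FeatureConfig | None = None) -> "FeatureMatrix":
        values = pd.read_csv(path, sep="\t", index_col="mutation_id")
        return cls(values=values, mask=values.isna(), config=config or FeatureConfig())


def featurize(
    mutations,
    structure: st.ProteinStructure,
    alignments: dict[str, cons.Alignment] | None = None,
    annotations: AnnotationSet | None = None,
    config: FeatureConfig | None = None,
    access: st.AccessibilityProfile | None = None,
) -> FeatureMatrix:
    """Compute the full feature registry for a list of mutations.

    Validates every mutation's wild-type residue against the structure first
    and raises a single itemized :class:`FeaturizeError` if any fail.
    """
    config = config or FeatureConfig()
    alignments = alignments or {}
    if annotations is not None:
        annotations.validate(len(structure))
    a2i = structure.author_to_index()
    errors = []
    sites = []
    for m in mutations:
        if m.author_number not in a2i:
            errors.append(f"{m.key}: position {m.author_number} not in structure")
            sites.append(None)
            continue
        idx = a2i[m.author_number]
        if structure.residues[idx].aa != m.wt_aa:
            errors.append(
                f"{m.key}: wild-type mismatch (structure has "
                f"{structure.residues[idx].aa} at {m.author_number})"
            )
            sites.append(None)
        else:
            sites.append(idx)
    if errors:
        raise FeaturizeError(errors)

    if access is None:
        access = st.compute_accessibility(
            structure, probe_radius=config.probe_radius, n_points=config.sasa_points
        )
    tess = nbh.delaunay_tessellation(structure.ca_coords())
    profiles = {
        level: cons.conservation_profile(aln, len(structure))
        for level, aln in alignments.items()
    }
    scale = config.hydrophobicity_scale()
    ddg_sources = sorted(annotations.ddg) if annotations is not None else []
    registry = feature_registry(ddg_sources=ddg_sources)

    rows = []
    n = len(structure)
    for m, site in zip(mutations, sites):
        row: dict[str, float] = {}
        row.update(site_physchem(m, config))
        rsa_wt = float(access.rsa[site])
        sasa_wt = float(access.sasa[site])
        row["site.sasa_wt"] = sasa_wt
        row["site.rsa_wt"] = rsa_wt
        row["site.sasa_mut"] = sasa_wt  # wild-type geometry approximation
        row["site.rsa_mut"] = sasa_wt / MAX_ASA[m.mut_aa]
        bw, bm = buried_and_charged(rsa_wt, m.wt_aa, m.mut_aa, config.buried_rsa_threshold)
        row["site.buried_charged_wt"] = bw
        row["site.buried_charged_mut"] = bm
        tf = st.thermal_factor_features(structure, site)
        row["site.b_residue"] = tf.b_residue
        row["site.b_sidechain"] = tf.b_sidechain
        row["site.z_b_residue"] = tf.z_residue
        row["site.z_b_sidechain"] = tf.z_sidechain
        for level in ALIGNMENT_LEVELS:
            if level in profiles:
                row[f"site.entropy_{level}"] = float(profiles[level].entropy[site])
                row[f"site.rel_entropy_{level}"] = float(profiles[level].rel_entropy[site])
            else:
                row[f"site.entropy_{level}"] = float("nan")
                row[f"site.rel_entropy_{level}"] = float("nan")
        row.update(secondary_structure_features(m, site, annotations, config))
        func = annotations.functional_sites if annotations is not None else set()
        row["site.dist_functional_seq"] = distance_to_functional_site(
            structure, site, func, "sequence"
        )
        row["site.dist_functional_eucl"] = distance_to_functional_site(
            structure, site, func, "euclidean"
        )
        for src in ddg_sources:
            row[f"site.ddg_{src}"] = annotations.ddg[src].get(
                (m.author_number, m.wt_aa, m.mut_aa), float("nan")
            )

        nbs = {
            "seq": nbh.sequence_neighborhood(n, site, config.seq_window),
            "eucl": nbh.euclidean_neighborhood(structure, site, config.eucl_radius),
            "topo": nbh.topological_neighborhood(structure, tess, site, config.topo_radius),
        }
        for key, nb in nbs.items():
            row.update(
                neighborhood_aggregates(
                    structure, nb, access, profiles, config,
                    tessellation=tess if key == "topo" else None,
                    prefix=f"{key}_nb",
                    include_site=config.include_site_in_aggregates,
                )
            )
        lo, hi = max(0, site - config.seq_window), min(n - 1, site + config.seq_window)
        row["seq_nb.hydrophobic_moment"] = hydrophobic_moment(
            (scale[structure.sequence[j]] for j in range(lo, hi + 1)),
            config.moment_angle_deg,
        )
        hb, sb = interaction_counts(structure, nbs["eucl"])
        row["eucl_nb.n_hbond"] = hb
        row["eucl_nb.n_saltbridge"] = sb
        rows.append(row)

    values = pd.DataFrame(rows, index=[m.key for m in mutations])
    values = values.reindex(columns=registry)
    return FeatureMatrix(values=values, mask=values.isna(), config=config)
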