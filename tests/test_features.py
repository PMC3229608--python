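"""Feature operations and matrix assembly."""

import math

import numpy as np
import pytest

import tsmut
from tsmut import (
    AnnotationSet,
    FeatureConfig,
    FeaturizeError,
    Mutation,
    buried_and_charged,
    distance_to_functional_site,
    featurize,
    hydrophobic_moment,
    interaction_counts,
    residue_counts_by_type,
    secondary_structure_features,
    site_physchem,
)
from tsmut.constants import AA_ORDER, CLASS_ORDER, HYDROPHOBICITY_KD, grantham
from tsmut.features import feature_groups, feature_registry
from tsmut.neighborhoods import Neighborhood, sequence_neighborhood

from conftest import make_pdb


class TestResidueCounts:
    def test_counts_match_members(self, compact_structure):
        nb = sequence_neighborhood(len(compact_structure), 10, window=5)
        counts = residue_counts_by_type(compact_structure, nb)
        assert counts.sum() == len(nb)
        seq = compact_structure.sequence
        for aa, c in zip(AA_ORDER, counts):
            assert c == sum(1 for j in nb.members if seq[j] == aa)

    def test_empty_neighborhood_zero_vector(self, compact_structure):
        nb = Neighborhood("euclidean", 0, 0.0, frozenset())
        assert residue_counts_by_type(compact_structure, nb).sum() == 0

    def test_full_chain_equals_composition(self, compact_structure):
        n = len(compact_structure)
        nb = Neighborhood("sequence", 0, float(n), frozenset(range(1, n)))
        counts = residue_counts_by_type(compact_structure, nb)
        seq = compact_structure.sequence[1:]
        np.testing.assert_array_equal(
            counts, [seq.count(aa) for aa in AA_ORDER]
        )


class TestSitePhyschem:
    def test_leu_to_lys_class_indicators(self):
        f = site_physchem(Mutation("p", "A", 1, "L", "K"))
        assert f["site.wt_class_nonpolar"] == 1
        assert f["site.mut_class_charged"] == 1
        assert f["site.sub_nonpolar_to_charged"] == 1
        subs = [v for k, v in f.items() if k.startswith("site.sub_")]
        assert sum(subs) == 1 and len(subs) == 9

    def test_exactly_one_substitution_indicator_for_any_pair(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            wt, mu = rng.choice(list(AA_ORDER), 2, replace=False)
            f = site_physchem(Mutation("p", "A", 1, wt, mu))
            assert sum(v for k, v in f.items() if k.startswith("site.sub_")) == 1

    @pytest.mark.parametrize(
        "wt, mu, expected", [("L", "I", 5), ("C", "W", 215), ("W", "C", 215)]
    )
    def test_grantham_values(self, wt, mu, expected):
        assert site_physchem(Mutation("p", "A", 1, wt, mu))["site.grantham"] == expected

    def test_grantham_identity_zero(self):
        for aa in AA_ORDER:
            assert grantham(aa, aa) == 0

    def test_deltas(self):
        f = site_physchem(Mutation("p", "A", 1, "A", "V"))
        assert f["site.delta_hydrophobicity"] == pytest.approx(
            HYDROPHOBICITY_KD["V"] - HYDROPHOBICITY_KD["A"]
        )

    def test_nonstandard_aa_rejected(self):
        with pytest.raises(ValueError):
            Mutation("p", "A", 1, "X", "A")


class TestHydrophobicMoment:
    def test_zero_values_zero_moment(self):
        assert hydrophobic_moment([0.0] * 7) == 0.0

    def test_single_residue_unit(self):
        assert hydrophobic_moment([1.0]) == pytest.approx(1.0)

    def test_matches_complex_sum(self):
        h = [(-1.0) ** k for k in range(18)]
        delta = math.radians(100.0)
        z = sum(hk * complex(math.cos(k * delta), math.sin(k * delta))
                for k, hk in enumerate(h))
        assert hydrophobic_moment(h) == pytest.approx(abs(z))


class TestBuriedAndCharged:
    @pytest.mark.parametrize(
        "rsa, wt, mu, expected",
        [
            (0.01, "D", "A", (1, 0)),
            (0.50, "D", "K", (0, 0)),
            (0.05, "K", "R", (1, 1)),  # boundary is inclusive
        ],
    )
    def test_rules(self, rsa, wt, mu, expected):
        assert buried_and_charged(rsa, wt, mu) == expected


class TestFunctionalDistance:
    def test_annotated_site_distance_zero(self, compact_structure):
        a2i = compact_structure.author_to_index()
        author = compact_structure.residues[5].author_number
        assert distance_to_functional_site(compact_structure, 5, {author}) == 0

    def test_sequence_mode(self, compact_structure):
        authors = {compact_structure.residues[10].author_number,
                   compact_structure.residues[30].author_number}
        assert distance_to_functional_site(compact_structure, 12, authors) == 2

    def test_euclidean_mode_matches_brute_force(self, compact_structure):
        authors = {compact_structure.residues[j].author_number for j in (3, 17, 25)}
        coords = compact_structure.ca_coords()
        expected = min(np.linalg.norm(coords[j] - coords[8]) for j in (3, 17, 25))
        got = distance_to_functional_site(compact_structure, 8, authors, "euclidean")
        assert got == pytest.approx(expected)

    def test_empty_annotations_masked(self, compact_structure):
        assert math.isnan(distance_to_functional_site(compact_structure, 0, set()))


class TestInteractionCounts:
    def test_constructed_hbond_and_saltbridge(self):
        residues = [
            ("LYS", "A", 1, [("CA", (0, 0, 0), 20.0), ("NZ", (0, 3.0, 0), 20.0)]),
            ("ALA", "A", 2, [("CA", (6, 0, 0), 20.0)]),
            ("GLU", "A", 3, [("CA", (0, 6.5, 0), 20.0),
                             ("OE1", (0, 6.9, 0), 20.0)]),
        ]
        s = tsmut.read_structure(make_pdb(residues), "A")
        nb = Neighborhood("euclidean", 0, 13.0, frozenset({1, 2}))
        hb, sb = interaction_counts(s, nb)
        # NZ(1)–OE1(3) at 3.9 Å: salt bridge and (N/O within 3.5? no: 3.9) no H-bond
        assert sb == 1
        assert hb == 0

    def test_hbond_threshold(self):
        residues = [
            ("ALA", "A", 1, [("CA", (0, 0, 0), 20.0), ("N", (0, 1.0, 0), 20.0)]),
            ("SER", "A", 5, [("CA", (5, 0, 0), 20.0), ("OG", (0, 4.4, 0), 20.0)]),
        ]
        s = tsmut.read_structure(make_pdb(residues), "A")
        nb = Neighborhood("euclidean", 0, 13.0, frozenset({1}))
        hb, sb = interaction_counts(s, nb)
        assert hb == 1 and sb == 0  # N…OG at 3.4 Å

    def test_ca_only_structure_masked(self):
        residues = [("ALA", "A", i + 1, [("CA", (3.8 * i, 0, 0), 20.0)])
                    for i in range(4)]
        s = tsmut.read_structure(make_pdb(residues), "A")
        nb = Neighborhood("euclidean", 0, 13.0, frozenset({1, 2}))
        hb, sb = interaction_counts(s, nb)
        assert math.isnan(hb) and math.isnan(sb)


class TestSecondaryStructure:
    def test_proline_in_helix_breaks(self):
        ann = AnnotationSet(secondary_structure="HHHH")
        f = secondary_structure_features(Mutation("p", "A", 2, "A", "P"), 1, ann)
        assert f["site.helix_breaker"] == 1
        assert f["site.in_helix"] == 1

    def test_alanine_does_not_break(self):
        ann = AnnotationSet(secondary_structure="HHHH")
        f = secondary_structure_features(Mutation("p", "A", 2, "L", "A"), 1, ann)
        assert f["site.helix_breaker"] == 0

    def test_no_annotation_all_masked(self):
        f = secondary_structure_features(Mutation("p", "A", 2, "L", "A"), 1, None)
        assert all(math.isnan(v) for v in f.values())


class TestFeaturize:
    def test_one_row_registry_width(self, study):
        structure, alignments, cohort = study
        m = cohort.mutations[0]
        fm = featurize([m], structure, alignments)
        assert fm.values.shape == (1, len(feature_registry()))
        assert list(fm.values.columns) == feature_registry()

    def test_deterministic(self, study):
        structure, alignments, cohort = study
        ms = cohort.mutations[:5]
        fm1 = featurize(ms, structure, alignments)
        fm2 = featurize(ms, structure, alignments)
        assert fm1.values.equals(fm2.values)

    def test_wt_mismatch_itemized(self, study):
        structure, alignments, _ = study
        res = structure.residues[3]
        wrong_wt = next(a for a in AA_ORDER if a != res.aa)
        mut_aa = next(a for a in AA_ORDER if a not in (wrong_wt, res.aa))
        bad = Mutation("p", "A", res.author_number, wrong_wt, mut_aa)
        with pytest.raises(FeaturizeError) as err:
            featurize([bad], structure, alignments)
        assert "mismatch" in str(err.value)

    def test_count_vectors_sum_to_sizes(self, study):
        structure, alignments, cohort = study
        fm = cohort.feature_matrix
        for key in ("seq", "eucl", "topo"):
            counts = fm.values[[f"{key}_nb.count_{aa}" for aa in AA_ORDER]]
            np.testing.assert_allclose(
                counts.sum(axis=1), fm.values[f"{key}_nb.n_members"]
            )

    def test_mask_matches_missing_rules(self, study):
        """Without annotations, exactly the annotation features are masked."""
        structure, alignments, cohort = study
        fm = featurize(cohort.mutations[:3], structure, alignments)
        always_masked = {
            "site.in_helix", "site.in_strand", "site.in_coil",
            "site.helix_breaker", "site.turn_breaker", "site.in_disordered",
            "site.dist_functional_seq", "site.dist_functional_eucl",
        }
        masked_cols = set(fm.mask.columns[fm.mask.all(axis=0)])
        assert masked_cols == always_masked

    def test_aggregates_match_loop_oracle(self, study):
        structure, alignments, cohort = study
        fm = cohort.feature_matrix
        m = cohort.mutations[0]
        site = structure.author_to_index()[m.author_number]
        from tsmut.neighborhoods import euclidean_neighborhood

        nb = euclidean_neighborhood(structure, site, 13.0)
        scale = HYDROPHOBICITY_KD
        seq = structure.sequence
        expected = np.mean([scale[seq[j]] for j in nb.members])
        assert fm.values.loc[m.key, "eucl_nb.mean_hydrophobicity"] == pytest.approx(expected)
        from tsmut.constants import VOLUME
        assert fm.values.loc[m.key, "eucl_nb.mean_volume"] == pytest.approx(
            np.mean([VOLUME[seq[j]] for j in nb.members])
        )

    def test_feature_groups_partition(self):
        names = feature_registry()
        groups = feature_groups(names)
        assert set(groups["site"]) | set(groups["neighborhood"]) == set(names)
        assert not set(groups["site"]) & set(groups["neighborhood"])
        assert (set(groups["seq_nb"]) | set(groups["eucl_nb"])
                | set(groups["topo_nb"])) == set(groups["neighborhood"])

    def test_tsv_roundtrip(self, study, tmp_path):
        _, _, cohort = study
        fm = cohort.feature_matrix
        path = tmp_path / "features.tsv"
        fm.to_tsv(path)
        again = tsmut.FeatureMatrix.from_tsv(path)
        assert list(again.values.columns) == list(fm.values.columns)
        np.testing.assert_allclose(
            again.values.to_numpy(float), fm.values.to_numpy(float),
            rtol=1e-6, equal_nan=True,
        )
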