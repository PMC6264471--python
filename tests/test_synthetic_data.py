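import numpy as np
import pytest

from milkpeptidome.cleavage_analysis import extract_cleavage_sites
from milkpeptidome.protease_attribution import match_site
from milkpeptidome.reference_data import AMINO_ACIDS, ProteinRecord, SpecificityMatrix
from milkpeptidome.synthetic_data import (
    DigestionConfig,
    digest_protein,
    simulate_study,
    study_scale_table,
)


def k_matrix():
    allowed = [AMINO_ACIDS] * 8
    allowed[3] = frozenset("K")
    return SpecificityMatrix(
        protease_id="PLG",
        position_sets=tuple(allowed),
        restrictions=tuple([frozenset()] * 8),
    )


def protein(seq, accession="X1", species="human"):
    return ProteinRecord(
        accession=accession,
        species=species,
        short_name="fixture",
        mature_sequence=seq,
    )


class TestDigestProtein:
    def test_deterministic_cut_after_lysine(self):
        p = protein("AAAKAAAAKAAAAAA")
        config = DigestionConfig(cleavage_probability=1.0, min_peptide_length=4)
        fragments = digest_protein(p, [k_matrix()], config, seed=0)
        assert fragments == [
            ("AAAK", 1, 4),
            ("AAAAK", 5, 9),
            ("AAAAAA", 10, 15),
        ]

    def test_zero_probability_leaves_protein_whole(self):
        p = protein("AAAKAAAAKAAAAAA")
        config = DigestionConfig(cleavage_probability=0.0, min_peptide_length=4)
        fragments = digest_protein(p, [k_matrix()], config, seed=0)
        assert fragments == [(p.mature_sequence, 1, 15)]

    def test_same_seed_reproduces_fragments(self, bovine_ref, matrices):
        config = DigestionConfig(cleavage_probability=0.5)
        prot = bovine_ref[0]
        mats = [matrices["PLG"], matrices["ELANE"]]
        first = digest_protein(prot, mats, config, seed=42)
        second = digest_protein(prot, mats, config, seed=42)
        assert first == second

    def test_fragments_match_parent_subsequence(self, bovine_ref, matrices):
        config = DigestionConfig(cleavage_probability=0.6)
        for prot in bovine_ref:
            for seq, start, stop in digest_protein(
                prot, list(matrices.values()), config, seed=5
            ):
                assert prot.mature_sequence[start - 1 : stop] == seq
                assert len(seq) >= config.min_peptide_length

    def test_truncated_contexts_never_cut(self, matrices):
        # lysines close to the ends sit in padded contexts, which are
        # ineligible; only the interior lysine bond can be cut
        p = protein("KKAAAAAKAAAAAKK")
        config = DigestionConfig(cleavage_probability=1.0, min_peptide_length=1)
        fragments = digest_protein(p, [k_matrix()], config, seed=0)
        assert fragments == [("KKAAAAAK", 1, 8), ("AAAAAKK", 9, 15)]

    def test_short_protein_yields_nothing(self):
        p = protein("AKAA")
        config = DigestionConfig(min_peptide_length=7)
        assert digest_protein(p, [k_matrix()], config, seed=0) == []

    def test_empty_matrix_list_rejected(self):
        p = protein("AAAKAAAAKAAAAAA")
        with pytest.raises(ValueError):
            digest_protein(p, [], DigestionConfig(), seed=0)


class TestSimulateStudy:
    def test_zero_missingness_gives_full_occurrence(self, human_ref, bovine_ref):
        config = DigestionConfig(
            seed=1, missingness=0.0, carryover_retention=1.0
        )
        study = simulate_study(human_ref, bovine_ref, config)
        for rec in study.records:
            for stype, n in study.sample_counts.items():
                occ = rec.occ(stype)
                assert occ in (0, n)

    def test_milk_contains_only_human_derived_peptides(self, human_ref, bovine_ref):
        config = DigestionConfig(seed=2)
        study = simulate_study(human_ref, bovine_ref, config)
        human_accessions = {p.accession for p in human_ref}
        for rec in study.records:
            if rec.occ("milk") > 0 and rec.occ("gastric") == 0 and rec.occ("hmf") == 0:
                assert rec.protein_accession in human_accessions

    def test_hmf_pool_is_bovine(self, human_ref, bovine_ref):
        config = DigestionConfig(seed=2)
        study = simulate_study(human_ref, bovine_ref, config)
        bovine_accessions = {p.accession for p in bovine_ref}
        for rec in study.records:
            if rec.occ("hmf") > 0:
                assert rec.protein_accession in bovine_accessions

    def test_gastric_only_sites_carry_generating_specificity(
        self, human_ref, bovine_ref, matrices
    ):
        config = DigestionConfig(
            seed=3,
            protease_ids_by_sample_type={
                "milk": ["PLG"], "hmf": ["PLG"], "gastric": ["PGA3"],
            },
        )
        study = simulate_study(human_ref, bovine_ref, config, matrices)
        proteins = human_ref + bovine_ref
        gastric_only = [
            r
            for r in study.records
            if r.occ("gastric") > 0 and r.occ("milk") == 0 and r.occ("hmf") == 0
        ]
        sites = extract_cleavage_sites(gastric_only, proteins, "gastric")
        pga3_p1 = matrices["PGA3"].position_sets[3]
        new_sites = [
            s
            for s in sites
            if match_site(s, matrices["PLG"], max_mismatches=0).matched is False
        ]
        assert new_sites, "expected gastric-only cleavage sites"
        for s in new_sites:
            assert s.p1_residue in pga3_p1

    def test_unknown_protease_rejected(self, human_ref, bovine_ref):
        config = DigestionConfig(
            protease_ids_by_sample_type={
                "milk": ["NOPE"], "hmf": ["PLG"], "gastric": ["PGA3"],
            }
        )
        with pytest.raises(ValueError, match="NOPE"):
            simulate_study(human_ref, bovine_ref, config)

    def test_fixed_seed_fixes_tables(self, human_ref, bovine_ref):
        config = DigestionConfig(seed=9)
        a = simulate_study(human_ref, bovine_ref, config)
        b = simulate_study(human_ref, bovine_ref, config)
        assert a.table.equals(b.table)
        assert a.intensities.equals(b.intensities)


class TestStudyScaleTable:
    def test_margins_match_published_structure(self):
        df = study_scale_table(seed=0)
        assert len(df) == 5264
        assert df["Sequence"].is_unique
        species = df["Species"].value_counts()
        assert species["Human"] == 3399
        assert species["Bovine"] == 1722
        assert species["Both"] == 138
        assert df["Milk"].sum() == 3598
        assert df["Gastric"].sum() == 8604
        assert (df["HMF"] > 0).sum() == 538
        assert (df["Milk"] == 5).sum() == 185
        assert (df["Gastric"] == 5).sum() == 310
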