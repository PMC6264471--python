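import numpy as np
import pytest
from Bio.Align import substitution_matrices

from milkpeptidome.mapping_profiles import (
    TANFORD_SCALE,
    WINDOW_WEIGHTS,
    align_orthologs,
    gastric_minus_feed,
    hydrophobicity_profile,
    residue_intensity_map,
    top_cleavage_sites,
)
from milkpeptidome.reference_data import ProteinRecord

from conftest import make_record, random_fixture_records
from oracles import (
    enumerate_affine_alignment_score,
    residue_accumulation,
    windowed_weighted_mean,
)


def protein(seq, accession="X1", species="bovine"):
    return ProteinRecord(
        accession=accession,
        species=species,
        short_name="fixture",
        mature_sequence=seq,
    )


class TestResidueIntensityMap:
    def test_single_peptide_covers_its_span(self, toy_protein):
        rec = make_record(
            toy_protein.mature_sequence[4:10], toy_protein, 5, gastric=7.0
        )
        profile = residue_intensity_map([rec], toy_protein, "gastric")
        expected = np.zeros(len(toy_protein))
        expected[4:10] = 7.0
        assert np.array_equal(profile.values, expected)

    def test_overlaps_add(self, toy_protein):
        r1 = make_record(
            toy_protein.mature_sequence[0:10], toy_protein, 1, gastric=3.0
        )
        r2 = make_record(
            toy_protein.mature_sequence[7:12], toy_protein, 8, gastric=5.0
        )
        profile = residue_intensity_map([r1, r2], toy_protein, "gastric")
        assert np.all(profile.values[7:10] == 8.0)
        assert np.all(profile.values[0:7] == 3.0)
        assert np.all(profile.values[10:12] == 5.0)

    def test_matches_brute_force_accumulation(self, toy_protein):
        rng = np.random.default_rng(11)
        records = random_fixture_records(toy_protein, rng, n_peptides=20)
        profile = residue_intensity_map(records, toy_protein, "gastric")
        oracle = residue_accumulation(
            [(r.start, r.stop, r.intensity_of("gastric")) for r in records],
            len(toy_protein),
        )
        assert np.allclose(profile.values, oracle)

    def test_intensity_conservation(self, toy_protein):
        rng = np.random.default_rng(5)
        records = random_fixture_records(toy_protein, rng)
        profile = residue_intensity_map(records, toy_protein, "gastric")
        expected_total = sum(
            r.intensity_of("gastric") * r.length for r in records
        )
        assert profile.values.sum() == pytest.approx(expected_total)

    def test_unmapped_protein_gives_zero_profile(self, toy_protein):
        other = protein("MKVLAERSTGYPFND", accession="OTHER")
        profile = residue_intensity_map([], other, "gastric")
        assert not profile.values.any()


class TestGastricMinusFeed:
    def test_feed_dominated_peptide_contributes_zero(self, toy_protein):
        rec = make_record(
            toy_protein.mature_sequence[0:8], toy_protein, 1,
            milk=10.0, gastric=4.0,
        )
        profile = gastric_minus_feed([rec], toy_protein)
        assert not profile.values.any()

    def test_feed_absent_peptide_contributes_fully(self, toy_protein):
        rec = make_record(
            toy_protein.mature_sequence[0:8], toy_protein, 1, gastric=4.0
        )
        profile = gastric_minus_feed([rec], toy_protein)
        assert np.all(profile.values[0:8] == 4.0)

    def test_matches_peptide_by_peptide_oracle(self, toy_protein):
        rng = np.random.default_rng(23)
        records = random_fixture_records(toy_protein, rng, n_peptides=25)
        profile = gastric_minus_feed(records, toy_protein)
        oracle = residue_accumulation(
            [
                (
                    r.start,
                    r.stop,
                    max(
                        r.intensity_of("gastric")
                        - r.intensity_of("milk")
                        - r.intensity_of("hmf"),
                        0.0,
                    ),
                )
                for r in records
            ],
            len(toy_protein),
        )
        assert np.allclose(profile.values, oracle)

    def test_bounded_by_gastric_profile(self, toy_protein):
        rng = np.random.default_rng(31)
        records = random_fixture_records(toy_protein, rng)
        net = gastric_minus_feed(records, toy_protein).values
        gross = residue_intensity_map(records, toy_protein, "gastric").values
        assert np.all(net <= gross + 1e-12)
        assert np.all(net >= 0)


class TestHydrophobicityProfile:
    def test_weight_vector(self):
        assert np.allclose(
            WINDOW_WEIGHTS, [0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25]
        )

    def test_homopolymer_profile_constant(self):
        p = protein("L" * 15)
        profile = hydrophobicity_profile(p)
        assert np.allclose(profile.values, TANFORD_SCALE["L"])

    def test_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(TANFORD_SCALE), size=20))
        p = protein(seq)
        profile = hydrophobicity_profile(p)
        oracle = windowed_weighted_mean(
            [TANFORD_SCALE[c] for c in seq], list(WINDOW_WEIGHTS)
        )
        assert np.allclose(profile.values, oracle)

    def test_reverse_sequence_mirrors_profile(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list(TANFORD_SCALE), size=30))
        forward = hydrophobicity_profile(protein(seq)).values
        backward = hydrophobicity_profile(protein(seq[::-1])).values
        assert np.allclose(forward, backward[::-1])


class TestAlignOrthologs:
    def test_identical_sequences_align_gap_free(self):
        p = protein("MKVLAERSTGYPFND")
        overlay = align_orthologs(p, protein(p.mature_sequence, "X2"))
        assert overlay.column_map == [
            (i, i) for i in range(1, len(p) + 1)
        ]

    def test_prefix_gives_trailing_gaps(self):
        long = protein("MKVLAERSTGYPFND", "L1")
        short = protein("MKVLAERSTG", "S1")
        overlay = align_orthologs(long, short)
        assert overlay.column_map[:10] == [(i, i) for i in range(1, 11)]
        assert overlay.column_map[10:] == [(i, None) for i in range(11, 16)]

    def test_each_position_used_exactly_once_and_increasing(
        self, human_ref, bovine_ref
    ):
        overlay = align_orthologs(human_ref[0], bovine_ref[0])
        hs = [h for h, _ in overlay.column_map if h is not None]
        bs = [b for _, b in overlay.column_map if b is not None]
        assert hs == list(range(1, len(human_ref[0]) + 1))
        assert bs == list(range(1, len(bovine_ref[0]) + 1))

    def test_score_matches_exhaustive_enumeration_on_tiny_inputs(self):
        blosum = substitution_matrices.load("BLOSUM62")
        pairs = [
            ("MKVLAERS", "MKVLERS"),   # one indel
            ("MKVLAERS", "MKVLAERS"),
            ("PEPTIDE", "PEPSTIDE"),
            ("AAGGWW", "AAWW"),
        ]
        for a, b in pairs:
            overlay = align_orthologs(protein(a), protein(b, "X2"))
            oracle = enumerate_affine_alignment_score(
                a, b, lambda x, y: float(blosum[x, y]), -11.0, -1.0
            )
            assert overlay.score == pytest.approx(oracle)


class TestTopCleavageSites:
    def test_most_intense_bond_ranks_first(self, toy_protein):
        seq = toy_protein.mature_sequence
        records = [
            make_record(seq[0:10], toy_protein, 1, gastric=100.0),
            make_record(seq[10:20], toy_protein, 11, gastric=90.0),
            make_record(seq[3:12], toy_protein, 4, gastric=1.0),
        ]
        ranked = top_cleavage_sites(records, toy_protein, "gastric")
        assert ranked[0][0] == 10  # bond shared by the two intense peptides
        assert ranked[0][3] == pytest.approx(190.0)

    def test_constructed_bovine_as1_digest_reports_leu20_leu21(self, bovine_ref):
        as1 = next(p for p in bovine_ref if p.accession == "P02662")
        seq = as1.mature_sequence
        records = [
            # fragments produced by cutting after Leu20
            make_record(seq[0:20], as1, 1, gastric=500.0),
            make_record(seq[20:40], as1, 21, gastric=450.0),
            make_record(seq[50:60], as1, 51, gastric=5.0),
        ]
        ranked = top_cleavage_sites(records, as1, "gastric")
        bond, p1, p1prime, intensity = ranked[0]
        assert (bond, p1, p1prime) == (20, "L", "L")
        assert intensity == pytest.approx(950.0)

    def test_no_peptides_gives_empty_ranking(self, toy_protein):
        assert top_cleavage_sites([], toy_protein, "gastric") == []
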