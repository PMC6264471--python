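import numpy as np
import pytest

from milkpeptidome import (
    DigestionConfig,
    PeptideRecord,
    default_bioactive_reference,
    default_protein_reference,
    default_specificity_matrices,
)
from milkpeptidome.reference_data import ProteinRecord


@pytest.fixture(scope="session")
def human_ref():
    return default_protein_reference("human")


@pytest.fixture(scope="session")
def bovine_ref():
    return default_protein_reference("bovine")


@pytest.fixture(scope="session")
def matrices():
    return default_specificity_matrices()


@pytest.fixture(scope="session")
def bioactives():
    return default_bioactive_reference()


@pytest.fixture
def toy_protein():
    return ProteinRecord(
        accession="TOY1",
        species="human",
        short_name="toy protein",
        mature_sequence="MKVLAERSTGYPFNDQWHIC" * 3,
    )


def make_record(
    sequence,
    protein,
    start,
    *,
    milk=0.0,
    hmf=0.0,
    gastric=0.0,
    occ=None,
):
    """Peptide record helper with intensities given per sample type."""
    stop = start + len(sequence) - 1
    assert protein.mature_sequence[start - 1 : stop] == sequence
    occurrence = occ or {
        "milk": int(milk > 0),
        "hmf": int(hmf > 0),
        "gastric": int(gastric > 0),
    }
    return PeptideRecord(
        sequence=sequence,
        species_assignment=protein.species,
        protein_accession=protein.accession,
        protein_name=protein.short_name,
        start=start,
        stop=stop,
        occurrence=occurrence,
        intensity={"milk": milk, "hmf": hmf, "gastric": gastric},
    )


def random_fixture_records(protein, rng, n_peptides=12):
    """Random peptides of a protein with random gastric/milk intensities."""
    records = []
    L = len(protein)
    for _ in range(n_peptides):
        start = int(rng.integers(1, L - 6))
        length = int(rng.integers(7, min(26, L - start + 2)))
        stop = min(start + length - 1, L)
        seq = protein.mature_sequence[start - 1 : stop]
        records.append(
            make_record(
                seq,
                protein,
                start,
                milk=float(rng.uniform(0, 50)),
                gastric=float(rng.uniform(0, 100)),
            )
        )
    return records
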