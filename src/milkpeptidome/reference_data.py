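"""Packaged reference data: milk protein sequences, protease specificity
matrices, and the bioactive-peptide reference table.

All positional coordinates downstream are 1-based on *mature* protein
sequences (signal peptide removed).  FASTA headers may annotate a signal
peptide length (``signal=N``) and whether the stored sequence is the
precursor or the mature chain (``form=precursor|mature``, default mature);
precursors are converted to mature form at load time.

Protease specificity matrices describe, for each of the eight subsites
P4 P3 P2 P1 | P1' P2' P3' P4' around a cleaved bond, the set of residues a
protease accepts, plus hard restrictions (residues that veto a match
regardless of the mismatch allowance) and optionally a list of
experimentally observed cleavage-context octamers.  The packaged matrices
are approximations assembled from published subsite preferences (plasmin
P1 in {K,R}; pepsin/cathepsin D P1 hydrophobic-aromatic with a hydrophobic
P1' preference; neutrophil elastase P1 in {A,V,S,G,T,I}; thrombin P1=R with
a P2 Gly/Pro preference; kallikreins tryptic-like).  They are data, not
code: substitute an exported MEROPS matrix file to use exact specificities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
SUBSITES = ("P4", "P3", "P2", "P1", "P1p", "P2p", "P3p", "P4p")
PAD = "-"

#: protease identifiers covered by the packaged default matrices
DEFAULT_PROTEASES = ("CTSD", "ELANE", "F2", "KLK6", "KLK11", "PLG", "PGA3")

#: human-readable names for reports
PROTEASE_NAMES = {
    "CTSD": "Cathepsin D",
    "ELANE": "Elastase",
    "F2": "Thrombin",
    "KLK6": "Kallikrein 6",
    "KLK11": "Kallikrein 11",
    "PLG": "Plasmin",
    "PGA3": "Pepsin",
}


class ReferenceDataError(ValueError):
    """Raised when a reference file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A mature (signal-peptide-stripped) milk protein sequence."""

    accession: str
    species: str
    short_name: str
    mature_sequence: str
    signal_peptide_length: int = 0

    def __post_init__(self) -> None:
        if self.species not in {"human", "bovine"}:
            raise ReferenceDataError(
                f"{self.accession}: species must be 'human' or 'bovine', "
                f"got {self.species!r}"
            )
        if not self.mature_sequence:
            raise ReferenceDataError(f"{self.accession}: empty sequence")
        if self.signal_peptide_length < 0:
            raise ReferenceDataError(
                f"{self.accession}: negative signal peptide length"
            )
        bad = [
            (i, c)
            for i, c in enumerate(self.mature_sequence, start=1)
            if c not in AMINO_ACIDS
        ]
        if bad:
            i, c = bad[0]
            raise ReferenceDataError(
                f"{self.accession}: invalid residue {c!r} at position {i}"
            )

    def __len__(self) -> int:
        return len(self.mature_sequence)


@dataclass(frozen=True)
class SpecificityMatrix:
    """One protease's allowed/forbidden residues per subsite.

    ``position_sets[i]`` is the allowed-residue set for subsite
    ``SUBSITES[i]`` (the full 20-letter alphabet means "wildcard");
    ``restrictions[i]`` holds residues that make a context unmatchable at
    that subsite no matter how many mismatches are tolerated.
    """

    protease_id: str
    position_sets: tuple[frozenset, ...]
    restrictions: tuple[frozenset, ...]
    observed_octamers: frozenset = frozenset()

    def __post_init__(self) -> None:
        if len(self.position_sets) != 8 or len(self.restrictions) != 8:
            raise ReferenceDataError(
                f"{self.protease_id}: need exactly 8 subsite definitions"
            )
        for name, allowed, forbidden in zip(
            SUBSITES, self.position_sets, self.restrictions
        ):
            if allowed & forbidden:
                raise ReferenceDataError(
                    f"{self.protease_id} {name}: residues "
                    f"{sorted(allowed & forbidden)} both allowed and forbidden"
                )
            if not allowed:
                raise ReferenceDataError(
                    f"{self.protease_id} {name}: empty allowed set"
                )
        for octamer in self.observed_octamers:
            if len(octamer) != 8:
                raise ReferenceDataError(
                    f"{self.protease_id}: observed octamer {octamer!r} "
                    "is not 8 residues"
                )


@dataclass(frozen=True)
class BioactiveEntry:
    """A literature-described bioactive milk peptide."""

    sequence: str
    species: str
    protein: str
    functions: tuple[str, ...]
    reference: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceDataError("bioactive entry with empty sequence")
        if not self.functions:
            raise ReferenceDataError(
                f"bioactive entry {self.sequence}: empty function list"
            )
        if self.species not in {"human", "bovine", "both"}:
            raise ReferenceDataError(
                f"bioactive entry {self.sequence}: bad species "
                f"{self.species!r}"
            )


def _parse_header(description: str) -> tuple[str, str, int, str]:
    """Split ``ACC|short name key=value ...`` into its parts."""
    tokens = description.split()
    head = tokens[0]
    accession, _, short_name = head.partition("|")
    signal = 0
    form = "mature"
    extra_name: list[str] = []
    for tok in tokens[1:]:
        if tok.startswith("signal="):
            signal = int(tok.split("=", 1)[1])
        elif tok.startswith("form="):
            form = tok.split("=", 1)[1]
        else:
            extra_name.append(tok)
    if not short_name:
        short_name = " ".join(extra_name) or accession
    return accession, short_name, signal, form


def load_protein_reference(path, species_label: str) -> list[ProteinRecord]:
    """Load a FASTA of milk proteins, stripping annotated signal peptides.

    Parameters
    ----------
    path : path-like
        FASTA file.  Headers are ``>ACCESSION|short-name [signal=N]
        [form=precursor|mature]``.
    species_label : {"human", "bovine"}
        Species assigned to every record in the file.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, short_name, signal, form = _parse_header(entry.description)
        seq = str(entry.seq).upper()
        if form == "precursor":
            if signal >= len(seq):
                raise ReferenceDataError(
                    f"{accession}: signal peptide length {signal} >= "
                    f"precursor length {len(seq)}"
                )
            seq = seq[signal:]
        elif form != "mature":
            raise ReferenceDataError(f"{accession}: unknown form {form!r}")
        if accession in seen:
            raise ReferenceDataError(f"duplicate accession {accession}")
        seen.add(accession)
        records.append(
            ProteinRecord(
                accession=accession,
                species=species_label,
                short_name=short_name,
                mature_sequence=seq,
                signal_peptide_length=signal,
            )
        )
    if not records:
        raise ReferenceDataError(f"no FASTA entries in {path}")
    return records


def _parse_cell(cell: str, where: str) -> tuple[frozenset, frozenset]:
    """Parse one subsite cell: allowed residues with optional ``!``-marked
    restrictions, ``*`` meaning the full alphabet."""
    cell = cell.strip()
    allowed_part, bang, forbidden_part = cell.partition("!")
    allowed_part = allowed_part.strip()
    if allowed_part == "*":
        allowed = set(AMINO_ACIDS)
    else:
        allowed = set(allowed_part)
    forbidden = set(forbidden_part.strip()) if bang else set()
    for res in allowed | forbidden:
        if res not in AMINO_ACIDS:
            raise ReferenceDataError(f"{where}: invalid residue {res!r}")
    if allowed_part != "*" and allowed & forbidden:
        raise ReferenceDataError(
            f"{where}: residues {sorted(allowed & forbidden)} listed as both "
            "allowed and forbidden"
        )
    allowed -= forbidden
    if not allowed:
        raise ReferenceDataError(f"{where}: empty allowed set")
    return frozenset(allowed), frozenset(forbidden)


def load_specificity_matrices(path) -> dict[str, SpecificityMatrix]:
    """Load protease specificity matrices from a TSV.

    One row per protease; columns ``protease``, the eight subsites
    P4..P4', and an optional comma-separated ``observed`` octamer list.
    """
    matrices: dict[str, SpecificityMatrix] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 9:
            raise ReferenceDataError(
                f"{path}: expected >= 9 columns (protease + 8 subsites)"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ReferenceDataError(
                    f"{path}:{lineno}: row has {len(fields) - 1} subsite "
                    "columns, need 8"
                )
            protease = fields[0].strip()
            allowed_sets = []
            forbidden_sets = []
            for name, cell in zip(SUBSITES, fields[1:9]):
                a, f = _parse_cell(cell, f"{path}:{lineno} ({protease} {name})")
                allowed_sets.append(a)
                forbidden_sets.append(f)
            observed: frozenset = frozenset()
            if len(fields) > 9 and fields[9].strip():
                observed = frozenset(
                    s.strip() for s in fields[9].split(",") if s.strip()
                )
            if protease in matrices:
                raise ReferenceDataError(
                    f"{path}:{lineno}: duplicate protease {protease}"
                )
            matrices[protease] = SpecificityMatrix(
                protease_id=protease,
                position_sets=tuple(allowed_sets),
                restrictions=tuple(forbidden_sets),
                observed_octamers=observed,
            )
    if not matrices:
        raise ReferenceDataError(f"no matrices in {path}")
    return matrices


def load_bioactive_reference(path) -> list[BioactiveEntry]:
    """Load the bioactive-peptide reference table (TSV).

    Columns: sequence, species, protein, functions (``;``-separated),
    reference.  Duplicate (sequence, protein, species) rows are collapsed
    with a warning, merging their function lists.
    """
    entries: dict[tuple, BioactiveEntry] = {}
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            logger.warning("bioactive reference %s is empty", path)
            return []
        header = [h.strip().lower() for h in header_line.rstrip("\n").split("\t")]
        required = {"sequence", "species", "protein", "functions"}
        missing = required - set(header)
        if missing:
            raise ReferenceDataError(
                f"{path}: missing column(s) {sorted(missing)}"
            )
        idx = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            seq = fields[idx["sequence"]].strip().upper()
            species = fields[idx["species"]].strip().lower()
            protein = fields[idx["protein"]].strip()
            functions = tuple(
                f.strip()
                for f in fields[idx["functions"]].split(";")
                if f.strip()
            )
            reference = (
                fields[idx["reference"]].strip()
                if "reference" in idx and len(fields) > idx["reference"]
                else ""
            )
            key = (seq, species, protein)
            if key in entries:
                logger.warning(
                    "%s:%d duplicate bioactive row %s; merging functions",
                    path,
                    lineno,
                    seq,
                )
                merged = tuple(
                    dict.fromkeys(entries[key].functions + functions)
                )
                entries[key] = BioactiveEntry(
                    seq, species, protein, merged, reference
                )
            else:
                entries[key] = BioactiveEntry(
                    seq, species, protein, functions, reference
                )
    return list(entries.values())


def _data_path(name: str) -> Path:
    return Path(resources.files("milkpeptidome").joinpath("data", name))


def default_protein_reference(species: str) -> list[ProteinRecord]:
    """Packaged milk protein reference for one species (major caseins and
    whey proteins; extensible by supplying your own FASTA)."""
    return load_protein_reference(
        _data_path(f"proteins_{species}.fasta"), species
    )


def default_specificity_matrices() -> dict[str, SpecificityMatrix]:
    """Packaged specificity matrices for the seven milk/gastric proteases."""
    return load_specificity_matrices(_data_path("protease_matrices.tsv"))


def default_bioactive_reference() -> list[BioactiveEntry]:
    """Packaged bioactive-peptide reference table."""
    return load_bioactive_reference(_data_path("bioactive_reference.tsv"))


def write_protein_reference(records: Iterable[ProteinRecord], path) -> None:
    """Write protein records back to FASTA (round-trips with the loader)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                f">{rec.accession}|{rec.short_name} "
                f"signal={rec.signal_peptide_length} form=mature\n"
            )
            seq = rec.mature_sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
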