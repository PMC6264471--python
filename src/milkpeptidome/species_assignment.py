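"""Assign peptides to human, bovine, or both by exact substring search
against the dual proteome reference.

Matching is literal: isoleucine and leucine are distinct residues even
though they are isobaric in MS (an I/L-collapsed mode exists but is off by
default).  A peptide found in at least one protein of each species is
``both``; one found in neither reference is ``unassigned`` (a value, not an
error): the four labels partition any peptide set.
"""

from __future__ import annotations

from typing import Iterable

from .reference_data import ProteinRecord


def locate_in_parent(sequence: str, protein: ProteinRecord) -> list[tuple[int, int]]:
    """All occurrences of ``sequence`` in the mature parent sequence as
    1-based inclusive (start, stop) spans; overlapping hits are reported."""
    if not sequence:
        return []
    parent = protein.mature_sequence
    spans = []
    pos = parent.find(sequence)
    while pos != -1:
        spans.append((pos + 1, pos + len(sequence)))
        pos = parent.find(sequence, pos + 1)
    return spans


def _collapse_il(s: str) -> str:
    return s.replace("I", "L")


def assign_species(
    sequence: str,
    human_ref: Iterable[ProteinRecord],
    bovine_ref: Iterable[ProteinRecord],
    collapse_il: bool = False,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Locate a peptide in the dual reference and call its species.

    Returns ``(species, loci)`` where species is one of ``human``,
    ``bovine``, ``both`` or ``unassigned`` and loci lists every
    ``(accession, start, stop)`` match sorted by (accession, start).
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    query = _collapse_il(sequence) if collapse_il else sequence
    loci: list[tuple[str, int, int]] = []
    seen_species: set[str] = set()
    for protein in list(human_ref) + list(bovine_ref):
        parent = protein
        if collapse_il:
            parent = ProteinRecord(
                accession=protein.accession,
                species=protein.species,
                short_name=protein.short_name,
                mature_sequence=_collapse_il(protein.mature_sequence),
                signal_peptide_length=protein.signal_peptide_length,
            )
        spans = locate_in_parent(query, parent)
        if spans:
            seen_species.add(protein.species)
            loci.extend((protein.accession, a, b) for a, b in spans)
    loci.sort()
    if not seen_species:
        species = "unassigned"
    elif seen_species == {"human", "bovine"}:
        species = "both"
    else:
        species = seen_species.pop()
    return species, loci
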