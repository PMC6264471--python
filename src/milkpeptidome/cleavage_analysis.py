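"""Cleavage sites from peptide termini, and P1/P1' residue statistics.

Every peptide terminus that does not coincide with the parent protein's own
terminus evidences a hydrolyzed bond.  Subsite naming follows the
Schechter-Berger convention: P1 is the residue immediately N-terminal of
the cleaved bond, P1' immediately C-terminal, and the P4..P4' context is
the 8-residue window around the bond.  Where the window runs off a protein
end the context is padded with ``-``; padded positions count as mismatches
during protease attribution.

Sites are merged per (protein, bond) with the per-terminus multiplicity
retained in ``support_count``, so count-weighted P1/P1' distributions tally
peptide termini while attribution operates on distinct bonds.  Intensity
weighting assigns each terminus its peptide's full sample-type-summed
intensity (not halved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .peptidome_io import PeptideRecord
from .reference_data import PAD, ProteinRecord

logger = logging.getLogger(__name__)

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class CleavageSite:
    """One hydrolyzed bond on a parent protein, with its P4..P4' context."""

    protein_accession: str
    bond_position: int  # bond between mature residues p and p+1
    context: str  # 8 characters, '-'-padded at protein ends
    termini: str  # which peptide ends support it: "N", "C" or "NC"
    support_count: int = 1
    support_intensity: float = 0.0

    @property
    def p1_residue(self) -> str:
        return self.context[3]

    @property
    def p1prime_residue(self) -> str:
        return self.context[4]


def bond_context(protein: ProteinRecord, bond: int) -> str:
    """P4..P4' context of the bond between residues ``bond`` and
    ``bond + 1`` (1-based), padded with ``-`` at protein ends."""
    seq = protein.mature_sequence
    if not 1 <= bond < len(seq):
        raise ValueError(
            f"bond {bond} outside 1..{len(seq) - 1} for {protein.accession}"
        )
    out = []
    for offset in range(-4, 4):
        idx = bond + offset  # 0-based index of residue at this subsite
        out.append(seq[idx] if 0 <= idx < len(seq) else PAD)
    return "".join(out)


def extract_cleavage_sites(
    records,
    proteins,
    sample_type: str,
) -> list[CleavageSite]:
    """Derive merged cleavage sites from the termini of peptides observed
    in a sample type (occurrence > 0), excluding termini that coincide with
    the mature protein's own termini."""
    by_accession = {p.accession: p for p in proteins}
    sites: dict[tuple, CleavageSite] = {}
    for rec in records:
        if rec.occ(sample_type) == 0:
            continue
        if rec.protein_accession not in by_accession:
            logger.warning(
                "peptide %s has no resolvable parent (%r); skipped",
                rec.sequence,
                rec.protein_accession,
            )
            continue
        if rec.start is None or rec.stop is None:
            logger.warning("peptide %s lacks coordinates; skipped", rec.sequence)
            continue
        protein = by_accession[rec.protein_accession]
        intensity = rec.intensity_of(sample_type)
        bonds = []
        if rec.start > 1:
            bonds.append((rec.start - 1, "N"))
        if rec.stop < len(protein):
            bonds.append((rec.stop, "C"))
        for bond, terminus in bonds:
            key = (protein.accession, bond)
            if key in sites:
                site = sites[key]
                site.support_count += 1
                site.support_intensity += intensity
                if terminus not in site.termini:
                    site.termini = "".join(sorted(site.termini + terminus))
            else:
                sites[key] = CleavageSite(
                    protein_accession=protein.accession,
                    bond_position=bond,
                    context=bond_context(protein, bond),
                    termini=terminus,
                    support_count=1,
                    support_intensity=intensity,
                )
    return [sites[k] for k in sorted(sites)]


def p1_distribution(sites, weighting: str = "count") -> pd.DataFrame:
    """Relative P1 and P1' residue frequencies (percent) over all sites.

    ``weighting="count"`` tallies peptide termini (``support_count``);
    ``weighting="intensity"`` weights each site by its summed supporting
    intensity.  Each column sums to 100.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no cleavage sites to summarize")
    if weighting not in {"count", "intensity"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    totals = {"P1": dict.fromkeys(AA_ORDER, 0.0), "P1p": dict.fromkeys(AA_ORDER, 0.0)}
    for site in sites:
        w = site.support_count if weighting == "count" else site.support_intensity
        totals["P1"][site.p1_residue] += w
        totals["P1p"][site.p1prime_residue] += w
    frame = pd.DataFrame(totals, index=list(AA_ORDER))
    sums = frame.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("zero total weight; cannot form distribution")
    return 100.0 * frame / sums


def sites_to_frame(sites) -> pd.DataFrame:
    """Tabular view of cleavage sites."""
    return pd.DataFrame(
        {
            "protein": [s.protein_accession for s in sites],
            "bond": [s.bond_position for s in sites],
            "context": [s.context for s in sites],
            "termini": [s.termini for s in sites],
            "P1": [s.p1_residue for s in sites],
            "P1p": [s.p1prime_residue for s in sites],
            "support_count": [s.support_count for s in sites],
            "support_intensity": [s.support_intensity for s in sites],
        }
    )
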