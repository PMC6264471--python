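"""Per-residue digestion maps and protein profiles.

``residue_intensity_map`` totals, at every mature-sequence position, the
ion intensity of all peptides covering that residue — a per-residue picture
of where a protein was digested.  ``gastric_minus_feed`` first subtracts
each peptide's feed (milk/fortifier) intensity from its gastric intensity,
floored at zero, so the map reflects peptides released in the stomach
rather than carried in with the feed.  ``hydrophobicity_profile`` is a
7-residue sliding-window average of the Tanford hydrophobicity scale with
linearly decaying weights (25% relative weight at the window edges).
``align_orthologs`` overlays the human and bovine copies of a protein on a
global pairwise alignment so the two species' digestion maps can be
compared column by column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .peptidome_io import PeptideRecord
from .reference_data import ProteinRecord

logger = logging.getLogger(__name__)

#: Tanford hydrophobicity scale (kcal/mol transfer free energy based),
#: as used for sliding-window protein profiles.
TANFORD_SCALE = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

#: relative weights across the 7-residue window, edge weight 25% of the
#: centre and varying linearly in between
WINDOW_WEIGHTS = np.array([0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25])


@dataclass
class ResidueProfile:
    """One value per mature-sequence residue of a protein."""

    protein_accession: str
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class AlignmentOverlay:
    """Column map of a global pairwise alignment between orthologs.

    Each column is ``(human_position, bovine_position)`` with ``None`` on
    the gapped side; positions are 1-based on the mature sequences.
    """

    column_map: list
    score: float


def _records_for(records, protein: ProteinRecord):
    return [
        r
        for r in records
        if r.protein_accession == protein.accession
        and r.start is not None
        and r.stop is not None
    ]


def residue_intensity_map(
    records,
    protein: ProteinRecord,
    sample_type: str,
    label: str | None = None,
) -> ResidueProfile:
    """Sum, per residue, the sample-type intensity of covering peptides."""
    values = np.zeros(len(protein))
    hits = _records_for(records, protein)
    if not hits:
        logger.warning(
            "no peptides mapped to %s; returning all-zero profile",
            protein.accession,
        )
    for rec in hits:
        values[rec.start - 1 : rec.stop] += rec.intensity_of(sample_type)
    return ResidueProfile(
        protein_accession=protein.accession,
        values=values,
        label=label or f"{sample_type} intensity",
    )


def gastric_minus_feed(records, protein: ProteinRecord) -> ResidueProfile:
    """Per-residue gastric intensity after subtracting each peptide's feed
    (milk + HMF) intensity, floored at zero before mapping."""
    values = np.zeros(len(protein))
    for rec in _records_for(records, protein):
        gastric = rec.intensity_of("gastric")
        feed = rec.intensity_of("milk") + rec.intensity_of("hmf")
        net = max(gastric - feed, 0.0)
        values[rec.start - 1 : rec.stop] += net
    return ResidueProfile(
        protein_accession=protein.accession,
        values=values,
        label="gastric-minus-feed intensity",
    )


def hydrophobicity_profile(
    protein: ProteinRecord, scale: dict | None = None
) -> ResidueProfile:
    """Sliding-window hydrophobicity: weighted mean of the scale over the
    7-residue window centred at each position, weights
    [0.25, 0.5, 0.75, 1, 0.75, 0.5, 0.25] renormalized where the window is
    truncated by the sequence ends."""
    scale = scale or TANFORD_SCALE
    seq = protein.mature_sequence
    n = len(seq)
    raw = np.array([scale[c] for c in seq])
    values = np.empty(n)
    half = len(WINDOW_WEIGHTS) // 2
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        w = WINDOW_WEIGHTS[lo - (i - half) : len(WINDOW_WEIGHTS) - ((i + half + 1) - hi)]
        values[i] = np.dot(raw[lo:hi], w) / w.sum()
    return ResidueProfile(
        protein_accession=protein.accession,
        values=values,
        label="hydrophobicity (Tanford)",
    )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def align_orthologs(
    human_protein: ProteinRecord, bovine_protein: ProteinRecord
) -> AlignmentOverlay:
    """Optimal global alignment (BLOSUM62, affine gaps) of two orthologs,
    reported as a 1-based column map.  The first optimal alignment of the
    dynamic program is used, which fixes tie-breaking deterministically."""
    aligner = _make_aligner()
    alignment = aligner.align(
        human_protein.mature_sequence, bovine_protein.mature_sequence
    )[0]
    column_map: list[tuple] = []
    hpos = 0
    bpos = 0
    # alignment.aligned gives matched blocks; walk them emitting gap columns
    blocks_h, blocks_b = alignment.aligned
    for (h0, h1), (b0, b1) in zip(blocks_h, blocks_b):
        while hpos < h0:
            column_map.append((hpos + 1, None))
            hpos += 1
        while bpos < b0:
            column_map.append((None, bpos + 1))
            bpos += 1
        for k in range(h1 - h0):
            column_map.append((h0 + k + 1, b0 + k + 1))
        hpos, bpos = h1, b1
    while hpos < len(human_protein):
        column_map.append((hpos + 1, None))
        hpos += 1
    while bpos < len(bovine_protein):
        column_map.append((None, bpos + 1))
        bpos += 1
    return AlignmentOverlay(column_map=column_map, score=float(alignment.score))


def top_cleavage_sites(
    records,
    protein: ProteinRecord,
    sample_type: str,
    subtract_feed: bool = False,
    limit: int | None = None,
) -> list[tuple[int, str, str, float]]:
    """Rank cleaved bonds of one protein by supporting peptide intensity.

    A peptide spanning start..stop supports the bond before its first
    residue and the bond after its last residue, except where a terminus
    coincides with the protein's own terminus.  Returns
    ``(bond_position, P1 residue, P1' residue, intensity)`` sorted by
    intensity (descending, position as tie-break).
    """
    seq = protein.mature_sequence
    support: dict[int, float] = {}
    for rec in _records_for(records, protein):
        weight = rec.intensity_of(sample_type)
        if subtract_feed:
            feed = rec.intensity_of("milk") + rec.intensity_of("hmf")
            weight = max(rec.intensity_of("gastric") - feed, 0.0)
        for bond in (rec.start - 1, rec.stop):
            if 1 <= bond < len(seq):
                support[bond] = support.get(bond, 0.0) + weight
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    if limit is not None:
        ranked = ranked[:limit]
    return [(p, seq[p - 1], seq[p], v) for p, v in ranked]


def profile_to_frame(profile: ResidueProfile, protein: ProteinRecord):
    """Tabular (position, residue, value) view of a profile."""
    import pandas as pd

    return pd.DataFrame(
        {
            "position": np.arange(1, len(protein) + 1),
            "residue": list(protein.mature_sequence),
            "value": profile.values,
        }
    )
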