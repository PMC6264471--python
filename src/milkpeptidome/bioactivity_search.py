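"""Homology search of peptides against the bioactive-peptide reference.

Similarity follows an identity-scored global alignment: matches score 1,
mismatches and gaps 0 (gap placement among co-optimal alignments is
resolved by an infinitesimal gap penalty, which does not change the
score).  Under that scoring the maximal number of aligned identities is
the longest-common-subsequence length, so

    percent_similarity = 100 * LCS(query, reference) / max(len(query),
                                                           len(reference))

The denominator is the longer sequence, so a short query cannot trivially
score 100% against a long reference; 100% therefore means the two
sequences are identical when their lengths agree, and an ``exact`` match
requires both.  Matches at or above the threshold (default 80%) are
reported with the reference entry's functions attached — one match per
reference entry, however many functions it carries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference_data import BioactiveEntry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomologyMatch:
    query_sequence: str
    reference: BioactiveEntry
    percent_similarity: float
    exact: bool


def _lcs_length(a: str, b: str) -> int:
    """Longest common subsequence length = max identities over all global
    alignments under identity scoring (match 1, mismatch/gap 0)."""
    if len(a) < len(b):
        a, b = b, a
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    for ca in a:
        curr = prev.copy()
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                curr[j] = prev[j - 1] + 1
            elif curr[j - 1] > curr[j]:
                curr[j] = curr[j - 1]
        prev = curr
    return int(prev[-1])


def percent_similarity(query: str, reference_seq: str) -> float:
    """Percent identity of the optimal identity-scored global alignment,
    relative to the longer sequence.  Symmetric in its arguments."""
    if not query or not reference_seq:
        raise ValueError("empty sequence")
    identities = _lcs_length(query, reference_seq)
    return 100.0 * identities / max(len(query), len(reference_seq))


def match_entry(query: str, entry: BioactiveEntry) -> HomologyMatch:
    pct = percent_similarity(query, entry.sequence)
    exact = pct == 100.0 and len(query) == len(entry.sequence)
    return HomologyMatch(query, entry, pct, exact)


def search_bioactives(
    records,
    reference,
    threshold: float = 80.0,
):
    """Search peptide records (or bare sequences) against the bioactive
    reference.

    Returns ``(matches, function_counts)``: all matches with
    ``percent_similarity >= threshold`` (one per reference entry, carrying
    its exact percentage), and per-function counts of distinct matched
    query peptides.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    reference = list(reference)
    if not reference:
        logger.warning("empty bioactive reference; no matches possible")
        return [], pd.Series(dtype=int)
    sequences = []
    for rec in records:
        sequences.append(rec if isinstance(rec, str) else rec.sequence)

    matches: list[HomologyMatch] = []
    for query in sequences:
        for entry in reference:
            m = match_entry(query, entry)
            if m.percent_similarity >= threshold:
                matches.append(m)

    function_counts: dict[str, set] = {}
    for m in matches:
        for fn in m.reference.functions:
            function_counts.setdefault(fn, set()).add(m.query_sequence)
    counts = pd.Series(
        {fn: len(qs) for fn, qs in sorted(function_counts.items())},
        dtype=int,
    )
    return matches, counts


def matches_to_frame(matches) -> pd.DataFrame:
    """Tabular view of homology matches."""
    return pd.DataFrame(
        {
            "query": [m.query_sequence for m in matches],
            "reference_sequence": [m.reference.sequence for m in matches],
            "reference_species": [m.reference.species for m in matches],
            "reference_protein": [m.reference.protein for m in matches],
            "percent_similarity": [m.percent_similarity for m in matches],
            "exact": [m.exact for m in matches],
            "functions": [";".join(m.reference.functions) for m in matches],
            "reference": [m.reference.reference for m in matches],
        }
    )
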