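"""Attribute cleavage sites to candidate proteases by P4..P4' matching.

A site's 8-residue context is compared against each candidate protease's
specificity matrix: the mismatch count is the number of subsites whose
residue falls outside the allowed set (``-`` padding always mismatches),
and a context whose residue hits a hard restriction can never match that
protease regardless of the mismatch allowance.  A context listed among a
protease's experimentally observed octamers matches at zero mismatches by
definition.

Each site receives exactly one category: the candidate with the fewest
mismatches.  When the minimal-mismatch set is exactly {cathepsin D,
pepsin} the joint category ``CTSD/PGA3`` is reported, since those two
enzymes' specificities overlap too much to separate.  Other ties are
broken deterministically: an observed-octamer match beats a predicted one,
then a fixed priority order (PLG > PGA3 > CTSD > ELANE > F2 > KLK6 >
KLK11).  Sites matching no candidate are ``Unassigned``.

By default milk-sample attributions exclude the gastric proteases
cathepsin D and pepsin, which are inactive at milk pH.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cleavage_analysis import CleavageSite
from .reference_data import PAD, SpecificityMatrix

JOINT_CATEGORY = "CTSD/PGA3"
UNASSIGNED = "Unassigned"

#: fixed tie-break priority after the joint cathepsin D / pepsin rule
TIE_PRIORITY = ("PLG", "PGA3", "CTSD", "ELANE", "F2", "KLK6", "KLK11")

#: default candidate sets per sample type; milk excludes the acid proteases
DEFAULT_CANDIDATES = {
    "milk": ("PLG", "ELANE", "F2", "KLK6", "KLK11"),
    "hmf": ("PLG", "ELANE", "F2", "KLK6", "KLK11"),
    "gastric": ("CTSD", "PGA3", "ELANE", "F2", "KLK6", "KLK11", "PLG"),
}


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    mismatches: int
    observed: bool


def match_site(
    site: CleavageSite | str,
    matrix: SpecificityMatrix,
    max_mismatches: int = 3,
) -> MatchResult:
    """Match one site context against one specificity matrix.

    ``site`` may be a :class:`CleavageSite` or a bare 8-character context.
    """
    if not 0 <= max_mismatches <= 7:
        raise ValueError("max_mismatches must be in 0..7")
    context = site if isinstance(site, str) else site.context
    if len(context) != 8:
        raise ValueError(f"context {context!r} is not 8 characters")
    if context in matrix.observed_octamers:
        return MatchResult(matched=True, mismatches=0, observed=True)
    mismatches = 0
    for residue, allowed, forbidden in zip(
        context, matrix.position_sets, matrix.restrictions
    ):
        if residue != PAD and residue in forbidden:
            return MatchResult(matched=False, mismatches=8, observed=False)
        if residue == PAD or residue not in allowed:
            mismatches += 1
    return MatchResult(
        matched=mismatches <= max_mismatches,
        mismatches=mismatches,
        observed=False,
    )


def categorize_site(
    site: CleavageSite,
    matrices: dict[str, SpecificityMatrix],
    candidates,
    max_mismatches: int = 3,
) -> tuple[str, int, bool]:
    """Best category for one site: (category, mismatches, observed)."""
    results = {}
    for protease in candidates:
        res = match_site(site, matrices[protease], max_mismatches)
        if res.matched:
            results[protease] = res
    if not results:
        return UNASSIGNED, -1, False
    best = min(r.mismatches for r in results.values())
    minimal = {p for p, r in results.items() if r.mismatches == best}
    if minimal == {"CTSD", "PGA3"}:
        return JOINT_CATEGORY, best, any(
            results[p].observed for p in minimal
        )
    observed = {p for p in minimal if results[p].observed}
    pool = observed or minimal
    ordered = sorted(
        pool,
        key=lambda p: TIE_PRIORITY.index(p) if p in TIE_PRIORITY else len(TIE_PRIORITY),
    )
    winner = ordered[0]
    return winner, best, results[winner].observed


def attribute_sites(
    sites,
    matrices: dict[str, SpecificityMatrix],
    candidate_proteases=None,
    max_mismatches: int = 3,
    sample_type: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Attribute every site and tabulate relative category percentages.

    Returns ``(per_site, summary)`` where ``per_site`` has one row per site
    (protein, bond, context, category, mismatches, observed) and
    ``summary`` maps each category to its percent of all sites (sums to
    100).  ``candidate_proteases`` defaults to the sample-type-specific
    candidate set when ``sample_type`` is given.
    """
    sites = list(sites)
    if candidate_proteases is None:
        if sample_type is None:
            raise ValueError("need candidate_proteases or sample_type")
        candidate_proteases = DEFAULT_CANDIDATES[sample_type]
    candidate_proteases = list(candidate_proteases)
    if not candidate_proteases:
        raise ValueError("empty candidate protease list")
    missing = [p for p in candidate_proteases if p not in matrices]
    if missing:
        raise ValueError(f"no specificity matrix for {missing}")

    rows = []
    for site in sites:
        category, mismatches, observed = categorize_site(
            site, matrices, candidate_proteases, max_mismatches
        )
        rows.append(
            {
                "protein": site.protein_accession,
                "bond": site.bond_position,
                "context": site.context,
                "category": category,
                "mismatches": mismatches,
                "observed": observed,
            }
        )
    per_site = pd.DataFrame(
        rows,
        columns=["protein", "bond", "context", "category", "mismatches", "observed"],
    )
    categories = candidate_proteases + [JOINT_CATEGORY, UNASSIGNED]
    if len(per_site):
        counts = per_site["category"].value_counts()
        summary = pd.Series(
            {c: 100.0 * counts.get(c, 0) / len(per_site) for c in categories}
        )
    else:
        summary = pd.Series({c: 0.0 for c in categories})
    return per_site, summary
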