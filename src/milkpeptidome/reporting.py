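"""Conservation and per-protein summaries of a peptidome.

Conservation level of a peptide is the number of biological samples (of
one type) it was identified in.  The headline "percent conserved" figure
is the number of peptides found in every sample of a type divided by the
*mean per-sample* peptide count of that type (total identifications over
number of samples); the alternative denominator — the union count of
peptides ever seen in that type — is reported alongside.
"""

from __future__ import annotations

import pandas as pd

from .peptidome_io import DEFAULT_SAMPLE_COUNTS, PeptideRecord


def conservation_summary(
    records, sample_type: str, n_samples: int
) -> dict:
    """Per-conservation-level counts and intensity shares.

    Returns a dict with a ``levels`` DataFrame (index k = 1..n_samples,
    columns ``count`` and, when intensities are present, ``intensity_share``
    in percent), the full-conservation count split by species, and the
    percentage of full-conservation peptides relative to both the mean
    per-sample count and the union count.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    records = [r for r in records if r.occ(sample_type) > 0]
    for rec in records:
        if rec.occ(sample_type) > n_samples:
            raise ValueError(
                f"peptide {rec.sequence}: {sample_type} occurrence "
                f"{rec.occ(sample_type)} exceeds n_samples={n_samples}"
            )
    counts = {k: 0 for k in range(1, n_samples + 1)}
    intensity = {k: 0.0 for k in range(1, n_samples + 1)}
    have_intensity = any(r.intensity is not None for r in records)
    for rec in records:
        k = rec.occ(sample_type)
        counts[k] += 1
        intensity[k] += rec.intensity_of(sample_type)
    levels = pd.DataFrame({"count": pd.Series(counts)})
    total_intensity = sum(intensity.values())
    if have_intensity and total_intensity > 0:
        levels["intensity_share"] = [
            100.0 * intensity[k] / total_intensity for k in levels.index
        ]

    full = [r for r in records if r.occ(sample_type) == n_samples]
    by_species: dict[str, int] = {}
    for rec in full:
        by_species[rec.species_assignment] = (
            by_species.get(rec.species_assignment, 0) + 1
        )
    total_ids = sum(r.occ(sample_type) for r in records)
    mean_per_sample = total_ids / n_samples
    union_count = len(records)
    return {
        "levels": levels,
        "full_count": len(full),
        "full_by_species": by_species,
        "mean_per_sample": mean_per_sample,
        "union_count": union_count,
        "pct_full_vs_mean": (
            100.0 * len(full) / mean_per_sample if mean_per_sample else 0.0
        ),
        "pct_full_vs_union": (
            100.0 * len(full) / union_count if union_count else 0.0
        ),
    }


def per_protein_shares(
    records, species: str, sample_type: str, fractional: bool = True
) -> pd.DataFrame:
    """Relative count and intensity percentages per parent protein,
    within one species and sample type.

    A sequence mapping to several parents contributes fractionally
    (1/n per parent) unless ``fractional`` is False, in which case each
    (sequence, parent) record counts fully.  Percentages sum to 100 per
    metric; rows are sorted by descending count share.
    """
    pool = [
        r
        for r in records
        if r.species_assignment == species and r.occ(sample_type) > 0
    ]
    if not pool:
        raise ValueError(f"no {species} peptides identified in {sample_type}")
    parents_per_seq: dict[str, int] = {}
    for rec in pool:
        parents_per_seq[rec.sequence] = parents_per_seq.get(rec.sequence, 0) + 1
    count: dict[str, float] = {}
    intensity: dict[str, float] = {}
    for rec in pool:
        name = rec.protein_name or rec.protein_accession or "unknown"
        weight = 1.0 / parents_per_seq[rec.sequence] if fractional else 1.0
        count[name] = count.get(name, 0.0) + weight
        intensity[name] = intensity.get(name, 0.0) + weight * rec.intensity_of(
            sample_type
        )
    frame = pd.DataFrame({"count": pd.Series(count), "intensity": pd.Series(intensity)})
    out = pd.DataFrame(index=frame.index)
    out["count_pct"] = 100.0 * frame["count"] / frame["count"].sum()
    total_int = frame["intensity"].sum()
    out["intensity_pct"] = (
        100.0 * frame["intensity"] / total_int if total_int > 0 else 0.0
    )
    return out.sort_values("count_pct", ascending=False)
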