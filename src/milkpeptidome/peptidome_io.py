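"""Peptide-identification tables: reading, modification-variant grouping,
writing, and count summaries.

The on-disk layout mirrors the study-style supplementary table: one row per
(possibly modified) peptide with columns Sequence, Species, Protein Name,
Start, Stop, HMF, Milk, Gastric (number of samples of each type the peptide
was identified in) and Modifications.  Optional per-sample-type intensity
columns (``Milk Intensity`` etc.) are carried when present.  Rows sharing a
bare sequence and parent protein are modification variants of one peptide
and are grouped into a single record: intensities are summed, modification
labels unioned, and the per-sample-type identification count taken as the
maximum over variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_TYPES = ("milk", "hmf", "gastric")
SPECIES_VALUES = ("human", "bovine", "both", "unassigned")

#: default number of biological samples per type (five mother-infant pairs
#: plus a single fortifier sample)
DEFAULT_SAMPLE_COUNTS = {"milk": 5, "hmf": 1, "gastric": 5}


class PeptideTableError(ValueError):
    """Raised when a peptide table violates the layout contract."""


@dataclass
class PeptideRecord:
    """A grouped peptide observation (modification variants merged)."""

    sequence: str
    species_assignment: str = "unassigned"
    protein_accession: str | None = None
    protein_name: str | None = None
    start: int | None = None
    stop: int | None = None
    #: per sample type, number of samples the peptide was identified in
    occurrence: dict = field(default_factory=dict)
    #: per sample type, summed ion intensity (arbitrary units); None when
    #: the source table carries no intensities
    intensity: dict | None = None
    modifications: frozenset = frozenset()
    #: all (accession, start, stop) loci when the sequence maps to several
    #: places; the primary locus is mirrored in start/stop
    loci: tuple = ()

    def occ(self, sample_type: str) -> int:
        return int(self.occurrence.get(sample_type, 0))

    def intensity_of(self, sample_type: str) -> float:
        if self.intensity is None:
            return 0.0
        return float(self.intensity.get(sample_type, 0.0))

    @property
    def length(self) -> int:
        return len(self.sequence)


_COLUMN_ALIASES = {
    "sequence": "sequence",
    "species": "species",
    "protein name": "protein_name",
    "protein": "protein_name",
    "accession": "protein_accession",
    "start": "start",
    "stop": "stop",
    "hmf": "hmf",
    "milk": "milk",
    "gastric": "gastric",
    "modifications": "modifications",
    "milk intensity": "milk_intensity",
    "hmf intensity": "hmf_intensity",
    "gastric intensity": "gastric_intensity",
}

_REQUIRED = (
    "sequence",
    "species",
    "protein_name",
    "start",
    "stop",
    "hmf",
    "milk",
    "gastric",
)


def _load_frame(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        return pd.read_excel(path)
    return pd.read_csv(path, sep="\t")


def read_peptide_table(path, sample_counts: dict | None = None) -> list[PeptideRecord]:
    """Read a peptide table (TSV or spreadsheet) into grouped records.

    Parameters
    ----------
    path : path-like
        Delimited text (tab) or ``.xlsx`` spreadsheet.
    sample_counts : dict, optional
        Declared number of samples per type; identification counts above
        the declared number are rejected.  Defaults to 5 milk / 1 HMF /
        5 gastric.
    """
    sample_counts = dict(DEFAULT_SAMPLE_COUNTS, **(sample_counts or {}))
    df = _load_frame(path)
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _COLUMN_ALIASES:
            rename[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise PeptideTableError(f"{path}: missing column(s) {missing}")

    has_intensity = any(f"{t}_intensity" in df.columns for t in SAMPLE_TYPES)

    grouped: dict[tuple, PeptideRecord] = {}
    order: list[tuple] = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        seq = str(row.sequence).strip().upper()
        species = str(row.species).strip().lower()
        if species not in SPECIES_VALUES:
            raise PeptideTableError(
                f"{path} row {rownum}: bad species {row.species!r}"
            )
        occurrence = {}
        for stype in SAMPLE_TYPES:
            raw = getattr(row, stype)
            value = 0 if pd.isna(raw) else raw
            if float(value) != int(float(value)):
                raise PeptideTableError(
                    f"{path} row {rownum}: non-integer {stype} count {raw!r}"
                )
            count = int(float(value))
            if count < 0 or count > sample_counts[stype]:
                raise PeptideTableError(
                    f"{path} row {rownum}: {stype} count {count} outside "
                    f"0..{sample_counts[stype]}"
                )
            occurrence[stype] = count
        start = None if pd.isna(row.start) else int(row.start)
        stop = None if pd.isna(row.stop) else int(row.stop)
        if start is not None and stop is not None:
            if not (1 <= start <= stop):
                raise PeptideTableError(
                    f"{path} row {rownum}: bad span {start}..{stop}"
                )
            if stop - start + 1 != len(seq):
                raise PeptideTableError(
                    f"{path} row {rownum}: span {start}..{stop} does not "
                    f"match sequence length {len(seq)}"
                )
        mods_raw = getattr(row, "modifications", None)
        mods = frozenset()
        if mods_raw is not None and not pd.isna(mods_raw) and str(mods_raw).strip():
            mods = frozenset(
                m.strip() for m in str(mods_raw).replace(",", ";").split(";") if m.strip()
            )
        intensity = None
        if has_intensity:
            intensity = {}
            for stype in SAMPLE_TYPES:
                col = f"{stype}_intensity"
                raw = getattr(row, col, 0.0) if col in df.columns else 0.0
                intensity[stype] = 0.0 if pd.isna(raw) else float(raw)
        accession = getattr(row, "protein_accession", None)
        accession = None if accession is None or pd.isna(accession) else str(accession)
        protein_name = str(row.protein_name).strip()

        key = (seq, protein_name, accession)
        if key not in grouped:
            order.append(key)
            grouped[key] = PeptideRecord(
                sequence=seq,
                species_assignment=species,
                protein_accession=accession,
                protein_name=protein_name,
                start=start,
                stop=stop,
                occurrence=occurrence,
                intensity=intensity,
                modifications=mods,
            )
        else:
            rec = grouped[key]
            rec.occurrence = {
                t: max(rec.occ(t), occurrence[t]) for t in SAMPLE_TYPES
            }
            rec.modifications = rec.modifications | mods
            if intensity is not None:
                if rec.intensity is None:
                    rec.intensity = dict(intensity)
                else:
                    for t in SAMPLE_TYPES:
                        rec.intensity[t] = rec.intensity.get(t, 0.0) + intensity[t]
    return [grouped[k] for k in order]


def write_peptide_table(records, path) -> None:
    """Write grouped records back to a study-layout TSV."""
    rows = []
    for rec in records:
        row = {
            "Sequence": rec.sequence,
            "Species": rec.species_assignment.capitalize(),
            "Protein Name": rec.protein_name or "",
            "Accession": rec.protein_accession or "",
            "Start": rec.start if rec.start is not None else "",
            "Stop": rec.stop if rec.stop is not None else "",
            "HMF": rec.occ("hmf"),
            "Milk": rec.occ("milk"),
            "Gastric": rec.occ("gastric"),
            "Modifications": ";".join(sorted(rec.modifications)),
        }
        if rec.intensity is not None:
            for stype in SAMPLE_TYPES:
                row[f"{stype.capitalize()} Intensity"] = repr(
                    float(rec.intensity.get(stype, 0.0))
                )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def summarize_counts(
    records, sample_counts: dict | None = None
) -> dict:
    """Count summary over grouped peptide records.

    Returns totals per species, per-sample-type mean identification counts
    (sum of per-sample identifications divided by the number of samples of
    that type), and the number of peptides identified in every sample of a
    type, overall and split by species.  ``total_records`` counts
    (sequence, parent) pairs; ``total_unique_sequences`` collapses parents.
    """
    sample_counts = dict(DEFAULT_SAMPLE_COUNTS, **(sample_counts or {}))
    records = list(records)
    by_species = {s: 0 for s in SPECIES_VALUES}
    for rec in records:
        by_species[rec.species_assignment] += 1

    mean_per_sample = {}
    found_in_all = {}
    found_in_all_by_species = {}
    for stype, n in sample_counts.items():
        total_ids = sum(rec.occ(stype) for rec in records)
        mean_per_sample[stype] = total_ids / n if n else 0.0
        full = [rec for rec in records if rec.occ(stype) == n]
        found_in_all[stype] = len(full)
        split = {s: 0 for s in SPECIES_VALUES}
        for rec in full:
            split[rec.species_assignment] += 1
        found_in_all_by_species[stype] = split

    return {
        "total_records": len(records),
        "total_unique_sequences": len({rec.sequence for rec in records}),
        "by_species": by_species,
        "identified": {
            stype: sum(1 for rec in records if rec.occ(stype) > 0)
            for stype in sample_counts
        },
        "mean_per_sample": mean_per_sample,
        "found_in_all": found_in_all,
        "found_in_all_by_species": found_in_all_by_species,
        "sample_counts": sample_counts,
    }
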