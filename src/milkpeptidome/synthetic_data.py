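"""In-silico digestion simulator emulating the study's peptidomic
structure: five milk samples (human proteins digested by milk proteases,
plasmin-dominated), one bovine-based fortifier sample, and five gastric
samples containing partially surviving feed peptides plus new fragments
released from both species' proteins by the acid proteases pepsin and
cathepsin D (with elastase).

The generative model, per sample type:

1. every peptide bond whose full P4..P4' context matches one of the
   type's protease matrices at zero mismatches (restrictions obeyed,
   end-truncated contexts ineligible) is cut independently with
   probability ``cleavage_probability`` scaled by the matching protease's
   relative activity;
2. the resulting single-pass fragments of at least ``min_peptide_length``
   residues (default 7, the identification floor of peptidomic database
   search) form the type's peptide pool;
3. each biological sample of the type observes each pool peptide with
   probability ``1 - missingness``, with a base-10 log-normal ion
   intensity; gastric samples additionally inherit the peptides observed
   in their matched milk sample (and in the fortifier) at a survival
   fraction of their feed intensity.

Fixing ``seed`` fixes every draw; the emitted tables are reproducible
byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peptidome_io import SAMPLE_TYPES, PeptideRecord
from .protease_attribution import match_site
from .reference_data import ProteinRecord, SpecificityMatrix
from .species_assignment import assign_species
from .cleavage_analysis import bond_context

logger = logging.getLogger(__name__)

#: relative activities scale each protease's per-bond cut probability;
#: the acid proteases and plasmin dominate their compartments, the
#: broad-specificity elastase is attenuated so tryptic-like (K/R) cuts
#: dominate milk and Leu/Phe cuts dominate gastric pools
DEFAULT_ACTIVITY = {
    "PLG": 1.0,
    "PGA3": 1.0,
    "CTSD": 1.0,
    "ELANE": 0.2,
    "F2": 0.3,
    "KLK6": 0.3,
    "KLK11": 0.2,
}


@dataclass
class DigestionConfig:
    """Study-structure parameters for the simulator."""

    protease_ids_by_sample_type: dict = field(
        default_factory=lambda: {
            "milk": ["PLG", "ELANE", "F2", "KLK6"],
            "hmf": ["PLG"],
            "gastric": ["PGA3", "CTSD", "ELANE"],
        }
    )
    cleavage_probability: float = 0.6
    min_peptide_length: int = 7
    abundance_mu: float = 6.0  # log10 intensity mean
    abundance_sigma: float = 0.8  # log10 intensity sd
    missingness: float = 0.2
    #: fraction of a feed peptide's intensity persisting in the stomach
    carryover_survival: float = 0.3
    #: probability a feed peptide escapes further gastric degradation and
    #: is identified at all in the matched gastric sample
    carryover_retention: float = 0.1
    n_milk_samples: int = 5
    n_gastric_samples: int = 5
    protease_activity: dict = field(default_factory=lambda: dict(DEFAULT_ACTIVITY))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cleavage_probability <= 1:
            raise ValueError("cleavage_probability must be in [0, 1]")
        for name in ("missingness", "carryover_survival", "carryover_retention"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_peptide_length < 1:
            raise ValueError("min_peptide_length must be >= 1")
        if self.n_milk_samples < 1 or self.n_gastric_samples < 1:
            raise ValueError("sample counts must be >= 1")


def eligible_bonds(
    protein: ProteinRecord, matrices
) -> list[tuple[int, float]]:
    """Bonds whose full context matches a matrix at zero mismatches,
    with the maximal relative activity among matching proteases."""
    out = []
    for bond in range(1, len(protein)):
        context = bond_context(protein, bond)
        best = 0.0
        for matrix in matrices:
            res = match_site(context, matrix, max_mismatches=0)
            if res.matched:
                activity = DEFAULT_ACTIVITY.get(matrix.protease_id, 1.0)
                best = max(best, activity)
        if best > 0:
            out.append((bond, best))
    return out


def digest_protein(
    protein: ProteinRecord,
    matrices,
    config: DigestionConfig,
    seed: int,
) -> list[tuple[str, int, int]]:
    """One stochastic single-pass digestion realization.

    Returns fragments as ``(sequence, start, stop)`` with 1-based
    inclusive coordinates on the mature sequence; fragments shorter than
    ``config.min_peptide_length`` are discarded.
    """
    if not list(matrices):
        raise ValueError("no specificity matrices supplied")
    seq = protein.mature_sequence
    if len(seq) < config.min_peptide_length:
        logger.warning(
            "%s shorter than min peptide length; no fragments",
            protein.accession,
        )
        return []
    rng = np.random.default_rng(seed)
    activity = dict(DEFAULT_ACTIVITY, **config.protease_activity)
    cuts = []
    for bond in range(1, len(seq)):
        context = bond_context(protein, bond)
        best = 0.0
        for matrix in matrices:
            if match_site(context, matrix, max_mismatches=0).matched:
                best = max(best, activity.get(matrix.protease_id, 1.0))
        if best == 0.0:
            continue
        if rng.random() < min(1.0, config.cleavage_probability * best):
            cuts.append(bond)
    boundaries = [0] + cuts + [len(seq)]
    fragments = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        if hi - lo >= config.min_peptide_length:
            fragments.append((seq[lo:hi], lo + 1, hi))
    return fragments


@dataclass
class SimulatedStudy:
    """Grouped peptide records plus the emitted tables."""

    records: list
    table: pd.DataFrame  # study-layout peptide table
    intensities: pd.DataFrame  # long format, one row per (sample, peptide)
    sample_counts: dict


def _sample_ids(config: DigestionConfig) -> dict:
    return {
        "milk": [f"milk_{i + 1}" for i in range(config.n_milk_samples)],
        "hmf": ["hmf_1"],
        "gastric": [f"gastric_{i + 1}" for i in range(config.n_gastric_samples)],
    }


def simulate_study(
    human_ref,
    bovine_ref,
    config: DigestionConfig,
    matrices: dict[str, SpecificityMatrix] | None = None,
) -> SimulatedStudy:
    """Simulate the full milk / fortifier / gastric peptidome study."""
    human_ref = list(human_ref)
    bovine_ref = list(bovine_ref)
    if not human_ref or not bovine_ref:
        raise ValueError("both protein references must be non-empty")
    if matrices is None:
        from .reference_data import default_specificity_matrices

        matrices = default_specificity_matrices()
    for stype, ids in config.protease_ids_by_sample_type.items():
        missing = [p for p in ids if p not in matrices]
        if missing:
            raise ValueError(f"{stype}: no matrix for protease(s) {missing}")

    ss = np.random.SeedSequence(config.seed)
    seed_pool = iter(ss.generate_state(4096))

    def next_seed() -> int:
        return int(next(seed_pool))

    substrates = {"milk": human_ref, "hmf": bovine_ref, "gastric": human_ref + bovine_ref}
    type_matrices = {
        stype: [matrices[p] for p in config.protease_ids_by_sample_type[stype]]
        for stype in SAMPLE_TYPES
    }

    # one digestion realization per sample type; per-sample variation comes
    # from missingness and intensity noise
    pools: dict[str, list] = {}
    for stype in SAMPLE_TYPES:
        pool = []
        for protein in substrates[stype]:
            for seq, start, stop in digest_protein(
                protein, type_matrices[stype], config, next_seed()
            ):
                pool.append((protein, seq, start, stop))
        pools[stype] = pool

    ids = _sample_ids(config)
    obs_rng = np.random.default_rng(next_seed())
    # observations[(sample_type, sample_id)] -> {(accession, seq, start, stop): intensity}
    observations: dict[tuple, dict] = {
        (stype, sid): {} for stype in SAMPLE_TYPES for sid in ids[stype]
    }

    def draw_intensity() -> float:
        return float(
            10.0 ** obs_rng.normal(config.abundance_mu, config.abundance_sigma)
        )

    for stype in ("milk", "hmf"):
        for sid in ids[stype]:
            for protein, seq, start, stop in pools[stype]:
                if obs_rng.random() < config.missingness:
                    continue
                key = (protein.accession, seq, start, stop)
                observations[(stype, sid)][key] = draw_intensity()

    for i, sid in enumerate(ids["gastric"]):
        sample = observations[("gastric", sid)]
        # new gastric fragments
        for protein, seq, start, stop in pools["gastric"]:
            if obs_rng.random() < config.missingness:
                continue
            key = (protein.accession, seq, start, stop)
            sample[key] = sample.get(key, 0.0) + draw_intensity()
        # survival of the matched milk sample's peptides
        feeds = [("milk", ids["milk"][i % len(ids["milk"])]), ("hmf", "hmf_1")]
        for feed_key in feeds:
            for key, intensity in observations[feed_key].items():
                if obs_rng.random() >= config.carryover_retention:
                    continue  # degraded beyond identification
                sample[key] = sample.get(key, 0.0) + intensity * config.carryover_survival

    proteins_by_acc = {p.accession: p for p in human_ref + bovine_ref}
    sample_counts = {
        "milk": config.n_milk_samples,
        "hmf": 1,
        "gastric": config.n_gastric_samples,
    }

    # group observations into peptide records
    grouped: dict[tuple, dict] = {}
    long_rows = []
    for (stype, sid), sample in observations.items():
        for (accession, seq, start, stop), intensity in sorted(sample.items()):
            long_rows.append(
                {
                    "sample_type": stype,
                    "sample_id": sid,
                    "sequence": seq,
                    "accession": accession,
                    "intensity": intensity,
                }
            )
            key = (seq, accession, start, stop)
            entry = grouped.setdefault(
                key,
                {
                    "samples": {t: set() for t in SAMPLE_TYPES},
                    "intensity": {t: 0.0 for t in SAMPLE_TYPES},
                },
            )
            entry["samples"][stype].add(sid)
            entry["intensity"][stype] += intensity

    mod_rng = np.random.default_rng(next_seed())
    records = []
    for (seq, accession, start, stop) in sorted(grouped):
        entry = grouped[(seq, accession, start, stop)]
        protein = proteins_by_acc[accession]
        species, loci = assign_species(seq, human_ref, bovine_ref)
        mods = set()
        if "M" in seq and mod_rng.random() < 0.15:
            mods.add("O")
        if ("S" in seq or "T" in seq) and mod_rng.random() < 0.25:
            mods.add("P")
        records.append(
            PeptideRecord(
                sequence=seq,
                species_assignment=species,
                protein_accession=accession,
                protein_name=protein.short_name,
                start=start,
                stop=stop,
                occurrence={
                    t: len(entry["samples"][t]) for t in SAMPLE_TYPES
                },
                intensity=dict(entry["intensity"]),
                modifications=frozenset(mods),
                loci=tuple(loci),
            )
        )

    table = pd.DataFrame(
        {
            "Sequence": [r.sequence for r in records],
            "Species": [r.species_assignment.capitalize() for r in records],
            "Protein Name": [r.protein_name for r in records],
            "Accession": [r.protein_accession for r in records],
            "Start": [r.start for r in records],
            "Stop": [r.stop for r in records],
            "HMF": [r.occ("hmf") for r in records],
            "Milk": [r.occ("milk") for r in records],
            "Gastric": [r.occ("gastric") for r in records],
            "Modifications": [";".join(sorted(r.modifications)) for r in records],
            "Milk Intensity": [r.intensity_of("milk") for r in records],
            "HMF Intensity": [r.intensity_of("hmf") for r in records],
            "Gastric Intensity": [r.intensity_of("gastric") for r in records],
        }
    )
    intensities = pd.DataFrame(
        long_rows,
        columns=["sample_type", "sample_id", "sequence", "accession", "intensity"],
    ).sort_values(["sample_type", "sample_id", "accession", "sequence"], kind="mergesort").reset_index(drop=True)
    return SimulatedStudy(
        records=records,
        table=table,
        intensities=intensities,
        sample_counts=sample_counts,
    )


def study_scale_table(seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in peptide table matching the published study's
    marginal structure (the deposited peptidomes themselves are not
    redistributable).

    The table has 5,264 unique peptides — 3,399 human, 1,722 bovine and
    138 species-indistinguishable — with 538 fortifier peptides, milk
    identification counts summing to 3,598 (mean 719.6 per milk sample,
    185 peptides in all five), and gastric counts summing to 8,604 (mean
    1,720.8 per gastric sample; 310 peptides in all five: 168 bovine,
    137 human, 5 indistinguishable).  Sequences are random and carry no
    biological meaning; the table exercises ingestion and count
    summaries at study scale.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    sequences: set[str] = set()

    def new_seq() -> str:
        while True:
            n = int(rng.integers(7, 26))
            s = "".join(rng.choice(alphabet, size=n))
            if s not in sequences:
                sequences.add(s)
                return s

    rows = []

    def add(species, milk, hmf, gastric):
        row = {
            "Sequence": new_seq(),
            "Species": species,
            "Protein Name": "synthetic protein",
            "Start": "",
            "Stop": "",
            "HMF": hmf,
            "Milk": milk,
            "Gastric": gastric,
            "Modifications": "",
        }
        rows.append(row)
        return row

    # peptides found in all five gastric samples (310 * 5 = 1550 ids)
    for _ in range(168):
        add("Bovine", 0, 0, 5)
    for _ in range(137):
        add("Human", 0, 0, 5)
    for _ in range(5):
        add("Both", 0, 0, 5)
    # peptides found in all five milk samples (185 * 5 = 925 ids)
    for _ in range(185):
        add("Human", 5, 0, 0)
    # fortifier peptides (538 ids in the single HMF sample)
    for _ in range(538):
        add("Bovine", 0, 1, 0)
    # milk-covered human peptides carrying the remaining
    # 3598 - 925 = 2673 milk identifications (668 * 4 + 1)
    for _ in range(668):
        add("Human", 4, 0, 0)
    add("Human", 1, 0, 0)

    # peptides whose only identifications are gastric, plus the species
    # splits printed alongside the 5,264 total (they sum to 5,259; five
    # peptides are left species-unassigned to reconcile the two)
    gastric_only = []
    for _ in range(1016):
        gastric_only.append(add("Bovine", 0, 0, 1))
    for _ in range(2408):
        gastric_only.append(add("Human", 0, 0, 1))
    for _ in range(133):
        gastric_only.append(add("Both", 0, 0, 1))
    for _ in range(5):
        gastric_only.append(add("Unassigned", 0, 0, 1))

    # distribute the remaining gastric identifications
    # (8604 - 1550 - len(gastric_only)) one bump at a time, capped below
    # the found-in-all level
    remaining = 8604 - 1550 - len(gastric_only)
    i = 0
    while remaining > 0:
        row = gastric_only[i % len(gastric_only)]
        if row["Gastric"] < 4:
            row["Gastric"] += 1
            remaining -= 1
        i += 1

    return pd.DataFrame(rows)
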