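"""End-to-end pipeline orchestration.

``run_pipeline`` executes ingest -> assign -> map -> cleavage ->
attribute -> bioactive -> summarize from a YAML configuration and writes
every stage artifact plus a manifest (package version, configuration
hash, seed, artifact checksums).  All randomness flows from the single
configured seed, and floats are serialized with ``repr`` so reruns with
the same configuration are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import metadata
from pathlib import Path

import pandas as pd
import yaml

from . import (
    bioactivity_search,
    cleavage_analysis,
    mapping_profiles,
    peptidome_io,
    protease_attribution,
    reference_data,
    reporting,
    species_assignment,
    synthetic_data,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_frame(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=True, float_format=None)


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh) or {}
    config.setdefault("seed", 0)
    config.setdefault("samples", {"milk": 5, "gastric": 5, "hmf": 1})
    config.setdefault("thresholds", {})
    config["thresholds"].setdefault("bioactive_similarity", 80.0)
    config["thresholds"].setdefault("max_mismatches", 3)
    config.setdefault("references", {})
    return config


def run_pipeline(config_path, outdir=None) -> Path:
    """Run every stage; returns the output directory.

    The config names either an input peptide ``table`` or ``table:
    simulate`` to run on simulator output; reference paths default to the
    packaged data.  Any stage failure raises :class:`PipelineError`
    naming the stage.
    """
    config = load_config(config_path)
    out = Path(outdir or config.get("outdir", "milkpeptidome_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    refs = config["references"]

    def stage(name):
        logger.info("stage: %s", name)

    artifacts: list[Path] = []

    try:
        stage("references")
        human_ref = (
            reference_data.load_protein_reference(refs["human"], "human")
            if refs.get("human")
            else reference_data.default_protein_reference("human")
        )
        bovine_ref = (
            reference_data.load_protein_reference(refs["bovine"], "bovine")
            if refs.get("bovine")
            else reference_data.default_protein_reference("bovine")
        )
        matrices = (
            reference_data.load_specificity_matrices(refs["matrices"])
            if refs.get("matrices")
            else reference_data.default_specificity_matrices()
        )
        if "bioactives" in refs and refs["bioactives"] is None:
            raise PipelineError(
                "stage bioactive: no bioactive reference configured"
            )
        bioactives = (
            reference_data.load_bioactive_reference(refs["bioactives"])
            if refs.get("bioactives")
            else reference_data.default_bioactive_reference()
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context added
        raise PipelineError(f"stage references: {exc}") from exc

    sample_counts = dict(config["samples"])

    try:
        stage("ingest")
        table_spec = config.get("table", "simulate")
        if table_spec == "simulate":
            sim_cfg = synthetic_data.DigestionConfig(
                seed=seed, **config.get("simulation", {})
            )
            sample_counts = {
                "milk": sim_cfg.n_milk_samples,
                "hmf": 1,
                "gastric": sim_cfg.n_gastric_samples,
            }
            study = synthetic_data.simulate_study(
                human_ref, bovine_ref, sim_cfg, matrices
            )
            records = study.records
            table_path = out / "peptides.tsv"
            peptidome_io.write_peptide_table(records, table_path)
            intens_path = out / "sample_intensities.tsv"
            study.intensities.to_csv(
                intens_path,
                sep="\t",
                index=False,
                float_format=None,
            )
            artifacts += [table_path, intens_path]
        else:
            records = peptidome_io.read_peptide_table(table_spec, sample_counts)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage ingest: {exc}") from exc

    have_intensity = any(r.intensity is not None for r in records)
    if not have_intensity:
        logger.info(
            "no intensities in input; intensity-weighted artifacts skipped"
        )

    try:
        stage("assign")
        for rec in records:
            if rec.species_assignment == "unassigned" or not rec.loci:
                species, loci = species_assignment.assign_species(
                    rec.sequence, human_ref, bovine_ref
                )
                if species != "unassigned":
                    rec.species_assignment = species
                    rec.loci = tuple(loci)
        summary = peptidome_io.summarize_counts(records, sample_counts)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        artifacts.append(out / "summary.json")
    except Exception as exc:
        raise PipelineError(f"stage assign: {exc}") from exc

    try:
        stage("summarize")
        for stype in ("milk", "gastric"):
            cons = reporting.conservation_summary(
                records, stype, sample_counts[stype]
            )
            path = out / f"conservation_{stype}.tsv"
            _write_frame(cons["levels"], path)
            artifacts.append(path)
        shares_written = []
        for species in ("human", "bovine"):
            for stype in ("milk", "gastric", "hmf"):
                try:
                    shares = reporting.per_protein_shares(records, species, stype)
                except ValueError:
                    continue
                path = out / f"protein_shares_{species}_{stype}.tsv"
                _write_frame(shares, path)
                shares_written.append(path)
        artifacts += shares_written
    except Exception as exc:
        raise PipelineError(f"stage summarize: {exc}") from exc

    proteins = {p.accession: p for p in human_ref + bovine_ref}

    if have_intensity:
        try:
            stage("map")
            for accession, protein in sorted(proteins.items()):
                profile = mapping_profiles.gastric_minus_feed(records, protein)
                if profile.values.sum() == 0:
                    continue
                frame = mapping_profiles.profile_to_frame(profile, protein)
                hydro = mapping_profiles.hydrophobicity_profile(protein)
                frame["hydrophobicity"] = hydro.values
                path = out / f"map_{accession}.tsv"
                frame.to_csv(path, sep="\t", index=False)
                artifacts.append(path)
        except Exception as exc:
            raise PipelineError(f"stage map: {exc}") from exc

    try:
        stage("cleavage")
        sites_by_type = {}
        for stype in ("milk", "gastric"):
            sites = cleavage_analysis.extract_cleavage_sites(
                records, proteins.values(), stype
            )
            sites_by_type[stype] = sites
            path = out / f"cleavage_sites_{stype}.tsv"
            cleavage_analysis.sites_to_frame(sites).to_csv(
                path, sep="\t", index=False
            )
            artifacts.append(path)
            if sites:
                dist = cleavage_analysis.p1_distribution(sites, "count")
                path = out / f"p1_distribution_{stype}_count.tsv"
                _write_frame(dist, path)
                artifacts.append(path)
                if have_intensity:
                    dist = cleavage_analysis.p1_distribution(sites, "intensity")
                    path = out / f"p1_distribution_{stype}_intensity.tsv"
                    _write_frame(dist, path)
                    artifacts.append(path)
    except Exception as exc:
        raise PipelineError(f"stage cleavage: {exc}") from exc

    try:
        stage("attribute")
        max_mm = int(config["thresholds"]["max_mismatches"])
        for stype, sites in sites_by_type.items():
            if not sites:
                continue
            per_site, summary_tbl = protease_attribution.attribute_sites(
                sites, matrices, sample_type=stype, max_mismatches=max_mm
            )
            per_site.to_csv(out / f"attribution_{stype}.tsv", sep="\t", index=False)
            summary_tbl.to_csv(
                out / f"attribution_summary_{stype}.tsv",
                sep="\t",
                header=["percent"],
            )
            artifacts += [
                out / f"attribution_{stype}.tsv",
                out / f"attribution_summary_{stype}.tsv",
            ]
    except Exception as exc:
        raise PipelineError(f"stage attribute: {exc}") from exc

    try:
        stage("bioactive")
        if not bioactives:
            raise ValueError("bioactive reference is empty")
        threshold = float(config["thresholds"]["bioactive_similarity"])
        matches, counts = bioactivity_search.search_bioactives(
            records, bioactives, threshold
        )
        bioactivity_search.matches_to_frame(matches).to_csv(
            out / "bioactive_matches.tsv", sep="\t", index=False
        )
        counts.to_csv(out / "bioactive_function_counts.tsv", sep="\t", header=["count"])
        artifacts += [
            out / "bioactive_matches.tsv",
            out / "bioactive_function_counts.tsv",
        ]
    except Exception as exc:
        raise PipelineError(f"stage bioactive: {exc}") from exc

    try:
        version = metadata.version("milkpeptidome")
    except metadata.PackageNotFoundError:
        version = "unknown"
    manifest = {
        "package": "milkpeptidome",
        "version": version,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "artifacts": {
            p.name: _sha256(p) for p in sorted(set(artifacts), key=lambda p: p.name)
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out
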