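"""End-to-end orchestration: catalog -> scores -> association -> loci.

A run is driven by a single YAML configuration, validates all inputs up
front, executes the stages in order, and writes versioned tabular outputs
plus a machine-readable manifest (config hash, seed, version, record counts
at every filter) into the output directory.  Any stage failure halts the run
with the stage name; outputs of completed stages are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (FDR_LEVEL, associate_all_scores, conditional_screen,
                          results_to_frame, screen_variants, subgroup_association)
from .catalog import (apply_quality_filters, load_variant_catalog, orient_effects,
                      select_leads)
from .cohort import DEFAULT_COVARIATES, load_cohort
from .errors import ConfigurationError, PleioscoreError
from .loci import (classify_consequence, define_locus, flag_known, loci_to_frame,
                   merge_loci, read_known_loci_bed)
from .scores import compute_genetic_scores, score_correlation_matrix, trait_variance_summary

logger = logging.getLogger(__name__)

_SUBGROUP_MAP = {"age75": "AGE75", "sex": "SEX", "subtype": "SUBTYPE",
                 "popbased": "POPULATION_BASED"}


@dataclass
class RunConfig:
    catalog: Path
    traits: Path
    genotypes: Path
    samples: Path
    outdir: Path
    known_loci: Path | None = None
    known_variants: Path | None = None
    consequences: Path | None = None
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    fdr: float = FDR_LEVEL
    subgroups: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("catalog", "traits", "genotypes", "samples", "outdir"):
            if key not in raw:
                raise ConfigurationError(f"config missing required key {key!r}")
        paths = {k: Path(raw[k]) for k in
                 ("catalog", "traits", "genotypes", "samples", "outdir")}
        optional = {k: Path(raw[k]) for k in
                    ("known_loci", "known_variants", "consequences") if raw.get(k)}
        return cls(
            **paths, **optional,
            covariates=tuple(raw.get("covariates", DEFAULT_COVARIATES)),
            fdr=float(raw.get("fdr", FDR_LEVEL)),
            subgroups=tuple(raw.get("subgroups", ())),
            seed=int(raw.get("seed", 0)),
        )

    def validate(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ConfigurationError(f"fdr {self.fdr} outside (0, 1)")
        for key in ("catalog", "traits", "genotypes", "samples",
                    "known_loci", "known_variants", "consequences"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{key} file not found: {p}")
        bad = [s for s in self.subgroups if s not in _SUBGROUP_MAP]
        if bad:
            raise ConfigurationError(f"unknown subgroups: {bad}")


@dataclass
class RunResult:
    outdir: Path
    manifest: dict
    outputs: dict[str, Path] = field(default_factory=dict)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write all outputs under ``outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config), "seed": config.seed,
        "version": __version__, "fdr": config.fdr, "counts": {},
    }
    counts = manifest["counts"]
    outputs: dict[str, Path] = {}
    stage = "catalog"
    try:
        catalog, ingest_report = load_variant_catalog(config.catalog, config.traits)
        counts["catalog_rows_kept"] = ingest_report.n_kept
        counts["catalog_rows_dropped"] = ingest_report.n_dropped
        catalog = orient_effects(catalog)
        catalog = select_leads(catalog)
        counts["lead_variants"] = catalog.n_variants

        stage = "cohort"
        cohort = load_cohort(config.genotypes, config.samples)
        counts["samples"] = cohort.n_samples
        counts["cases"] = int(cohort.case_mask.sum())
        counts["controls"] = int(cohort.control_mask.sum())
        counts["genotyped_variants"] = len(cohort.variant_meta)

        stage = "quality_filter"
        catalog, quality_report = apply_quality_filters(
            catalog, cohort.imputation_quality_map())
        counts["variants_after_quality"] = catalog.n_variants
        report = pd.concat([ingest_report.to_frame(), quality_report.to_frame()])
        outputs["filter_report"] = outdir / "filter_report.tsv"
        report.to_csv(outputs["filter_report"], sep="\t", index=False)

        stage = "scores"
        scores = compute_genetic_scores(cohort, catalog)
        counts["scored_traits"] = len(scores.trait_ids)
        outputs["scores"] = outdir / "scores.tsv"
        scores.to_frame().to_csv(outputs["scores"], sep="\t")
        if len(scores.trait_ids) >= 2:
            corr = score_correlation_matrix(scores)
            outputs["score_correlations"] = outdir / "score_correlations.tsv"
            corr.rho.to_csv(outputs["score_correlations"], sep="\t")
            outputs["score_correlation_q"] = outdir / "score_correlation_q.tsv"
            corr.q.to_csv(outputs["score_correlation_q"], sep="\t")

        stage = "variance"
        try:
            variance, var_summary = trait_variance_summary(catalog)
            outputs["variance_explained"] = outdir / "variance_explained.tsv"
            variance.to_csv(outputs["variance_explained"], sep="\t", index=False)
            manifest["variance_summary"] = var_summary
        except ConfigurationError as exc:
            logger.warning("variance stage skipped: %s", exc)
            manifest["variance_summary"] = {"skipped": str(exc)}

        stage = "score_association"
        score_results = associate_all_scores(scores, cohort, config.covariates)
        frame = results_to_frame(score_results)
        frame["significant"] = frame["q"] < config.fdr
        outputs["score_associations"] = outdir / "score_associations.tsv"
        frame.to_csv(outputs["score_associations"], sep="\t", index=False)
        counts["significant_scores"] = int(frame["significant"].sum())

        for sub in config.subgroups:
            strata = subgroup_association(scores, cohort, _SUBGROUP_MAP[sub],
                                          config.covariates)
            sub_frame = pd.concat(
                [results_to_frame(res) for res in strata.values()])
            key = f"score_associations_{sub}"
            outputs[key] = outdir / f"{key}.tsv"
            sub_frame.to_csv(outputs[key], sep="\t", index=False)

        stage = "variant_screen"
        raw_results = screen_variants(cohort, catalog, config.covariates)
        raw_frame = results_to_frame(raw_results).rename(columns={
            "lor": "lor_raw", "se": "se_raw", "p": "p_raw", "q": "q_raw"})
        counts["screened_variants"] = len(raw_results)
        known_ids: list[str] = []
        if config.known_variants is not None:
            known_ids = [ln.strip() for ln in
                         Path(config.known_variants).read_text().splitlines()
                         if ln.strip()]
            cond_results = conditional_screen(cohort, catalog, known_ids,
                                              config.covariates)
            cond_frame = results_to_frame(cond_results).rename(columns={
                "lor": "lor_adj", "se": "se_adj", "p": "p_adj", "q": "q_adj"})
            screen = raw_frame.merge(
                cond_frame[["target_id", "lor_adj", "se_adj", "p_adj", "q_adj"]],
                on="target_id", how="left")
            screen["significant"] = (screen["q_raw"] < config.fdr) & (
                screen["q_adj"] < config.fdr)
        else:
            screen = raw_frame
            screen["significant"] = screen["q_raw"] < config.fdr
        outputs["variant_screen"] = outdir / "variant_screen.tsv"
        screen.to_csv(outputs["variant_screen"], sep="\t", index=False)
        counts["significant_variants"] = int(screen["significant"].sum())

        stage = "loci"
        known_loci = (read_known_loci_bed(config.known_loci)
                      if config.known_loci is not None else [])
        sig_ids = set(screen.loc[screen["significant"], "target_id"])
        by_id = {}
        for v in catalog.all_variants:
            by_id.setdefault(v.variant_id, v)
        candidates = [by_id[vid] for vid in sig_ids if vid in by_id]
        known_hits, novel_hits = flag_known(candidates, known_loci)
        counts["hits_in_known_loci"] = len(known_hits)
        counts["novel_hit_variants"] = len(novel_hits)
        intervals = [define_locus(v, cohort) for v in novel_hits]
        distinct = merge_loci(intervals)
        counts["novel_loci"] = len(distinct)
        outputs["loci"] = outdir / "loci.tsv"
        loci_to_frame(distinct).to_csv(outputs["loci"], sep="\t", index=False)

        stage = "consequences"
        if config.consequences is not None:
            cons = pd.read_csv(config.consequences, sep="\t")
            parsed = [classify_consequence(c) for c in cons["consequence"]]
            cons["classification"] = [p.classification for p in parsed]
            outputs["consequences"] = outdir / "consequences.tsv"
            cons.to_csv(outputs["consequences"], sep="\t", index=False)
            counts["nonsynonymous"] = int(
                sum(p.classification == "NONSYNONYMOUS" for p in parsed))
            counts["synonymous"] = int(
                sum(p.classification == "SYNONYMOUS" for p in parsed))
    except PleioscoreError:
        logger.error("pipeline halted in stage %r", stage)
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    outputs["manifest"] = outdir / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=2))
    return RunResult(outdir=outdir, manifest=manifest, outputs=outputs)
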