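"""End-to-end pipeline orchestration with an audit manifest.

``run_pipeline`` chains the full study: adult filter -> relatedness
pruning -> LDL-C preparation -> principal components -> LDL-C scan ->
variant-selection cascade (primary or secondary) -> phecode assignment
-> phecode case-count filter -> logistic PheWAS scan -> Bonferroni
thresholding -> optional five-fold cross-validation of the hits.  Every
run emits one :class:`RunManifest` with the config snapshot, input
digests, seed and per-stage counts; all randomness flows from the single
manifest seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import GENE_REGIONS, PipelineConfig, SimulationConfig
from . import fileio, phecodes, scan as scan_mod, selection, validate
from .simulate import SyntheticCohort, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Audit trail for one pipeline run."""

    seed: int
    config: dict
    input_digests: Dict[str, str] = field(default_factory=dict)
    stage_counts: Dict[str, int] = field(default_factory=dict)
    version: str = __version__
    failed_stage: Optional[str] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


@dataclass
class PipelineOutput:
    """In-memory outputs of a pipeline run."""

    manifest: RunManifest
    selected_variants: List[str]
    selection_audit: pd.DataFrame
    ldl_stats: pd.DataFrame
    assignments: pd.DataFrame
    phecode_counts: pd.DataFrame
    results: Optional[scan_mod.PhewasResults]
    hits: pd.DataFrame
    crossval: Optional[pd.DataFrame]
    exclusions: pd.DataFrame


def run_pipeline(
    cohort: SyntheticCohort = None,
    *,
    config_path=None,
    out_dir=None,
    seed: Optional[int] = None,
    thresholds: Optional[PipelineConfig] = None,
    mode: str = "primary",
    include_site: bool = False,
    do_crossval: bool = False,
    crossval_k: int = 5,
) -> PipelineOutput:
    """Execute the full pipeline on a cohort (in memory or from a YAML config).

    A YAML config provides a ``simulate`` block (study design for the
    synthetic cohort) plus optional ``thresholds``, ``mode``,
    ``crossval`` and ``include_site`` keys.  Stage failures halt the run
    with a manifest recording the failed stage.
    """
    input_digests: Dict[str, str] = {}
    if cohort is None:
        if config_path is None:
            raise ValueError("provide either a cohort or a config_path")
        with open(config_path) as fh:
            raw = yaml.safe_load(fh)
        input_digests[str(config_path)] = fileio.file_digest(config_path)
        sim_cfg = SimulationConfig.from_dict(raw["simulate"])
        if seed is not None:
            sim_cfg.seed = seed
        thresholds = PipelineConfig.from_dict(raw.get("thresholds", {}))
        mode = raw.get("mode", mode)
        include_site = raw.get("include_site", include_site)
        do_crossval = raw.get("crossval", do_crossval)
        cohort = simulate_cohort(sim_cfg)
    if thresholds is None:
        thresholds = PipelineConfig()
    if seed is None:
        seed = cohort.config.seed
    if mode not in ("primary", "secondary"):
        raise ValueError(f"unknown selection mode {mode!r}")

    manifest = RunManifest(
        seed=seed,
        config={"thresholds": thresholds.to_dict(), "mode": mode,
                "simulate": cohort.config.to_dict()},
        input_digests=input_digests,
    )
    counts = manifest.stage_counts
    counts["persons_input"] = len(cohort.dosages)
    counts["variants_input"] = len(cohort.variants)
    exclusion_rows = []

    try:
        stage = "phecode_assignment"
        date_counts = phecodes.map_icd_to_phecodes(cohort.events, cohort.phecode_map)
        assignments = phecodes.assign_case_control(
            date_counts, cohort.phecode_map, cohort=cohort.dosages.index
        )

        stage = "adult_filter"
        assignments = phecodes.filter_adults(
            assignments, cohort.demographics, cohort.events, thresholds.adult_age_min
        )
        removed = cohort.dosages.index.difference(assignments.index)
        exclusion_rows += [dict(person=p, reason="not_adult") for p in removed]
        counts["persons_adult"] = len(assignments)

        stage = "relatedness_pruning"
        retained = selection.prune_relatives(
            cohort.relatedness, assignments.index, thresholds.ibd_threshold, seed=seed
        )
        removed = assignments.index.difference(retained)
        exclusion_rows += [dict(person=p, reason="related") for p in removed]
        assignments = assignments.loc[retained]
        counts["persons_unrelated"] = len(assignments)
        persons = assignments.index

        stage = "ldl_preparation"
        ldl = selection.prepare_ldl(cohort.measurements, thresholds.llm_adjust_factor)
        ldl = ldl.reindex(persons)
        counts["persons_with_ldl"] = int(ldl.notna().sum())

        stage = "principal_components"
        pcs, explained = selection.compute_pcs(
            cohort.dosages.loc[persons], thresholds.n_pcs
        )

        stage = "ldl_scan"
        llm_status = (
            cohort.measurements.groupby("person")["on_llm"].max().reindex(persons).fillna(0)
        )
        med_age = phecodes.median_event_ages(cohort.events, cohort.demographics.loc[persons])
        ldl_cov = pd.DataFrame(
            {"age": med_age, "sex": cohort.demographics.loc[persons, "sex"],
             "llm": llm_status}
        ).join(pcs)
        ldl_stats = selection.ldl_scan(cohort.dosages.loc[persons], ldl, ldl_cov)

        stage = "variant_selection"
        select = (
            selection.select_primary_variants
            if mode == "primary"
            else selection.select_secondary_variants
        )
        selected, audit = select(
            cohort.variants, cohort.dosages.loc[persons], ldl_stats,
            GENE_REGIONS, thresholds,
        )
        counts["variants_selected"] = len(selected)

        stage = "phecode_filter"
        kept, phecode_counts = phecodes.filter_phecodes(assignments, thresholds.min_cases)
        counts["phecodes_analyzed"] = len(kept)

        results = None
        hits = pd.DataFrame()
        cv = None
        if selected and kept:
            stage = "phewas_scan"
            cov = scan_mod.build_covariates(
                med_age, cohort.demographics.loc[persons], pcs, include_site=include_site
            )
            model = scan_mod.PhewasScan(
                cohort.dosages.loc[persons], assignments[kept], cov,
                phecodes=kept, variants=selected, config=thresholds,
            )
            results = model.fit()
            hits = results.significant_hits()
            counts["significant_hits"] = len(hits)

            if do_crossval and len(hits):
                stage = "cross_validation"
                cv = validate.cross_validate(
                    list(zip(hits["rsid"], hits["phecode"])),
                    cohort.dosages.loc[persons], assignments, cov,
                    k=crossval_k, seed=seed,
                )
        else:
            logger.info("scan skipped: %d variants selected, %d phecodes analyzable",
                        len(selected), len(kept))
            counts["significant_hits"] = 0
    except Exception:
        manifest.failed_stage = stage
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            manifest.to_json(Path(out_dir) / "manifest.json")
        raise

    exclusions = pd.DataFrame(exclusion_rows, columns=["person", "reason"])
    output = PipelineOutput(
        manifest=manifest,
        selected_variants=selected,
        selection_audit=audit,
        ldl_stats=ldl_stats,
        assignments=assignments,
        phecode_counts=phecode_counts,
        results=results,
        hits=hits,
        crossval=cv,
        exclusions=exclusions,
    )
    if out_dir is not None:
        _write_outputs(Path(out_dir), output)
    return output


def _write_outputs(out_dir: Path, output: PipelineOutput) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    output.manifest.to_json(out_dir / "manifest.json")
    fileio.write_table(out_dir / "selection_audit.tsv", output.selection_audit.reset_index())
    fileio.write_table(out_dir / "ldl_associations.tsv", output.ldl_stats.reset_index())
    output.assignments.to_csv(out_dir / "assignments.tsv", sep="\t")
    fileio.write_table(out_dir / "phecode_counts.tsv", output.phecode_counts.reset_index())
    if output.results is not None:
        fileio.write_table(out_dir / "scan_results.tsv", output.results.results)
    fileio.write_table(out_dir / "significant_hits.tsv", output.hits)
    if output.crossval is not None:
        cv = output.crossval.copy()
        cv["fold_p"] = cv["fold_p"].apply(lambda ps: ",".join(f"{p:.6g}" for p in ps))
        fileio.write_table(out_dir / "crossval.tsv", cv)
    fileio.write_table(out_dir / "exclusions.tsv", output.exclusions)
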