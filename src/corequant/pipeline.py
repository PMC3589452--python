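"""End-to-end orchestration: dataset in, staged differential results out."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .identifications import FilterPolicy, drop_single_count_peptides, filter_psms, rollup
from .matrix import AbundanceMatrix
from .orthology import (
    DetectionSet,
    OrthologGroupBuilder,
    core_proteins_of_genome,
    detected_core_percent,
    fraction_table,
)
from .quantification import (
    ZPolicy,
    call_significance,
    impute_missing,
    log_transform,
    normalize_by_length,
    stage_aggregate,
    zscore_rows,
)
from .functional import summarize_shifts
from .simulate import Dataset
from .staging import StageAssignment, StageClusterer


@dataclass
class PipelineResult:
    counts: AbundanceMatrix
    log_matrix: AbundanceMatrix
    zscores: AbundanceMatrix
    zscores_imputed: AbundanceMatrix
    stage_assignment: StageAssignment
    stage_matrix: pd.DataFrame
    calls: pd.DataFrame
    groups_builder: OrthologGroupBuilder | None
    detection: DetectionSet
    core_protein_ids: set[str]
    fraction_table: pd.DataFrame | None
    core_detected_pct: float | None
    cog_summary: pd.DataFrame


def run_pipeline(
    dataset: Dataset,
    filter_policy: FilterPolicy | None = None,
    z_policy: ZPolicy | None = None,
    n_stages: int = 3,
    with_orthology: bool = True,
) -> PipelineResult:
    """Run filtering, roll-up, quantification, staging, ΔZ calls,
    orthology and the COG summary on one dataset."""
    filter_policy = filter_policy or FilterPolicy()
    z_policy = z_policy or ZPolicy()

    surviving = drop_single_count_peptides(
        filter_psms(dataset.psms, filter_policy), filter_policy
    )
    counts = rollup(surviving, dataset.focal_catalog, sample_ids=dataset.sample_ids)
    detection = DetectionSet.from_matrix(counts)

    log_m = log_transform(normalize_by_length(counts, dataset.focal_catalog), z_policy)
    z = zscore_rows(log_m, z_policy)
    z_imp = impute_missing(z, z_policy)

    clusterer = StageClusterer(n_stages=n_stages).fit(dataset.geochem)
    assignment = clusterer.stage_assignment_
    stage_of_sample = {f"day{d}": s for d, s in assignment.mapping.items()}
    stage_order = [s for s in assignment.stage_order]
    stage_matrix = stage_aggregate(z_imp, stage_of_sample, stage_order)
    calls = call_significance(stage_matrix, z_policy)

    builder = None
    core_proteins: set[str] = set()
    fractions = None
    core_pct = None
    if with_orthology and len(dataset.similarity):
        builder = OrthologGroupBuilder().fit(dataset.similarity)
        genomes = [c.genome for c in dataset.catalogs]
        core_proteins = core_proteins_of_genome(
            builder.groups_, genomes, dataset.focal_genome
        )
        fractions = fraction_table(
            builder.groups_, dataset.catalogs, detection, dataset.focal_genome
        )
        if core_proteins:
            core_pct = detected_core_percent(core_proteins, detection)

    cogs = dataset.focal_catalog.cogs().to_dict()
    summary = summarize_shifts(calls, cogs, detection)

    return PipelineResult(
        counts=counts,
        log_matrix=log_m,
        zscores=z,
        zscores_imputed=z_imp,
        stage_assignment=assignment,
        stage_matrix=stage_matrix,
        calls=calls,
        groups_builder=builder,
        detection=detection,
        core_protein_ids=core_proteins,
        fraction_table=fractions,
        core_detected_pct=core_pct,
        cog_summary=summary,
    )
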