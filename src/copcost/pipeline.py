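"""End-to-end orchestration: raw tables -> cost cells -> annual report.

The stage order mirrors the accounting identity chain: classify and
allocate funding, filter to IO/university scope, estimate and apply
retention, take direct and back-filled exclusions, derive NEC, and invert
it into indirect costs under each rate scenario.

Retention rates are estimated from the *pre-allocation* in-scope funding
(sub-award observations relate to actual mechanisms, not to imputed NA
amounts); the resulting rates are then applied to the post-allocation
cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import classification, cop_data, exclusions, reporting, retention, scenarios

log = logging.getLogger("copcost")


@dataclass
class PipelineResult:
    cells: pd.DataFrame
    retention_table: retention.RetentionTable
    report: reporting.AnnualReport
    excluded_classes: dict[str, int]
    allocation_audit: classification.AllocationAudit
    exclusion_audit: exclusions.ExclusionAudit
    policy: exclusions.ExclusionPolicy
    audit_lines: list[str] = field(default_factory=list)


def run_pipeline(
    funding: pd.DataFrame,
    subawards: pd.DataFrame,
    crosscutting: pd.DataFrame,
    classes: pd.DataFrame | dict[str, str],
    rates: pd.DataFrame | dict,
    policy: exclusions.ExclusionPolicy | None = None,
    specs: tuple[scenarios.ScenarioSpec, ...] = scenarios.DEFAULT_SCENARIOS,
    window_years: list[int] | None = None,
    io_reference_year: int | None = None,
    threshold_cents: int = retention.DEFAULT_IO_SUB_THRESHOLD_CENTS,
    io_override: dict[str, bool] | None = None,
) -> PipelineResult:
    """Run the whole model on canonicalized input tables.

    ``classes`` and ``rates`` accept either the DataFrames returned by
    :func:`copcost.cop_data.read_table` or pre-built lookup structures.
    Observation windows default to the years actually present in the
    sub-award and cross-cutting tables.
    """
    class_table = (
        classes if isinstance(classes, dict) else cop_data.class_lookup(classes)
    )
    nicra = rates if isinstance(rates, dict) else cop_data.rate_table(rates)
    policy = exclusions.resolve_observed_years(
        policy or exclusions.ExclusionPolicy(), crosscutting
    )

    classified = classification.classify_funding(funding, class_table)
    scoped_raw, _ = classification.filter_in_scope(classified)

    allocated, alloc_audit = classification.allocate_na(classified)
    scoped, excluded_classes = classification.filter_in_scope(allocated)
    cells = classification.cell_totals(scoped)

    rt = retention.build_retention_table(
        subawards,
        scoped_raw,
        class_table,
        window_years=window_years,
        io_reference_year=io_reference_year,
        threshold_cents=threshold_cents,
    )
    cells = retention.apply_retention(cells, rt)

    cells, exc_audit = exclusions.direct_exclusions(cells, scoped, crosscutting, policy)
    cells, exc_audit = exclusions.backfill_exclusions(cells, policy, exc_audit)
    cells, exc_audit = exclusions.compute_nec(cells, exc_audit)

    cells = scenarios.run_scenarios(cells, specs, nicra, io_override)
    report = reporting.build_report(cells, tuple(s.id for s in specs))

    audit = [
        f"in-scope cells: {len(cells)}",
        f"excluded class totals (cents): {excluded_classes}",
        f"NA allocated (cents): {alloc_audit.allocated_cents}; "
        f"unallocatable: {alloc_audit.unallocatable_cents}",
        f"retention clamped pairs: {rt.clamped_pairs}",
        f"EC components clamped: {len(exc_audit.clamped_components)}",
        f"negative-NEC cells: {len(exc_audit.negative_nec_cells)}",
        f"back-fill provenance: {exc_audit.backfill_provenance}",
    ]
    return PipelineResult(
        cells=cells,
        retention_table=rt,
        report=report,
        excluded_classes=excluded_classes,
        allocation_audit=alloc_audit,
        exclusion_audit=exc_audit,
        policy=policy,
        audit_lines=audit,
    )


def run_from_paths(
    funding_path,
    subawards_path,
    crosscutting_path,
    classes_path,
    rates_path,
    **kwargs,
) -> PipelineResult:
    """Convenience wrapper reading the five CSVs, then running the model."""
    return run_pipeline(
        cop_data.read_table(funding_path, "funding"),
        cop_data.read_table(subawards_path, "subawards"),
        cop_data.read_table(crosscutting_path, "crosscutting"),
        cop_data.read_table(classes_path, "classes"),
        cop_data.read_table(rates_path, "rates"),
        **kwargs,
    )
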