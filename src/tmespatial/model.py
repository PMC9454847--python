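"""Cohort-level model facade.

:class:`SpatialCohortModel` wraps the full analysis the way a statsmodels
model wraps a fit: construct it from a cell table (CSV, DataFrame, or
already-built cores), call :meth:`~SpatialCohortModel.fit`, and receive a
:class:`SpatialCohortResults` carrying per-core and per-patient spatial
summaries, the HIGH/LOW stratification, the comparison battery with BH
adjustment, and the HLA-DR correlations, with a ``summary()`` table.

Example
-------
>>> from tmespatial import SpatialCohortModel, synthetic
>>> patients, truth = synthetic.generate_cohort(synthetic.default_config(seed=1))
>>> cores = [c for p in patients for c in p.cores]
>>> res = SpatialCohortModel(cores).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import (
    CoreSample,
    PatientRecord,
    Stratum,
    build_patients,
    cores_from_frame,
    read_cell_table,
    stratify_cohort_by_mean,
)
from .phenotype import count_marker_conflicts
from .spatial import (
    DEFAULT_PAIRS,
    PairSpec,
    SpatialSummary,
    aggregate_patient,
    default_r_grid,
    pooled_patient_summary,
    summarize_core,
)
from .stats import (
    ComparisonResult,
    CorrelationResult,
    comparisons_frame,
    correlations_frame,
    run_comparison_battery,
)

logger = logging.getLogger(__name__)


class SpatialCohortModel:
    """Spatial tumor-microenvironment analysis of a multi-core TMA cohort.

    Parameters
    ----------
    cores
        The cohort's cores.  Phenotypes need not be assigned; ``fit``
        assigns them from the marker flags.
    config
        Pipeline constants; defaults mirror the analysis design (40 um
        engagement, 60 um G AUC, per-core averaging, alpha = 0.05).
    pairs
        The reference->target relationships to summarise; defaults to the
        full analysis panel.
    """

    def __init__(
        self,
        cores: list[CoreSample],
        config: RunConfig | None = None,
        pairs: tuple[PairSpec, ...] = DEFAULT_PAIRS,
    ) -> None:
        if not cores:
            raise ValueError("cohort has no cores")
        self.cores = cores
        self.config = config or RunConfig()
        self.pairs = pairs

    @classmethod
    def from_cell_table(
        cls, path: str | Path, config: RunConfig | None = None, **kwargs
    ) -> "SpatialCohortModel":
        return cls(read_cell_table(path), config=config, **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: RunConfig | None = None, **kwargs
    ) -> "SpatialCohortModel":
        return cls(cores_from_frame(df), config=config, **kwargs)

    def fit(self) -> "SpatialCohortResults":
        """Run phenotyping, spatial summaries, stratification and the battery."""
        cfg = self.config
        r_grid = default_r_grid(cfg.g_auc_radius, cfg.r_step)
        conflicts: dict[str, int] = {}
        core_summaries: list[SpatialSummary] = []
        for core in self.cores:
            core.assign_phenotypes()
            conflicts[core.core_id] = count_marker_conflicts(core.cells)
            core_summaries.append(
                summarize_core(
                    core,
                    pairs=self.pairs,
                    engagement_radius=cfg.engagement_radius,
                    r_grid=r_grid,
                    g_r_max=cfg.g_auc_radius,
                )
            )
        total_conflicts = sum(conflicts.values())
        if total_conflicts:
            logger.info("marker conflicts resolved by lineage precedence: %d",
                        total_conflicts)

        by_core = {s.unit_id: s for s in core_summaries}
        patients = build_patients(self.cores)
        for p in patients:
            if cfg.aggregation == "POOLED":
                p.summary = pooled_patient_summary(
                    p.cores, p.patient_id, pairs=self.pairs,
                    engagement_radius=cfg.engagement_radius,
                    r_grid=r_grid, g_r_max=cfg.g_auc_radius,
                )
            else:
                p.summary = aggregate_patient(
                    [by_core[c.core_id] for c in p.cores], p.patient_id
                )
        stratify_cohort_by_mean(patients)
        comparisons, correlations = run_comparison_battery(
            patients, families=cfg.bh_families, alpha_normality=cfg.alpha
        )
        threshold = float(np.mean([p.hladr_mean_pct for p in patients]))
        return SpatialCohortResults(
            model=self,
            patients=patients,
            core_summaries=core_summaries,
            comparisons=comparisons,
            correlations=correlations,
            hladr_threshold_pct=threshold,
            marker_conflicts=conflicts,
        )


@dataclass
class SpatialCohortResults:
    """Fitted cohort analysis: summaries, stratification, and test battery."""

    model: SpatialCohortModel
    patients: list[PatientRecord]
    core_summaries: list[SpatialSummary]
    comparisons: list[ComparisonResult]
    correlations: list[CorrelationResult]
    hladr_threshold_pct: float
    marker_conflicts: dict[str, int] = field(default_factory=dict)

    # -- frames -------------------------------------------------------------

    @property
    def n_high(self) -> int:
        return sum(p.stratum is Stratum.HIGH for p in self.patients)

    @property
    def n_low(self) -> int:
        return sum(p.stratum is Stratum.LOW for p in self.patients)

    def comparisons_frame(self) -> pd.DataFrame:
        return comparisons_frame(self.comparisons)

    def correlations_frame(self) -> pd.DataFrame:
        return correlations_frame(self.correlations)

    def summaries_frame(self, level: str = "PATIENT") -> pd.DataFrame:
        """Tidy long table of spatial summaries at CORE or PATIENT level."""
        rows = []
        if level == "CORE":
            items = self.core_summaries
        elif level == "PATIENT":
            items = [p.summary for p in self.patients]
        else:
            raise ValueError("level must be CORE or PATIENT")
        for s in items:
            for key, value in s.metrics.items():
                kind, _, pair = key.partition("|")
                ref = target = state = None
                if pair:
                    try:
                        spec = PairSpec.parse(pair)
                        ref, target = spec.ref, spec.target
                        state = spec.ref_state or spec.target_state
                    except ValueError:
                        ref = pair
                n_ref, n_target = s.pair_counts.get(pair, (None, None))
                rows.append({
                    "unit_id": s.unit_id,
                    "level": s.level,
                    "metric": key,
                    "ref": ref,
                    "target": target,
                    "state_filter": state,
                    "value": value,
                    "n_ref": n_ref,
                    "n_target": n_target,
                })
        return pd.DataFrame(rows)

    def patients_frame(self) -> pd.DataFrame:
        """One row per patient: stratum, HLA-DR, core/cell counts."""
        return pd.DataFrame({
            "patient_id": [p.patient_id for p in self.patients],
            "stratum": [p.stratum.value if p.stratum else None for p in self.patients],
            "hladr_mean_pct": [p.hladr_mean_pct for p in self.patients],
            "n_cores": [len(p.cores) for p in self.patients],
            "n_cells": [sum(c.n_cells for c in p.cores) for p in self.patients],
        })

    # -- presentation -------------------------------------------------------

    def summary(self, max_rows: int | None = None) -> str:
        """Human-readable results table, one panel per metric family."""
        lines: list[str] = []
        bar = "=" * 78
        lines.append(bar)
        lines.append("Spatial TME cohort analysis — HLA-DR stratification")
        lines.append(bar)
        n_cells = sum(c.n_cells for c in self.model.cores)
        lines.append(
            f"Patients: {len(self.patients)}  (HIGH {self.n_high} / LOW {self.n_low})"
            f"   Cores: {len(self.model.cores)}   Cells: {n_cells}"
        )
        lines.append(
            f"HLA-DR stratification threshold (cohort mean): "
            f"{self.hladr_threshold_pct:.2f}% positive surface area"
        )
        conflicts = sum(self.marker_conflicts.values())
        lines.append(f"Marker-lineage conflicts resolved: {conflicts}")
        cmp_df = self.comparisons_frame()
        for family, fam_df in cmp_df.groupby("family", sort=False):
            lines.append("-" * 78)
            lines.append(f"[{family}]  (group means; ANOVA/Wilcoxon; BH within panel)")
            view = fam_df[
                ["metric", "mean_high", "mean_low", "test", "statistic", "p_raw", "p_bh"]
            ].copy()
            if max_rows:
                view = view.head(max_rows)
            lines.append(
                view.to_string(
                    index=False,
                    float_format=lambda v: f"{v:.4g}",
                    na_rep="--",
                )
            )
        corr = self.correlations_frame()
        if len(corr):
            lines.append("-" * 78)
            lines.append("[correlations vs HLA-DR % surface area]  (Pearson)")
            lines.append(
                corr.to_string(
                    index=False, float_format=lambda v: f"{v:.4g}", na_rep="--"
                )
            )
        lines.append(bar)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SpatialCohortResults: {len(self.patients)} patients, "
            f"{len(self.comparisons)} comparisons>"
        )
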