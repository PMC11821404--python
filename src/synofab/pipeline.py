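"""High-level pipeline stages binding the modules into the three-tier analysis.

These functions are the programmatic equivalents of the CLI subcommands:
``run_fab_pipeline`` takes stacked component tables through filtering,
within-run merging, tolerance calibration, cross-sample clustering, standard
identification and quantification to repertoire statistics;
``run_proteome_pipeline`` takes an LFQ table through the detection filter,
imputation, the correlation filter, categorization and the paired
correlation analyses.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fab_core, fab_quant, proteome_compare, repertoire_stats
from .errors import CalibrationError
from .fab_core import ToleranceModel
from .fab_quant import Repertoire, StandardMab, StandardReport
from .proteome_compare import ProteinQuantTable

log = logging.getLogger("synofab")

__all__ = ["FabPipelineResult", "run_fab_pipeline", "run_proteome_pipeline"]


@dataclasses.dataclass
class FabPipelineResult:
    """Everything the Fab-profiling stage produces, by sub-stage."""

    tolerance: ToleranceModel
    clones: list[fab_core.FabClone]
    standard_report: StandardReport
    repertoires: dict[str, Repertoire]
    overlap: pd.DataFrame
    correlation: pd.DataFrame
    regressions: dict[str, repertoire_stats.RegressionResult]
    top_contributions: dict[str, pd.DataFrame]


def _standard_observations(
    components: pd.DataFrame, standards: Sequence[StandardMab], search_window: tuple[float, float]
) -> dict[str, list[tuple[float, float]]]:
    """Collect per-run (mass, rt) observations of each standard.

    Calibration precedes the tolerance model, so standards are located with a
    generous fixed search window (Da, min) around their expected positions,
    taking the most intense in-window component per run.
    """
    wm, wr = search_window
    obs: dict[str, list[tuple[float, float]]] = {s.name: [] for s in standards}
    for _sid, run in components.groupby("sample_id"):
        for std in standards:
            near = run[
                (run["mass_da"].sub(std.mass_da).abs() <= wm)
                & (run["rt_min"].sub(std.rt_min).abs() <= wr)
            ]
            if near.empty:
                continue
            top = near.loc[near["sum_intensity"].idxmax()]
            obs[std.name].append((float(top["mass_da"]), float(top["rt_min"])))
    return obs


def run_fab_pipeline(
    components: pd.DataFrame,
    sample_meta: pd.DataFrame,
    standards: Sequence[StandardMab],
    k: float = 3.0,
    floor_mass_da: float = 0.5,
    floor_rt_min: float = 0.05,
    standard_search_window: tuple[float, float] = (20.0, 1.0),
    impute_ug_ml: float = repertoire_stats.DEFAULT_IMPUTE_UG_ML,
    top_n: int = 10,
) -> FabPipelineResult:
    """Run the full Fab-profiling tier on stacked component tables.

    Stages: Fab filtering -> per-run duplicate merging -> tolerance
    calibration from the spiked standards -> greedy cross-sample clustering ->
    standard identification and removal -> spike-normalized quantification ->
    overlap / correlation / per-patient paired regression / top-N summaries.
    Samples missing a standard are flagged in the standard report and excluded
    from quantification; the run continues.
    """
    n_in = len(components)
    filtered = fab_core.filter_fab_components(components)
    log.info("fab filter: %d -> %d components", n_in, len(filtered))

    obs = _standard_observations(filtered, standards, standard_search_window)
    try:
        tol = fab_core.estimate_tolerances(
            obs, k=k, floor_mass_da=floor_mass_da, floor_rt_min=floor_rt_min
        )
    except CalibrationError:
        if len(filtered):
            raise
        tol = ToleranceModel(0.0, 0.0, k, floor_mass_da, floor_rt_min, 0, True)

    merged = (
        pd.concat(
            [fab_core.profile_sample(run, tol) for _s, run in filtered.groupby("sample_id")],
            ignore_index=True,
        )
        if len(filtered)
        else filtered
    )
    log.info("within-run merge: %d -> %d components", len(filtered), len(merged))

    clones = fab_core.cluster_clones(merged, tol)
    log.info("clustering: %d components -> %d clones", len(merged), len(clones))

    spike_ng_per_mab = float(np.mean([s.spike_ng for s in standards])) if standards else 0.0
    report, remaining = fab_quant.identify_standards(
        clones, standards, tol, list(sample_meta.index)
    )
    for sid, missing in report.invalid_samples.items():
        log.warning("sample %s missing standards %s; excluded from quantification", sid, missing)
    repertoires = fab_quant.quantify_repertoires(remaining, report, sample_meta, spike_ng_per_mab)

    reps = list(repertoires.values())
    overlap = repertoire_stats.overlap_matrix(reps, tol)
    correlation = repertoire_stats.repertoire_correlation_matrix(reps, impute_ug_ml)

    regressions: dict[str, repertoire_stats.RegressionResult] = {}
    by_patient: dict[str, dict[str, Repertoire]] = {}
    for rep in reps:
        by_patient.setdefault(rep.patient, {})[rep.fluid] = rep
    for patient, fluids in sorted(by_patient.items()):
        if "plasma" in fluids and "SF" in fluids:
            try:
                regressions[patient] = repertoire_stats.paired_fluid_regression(
                    fluids["plasma"], fluids["SF"], impute_ug_ml
                )
            except Exception as exc:  # degenerate pairs are reported, not fatal
                log.warning("paired regression failed for patient %s: %s", patient, exc)

    tops = {
        rep.sample_id: repertoire_stats.top_contributions(rep, top_n)
        for rep in reps
        if len(rep) > 0
    }
    return FabPipelineResult(tol, clones, report, repertoires, overlap, correlation, regressions, tops)


def run_proteome_pipeline(
    table: ProteinQuantTable,
    category_map: Mapping[str, str] | pd.Series | None = None,
    ig_variable_genes: Sequence[str] = (),
    min_samples: int = 6,
    group_size: int | None = 9,
    min_lfq: float = proteome_compare.DEFAULT_MIN_LFQ,
    mw_annotations: pd.DataFrame | None = None,
) -> dict:
    """Run the bulk-proteome tier: filters, imputation, categories, correlations."""
    n0 = len(table.lfq)
    table = proteome_compare.filter_by_detection(table, min_samples, group_size)
    log.info("detection filter: %d -> %d genes", n0, len(table.lfq))
    table = proteome_compare.impute_missing(table)
    n1 = len(table.lfq)
    table = proteome_compare.filter_for_correlation(table, min_lfq, ig_variable_genes)
    log.info("correlation filter: %d -> %d genes", n1, len(table.lfq))
    if category_map is not None:
        table = proteome_compare.categorize(table, category_map)

    result: dict = {
        "table": table,
        "averaged": proteome_compare.paired_abundance_correlation(table, "averaged"),
        "per_patient": proteome_compare.paired_abundance_correlation(table, "per_patient"),
    }
    if table.categories is not None:
        result["category_summary"] = proteome_compare.category_summary(table)
    if mw_annotations is not None:
        result["size_stratified"] = proteome_compare.size_stratified_correlation(
            table, mw_annotations
        )
    return result
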