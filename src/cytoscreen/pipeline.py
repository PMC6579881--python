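"""End-to-end orchestration of the screen analytics stages.

Chains the stages the platform runs per experiment: simulate (or
load) barcoded batches, arcsinh-transform, two-tier debarcode, label
cell subsets per sample unit with the hierarchy labeler, profile each
terminal subset (pooled across sample units, so profiling subsets are
comparable between donors and treatments), compute the AOF quality
matrix per batch, and summarize the screen (percent positive and
medians, fixation classes, differential markers).

Every stage is a plain function over in-memory objects; the CLI adds
file I/O around them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .debarcode import DEFAULT_MIN_SEPARATION, two_tier_debarcode
from .design import ExperimentManifest
from .ekbalam import UNASSIGNED, ClusterParams, GatingHierarchy, label_events
from .fcs import EventMatrix, arcsinh_transform
from .profiling import ProfilingParams, ProfilingResult, profile_subset
from .qc import AofReport, aof, split_modalities
from .screen import (
    FixationReport,
    ScreenSummary,
    differential_markers,
    fixation_classify,
    summarize_screen,
)
from .synthetic import SimulationConfig, simulate_batch

__all__ = ["PipelineOptions", "PipelineResult", "run_all", "label_batch", "aof_matrix"]


@dataclass
class PipelineOptions:
    min_separation: float = DEFAULT_MIN_SEPARATION
    debarcode_method: str = "topk"
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    profiling_params: ProfilingParams = field(default_factory=ProfilingParams)
    profiling_markers: list[str] | None = None  # default: hierarchy markers
    qc_markers: list[str] | None = None
    blank_antibody: str = "Blank"
    fresh_treatment: str = "fresh"
    fixed_treatment: str = "fixed"
    diff_target: str | None = None     # profiling subset compared...
    diff_reference: str | None = None  # ...against this one
    fold_threshold: float = 2.0
    expression_floor: float = 5.0
    residual_cutoff: float = 2.0
    seed: int = 0


@dataclass
class PipelineResult:
    events: pd.DataFrame                 # one row per assigned event
    marker_matrix: np.ndarray            # arcsinh markers aligned to `events`
    marker_names: list[str]
    assignments: dict[str, pd.DataFrame] # per batch, per-event debarcoding table
    profiling: ProfilingResult | None = None
    aof_report: AofReport | None = None
    screen_summary: ScreenSummary | None = None
    fixation: FixationReport | None = None
    diffexp: pd.DataFrame | None = None

    def labeled_event_matrix(self, mask=None) -> EventMatrix:
        values = self.marker_matrix if mask is None else self.marker_matrix[mask]
        return EventMatrix(values, self.marker_names, scale="arcsinh")


def label_batch(
    raw_events: EventMatrix,
    manifest: ExperimentManifest,
    batch_id: str,
    hierarchy: GatingHierarchy,
    opts: PipelineOptions,
) -> tuple[pd.DataFrame, pd.DataFrame, EventMatrix]:
    """Debarcode one batch and label each resolved sample unit.

    Returns (per-event debarcode table, per-event labeled frame for
    assigned events, the batch's arcsinh event matrix).
    """
    events = arcsinh_transform(raw_events) if raw_events.scale == "raw" else raw_events
    assign_df = two_tier_debarcode(
        events, manifest, batch_id,
        method=opts.debarcode_method, min_separation=opts.min_separation,
        seed=opts.seed,
    )
    antibody_of = {w.well_id: w.antibody for w in manifest.wells}
    rows = []
    labels = np.full(events.n_events, UNASSIGNED, dtype=object)
    assigned = assign_df["assigned"].to_numpy()
    units = assign_df.loc[assigned].groupby(["donor", "treatment", "well"], sort=True)
    for (donor, treatment, well), grp in units:
        idx = grp.index.to_numpy()
        unit_events = events.take(idx)
        labeling = label_events(
            unit_events, hierarchy, params=opts.cluster_params, seed=opts.seed
        )
        labels[idx] = labeling.labels
        for i, lab in zip(idx, labeling.labels):
            rows.append(
                {"batch": batch_id, "event_index": int(i), "donor": donor,
                 "treatment": treatment, "well": well,
                 "antibody": antibody_of.get(well, well), "subset": lab}
            )
    labeled = pd.DataFrame(rows)
    return assign_df, labeled, events


def aof_matrix(
    batches: dict[str, EventMatrix],
    markers: list[str],
) -> AofReport:
    """AOF per (marker, batch) with a two-means modality split."""
    data: dict[str, list[float]] = {}
    for batch_id, events in batches.items():
        col = []
        for marker in markers:
            try:
                neg, pos = split_modalities(events.column(marker), "two_means")
                col.append(aof(neg, pos))
            except ValueError:
                col.append(np.nan)
        data[batch_id] = col
    matrix = pd.DataFrame(data, index=markers)
    return AofReport.from_aof(matrix)


def run_all(
    sim_config: SimulationConfig,
    manifest: ExperimentManifest,
    hierarchy: GatingHierarchy,
    opts: PipelineOptions | None = None,
    sidecars: bool = False,
) -> PipelineResult:
    """Simulate every batch and run all analysis stages.

    With ``sidecars=True`` the per-event ground-truth frame of each
    batch is attached to the assignment tables (columns prefixed
    ``true_``) for scoring.
    """
    opts = opts or PipelineOptions()
    terminal = hierarchy.terminal_labels
    marker_names = sim_config.markers + [sim_config.readout_channel]

    assignments: dict[str, pd.DataFrame] = {}
    labeled_frames = []
    matrices = []
    batch_events: dict[str, EventMatrix] = {}
    for batch_id, _wells in manifest.batches:
        raw, sidecar = simulate_batch(sim_config, manifest, batch_id)
        assign_df, labeled, events = label_batch(raw, manifest, batch_id, hierarchy, opts)
        if sidecars:
            assign_df = assign_df.join(sidecar.add_prefix("true_"))
        assignments[batch_id] = assign_df
        batch_events[batch_id] = events
        if not labeled.empty:
            idx = labeled["event_index"].to_numpy()
            matrices.append(events.subset_channels(marker_names)[idx])
            labeled_frames.append(labeled)

    events_df = pd.concat(labeled_frames, ignore_index=True)
    marker_matrix = np.vstack(matrices)
    excluded = events_df["well"].isin(manifest.exclusions).to_numpy()
    keep = ~excluded
    events_df = events_df.loc[keep].reset_index(drop=True)
    marker_matrix = marker_matrix[keep]
    result = PipelineResult(
        events=events_df,
        marker_matrix=marker_matrix,
        marker_names=marker_names,
        assignments=assignments,
    )

    # --- profiling: each terminal subset pooled across sample units
    prof_markers = opts.profiling_markers or hierarchy.markers()
    prof_markers = [m for m in prof_markers if m in marker_names]
    profiling = ProfilingResult()
    events_df["profiling_subset"] = events_df["subset"].to_numpy(dtype=object)
    for subset in sorted(terminal):
        mask = (events_df["subset"] == subset).to_numpy()
        if not mask.any():
            continue
        subset_events = result.labeled_event_matrix(mask)
        prof = profile_subset(
            subset_events, subset, prof_markers,
            params=opts.profiling_params, seed=opts.seed,
        )
        profiling.profiles[subset] = prof
        events_df.loc[mask, "profiling_subset"] = prof.labels
    result.profiling = profiling

    # --- AOF QC per batch
    qc_markers = opts.qc_markers or [m for m in sim_config.markers]
    result.aof_report = aof_matrix(batch_events, qc_markers)

    # --- screen summary, fixation, differential markers
    readout_idx = marker_names.index(sim_config.readout_channel)
    screen_events = events_df.assign(value=marker_matrix[:, readout_idx])
    summary = summarize_screen(screen_events, blank_antibody=opts.blank_antibody)
    result.screen_summary = summary

    def condition(treatment: str) -> ScreenSummary:
        t = summary.table.loc[summary.table["treatment"] == treatment]
        thr = {k: v for k, v in summary.blank_thresholds.items() if k[1] == treatment}
        return ScreenSummary(table=t.reset_index(drop=True), blank_thresholds=thr)

    treatments = set(summary.table["treatment"])
    if {opts.fresh_treatment, opts.fixed_treatment} <= treatments:
        result.fixation = fixation_classify(
            condition(opts.fresh_treatment), condition(opts.fixed_treatment),
            fold_threshold=opts.fold_threshold,
            expression_floor=opts.expression_floor,
            cofactor=sim_config.cofactor,
        )

    if opts.diff_target and opts.diff_reference:
        fresh = summary.table.loc[
            (summary.table["treatment"] == opts.fresh_treatment)
            & (summary.table["antibody"] != opts.blank_antibody)
        ]
        pos = fresh.loc[fresh["subset"] == opts.diff_target]
        neg = fresh.loc[fresh["subset"] == opts.diff_reference]
        merged = pos.merge(
            neg, on=["donor", "antibody"], suffixes=("_pos", "_neg")
        )[["donor", "antibody", "pct_positive_pos", "pct_positive_neg"]]
        merged = merged.rename(
            columns={"pct_positive_pos": "pp_pos", "pct_positive_neg": "pp_neg"}
        ).dropna()
        try:
            result.diffexp = differential_markers(merged, residual_cutoff=opts.residual_cutoff)
        except ValueError as exc:
            warnings.warn(f"differential-marker test skipped: {exc}")
    return result
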