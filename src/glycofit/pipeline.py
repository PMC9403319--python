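"""Batch pipeline: GPR directory in → results spreadsheet + graphics out.

Stages: parse and validate the file set → aggregate replicates →
assemble the dose matrix → fit and classify every glycan → write the
results spreadsheet (CSV + XLSX) → render the requested graphics →
write a JSON run manifest listing every artifact, the class counts, the
echoed configuration and per-stage timings.

A ``_INCOMPLETE`` marker file exists in the output directory while a run
is in progress and on failure, so partial output is never mistaken for a
finished run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import read_catalog
from .config import RunConfig
from .dose import aggregate_replicates, aggregates_to_frame, build_dose_matrix
from .gpr import build_manifest
from .isotherm import (
    BindingStatus,
    analyze_matrix,
    results_frame,
    write_results,
)
from .reporting import (
    build_concentration_bars,
    build_dose_curve,
    build_heatmap,
    build_ka_vs_rfu,
    build_rank_table,
    render_bars,
    render_dose_curve,
    render_heatmap,
    render_rank_table,
    render_scatter,
    write_rank_table_csv,
)
from .ringchart import build_ring_models, render_ring

__all__ = ["RunSummary", "PipelineError", "run_pipeline"]

log = logging.getLogger("glycofit")

INCOMPLETE_MARKER = "_INCOMPLETE"


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""


@dataclass
class RunSummary:
    output_dir: Path
    n_glycans: int
    n_saturated: int
    n_unsaturated: int
    n_nonbinders: int
    artifacts: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)
    results_csv: Path | None = None
    truth_comparison: dict | None = None

    @property
    def counts(self) -> dict[str, int]:
        return {
            "glycans": self.n_glycans,
            "saturated": self.n_saturated,
            "unsaturated": self.n_unsaturated,
            "nonbinders": self.n_nonbinders,
        }


class _Stages:
    """Per-stage wall-clock bookkeeping with stage-labeled errors."""

    def __init__(self) -> None:
        self.timings: dict[str, float] = {}

    def run(self, name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as e:
            raise PipelineError(f"[{name}] {e}") from e
        dt = time.perf_counter() - t0
        self.timings[name] = round(dt, 4)
        log.info("stage %-12s %.3fs", name, dt)
        return result


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the full analysis described by ``config``.

    Returns the run summary; every produced file is listed in
    ``run_manifest.json`` inside the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / INCOMPLETE_MARKER
    marker.write_text("run in progress\n")
    stages = _Stages()
    artifacts: list[str] = []

    def emit(relpath: str) -> Path:
        artifacts.append(relpath)
        p = out / relpath
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    manifest = stages.run(
        "parse",
        build_manifest,
        [(p, c) for p, c in sorted(config.files.items(), key=lambda kv: kv[1])],
        protein_name=config.protein,
        channel=config.channel,
    )

    catalog = None
    if config.catalog is not None:
        catalog = stages.run("catalog", read_catalog, config.catalog)
        catalog = catalog.resolved()

    aggregates = stages.run(
        "aggregate",
        lambda: [
            aggregate_replicates(
                e.gpr,
                e.concentration,
                config.replicate_policy,
                exclude_flagged=config.exclude_flagged,
                clamp_negative=config.clamp_negative,
            )
            for e in manifest.entries
        ],
    )
    aggregates_to_frame(aggregates).to_csv(emit("aggregates.csv"), index=False)

    matrix = stages.run(
        "matrix",
        build_dose_matrix,
        manifest,
        aggregates,
        on_missing=config.on_missing,
    )

    fits = stages.run("fit", analyze_matrix, matrix, config.rules)

    df = results_frame(fits, matrix, catalog)
    stages.run(
        "results",
        write_results,
        df,
        emit("results.csv"),
        emit("results.xlsx"),
    )

    def _plots():
        if config.plots.curves:
            for gid, fit in fits.items():
                model = build_dose_curve(matrix.series[gid], fit)
                render_dose_curve(model, emit(f"curves/glycan_{gid}.png"))
        if config.plots.bars:
            for per_file in aggregates:
                model = build_concentration_bars(per_file)
                render_bars(model, emit(f"bars/conc_{model.concentration:g}uM.png"))
        if config.plots.heatmap and catalog is not None:
            render_heatmap(build_heatmap(matrix, catalog), emit("heatmap.png"))
        if config.plots.ka_vs_rfu:
            model = build_ka_vs_rfu(fits, matrix)
            if model.glycan_ids:
                render_scatter(model, emit("ka_vs_rfu.png"))
        if config.plots.rank_table:
            model = build_rank_table(fits, matrix, n=config.top_n, sort_by=config.sort_by)
            render_rank_table(model, emit("rank_table.png"))
            write_rank_table_csv(model, emit("rank_table.csv"))
        if config.plots.rings and catalog is not None:
            for group, model in build_ring_models(fits, catalog).items():
                render_ring(model, emit(f"rings/{group.value}.png"))

    stages.run("plots", _plots)

    truth_cmp = None
    if config.truth is not None:
        truth_cmp = stages.run("truth", _compare_truth, df, config.truth)
        pd.DataFrame([truth_cmp]).to_csv(emit("truth_comparison.csv"), index=False)

    n_sat = sum(1 for f in fits.values() if f.status is BindingStatus.SATURATED)
    n_unsat = sum(1 for f in fits.values() if f.status is BindingStatus.UNSATURATED)
    n_non = sum(1 for f in fits.values() if f.status is BindingStatus.NONBINDER)

    summary = RunSummary(
        output_dir=out,
        n_glycans=len(fits),
        n_saturated=n_sat,
        n_unsaturated=n_unsat,
        n_nonbinders=n_non,
        artifacts=artifacts,
        timings=stages.timings,
        results_csv=out / "results.csv",
        truth_comparison=truth_cmp,
    )

    artifacts.append("run_manifest.json")
    manifest_doc = {
        "version": __version__,
        "protein": config.protein,
        "counts": summary.counts,
        "artifacts": sorted(artifacts),
        "timings": stages.timings,
        "config": config.echo(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest_doc, indent=2) + "\n")
    marker.unlink()
    return summary


def _compare_truth(results: pd.DataFrame, truth_path: Path) -> dict:
    """Join fitted constants with a generator truth table.

    Reports the median and 90th-percentile relative Kd error over
    glycans with a finite true Kd and a converged fit.
    """
    truth = pd.read_csv(truth_path, dtype={"glycan_id": str})
    merged = results.astype({"glycan_id": str}).merge(truth, on="glycan_id")
    mask = (
        merged["true_kd"].notna()
        & merged["kd_uM"].notna()
        & merged["converged"].astype(bool)
    )
    sub = merged[mask]
    if len(sub) == 0:
        return {"n_compared": 0, "median_kd_rel_error": float("nan"),
                "p90_kd_rel_error": float("nan")}
    rel = np.abs(sub["kd_uM"] - sub["true_kd"]) / sub["true_kd"]
    return {
        "n_compared": int(len(sub)),
        "median_kd_rel_error": float(np.median(rel)),
        "p90_kd_rel_error": float(np.quantile(rel, 0.9)),
    }
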