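"""Graphics for the non-ring figures.

Every figure is built in two stages: a pure, inspectable *plot model*
(dataclass holding exactly the data to be drawn) and a matplotlib
renderer over it.  Tests assert on the models; rendering is only
smoke-tested, so no test ever parses pixels.

Figures covered: per-glycan fitted dose-response curves (green =
saturated, gray = unsaturated), per-concentration RFU bar charts, the
motif-grouped single-hue heatmap (darker = higher RFU), the Ka-vs-RFU
scatter for saturated binders, and the dual-gradient top-N rank table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib import colormaps

from .catalog import GROUP_ORDER, GlycanCatalog, StructureGroup
from .dose import AggregateSignal, DoseMatrix, DoseSeries
from .isotherm import BindingStatus, FitResult, one_site

__all__ = [
    "SATURATED_COLOR",
    "UNSATURATED_COLOR",
    "DoseCurvePlot",
    "BarChartModel",
    "HeatmapModel",
    "ScatterModel",
    "RankTableModel",
    "build_dose_curve",
    "build_concentration_bars",
    "build_heatmap",
    "build_ka_vs_rfu",
    "build_rank_table",
    "render_dose_curve",
    "render_bars",
    "render_heatmap",
    "render_scatter",
    "render_rank_table",
    "ReportingError",
]


class ReportingError(ValueError):
    pass


SATURATED_COLOR = "#2e8b57"  # green fitted line
UNSATURATED_COLOR = "#808080"  # gray fitted line


def _gid_key(gid: str):
    try:
        return (0, int(gid), "")
    except ValueError:
        return (1, 0, gid)


# ---------------------------------------------------------------------------
# dose-response curves

@dataclass
class DoseCurvePlot:
    glycan_id: str
    concentrations: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    curve_conc: np.ndarray | None
    curve_rfu: np.ndarray | None
    line_color: str | None
    annotation: str | None
    log_x: bool = True


def build_dose_curve(series: DoseSeries, fit: FitResult) -> DoseCurvePlot:
    """Plot model for one glycan: mean ± SD points plus the fitted curve.

    Nonbinders get a points-only model (no curve, no annotation); binders
    carry the fitted line colored by saturation status and an annotation
    with the calculated Ka and the top-concentration RFU.
    """
    if fit.status is BindingStatus.NONBINDER or fit.kd is None:
        curve_c = curve_y = None
        color = annotation = None
    else:
        conc = series.concentrations
        curve_c = np.geomspace(conc[0] / 2.0, conc[-1] * 2.0, 200)
        curve_y = one_site(curve_c, fit.bmax, fit.kd, fit.hill)
        color = (
            SATURATED_COLOR
            if fit.status is BindingStatus.SATURATED
            else UNSATURATED_COLOR
        )
        annotation = f"KA = {fit.ka:.3g} /µM\nRFU = {series.top_rfu:.0f}"
    return DoseCurvePlot(
        glycan_id=series.glycan_id,
        concentrations=series.concentrations,
        means=series.means,
        sds=series.sds,
        curve_conc=curve_c,
        curve_rfu=curve_y,
        line_color=color,
        annotation=annotation,
    )


def render_dose_curve(model: DoseCurvePlot, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(
        model.concentrations, model.means, yerr=model.sds,
        fmt="o", ms=4, color="k", ecolor="0.6", capsize=2,
    )
    if model.curve_conc is not None:
        ax.plot(model.curve_conc, model.curve_rfu, color=model.line_color, lw=1.5)
    if model.annotation:
        ax.text(
            0.98, 0.98, model.annotation, transform=ax.transAxes,
            ha="right", va="top", fontsize=8,
            bbox=dict(boxstyle="round", fc="white", ec="0.7"),
        )
    if model.log_x:
        ax.set_xscale("log")
    ax.set_xlabel("concentration (µM)")
    ax.set_ylabel("RFU")
    ax.set_title(f"glycan {model.glycan_id}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# per-concentration bar charts

@dataclass
class BarChartModel:
    concentration: float
    glycan_ids: list[str]
    heights: np.ndarray
    errors: np.ndarray


def build_concentration_bars(aggregates: list[AggregateSignal]) -> BarChartModel:
    """One bar per glycan at a single concentration, ordered by chart number."""
    if not aggregates:
        raise ReportingError("no aggregates to plot")
    aggs = sorted(aggregates, key=lambda a: _gid_key(a.glycan_id))
    conc = aggs[0].concentration
    return BarChartModel(
        concentration=conc,
        glycan_ids=[a.glycan_id for a in aggs],
        heights=np.array([a.mean_rfu for a in aggs]),
        errors=np.array([a.sd_rfu for a in aggs]),
    )


def render_bars(model: BarChartModel, path: str | Path) -> None:
    n = len(model.glycan_ids)
    fig, ax = plt.subplots(figsize=(max(4.0, min(16.0, n * 0.03 + 2)), 3))
    x = np.arange(n)
    ax.bar(x, model.heights, yerr=model.errors, width=1.0, color="#4878a8",
           error_kw=dict(lw=0.5))
    ax.set_xlim(-0.5, n - 0.5)
    if n <= 30:
        ax.set_xticks(x)
        ax.set_xticklabels(model.glycan_ids, rotation=90, fontsize=6)
    ax.set_ylabel("mean RFU")
    ax.set_title(f"{model.concentration:g} µM", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# motif-grouped heatmap

@dataclass
class HeatmapModel:
    row_ids: list[str]
    row_groups: list[StructureGroup]
    group_blocks: list[tuple[StructureGroup, int, int]]  # (group, start, stop)
    concentrations: tuple[float, ...]
    values: np.ndarray  # rows × concentrations, mean RFU
    vmax: float

    def normalized(self) -> np.ndarray:
        """Min–max normalised cell values on [0, 1]; the color map is a
        monotone single-hue function of these."""
        return self.values / self.vmax


def build_heatmap(matrix: DoseMatrix, catalog: GlycanCatalog) -> HeatmapModel:
    """Heatmap model with rows blocked by structure group.

    Row order: fixed group order (N-glycan, blood-group antigen, sialic
    acid, other), then terminal motif lexicographically, then chart
    number.  The color scale spans [0, global max RFU]; darker = higher.
    """
    cat = catalog.resolved()
    keyed = []
    for gid in matrix.glycan_ids():
        if gid not in cat:
            raise ReportingError(f"glycan {gid} is not annotated in the catalog")
        ann = cat.get(gid)
        keyed.append((GROUP_ORDER.index(ann.structure_group), ann.terminal_motif,
                      _gid_key(gid), gid, ann.structure_group))
    keyed.sort(key=lambda t: t[:3])

    row_ids = [t[3] for t in keyed]
    row_groups = [t[4] for t in keyed]
    values = np.array([matrix.series[g].means for g in row_ids])
    vmax = float(values.max()) if values.size and values.max() > 0 else 1.0

    blocks: list[tuple[StructureGroup, int, int]] = []
    start = 0
    for i in range(1, len(row_groups) + 1):
        if i == len(row_groups) or row_groups[i] is not row_groups[start]:
            blocks.append((row_groups[start], start, i))
            start = i
    return HeatmapModel(
        row_ids=row_ids,
        row_groups=row_groups,
        group_blocks=blocks,
        concentrations=matrix.concentrations,
        values=values,
        vmax=vmax,
    )


def render_heatmap(model: HeatmapModel, path: str | Path) -> None:
    n = len(model.row_ids)
    fig, ax = plt.subplots(figsize=(4, max(3.0, min(14.0, n * 0.02 + 2))))
    ax.imshow(
        model.normalized(), aspect="auto", cmap="Blues", vmin=0.0, vmax=1.0,
        interpolation="nearest",
    )
    for _, _, stop in model.group_blocks[:-1]:
        ax.axhline(stop - 0.5, color="k", lw=0.8)
    ax.set_xticks(range(len(model.concentrations)))
    ax.set_xticklabels([f"{c:g}" for c in model.concentrations], fontsize=7)
    ax.set_xlabel("concentration (µM)")
    if n <= 60:
        ax.set_yticks(range(n))
        ax.set_yticklabels(model.row_ids, fontsize=5)
    else:
        ax.set_yticks([])
    labels = " | ".join(
        f"{g.value}: {stop - start}" for g, start, stop in model.group_blocks
    )
    ax.set_title(labels, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Ka vs RFU scatter

@dataclass
class ScatterModel:
    glycan_ids: list[str]
    ka: np.ndarray  # µM⁻¹
    rfu: np.ndarray  # top-concentration mean RFU
    log_x: bool


def build_ka_vs_rfu(
    fits: dict[str, FitResult],
    matrix: DoseMatrix,
    log_x: str | bool = "auto",
) -> ScatterModel:
    """Top-concentration RFU vs Ka for every saturated glycan.

    With ``log_x="auto"`` the Ka axis switches to logarithmic when the
    plotted values span three or more decades.
    """
    sat = [
        f for f in fits.values()
        if f.status is BindingStatus.SATURATED and f.ka is not None
    ]
    sat.sort(key=lambda f: _gid_key(f.glycan_id))
    if not sat:
        warnings.warn("no saturated fits: Ka-vs-RFU scatter will be empty")
    ka = np.array([f.ka for f in sat])
    rfu = np.array([matrix.series[f.glycan_id].top_rfu for f in sat])
    if log_x == "auto":
        use_log = bool(ka.size) and float(ka.max()) / float(ka.min()) >= 1e3
    else:
        use_log = bool(log_x)
    return ScatterModel(
        glycan_ids=[f.glycan_id for f in sat], ka=ka, rfu=rfu, log_x=use_log
    )


def render_scatter(model: ScatterModel, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.scatter(model.ka, model.rfu, s=14, color="#2e8b57", alpha=0.75)
    if model.log_x:
        ax.set_xscale("log")
    ax.set_xlabel("KA (µM$^{-1}$)")
    ax.set_ylabel("RFU at top concentration")
    ax.set_title(f"saturated glycans (n={len(model.glycan_ids)})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# dual-gradient rank table

@dataclass
class RankTableModel:
    """Top-N glycans with paired Ka/RFU columns, each min–max normalised
    to its own white→full-tint gradient (red for Ka, blue for RFU)."""

    frame: pd.DataFrame  # columns: glycan_id, ka_per_uM, top_rfu
    sort_by: str
    gradients: dict[str, np.ndarray] = field(default_factory=dict)


def _minmax(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    out = np.zeros_like(v)
    finite = np.isfinite(v)
    if finite.any():
        lo, hi = v[finite].min(), v[finite].max()
        out[finite] = 1.0 if hi <= lo else 0.0  # degenerate: full tint
        if hi > lo:
            out[finite] = (v[finite] - lo) / (hi - lo)
    return out


def build_rank_table(
    fits: dict[str, FitResult],
    matrix: DoseMatrix,
    n: int = 60,
    sort_by: str = "rfu",
) -> RankTableModel:
    """Top-N glycans sorted by top-concentration RFU (or by Ka) descending.

    Ties break toward the lower chart number.  When fewer than N glycans
    are available the table truncates with a warning.
    """
    if sort_by not in ("rfu", "ka"):
        raise ReportingError(f"sort_by must be 'rfu' or 'ka', got {sort_by!r}")
    rows = []
    for gid in matrix.glycan_ids():
        f = fits.get(gid)
        rows.append(
            {
                "glycan_id": gid,
                "ka_per_uM": f.ka if f is not None and f.ka is not None else np.nan,
                "top_rfu": matrix.series[gid].top_rfu,
            }
        )
    df = pd.DataFrame(rows, columns=["glycan_id", "ka_per_uM", "top_rfu"])
    key = "top_rfu" if sort_by == "rfu" else "ka_per_uM"
    df["_id"] = [_gid_key(g) for g in df["glycan_id"]]
    df = df.sort_values(
        [key, "_id"], ascending=[False, True], na_position="last", kind="mergesort"
    ).drop(columns="_id")
    if n > len(df):
        warnings.warn(f"requested top {n} but only {len(df)} glycans available")
        n = len(df)
    df = df.head(n).reset_index(drop=True)
    gradients = {
        "ka_per_uM": _minmax(df["ka_per_uM"].to_numpy()),
        "top_rfu": _minmax(df["top_rfu"].to_numpy()),
    }
    return RankTableModel(frame=df, sort_by=sort_by, gradients=gradients)


def render_rank_table(model: RankTableModel, path: str | Path) -> None:
    df = model.frame
    n = len(df)
    fig, ax = plt.subplots(figsize=(4, max(2.0, 0.18 * n + 1)))
    ax.axis("off")
    cell_text = [
        [g, "" if not np.isfinite(k) else f"{k:.3g}", f"{r:.0f}"]
        for g, k, r in df.itertuples(index=False)
    ]
    table = ax.table(
        cellText=cell_text,
        colLabels=["glycan", "KA (/µM)", "RFU"],
        loc="center",
        cellLoc="center",
    )
    table.auto_set_font_size(False)
    table.set_fontsize(6)
    reds, blues = colormaps["Reds"], colormaps["Blues"]
    for i in range(n):
        table[i + 1, 1].set_facecolor(reds(0.8 * model.gradients["ka_per_uM"][i]))
        table[i + 1, 2].set_facecolor(blues(0.8 * model.gradients["top_rfu"][i]))
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def write_rank_table_csv(model: RankTableModel, path: str | Path) -> None:
    model.frame.to_csv(path, index=False)
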