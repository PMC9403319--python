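"""Three-layer nested ring (pie) charts of per-glycan affinity.

One chart per structure family (N-glycans, blood-group antigens,
sialylated glycans).  Each glycan is a wedge of equal angular width; the
three concentric layers carry, from inner to outer:

1. affinity — a white→red gradient of Ka for saturated glycans, a
   white→blue gradient of %max for unsaturated ones, plain white for
   nonbinders;
2. linkage — a fixed discrete palette over the LacNAc linkage classes;
3. structure — the glycan's structure label.

The chart is built as a pure :class:`RingModel` first (wedge fractions,
values, kinds) and rendered separately, so the geometry and the color
semantics are testable without touching pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import matplotlib.pyplot as plt
from matplotlib.patches import Patch

from .catalog import GlycanCatalog, LinkageClass, StructureGroup
from .isotherm import BindingStatus, FitResult

__all__ = [
    "InnerKind",
    "RingWedge",
    "RingModel",
    "RING_GROUPS",
    "LINKAGE_PALETTE",
    "build_ring_models",
    "ring_models_from_table",
    "load_results_table",
    "affinity_color",
    "ka_scale",
    "render_ring",
    "RingChartError",
]


class RingChartError(ValueError):
    pass


class InnerKind(str, Enum):
    KA = "ka"
    PERCENT_MAX = "percent_max"
    NONE = "none"


#: The three structure families plotted as ring charts.
RING_GROUPS = (
    StructureGroup.N_GLYCAN,
    StructureGroup.BLOOD_GROUP_ANTIGEN,
    StructureGroup.SIALIC_ACID,
)

#: Fixed discrete palette for the middle (linkage) layer; stable across
#: figures so charts of different proteins are directly comparable.
LINKAGE_PALETTE: dict[LinkageClass, str] = {
    LinkageClass.TYPE1_LACNAC: "#1b9e77",
    LinkageClass.TYPE2_LACNAC: "#7570b3",
    LinkageClass.OTHER: "#d95f02",
    LinkageClass.UNKNOWN: "#bdbdbd",
}

_LINKAGE_ORDER = (
    LinkageClass.TYPE1_LACNAC,
    LinkageClass.TYPE2_LACNAC,
    LinkageClass.OTHER,
    LinkageClass.UNKNOWN,
)


@dataclass(frozen=True)
class RingWedge:
    glycan_id: str
    angular_fraction: float
    inner_value: float | None  # Ka (µM⁻¹) or %max, per inner_kind
    inner_kind: InnerKind
    linkage_class: LinkageClass
    structure_label: str


@dataclass
class RingModel:
    group: StructureGroup
    wedges: list[RingWedge]
    #: fixed layer order, innermost first
    layers: tuple[str, str, str] = ("affinity", "linkage", "structure")

    def __post_init__(self) -> None:
        if self.wedges:
            total = sum(w.angular_fraction for w in self.wedges)
            if abs(total - 1.0) > 1e-9:
                raise RingChartError(
                    f"{self.group.value}: wedge fractions sum to {total}, not 1"
                )


def _gid_key(gid: str):
    try:
        return (0, int(gid), "")
    except ValueError:
        return (1, 0, gid)


def _make_wedge(
    gid: str,
    status: BindingStatus | None,
    ka: float | None,
    pm: float | None,
    linkage: LinkageClass,
    structure: str,
    fraction: float,
) -> RingWedge:
    if status is BindingStatus.SATURATED and ka is not None:
        kind, value = InnerKind.KA, float(ka)
    elif status is BindingStatus.UNSATURATED and pm is not None:
        kind, value = InnerKind.PERCENT_MAX, float(pm)
    else:
        kind, value = InnerKind.NONE, None
    return RingWedge(
        glycan_id=gid,
        angular_fraction=fraction,
        inner_value=value,
        inner_kind=kind,
        linkage_class=linkage,
        structure_label=structure,
    )


def build_ring_models(
    fits: dict[str, FitResult], catalog: GlycanCatalog
) -> dict[StructureGroup, RingModel]:
    """One ring model per structure family.

    Every fitted glycan annotated with one of the three ring groups gets
    an equal-width wedge; wedges are ordered by linkage class then chart
    number, so same-linkage arcs are contiguous.  An empty group yields
    a zero-wedge model with a warning.
    """
    cat = catalog.resolved()
    members: dict[StructureGroup, list[str]] = {g: [] for g in RING_GROUPS}
    for gid in fits:
        ann = cat.get(gid)  # unannotated glycan -> CatalogError naming it
        if ann.structure_group in members:
            members[ann.structure_group].append(gid)

    models: dict[StructureGroup, RingModel] = {}
    for group, gids in members.items():
        gids.sort(
            key=lambda g: (
                _LINKAGE_ORDER.index(cat.get(g).linkage_class), _gid_key(g)
            )
        )
        if not gids:
            warnings.warn(f"ring group {group.value} has no glycans")
            models[group] = RingModel(group=group, wedges=[])
            continue
        frac = 1.0 / len(gids)
        wedges = [
            _make_wedge(
                g,
                fits[g].status,
                fits[g].ka,
                fits[g].percent_max,
                cat.get(g).linkage_class,
                cat.get(g).structure,
                frac,
            )
            for g in gids
        ]
        models[group] = RingModel(group=group, wedges=wedges)
    return models


# ---------------------------------------------------------------------------
# spreadsheet intake (the stand-alone ring-chart entry point)

#: Columns the results spreadsheet must provide for ring plotting.
REQUIRED_TABLE_COLUMNS = (
    "glycan_id",
    "linkage_class",
    "structure_group",
    "ka_per_uM",
    "percent_max",
    "status",
)


def load_results_table(path: str | Path) -> pd.DataFrame:
    """Read the per-glycan results spreadsheet (CSV or XLSX) and check
    that every column the ring charts need is present."""
    p = str(path)
    if p.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    for col in REQUIRED_TABLE_COLUMNS:
        if col not in df.columns:
            raise RingChartError(
                f"results table is missing required column {col!r}"
            )
    return df


def ring_models_from_table(df: pd.DataFrame) -> dict[StructureGroup, RingModel]:
    """Build the three ring models straight from a results spreadsheet."""
    for col in REQUIRED_TABLE_COLUMNS:
        if col not in df.columns:
            raise RingChartError(f"results table is missing required column {col!r}")
    members: dict[StructureGroup, list[dict]] = {g: [] for g in RING_GROUPS}
    for rec in df.to_dict("records"):
        try:
            group = StructureGroup(str(rec["structure_group"]))
        except ValueError:
            continue
        if group in members:
            members[group].append(rec)

    models: dict[StructureGroup, RingModel] = {}
    for group, recs in members.items():
        if not recs:
            warnings.warn(f"ring group {group.value} has no glycans")
            models[group] = RingModel(group=group, wedges=[])
            continue
        def link_of(r):
            try:
                return LinkageClass(str(r["linkage_class"]))
            except ValueError:
                return LinkageClass.UNKNOWN
        recs.sort(
            key=lambda r: (_LINKAGE_ORDER.index(link_of(r)), _gid_key(str(r["glycan_id"])))
        )
        frac = 1.0 / len(recs)
        wedges = []
        for r in recs:
            status = None
            try:
                status = BindingStatus(str(r["status"]))
            except ValueError:
                pass
            ka = r.get("ka_per_uM")
            pm = r.get("percent_max")
            wedges.append(
                _make_wedge(
                    str(r["glycan_id"]),
                    status,
                    None if pd.isna(ka) else float(ka),
                    None if pd.isna(pm) else float(pm),
                    link_of(r),
                    str(r.get("structure") or ""),
                    frac,
                )
            )
        models[group] = RingModel(group=group, wedges=wedges)
    return models


# ---------------------------------------------------------------------------
# colors

def ka_scale(model: RingModel) -> tuple[float, float]:
    """(min, max) Ka over the saturated wedges of one ring; (0, 0) when none."""
    kas = [w.inner_value for w in model.wedges if w.inner_kind is InnerKind.KA]
    if not kas:
        return (0.0, 0.0)
    return (min(kas), max(kas))


def affinity_color(
    wedge: RingWedge, ka_range: tuple[float, float]
) -> tuple[float, float, float]:
    """RGB color of a wedge's inner (affinity) layer.

    Ka maps onto a white→red gradient min–max normalised within the
    ring's saturated wedges (a degenerate all-equal scale paints full
    red); %max maps onto white→blue on the fixed [0, 100] scale; absent
    binding is white.
    """
    if wedge.inner_kind is InnerKind.NONE or wedge.inner_value is None:
        return (1.0, 1.0, 1.0)
    if wedge.inner_kind is InnerKind.KA:
        lo, hi = ka_range
        t = 1.0 if hi <= lo else (wedge.inner_value - lo) / (hi - lo)
        t = float(np.clip(t, 0.0, 1.0))
        return (1.0, 1.0 - t, 1.0 - t)
    t = float(np.clip(wedge.inner_value / 100.0, 0.0, 1.0))
    return (1.0 - t, 1.0 - t, 1.0)


# ---------------------------------------------------------------------------
# rendering

@dataclass
class RenderedRing:
    """Angular spans (fractions of the full circle) actually drawn, per layer."""

    spans: list[tuple[str, float]]  # (glycan_id, fraction)


def render_ring(
    model: RingModel,
    path: str | Path,
    *,
    ka_range: tuple[float, float] | None = None,
) -> RenderedRing:
    """Render a ring model to an image file.

    ``ka_range`` overrides the per-ring Ka normalisation — pass a shared
    range to compare several proteins on one color scale.  Returns the
    drawn angular spans for inspection.
    """
    fig, ax = plt.subplots(figsize=(6, 6.8))
    ax.set_aspect("equal")
    ax.axis("off")
    title = model.group.value.replace("_", " ")
    if not model.wedges:
        ax.text(0.5, 0.5, f"{title}\n(no glycans)", ha="center", va="center",
                transform=ax.transAxes)
        fig.savefig(path, dpi=110)
        plt.close(fig)
        return RenderedRing(spans=[])

    scale = ka_range if ka_range is not None else ka_scale(model)
    fracs = [w.angular_fraction for w in model.wedges]
    inner_colors = [affinity_color(w, scale) for w in model.wedges]
    middle_colors = [LINKAGE_PALETTE[w.linkage_class] for w in model.wedges]
    n = len(model.wedges)
    outer_cycle = plt.get_cmap("Pastel2").colors
    outer_colors = [outer_cycle[i % len(outer_cycle)] for i in range(n)]

    common = dict(startangle=90, counterclock=False)
    # layers from inner to outer: affinity, linkage, structure
    ax.pie(fracs, radius=0.5, colors=inner_colors,
           wedgeprops=dict(width=0.26, edgecolor="w", linewidth=0.3), **common)
    ax.pie(fracs, radius=0.76, colors=middle_colors,
           wedgeprops=dict(width=0.26, edgecolor="w", linewidth=0.3), **common)
    labels = (
        [w.structure_label[:28] for w in model.wedges] if n <= 36 else None
    )
    ax.pie(fracs, radius=1.02, colors=outer_colors, labels=labels,
           textprops=dict(fontsize=4),
           wedgeprops=dict(width=0.26, edgecolor="w", linewidth=0.3), **common)

    handles = [
        Patch(facecolor=LINKAGE_PALETTE[lc], label=lc.value.replace("_", " "))
        for lc in _LINKAGE_ORDER
    ]
    handles += [
        Patch(facecolor=(1, 0.3, 0.3), label="KA (saturated), white→red"),
        Patch(facecolor=(0.3, 0.3, 1), label="%max (unsaturated), white→blue"),
        Patch(facecolor="white", edgecolor="0.6", label="no significant binding"),
    ]
    ax.legend(handles=handles, loc="upper center", bbox_to_anchor=(0.5, -0.02),
              fontsize=6, ncol=2, frameon=False)
    ax.set_title(title, fontsize=11)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return RenderedRing(spans=[(w.glycan_id, w.angular_fraction) for w in model.wedges])
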