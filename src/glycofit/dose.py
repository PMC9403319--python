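"""Replicate-spot aggregation and dose-matrix assembly.

Each glycan is printed in replicate (6 spots on CFG arrays); per
concentration the replicates collapse to a mean RFU ± sample standard
deviation.  Stacking those aggregates across the concentration ladder
gives one :class:`DoseSeries` per glycan — the input of the isotherm
fit — and the full glycan × concentration :class:`DoseMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpr import ExperimentManifest, GprFile, spot_rfu

__all__ = [
    "AggregateSignal",
    "DoseSeries",
    "DoseMatrix",
    "DoseError",
    "aggregate_replicates",
    "build_dose_matrix",
    "aggregates_to_frame",
]


class DoseError(ValueError):
    pass


@dataclass(frozen=True)
class AggregateSignal:
    """Mean RFU ± SD of one glycan's replicate spots at one concentration."""

    glycan_id: str
    concentration: float  # µM
    mean_rfu: float
    sd_rfu: float
    n_spots: int


@dataclass
class DoseSeries:
    """One glycan's (concentration, mean RFU, SD) triples, ascending in dose."""

    glycan_id: str
    points: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        concs = [p[0] for p in self.points]
        if len(concs) < 2:
            raise DoseError(
                f"glycan {self.glycan_id}: a dose series needs >= 2 concentrations"
            )
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise DoseError(
                f"glycan {self.glycan_id}: concentrations must be strictly ascending"
            )

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def means(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def sds(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])

    @property
    def c_max(self) -> float:
        return self.points[-1][0]

    @property
    def top_rfu(self) -> float:
        return self.points[-1][1]

    @property
    def top_sd(self) -> float:
        return self.points[-1][2]


@dataclass
class DoseMatrix:
    """All dose series of one experiment over a shared concentration ladder."""

    series: dict[str, DoseSeries]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        for gid, s in self.series.items():
            if tuple(s.concentrations) != self.concentrations:
                raise DoseError(
                    f"glycan {gid}: series ladder {tuple(s.concentrations)} "
                    f"differs from the shared ladder {self.concentrations}"
                )

    def __len__(self) -> int:
        return len(self.series)

    def glycan_ids(self) -> list[str]:
        return sorted(self.series, key=_id_key)

    def to_frame(self) -> pd.DataFrame:
        """Mean-RFU table, glycans × concentrations."""
        data = {gid: self.series[gid].means for gid in self.glycan_ids()}
        return pd.DataFrame.from_dict(
            data, orient="index", columns=list(self.concentrations)
        ).rename_axis("glycan_id")


def _id_key(gid: str):
    try:
        return (0, int(gid), "")
    except ValueError:
        return (1, 0, gid)


def aggregate_replicates(
    gpr: GprFile,
    concentration: float,
    policy: str = "mean_all",
    *,
    exclude_flagged: bool = True,
    clamp_negative: bool = True,
) -> list[AggregateSignal]:
    """Collapse replicate spots to one mean ± SD per glycan.

    ``policy`` is ``"mean_all"`` (average every usable replicate) or
    ``"trimmed"`` (drop the single lowest and highest replicate first;
    needs >= 3 usable spots, otherwise all are kept).  SD is the sample
    standard deviation (n−1 denominator), 0 for a single spot.  Spots
    flagged bad by the scanner (flag < 0) are excluded by default; a
    glycan left with no usable spot is skipped with a warning rather
    than failing the run.
    """
    if policy not in ("mean_all", "trimmed"):
        raise DoseError(f"unknown replicate policy {policy!r}")

    groups: dict[str, list[float]] = {}
    for spot in gpr.spots:
        if exclude_flagged and spot.flag < 0:
            continue
        groups.setdefault(spot.glycan_id, []).append(
            spot_rfu(spot, clamp_negative=clamp_negative)
        )
    # keep glycans with only flagged spots visible as missing
    all_ids = {s.glycan_id for s in gpr.spots}

    out: list[AggregateSignal] = []
    for gid in sorted(all_ids, key=_id_key):
        values = groups.get(gid, [])
        if not values:
            warnings.warn(
                f"glycan {gid}: no usable spots at {concentration} µM "
                "(all flagged); recorded as missing"
            )
            continue
        v = np.asarray(values, dtype=float)
        if policy == "trimmed" and v.size >= 3:
            v = np.delete(v, [int(np.argmin(v)), int(np.argmax(v))])
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        out.append(
            AggregateSignal(
                glycan_id=gid,
                concentration=concentration,
                mean_rfu=mean,
                sd_rfu=sd,
                n_spots=int(v.size),
            )
        )
    return out


def build_dose_matrix(
    manifest: ExperimentManifest,
    aggregates: list[list[AggregateSignal]] | None = None,
    *,
    on_missing: str = "error",
    policy: str = "mean_all",
    exclude_flagged: bool = True,
    clamp_negative: bool = True,
) -> DoseMatrix:
    """Assemble the glycan × concentration matrix from a manifest.

    ``aggregates``, when given, must align with ``manifest.entries``;
    otherwise they are computed here.  A glycan missing at some
    concentration is an error naming the glycan and dose
    (``on_missing="error"``) or drops the glycan with a warning
    (``on_missing="drop"``).
    """
    if on_missing not in ("error", "drop"):
        raise DoseError(f"on_missing must be 'error' or 'drop', got {on_missing!r}")
    if aggregates is None:
        aggregates = [
            aggregate_replicates(
                e.gpr,
                e.concentration,
                policy,
                exclude_flagged=exclude_flagged,
                clamp_negative=clamp_negative,
            )
            for e in manifest.entries
        ]
    if len(aggregates) != len(manifest.entries):
        raise DoseError(
            f"{len(aggregates)} aggregate lists for {len(manifest.entries)} files"
        )

    ladder = tuple(e.concentration for e in manifest.entries)
    cells: dict[str, dict[float, tuple[float, float]]] = {}
    for entry, aggs in zip(manifest.entries, aggregates):
        for a in aggs:
            cells.setdefault(a.glycan_id, {})[entry.concentration] = (
                a.mean_rfu,
                a.sd_rfu,
            )

    series: dict[str, DoseSeries] = {}
    for gid in sorted(cells, key=_id_key):
        row = cells[gid]
        missing = [c for c in ladder if c not in row]
        if missing:
            if on_missing == "error":
                raise DoseError(
                    f"glycan {gid} has no aggregate at concentration(s) "
                    f"{missing} µM"
                )
            warnings.warn(f"dropping glycan {gid}: missing at {missing} µM")
            continue
        series[gid] = DoseSeries(
            glycan_id=gid,
            points=[(c, row[c][0], row[c][1]) for c in ladder],
        )
    return DoseMatrix(series=series, concentrations=ladder)


def aggregates_to_frame(aggregates: list[list[AggregateSignal]]) -> pd.DataFrame:
    """Flat table of every aggregate, for CSV export."""
    rows = [
        {
            "glycan_id": a.glycan_id,
            "concentration": a.concentration,
            "mean_rfu": a.mean_rfu,
            "sd_rfu": a.sd_rfu,
            "n_spots": a.n_spots,
        }
        for per_file in aggregates
        for a in per_file
    ]
    return pd.DataFrame(
        rows, columns=["glycan_id", "concentration", "mean_rfu", "sd_rfu", "n_spots"]
    )
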