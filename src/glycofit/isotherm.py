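"""One-site saturation binding analysis per glycan.

The model is the Langmuir isotherm for specific binding,

    RFU(c) = Bmax * c / (Kd + c),

fit by nonlinear least squares to a glycan's mean RFU across the
concentration ladder.  Kd (µM) is the protein concentration at
half-maximal binding; Ka = 1/Kd (µM⁻¹) is the association constant
reported in the figures.  Because the array gives no absolute measure of
printed glycan density, both are *relative* constants — comparable
across glycans within one experiment, not thermodynamic affinities.

Each glycan is classified as

* ``saturated``   — the fit converged, the predicted fractional occupancy
  c_max/(Kd + c_max) at the top tested concentration reaches the
  threshold (default 0.8), and Kd is well determined (relative standard
  error ≤ 0.5 by default);
* ``unsaturated`` — detectable binding that does not plateau inside the
  ladder; reported via %max, the glycan's top-concentration RFU as a
  percentage of the experiment-wide maximum top-concentration RFU;
* ``nonbinder``   — top-concentration signal below the binding floor
  max(absolute floor, k·SD); no constants are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .catalog import GlycanCatalog
from .dose import DoseMatrix, DoseSeries

__all__ = [
    "BindingStatus",
    "ClassificationRules",
    "FitResult",
    "one_site",
    "fit_isotherm",
    "classify_saturation",
    "is_binder",
    "percent_max",
    "analyze_matrix",
    "results_frame",
    "write_results",
    "IsothermError",
]


class IsothermError(ValueError):
    pass


class BindingStatus(str, Enum):
    SATURATED = "saturated"
    UNSATURATED = "unsaturated"
    NONBINDER = "nonbinder"


def one_site(c, bmax: float, kd: float, hill: float = 1.0):
    """One-site specific binding isotherm; ``hill`` ≠ 1 gives the Hill variant.

    Satisfies one_site(0) = 0, one_site(kd) = bmax/2 (for hill=1) and
    one_site(c) → bmax as c → ∞.
    """
    c = np.asarray(c, dtype=float)
    if hill == 1.0:
        return bmax * c / (kd + c)
    ch = np.power(c, hill)
    return bmax * ch / (kd**hill + ch)


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds for saturation/binder classification.

    occupancy_threshold:
        Minimum predicted fractional occupancy at the top tested
        concentration for a fit to count as saturated (unitless, in
        (0, 1]).
    kd_rel_se_max:
        Maximum relative standard error of Kd for a saturated call.
    binder_floor_rfu:
        Absolute top-concentration RFU floor below which a glycan is a
        nonbinder.
    binder_floor_k_sd:
        The floor is max(binder_floor_rfu, binder_floor_k_sd · SD at the
        top concentration).
    """

    occupancy_threshold: float = 0.8
    kd_rel_se_max: float = 0.5
    binder_floor_rfu: float = 100.0
    binder_floor_k_sd: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.occupancy_threshold <= 1):
            raise IsothermError("occupancy_threshold must be in (0, 1]")
        if self.kd_rel_se_max <= 0:
            raise IsothermError("kd_rel_se_max must be positive")
        if self.binder_floor_rfu < 0 or self.binder_floor_k_sd < 0:
            raise IsothermError("binder floors must be non-negative")


@dataclass
class FitResult:
    """Per-glycan fit outcome.

    ``bmax``/``kd`` are ``None`` for nonbinders; ``ka`` is derived as
    1/kd so the Ka·Kd = 1 identity holds exactly.  ``percent_max`` is
    present iff the status is unsaturated.
    """

    glycan_id: str
    bmax: float | None
    kd: float | None  # µM
    sse: float
    converged: bool
    kd_rel_se: float
    status: BindingStatus | None = None
    percent_max: float | None = None
    hill: float = 1.0

    @property
    def ka(self) -> float | None:
        """Association constant, µM⁻¹ — the exact inverse of Kd."""
        return None if self.kd is None else 1.0 / self.kd


_NONBINDER_TEMPLATE = dict(bmax=None, kd=None, sse=0.0, converged=False, kd_rel_se=0.0)


def fit_isotherm(series: DoseSeries, *, free_hill: bool = False) -> FitResult:
    """Fit the one-site isotherm to one dose series.

    All-zero series are routed to nonbinder without a fit.  Otherwise a
    bounded trust-region least-squares fit is run on the replicate means,
    unweighted, with a deterministic initialisation: bmax₀ = max mean
    RFU, kd₀ = the tested concentration whose RFU is nearest bmax₀/2.
    Bounds: bmax ∈ (0, 10·max RFU], kd ∈ (0, 10⁴·c_max].  Non-convergence
    and degenerate series (all RFU equal and positive) are retained with
    ``converged=False``; the Kd relative standard error comes from the
    asymptotic covariance of the fit.
    """
    conc = series.concentrations
    rfu = series.means
    top = float(rfu.max())
    if top <= 0:
        return FitResult(
            glycan_id=series.glycan_id, status=BindingStatus.NONBINDER,
            **_NONBINDER_TEMPLATE,
        )

    c_max = float(conc[-1])
    bmax0 = top
    kd0 = float(conc[int(np.argmin(np.abs(rfu - bmax0 / 2.0)))])
    lo = [1e-9, 1e-9]
    hi = [10.0 * top, 1e4 * c_max]
    x0 = [min(max(bmax0, lo[0]), hi[0]), min(max(kd0, lo[1]), hi[1])]
    if free_hill:
        lo.append(0.1)
        hi.append(10.0)
        x0.append(1.0)

    def resid(x):
        return one_site(conc, *x) - rfu if free_hill else one_site(conc, x[0], x[1]) - rfu

    res = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    bmax, kd = float(res.x[0]), float(res.x[1])
    hill = float(res.x[2]) if free_hill else 1.0
    sse = float(np.sum(res.fun**2))
    converged = bool(res.success)
    if np.ptp(rfu) == 0:  # flat positive series carries no dose information
        converged = False

    kd_rel_se = _kd_relative_se(res.jac, sse, len(conc), kd)
    return FitResult(
        glycan_id=series.glycan_id,
        bmax=bmax,
        kd=kd,
        sse=sse,
        converged=converged,
        kd_rel_se=kd_rel_se,
        hill=hill,
    )


def _kd_relative_se(jac: np.ndarray, sse: float, n: int, kd: float) -> float:
    p = jac.shape[1]
    dof = n - p
    if dof <= 0:
        return 0.0
    s2 = sse / dof
    jtj = jac.T @ jac
    try:
        cov = s2 * np.linalg.pinv(jtj)
        var_kd = float(cov[1, 1])
    except np.linalg.LinAlgError:
        return float("inf")
    if not np.isfinite(var_kd) or var_kd < 0:
        return float("inf")
    return float(np.sqrt(var_kd) / kd)


def is_binder(series: DoseSeries, rules: ClassificationRules = ClassificationRules()) -> bool:
    """Binding floor: top-concentration mean RFU ≥ max(A, k·SD at top)."""
    floor = max(rules.binder_floor_rfu, rules.binder_floor_k_sd * series.top_sd)
    return series.top_rfu >= floor


def classify_saturation(
    fit: FitResult,
    series: DoseSeries,
    rules: ClassificationRules = ClassificationRules(),
) -> BindingStatus:
    """Total classification of one fitted glycan.

    Saturated requires a converged fit whose predicted occupancy at the
    top tested concentration, c_max/(kd + c_max), reaches the threshold
    and whose Kd relative standard error is within bounds; any other
    binder is unsaturated; sub-floor signal is a nonbinder.
    """
    if not is_binder(series, rules):
        return BindingStatus.NONBINDER
    if fit.kd is None or not fit.converged:
        return BindingStatus.UNSATURATED
    occupancy = series.c_max / (fit.kd + series.c_max)
    if occupancy >= rules.occupancy_threshold and fit.kd_rel_se <= rules.kd_rel_se_max:
        return BindingStatus.SATURATED
    return BindingStatus.UNSATURATED


def percent_max(matrix: DoseMatrix, unsaturated_ids: list[str]) -> dict[str, float]:
    """%max for unsaturated binders.

    %max_i = 100 · RFU_i(c_max) / max_j RFU_j(c_max), the glycan's
    top-concentration signal relative to the strongest top-concentration
    signal over *all* glycans in the experiment.  Scale-invariant by
    construction.
    """
    tops = {gid: s.top_rfu for gid, s in matrix.series.items()}
    denom = max(tops.values(), default=0.0)
    if denom <= 0:
        raise IsothermError(
            "cannot compute %max: no glycan has positive RFU at the top concentration"
        )
    # ratio before scaling: t/denom <= 1 exactly, so values stay in [0, 100]
    return {gid: 100.0 * (tops[gid] / denom) for gid in unsaturated_ids}


def analyze_matrix(
    matrix: DoseMatrix,
    rules: ClassificationRules = ClassificationRules(),
    *,
    free_hill: bool = False,
) -> dict[str, FitResult]:
    """Fit, classify and annotate every glycan of a dose matrix."""
    fits: dict[str, FitResult] = {}
    for gid in matrix.glycan_ids():
        series = matrix.series[gid]
        if not is_binder(series, rules):
            fits[gid] = FitResult(
                glycan_id=gid, status=BindingStatus.NONBINDER, **_NONBINDER_TEMPLATE
            )
            continue
        fit = fit_isotherm(series, free_hill=free_hill)
        if fit.status is not BindingStatus.NONBINDER:
            fit.status = classify_saturation(fit, series, rules)
        fits[gid] = fit

    unsat = [g for g, f in fits.items() if f.status is BindingStatus.UNSATURATED]
    if unsat:
        for gid, pm in percent_max(matrix, unsat).items():
            fits[gid].percent_max = pm
    return fits


# ---------------------------------------------------------------------------
# results table

RESULTS_COLUMNS = [
    "glycan_id",
    "structure",
    "linkage_class",
    "structure_group",
    "bmax",
    "kd_uM",
    "ka_per_uM",
    "sse",
    "kd_rel_se",
    "converged",
    "status",
    "percent_max",
]


def results_frame(
    fits: dict[str, FitResult],
    matrix: DoseMatrix | None = None,
    catalog: GlycanCatalog | None = None,
) -> pd.DataFrame:
    """Flat per-glycan results table (the spreadsheet output).

    Adds the top-concentration RFU when a matrix is supplied and the
    structure/linkage/group annotations when a catalog is supplied.
    """
    cat = catalog.resolved() if catalog is not None else None
    rows = []
    for gid in sorted(fits, key=_gid_key):
        f = fits[gid]
        ann = cat.get(gid) if cat is not None and gid in cat else None
        rows.append(
            {
                "glycan_id": gid,
                "structure": ann.structure if ann else "",
                "linkage_class": ann.linkage_class.value if ann else "",
                "structure_group": (
                    ann.structure_group.value if ann and ann.structure_group else ""
                ),
                "bmax": f.bmax,
                "kd_uM": f.kd,
                "ka_per_uM": f.ka,
                "sse": f.sse,
                "kd_rel_se": f.kd_rel_se,
                "converged": f.converged,
                "status": f.status.value if f.status else "",
                "percent_max": f.percent_max,
                "top_rfu": (
                    matrix.series[gid].top_rfu
                    if matrix is not None and gid in matrix.series
                    else None
                ),
            }
        )
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS + ["top_rfu"])


def _gid_key(gid: str):
    try:
        return (0, int(gid), "")
    except ValueError:
        return (1, 0, gid)


def write_results(
    df: pd.DataFrame,
    csv_path: str | Path | None = None,
    xlsx_path: str | Path | None = None,
) -> None:
    """Write the results table as CSV and/or XLSX (Excel) files."""
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if xlsx_path is not None:
        df.to_excel(xlsx_path, index=False, sheet_name="results")
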