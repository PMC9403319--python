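"""Plot models for curves, bars, heatmap, scatter and rank table."""

import io

import numpy as np
import pytest
from scipy.stats import spearmanr

from glycofit.catalog import GlycanCatalog, StructureGroup
from glycofit.dose import AggregateSignal, DoseMatrix, DoseSeries
from glycofit.isotherm import BindingStatus, FitResult, analyze_matrix
from glycofit.reporting import (
    SATURATED_COLOR,
    UNSATURATED_COLOR,
    ReportingError,
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
)
from glycofit.simulate import make_catalog_fixture

from conftest import LADDER, model_series


def fit_of(gid, kd, status, pm=None):
    return FitResult(
        glycan_id=gid, bmax=1000.0, kd=kd, sse=0.0, converged=True,
        kd_rel_se=0.0, status=status, percent_max=pm,
    )


class TestDoseCurve:
    def test_saturated_curve_is_green_with_annotation(self):
        series = model_series("1", 30000.0, 0.2, LADDER)
        model = build_dose_curve(series, fit_of("1", 0.2, BindingStatus.SATURATED))
        assert model.line_color == SATURATED_COLOR
        assert "KA" in model.annotation and "RFU" in model.annotation
        assert model.curve_conc is not None and model.log_x

    def test_unsaturated_curve_is_gray(self):
        series = model_series("1", 30000.0, 100.0, LADDER)
        model = build_dose_curve(series, fit_of("1", 100.0, BindingStatus.UNSATURATED, pm=40.0))
        assert model.line_color == UNSATURATED_COLOR

    def test_nonbinder_has_points_only(self):
        series = DoseSeries("1", [(c, 0.0, 0.0) for c in LADDER])
        fit = FitResult("1", None, None, 0.0, False, 0.0, BindingStatus.NONBINDER)
        model = build_dose_curve(series, fit)
        assert model.curve_conc is None and model.line_color is None
        assert model.annotation is None

    def test_render_smoke(self, tmp_path):
        series = model_series("1", 30000.0, 0.2, LADDER)
        model = build_dose_curve(series, fit_of("1", 0.2, BindingStatus.SATURATED))
        render_dose_curve(model, tmp_path / "curve.png")
        assert (tmp_path / "curve.png").stat().st_size > 0


def aggs_at(conc, tops):
    return [
        AggregateSignal(gid, conc, top, top * 0.05, 6) for gid, top in tops.items()
    ]


class TestBars:
    def test_bars_ordered_by_chart_number(self):
        model = build_concentration_bars(aggs_at(1.0, {"10": 5.0, "2": 7.0, "1": 3.0}))
        assert model.glycan_ids == ["1", "2", "10"]
        assert list(model.heights) == [3.0, 7.0, 5.0]

    def test_zero_height_bar_retained(self):
        model = build_concentration_bars(aggs_at(1.0, {"1": 0.0, "2": 5.0}))
        assert model.glycan_ids == ["1", "2"]
        assert model.heights[0] == 0.0

    def test_many_bars_render(self, tmp_path):
        tops = {str(i): float(i % 100) for i in range(1, 556)}
        model = build_concentration_bars(aggs_at(10.0, tops))
        assert len(model.glycan_ids) == 555
        render_bars(model, tmp_path / "bars.png")
        assert (tmp_path / "bars.png").stat().st_size > 0

    def test_empty_rejected(self):
        with pytest.raises(ReportingError):
            build_concentration_bars([])


def matrix_of(series_list):
    ladder = tuple(series_list[0].concentrations)
    return DoseMatrix(series={s.glycan_id: s for s in series_list}, concentrations=ladder)


class TestHeatmap:
    def test_rows_grouped_contiguously(self):
        catalog = make_catalog_fixture(4, (0.5, 0.0, 0.5, 0.0))
        series = [model_series(str(i), 1000.0 * i, 0.5, LADDER) for i in range(1, 5)]
        model = build_heatmap(matrix_of(series), catalog)
        assert [g for g, _, _ in model.group_blocks] == [
            StructureGroup.N_GLYCAN, StructureGroup.SIALIC_ACID,
        ]
        assert model.row_ids == ["1", "2", "3", "4"]

    def test_uniform_matrix_has_degenerate_scale(self):
        catalog = make_catalog_fixture(2, (1.0, 0.0, 0.0, 0.0))
        series = [
            DoseSeries(str(i), [(c, 7.0, 0.0) for c in LADDER]) for i in (1, 2)
        ]
        model = build_heatmap(matrix_of(series), catalog)
        assert model.vmax == 7.0
        assert np.allclose(model.normalized(), 1.0)

    def test_color_rank_order_equals_value_rank_order(self):
        catalog = make_catalog_fixture(6)
        rng = np.random.default_rng(7)
        series = [
            model_series(str(i), float(rng.uniform(100, 50000)), 0.5, LADDER)
            for i in range(1, 7)
        ]
        model = build_heatmap(matrix_of(series), catalog)
        flat = model.values.ravel()
        norm = model.normalized().ravel()
        # the normalised map (what the single-hue palette is applied to)
        # is a strictly monotone function of the cell value
        order = np.argsort(flat)
        assert np.all(np.diff(norm[order]) >= 0)

    def test_unannotated_glycan_is_error(self):
        catalog = make_catalog_fixture(1)
        series = [model_series("9", 1000.0, 0.5, LADDER)]
        with pytest.raises(Exception, match="9"):
            build_heatmap(matrix_of(series), catalog)

    def test_render_smoke(self, tmp_path):
        catalog = make_catalog_fixture(4)
        series = [model_series(str(i), 1000.0 * i, 0.5, LADDER) for i in range(1, 5)]
        model = build_heatmap(matrix_of(series), catalog)
        render_heatmap(model, tmp_path / "hm.png")
        assert (tmp_path / "hm.png").stat().st_size > 0


class TestScatter:
    def _fits_and_matrix(self, kds):
        series, fits = [], {}
        for i, kd in enumerate(kds, start=1):
            gid = str(i)
            s = model_series(gid, 1000.0 * i, kd, LADDER)
            series.append(s)
            fits[gid] = fit_of(gid, kd, BindingStatus.SATURATED)
        return fits, matrix_of(series)

    def test_point_count_equals_saturated_count(self):
        fits, matrix = self._fits_and_matrix([0.1, 0.2, 0.3, 0.4, 0.5])
        fits["3"].status = BindingStatus.UNSATURATED
        model = build_ka_vs_rfu(fits, matrix)
        assert len(model.glycan_ids) == 4

    def test_log_axis_engages_over_three_decades(self):
        fits, matrix = self._fits_and_matrix([0.001, 0.01, 0.1, 1.0, 10.0])
        assert build_ka_vs_rfu(fits, matrix).log_x
        fits2, matrix2 = self._fits_and_matrix([0.1, 0.2, 0.5])
        assert not build_ka_vs_rfu(fits2, matrix2).log_x

    def test_zero_saturated_warns_not_fails(self):
        fits, matrix = self._fits_and_matrix([0.1])
        fits["1"].status = BindingStatus.UNSATURATED
        with pytest.warns(UserWarning, match="no saturated"):
            model = build_ka_vs_rfu(fits, matrix)
        assert model.glycan_ids == []

    def test_spearman_matches_direct_computation(self, tmp_path):
        rng = np.random.default_rng(42)
        kds = list(rng.uniform(0.05, 2.0, 20))
        fits, matrix = self._fits_and_matrix(kds)
        model = build_ka_vs_rfu(fits, matrix)
        rho_plot = spearmanr(model.ka, model.rfu).statistic
        ka_direct = [fits[g].ka for g in model.glycan_ids]
        rfu_direct = [matrix.series[g].top_rfu for g in model.glycan_ids]
        rho_direct = spearmanr(ka_direct, rfu_direct).statistic
        assert rho_plot == pytest.approx(rho_direct)
        render_scatter(model, tmp_path / "scatter.png")
        assert (tmp_path / "scatter.png").stat().st_size > 0


class TestRankTable:
    def _setup(self, tops, kas=None):
        series, fits = [], {}
        for i, top in enumerate(tops, start=1):
            gid = str(i)
            s = DoseSeries(gid, [(1.0, top / 2, 0.0), (10.0, top, 0.0)])
            series.append(s)
            ka = kas[i - 1] if kas else 1.0 / i
            fits[gid] = FitResult(gid, top, 1.0 / ka, 0.0, True, 0.0,
                                  BindingStatus.SATURATED)
        return fits, matrix_of(series)

    def test_top_n_by_rfu(self):
        fits, matrix = self._setup([10, 9, 8, 7, 6])
        model = build_rank_table(fits, matrix, n=3)
        assert list(model.frame["glycan_id"]) == ["1", "2", "3"]

    def test_tie_breaks_toward_lower_chart_number(self):
        fits, matrix = self._setup([5, 9, 9, 7])
        model = build_rank_table(fits, matrix, n=4)
        assert list(model.frame["glycan_id"]) == ["2", "3", "4", "1"]

    def test_sort_by_ka(self):
        fits, matrix = self._setup([10, 9, 8], kas=[0.1, 5.0, 1.0])
        model = build_rank_table(fits, matrix, n=3, sort_by="ka")
        assert list(model.frame["glycan_id"]) == ["2", "3", "1"]

    def test_truncates_with_warning(self):
        fits, matrix = self._setup([3, 2, 1])
        with pytest.warns(UserWarning, match="only 3"):
            model = build_rank_table(fits, matrix, n=60)
        assert len(model.frame) == 3

    def test_gradients_are_minmax_and_monotone(self, tmp_path):
        fits, matrix = self._setup([10, 20, 30, 40])
        model = build_rank_table(fits, matrix, n=4)
        g = model.gradients["top_rfu"]
        assert g.min() == 0.0 and g.max() == 1.0
        values = model.frame["top_rfu"].to_numpy()
        assert np.all(np.diff(g[np.argsort(values)]) >= 0)
        render_rank_table(model, tmp_path / "rank.png")
        assert (tmp_path / "rank.png").stat().st_size > 0
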