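"""Nested ring-chart models and affinity color semantics."""

import numpy as np
import pandas as pd
import pytest

from glycofit.catalog import CatalogError, LinkageClass, StructureGroup
from glycofit.isotherm import BindingStatus, FitResult
from glycofit.ringchart import (
    RING_GROUPS,
    InnerKind,
    RingChartError,
    RingModel,
    RingWedge,
    affinity_color,
    build_ring_models,
    ka_scale,
    load_results_table,
    render_ring,
    ring_models_from_table,
)
from glycofit.simulate import make_catalog_fixture


def fit_of(gid, status, ka=None, pm=None):
    kd = None if ka is None else 1.0 / ka
    return FitResult(gid, None if kd is None else 1000.0, kd, 0.0, kd is not None,
                     0.0, status, percent_max=pm)


def wedge_of(kind, value, gid="1"):
    return RingWedge(
        glycan_id=gid, angular_fraction=1.0, inner_value=value,
        inner_kind=kind, linkage_class=LinkageClass.OTHER, structure_label="s",
    )


class TestBuildModels:
    def test_equal_fractions(self):
        catalog = make_catalog_fixture(4, (1.0, 0.0, 0.0, 0.0))
        fits = {str(i): fit_of(str(i), BindingStatus.SATURATED, ka=1.0) for i in range(1, 5)}
        models = build_ring_models(fits, catalog)
        wedges = models[StructureGroup.N_GLYCAN].wedges
        assert len(wedges) == 4
        assert all(w.angular_fraction == pytest.approx(0.25) for w in wedges)

    def test_inner_kind_follows_status(self):
        catalog = make_catalog_fixture(4, (1.0, 0.0, 0.0, 0.0))
        fits = {
            "1": fit_of("1", BindingStatus.SATURATED, ka=2.0),
            "2": fit_of("2", BindingStatus.SATURATED, ka=1.0),
            "3": fit_of("3", BindingStatus.UNSATURATED, ka=0.01, pm=40.0),
            "4": fit_of("4", BindingStatus.NONBINDER),
        }
        models = build_ring_models(fits, catalog)
        kinds = {w.glycan_id: w.inner_kind for w in models[StructureGroup.N_GLYCAN].wedges}
        assert kinds == {
            "1": InnerKind.KA, "2": InnerKind.KA,
            "3": InnerKind.PERCENT_MAX, "4": InnerKind.NONE,
        }

    def test_three_models_partition_the_classified_glycans(self):
        catalog = make_catalog_fixture(30, (0.4, 0.3, 0.3, 0.0))
        fits = {str(i): fit_of(str(i), BindingStatus.SATURATED, ka=1.0 + i)
                for i in range(1, 31)}
        models = build_ring_models(fits, catalog)
        seen: list[str] = []
        for group in RING_GROUPS:
            ids = [w.glycan_id for w in models[group].wedges]
            expected = {
                str(n) for n, ann in catalog.annotations.items()
                if ann.structure_group is group
            }
            assert set(ids) == expected
            seen.extend(ids)
        assert len(seen) == len(set(seen)) == 30  # no glycan in two rings
        for group in RING_GROUPS:
            total = sum(w.angular_fraction for w in models[group].wedges)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_wedges_ordered_by_linkage_then_chart_number(self):
        catalog = make_catalog_fixture(6, (1.0, 0.0, 0.0, 0.0))
        fits = {str(i): fit_of(str(i), BindingStatus.SATURATED, ka=1.0)
                for i in range(1, 7)}
        model = build_ring_models(fits, catalog)[StructureGroup.N_GLYCAN]
        links = [w.linkage_class for w in model.wedges]
        assert links == sorted(
            links, key=[LinkageClass.TYPE1_LACNAC, LinkageClass.TYPE2_LACNAC,
                        LinkageClass.OTHER, LinkageClass.UNKNOWN].index
        )

    def test_empty_group_warns(self):
        catalog = make_catalog_fixture(2, (1.0, 0.0, 0.0, 0.0))
        fits = {"1": fit_of("1", BindingStatus.SATURATED, ka=1.0),
                "2": fit_of("2", BindingStatus.NONBINDER)}
        with pytest.warns(UserWarning, match="sialic_acid"):
            models = build_ring_models(fits, catalog)
        assert models[StructureGroup.SIALIC_ACID].wedges == []

    def test_unannotated_glycan_is_error(self):
        catalog = make_catalog_fixture(1)
        fits = {"99": fit_of("99", BindingStatus.SATURATED, ka=1.0)}
        with pytest.raises(CatalogError, match="99"):
            build_ring_models(fits, catalog)

    def test_fraction_sum_invariant_enforced(self):
        w = wedge_of(InnerKind.KA, 1.0)
        with pytest.raises(RingChartError, match="sum"):
            RingModel(group=StructureGroup.N_GLYCAN, wedges=[w, w])


class TestColors:
    def test_max_ka_is_pure_red(self):
        w = wedge_of(InnerKind.KA, 5.0)
        assert affinity_color(w, (0.5, 5.0)) == (1.0, 0.0, 0.0)

    def test_min_ka_is_white(self):
        w = wedge_of(InnerKind.KA, 0.5)
        assert affinity_color(w, (0.5, 5.0)) == (1.0, 1.0, 1.0)

    def test_percent_max_endpoints(self):
        assert affinity_color(wedge_of(InnerKind.PERCENT_MAX, 0.0), (0, 0)) == (1, 1, 1)
        assert affinity_color(wedge_of(InnerKind.PERCENT_MAX, 100.0), (0, 0)) == (0, 0, 1)

    def test_nonbinder_is_white(self):
        assert affinity_color(wedge_of(InnerKind.NONE, None), (0, 1)) == (1, 1, 1)

    def test_degenerate_scale_paints_full_red(self):
        w = wedge_of(InnerKind.KA, 2.0)
        assert affinity_color(w, (2.0, 2.0)) == (1.0, 0.0, 0.0)

    def test_color_monotone_in_ka(self):
        scale = (0.0, 10.0)
        reds = [
            1.0 - affinity_color(wedge_of(InnerKind.KA, v), scale)[1]
            for v in np.linspace(0, 10, 11)
        ]
        assert np.all(np.diff(reds) >= 0)

    def test_ka_scale_over_saturated_wedges_only(self):
        wedges = [
            RingWedge("1", 0.5, 2.0, InnerKind.KA, LinkageClass.OTHER, "a"),
            RingWedge("2", 0.5, 90.0, InnerKind.PERCENT_MAX, LinkageClass.OTHER, "b"),
        ]
        model = RingModel(group=StructureGroup.N_GLYCAN, wedges=wedges)
        assert ka_scale(model) == (2.0, 2.0)


class TestRender:
    def test_single_wedge_full_circle(self, tmp_path):
        catalog = make_catalog_fixture(1, (1.0, 0.0, 0.0, 0.0))
        fits = {"1": fit_of("1", BindingStatus.SATURATED, ka=1.0)}
        model = build_ring_models(fits, catalog)[StructureGroup.N_GLYCAN]
        rendered = render_ring(model, tmp_path / "ring.png")
        assert rendered.spans == [("1", 1.0)]
        assert (tmp_path / "ring.png").stat().st_size > 0

    def test_zero_wedge_placeholder(self, tmp_path):
        model = RingModel(group=StructureGroup.SIALIC_ACID, wedges=[])
        rendered = render_ring(model, tmp_path / "empty.png")
        assert rendered.spans == []
        assert (tmp_path / "empty.png").stat().st_size > 0

    def test_spans_match_fractions(self, tmp_path):
        catalog = make_catalog_fixture(5, (1.0, 0.0, 0.0, 0.0))
        fits = {str(i): fit_of(str(i), BindingStatus.SATURATED, ka=float(i))
                for i in range(1, 6)}
        model = build_ring_models(fits, catalog)[StructureGroup.N_GLYCAN]
        rendered = render_ring(model, tmp_path / "r.png")
        for _, frac in rendered.spans:
            assert frac == pytest.approx(0.2, abs=1e-6)


class TestTableIntake:
    def _frame(self):
        return pd.DataFrame(
            {
                "glycan_id": ["1", "2", "3"],
                "structure": ["a", "b", "c"],
                "linkage_class": ["Type1_LacNAc", "Type2_LacNAc", "other"],
                "structure_group": ["N_glycan", "N_glycan", "sialic_acid"],
                "ka_per_uM": [2.0, None, None],
                "percent_max": [None, 55.0, None],
                "status": ["saturated", "unsaturated", "nonbinder"],
            }
        )

    def test_models_from_spreadsheet(self, tmp_path):
        path = tmp_path / "results.csv"
        self._frame().to_csv(path, index=False)
        df = load_results_table(path)
        with pytest.warns(UserWarning):  # blood-group ring is empty
            models = ring_models_from_table(df)
        n_model = models[StructureGroup.N_GLYCAN]
        assert [w.inner_kind for w in n_model.wedges] == [
            InnerKind.KA, InnerKind.PERCENT_MAX,
        ]
        sa = models[StructureGroup.SIALIC_ACID].wedges
        assert sa[0].inner_kind is InnerKind.NONE

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        self._frame().drop(columns=["percent_max"]).to_csv(path, index=False)
        with pytest.raises(RingChartError, match="percent_max"):
            load_results_table(path)
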