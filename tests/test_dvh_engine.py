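"""DVH curves, exact DVH-point metrics, bands, and worst-case values."""

import numpy as np
import pytest

import imptrobust as ir
from imptrobust._errors import MetricParameterError, ValidationError
from imptrobust.dvh_engine import MetricSpec, parse_metric, summarize_metric_values

from conftest import make_random_scenario_set


def column_roi(doses, rx=100.0, role="oar", spacing=(2.5, 2.5, 2.5)):
    """An Nx1x1 grid/mask pair holding the given voxel doses."""
    values = np.asarray(doses, dtype=float).reshape(-1, 1, 1)
    grid = ir.DoseGrid(values, spacing)
    roi = ir.ROIMask(np.ones(values.shape, bool), "roi", role, rx=rx)
    return grid, roi


def vf_at(curve, dose):
    return float(np.interp(dose, curve.dose_edges, curve.volume_fraction))


class TestCurves:
    def test_uniform_roi_is_a_step_function(self):
        grid, roi = column_roi([60.0] * 8)
        c = ir.compute_dvh(grid, roi)
        assert vf_at(c, 0.0) == 100.0
        assert vf_at(c, 59.5) == 100.0
        assert c.volume_fraction[-1] == 0.0
        assert c.dose_edges[-1] > 60.0

    def test_two_voxel_half_volume(self):
        grid, roi = column_roi([50.0, 70.0])
        c = ir.compute_dvh(grid, roi)
        assert vf_at(c, 60.0) == pytest.approx(50.0)

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(2)
        grid, roi = column_roi(rng.uniform(0, 70, 200))
        c = ir.compute_dvh(grid, roi)
        assert np.all(np.diff(c.volume_fraction) <= 0)
        assert c.roi_volume_cc == pytest.approx(200 * grid.voxel_volume_cc)


class TestMetrics:
    def test_uniform_roi_metrics(self):
        grid, roi = column_roi([60.0] * 10, rx=60.0)
        assert ir.extract_metric((grid, roi), MetricSpec.d_percent(95)) == 60.0
        assert ir.extract_metric((grid, roi), MetricSpec.d_mean()) == 60.0
        assert ir.extract_metric((grid, roi), MetricSpec.v_percent_rx(90)) == 100.0

    def test_hundred_voxel_enumeration(self):
        """Doses 1..100 Gy: the k-th-largest rule gives D95 = 6 Gy (95 voxels
        receive >= 6), V65 = 36% (doses 65..100), V90 = 11%."""
        grid, roi = column_roi(np.arange(1.0, 101.0), rx=100.0)
        assert ir.extract_metric((grid, roi), MetricSpec.d_percent(95)) == 6.0
        assert ir.extract_metric((grid, roi), MetricSpec.v_percent_rx(65)) == 36.0
        assert ir.extract_metric((grid, roi), MetricSpec.v_percent_rx(90)) == 11.0
        assert ir.extract_metric((grid, roi), MetricSpec.d_mean()) == pytest.approx(50.5)

    def test_d001cc_smaller_than_voxel_takes_hottest(self):
        grid, roi = column_roi(np.arange(1.0, 11.0))  # voxel = 0.015625 cc
        assert ir.extract_metric((grid, roi), MetricSpec.d_cc(0.01)) == 10.0

    def test_dcc_beyond_roi_volume_rejected(self):
        grid, roi = column_roi([1.0, 2.0])
        with pytest.raises(MetricParameterError):
            ir.extract_metric((grid, roi), MetricSpec.d_cc(1.0))

    def test_curve_metric_consistent_with_exact_within_one_bin(self):
        rng = np.random.default_rng(3)
        grid, roi = column_roi(rng.uniform(0, 70, 500))
        bin_width = 0.05
        curve = ir.compute_dvh(grid, roi, bin_width)
        exact = ir.extract_metric((grid, roi), MetricSpec.d_percent(95))
        from_curve = ir.extract_metric(curve, MetricSpec.d_percent(95))
        assert abs(from_curve - exact) <= bin_width

    def test_dmean_from_histogram_within_half_bin(self):
        rng = np.random.default_rng(4)
        grid, roi = column_roi(rng.uniform(0, 70, 500))
        bin_width = 0.05
        curve = ir.compute_dvh(grid, roi, bin_width)
        assert abs(
            ir.extract_metric(curve, MetricSpec.d_mean())
            - float(grid.values.mean())
        ) <= bin_width / 2

    @pytest.mark.parametrize(
        "label,kind,param",
        [
            ("D95%", "D_percent_volume", 95.0),
            ("D0.01cc", "D_absolute_volume", 0.01),
            ("Dmean", "D_mean", None),
            ("V90%", "V_percent_rx", 90.0),
        ],
    )
    def test_parse_metric_labels(self, label, kind, param):
        spec = parse_metric(label)
        assert spec.kind == kind and spec.parameter == param
        assert spec.label == label


class TestBand:
    def test_degenerate_band_has_zero_width(self):
        g = ir.DoseGrid(np.full((4, 4, 4), 50.0), (2, 2, 2))
        sset = ir.assemble_scenario_set(g, [g] * 12, ir.build_scenario_table(5, 3.5))
        roi = ir.ROIMask(np.ones((4, 4, 4), bool), "r", "oar", rx=60.0)
        band = ir.compute_dvh_band(sset, roi)
        assert np.array_equal(band.upper, band.lower)
        assert band.band_area() == 0.0

    def test_all_curves_inside_envelope(self):
        sset = make_random_scenario_set(7)
        roi = ir.ROIMask(np.ones((8, 8, 8), bool), "r", "oar", rx=60.0)
        band = ir.compute_dvh_band(sset, roi)
        for c in band.curves:
            assert np.all(c.volume_fraction <= band.upper + 1e-12)
            assert np.all(c.volume_fraction >= band.lower - 1e-12)

    def test_ctv_band_narrower_than_abutting_oar_band(self, prostate_plan):
        ab = next(r for r in prostate_plan.oars if r.abutting)
        a = ir.compute_dvh_band(prostate_plan.scenario_set, prostate_plan.ctv.mask, 0.1)
        b = ir.compute_dvh_band(prostate_plan.scenario_set, ab.mask, 0.1)
        assert a.band_area() < b.band_area()


class TestBandSummary:
    def test_highest_constrictor_mean_dose_named_scenario(self):
        s = summarize_metric_values(
            {"nominal": 28.6, "U2": 31.1, "U4": 28.2}, "higher_is_worse"
        )
        assert s.band_worst == 31.1
        assert s.worst_scenario_id == "U2"
        assert s.bandwidth == pytest.approx(31.1 - 28.2)

    def test_highest_parotid_mean_dose_named_scenario(self):
        s = summarize_metric_values(
            {"nominal": 21.7, "U2": 18.8, "U4": 27.8}, "higher_is_worse"
        )
        assert s.band_worst == 27.8
        assert s.worst_scenario_id == "U4"

    def test_ties_resolve_to_lowest_scenario_index(self):
        s = summarize_metric_values(
            {"nominal": 30.0, "U1": 30.0, "U2": 29.0}, "higher_is_worse"
        )
        assert s.worst_scenario_id == "nominal"

    def test_degenerate_set_bandwidth_zero(self):
        g = ir.DoseGrid(np.full((3, 3, 3), 42.0), (2, 2, 2))
        sset = ir.assemble_scenario_set(g, [g] * 12, ir.build_scenario_table(5, 3.5))
        roi = ir.ROIMask(np.ones((3, 3, 3), bool), "r", "target", rx=42.0)
        s = ir.band_metric_summary(sset, roi, MetricSpec.d_percent(95))
        assert s.bandwidth == 0.0
        assert s.band_worst == s.nominal_value


class TestWorstCase:
    def test_degenerate_set_equals_nominal_metric(self):
        g = ir.DoseGrid(np.full((3, 3, 3), 42.0), (2, 2, 2))
        sset = ir.assemble_scenario_set(g, [g] * 12, ir.build_scenario_table(5, 3.5))
        roi = ir.ROIMask(np.ones((3, 3, 3), bool), "r", "target", rx=42.0)
        maps = ir.compute_maps(sset)
        assert ir.worstcase_metric(maps, roi, MetricSpec.d_percent(95)) == 42.0

    def test_voxelwise_worst_dominates_band_worst(self, hn_plan):
        maps = ir.compute_maps(hn_plan.scenario_set)
        d95 = MetricSpec.d_percent(95)
        s = ir.band_metric_summary(hn_plan.scenario_set, hn_plan.ctv.mask, d95)
        assert ir.worstcase_metric(maps, hn_plan.ctv.mask, d95) <= s.band_worst
        for roi in hn_plan.oars:
            for spec in roi.metrics:
                s = ir.band_metric_summary(hn_plan.scenario_set, roi.mask, spec)
                assert ir.worstcase_metric(maps, roi.mask, spec) >= s.band_worst

    def test_vw_min_dvh_below_every_scenario_dvh(self, prostate_plan):
        maps = ir.compute_maps(prostate_plan.scenario_set)
        roi = prostate_plan.ctv.mask
        band = ir.compute_dvh_band(prostate_plan.scenario_set, roi, 0.1)
        lo = maps.vw_min.values[roi.mask]
        hi = maps.vw_max.values[roi.mask]
        edges = band.dose_edges
        vf_lo = 100.0 * (lo[:, None] >= edges[None, :]).mean(axis=0)
        vf_hi = 100.0 * (hi[:, None] >= edges[None, :]).mean(axis=0)
        assert np.all(vf_lo <= band.lower + 1e-12)
        assert np.all(vf_hi >= band.upper - 1e-12)
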