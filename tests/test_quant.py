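import numpy as np
import pandas as pd
import pytest

from qamskit import io, quant
from qamskit.quant import ExtractionFactor, RcfTable


def make_calib(slopes, intercepts=None):
    intercepts = intercepts or {k: 0.0 for k in slopes}
    df = pd.DataFrame({
        "slope": pd.Series(slopes, dtype=float),
        "intercept": pd.Series(intercepts, dtype=float),
        "range_low": 0.01, "range_high": 100.0,
        "r_squared": 0.999, "lod": 0.001, "loq": 0.003,
    })
    return io.CalibrationTable(df)


class TestComputeRcf:
    @pytest.mark.parametrize("analyte,slope,expected", [
        ("p-hydroxybenzyl alcohol", 39300, 2.1090),
        ("parishin A", 11769, 0.6316),
    ])
    def test_published_slope_ratios(self, analyte, slope, expected):
        calib = make_calib({"gastrodin": 18634, analyte: slope})
        rcf = quant.compute_rcf(calib, "gastrodin")
        assert rcf.factors[analyte] == pytest.approx(expected, abs=5e-5)

    def test_marker_factor_is_exactly_one(self, calib):
        rcf = quant.compute_rcf(calib, "gastrodin")
        assert rcf.factors["gastrodin"] == 1.0

    def test_scale_invariance(self, calib):
        rcf = quant.compute_rcf(calib, "gastrodin")
        scaled = make_calib({k: 3.7 * calib.slope(k) for k in calib.analytes})
        rcf2 = quant.compute_rcf(scaled, "gastrodin")
        for k in rcf.factors:
            assert rcf2.factors[k] == pytest.approx(rcf.factors[k], rel=1e-12)

    def test_absent_marker_rejected(self, calib):
        with pytest.raises(ValueError, match="absent"):
            quant.compute_rcf(calib, "nonexistent")

    def test_rcf_table_invariants(self):
        with pytest.raises(ValueError):
            RcfTable("m", {"m": 1.0, "x": -2.0})
        with pytest.raises(ValueError):
            RcfTable("m", {"m": 0.9, "x": 2.0})


class TestQuantifyEsm:
    def test_forward_inverse_identity(self):
        calib = make_calib({"gastrodin": 18634}, {"gastrodin": -264.07})
        area = 18634 * 0.25 - 264.07
        peaks = io.PeakTable(pd.DataFrame({"gastrodin": [area]}, index=["A"]))
        table = quant.quantify_esm(peaks, calib)
        assert table.contents.loc["A", "gastrodin"] == pytest.approx(0.25)

    def test_reference_cell_hand_oracle(self, calib, peak_panel):
        table = quant.quantify_esm(peak_panel, calib)
        assert table.contents.loc["S1", "gastrodin"] == pytest.approx(
            (1797.1 + 264.07) / 18634, abs=1e-12)

    def test_area_below_intercept_clipped_and_flagged(self):
        calib = make_calib({"x": 100.0}, {"x": 50.0})
        peaks = io.PeakTable(pd.DataFrame({"x": [10.0]}, index=["A"]))
        table = quant.quantify_esm(peaks, calib)
        assert table.contents.loc["A", "x"] == 0.0
        assert table.flags[("A", "x")] == "below-zero"

    def test_missing_curve_rejected(self, peak_panel):
        calib = make_calib({"gastrodin": 18634})
        with pytest.raises(ValueError, match="no calibration curve"):
            quant.quantify_esm(peak_panel, calib)

    def test_missing_area_gives_missing_content(self):
        calib = make_calib({"x": 100.0})
        peaks = io.PeakTable(pd.DataFrame({"x": [np.nan]}, index=["A"]))
        table = quant.quantify_esm(peaks, calib)
        assert np.isnan(table.contents.loc["A", "x"])


class TestQuantifyQams:
    def test_minimal_hand_example(self):
        calib = make_calib({"m": 10.0, "x": 20.0})
        rcf = RcfTable("m", {"m": 1.0, "x": 2.0})
        peaks = io.PeakTable(pd.DataFrame({"m": [5.0], "x": [40.0]}, index=["A"]))
        table = quant.quantify_qams(peaks, rcf, calib)
        assert table.contents.loc["A", "x"] == pytest.approx(2.0)

    def test_reference_cell_hand_oracle(self, calib, peak_panel):
        rcf = quant.compute_rcf(calib, "gastrodin")
        table = quant.quantify_qams(peak_panel, rcf, calib)
        assert table.contents.loc["S1", "parishin A"] == pytest.approx(
            4340.3 / 11769, abs=1e-12)

    def test_gap_to_esm_is_exactly_the_intercept_term(self, calib, peak_panel):
        factor = ExtractionFactor(2.5)
        rcf = quant.compute_rcf(calib, "gastrodin")
        esm = quant.quantify_esm(peak_panel, calib, factor)
        qams = quant.quantify_qams(peak_panel, rcf, calib, factor)
        for k in peak_panel.analytes:
            if k == "gastrodin":
                continue
            gap = qams.contents[k] - esm.contents[k]
            expected = calib.intercept(k) / calib.slope(k) * factor.value
            np.testing.assert_allclose(gap, expected, rtol=1e-10)

    def test_linear_in_areas(self, calib, peak_panel):
        rcf = quant.compute_rcf(calib, "gastrodin")
        doubled = io.PeakTable(peak_panel.areas * 2, panel=peak_panel.panel)
        q1 = quant.quantify_qams(peak_panel, rcf, calib, marker_by_esm=False)
        q2 = quant.quantify_qams(doubled, rcf, calib, marker_by_esm=False)
        np.testing.assert_allclose(q2.contents, 2 * q1.contents)

    def test_zero_intercepts_make_methods_identical(self, peak_panel):
        calib = make_calib({k: 1000.0 + 100 * i
                            for i, k in enumerate(peak_panel.analytes)})
        rcf = quant.compute_rcf(calib, "gastrodin")
        esm = quant.quantify_esm(peak_panel, calib)
        qams = quant.quantify_qams(peak_panel, rcf, calib)
        np.testing.assert_allclose(esm.contents, qams.contents, rtol=1e-12)


class TestSummarizeContents:
    def test_reference_column_mean_and_row_totals(self, content_tables):
        esm, _ = content_tables
        summary = quant.summarize_contents(esm)
        assert round(summary.analyte_means["gastrodin"], 2) == 3.53
        assert round(summary.sample_totals["S1"], 2) == 27.68

    def test_single_sample_total_is_row_sum(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.5]}, index=["A"])
        summary = quant.summarize_contents(io.ContentTable(df, "ESM"))
        assert summary.sample_totals["A"] == pytest.approx(3.5)

    def test_qams_means_match_published_report(self, content_tables):
        # mean single-marker contents quoted in the study text, mg/g
        _, qams = content_tables
        summary = quant.summarize_contents(qams)
        assert summary.analyte_means["parishin A"] == pytest.approx(9.5303, abs=5e-3)
        assert summary.analyte_means["parishin E"] == pytest.approx(3.6511, abs=5e-3)


def test_extraction_factor_must_be_positive():
    with pytest.raises(ValueError):
        ExtractionFactor(0.0)
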