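import numpy as np
import pytest

from qamskit import fingerprint
from qamskit.io import Chromatogram


def gaussian_trace(t0=0.0, t1=20.0, dt=0.01, peaks=(), noise_sd=0.0, seed=0,
                   drift=None):
    t = np.arange(t0, t1 + dt / 2, dt)
    y = np.zeros_like(t)
    for h, rt, sigma in peaks:
        y += h * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
    if drift is not None:
        y += drift(t)
    if noise_sd:
        y += np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return Chromatogram(t, y, dt)


class TestEstimateNoise:
    def test_pure_gaussian_noise_recovered(self):
        chrom = gaussian_trace(t1=100.0, noise_sd=1.0, seed=1)
        est = fingerprint.estimate_noise(chrom, baseline_region=(0, 100))
        assert 0.95 <= est <= 1.05

    def test_constant_baseline_zero(self):
        chrom = gaussian_trace()
        assert fingerprint.estimate_noise(chrom, (0, 20)) == 0.0

    def test_linear_drift_detrended_away(self):
        chrom = gaussian_trace(drift=lambda t: 3.0 * t + 7.0)
        assert fingerprint.estimate_noise(chrom, (0, 20)) == pytest.approx(0, abs=1e-9)

    def test_short_region_rejected(self):
        chrom = gaussian_trace()
        with pytest.raises(ValueError, match="20 samples"):
            fingerprint.estimate_noise(chrom, (0, 0.1))


class TestDetectPeaks:
    def test_noiseless_gaussian_area_within_1_percent(self):
        h, sigma = 100.0, 0.05
        chrom = gaussian_trace(peaks=[(h, 10.0, sigma)], dt=0.005)
        peaks = fingerprint.detect_peaks(chrom)
        assert len(peaks) == 1
        analytic = h * sigma * np.sqrt(2 * np.pi)
        assert peaks[0].area == pytest.approx(analytic, rel=0.01)
        assert peaks[0].apex_time == pytest.approx(10.0, abs=0.005)

    def test_area_accurate_at_both_grid_resolutions(self):
        # the residual error is bound by tail truncation at the integration
        # bounds, not by the grid, so both resolutions sit under 1%
        h, sigma = 100.0, 0.05
        analytic = h * sigma * np.sqrt(2 * np.pi)
        for dt in (0.01, 0.002):
            chrom = gaussian_trace(peaks=[(h, 10.0, sigma)], dt=dt)
            (peak,) = fingerprint.detect_peaks(chrom)
            assert peak.area == pytest.approx(analytic, rel=0.01)

    def test_flat_trace_yields_nothing(self):
        assert fingerprint.detect_peaks(gaussian_trace()) == []

    def test_well_separated_pair_gives_two_peaks(self):
        # resolution Rs = 2*(rt2-rt1)/(w1+w2) with w = 4*sigma
        sigma = 0.1
        rt1, rt2 = 9.0, 9.0 + 1.6 * (4 * sigma)  # Rs = 1.6 > 1.5
        chrom = gaussian_trace(peaks=[(100, rt1, sigma), (80, rt2, sigma)])
        peaks = fingerprint.detect_peaks(chrom)
        assert len(peaks) == 2
        assert peaks[0].apex_time < peaks[1].apex_time


class TestBuildReference:
    def test_identical_inputs_pass_through(self):
        chrom = gaussian_trace(peaks=[(10, 5.0, 0.1)])
        ref = fingerprint.build_reference([chrom, chrom.copy(), chrom.copy()])
        np.testing.assert_array_equal(ref.intensities, chrom.intensities)

    def test_median_ignores_single_outlier(self):
        base = gaussian_trace(peaks=[(10, 5.0, 0.1)])
        outlier = Chromatogram(base.times, base.intensities + 500.0)
        ref = fingerprint.build_reference([base.copy() for _ in range(4)] + [outlier])
        np.testing.assert_array_equal(ref.intensities, base.intensities)

    def test_mean_is_pointwise_average(self):
        a = gaussian_trace(peaks=[(10, 5.0, 0.1)])
        b = Chromatogram(a.times, np.zeros_like(a.intensities))
        ref = fingerprint.build_reference([a, b], method="mean")
        np.testing.assert_allclose(ref.intensities, a.intensities / 2)

    def test_mismatched_grids_rejected(self):
        a = gaussian_trace(t1=20.0)
        b = gaussian_trace(t1=10.0)
        with pytest.raises(ValueError, match="common grid"):
            fingerprint.build_reference([a, b])


PANEL = [(120, 5.0, 0.1), (80, 8.0, 0.12), (150, 12.0, 0.1), (60, 15.0, 0.12)]


class TestAlignment:
    def test_self_alignment_is_identity(self):
        chrom = gaussian_trace(peaks=PANEL)
        aligned, amap = fingerprint.align_to_reference(chrom, chrom)
        assert amap.warning is None
        assert len(amap.anchors) == len(PANEL)
        np.testing.assert_allclose(aligned.intensities, chrom.intensities,
                                   atol=1e-9)

    def test_uniform_shift_corrected_within_one_sample(self):
        ref = gaussian_trace(peaks=PANEL)
        shifted = gaussian_trace(peaks=[(h, rt + 0.3, s) for h, rt, s in PANEL])
        aligned, amap = fingerprint.align_to_reference(shifted, ref)
        assert len(amap.anchors) == len(PANEL)
        apexes = [p.apex_time for p in fingerprint.detect_peaks(aligned)]
        for (_, rt, _), apex in zip(PANEL, sorted(apexes)):
            assert apex == pytest.approx(rt, abs=ref.sampling_interval + 1e-9)

    def test_shift_beyond_window_matches_nothing(self):
        ref = gaussian_trace(peaks=PANEL)
        shifted = gaussian_trace(peaks=[(h, rt + 0.8, s) for h, rt, s in PANEL])
        aligned, amap = fingerprint.align_to_reference(shifted, ref, window=0.5)
        assert amap.warning is not None
        assert amap.anchors == []
        np.testing.assert_array_equal(aligned.intensities, shifted.intensities)

    def test_warp_never_reorders_peaks(self):
        rng = np.random.default_rng(3)
        ref = gaussian_trace(peaks=PANEL)
        jittered = gaussian_trace(
            peaks=[(h, rt + rng.normal(0, 0.1), s) for h, rt, s in PANEL])
        aligned, _ = fingerprint.align_to_reference(jittered, ref)
        apexes = [p.apex_time for p in fingerprint.detect_peaks(aligned)]
        assert apexes == sorted(apexes)
        assert len(apexes) == len(PANEL)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        chrom = gaussian_trace(peaks=PANEL, noise_sd=0.5)
        assert fingerprint.similarity(chrom, chrom) == pytest.approx(1.0)

    def test_disjoint_peaks_cosine_orthogonal(self):
        a = gaussian_trace(peaks=[(100, 5.0, 0.05)])
        b = gaussian_trace(peaks=[(100, 15.0, 0.05)])
        assert fingerprint.similarity(a, b, metric="cosine") == \
            pytest.approx(0.0, abs=1e-6)

    def test_pearson_location_scale_invariant(self):
        a = gaussian_trace(peaks=PANEL, noise_sd=0.5, seed=5)
        b = gaussian_trace(peaks=PANEL, noise_sd=0.5, seed=6)
        r0 = fingerprint.similarity(a, b)
        rescaled = Chromatogram(a.times, 3.0 * a.intensities + 40.0)
        assert fingerprint.similarity(rescaled, b) == pytest.approx(r0, abs=1e-12)

    def test_cosine_scale_invariant_only(self):
        a = gaussian_trace(peaks=PANEL)
        b = gaussian_trace(peaks=PANEL[:2])
        c0 = fingerprint.similarity(a, b, metric="cosine")
        scaled = Chromatogram(a.times, 2.0 * a.intensities)
        assert fingerprint.similarity(scaled, b, metric="cosine") == \
            pytest.approx(c0, abs=1e-12)

    def test_constant_trace_flagged_nan(self):
        a = gaussian_trace(peaks=PANEL)
        flat = Chromatogram(a.times, np.ones_like(a.intensities))
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(fingerprint.similarity(a, flat))

    def test_symmetry(self):
        a = gaussian_trace(peaks=PANEL, noise_sd=0.5, seed=5)
        b = gaussian_trace(peaks=PANEL, noise_sd=0.5, seed=6)
        assert fingerprint.similarity(a, b) == pytest.approx(
            fingerprint.similarity(b, a), abs=1e-14)


class TestAssignPeaks:
    def test_nearest_within_window(self):
        chrom = gaussian_trace(peaks=PANEL)
        peaks = fingerprint.detect_peaks(chrom)
        assigned = fingerprint.assign_peaks_to_panel(
            peaks, {"a": 5.1, "b": 12.0, "c": 18.0}, window=0.5)
        assert assigned["a"].apex_time == pytest.approx(5.0, abs=0.01)
        assert assigned["b"].apex_time == pytest.approx(12.0, abs=0.01)
        assert assigned["c"] is None
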