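"""Envelope-normalized peak identification (smoothing, envelope, thresholds,
prominence)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import csfpulse.peakfind as pf
from csfpulse import (PeakFindParams, Spectrum, adjust_spectrum, baseline_stats,
                      detect_final_peaks, detect_primary_peaks, identify_peaks,
                      lower_envelope, make_frequency_grid, smooth_spectrum)


def spectrum_from_values(values, delta_f=0.01):
    values = np.asarray(values, dtype=float)
    n = 2 * (len(values) - 1)
    tr = 1.0 / (delta_f * n)
    grid = make_frequency_grid(n, tr)
    return Spectrum(grid=grid, magnitude=values, provenance="test", n_samples=n, tr=tr)


def sliding_polyfit(values, window, order):
    """Independent sliding local-least-squares smoother (scipy-free), with
    truncated-window polynomial fits at the edges (interp-mode behavior)."""
    n = len(values)
    half = window // 2
    out = np.empty(n)
    x = np.arange(n, dtype=float)
    for i in range(n):
        if i < half:
            sel = slice(0, window)
        elif i >= n - half:
            sel = slice(n - window, n)
        else:
            sel = slice(i - half, i + half + 1)
        coeffs = np.polyfit(x[sel], values[sel], order)
        out[i] = np.polyval(coeffs, x[i])
    return out


class TestSavitzkyGolay:
    def test_quadratic_reproduced_exactly(self):
        f = np.linspace(0, 3, 301)
        values = 2.0 + 0.5 * f - 0.1 * f ** 2
        spec = spectrum_from_values(values)
        np.testing.assert_allclose(smooth_spectrum(spec), values, atol=1e-9)

    def test_constant_unchanged(self):
        spec = spectrum_from_values(np.full(100, 3.3))
        np.testing.assert_allclose(smooth_spectrum(spec), 3.3, atol=1e-12)

    def test_matches_sliding_polyfit_oracle(self, rng):
        values = rng.gamma(2.0, 1.0, size=200)
        spec = spectrum_from_values(values)
        params = PeakFindParams()
        window = pf.sg_window_samples(spec.grid.delta_f, params, len(values))
        expected = sliding_polyfit(values, window, params.sg_order)
        np.testing.assert_allclose(smooth_spectrum(spec, params), expected, rtol=1e-9, atol=1e-9)

    def test_window_sample_derivation(self):
        # 0.133 Hz at the whole-brain grid spacing: 12 samples, forced odd
        assert pf.sg_window_samples(0.010753, PeakFindParams(), 300) == 13
        # doubled for short-TR acquisitions
        short = PeakFindParams.for_tr(0.051)
        assert short.sg_window_multiplier == 2
        assert pf.sg_window_samples(0.010753, short, 300) == 25
        # never below 5, capped (odd) at the spectrum length
        assert pf.sg_window_samples(1.0, PeakFindParams(), 300) == 5
        assert pf.sg_window_samples(0.001, PeakFindParams(), 10) == 9

    def test_too_short_spectrum_rejected(self):
        spec = spectrum_from_values(np.ones(6))
        with pytest.raises(ValueError):
            smooth_spectrum(spectrum_from_values(np.ones(4)))
        # but 6 bins work
        smooth_spectrum(spec)


class TestLowerEnvelope:
    def test_constant_spectrum_envelope_equals_spectrum(self):
        grid = make_frequency_grid(100, 0.5)
        env = lower_envelope(np.full(51, 2.0), grid)
        np.testing.assert_allclose(env, 2.0)

    def test_v_shape_envelope_equals_spectrum(self):
        grid = make_frequency_grid(20, 0.5)
        values = np.abs(np.arange(11) - 5.0) + 1.0
        env = lower_envelope(values, grid)
        np.testing.assert_allclose(env, values, rtol=1e-12)

    def test_two_bump_envelope_properties(self, rng):
        """Envelope ≤ smoothed, linear between knots, equal at knots."""
        grid = make_frequency_grid(200, 0.5)
        f = grid.frequencies
        values = 1.0 + np.exp(-((f - 0.2) / 0.05) ** 2) + np.exp(-((f - 0.7) / 0.05) ** 2)
        env = lower_envelope(values, grid)
        assert np.all(env <= values + 1e-12)
        knots = [0] + [i for i in range(1, len(values) - 1)
                       if values[i] < values[i - 1] and values[i] < values[i + 1]] + [len(values) - 1]
        for a, b in zip(knots[:-1], knots[1:]):
            seg = np.interp(f[a:b + 1], [f[a], f[b]], [values[a], values[b]])
            np.testing.assert_allclose(env[a:b + 1], np.minimum(seg, values[a:b + 1]), rtol=1e-9)

    def test_adjusted_zero_at_knots(self, rng):
        values = rng.gamma(3.0, 1.0, size=120) + 1.0
        grid = make_frequency_grid(238, 0.5)
        env = lower_envelope(values, grid)
        adjusted = adjust_spectrum(values, env)
        assert np.all(adjusted >= 0)
        interior = np.arange(1, 119)
        mins = interior[(values[interior] < values[interior - 1]) & (values[interior] < values[interior + 1])]
        np.testing.assert_allclose(adjusted[mins], 0.0, atol=1e-9)


class TestAdjustSpectrum:
    def test_equal_curves_give_zero(self):
        v = np.linspace(1, 2, 10)
        np.testing.assert_allclose(adjust_spectrum(v, v), 0.0)

    def test_doubling_gives_one(self):
        env = np.ones(5)
        sm = np.array([1.0, 2.0, 1.0, 1.0, 1.0])
        np.testing.assert_allclose(adjust_spectrum(sm, env), [0, 1, 0, 0, 0])

    def test_zero_envelope_rejected(self):
        with pytest.raises(ValueError):
            adjust_spectrum(np.ones(3), np.array([1.0, 0.0, 1.0]))


def brute_force_peaks(adjusted, threshold):
    """All interior strict local maxima (plateau center) above threshold."""
    out = []
    i = 1
    n = len(adjusted)
    while i < n - 1:
        j = i
        while j + 1 < n and adjusted[j + 1] == adjusted[j]:
            j += 1
        left_ok = adjusted[i] > adjusted[i - 1]
        right_ok = j + 1 < n and adjusted[j] > adjusted[j + 1]
        if left_ok and right_ok and adjusted[i] >= threshold:
            out.append((i + j) // 2)
        i = j + 1
    return out


class TestPrimaryPeaks:
    def test_flat_spectrum_no_peaks(self):
        grid = make_frequency_grid(40, 0.5)
        assert detect_primary_peaks(np.zeros(21), grid) == []

    def test_single_dominant_bump(self):
        grid = make_frequency_grid(80, 0.5)
        adjusted = np.zeros(41)
        adjusted[18:23] = [0.2, 0.8, 1.0, 0.8, 0.2]
        peaks = detect_primary_peaks(adjusted, grid)
        assert [p.index for p in peaks] == [20]

    def test_matches_brute_force_on_random(self, rng):
        grid = make_frequency_grid(160, 0.5)
        adjusted = np.maximum(rng.normal(0.1, 0.2, size=81), 0.0)
        adjusted[0] = 0.0
        body = adjusted[1:]
        threshold = body.mean() + body.std(ddof=1)
        expected = brute_force_peaks(adjusted, threshold)
        got = [p.index for p in detect_primary_peaks(adjusted, grid)]
        assert got == expected

    def test_plateau_tie_breaks_to_lower_frequency(self):
        grid = make_frequency_grid(40, 0.5)
        adjusted = np.zeros(21)
        adjusted[8:12] = 1.0  # 4-bin plateau -> center rounds down to bin 9
        peaks = detect_primary_peaks(adjusted, grid)
        assert [p.index for p in peaks] == [9]


class TestBaselineStats:
    def test_no_peaks_uses_whole_spectrum_minus_dc(self, rng):
        grid = make_frequency_grid(60, 0.5)
        adjusted = rng.uniform(0, 1, size=31)
        mean, std = baseline_stats(adjusted, grid, [])
        assert mean == pytest.approx(adjusted[1:].mean())
        assert std == pytest.approx(adjusted[1:].std(ddof=1))

    def test_exclusion_interval_around_peak(self):
        grid = make_frequency_grid(600, 0.155)
        adjusted = np.arange(len(grid), dtype=float)
        peak = pf.Peak(center_frequency=1.2043, height=5.0, index=112)
        mean, _ = baseline_stats(adjusted, grid, [peak])
        f = grid.frequencies
        expected_keep = (np.abs(f - 1.2043) > 0.667 / 2) & (f > 0)
        assert mean == pytest.approx(adjusted[expected_keep].mean())

    def test_half_width_flag_doubles_the_zone(self):
        grid = make_frequency_grid(600, 0.155)
        adjusted = np.ones(len(grid))
        peak = pf.Peak(center_frequency=1.2043, height=5.0, index=112)
        params = PeakFindParams(exclusion_is_half_width=True)
        f = grid.frequencies
        keep = (np.abs(f - 1.2043) > 0.667) & (f > 0)
        mean, _ = baseline_stats(adjusted, grid, [peak], params)
        assert mean == pytest.approx(adjusted[keep].mean())

    def test_full_coverage_raises(self):
        grid = make_frequency_grid(20, 1.0)  # grid spans 0..0.5 Hz
        adjusted = np.ones(len(grid))
        peak = pf.Peak(center_frequency=0.25, height=5.0, index=5)
        with pytest.raises(ValueError, match="exclusion"):
            baseline_stats(adjusted, grid, [peak])


class TestFinalPeaks:
    def test_flat_spectrum_empty(self):
        grid = make_frequency_grid(40, 0.5)
        assert detect_final_peaks(np.zeros(21), grid, (0.0, 0.0)) == []

    def test_six_db_bump_detected(self):
        grid = make_frequency_grid(80, 0.5)
        adjusted = np.zeros(41)
        adjusted[20] = 1.0  # ratio 2 -> ~6.02 dB prominence
        adjusted[19] = adjusted[21] = 0.4
        peaks = detect_final_peaks(adjusted, grid, (0.0, 0.05))
        assert [p.index for p in peaks] == [20]
        assert peaks[0].prominence_db == pytest.approx(20 * np.log10(2.0))

    def test_low_prominence_bump_suppressed(self):
        """A bump whose envelope-ratio prominence is ~1.1 dB fails the
        1.5 dB gate even though it clears the height threshold."""
        grid = make_frequency_grid(80, 0.5)
        height = 10 ** (1.1 / 20) - 1.0  # ≈ 0.135
        adjusted = np.zeros(41)
        adjusted[20] = height
        adjusted[19] = adjusted[21] = height / 2
        assert detect_final_peaks(adjusted, grid, (0.0, 0.0)) == []

    @given(st.floats(min_value=1.5, max_value=12.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_raising_prominence_threshold_never_adds_peaks(self, threshold_db):
        rng = np.random.default_rng(7)
        grid = make_frequency_grid(200, 0.5)
        adjusted = np.maximum(rng.normal(0.3, 0.4, size=101), 0.0)
        adjusted[0] = 0.0
        base = detect_final_peaks(adjusted, grid, (0.0, 0.0),
                                  PeakFindParams(min_prominence_db=1.5))
        strict = detect_final_peaks(adjusted, grid, (0.0, 0.0),
                                    PeakFindParams(min_prominence_db=threshold_db))
        assert {p.index for p in strict} <= {p.index for p in base}


class TestIdentifyPeaks:
    def test_scale_invariance(self, small_phantom_spectra):
        """Multiplying the raw spectrum by any c > 0 leaves the adjusted
        spectrum and peak frequencies unchanged."""
        spec = small_phantom_spectra["csf"]
        adj1, peaks1 = identify_peaks(spec)
        scaled = Spectrum(grid=spec.grid, magnitude=spec.magnitude * 37.5,
                          provenance=spec.provenance, n_samples=spec.n_samples, tr=spec.tr)
        adj2, peaks2 = identify_peaks(scaled)
        np.testing.assert_allclose(adj2.adjusted, adj1.adjusted, rtol=1e-9, atol=1e-12)
        assert [p.center_frequency for p in peaks1] == [p.center_frequency for p in peaks2]

    def test_stage_invariants_on_phantom(self, small_phantom_spectra):
        for region, spec in small_phantom_spectra.items():
            adj, peaks = identify_peaks(spec)
            assert np.all(adj.envelope > 0)
            assert np.all(adj.envelope[1:] <= adj.smoothed[1:] + 1e-12)
            assert np.all(adj.adjusted >= 0)
            baseline = baseline_stats(adj.adjusted, adj.grid,
                                      detect_primary_peaks(adj.adjusted, adj.grid))
            for p in peaks:
                assert p.height >= baseline[0] + baseline[1]
                assert p.prominence_db >= 1.5
                # final peaks are local maxima of the adjusted curve
                i = p.index
                assert adj.adjusted[i] >= adj.adjusted[i - 1]
                assert adj.adjusted[i] >= adj.adjusted[i + 1]

    def test_phantom_csf_recovers_components(self, small_phantom, small_phantom_spectra):
        _, _, truth = small_phantom
        adj, peaks = identify_peaks(small_phantom_spectra["csf"])
        found = sorted(p.center_frequency for p in peaks)
        assert len(found) == 3
        for f_true in sorted(truth.frequencies.values()):
            assert min(abs(f - f_true) for f in found) <= adj.grid.delta_f + 1e-9

    def test_deterministic(self, small_phantom_spectra):
        spec = small_phantom_spectra["cgm"]
        a1, p1 = identify_peaks(spec)
        a2, p2 = identify_peaks(spec)
        np.testing.assert_array_equal(a1.adjusted, a2.adjusted)
        assert p1 == p2
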