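import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slimim.peaks import (
    GAUSSIAN_BASELINE_FACTOR,
    PeakFit,
    ccs_per_time_slope,
    fit_peaks,
    percent_ccs_difference,
    percent_valley,
    resolving_power_ccs,
    spectrum_resolving_power,
    two_peak_resolution,
)
from slimim.synthetic import IMTrace

FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def make_trace(centers, fwhms, heights, dt=0.1, baseline=0.0, pad=6.0):
    lo = min(c - pad * w for c, w in zip(centers, fwhms))
    hi = max(c + pad * w for c, w in zip(centers, fwhms))
    t = np.arange(lo, hi, dt)
    y = np.full_like(t, baseline)
    for c, w, h in zip(centers, fwhms, heights):
        y += h * np.exp(-0.5 * ((t - c) / (w / FWHM_SIGMA)) ** 2)
    return IMTrace(time_ms=t, intensity=y, metadata={})


def test_single_gaussian_self_fit_is_exact():
    trace = make_trace([500.0], [2.0], [1000.0], baseline=5.0)
    fit = fit_peaks(trace, 1)[0]
    assert fit.t_p_ms == pytest.approx(500.0, abs=1e-6)
    assert fit.fwhm_ms == pytest.approx(2.0, rel=1e-6)
    assert fit.height == pytest.approx(1000.0, rel=1e-6)
    assert fit.fit_r2 > 0.999999


def test_two_gaussians_at_rpp_1p5_both_recovered():
    w = 2.0
    sep = 1.5 * GAUSSIAN_BASELINE_FACTOR * w
    trace = make_trace([500.0, 500.0 + sep], [w, w], [1000.0, 700.0])
    p1, p2 = fit_peaks(trace, 2)
    assert abs(p1.t_p_ms - 500.0) < 0.1 * w
    assert abs(p2.t_p_ms - (500.0 + sep)) < 0.1 * w


def test_fit_with_initial_windows_separates_close_peaks():
    trace = make_trace([500.0, 503.0], [2.0, 2.0], [1000.0, 800.0])
    p1, p2 = fit_peaks(trace, 2, initial_windows=[(495, 501), (501, 508)])
    assert p1.t_p_ms == pytest.approx(500.0, abs=0.05)
    assert p2.t_p_ms == pytest.approx(503.0, abs=0.05)


def test_peaks_sorted_by_centroid():
    trace = make_trace([600.0, 400.0], [3.0, 3.0], [500.0, 1000.0])
    fits = fit_peaks(trace, 2)
    assert fits[0].t_p_ms < fits[1].t_p_ms


def test_slope_direct_quotient_and_symmetry():
    p1 = PeakFit(400.0, 2.0, 1.0, assigned_ccs=200.0)
    p2 = PeakFit(450.0, 2.0, 1.0, assigned_ccs=210.0)
    s = ccs_per_time_slope(p1, p2)
    assert s == pytest.approx(0.2)
    assert ccs_per_time_slope(p2, p1) == pytest.approx(s)
    # slope applied over the pair's own time difference returns their CCS gap
    assert s * (p2.t_p_ms - p1.t_p_ms) == pytest.approx(10.0)
    with pytest.raises(ZeroDivisionError):
        ccs_per_time_slope(p1, PeakFit(400.0, 2.0, 1.0, assigned_ccs=205.0))


def test_resolving_power_formula_and_scaling():
    peak = PeakFit(500.0, 2.0, 1.0)
    assert resolving_power_ccs(peak, 0.1, 250.0) == pytest.approx(1250.0)
    wide = PeakFit(500.0, 4.0, 1.0)
    assert resolving_power_ccs(wide, 0.1, 250.0) == pytest.approx(625.0)
    with pytest.raises(ValueError):
        resolving_power_ccs(peak, 0.0, 250.0)
    with pytest.raises(ValueError):
        resolving_power_ccs(peak, 0.1, -1.0)


def test_spectrum_resolving_power_uses_average_ccs():
    peaks = [PeakFit(400.0, 2.0, 1.0), PeakFit(450.0, 2.0, 1.0)]
    rp = spectrum_resolving_power(peaks, 0.2, [200.0, 210.0])
    assert rp == pytest.approx(205.0 / (0.2 * 2.0))


def test_rp_invariant_under_affine_time_rescaling():
    """Stretching/offsetting the time axis (trace + calibration pair together)
    leaves the CCS-space resolving power unchanged."""
    ccs = (200.0, 210.0)
    trace = make_trace([400.0, 450.0], [2.0, 2.5], [1000.0, 900.0])
    for a, b in [(1.0, 0.0), (2.5, 30.0), (0.4, -50.0)]:
        scaled = IMTrace(time_ms=a * trace.time_ms + b, intensity=trace.intensity, metadata={})
        p1, p2 = fit_peaks(scaled, 2)
        slope = ccs_per_time_slope(p1, p2, *ccs)
        rp = resolving_power_ccs(p1, slope, ccs[0])
        assert rp == pytest.approx(200.0 / ((10.0 / 50.0) * 2.0), rel=1e-4)


def test_two_peak_resolution_conventions():
    w = 3.0
    p = PeakFit(500.0, w, 1.0)
    assert two_peak_resolution(p, PeakFit(500.0, w, 2.0)) == 0.0
    q = PeakFit(500.0 + GAUSSIAN_BASELINE_FACTOR * w, w, 1.0)
    assert two_peak_resolution(p, q) == pytest.approx(1.0)
    assert two_peak_resolution(q, p) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "rpp,expected_valley",
    [
        (1.5, 97.78),  # baseline separation: ~100% valley
        (1.1, 82.23),  # near-baseline: analytic two-Gaussian oracle
    ],
)
def test_valley_of_equal_gaussians_matches_analytic_oracle(rpp, expected_valley):
    # oracle: V = 100*(1 - y(midpoint)/y(apex)) for two unit Gaussians,
    # evaluated from the closed form of the mixture before the fit
    w = 2.0
    sep = rpp * GAUSSIAN_BASELINE_FACTOR * w
    sigma = w / FWHM_SIGMA
    mid = 2.0 * math.exp(-0.5 * (sep / 2.0 / sigma) ** 2)
    apex = 1.0 + math.exp(-0.5 * (sep / sigma) ** 2)
    oracle = 100.0 * (1.0 - mid / apex)
    assert oracle == pytest.approx(expected_valley, abs=0.01)

    p1 = PeakFit(100.0, w, 1.0)
    p2 = PeakFit(100.0 + sep, w, 1.0)
    result = percent_valley((p1, p2))
    assert result.has_valley
    assert result.pct == pytest.approx(oracle, abs=0.1)


def test_valley_limits():
    w = 2.0
    far = percent_valley((PeakFit(100.0, w, 1.0), PeakFit(200.0, w, 1.0)))
    assert far.pct == pytest.approx(100.0, abs=1e-6)
    merged = percent_valley((PeakFit(100.0, w, 1.0), PeakFit(100.4, w, 1.0)))
    assert merged.pct == 0.0 and not merged.has_valley


def test_valley_from_measured_trace():
    w, sep = 2.0, 6.0
    trace = make_trace([500.0, 500.0 + sep], [w, w], [1000.0, 600.0], dt=0.05)
    p1, p2 = fit_peaks(trace, 2)
    measured = percent_valley(trace, p1, p2)
    model = percent_valley((p1, p2))
    assert measured.has_valley
    assert measured.pct == pytest.approx(model.pct, abs=1.0)


@settings(derandomize=True, max_examples=40)
@given(st.floats(min_value=0.0, max_value=6.0), st.floats(min_value=0.1, max_value=4.0))
def test_valley_monotone_in_separation(sep, extra):
    w = 2.0
    v1 = percent_valley((PeakFit(100.0, w, 1.0), PeakFit(100.0 + sep, w, 1.0))).pct
    v2 = percent_valley((PeakFit(100.0, w, 1.0), PeakFit(100.0 + sep + extra, w, 1.0))).pct
    assert v2 >= v1 - 1e-6


@pytest.mark.parametrize(
    "ccs1,ccs2,expected",
    [(203.5, 205.4, 0.9), (300.0, 300.0, 0.0), (200.0, 202.0, 1.0)],
)
def test_percent_ccs_difference_one_decimal(ccs1, ccs2, expected):
    assert round(percent_ccs_difference(ccs1, ccs2), 1) == expected
    assert round(percent_ccs_difference(ccs2, ccs1), 1) == expected


def test_seeded_noise_centroid_recovery(mc_centroid_errors):
    """1% gaussian noise: centroid recovered within 0.05 ms over 100 replicates."""
    assert np.max(np.abs(mc_centroid_errors)) < 0.05
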