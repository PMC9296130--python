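import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slimim.geometry import WaveConfig
from slimim.ions import IonSpecies, tune_mix_panel
from slimim.peaks import fit_peaks
from slimim.synthetic import (
    SimConfig,
    TransportParams,
    arrival_time,
    ccs_from_mobility,
    ion_speed_fraction,
    mean_ion_speed,
    mobility_from_ccs,
    peak_width,
    simulate_trace,
    wave_ratio,
)

FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def test_mason_schamp_against_hand_evaluation():
    """Frozen oracle: plain-arithmetic Mason-Schamp for a 622 Th, 202 A^2 ion."""
    kB, e, u = 1.380649e-23, 1.602176634e-19, 1.66053906660e-27
    T, P = 300.0, 2.5 * 133.322368
    n = P / (kB * T)
    mu = (622.0 * 28.0134) / (622.0 + 28.0134) * u
    expected = 3 * e / (16 * n) * math.sqrt(2 * math.pi / (mu * kB * T)) / 202e-20 * 1e4
    species = IonSpecies("tune622", mz=622.0, z=1, ccs=202.0)
    assert mobility_from_ccs(species, TransportParams()) == pytest.approx(expected, rel=1e-6)
    assert expected == pytest.approx(341.17, rel=1e-4)  # cm^2/(V s) at 2.5 Torr


def test_doubling_ccs_halves_mobility():
    tr = TransportParams()
    k1 = mobility_from_ccs(IonSpecies("a", 622.0, 1, 200.0), tr)
    k2 = mobility_from_ccs(IonSpecies("b", 622.0, 1, 400.0), tr)
    assert k1 / k2 == pytest.approx(2.0, rel=1e-12)


def test_mobility_ccs_round_trip():
    tr = TransportParams()
    species = IonSpecies("a", 1222.0, 1, 288.1)
    k = mobility_from_ccs(species, tr)
    assert ccs_from_mobility(k, 1222.0, 1, tr) == pytest.approx(288.1, rel=1e-10)
    with pytest.raises(ValueError):
        ccs_from_mobility(-1.0, 622.0, 1, tr)
    with pytest.raises(ValueError):
        mobility_from_ccs(IonSpecies("a", 622.0, 1, None), tr)


def _config_with_ratio(species, target_c):
    """Scale the wave speed so this species sits at the requested wave ratio."""
    cfg = SimConfig(wave=WaveConfig(wave_speed_m_s=100.0, amplitude_vpp=40.0), noise="none")
    c0 = wave_ratio(species, cfg)
    v = 100.0 * c0 / target_c
    return SimConfig(wave=WaveConfig(wave_speed_m_s=v, amplitude_vpp=40.0), noise="none")


def test_mean_speed_surfing_limit_is_exact_wave_speed():
    species = tune_mix_panel()[0]
    cfg = _config_with_ratio(species, 1.3)
    assert wave_ratio(species, cfg) > 1.0
    assert mean_ion_speed(species, cfg) == cfg.wave.wave_speed_m_s


def test_mean_speed_rollover_closed_form():
    # c = 0.6 -> mean speed is (1 - sqrt(1 - 0.36)) = 0.2 of the wave speed
    species = tune_mix_panel()[0]
    cfg = _config_with_ratio(species, 0.6)
    assert wave_ratio(species, cfg) == pytest.approx(0.6, rel=1e-12)
    assert mean_ion_speed(species, cfg) == pytest.approx(0.2 * cfg.wave.wave_speed_m_s, rel=1e-9)


def test_mean_speed_monotone_in_wave_ratio():
    species = tune_mix_panel()[4]
    speeds = [mean_ion_speed(species, _config_with_ratio(species, c)) /
              _config_with_ratio(species, c).wave.wave_speed_m_s
              for c in (0.2, 0.4, 0.6, 0.8, 0.99)]
    assert all(b > a for a, b in zip(speeds, speeds[1:]))


@settings(derandomize=True, max_examples=30)
@given(st.floats(min_value=30.0, max_value=225.0), st.floats(min_value=1.0, max_value=100.0))
def test_lower_wave_speed_moves_every_ion_toward_surfing(v, dv):
    cfg_fast = SimConfig(wave=WaveConfig(wave_speed_m_s=v + dv, amplitude_vpp=40.0))
    cfg_slow = SimConfig(wave=WaveConfig(wave_speed_m_s=v, amplitude_vpp=40.0))
    for species in tune_mix_panel():
        assert wave_ratio(species, cfg_slow) > wave_ratio(species, cfg_fast)


def test_surfing_arrival_time_is_path_over_wave_speed():
    species = tune_mix_panel()[0]
    cfg = _config_with_ratio(species, 1.5)
    cfg = replace(cfg, transport=replace(cfg.transport, t0_ms=0.0))
    v = cfg.wave.wave_speed_m_s
    assert arrival_time(species, cfg) == pytest.approx(13.0 / v * 1000.0, rel=1e-12)


def test_ion_speed_fraction_reciprocal_relation():
    cfg = SimConfig(wave=WaveConfig(wave_speed_m_s=225.0, amplitude_vpp=40.0))
    t_surf = 13.0 / 225.0 * 1000.0 + cfg.transport.t0_ms
    t3 = 3.0 * (t_surf - cfg.transport.t0_ms) + cfg.transport.t0_ms
    t15 = 1.5 * (t_surf - cfg.transport.t0_ms) + cfg.transport.t0_ms
    assert 100 * ion_speed_fraction(t3, cfg) == pytest.approx(33.3, abs=0.05)
    assert 100 * ion_speed_fraction(t15, cfg) == pytest.approx(66.7, abs=0.05)
    with pytest.raises(ValueError):
        ion_speed_fraction(cfg.transport.t0_ms, cfg)


def test_peak_width_reduces_to_instrument_floor_without_diffusion():
    # vanishing drift time: the diffusive and slip variances go to zero
    tr = TransportParams(slip_fano=0.0, width_floor_fwhm_ms=4.2)
    species = IonSpecies("a", 622.0, 1, 202.0)
    cfg = SimConfig(wave=WaveConfig(wave_speed_m_s=180.0, amplitude_vpp=40.0), transport=tr)
    assert peak_width(species, tr.t0_ms + 1e-6, cfg) == pytest.approx(4.2, rel=1e-6)


def test_diffusive_width_scales_as_sqrt_drift_time():
    tr = TransportParams(width_floor_fwhm_ms=0.0, slip_fano=0.0, t0_ms=0.0)
    species = tune_mix_panel()[3]
    cfg = SimConfig(wave=WaveConfig(wave_speed_m_s=180.0, amplitude_vpp=40.0), transport=tr)
    w1 = peak_width(species, 200.0, cfg)
    w4 = peak_width(species, 800.0, cfg)
    assert w4 / w1 == pytest.approx(2.0, rel=1e-9)


def test_trace_argmax_at_analytic_arrival(cfg_180_40, panel):
    species = panel[2]
    trace = simulate_trace([species], cfg_180_40)
    t_peak = trace.time_ms[np.argmax(trace.intensity)]
    assert abs(t_peak - arrival_time(species, cfg_180_40)) <= cfg_180_40.sampling_interval_ms


def test_same_seed_reproduces_trace_bitwise(panel):
    cfg = SimConfig(wave=WaveConfig(wave_speed_m_s=180.0, amplitude_vpp=40.0),
                    noise="gaussian", seed=42)
    t1 = simulate_trace(panel, cfg)
    t2 = simulate_trace(panel, cfg)
    assert np.array_equal(t1.intensity, t2.intensity)
    t3 = simulate_trace(panel, cfg.with_seed(43))
    assert not np.array_equal(t1.intensity, t3.intensity)


def test_noiseless_trace_integral_matches_peak_areas(panel, cfg_180_40):
    trace = simulate_trace(panel, cfg_180_40)
    area = np.trapezoid(trace.intensity, trace.time_ms)
    expected = sum(
        p["height"] * (p["fwhm_ms"] / FWHM_SIGMA) * math.sqrt(2 * math.pi)
        for p in trace.metadata["peaks"]
    )
    assert area == pytest.approx(expected, rel=1e-3)


def test_clipped_window_recorded_as_warning(panel):
    cfg = SimConfig(wave=WaveConfig(wave_speed_m_s=180.0, amplitude_vpp=40.0),
                    noise="none", window_ms=(0.0, 400.0))
    trace = simulate_trace(panel, cfg)
    assert any("clipped" in w for w in trace.metadata["warnings"])


def test_surfing_ions_co_arrive(panel):
    # very low speed, high amplitude: every ion locked to the wave
    cfg = SimConfig(wave=WaveConfig(wave_speed_m_s=20.0, amplitude_vpp=40.0), noise="none")
    assert all(wave_ratio(s, cfg) >= 1 for s in panel)
    times = [arrival_time(s, cfg) for s in panel]
    assert max(times) - min(times) < cfg.sampling_interval_ms


def test_noiseless_fit_recovers_generator_parameters(panel, cfg_180_40):
    """Peaks fitted from noiseless traces recover centroid to <0.1 sample, fwhm to <1%."""
    for species in panel:
        trace = simulate_trace([species], cfg_180_40)
        truth = trace.metadata["peaks"][0]
        fit = fit_peaks(trace, 1)[0]
        assert abs(fit.t_p_ms - truth["t_ms"]) < 0.1 * cfg_180_40.sampling_interval_ms
        assert abs(fit.fwhm_ms - truth["fwhm_ms"]) / truth["fwhm_ms"] < 0.01


def test_invalid_sim_inputs():
    with pytest.raises(ValueError):
        simulate_trace([], SimConfig(wave=WaveConfig(wave_speed_m_s=100.0)))
    with pytest.raises(ValueError):
        TransportParams(pressure_torr=0.0)
    with pytest.raises(ValueError):
        SimConfig(wave=WaveConfig(wave_speed_m_s=100.0), noise="pink")
    with pytest.raises(ValueError):
        SimConfig(wave=WaveConfig(wave_speed_m_s=100.0), sampling_interval_ms=0.0)
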