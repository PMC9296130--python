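import numpy as np
import pytest

from slimim import (
    BenchmarkGrid,
    SimConfig,
    WaveConfig,
    fit_peaks,
    run_grid,
    simulate_trace,
    tune_mix_panel,
)


@pytest.fixture(scope="session")
def panel():
    return tune_mix_panel()


@pytest.fixture(scope="session")
def cfg_180_40():
    """The benchmark anchor condition: sine, 180 m/s, 40 V_pp, noiseless."""
    return SimConfig(
        wave=WaveConfig(waveform="sine", amplitude_vpp=40.0, wave_speed_m_s=180.0),
        noise="none",
    )


@pytest.fixture(scope="session")
def default_grid_result(panel):
    """The full default benchmarking grid (both waveforms, 3 replicates)."""
    return run_grid(panel=panel, grid=BenchmarkGrid(seed=1))


@pytest.fixture(scope="session")
def mc_centroid_errors(panel, cfg_180_40):
    """Centroid fit errors (ms) for 100 seeded replicates at 1% gaussian noise."""
    species = panel[3]
    errors = []
    for seed in range(100):
        cfg = SimConfig(wave=cfg_180_40.wave, noise="gaussian", noise_scale=0.01, seed=seed)
        trace = simulate_trace([species], cfg)
        fit = fit_peaks(trace, 1)[0]
        errors.append(fit.t_p_ms - trace.metadata["peaks"][0]["t_ms"])
    return np.asarray(errors)
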