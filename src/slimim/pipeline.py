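"""Desk-scale benchmarking experiments built on the simulator.

Three studies mirror the characterization workflow for a traveling-wave
SLIM instrument:

* :func:`run_grid` — resolving power across a wave-speed × amplitude ×
  waveform grid for the tune-mix panel, with surfing cells flagged;
* :func:`summarize_regions` — binned arrival-time statistics exposing the
  surfing / mobility-selective drift / diffusion-degraded regimes;
* :func:`isomer_report` — two-peak separation metrics (ΔCCS%, R_pp, percent
  valley) for isomeric mixtures;
* :func:`compare_calibrations` — ranking of the calibration model families
  by mean absolute CCS bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import ReferencePoint, apply_calibration, ccs_bias, fit_calibration
from .geometry import TrackGeometry, WaveConfig
from .ions import IonSpecies, tune_mix_panel
from .peaks import (
    PeakFit,
    ccs_per_time_slope,
    fit_peaks,
    percent_ccs_difference,
    percent_valley,
    spectrum_resolving_power,
    two_peak_resolution,
)
from .synthetic import IMTrace, SimConfig, TransportParams, simulate_trace, wave_ratio

__all__ = [
    "BenchmarkGrid",
    "run_grid",
    "summarize_regions",
    "isomer_report",
    "compare_calibrations",
    "scan_calibration_speeds",
]

log = logging.getLogger(__name__)

GRID_COLUMNS = [
    "ion", "mz", "wave_speed_m_s", "amplitude_vpp", "waveform", "replicate",
    "arrival_time_ms", "fwhm_ms", "fit_r2", "rp_ccs", "regime", "flags",
]


@dataclass(frozen=True)
class BenchmarkGrid:
    """The benchmarking grid: wave speeds × amplitudes × waveforms × replicates."""

    wave_speeds: tuple[float, ...] = (45.0, 90.0, 135.0, 180.0, 225.0)
    amplitudes: tuple[float, ...] = (30.0, 35.0, 40.0)
    waveforms: tuple[str, ...] = ("sine", "square")
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.wave_speeds and self.amplitudes and self.waveforms):
            raise ValueError("grid axes must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.wave_speeds) * len(self.amplitudes) * len(self.waveforms) * self.replicates


def _slope_partner(i: int, surfing: Sequence[bool], times: Sequence[float]) -> int | None:
    """Index of the neighbor used for the local time→CCS slope.

    Preference is the next-highest-m/z ion; the last ion (or one whose
    upper neighbor is unusable) falls back to the next-lowest. Surfing or
    co-arriving neighbors are unusable.
    """
    def usable(j: int) -> bool:
        return 0 <= j < len(times) and not surfing[j] and times[j] != times[i]

    if usable(i + 1):
        return i + 1
    if usable(i - 1):
        return i - 1
    return None


def run_grid(
    panel: Sequence[IonSpecies] | None = None,
    grid: BenchmarkGrid | None = None,
    transport: TransportParams | None = None,
    geometry: TrackGeometry | None = None,
    base_config: SimConfig | None = None,
) -> pd.DataFrame:
    """Simulate, fit, and score every grid cell; one row per ion × condition × replicate.

    Per-ion traces are extracted (as from narrow m/z windows of an IM-MS
    acquisition) and fitted with single Gaussians. The time→CCS slope for
    each ion uses the next-highest-m/z ion in the same acquisition. Surfing
    ions (wave ratio c ≥ 1) are transmitted and timed but carry no R_p —
    they co-arrive at the wave speed with no mobility separation. Replicate
    seeds are derived deterministically from the master seed; fit failures
    are recorded per cell, never aborting the grid.
    """
    panel = list(panel) if panel is not None else tune_mix_panel()
    grid = grid or BenchmarkGrid()
    transport = transport or TransportParams()
    geometry = geometry or TrackGeometry()

    rows = []
    for iw, waveform in enumerate(grid.waveforms):
        for iv, speed in enumerate(grid.wave_speeds):
            for ia, amp in enumerate(grid.amplitudes):
                wave = WaveConfig(waveform=waveform, amplitude_vpp=amp, wave_speed_m_s=speed)
                cfg0 = base_config or SimConfig()
                cfg0 = replace(cfg0, wave=wave, transport=transport, geometry=geometry)
                ratios = [wave_ratio(sp, cfg0) for sp in panel]
                surfing = [c >= 1.0 for c in ratios]
                for rep in range(grid.replicates):
                    fits: list[PeakFit | None] = []
                    for k, sp in enumerate(panel):
                        ss = np.random.SeedSequence(
                            entropy=grid.seed, spawn_key=(iw, iv, ia, rep, k)
                        )
                        cfg = cfg0.with_seed(int(ss.generate_state(1)[0] % (2**31)))
                        trace = simulate_trace([sp], cfg)
                        try:
                            fits.append(fit_peaks(trace, 1)[0])
                        except Exception as exc:  # fit failure -> record, keep going
                            log.debug("fit failed for %s at %s m/s %s Vpp: %s",
                                      sp.label, speed, amp, exc)
                            fits.append(None)
                    times = [f.t_p_ms if f else np.nan for f in fits]
                    for k, sp in enumerate(panel):
                        f = fits[k]
                        flags = []
                        rp = np.nan
                        if f is None:
                            flags.append("fit_failed")
                        elif surfing[k]:
                            flags.append("surfing_no_separation")
                        else:
                            j = _slope_partner(k, surfing, times)
                            if j is None or fits[j] is None:
                                flags.append("no_slope_partner")
                            else:
                                slope = (panel[j].ccs - sp.ccs) / (times[j] - times[k])
                                rp = sp.ccs / (abs(slope) * f.fwhm_ms)
                        rows.append({
                            "ion": sp.label, "mz": sp.mz,
                            "wave_speed_m_s": speed, "amplitude_vpp": amp,
                            "waveform": waveform, "replicate": rep,
                            "arrival_time_ms": f.t_p_ms if f else np.nan,
                            "fwhm_ms": f.fwhm_ms if f else np.nan,
                            "fit_r2": f.fit_r2 if f else np.nan,
                            "rp_ccs": rp,
                            "regime": "surfing" if surfing[k] else "drift",
                            "flags": ";".join(flags),
                        })
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def summarize_regions(result: pd.DataFrame, bin_width_ms: float = 200.0) -> pd.DataFrame:
    """Arrival-time-binned R_p statistics (median and quartiles per bin).

    Only records carrying an R_p value (mobility-selective, successfully
    fitted) enter the summary. The returned frame's ``attrs`` identify the
    bin with the maximum median R_p; an empty input yields an empty frame
    flagged in ``attrs``.
    """
    if result.empty:
        out = pd.DataFrame(columns=["bin_start_ms", "bin_end_ms", "n", "median_rp", "q1_rp", "q3_rp"])
        out.attrs["empty"] = True
        return out
    ok = result.dropna(subset=["rp_ccs", "arrival_time_ms"])
    if ok.empty:
        out = pd.DataFrame(columns=["bin_start_ms", "bin_end_ms", "n", "median_rp", "q1_rp", "q3_rp"])
        out.attrs["empty"] = True
        return out
    start = (ok["arrival_time_ms"] // bin_width_ms).astype(int) * bin_width_ms
    rows = []
    for b, g in ok.groupby(start):
        rows.append({
            "bin_start_ms": float(b),
            "bin_end_ms": float(b) + bin_width_ms,
            "n": len(g),
            "median_rp": float(g["rp_ccs"].median()),
            "q1_rp": float(g["rp_ccs"].quantile(0.25)),
            "q3_rp": float(g["rp_ccs"].quantile(0.75)),
        })
    out = pd.DataFrame(rows).sort_values("bin_start_ms").reset_index(drop=True)
    out.attrs["empty"] = False
    best = out.loc[out["median_rp"].idxmax()]
    out.attrs["max_median_bin"] = (float(best["bin_start_ms"]), float(best["bin_end_ms"]))
    out.attrs["max_median_rp"] = float(best["median_rp"])
    return out


def isomer_report(
    traces: Sequence[IMTrace],
    known_ccs: Mapping[str, Sequence[float]],
    min_separation_fwhm: float = 0.25,
) -> pd.DataFrame:
    """Separation metrics for isomeric-mixture spectra.

    Each trace is fitted to as many Gaussians as it has known CCS values
    (``known_ccs`` is keyed by the trace's ``metadata['label']``, values in
    elution order). For every adjacent peak pair the report gives ΔCCS%,
    R_pp, percent valley, and a separable flag; the per-spectrum R_p uses
    the average-CCS convention. Pairs whose fitted centroids collapse
    (closer than ``min_separation_fwhm`` mean widths) are reported as not
    separable rather than given meaningless metrics.
    """
    rows = []
    for trace in traces:
        label = trace.metadata.get("label", "trace")
        ccs_list = list(known_ccs[label])
        n = len(ccs_list)
        fits = fit_peaks(trace, n)
        slope = None
        if n >= 2 and fits[-1].t_p_ms != fits[0].t_p_ms:
            slope = ccs_per_time_slope(fits[0], fits[-1], ccs_list[0], ccs_list[-1])
        rp_spectrum = (
            spectrum_resolving_power(fits, slope, ccs_list) if slope else np.nan
        )
        for i in range(n - 1):
            p1, p2 = fits[i], fits[i + 1]
            dccs = percent_ccs_difference(ccs_list[i], ccs_list[i + 1]) if ccs_list[i] != ccs_list[i + 1] else 0.0
            mean_fwhm = 0.5 * (p1.fwhm_ms + p2.fwhm_ms)
            collapsed = abs(p2.t_p_ms - p1.t_p_ms) < min_separation_fwhm * mean_fwhm
            if collapsed:
                rpp, valley, has_valley = 0.0, 0.0, False
            else:
                rpp = two_peak_resolution(p1, p2)
                valley, has_valley = percent_valley(trace, p1, p2)
            rows.append({
                "trace": label,
                "pair": f"{i + 1}-{i + 2}",
                "ccs_1": ccs_list[i], "ccs_2": ccs_list[i + 1],
                "t_1_ms": p1.t_p_ms, "t_2_ms": p2.t_p_ms,
                "delta_ccs_pct": round(dccs, 1),
                "rpp": rpp,
                "valley_pct": valley,
                "separable": bool(has_valley and not collapsed),
                "rp_ccs_spectrum": rp_spectrum,
            })
    return pd.DataFrame(rows)


def scan_calibration_speeds(
    panel: Sequence[IonSpecies] | None = None,
    amplitude_vpp: float = 40.0,
    frequencies_khz: Sequence[float] | None = None,
    kind: str = "poly3",
    transport: TransportParams | None = None,
    geometry: TrackGeometry | None = None,
) -> pd.DataFrame:
    """CCS bias of one calibration family across the wave-speed operating range.

    The switching frequency is scanned over the instrument's digital raster
    (integer kHz, 5–25 by default). Conditions where any panel ion surfs are
    skipped — surfing calibrants carry no mobility information. For each
    remaining speed the panel's analytic arrival times are fitted and the
    held-in CCS biases evaluated, mirroring the practice of picking the
    acquisition speed that minimizes calibration bias.
    """
    panel = list(panel) if panel is not None else tune_mix_panel()
    geometry = geometry or TrackGeometry()
    transport = transport or TransportParams()
    if frequencies_khz is None:
        frequencies_khz = range(5, 26)
    from .synthetic import arrival_time  # local import to avoid cycle noise

    rows = []
    for f in frequencies_khz:
        wave = WaveConfig(amplitude_vpp=amplitude_vpp, frequency_khz=float(f))
        cfg = SimConfig(wave=wave, transport=transport, geometry=geometry, noise="none")
        if max(wave_ratio(sp, cfg) for sp in panel) >= 1.0:
            continue
        points = [
            ReferencePoint(sp.label, sp.mz, sp.z, arrival_time(sp, cfg), sp.ccs)
            for sp in panel
        ]
        model = fit_calibration(points, kind)
        biases = [
            ccs_bias(apply_calibration(model, p.arrival_time_ms, p.mz, p.z, p.m_gas), p.ccs_ref)
            for p in points
        ]
        rows.append({
            "frequency_khz": float(f),
            "wave_speed_m_s": wave.speed(geometry),
            "kind": kind,
            "r2": model.r2,
            "mean_abs_bias_pct": float(np.mean(np.abs(biases))),
            "max_abs_bias_pct": float(np.max(np.abs(biases))),
        })
    return pd.DataFrame(rows)


def compare_calibrations(
    points: Sequence[ReferencePoint],
    kinds: Sequence[str] = ("power", "poly2", "poly3"),
) -> pd.DataFrame:
    """Fit each requested model family and rank by mean absolute CCS bias.

    Bias is evaluated on the (held-in) calibration points themselves: each
    model's prediction at a calibrant's arrival time is inverted to CCS and
    compared against the reference value.
    """
    if len(points) < 5:
        raise ValueError("need at least 5 reference points")
    rows = []
    for kind in kinds:
        model = fit_calibration(points, kind)
        biases = [
            ccs_bias(apply_calibration(model, p.arrival_time_ms, p.mz, p.z, p.m_gas), p.ccs_ref)
            for p in points
        ]
        rows.append({
            "kind": kind,
            "r2": model.r2,
            "mean_abs_bias_pct": float(np.mean(np.abs(biases))),
            "mean_signed_bias_pct": float(np.mean(biases)),
        })
    out = pd.DataFrame(rows)
    out["rank"] = out["mean_abs_bias_pct"].rank(method="min").astype(int)
    return out.sort_values("rank").reset_index(drop=True)
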