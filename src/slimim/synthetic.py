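"""Synthetic traveling-wave SLIM arrival-time traces.

The generator implements a low-field transport model for ions carried by a
traveling potential wave:

* **Mobility** from CCS via the Mason–Schamp relation (nitrogen buffer gas,
  low-field limit).
* **Mean drift speed** from a sinusoidal roll-over law. With
  ``c = K·E_max / v_wave`` (the ratio of the ion's maximum field-driven drift
  speed to the wave speed), an ion with ``c ≥ 1`` *surfs* — it stays locked to
  the wave and moves at exactly the wave speed with no mobility selectivity.
  For ``c < 1`` the ion periodically slips over wave crests ("roll-over") and
  its cycle-averaged speed is ``v_wave · (1 − sqrt(1 − c²))``, a standard
  result for drift in a moving sinusoidal potential.
* **Peak widths** from three components in quadrature: ion-gas diffusion
  (Einstein relation), a slip-dispersion term for the stochastic character of
  roll-over events, and a fixed instrument width floor (gate width, transfer
  optics).

Traces are sums of Gaussian peaks with optional seeded noise, suitable for
exercising the full fitting → metrics → calibration pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import constants as _const

from .geometry import TrackGeometry, WaveConfig, wavelength
from .ions import IonSpecies

__all__ = [
    "TransportParams",
    "SimConfig",
    "IMTrace",
    "mobility_from_ccs",
    "ccs_from_mobility",
    "wave_ratio",
    "mean_ion_speed",
    "arrival_time",
    "ion_speed_fraction",
    "peak_width",
    "simulate_trace",
]

_TORR_PA = _const.torr  # 133.322... Pa
_FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class TransportParams:
    """Gas state, path, and instrument transport constants.

    Parameters
    ----------
    path_length_m:
        Ion path length through the separation region (13 m prototype).
    gas, gas_mass_da:
        Buffer gas identity and molar mass; nitrogen at 28.0134 Da.
    pressure_torr, temperature_k:
        Gas state in the separation region (~2.5 Torr; 300 K assumed —
        instrument temperature is not controlled tightly enough to matter
        at the fidelity of this generator).
    t0_ms:
        Arrival-time contribution from outside the mobility path (transfer
        optics, funnels); added to every arrival time.
    field_efficiency:
        Fraction of the ideal surface-wave field ``π·A/λ`` actually felt by
        ions mid-gap between the two SLIM boards. Surface potentials decay
        away from the electrode plane, so the effective axial field is well
        below the ideal value; 0.285 places the surfing→drift transition in
        the experimentally observed wave-speed range.
    width_floor_fwhm_ms:
        Mobility-independent instrument peak width (fwhm), added in
        quadrature; dominated by the ion-gate release width.
    slip_fano:
        Dispersion (Fano-like) factor of the roll-over slip process; scales
        a variance contribution ``slip_fano·λ·v_wave·sqrt(1−c²)·t_drift``
        that vanishes in the surfing limit and degrades resolving power at
        long residence times.
    """

    path_length_m: float = 13.0
    gas: str = "N2"
    gas_mass_da: float = 28.0134
    pressure_torr: float = 2.5
    temperature_k: float = 300.0
    t0_ms: float = 5.0
    field_efficiency: float = 0.285
    width_floor_fwhm_ms: float = 3.5
    slip_fano: float = 1.5e-3

    def __post_init__(self) -> None:
        if self.pressure_torr <= 0:
            raise ValueError(f"pressure_torr must be > 0, got {self.pressure_torr}")
        if self.temperature_k <= 0:
            raise ValueError(f"temperature_k must be > 0, got {self.temperature_k}")
        if self.t0_ms < 0:
            raise ValueError(f"t0_ms must be >= 0, got {self.t0_ms}")
        if self.path_length_m <= 0:
            raise ValueError(f"path_length_m must be > 0, got {self.path_length_m}")
        if not 0 < self.field_efficiency <= 1:
            raise ValueError(f"field_efficiency must be in (0, 1], got {self.field_efficiency}")

    @property
    def number_density_m3(self) -> float:
        """Buffer-gas number density in m⁻³."""
        return self.pressure_torr * _TORR_PA / (_const.k * self.temperature_k)


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to simulate one acquisition."""

    wave: WaveConfig = field(default_factory=lambda: WaveConfig(wave_speed_m_s=180.0))
    transport: TransportParams = field(default_factory=TransportParams)
    geometry: TrackGeometry = field(default_factory=TrackGeometry)
    sampling_interval_ms: float = 0.5
    noise: str = "gaussian"
    noise_scale: float = 0.01
    seed: int = 0
    window_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sampling_interval_ms <= 0:
            raise ValueError(f"sampling_interval_ms must be > 0, got {self.sampling_interval_ms}")
        if self.noise not in ("none", "gaussian", "shot"):
            raise ValueError(f"noise must be none/gaussian/shot, got {self.noise!r}")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class IMTrace:
    """A sampled arrival-time intensity profile with acquisition metadata."""

    time_ms: np.ndarray
    intensity: np.ndarray
    metadata: dict

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_ms.shape != self.intensity.shape:
            raise ValueError("time and intensity arrays must have the same shape")


def mobility_from_ccs(species: IonSpecies, transport: TransportParams) -> float:
    """Low-field ion mobility K in cm²/(V·s) via Mason–Schamp.

    ``K = (3 z e / 16 N) · sqrt(2π / (μ k_B T)) / Ω`` with the ion-neutral
    reduced mass μ and the gas number density N at the configured pressure.
    The ion mass is taken as mz × z.
    """
    if species.ccs is None or species.ccs <= 0:
        raise ValueError(f"species {species.label!r} needs a positive CCS")
    m_ion = species.ion_mass_da
    mu_kg = (m_ion * transport.gas_mass_da / (m_ion + transport.gas_mass_da)) * _const.u
    n = transport.number_density_m3
    k_si = (
        3.0 * species.z * _const.e / (16.0 * n)
        * math.sqrt(2.0 * math.pi / (mu_kg * _const.k * transport.temperature_k))
        / (species.ccs * 1e-20)
    )
    return k_si * 1e4  # m²/(V·s) → cm²/(V·s)


def ccs_from_mobility(k_cm2: float, mz: float, z: int, transport: TransportParams) -> float:
    """Inverse of :func:`mobility_from_ccs`: CCS in Å² from K in cm²/(V·s)."""
    if k_cm2 <= 0:
        raise ValueError(f"mobility must be > 0, got {k_cm2}")
    probe = IonSpecies(label="probe", mz=mz, z=z, ccs=1.0)
    return mobility_from_ccs(probe, transport) / k_cm2


def _max_field_v_m(config: SimConfig) -> float:
    """Effective peak axial field of the traveling wave, in V/m.

    For a sinusoidal potential of peak-to-peak amplitude A over wavelength λ
    the maximum gradient is π·A/λ; a square drive is represented by its
    fundamental, which is 4/π larger. The geometric ``field_efficiency``
    accounts for the decay of the surface potential at the ion's position
    between the boards.
    """
    lam_m = wavelength(config.geometry) * 1e-3
    e_ideal = math.pi * config.wave.amplitude_vpp / lam_m
    if config.wave.waveform == "square":
        e_ideal *= 4.0 / math.pi
    return config.transport.field_efficiency * e_ideal


def wave_ratio(species: IonSpecies, config: SimConfig) -> float:
    """c = K·E_max / v_wave — the surfing criterion (c ≥ 1 ⇒ surfing)."""
    v_wave = config.wave.speed(config.geometry)
    if v_wave <= 0:
        raise ValueError("wave speed must be > 0")
    k_si = mobility_from_ccs(species, config.transport) * 1e-4
    return k_si * _max_field_v_m(config) / v_wave


def mean_ion_speed(species: IonSpecies, config: SimConfig) -> float:
    """Cycle-averaged ion speed in m/s under the roll-over law.

    Surfing ions (c ≥ 1) move at the wave speed; otherwise
    ``v̄ = v_wave·(1 − sqrt(1 − c²))``, which is monotone increasing in c.
    """
    v_wave = config.wave.speed(config.geometry)
    c = wave_ratio(species, config)
    if c >= 1.0:
        return v_wave
    return v_wave * (1.0 - math.sqrt(1.0 - c * c))


def arrival_time(species: IonSpecies, config: SimConfig) -> float:
    """Arrival time in ms: path over mean speed, plus the non-IM offset t₀.

    A zero mean speed (immobile ion) yields ``inf`` — the ion is flagged as
    non-transmitted by the caller rather than raising.
    """
    v = mean_ion_speed(species, config)
    if v <= 0.0:
        return math.inf
    return config.transport.path_length_m / v * 1000.0 + config.transport.t0_ms


def ion_speed_fraction(arrival_time_ms: float, config: SimConfig) -> float:
    """Mean ion speed as a fraction of the wave speed, from an arrival time.

    ``(L / (t − t₀)) / v_wave``; e.g. an arrival at 3× the surf-only time
    corresponds to a fraction of 1/3.
    """
    t_drift_s = (arrival_time_ms - config.transport.t0_ms) * 1e-3
    if t_drift_s <= 0:
        raise ValueError("arrival time must exceed the non-IM offset t0")
    return (config.transport.path_length_m / t_drift_s) / config.wave.speed(config.geometry)


def peak_width(species: IonSpecies, t_arrival_ms: float, config: SimConfig) -> float:
    """Arrival-time peak fwhm in ms at a given arrival time.

    Spatial variance accumulates as ``2·D·t_drift`` (diffusion, with
    ``D = k_B·T·K/q``) plus ``slip_fano·λ·v_wave·sqrt(1−c²)·t_drift``
    (roll-over slip dispersion, zero for surfing ions). The spatial sigma is
    converted to time through the mean ion speed and added in quadrature
    with the instrument width floor.
    """
    tr = config.transport
    if t_arrival_ms <= tr.t0_ms:
        raise ValueError("arrival time must exceed t0")
    t_drift_s = (t_arrival_ms - tr.t0_ms) * 1e-3
    v_bar = mean_ion_speed(species, config)
    k_si = mobility_from_ccs(species, config.transport) * 1e-4
    d = _const.k * tr.temperature_k * k_si / (species.z * _const.e)
    c = wave_ratio(species, config)
    lam_m = wavelength(config.geometry) * 1e-3
    v_wave = config.wave.speed(config.geometry)
    slip = tr.slip_fano * lam_m * v_wave * math.sqrt(max(0.0, 1.0 - min(c, 1.0) ** 2))
    sigma_x = math.sqrt((2.0 * d + slip) * t_drift_s)
    fwhm_diff_ms = _FWHM_SIGMA * sigma_x / v_bar * 1000.0
    return math.hypot(fwhm_diff_ms, tr.width_floor_fwhm_ms)


def _gaussian(t: np.ndarray, center: float, fwhm: float, height: float) -> np.ndarray:
    sigma = fwhm / _FWHM_SIGMA
    return height * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def simulate_trace(
    panel: Sequence[IonSpecies],
    config: SimConfig,
    heights: Sequence[float] | None = None,
) -> IMTrace:
    """Simulate one arrival-time trace for a panel of ions.

    Each transmitted ion contributes a Gaussian at its analytic arrival time
    with its analytic width; noise is added per the config's noise model
    (gaussian: σ = ``noise_scale`` × the tallest peak; shot: Poisson counts).
    Generation is bit-reproducible for a fixed ``config.seed``.

    The sampling window defaults to covering every peak ±6 fwhm; an explicit
    window that clips peaks is honored but recorded as a warning in the
    trace metadata.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    if heights is None:
        heights = [1000.0] * len(panel)
    if len(heights) != len(panel):
        raise ValueError("heights must match panel length")

    warnings: list[str] = []
    peaks = []
    for species, height in zip(panel, heights):
        t_a = arrival_time(species, config)
        if not math.isfinite(t_a):
            warnings.append(f"{species.label}: zero mean speed, not transmitted")
            continue
        fwhm = peak_width(species, t_a, config)
        peaks.append({"label": species.label, "mz": species.mz, "z": species.z,
                      "ccs": species.ccs, "t_ms": t_a, "fwhm_ms": fwhm,
                      "height": float(height)})
    if not peaks and config.window_ms is None:
        raise ValueError("no transmitted ions and no explicit sampling window")

    if config.window_ms is not None:
        lo, hi = config.window_ms
    else:
        lo = max(0.0, min(p["t_ms"] - 6.0 * p["fwhm_ms"] for p in peaks))
        hi = max(p["t_ms"] + 6.0 * p["fwhm_ms"] for p in peaks)
    for p in peaks:
        if p["t_ms"] - 2 * p["fwhm_ms"] < lo or p["t_ms"] + 2 * p["fwhm_ms"] > hi:
            warnings.append(f"{p['label']}: peak at {p['t_ms']:.1f} ms clipped by window")

    t = np.arange(lo, hi + config.sampling_interval_ms / 2.0, config.sampling_interval_ms)
    signal = np.zeros_like(t)
    for p in peaks:
        signal += _gaussian(t, p["t_ms"], p["fwhm_ms"], p["height"])

    rng = np.random.default_rng(config.seed)
    if config.noise == "gaussian" and peaks:
        sigma = config.noise_scale * max(p["height"] for p in peaks)
        signal = signal + rng.normal(0.0, sigma, size=signal.shape)
    elif config.noise == "shot":
        signal = rng.poisson(np.clip(signal, 0.0, None)).astype(float)

    meta = {
        "wave_speed_m_s": config.wave.speed(config.geometry),
        "amplitude_vpp": config.wave.amplitude_vpp,
        "waveform": config.wave.waveform,
        "pressure_torr": config.transport.pressure_torr,
        "temperature_k": config.transport.temperature_k,
        "seed": config.seed,
        "noise": config.noise,
        "peaks": peaks,
        "warnings": warnings,
    }
    return IMTrace(time_ms=t, intensity=signal, metadata=meta)
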