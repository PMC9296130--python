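"""SLIM track geometry and traveling-wave waveform calculations.

A SLIM (structures for lossless ion manipulation) separation track is a long
serpentine path of small "conveyor" pad electrodes. Groups of
``pads_per_cycle`` consecutive pads (a *set*) carry one full cycle of a
traveling potential waveform; stepping the waveform phase across the set makes
the potential wave move down the track and push ions along. Everything in
this module is exact arithmetic on the track layout and the applied
waveform — no ion physics.

Internal units: mm for lengths on the board, m for the path, kHz for
switching frequencies, ms for time, volts for potentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrackGeometry",
    "WaveConfig",
    "wavelength",
    "wave_speed",
    "switching_frequency",
    "electrode_sets",
    "total_conveyor_pads",
    "waveform_potentials",
]


@dataclass(frozen=True)
class TrackGeometry:
    """Layout of the traveling-wave separation track.

    Parameters
    ----------
    pad_pitch_mm:
        Pad-to-pad distance (pad length plus inter-pad gap). The prototype
        uses 1.0 mm pads with 0.125 mm gaps, i.e. a 1.125 mm pitch.
    pads_per_cycle:
        Number of consecutive pads spanning one full waveform cycle
        (one *set*); 8 on the prototype.
    path_length_m:
        Total ion path length in metres (~13 m serpentine).
    """

    pad_pitch_mm: float = 1.125
    pads_per_cycle: int = 8
    path_length_m: float = 13.0

    def __post_init__(self) -> None:
        if self.pad_pitch_mm <= 0:
            raise ValueError(f"pad_pitch_mm must be > 0, got {self.pad_pitch_mm}")
        if int(self.pads_per_cycle) != self.pads_per_cycle or self.pads_per_cycle < 1:
            raise ValueError(f"pads_per_cycle must be a positive integer, got {self.pads_per_cycle}")
        if self.path_length_m <= 0:
            raise ValueError(f"path_length_m must be > 0, got {self.path_length_m}")

    @property
    def wavelength_mm(self) -> float:
        return wavelength(self)

    @property
    def phase_step_deg(self) -> float:
        """Phase shift between adjacent pads; 45 degrees for 8-pad sets."""
        return 360.0 / self.pads_per_cycle


@dataclass(frozen=True)
class WaveConfig:
    """Traveling-wave drive settings.

    Exactly one of ``wave_speed_m_s`` / ``frequency_khz`` is authoritative
    (whichever is not ``None``); the other is derived from the track
    geometry via :func:`wave_speed` / :func:`switching_frequency`.
    """

    waveform: str = "sine"
    amplitude_vpp: float = 40.0
    wave_speed_m_s: float | None = None
    frequency_khz: float | None = None

    def __post_init__(self) -> None:
        if self.waveform not in ("sine", "square"):
            raise ValueError(f"waveform must be 'sine' or 'square', got {self.waveform!r}")
        if self.amplitude_vpp <= 0:
            raise ValueError(f"amplitude_vpp must be > 0, got {self.amplitude_vpp}")
        if (self.wave_speed_m_s is None) == (self.frequency_khz is None):
            raise ValueError("exactly one of wave_speed_m_s / frequency_khz must be given")
        auth = self.wave_speed_m_s if self.wave_speed_m_s is not None else self.frequency_khz
        if auth < 0:
            raise ValueError("wave speed / frequency must be non-negative")

    def speed(self, geometry: TrackGeometry) -> float:
        """Wave speed in m/s for this drive on ``geometry``."""
        if self.wave_speed_m_s is not None:
            return self.wave_speed_m_s
        return wave_speed(self.frequency_khz, geometry)

    def frequency(self, geometry: TrackGeometry) -> float:
        """Waveform switching frequency in kHz on ``geometry``."""
        if self.frequency_khz is not None:
            return self.frequency_khz
        return switching_frequency(self.wave_speed_m_s, geometry)


def wavelength(geometry: TrackGeometry) -> float:
    """Spatial period of the traveling wave in mm.

    One waveform cycle is stepped across ``pads_per_cycle`` pads, so the
    wavelength is ``pad_pitch × pads_per_cycle`` (1.125 mm × 8 = 9.0 mm on
    the prototype).
    """
    return geometry.pad_pitch_mm * geometry.pads_per_cycle


def wave_speed(frequency_khz: float, geometry: TrackGeometry) -> float:
    """Traveling-wave speed in m/s for a given switching frequency in kHz.

    speed = frequency × wavelength; with kHz and mm the product is directly
    m/s (10³ · 10⁻³).  5 kHz × 9.0 mm → 45 m/s; 25 kHz → 225 m/s.
    """
    if frequency_khz < 0:
        raise ValueError(f"frequency must be >= 0, got {frequency_khz}")
    return frequency_khz * wavelength(geometry)


def switching_frequency(speed_m_s: float, geometry: TrackGeometry) -> float:
    """Inverse of :func:`wave_speed`: frequency in kHz for a wave speed in m/s."""
    if speed_m_s < 0:
        raise ValueError(f"speed must be >= 0, got {speed_m_s}")
    return speed_m_s / wavelength(geometry)


def electrode_sets(geometry: TrackGeometry) -> int:
    """Number of complete waveform sets along the path (floor division).

    A partial set at the track end is not counted. 13 m over a 9.0 mm
    wavelength gives 1444 sets per conveyor row.
    """
    return int(np.floor(geometry.path_length_m * 1000.0 / wavelength(geometry)))


def total_conveyor_pads(geometry: TrackGeometry, n_rows: int = 5) -> int:
    """Total conveyor pad count: sets × pads_per_cycle × number of rows.

    The prototype runs five parallel conveyor-pad rows per board, giving
    ~58k pads over the full track.
    """
    if n_rows < 1:
        raise ValueError(f"n_rows must be >= 1, got {n_rows}")
    return electrode_sets(geometry) * geometry.pads_per_cycle * n_rows


def waveform_potentials(
    config: WaveConfig,
    time_ms: float,
    n_electrodes: int | None = None,
    geometry: TrackGeometry | None = None,
) -> np.ndarray:
    """Instantaneous potential on each electrode of one set, in volts.

    Electrode ``i`` receives the drive waveform delayed by ``i`` phase steps,
    so the potential pattern translates one pad per ``1/(pads_per_cycle·f)``.

    sine
        ``V_i(t) = (A/2)·sin(2π f t − i·Δφ)`` — peak-to-peak span equals the
        configured amplitude.
    square
        Two-level approximation: the sign of the same phase argument selects
        ``+A/2`` or ``−A/2``, i.e. half the electrodes high and half low in
        each half-cycle, advancing one pad per switching step.
    """
    geometry = geometry or TrackGeometry()
    if n_electrodes is None:
        n_electrodes = geometry.pads_per_cycle
    if n_electrodes != geometry.pads_per_cycle:
        raise ValueError(
            f"n_electrodes ({n_electrodes}) must equal pads_per_cycle "
            f"({geometry.pads_per_cycle})"
        )
    f_khz = config.frequency(geometry)
    i = np.arange(n_electrodes)
    phase = 2.0 * np.pi * f_khz * time_ms - np.deg2rad(geometry.phase_step_deg) * i
    half = config.amplitude_vpp / 2.0
    if config.waveform == "sine":
        return half * np.sin(phase)
    # square: sign of the sine argument, mapping sin==0 to the high level
    return np.where(np.sin(phase) >= 0.0, half, -half)
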