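"""Gaussian peak fitting and ion-mobility separation metrics.

Arrival-time peaks are fitted with normal distributions (plus a constant
baseline). A locally linear time→CCS conversion between two peaks of known
CCS then expresses peak widths in CCS space, giving the CCS-based resolving
power R_p = CCS/ΔCCS. Two-peak separation quality is quantified by the
two-peak resolution R_pp, the percent valley V, and the percent CCS
difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lmfit import Model
from lmfit.models import ConstantModel, GaussianModel
from scipy.signal import find_peaks as _find_peaks
from typing import NamedTuple

from .synthetic import IMTrace

__all__ = [
    "PeakFit",
    "SeparationMetrics",
    "ValleyResult",
    "fit_peaks",
    "ccs_per_time_slope",
    "resolving_power_ccs",
    "spectrum_resolving_power",
    "two_peak_resolution",
    "percent_valley",
    "percent_ccs_difference",
    "GAUSSIAN_BASELINE_FACTOR",
]

_FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Baseline-width convention for two-peak resolution: for Gaussians the
#: baseline width is taken as 1.699 × fwhm, so that R_pp = 1.5 corresponds
#: to baseline separation (≈100% valley).
GAUSSIAN_BASELINE_FACTOR = 1.699


@dataclass
class PeakFit:
    """A fitted Gaussian arrival-time peak."""

    t_p_ms: float
    fwhm_ms: float
    height: float
    fit_r2: float = float("nan")
    assigned_ccs: float | None = None
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.converged:
            if self.fwhm_ms <= 0:
                raise ValueError(f"fwhm_ms must be > 0, got {self.fwhm_ms}")
            if self.height <= 0:
                raise ValueError(f"height must be > 0, got {self.height}")


@dataclass(frozen=True)
class SeparationMetrics:
    """Separation statistics for a peak pair within one spectrum."""

    rp_ccs: float
    rpp: float
    valley_pct: float
    delta_ccs_pct: float

    def __post_init__(self) -> None:
        for name in ("rp_ccs", "rpp", "valley_pct", "delta_ccs_pct"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if np.isfinite(self.valley_pct) and self.valley_pct > 100:
            raise ValueError("valley_pct cannot exceed 100")


class ValleyResult(NamedTuple):
    """Percent valley plus whether an interior minimum actually exists."""

    pct: float
    has_valley: bool


def _initial_guesses(
    trace: IMTrace, n_peaks: int, windows: Sequence[tuple[float, float]] | None
) -> list[tuple[float, float, float]]:
    """(center, height, sigma guess) for each requested peak."""
    t, y = trace.time_ms, trace.intensity
    dt = float(np.median(np.diff(t)))
    guesses = []
    if windows is not None:
        if len(windows) != n_peaks:
            raise ValueError("initial_windows must have one window per peak")
        for lo, hi in windows:
            m = (t >= lo) & (t <= hi)
            if not m.any():
                raise ValueError(f"window ({lo}, {hi}) contains no samples")
            i = int(np.argmax(y[m]))
            guesses.append((float(t[m][i]), float(y[m][i]), max((hi - lo) / 6.0, dt)))
        return guesses
    # prominence-ranked apex detection on the raw trace (no smoothing)
    span = float(y.max() - y.min())
    idx, props = _find_peaks(y, prominence=0.02 * span)
    if len(idx) < n_peaks:
        idx, props = _find_peaks(y, prominence=0.002 * span)
    order = np.argsort(props["prominences"])[::-1][:n_peaks]
    sel = np.sort(idx[order])
    for i in sel:
        # half-height crossing scan for a width guess
        half = y[i] / 2.0
        j = i
        while j + 1 < len(y) and y[j + 1] > half:
            j += 1
        width = max(2.0 * (t[min(j, len(t) - 1)] - t[i]), 2.0 * dt)
        guesses.append((float(t[i]), float(y[i]), width / _FWHM_SIGMA))
    while len(guesses) < n_peaks:
        guesses.append((float(t[np.argmax(y)]), float(y.max()), 5.0 * dt))
    return guesses


def fit_peaks(
    trace: IMTrace,
    n_peaks: int = 1,
    initial_windows: Sequence[tuple[float, float]] | None = None,
) -> list[PeakFit]:
    """Nonlinear least-squares fit of ``n_peaks`` Gaussians plus a constant.

    Peaks are returned sorted by centroid (ties broken by descending
    height). Per-peak goodness of fit (``fit_r2``) is the coefficient of
    determination of the full model evaluated within ±1.5 fwhm of the
    peak. A non-converged fit is returned flagged, never dropped silently.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    t, y = trace.time_ms, trace.intensity
    guesses = _initial_guesses(trace, n_peaks, initial_windows)

    model: Model = ConstantModel(prefix="bl_")
    params = model.make_params(bl_c=float(np.percentile(y, 5)))
    for k, (center, height, sigma) in enumerate(guesses):
        g = GaussianModel(prefix=f"g{k}_")
        model = model + g
        params.update(g.make_params())
        params[f"g{k}_center"].set(value=center, min=t[0] - 10, max=t[-1] + 10)
        params[f"g{k}_sigma"].set(value=sigma, min=1e-6)
        params[f"g{k}_amplitude"].set(value=height * sigma * math.sqrt(2 * math.pi), min=0)

    result = model.fit(y, params, x=t)

    peaks: list[PeakFit] = []
    best = result.best_fit
    for k in range(n_peaks):
        center = float(result.params[f"g{k}_center"].value)
        fwhm = float(result.params[f"g{k}_fwhm"].value)
        height = float(result.params[f"g{k}_height"].value)
        flags = []
        converged = bool(result.success)
        if not result.success:
            flags.append("fit did not converge")
        if height <= 0 or fwhm <= 0:
            flags.append("degenerate component (zero height or width)")
            converged = False
        m = (t >= center - 1.5 * fwhm) & (t <= center + 1.5 * fwhm)
        if m.sum() >= 3:
            ss_res = float(np.sum((y[m] - best[m]) ** 2))
            ss_tot = float(np.sum((y[m] - y[m].mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
            r2 = min(max(r2, 0.0), 1.0)
        else:
            r2 = float("nan")
            flags.append("too few samples for per-peak r2")
        peaks.append(
            PeakFit(t_p_ms=center, fwhm_ms=abs(fwhm) if fwhm else 1e-9,
                    height=abs(height) if height else 1e-9,
                    fit_r2=r2, converged=converged, flags=flags)
        )
    peaks.sort(key=lambda p: (p.t_p_ms, -p.height))
    return peaks


def _peak_ccs(peak: PeakFit, ccs: float | None) -> float:
    if ccs is None:
        ccs = peak.assigned_ccs
    if ccs is None:
        raise ValueError("peak needs a known CCS (argument or assigned_ccs)")
    return ccs


def ccs_per_time_slope(
    p1: PeakFit, p2: PeakFit, ccs1: float | None = None, ccs2: float | None = None
) -> float:
    """Local time→CCS conversion slope in Å²/ms between two known peaks.

    ``(CCS₂ − CCS₁)/(t₂ − t₁)`` — symmetric under swapping the peaks. The
    linearity is a *local* assumption, valid only across the width of a
    peak; the global arrival-time/CCS relation of a traveling-wave
    separation is nonlinear.
    """
    c1, c2 = _peak_ccs(p1, ccs1), _peak_ccs(p2, ccs2)
    dt = p2.t_p_ms - p1.t_p_ms
    if dt == 0:
        raise ZeroDivisionError("coincident centroids: slope undefined")
    return (c2 - c1) / dt


def resolving_power_ccs(peak: PeakFit, slope: float, peak_ccs: float | None = None) -> float:
    """CCS-based resolving power R_p = CCS / (|slope| · Δt_fwhm)."""
    ccs = _peak_ccs(peak, peak_ccs)
    if ccs <= 0:
        raise ValueError(f"peak CCS must be > 0, got {ccs}")
    if slope == 0:
        raise ValueError("slope must be non-zero")
    if peak.fwhm_ms <= 0:
        raise ValueError("peak width must be > 0")
    return ccs / (abs(slope) * peak.fwhm_ms)


def spectrum_resolving_power(
    peaks: Sequence[PeakFit], slope: float, ccs_values: Sequence[float] | None = None
) -> float:
    """Resolving power of a multi-peak spectrum, average-CCS convention.

    The mean CCS of the peaks is used as the numerator for each peak's
    R_p, and the reported value is the mean over peaks.
    """
    if not peaks:
        raise ValueError("need at least one peak")
    if ccs_values is None:
        ccs_values = [_peak_ccs(p, None) for p in peaks]
    mean_ccs = float(np.mean(ccs_values))
    return float(np.mean([resolving_power_ccs(p, slope, mean_ccs) for p in peaks]))


def two_peak_resolution(
    p1: PeakFit, p2: PeakFit, baseline_factor: float = GAUSSIAN_BASELINE_FACTOR
) -> float:
    """Two-peak resolution R_pp = 2·|Δt| / (factor·(fwhm₁ + fwhm₂)).

    With the Gaussian baseline-width convention (factor 1.699), R_pp = 1.5
    corresponds to baseline separation of equal Gaussians.
    """
    return 2.0 * abs(p2.t_p_ms - p1.t_p_ms) / (baseline_factor * (p1.fwhm_ms + p2.fwhm_ms))


def percent_valley(
    source: IMTrace | tuple[PeakFit, PeakFit],
    p1: PeakFit | None = None,
    p2: PeakFit | None = None,
) -> ValleyResult:
    """Percent valley between two peaks: V = 100·(1 − I_valley/I_lower_apex).

    Accepts either a measured trace plus the two fitted peaks (apexes and
    the interior minimum are read off the sampled data), or just the two
    Gaussian fits (the noiseless two-Gaussian model is evaluated on a fine
    grid). 100% means baseline-resolved; a missing interior minimum returns
    0% with ``has_valley=False``. The lower apex is the reference, which is
    conservative for unequal-abundance pairs.
    """
    if isinstance(source, IMTrace):
        if p1 is None or p2 is None:
            raise ValueError("trace input requires the two fitted peaks")
        t, y = source.time_ms, source.intensity
        pk1, pk2 = sorted((p1, p2), key=lambda p: p.t_p_ms)
        i1 = int(np.argmin(np.abs(t - pk1.t_p_ms)))
        i2 = int(np.argmin(np.abs(t - pk2.t_p_ms)))
    else:
        pk1, pk2 = sorted(source, key=lambda p: p.t_p_ms)
        lo = pk1.t_p_ms - 3 * pk1.fwhm_ms
        hi = pk2.t_p_ms + 3 * pk2.fwhm_ms
        t = np.linspace(lo, hi, 4001)
        s1, s2 = pk1.fwhm_ms / _FWHM_SIGMA, pk2.fwhm_ms / _FWHM_SIGMA
        y = pk1.height * np.exp(-0.5 * ((t - pk1.t_p_ms) / s1) ** 2) \
            + pk2.height * np.exp(-0.5 * ((t - pk2.t_p_ms) / s2) ** 2)
        i1 = int(np.argmin(np.abs(t - pk1.t_p_ms)))
        i2 = int(np.argmin(np.abs(t - pk2.t_p_ms)))
    if i2 <= i1 + 1:
        return ValleyResult(0.0, False)
    # refine apexes to the local maxima nearest the centroids
    apex1 = float(np.max(y[max(i1 - 2, 0): i1 + 3]))
    apex2 = float(np.max(y[max(i2 - 2, 0): i2 + 3]))
    interior = y[i1: i2 + 1]
    j = i1 + int(np.argmin(interior))
    # a merged (unimodal) pair has its interval minimum at an endpoint,
    # not at a true interior local minimum
    if j <= i1 or j >= i2 or y[j] > y[j - 1] or y[j] > y[j + 1]:
        return ValleyResult(0.0, False)
    valley = float(y[j])
    lower_apex = min(apex1, apex2)
    if lower_apex <= 0 or valley >= lower_apex:
        return ValleyResult(0.0, False)
    v = 100.0 * (1.0 - valley / lower_apex)
    return ValleyResult(float(np.clip(v, 0.0, 100.0)), True)


def percent_ccs_difference(ccs1: float, ccs2: float) -> float:
    """Percent CCS difference, 100·|ΔCCS| relative to the smaller value."""
    if ccs1 <= 0 or ccs2 <= 0:
        raise ValueError("CCS values must be positive")
    lo, hi = sorted((ccs1, ccs2))
    return 100.0 * (hi - lo) / lo
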