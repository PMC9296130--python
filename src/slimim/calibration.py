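"""Arrival-time → CCS calibration via reduced-CCS regression.

Reference CCS values (drift-tube measurements) are rescaled to a "reduced
CCS" that removes the ion-neutral reduced-mass and charge-state dependencies:

    CCS′ = CCS · sqrt(μ) / z,    μ = m_ion·m_gas / (m_ion + m_gas)

so that a single regression curve of CCS′ against arrival time spans ions of
differing mass and charge. Supported model families: a power law
``CCS′ = a·t^b`` and second-/third-order polynomials. Accuracy is assessed
as the signed percent CCS bias against the reference values. Polynomial
fits interpolate well but must not be extrapolated; predictions outside the
fitted time range require an explicit override.
"""

from __future__ import annotations

import json
import math
import warnings as _warnings
from dataclasses import dataclass, field as _field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ReferencePoint",
    "CalibrationModel",
    "reduced_mass",
    "reduced_ccs",
    "ccs_from_reduced",
    "fit_calibration",
    "apply_calibration",
    "ccs_bias",
    "aggregate_bias",
    "N2_MASS_DA",
]

#: Molar mass of molecular nitrogen in Da.
N2_MASS_DA = 28.0134

_KINDS = {"power": 2, "poly2": 3, "poly3": 4}  # parameters per family


def reduced_mass(m_ion: float, m_gas: float) -> float:
    """Ion-neutral reduced mass μ = m_ion·m_gas/(m_ion+m_gas), in Da."""
    if m_ion <= 0 or m_gas <= 0:
        raise ValueError("masses must be positive")
    return m_ion * m_gas / (m_ion + m_gas)


def reduced_ccs(ccs: float, mz: float, z: int, m_gas: float = N2_MASS_DA) -> float:
    """Reduced CCS: CCS·sqrt(μ)/z with the ion mass taken as mz×z."""
    if z == 0:
        raise ValueError("z must be non-zero")
    if ccs <= 0 or mz <= 0:
        raise ValueError("ccs and mz must be positive")
    mu = reduced_mass(mz * abs(z), m_gas)
    return ccs * math.sqrt(mu) / abs(z)


def ccs_from_reduced(ccs_reduced: float, mz: float, z: int, m_gas: float = N2_MASS_DA) -> float:
    """Exact inverse of :func:`reduced_ccs`."""
    if z == 0:
        raise ValueError("z must be non-zero")
    mu = reduced_mass(mz * abs(z), m_gas)
    return ccs_reduced * abs(z) / math.sqrt(mu)


@dataclass(frozen=True)
class ReferencePoint:
    """One calibrant: identity, measured arrival time, and reference CCS."""

    label: str
    mz: float
    z: int
    arrival_time_ms: float
    ccs_ref: float
    m_gas: float = N2_MASS_DA

    def __post_init__(self) -> None:
        if min(self.mz, self.arrival_time_ms, self.ccs_ref) <= 0 or self.z < 1:
            raise ValueError(f"invalid reference point {self.label!r}")

    @property
    def ccs_reduced(self) -> float:
        return reduced_ccs(self.ccs_ref, self.mz, self.z, self.m_gas)


@dataclass
class CalibrationModel:
    """A fitted reduced-CCS-vs-arrival-time model."""

    kind: str
    coefficients: tuple[float, ...]
    valid_time_range: tuple[float, float]
    r2: float
    monotone_in_range: bool = True
    provenance: dict = _field(default_factory=dict)

    def predict_reduced(self, t_ms: float | np.ndarray, extrapolate: bool = False):
        """Predicted CCS′ at arrival time(s) t_ms."""
        t = np.asarray(t_ms, dtype=float)
        lo, hi = self.valid_time_range
        if not extrapolate and (np.any(t < lo) or np.any(t > hi)):
            raise ValueError(
                f"arrival time outside calibration range [{lo:.1f}, {hi:.1f}] ms; "
                "pass extrapolate=True to override (expect high error for "
                "polynomial fits)"
            )
        if self.kind == "power":
            a, b = self.coefficients
            out = a * t ** b
        else:
            out = np.polyval(self.coefficients, t)
        return out if out.ndim else float(out)

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind,
            "coefficients": list(self.coefficients),
            "valid_time_range": list(self.valid_time_range),
            "r2": self.r2,
            "monotone_in_range": self.monotone_in_range,
            "provenance": self.provenance,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            coefficients=tuple(d["coefficients"]),
            valid_time_range=tuple(d["valid_time_range"]),
            r2=d["r2"],
            monotone_in_range=d.get("monotone_in_range", True),
            provenance=d.get("provenance", {}),
        )


def fit_calibration(
    points: Sequence[ReferencePoint], kind: str = "poly3", provenance: dict | None = None
) -> CalibrationModel:
    """Unweighted least-squares fit of CCS′ against arrival time.

    ``kind`` is ``power`` (CCS′ = a·t^b), ``poly2``, or ``poly3``. Requires
    at least one more point than the model has parameters, with strictly
    increasing arrival times. R² is computed on CCS′. A fitted curve that is
    non-monotone inside the calibration range is flagged (not an error).
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {sorted(_KINDS)}")
    n_par = _KINDS[kind]
    pts = sorted(points, key=lambda p: p.arrival_time_ms)
    t = np.array([p.arrival_time_ms for p in pts])
    if len(pts) < n_par + 1:
        raise ValueError(f"{kind} fit needs >= {n_par + 1} points, got {len(pts)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("arrival times must be strictly increasing")
    y = np.array([p.ccs_reduced for p in pts])

    if kind == "power":
        # log-log line gives the starting point for the nonlinear fit
        b0, loga0 = np.polyfit(np.log(t), np.log(y), 1)
        coef, _ = curve_fit(lambda x, a, b: a * x ** b, t, y,
                            p0=[math.exp(loga0), b0], maxfev=20000)
        pred = coef[0] * t ** coef[1]
        coefficients = (float(coef[0]), float(coef[1]))
    else:
        degree = n_par - 1
        coef = np.polyfit(t, y, degree)
        pred = np.polyval(coef, t)
        coefficients = tuple(float(c) for c in coef)

    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    model = CalibrationModel(
        kind=kind,
        coefficients=coefficients,
        valid_time_range=(float(t[0]), float(t[-1])),
        r2=min(max(r2, 0.0), 1.0) if np.isfinite(r2) else r2,
        provenance=provenance or {},
    )
    dense = np.linspace(t[0], t[-1], 512)
    deriv = np.diff(model.predict_reduced(dense))
    if np.any(deriv <= 0) and np.any(deriv >= 0) and not (np.all(deriv >= 0) or np.all(deriv <= 0)):
        model.monotone_in_range = False
        _warnings.warn(f"{kind} calibration is non-monotone inside its time range")
    return model


def apply_calibration(
    model: CalibrationModel,
    arrival_time_ms: float,
    mz: float,
    z: int,
    m_gas: float = N2_MASS_DA,
    extrapolate: bool = False,
) -> float:
    """CCS in Å² for an ion at a given arrival time under a fitted model.

    Predicts CCS′ then inverts the reduced-CCS transform for this ion's
    reduced mass and charge.
    """
    ccs_red = model.predict_reduced(arrival_time_ms, extrapolate=extrapolate)
    return ccs_from_reduced(float(ccs_red), mz, z, m_gas)


def ccs_bias(ccs_calc: float, ccs_ref: float) -> float:
    """Signed percent CCS bias: 100·(calc − ref)/ref."""
    if ccs_ref <= 0:
        raise ValueError("reference CCS must be positive")
    return 100.0 * (ccs_calc - ccs_ref) / ccs_ref


def aggregate_bias(pairs: Sequence[tuple[float, float]]) -> dict:
    """Mean absolute and mean signed percent bias over (calc, ref) pairs."""
    biases = [ccs_bias(c, r) for c, r in pairs]
    return {
        "mean_abs_bias_pct": float(np.mean(np.abs(biases))),
        "mean_signed_bias_pct": float(np.mean(biases)),
        "n": len(biases),
    }
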