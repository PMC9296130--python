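"""Ion species, adduct m/z utilities, and the tune-mix calibrant panel.

Monoisotopic masses come from :mod:`pyteomics.mass`; this module only adds
the adduct bookkeeping and the panel definitions used throughout the
package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "IonSpecies",
    "ion_mz",
    "neutral_monoisotopic_mass",
    "tune_mix_panel",
    "TUNE_MIX_MZ",
    "SYNTHETIC_TUNE_MIX_CCS",
    "PROTON_MASS",
]

#: Mass of a proton in Da (H atom minus the electron).
PROTON_MASS = 1.00727646688

_ELECTRON_MASS = 0.000548579909
#: Mass of the Na+ cation in Da.
_SODIUM_CATION = 22.98976928 - _ELECTRON_MASS

# adduct name -> (mass added to the neutral, implied charge count)
_ADDUCTS: dict[str, tuple[float, int]] = {
    "+H": (PROTON_MASS, 1),
    "+2H": (2 * PROTON_MASS, 2),
    "+Na": (_SODIUM_CATION, 1),
    "+2Na": (2 * _SODIUM_CATION, 2),
    "-H": (-PROTON_MASS, 1),
    "-2H": (-2 * PROTON_MASS, 2),
}

_FORMULA_RE = re.compile(r"^([A-Z][a-z]?\d*)+$")


@dataclass(frozen=True)
class IonSpecies:
    """A mobility-analyzed ion.

    ``ccs`` is the nitrogen collision cross section in Å² — the simulation
    ground truth for synthetic species, or a drift-tube reference value for
    real calibrants. ``neutral_mass`` is optional; when absent the ion mass
    used for transport is taken as ``mz × z`` (electron/adduct masses folded
    into m/z).
    """

    label: str
    mz: float
    z: int = 1
    ccs: float | None = None
    neutral_mass: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"mz must be > 0, got {self.mz}")
        if self.z < 1:
            raise ValueError(f"z must be >= 1, got {self.z}")
        if self.ccs is not None and self.ccs <= 0:
            raise ValueError(f"ccs must be > 0, got {self.ccs}")

    @property
    def ion_mass_da(self) -> float:
        """Mass of the charged ion in Da, as mz × z."""
        return self.mz * self.z


def neutral_monoisotopic_mass(composition: str) -> float:
    """Monoisotopic mass in Da of a peptide sequence or elemental formula.

    Strings containing a digit (e.g. ``"C18H32O16"``) are treated as
    elemental formulas; otherwise the string is read as a one-letter peptide
    sequence (residue masses plus one water).
    """
    if any(ch.isdigit() for ch in composition):
        if not _FORMULA_RE.match(composition):
            raise ValueError(f"not a valid elemental formula: {composition!r}")
        return _pmass.calculate_mass(formula=composition)
    try:
        return _pmass.calculate_mass(sequence=composition)
    except Exception as exc:  # pyteomics raises its own error type
        raise ValueError(f"unknown residue in sequence {composition!r}") from exc


def ion_mz(composition: str, adduct: str = "+H", z: int | None = None) -> float:
    """m/z (Th) of an adduct ion of a peptide or elemental composition.

    ``adduct`` is one of ``+H, +2H, +Na, +2Na, -H, -2H``; ``z`` defaults to
    the charge count implied by the adduct. Examples: ``ion_mz("SDGRG")`` →
    491.22 Th; ``ion_mz("C18H32O16", "+Na")`` → 527.16 Th.
    """
    if adduct not in _ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(_ADDUCTS)}")
    delta, implied_z = _ADDUCTS[adduct]
    if z is None:
        z = implied_z
    if z == 0:
        raise ValueError("charge z must be non-zero")
    return (neutral_monoisotopic_mass(composition) + delta) / abs(z)


#: m/z values of the eight singly charged phosphazene tune-mix ions that
#: dominate the positive-mode spectrum of the vendor tuning mixture.
TUNE_MIX_MZ: tuple[int, ...] = (622, 922, 1222, 1522, 1822, 2122, 2422, 2722)

#: SYNTHETIC nitrogen CCS ladder (Å²) for the tune-mix panel.
#:
#: These are NOT literature drift-tube values: the published reference values
#: are not redistributed here. The ladder is a smooth power law in m/z
#: (6.9 · mz^0.525, rounded to 0.1 Å²) with realistic magnitudes and strict
#: monotonicity, which is all the simulation and the calibration machinery
#: require. Supply your own table for real-data work.
SYNTHETIC_TUNE_MIX_CCS: dict[int, float] = {
    622: 202.1,
    922: 248.5,
    1222: 288.1,
    1522: 323.3,
    1822: 355.3,
    2122: 384.9,
    2422: 412.6,
    2722: 438.7,
}


def tune_mix_panel(
    ccs_table: Mapping[int, float] | Sequence[float] | None = None,
) -> list[IonSpecies]:
    """The eight-ion singly charged tune-mix panel (m/z 622…2722).

    By default each ion carries the packaged synthetic CCS ladder
    (:data:`SYNTHETIC_TUNE_MIX_CCS`). Pass ``ccs_table`` (a mapping keyed by
    nominal m/z, or a sequence aligned with :data:`TUNE_MIX_MZ`) to use
    measured reference values instead.
    """
    if ccs_table is None:
        table = SYNTHETIC_TUNE_MIX_CCS
    elif isinstance(ccs_table, Mapping):
        table = dict(ccs_table)
    else:
        if len(ccs_table) != len(TUNE_MIX_MZ):
            raise ValueError(f"need {len(TUNE_MIX_MZ)} CCS values, got {len(ccs_table)}")
        table = dict(zip(TUNE_MIX_MZ, ccs_table))
    panel = [
        IonSpecies(label=f"m/z {mz}", mz=float(mz), z=1, ccs=float(table[mz]))
        for mz in TUNE_MIX_MZ
    ]
    ccs_values = [s.ccs for s in panel]
    if any(b <= a for a, b in zip(ccs_values, ccs_values[1:])):
        raise ValueError("tune-mix CCS ladder must be strictly increasing with m/z")
    return panel
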