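"""Assay conditions, activity units, and spectrophotometric rate conversions.

Plasma butyrylcholinesterase (BChE) activity is measured photometrically:
butyrylthiocholine (BTC) hydrolysis releases thiocholine which reacts with
DTNB (Ellman assay, absorbance increase at 412 nm, ε = 16,360 M⁻¹cm⁻¹);
benzoylcholine (BzCh) hydrolysis is followed directly as an absorbance
decrease at 240 nm (Δε = 6,700 M⁻¹cm⁻¹).  One unit (U) of activity
hydrolyzes 1 µmol of substrate per minute; clinical analyzers report IU/L,
with 1 U/mL ≡ 1,000 IU/L exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class Substrate(str, Enum):
    BTC = "BTC"          # butyrylthiocholine (Ellman, 412 nm)
    BZCH = "BzCh"        # benzoylcholine (240 nm, decreasing absorbance)
    SCDTC = "SCdTC"      # succinyldithiocholine


#: Default molar extinction coefficients (M⁻¹ cm⁻¹); magnitude of the change.
DEFAULT_EXTINCTION: dict[Substrate, float] = {
    Substrate.BTC: 16_360.0,
    Substrate.BZCH: 6_700.0,
}


class UnitScale(str, Enum):
    U_PER_ML = "U_per_mL"
    IU_PER_L = "IU_per_L"


class ReferenceGroup(str, Enum):
    MEN = "men"
    WOMEN_UNDER_39 = "women_under_39"
    INFANTS = "infants"


class ActivityFlag(str, Enum):
    DEFICIENT = "deficient"
    WITHIN_INTERVAL = "within_interval"
    ABOVE_INTERVAL = "above_interval"


class InvalidConditionsError(ValueError):
    """Raised when assay conditions violate physical constraints."""


@dataclass(frozen=True)
class AssayConditions:
    """Photometric assay setup.

    Parameters
    ----------
    substrate : Substrate
        Chromogenic substrate; determines the default extinction coefficient.
    extinction_coeff : float, optional
        |Δε| in M⁻¹cm⁻¹.  Defaults per substrate (BTC 16,360; BzCh 6,700);
        must be supplied explicitly for SCdTC.
    pathlength_cm : float
        Cuvette path length, cm.
    dilution_factor : float
        Total assay volume / plasma volume (≥ 1).  Supplied by the caller;
        :func:`dilution_factor_from_volumes` can compute it when all pipetted
        volumes are known.
    """

    substrate: Substrate
    extinction_coeff: float | None = None
    pathlength_cm: float = 1.0
    dilution_factor: float = 1.0
    temperature_c: float = 25.0
    wavelength_nm: float | None = None
    buffer_descr: str = ""

    def __post_init__(self) -> None:
        substrate = Substrate(self.substrate)
        object.__setattr__(self, "substrate", substrate)
        eps = self.extinction_coeff
        if eps is None:
            eps = DEFAULT_EXTINCTION.get(substrate)
            if eps is None:
                raise InvalidConditionsError(
                    f"no default extinction coefficient for {substrate.value}; "
                    "supply extinction_coeff explicitly"
                )
            object.__setattr__(self, "extinction_coeff", eps)
        if not (eps > 0 and math.isfinite(eps)):
            raise InvalidConditionsError("extinction_coeff must be positive")
        if not (self.pathlength_cm > 0 and math.isfinite(self.pathlength_cm)):
            raise InvalidConditionsError("pathlength_cm must be positive")
        if not self.dilution_factor >= 1:
            raise InvalidConditionsError("dilution_factor must be >= 1")


def dilution_factor_from_volumes(plasma_ul: float, *other_volumes_ul: float) -> float:
    """Total assay volume over plasma volume, all in µL."""
    if plasma_ul <= 0:
        raise InvalidConditionsError("plasma volume must be positive")
    if any(v < 0 for v in other_volumes_ul):
        raise InvalidConditionsError("assay volumes must be nonnegative")
    return (plasma_ul + sum(other_volumes_ul)) / plasma_ul


@dataclass(frozen=True)
class ActivityValue:
    """Enzyme activity with an explicit unit scale (1 U/mL = 1,000 IU/L).

    Conversions remember the originally constructed (value, unit) pair, so
    converting away and back returns the original value bit-exactly even
    where a multiply/divide pair by 1,000 would round.
    """

    value: float
    unit: UnitScale = UnitScale.U_PER_ML
    _origin: tuple | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", UnitScale(self.unit))
        if not (self.value >= 0 and math.isfinite(self.value)):
            raise ValueError("activity must be finite and nonnegative")

    def to(self, target: UnitScale | str) -> "ActivityValue":
        target = UnitScale(target)
        if target == self.unit:
            return self
        origin = self._origin or (self.value, self.unit)
        if origin[1] == target:
            return ActivityValue(origin[0], target)
        if target == UnitScale.IU_PER_L:
            return ActivityValue(self.value * 1000.0, target, _origin=origin)
        return ActivityValue(self.value / 1000.0, target, _origin=origin)

    @property
    def iu_per_l(self) -> float:
        return self.to(UnitScale.IU_PER_L).value

    @property
    def u_per_ml(self) -> float:
        return self.to(UnitScale.U_PER_ML).value


def convert_activity(a: ActivityValue, target: UnitScale | str) -> ActivityValue:
    """Exact scale conversion between U/mL and IU/L (round-trip identity)."""
    return a.to(target)


def rate_from_slope(slope: float, conditions: AssayConditions) -> ActivityValue:
    """Convert an absorbance slope (A/min) to plasma activity in U/mL.

    Beer–Lambert: the in-cuvette hydrolysis rate is |slope| / (ε·l) in M/min;
    multiplying by the dilution factor refers it back to undiluted plasma.
    1 M/min referred to plasma equals 1,000 µmol·min⁻¹·mL⁻¹ = 1,000 U/mL.
    For decreasing-absorbance assays (BzCh at 240 nm) the caller passes the
    slope magnitude; the sign is discarded either way.
    """
    if not math.isfinite(slope):
        raise ValueError("slope must be finite")
    molar_per_min = abs(slope) / (conditions.extinction_coeff * conditions.pathlength_cm)
    u_per_ml = molar_per_min * 1000.0 * conditions.dilution_factor
    return ActivityValue(u_per_ml, UnitScale.U_PER_ML)


@dataclass(frozen=True)
class ReferenceInterval:
    """Healthy-population activity interval (IU/L); endpoints inclusive."""

    group: ReferenceGroup
    low: float
    high: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", ReferenceGroup(self.group))
        if not self.low < self.high:
            raise ValueError("reference interval requires low < high")


#: Reference intervals for plasma BChE on an automated analyzer (IU/L).
REFERENCE_INTERVALS: dict[ReferenceGroup, ReferenceInterval] = {
    ReferenceGroup.MEN: ReferenceInterval(ReferenceGroup.MEN, 5_320.0, 12_920.0),
    ReferenceGroup.WOMEN_UNDER_39: ReferenceInterval(
        ReferenceGroup.WOMEN_UNDER_39, 4_260.0, 11_250.0
    ),
    ReferenceGroup.INFANTS: ReferenceInterval(ReferenceGroup.INFANTS, 2_260.0, 6_460.0),
}


def flag_deficiency(a: ActivityValue, group: ReferenceGroup | str) -> ActivityFlag:
    """Flag an activity against the group's reference interval.

    Boundary values count as within the interval (inclusive clinical ranges).
    """
    try:
        interval = REFERENCE_INTERVALS[ReferenceGroup(group)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown reference group: {group!r}") from exc
    x = a.iu_per_l
    if x < interval.low:
        return ActivityFlag.DEFICIENT
    if x > interval.high:
        return ActivityFlag.ABOVE_INTERVAL
    return ActivityFlag.WITHIN_INTERVAL
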