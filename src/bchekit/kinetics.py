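"""Steady-state rate laws for cholinesterase substrate hydrolysis.

Human BChE shows non-Michaelian kinetics with positively charged substrates:
besides the catalytic site, a second substrate molecule can occupy the
peripheral anionic site (PAS), forming a ternary substrate–enzyme–substrate
complex with dissociation constant K_ss whose turnover is modulated by the
dimensionless factor ``b``:

    v(S) = Vmax · S/(Km + S) · (1 + b·S/Kss) / (1 + S/Kss)

``b > 1`` is substrate activation (BTC on the usual enzyme), ``b < 1`` is
inhibition by excess substrate (BzCh), and ``b = 1`` — or no PAS binding at
all, Kss = ∞ — reduces the law to simple Michaelis–Menten kinetics.  The
Michaelis constant decomposes over the acyl-enzyme scheme as
Km = Ks·k3/(k2+k3) with Ks = k₋₁/k₁, and kcat = Vmax/[E] for active-site
concentration [E].

Heterozygous plasma contains hybrid tetramers assembled from two subunit
kinds; initial rates of such mixtures superpose linearly by species fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "KineticParameters",
    "MechanisticRates",
    "SpeciesMixture",
    "rate_two_site",
    "rate_michaelis",
    "rate_mixture",
    "km_from_mechanism",
    "kcat_from_vmax",
]


@dataclass(frozen=True)
class KineticParameters:
    """The quartet (Vmax, Km, Kss, b) defining one enzyme species' rate law.

    Units as conventionally tabulated: Vmax in U/mL (plasma-referred),
    Km in µM, Kss in mM, b dimensionless.  ``kss_mm = inf`` encodes
    "no peripheral-site binding", distinct from ``b = 1``.
    """

    vmax: float                 # U/mL
    km_um: float                # µM
    kss_mm: float = math.inf    # mM; inf = no PAS binding
    b: float = 1.0

    def __post_init__(self) -> None:
        if not self.vmax > 0:
            raise ValueError("Vmax must be positive")
        if not self.km_um > 0:
            raise ValueError("Km must be positive")
        if not self.kss_mm > 0:
            raise ValueError("Kss must be positive (use inf for no PAS binding)")
        if not self.b > 0:
            raise ValueError("b must be positive")

    @property
    def is_michaelian(self) -> bool:
        """True when the law coincides with Michaelis–Menten at every S."""
        return self.b == 1.0 or math.isinf(self.kss_mm)

    def to_dict(self) -> dict:
        return {
            "vmax": {"value": self.vmax, "unit": "U/mL"},
            "km": {"value": self.km_um, "unit": "uM"},
            "kss": {"value": None if math.isinf(self.kss_mm) else self.kss_mm,
                    "unit": "mM"},
            "b": {"value": self.b, "unit": ""},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        kss = d["kss"]["value"] if "kss" in d else None
        return cls(
            vmax=d["vmax"]["value"],
            km_um=d["km"]["value"],
            kss_mm=math.inf if kss is None else kss,
            b=d.get("b", {"value": 1.0})["value"],
        )


def _as_nonnegative_array(S) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be nonnegative")
    return S


def rate_michaelis(S, vmax: float, km_um: float):
    """Michaelis–Menten rate v = Vmax·S/(Km+S); S in µM, v in U/mL."""
    S = _as_nonnegative_array(S)
    out = vmax * S / (km_um + S)
    return out if out.ndim else float(out)


def rate_two_site(S, p: KineticParameters):
    """Two-site substrate-modulation rate law; S in µM, v in U/mL.

    v = 0 at S = 0 and v → b·Vmax as S → ∞.  With b = 1 or Kss = ∞ the
    modulation factor is identically 1 and the Michaelian value is returned.
    """
    S = _as_nonnegative_array(S)
    core = p.vmax * S / (p.km_um + S)
    if p.is_michaelian:
        out = core
    else:
        kss_um = p.kss_mm * 1000.0
        out = core * (1.0 + p.b * S / kss_um) / (1.0 + S / kss_um)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SpeciesMixture:
    """Linear mixture of enzyme species (e.g. hybrid heterozygote tetramers)."""

    components: tuple[tuple[float, KineticParameters], ...]

    def __post_init__(self) -> None:
        comps = tuple((float(f), p) for f, p in self.components)
        if not comps:
            raise ValueError("mixture must have at least one component")
        if any(f < 0 for f, _ in comps):
            raise ValueError("mixture fractions must be nonnegative")
        if abs(sum(f for f, _ in comps) - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")
        object.__setattr__(self, "components", comps)


def rate_mixture(S, mix: SpeciesMixture):
    """Fraction-weighted sum of component rates; single component reduces
    to :func:`rate_two_site`."""
    S = _as_nonnegative_array(S)
    out = sum(f * np.asarray(rate_two_site(S, p)) for f, p in mix.components)
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MechanisticRates:
    """Elementary rate constants of the acyl-enzyme scheme.

    k1 (µM⁻¹min⁻¹) and k_minus1 (min⁻¹) govern substrate binding with
    Ks = k₋₁/k₁; k2 and k3 (min⁻¹) are acylation and deacylation.
    """

    k1: float
    k_minus1: float
    k2: float
    k3: float
    ks_um: float | None = None
    e_conc_nm: float | None = None

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "k2", "k3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        implied = self.k_minus1 / self.k1
        if self.ks_um is None:
            object.__setattr__(self, "ks_um", implied)
        elif abs(self.ks_um - implied) / self.ks_um >= 1e-9:
            raise ValueError("Ks inconsistent with k_minus1/k1")
        if self.e_conc_nm is not None and not self.e_conc_nm > 0:
            raise ValueError("active-site concentration must be positive")


def km_from_mechanism(m: MechanisticRates) -> float:
    """Km (µM) from the acyl-enzyme scheme: Km = Ks·k3/(k2+k3).

    Deacylation-limited (k2 → 0) gives Km → Ks; k2 = k3 gives Ks/2.
    """
    return m.ks_um * m.k3 / (m.k2 + m.k3)


def kcat_from_vmax(vmax_u_per_ml: float, e_conc_nm: float) -> float:
    """Turnover number kcat = Vmax/[E] in min⁻¹.

    Vmax in U/mL equals 10⁻³ mol·L⁻¹·min⁻¹; [E] in nM equals 10⁻⁹ mol·L⁻¹,
    so kcat = Vmax/[E] · 10⁶ min⁻¹.
    """
    if not e_conc_nm > 0:
        raise ValueError("active-site concentration must be positive")
    if vmax_u_per_ml < 0:
        raise ValueError("Vmax must be nonnegative")
    return vmax_u_per_ml / e_conc_nm * 1.0e6
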