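"""Dibucaine/fluoride inhibition numbers and BChE phenotype classification.

The classical phenotyping assay measures hydrolysis of 50 µM benzoylcholine
with and without a fixed inhibitor concentration (10 µM dibucaine or 50 µM
sodium fluoride).  The inhibition number is the percent inhibition,
100·(1 − vi/v0): the usual enzyme gives dibucaine numbers near 80, the
atypical (p.Asp70Gly) enzyme near 5–10, and heterozygotes fall in between.

Classification bands (DN thresholds 70/40/30) follow classical
cholinesterase phenotyping practice; printed family/control exemplars
bracket the bands but do not themselves define decision boundaries.  A
usual/silent heterozygote is not separable from usual/usual by DN alone —
both land in the "usual" band and the call's rationale records the
ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .assay import ActivityFlag
from .kinetics import rate_michaelis

__all__ = [
    "Inhibitor",
    "InhibitionAssay",
    "PhenotypeLabel",
    "PhenotypeCall",
    "inhibition_number",
    "competitive_inhibited_rate",
    "classify_phenotype",
    "CANONICAL_INHIBITOR_CONC_UM",
]


class Inhibitor(str, Enum):
    DIBUCAINE = "dibucaine"
    FLUORIDE = "fluoride"


#: Fixed inhibitor concentrations of the classical assays (µM).
CANONICAL_INHIBITOR_CONC_UM: dict[Inhibitor, float] = {
    Inhibitor.DIBUCAINE: 10.0,
    Inhibitor.FLUORIDE: 50.0,
}

#: Noise tolerance: vi may exceed v0 by at most this relative excess.
VI_EXCESS_TOLERANCE = 0.05


class DataQualityError(ValueError):
    """Inhibited rate exceeds the uninhibited rate beyond noise tolerance."""


@dataclass(frozen=True)
class InhibitionAssay:
    """Paired uninhibited/inhibited BzCh hydrolysis rates for one inhibitor."""

    inhibitor: Inhibitor
    v0: float                       # U/mL, uninhibited
    vi: float                       # U/mL, inhibited
    inhibitor_conc_um: float | None = None
    substrate: str = "BzCh"
    substrate_conc_um: float = 50.0

    def __post_init__(self) -> None:
        inhibitor = Inhibitor(self.inhibitor)
        object.__setattr__(self, "inhibitor", inhibitor)
        if self.inhibitor_conc_um is None:
            object.__setattr__(
                self, "inhibitor_conc_um", CANONICAL_INHIBITOR_CONC_UM[inhibitor]
            )
        if self.inhibitor_conc_um < 0:
            raise ValueError("inhibitor concentration must be nonnegative")
        if not self.v0 > 0:
            raise ValueError("uninhibited rate v0 must be positive")
        if self.vi < 0:
            raise ValueError("inhibited rate vi must be nonnegative")
        if self.vi > self.v0 * (1 + VI_EXCESS_TOLERANCE):
            raise DataQualityError(
                f"vi = {self.vi:g} exceeds v0 = {self.v0:g} beyond the "
                f"{VI_EXCESS_TOLERANCE:.0%} noise tolerance"
            )


def inhibition_number(a: InhibitionAssay) -> float:
    """Percent inhibition 100·(1 − vi/v0), clamped to [0, 100].

    Antitone in vi and invariant to common rescaling of (v0, vi); a vi
    marginally above v0 (within the assay noise tolerance) clamps to 0.
    """
    return float(min(max(100.0 * (1.0 - a.vi / a.v0), 0.0), 100.0))


def competitive_inhibited_rate(
    s_um: float, i_um: float, vmax: float, km_um: float, ki_um: float
):
    """Michaelian rate under competitive inhibition.

    v = Vmax·S / (Km·(1 + I/Ki) + S); I = 0 recovers the uninhibited rate.
    Used as the forward model when synthesizing inhibition assay pairs.
    """
    if not ki_um > 0:
        raise ValueError("Ki must be positive")
    if i_um < 0:
        raise ValueError("inhibitor concentration must be nonnegative")
    return rate_michaelis(s_um, vmax, km_um * (1.0 + i_um / ki_um))


class PhenotypeLabel(str, Enum):
    USUAL = "usual"
    HETEROZYGOUS_ATYPICAL_OR_SILENT = "heterozygous_atypical_or_silent"
    ATYPICAL_HOMOZYGOUS_LIKE = "atypical_homozygous_like"
    ATYPICAL_SILENT_LIKE = "atypical_silent_like"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PhenotypeCall:
    label: PhenotypeLabel
    dn: float
    fn: float
    activity_flag: ActivityFlag
    rationale: str

    def to_dict(self) -> dict:
        return {
            "label": self.label.value,
            "dn": {"value": self.dn, "unit": "%"},
            "fn": {"value": self.fn, "unit": "%"},
            "activity_flag": self.activity_flag.value,
            "rationale": self.rationale,
        }


#: Published family/control exemplars (genotype, DN %, FN %) used only to
#: annotate the rationale string of a call.
_EXEMPLARS: tuple[tuple[str, float, float], ...] = (
    ("UU (usual/usual control)", 78.8, 52.1),
    ("US (usual/silent father)", 75.3, 51.6),
    ("AKU (usual/atypical-K mother)", 58.3, 42.6),
    ("AKS (atypical-K/silent proband)", 7.2, 15.7),
    ("AA (atypical homozygous control)", 5.1, 13.0),
    ("AS (atypical/silent control)", 11.1, 15.0),
)

DN_USUAL_MIN = 70.0
DN_HETEROZYGOUS_MIN = 40.0
DN_ATYPICAL_MAX = 30.0


def _nearest_exemplar(dn: float, fn: float) -> str:
    name, _, _ = min(_EXEMPLARS, key=lambda e: (e[1] - dn) ** 2 + (e[2] - fn) ** 2)
    return name


def classify_phenotype(
    dn: float, fn: float, activity_flag: ActivityFlag | str
) -> PhenotypeCall:
    """Deterministic band lookup on (DN, activity flag).

    DN ≥ 70 → usual (note: usual/silent heterozygotes are indistinguishable
    from usual homozygotes by DN and land here too); 40 ≤ DN < 70 →
    heterozygous atypical-or-silent; DN < 30 with deficient activity →
    atypical+silent-like; DN < 30 otherwise → atypical-homozygous-like;
    the 30–40 gap is indeterminate.
    """
    if not (0.0 <= dn <= 100.0) or not (0.0 <= fn <= 100.0):
        raise ValueError("DN and FN must lie in [0, 100]")
    flag = ActivityFlag(activity_flag)
    exemplar = _nearest_exemplar(dn, fn)
    if dn >= DN_USUAL_MIN:
        label = PhenotypeLabel.USUAL
        note = (
            "DN in the usual band; a usual/silent heterozygote is not "
            "separable from usual/usual by DN alone"
        )
    elif dn >= DN_HETEROZYGOUS_MIN:
        label = PhenotypeLabel.HETEROZYGOUS_ATYPICAL_OR_SILENT
        note = "DN in the heterozygous band"
    elif dn < DN_ATYPICAL_MAX:
        if flag == ActivityFlag.DEFICIENT:
            label = PhenotypeLabel.ATYPICAL_SILENT_LIKE
            note = "DN in the atypical band with deficient activity"
        else:
            label = PhenotypeLabel.ATYPICAL_HOMOZYGOUS_LIKE
            note = "DN in the atypical band without activity deficiency"
    else:
        label = PhenotypeLabel.INDETERMINATE
        note = "DN between the atypical and heterozygous bands"
    rationale = (
        f"{note}; nearest published exemplar: {exemplar} "
        f"(observed DN {dn:.1f}%, FN {fn:.1f}%, activity {flag.value})"
    )
    return PhenotypeCall(label=label, dn=dn, fn=fn, activity_flag=flag,
                         rationale=rationale)
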