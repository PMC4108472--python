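"""Synthetic plasma-assay generator with genotype-labeled ground truth.

Every input the analysis pipeline consumes can be synthesized here: BTC
saturation curves over the standard 10 µM–50 mM design, paired
uninhibited/inhibited BzCh rates for dibucaine and fluoride numbers, and
automated-analyzer activities (IU/L) — all from a registry of genotype
profiles (UU, US, AKU, AKS, AA, AS) whose BTC kinetics mirror published
family/control parameter sets.

Measurement noise is multiplicative Gaussian (default CV 3%, consistent
with few-percent duplicate scatter in clinical cholinesterase assays).
Dibucaine/fluoride Ki values are calibrated analytically per genotype so
the noiseless inhibition pair reproduces the profile's target DN/FN
exactly; they are generator constants, not published measurements.  All
randomness descends from a single integer seed through per-assay
substreams, so any panel regenerates bit-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .assay import ActivityValue, ReferenceGroup, UnitScale
from .fitting import RateCurve
from .kinetics import KineticParameters, SpeciesMixture, rate_mixture, rate_two_site
from .phenotype import (
    CANONICAL_INHIBITOR_CONC_UM,
    InhibitionAssay,
    Inhibitor,
    PhenotypeLabel,
    competitive_inhibited_rate,
)

__all__ = [
    "GenotypeProfile",
    "SyntheticPanel",
    "load_registry",
    "default_design",
    "calibrate_ki",
    "generate_rate_curve",
    "generate_inhibition_pair",
    "generate_panel",
    "generate_family_panel",
    "DEFAULT_FAMILY",
    "DEFAULT_NOISE_CV",
]

DEFAULT_NOISE_CV = 0.03
#: Proband, father, mother — the pedigree's three sampled individuals.
DEFAULT_FAMILY = ("AKS", "US", "AKU")

BZCH_ASSAY_S_UM = 50.0


def calibrate_ki(km_um: float, dn_target: float, inhibitor_conc_um: float,
                 s_um: float = BZCH_ASSAY_S_UM) -> float:
    """Ki (µM) such that the competitive model yields exactly ``dn_target``.

    Inverting 1 − vi/v0 = dn/100 for the competitive law at substrate S and
    inhibitor I gives Ki = Km·I·f / ((Km + S)(1 − f)) with f = 1 − dn/100.
    """
    if not 0 < dn_target < 100:
        raise ValueError("dn_target must be strictly inside (0, 100)")
    f = 1.0 - dn_target / 100.0
    return km_um * inhibitor_conc_um * f / ((km_um + s_um) * (1.0 - f))


@dataclass(frozen=True)
class GenotypeProfile:
    """Generative ground truth for one genotype's plasma panel."""

    name: str
    description: str
    btc: KineticParameters | SpeciesMixture
    bzch_vmax: float            # U/mL
    bzch_km_um: float
    ki_dibucaine_um: float
    ki_fluoride_um: float
    dn_target: float
    fn_target: float
    analyzer_activity_iu_l: float
    reference_group: ReferenceGroup
    expected_label: PhenotypeLabel

    def btc_rate(self, s_um):
        if isinstance(self.btc, SpeciesMixture):
            return rate_mixture(s_um, self.btc)
        return rate_two_site(s_um, self.btc)

    def bzch_rate(self, s_um=BZCH_ASSAY_S_UM):
        from .kinetics import rate_michaelis

        return rate_michaelis(s_um, self.bzch_vmax, self.bzch_km_um)


def _profile_from_record(name: str, rec: dict) -> GenotypeProfile:
    btc = rec["btc"]
    params = KineticParameters(
        vmax=btc["vmax"],
        km_um=btc["km_um"],
        kss_mm=math.inf if btc.get("kss_mm") is None else btc["kss_mm"],
        b=btc.get("b", 1.0),
    )
    v50, km_bzch = rec["bzch"]["v50"], rec["bzch"]["km_um"]
    # BzCh Vmax back-solved so the uninhibited 50 µM rate equals v50
    bzch_vmax = v50 * (km_bzch + BZCH_ASSAY_S_UM) / BZCH_ASSAY_S_UM
    return GenotypeProfile(
        name=name,
        description=rec.get("description", ""),
        btc=params,
        bzch_vmax=bzch_vmax,
        bzch_km_um=km_bzch,
        ki_dibucaine_um=calibrate_ki(
            km_bzch, rec["dn_target"],
            CANONICAL_INHIBITOR_CONC_UM[Inhibitor.DIBUCAINE],
        ),
        ki_fluoride_um=calibrate_ki(
            km_bzch, rec["fn_target"],
            CANONICAL_INHIBITOR_CONC_UM[Inhibitor.FLUORIDE],
        ),
        dn_target=rec["dn_target"],
        fn_target=rec["fn_target"],
        analyzer_activity_iu_l=rec["analyzer_activity_iu_l"],
        reference_group=ReferenceGroup(rec["reference_group"]),
        expected_label=PhenotypeLabel(rec["expected_label"]),
    )


def load_registry(path=None) -> dict[str, GenotypeProfile]:
    """Load the genotype registry (shipped JSON by default, editable copy
    via ``path``)."""
    if path is None:
        text = (
            resources.files("bchekit").joinpath("data/genotypes.json").read_text()
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = json.loads(text)
    return {
        name: _profile_from_record(name, rec)
        for name, rec in raw.items()
        if not name.startswith("_")
    }


_REGISTRY: dict[str, GenotypeProfile] | None = None


def get_profile(name: str) -> GenotypeProfile:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_registry()
    try:
        return _REGISTRY[name]
    except KeyError as exc:
        raise KeyError(
            f"unknown genotype {name!r}; known: {sorted(_REGISTRY)}"
        ) from exc


def default_design(n: int = 12, low_um: float = 10.0,
                   high_um: float = 50_000.0) -> np.ndarray:
    """Log-spaced BTC design spanning the standard 10 µM–50 mM range."""
    return np.geomspace(low_um, high_um, n)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_rate_curve(
    p: KineticParameters | SpeciesMixture,
    design=None,
    noise_cv: float = DEFAULT_NOISE_CV,
    replicates: int = 3,
    seed=0,
    label: str = "",
) -> RateCurve:
    """Simulate a saturation curve: v = v_true·(1 + ε), ε ~ N(0, noise_cv).

    Noise is independent per point and replicate; negative draws clamp to 0.
    With ``noise_cv = 0`` the curve equals the closed-form law exactly.
    """
    design = default_design() if design is None else np.asarray(design, float)
    if design.size == 0:
        raise ValueError("design must contain at least one concentration")
    if np.any(design < 1.0) or np.any(design > 1.0e6):
        raise ValueError("design concentrations must lie in [1, 1e6] µM")
    if not 0.0 <= noise_cv <= 0.2:
        raise ValueError("noise_cv must lie in [0, 0.2]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = _rng(seed)
    if isinstance(p, SpeciesMixture):
        v_true = np.asarray(rate_mixture(design, p))
    else:
        v_true = np.asarray(rate_two_site(design, p))
    # order: all replicates of point 0, then point 1, ... (stable layout)
    s = np.repeat(design, replicates)
    rep = np.tile(np.arange(replicates), design.size)
    v_true_rep = np.repeat(v_true, replicates)
    eps = rng.normal(0.0, noise_cv, size=s.size) if noise_cv > 0 else 0.0
    v = np.clip(v_true_rep * (1.0 + eps), 0.0, None)
    return RateCurve(s_um=s, v=v, replicate=rep, label=label)


def generate_inhibition_pair(
    profile: GenotypeProfile,
    inhibitor: Inhibitor | str,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed=0,
    inhibitor_conc_um: float | None = None,
) -> InhibitionAssay:
    """Simulate one paired BzCh assay (uninhibited v0, inhibited vi).

    v0 comes from the profile's Michaelian BzCh rate at 50 µM; vi from the
    competitive forward model at the canonical inhibitor concentration with
    the profile's calibrated Ki.  Noise is multiplicative as for curves; a
    noisy vi is capped at the assay's tolerance bound (1.05·v0) so that
    extreme draws cannot produce an invalid assay.
    """
    inhibitor = Inhibitor(inhibitor)
    ki = (
        profile.ki_dibucaine_um
        if inhibitor == Inhibitor.DIBUCAINE
        else profile.ki_fluoride_um
    )
    if not math.isfinite(ki) or ki <= 0:
        raise ValueError(f"profile {profile.name} lacks a calibrated Ki")
    conc = (
        CANONICAL_INHIBITOR_CONC_UM[inhibitor]
        if inhibitor_conc_um is None
        else inhibitor_conc_um
    )
    if conc < 0:
        raise ValueError("inhibitor concentration must be nonnegative")
    rng = _rng(seed)
    v0_true = profile.bzch_rate()
    vi_true = competitive_inhibited_rate(
        BZCH_ASSAY_S_UM, conc, profile.bzch_vmax, profile.bzch_km_um, ki
    )
    if noise_cv > 0:
        v0 = max(v0_true * (1.0 + rng.normal(0.0, noise_cv)), 1e-12)
        vi = max(vi_true * (1.0 + rng.normal(0.0, noise_cv)), 0.0)
        vi = min(vi, v0 * 1.05)
    else:
        v0, vi = v0_true, vi_true
    return InhibitionAssay(
        inhibitor=inhibitor, v0=v0, vi=vi, inhibitor_conc_um=conc
    )


@dataclass(frozen=True)
class SyntheticPanel:
    """One individual's generated bundle, with full generative truth attached."""

    genotype: str
    curve: RateCurve
    dibucaine_assay: InhibitionAssay
    fluoride_assay: InhibitionAssay
    analyzer_activity: ActivityValue
    reference_group: ReferenceGroup
    seed: int
    truth: dict

    def to_dict(self) -> dict:
        return {
            "genotype": self.genotype,
            "curve": {
                "S_uM": self.curve.s_um.tolist(),
                "rate_U_per_mL": self.curve.v.tolist(),
                "replicate": self.curve.replicate.tolist(),
                "label": self.curve.label,
            },
            "dibucaine_assay": _assay_dict(self.dibucaine_assay),
            "fluoride_assay": _assay_dict(self.fluoride_assay),
            "analyzer_activity": {
                "value": self.analyzer_activity.value,
                "unit": self.analyzer_activity.unit.value,
            },
            "reference_group": self.reference_group.value,
            "seed": self.seed,
            "truth": self.truth,
        }


def _assay_dict(a: InhibitionAssay) -> dict:
    return {
        "inhibitor": a.inhibitor.value,
        "inhibitor_conc_uM": a.inhibitor_conc_um,
        "substrate": a.substrate,
        "substrate_conc_uM": a.substrate_conc_um,
        "v0_U_per_mL": a.v0,
        "vi_U_per_mL": a.vi,
    }


def generate_panel(
    genotype: str | GenotypeProfile,
    seed: int = 0,
    noise_cv: float = DEFAULT_NOISE_CV,
    design=None,
    replicates: int = 3,
) -> SyntheticPanel:
    """Generate one individual's full panel from a genotype profile.

    Per-assay randomness descends from ``seed`` through spawned substreams,
    so regeneration from (genotype, seed, design) is bit-identical.
    """
    profile = genotype if isinstance(genotype, GenotypeProfile) else get_profile(genotype)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(4)]
    curve = generate_rate_curve(
        profile.btc, design=design, noise_cv=noise_cv,
        replicates=replicates, seed=streams[0], label=profile.name,
    )
    dib = generate_inhibition_pair(
        profile, Inhibitor.DIBUCAINE, noise_cv=noise_cv, seed=streams[1]
    )
    fluo = generate_inhibition_pair(
        profile, Inhibitor.FLUORIDE, noise_cv=noise_cv, seed=streams[2]
    )
    act_true = profile.analyzer_activity_iu_l
    if noise_cv > 0:
        act = max(act_true * (1.0 + streams[3].normal(0.0, noise_cv)), 0.0)
    else:
        act = act_true
    btc = profile.btc
    truth = {
        "genotype": profile.name,
        "btc_params": btc.to_dict() if isinstance(btc, KineticParameters) else {
            "mixture": [
                {"fraction": f, "params": p.to_dict()} for f, p in btc.components
            ]
        },
        "bzch": {"vmax_U_per_mL": profile.bzch_vmax, "km_uM": profile.bzch_km_um},
        "ki_uM": {
            "dibucaine": profile.ki_dibucaine_um,
            "fluoride": profile.ki_fluoride_um,
        },
        "dn_target": profile.dn_target,
        "fn_target": profile.fn_target,
        "analyzer_activity_iu_l": act_true,
        "expected_label": profile.expected_label.value,
        "noise_cv": noise_cv,
    }
    return SyntheticPanel(
        genotype=profile.name,
        curve=curve,
        dibucaine_assay=dib,
        fluoride_assay=fluo,
        analyzer_activity=ActivityValue(act, UnitScale.IU_PER_L),
        reference_group=profile.reference_group,
        seed=seed,
        truth=truth,
    )


def generate_family_panel(
    genotypes=DEFAULT_FAMILY, seed: int = 0, noise_cv: float = DEFAULT_NOISE_CV
) -> list[SyntheticPanel]:
    """One panel per family member (default: proband AKS, father US,
    mother AKU), with independent per-individual substreams."""
    genotypes = tuple(genotypes)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(genotypes))
    panels = []
    for name, child in zip(genotypes, child_seeds):
        panels.append(generate_panel(name, seed=int(child) % (2**31), noise_cv=noise_cv))
    return panels
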