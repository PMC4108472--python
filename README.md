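# bchekit

Butyrylcholinesterase (BChE) deficiency toolkit: kinetic curve fitting,
dibucaine/fluoride phenotyping, and synthetic plasma-assay simulation.

## The problem

Plasma BChE hydrolyzes the muscle relaxant suxamethonium; patients with
deficient variants suffer prolonged apnea after anesthesia. The clinical
workup combines three measurements:

- **activity** on an automated analyzer (IU/L), flagged against reference
  intervals (men 5,320–12,920; women under 39 4,260–11,250; infants
  2,260–6,460 IU/L);
- **inhibition numbers** — the percent inhibition of 50 µM benzoylcholine
  (BzCh) hydrolysis by 10 µM dibucaine (DN) or 50 µM fluoride (FN), which
  separate usual from atypical enzyme;
- **kinetics** of butyrylthiocholine (BTC) hydrolysis over 10 µM–50 mM
  (Ellman assay, ε₄₁₂ = 16,360 M⁻¹cm⁻¹).

BChE binds a second BTC molecule at its peripheral anionic site (PAS),
so the saturation curve follows the two-site substrate-modulation law

```
v(S) = Vmax · S/(Km + S) · (1 + b·S/Kss) / (1 + S/Kss)
```

where `Kss` is the dissociation constant of the ternary
substrate–enzyme–substrate complex and `b` multiplies turnover when the PAS
is occupied: `b > 1` is substrate activation (usual enzyme with BTC,
b ≈ 3.2), `b < 1` inhibition by excess substrate, and `b = 1` collapses the
law to Michaelis–Menten — the signature of a PAS-dead or silent-subunit
enzyme. `bchekit` implements this law, scikit-learn-style nonlinear
estimators with nested model selection (extra-sum-of-squares F-test),
inhibition-number phenotype bands, Ellman unit conversions, and a seeded
generator of complete synthetic plasma panels for six genotypes
(UU, US, AKU, AKS, AA, AS).

## Worked example

Simulate the proband-like AKS panel (atypical-Kalow/silent compound
heterozygote), fit it, and phenotype it:

```bash
bchekit simulate --genotype AKS --seed 1 --out demo
bchekit fit --in demo/AKS_curve.csv --out demo/fit.json
bchekit phenotype --in demo/AKS_panel.json --out demo/call.json
```

The fit JSON reports `"model": "michaelian"` with Km ≈ 270 µM and
Vmax ≈ 0.50 U/mL — the F-test finds no substrate activation (b = 1), and
the phenotype call is `atypical_silent_like` (DN ≈ 11%, deficient
activity). The same pipeline over the whole family:

```bash
$ bchekit report --seed 1
individual   activity flag                DN%    FN% model          Vmax   Km_uM  Kss_mM     b  call
----------------------------------------------------------------------------------------------------
AKS        1278 IU/L deficient           3.5   11.7 michaelian     0.50   278.2       -  1.00  atypical_silent_like
US         7040 IU/L within_interval    75.5   54.1 two_site       8.33    24.9    0.58  2.18  usual
AKU        7661 IU/L within_interval    57.6   40.5 two_site       6.10    27.9    0.52  2.49  heterozygous_atypical_or_silent
```

Reading the rows: the proband (AKS) is activity-deficient with a low
dibucaine number and a purely Michaelian curve with a ~10-fold raised Km —
consistent with a silent/atypical hybrid enzyme. Both parents keep
substrate activation (two-site model selected, b > 2) because half of
their tetramer subunits are usual; the mother's intermediate DN places her
in the heterozygous atypical band, while the father's DN is
indistinguishable from usual/usual (the call's rationale records that
ambiguity).

The same operations are available as a library:

```python
from bchekit import generate_rate_curve, select_model, KineticParameters

truth = KineticParameters(vmax=7.5, km_um=18, kss_mm=1.0, b=3.2)  # usual enzyme
curve = generate_rate_curve(truth, noise_cv=0.03, seed=1)
result = select_model(curve, alpha=0.05)
print(result.model, result.params)      # two_site, b ≈ 3.2
```

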