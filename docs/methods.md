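# Methods

## Rate laws

Initial-rate BTC hydrolysis by BChE is modeled with the two-site
substrate-modulation law

v(S) = Vmax · S/(Km+S) · (1 + b·S/Kss)/(1 + S/Kss)

with Vmax in U/mL (1 U = 1 µmol·min⁻¹, referred to undiluted plasma), Km
in µM, Kss in mM (converted to µM internally; all unit conversions are
centralized in the parameter type), and b dimensionless. The law assumes
steady-state initial rates (no progress-curve integration), a single
catalytic site plus one peripheral anionic site (PAS), and rapid
equilibrium of the ternary complex. Limiting behaviors: v(0) = 0,
v → b·Vmax as S → ∞, strict monotonicity for b ≥ 1, an interior maximum
(inhibition by excess substrate) for b < 1, and exact reduction to
Michaelis–Menten at b = 1 or Kss = ∞. `Kss = inf` is representable to
state "no PAS binding" distinctly from b = 1.

The mechanistic decomposition uses the classical acyl-enzyme scheme:
Km = Ks·k₃/(k₂+k₃) with Ks = k₋₁/k₁, and kcat = Vmax/[E] for active-site
concentration [E] (≈ 50 nM in normal plasma, giving kcat ≈ 24,000 min⁻¹
at Vmax ≈ 1.2 U/mL). Heterozygous plasma holds hybrid tetramers; the
package exposes a linear species mixture whose rate is the
fraction-weighted sum of component rates — an initial-rate superposition,
valid because species do not interact kinetically.

## Fitting

Estimation is unweighted nonlinear least squares on v (a
`weighting="proportional"` option exists because the noise is plausibly
multiplicative). The Michaelian fit (Vmax, Km) is initialized from the
Hanes–Woolf linearization S/v = S/Vmax + Km/Vmax; the two-site fit
(Vmax, Km, Kss, b) takes (Vmax, Km) from a Michaelian subfit of the
S ≤ 300 µM points, b from the high-S plateau/Vmax ratio, and Kss from
1 mM, with bounds Vmax, Km, Kss > 0 and b ∈ (0.01, 100). Optimization is
Levenberg–Marquardt (lmfit) at 10⁻⁸ relative tolerance with up to 5
deterministically jittered re-initializations; a fit that still fails is
reported `converged = False` with NaN parameters, never silently. Designs
with no point above 1 mM cannot identify (Kss, b) and are flagged.
Replicates are fitted pooled rather than averaged, which preserves the
residual structure for the bootstrap.

Model choice between the nested laws uses the extra-sum-of-squares F-test
with 2 numerator degrees of freedom at α = 0.05: the two-site model is
kept only when its RSS reduction is larger than noise explains. When the
full model fits exactly (RSS = 0), the simpler model is kept only if it is
also exact. Parameter uncertainty beyond the asymptotic standard errors
comes from a residual-resampling bootstrap (recentred residuals, rates
clipped at 0, B ≥ 50, default 500) with percentile intervals, bit-reproducible
under a fixed seed. In the suite's coverage study (100 synthetic proband
curves, B = 199) the nominal-68% Km interval covered the generative value
73% of the time.

The test suite cross-checks the continuous optimizer against an
independent exhaustive oracle: for the Michaelian law the conditionally
optimal Vmax at fixed Km is the exact linear-least-squares solution
Σ(v·g)/Σ(g²) with g = S/(Km+S), so a fine 1-D Km lattice searches the
entire surface; the fitted optimum must land within one lattice step.

## Phenotyping

The inhibition number is 100·(1 − vi/v0) for 50 µM BzCh with 10 µM
dibucaine (DN) or 50 µM fluoride (FN), clamped to [0, 100]; an inhibited
rate up to 5% above the uninhibited one is tolerated as noise, larger
excesses are data-quality errors. Classification bands follow classical
cholinesterase phenotyping practice: DN ≥ 70 usual; 40–70 heterozygous
atypical-or-silent; DN < 30 atypical-like, split by the activity flag into
atypical+silent-like (deficient) versus atypical-homozygous-like
(not deficient); 30–40 indeterminate. The published family and control
exemplars bracket these bands but do not define them. A usual/silent
heterozygote (DN ≈ 75) cannot be separated from usual/usual (DN ≈ 79) by
DN; both land in the usual band and every call's rationale string names
its nearest exemplar and, in that band, the ambiguity. Reference-interval
endpoints count as within the interval (inclusive clinical convention).

## Synthetic panels

The generator emulates the three clinical inputs per individual from a
genotype registry (shipped, editable JSON):

- **BTC saturation curves** on a 12-point log-spaced design over
  10 µM–50 mM, 3 replicates, multiplicative Gaussian noise with CV 3% by
  default (duplicate scatter in tabulated clinical assays is a
  few percent; CV is capped at 20%), negative draws clamped at 0.
- **Inhibition pairs** from a Michaelian BzCh forward model plus
  competitive inhibition v = Vmax·S/(Km(1+I/Ki)+S). Treating fluoride as
  competitive is a modeling convenience. Per-genotype Ki values are
  calibrated analytically so the noiseless pair reproduces the genotype's
  target DN/FN exactly; they are generator constants, not measurements.
- **Analyzer activities** (IU/L) with the same multiplicative noise.

Registry BTC parameters mirror the published family/control sets
(AKS 0.50 U/mL, 265 µM, b = 1; US 7.51, 21 µM, 0.49 mM, 2.4;
AKU 6.07, 27 µM, 0.51 mM, 2.5; UU 18 µM, 1.0 mM, 3.2;
AA 150 µM, 1.1 mM, 1.2). Non-published generator constants, chosen once:
the usual-enzyme Vmax is fixed at 7.5 U/mL (only a literature kcat is
tabulated for it); AA and AS Vmax (1.22 and 0.34 U/mL) are set so the
two-site rate at 1 mM BTC matches the tabulated 1 mM activities (1.16 and
0.32 U/mL); BzCh Km is 5 µM for genotypes containing usual subunits and
25 µM for purely atypical ones (atypical enzyme binds choline esters more
weakly), with BzCh Vmax back-solved from the tabulated 50 µM rates;
analyzer activities for non-proband genotypes are scaled from the 1 mM
BTC activities by the proband's measured analyzer/manual ratio
(1,270 IU/L / 0.41 U/mL), except AA (6,000 IU/L) and AS (2,000 IU/L),
set so their activity flags match the band semantics (homozygous-atypical
is not activity-deficient against the men's interval; atypical/silent is).

All randomness descends from one integer seed through spawned
`numpy.random` substreams (no global state), so any panel regenerates
bit-identically from (genotype, seed, design).

Note that the tabulated parent and control parameter sets are *not*
numerically consistent with the tabulated 1 mM activities under this (or
any standard) form of the two-site law — e.g. the usual-enzyme parameters
predict ≈ 15 U/mL at 1 mM against a tabulated 2.93 U/mL; only the
proband's row is consistent (0.395 predicted vs 0.41 ± 0.02 measured).
The generator therefore treats analyzer activity as an independent
quantity and attempts no hidden rescaling.

## What the simulations do and do not show

Passing parameter recovery shows that under the stated design (12
log-spaced concentrations, 3 replicates, 3% multiplicative noise) the
estimators are unbiased enough for their medians over 100 seeded curves to
sit inside the published ± intervals, and that the F-test separates b = 1
from b ≈ 3.2 essentially always while keeping its size near α. Real
plasma assays add features the generator does not emulate: spontaneous
substrate hydrolysis (subtracted upstream in practice), correlated
within-run drift, heteroscedasticity beyond a constant CV, pipetting
outliers, and between-individual biological variation in Vmax. Phenotype
band recovery shows internal consistency of the calibrated generator and
the fixed thresholds, not diagnostic accuracy on real populations —
AS vs AKS exemplars (DN 11.1 vs 7.2) overlap within their scatter and are
deliberately mapped to the same band.

## Study sizes and numerical choices

Recovery studies use 100 seeded curves per parameter set and
model-selection size/power use 200 — enough for binomial bounds at the
asserted ≥ 90/95/99% rates while keeping a full run interactive
(each fit is a few milliseconds). Convergence tolerance is 10⁻⁸ relative;
tie-breaks in classification are resolved by half-open bands
([70, 100] usual, [40, 70) heterozygous, [0, 30) atypical); degenerate
inputs (empty designs, non-positive concentrations, vi > 1.05·v0,
B < 50) raise typed errors rather than propagating garbage.
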