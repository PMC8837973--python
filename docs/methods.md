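# Methods

This note documents the models, conventions and numerical choices
behind `cholinetrace`, in the order data flows through the package.

## Units and conventions

All internal amounts are nmol, tissue masses mg, plasma volumes µL,
time hours. Report layers convert to µmol where a table conventionally
prints µmol. Whole-compartment *pool sizes* are concentration × organ
wet weight (tissues), concentration × total plasma volume (plasma), or
the total recovered amount (lung lavage fluid, which has no meaningful
volume normalization). The plasma compartment size may be given either
as a mass (mg, divided by the plasma density 1.025 g/mL) or modeled
from body weight; `pools` supports both and callers record which was
used — the two agree within ~2% at the reference body weight.

## SRM quantification

**¹³C correction.** Within a lipid class measured through a shared
diagnostic product ion, species differing by one double bond lie 2 Da
apart, so the M+2 isotopologue of the more unsaturated species (exactly
two ¹³C among its *n* carbons, probability C(n,2)·p²·(1−p)ⁿ⁻²,
p = 0.0107 by default, configurable in [0, 0.02]) is recorded under its
neighbour's channel. The spillover probabilities form a unit-diagonal
matrix **C** with one off-diagonal band; corrected abundances solve
**C**·x = raw. Only the M+2 overlap is handled: M+1 channels are not
acquired in this transition set, and cross-class interference is out of
scope. Solutions that come out negative (noise at low abundance) are
clipped to zero and flagged; round-off-level negatives at true zeros
(below 10⁻¹² of the sample's largest count) are zeroed silently. The
m/z tolerance for recognizing a +2 Da overlap is 0.30 Da; two
precursors within that tolerance of *each other* are an error
(ambiguous channel assignment).

**Internal standards.** Each analyte maps to exactly one spiked
standard: D4-choline for the water phase, PC20:0/20:0 for choline
lipids (PC, lyso-PC, SPH), PE14:0/14:0 for PE. The standard is added to
the primary extract and co-diluted with the analytes, so the count
ratio is dilution-invariant; dilution factors (1:7.5 / 1:110 water
phase, 1:157 lipids) are validated and recorded on the measurement
table but do not enter the ratio. Amount = ratio × spike amount /
response. The ionization response model is affine in total carbon
number, normalized to 1.0 at the class standard; the default slope is
0 (no correction) because no calibration coefficients are published —
supply a fitted slope to enable it.

**Species panel.** The packaged registry defines an 8-species PC
ladder (PC32:0, 34:1, 34:2, 36:2, 36:4, 38:4, 38:6, 40:6) covering the
five acyl sub-groups (di-saturated, C18:1, C18:2, C20:4, C22:6), one
lyso-PC and one SPH species, each in unlabeled/D9/D3 states, plus a
five-species endogenous PE panel. This is a representative panel, not
an exhaustive lipidome; sub-group sums and coverage fractions are
computed from the registry's single acyl-group tag per species, which
is authoritative.

## Dose and label accounting

The injected compound is the chloride salt: M = 139.62 + 9·1.00628 =
148.68 g/mol, so 50 mg/kg ≡ 336 nmol per g body weight. Dose fractions
are methyl-corrected: a labeled pool counts as
100 · pool · (n_CD₃/3) / dose, with n_CD₃ = 3 for D9 species, 2 for
D6-dimethylglycine, 1 for D3 species. Under this weighting the three
methyls of every injected molecule are counted exactly once however
they are split between metabolites, so in a closed system total
corrected label is conserved at 100%. Enrichment is
100 · labeled/(labeled + unlabeled); the formula is a declared
convention (several near-equivalent definitions exist at tracer
abundances). Unobserved label (urine, intestine, carcass) is reported
as a residual, never imputed. Fold-decreases are reported in both
conventions — ratio of group means and mean of per-animal ratios —
because the two differ for skewed data and published values may use
either.

## Statistics

Two groups: two-tailed Welch t test. Three or more (the three
sacrifice times): Tukey's range test computed directly from the
studentized-range distribution with a pooled within-group variance;
raw pair p-values are then Bonferroni-multiplied by the number of
analyte families analyzed (capped at 1). This "Tukey within a family,
Bonferroni across families" composition keeps each step standard and
testable; the implementation is verified against a permutation
max-range oracle. When only printed summaries (mean ± SE, n) are
available, a Welch t from the SEs with Welch–Satterthwaite df is used
and flagged `approximate`. The normality screen is the
skewness/kurtosis omnibus test at 0.05, advisory only (n < 8 returns
"insufficient n"); it gates nothing, matching the descriptive role such
checks play in small-animal studies.

## The tracer network simulator

A linear (first-order mass-action) compartmental model over
(organ, species, label) states. Linearity is justified at tracer doses
— choline transporters have high Michaelis constants, so uptake is
proportional to concentration — and makes the system exactly solvable,
which turns conservation and matrix-exponential cross-checks into sharp
tests. Organs: liver, plasma, lung, lung lavage fluid, cerebrum,
cerebellum (observed) plus peritoneum (injection site), a lumped
whole-body "carcass" (muscle, kidney, intestine, skin, excretion) and
bile (unobserved). Unlabeled endogenous pools are *not* simulated; they
are treated as steady-state references, which is appropriate because
the tracer is a trace perturbation of much larger constant pools.

Structural choices that proved necessary (single-pool,
constant-coefficient variants provably cannot reproduce the reference
kinetics):

- **Two hepatic/pulmonary PC pools.** De novo synthesis feeds a
  nascent secretory pool exported quickly (VLDL/bile for liver,
  HDL/surfactant for lung) or incorporated into a slowly turning-over
  membrane pool; plasma-derived PC lands in the membrane pool. This
  yields the observed fast-then-slow decline of total labeled
  phospholipid (≈15% → ≈11% in 4.5 h, then nearly flat to 24 h) —
  a single pool with constant export would keep falling.
- **Whole-body exchangeable choline and betaine pools.** The carcass
  stores label and releases it back into plasma; without this return
  the observed betaine pool (≈10% → ≈1.8% → ≈0.6% of dose) would decay
  as a single exponential, which cannot be fast early and slow late.
- **Exact per-methyl label bookkeeping.** Betaine demethylation emits
  D6-dimethylglycine *and* a methionine-bound D3 methyl on the same
  edge (weights 2/3 + 1/3 = 1); PEMT consumes one methionine-bound
  methyl per D3-PC. Every edge conserves methyl weight by
  construction, validated at network build time, so the methyl-
  weighted total over all compartments equals the dose at all times
  (tested to 1e-8 relative).

**Rate constants.** The per-animal raw data behind the emulated study
design are not publicly deposited, so absolute rates cannot be fitted;
the defaults are the package's own calibration, obtained by bounded
least squares of the deterministic trajectories against the reference
summaries (the category dose-fraction table at 1.5/6/24 h, the betaine
fractions, the printed organ-level D9-PC pools and the lavage-fluid
time course), then frozen. At the freeze the category fractions
reproduce the references within ~10% relative (phospholipids) to ~25%
(the D3-phospholipid tail), all within ≈1 reference SE for the headline
1.5 h values. Several constants are *effective* lumped rates, not
enzyme kinetics — e.g. plasma free-choline clearance of ~190/h encodes
the sub-minute distribution half-life of an intraperitoneal bolus, and
rapid dimethylglycine/methionine clearance stands in for pools
(sarcosine, protein synthesis) that are not modeled.

**Known limitation.** With constant coefficients, late lung/brain PC
accretion must be driven by a plasma PC pool that stays elevated, so
the model's plasma D9-PC peaks later and declines more slowly than the
reference kinetics suggest (a 6 h peak). The required qualitative sign
pattern — liver and lung D9-PC fall from 1.5 to 6 h; lung, cerebrum and
cerebellum rise from 6 to 24 h; lavage PC rises monotonically; brain
never decreases; water-soluble precursors fall more than 7-fold by
6 h — is reproduced and tested. Enterohepatic recirculation of biliary
PC is not modeled (bile is absorbing), so late biliary losses are
somewhat overstated.

**Study sampling.** Per time point, n = 9 animals (the emulated design
uses 8–10); body weight ~ Normal(28.2, 2.1²) g; organ weights scale
with body weight around the reference means, with between-animal SD
implied by the reference SEs (×√27). Per-animal labeled pools are the
deterministic trajectory × dose × a unit-mean lognormal animal effect
(CV 0.15, the biological variation); endogenous pools are reference
concentrations × the animal's compartment sizes with the same CV. PC
class amounts are distributed over species by acyl profiles: labeled PC
relaxes exponentially from a linoleoyl-rich hepatic synthesis profile
toward each organ's equilibrium profile at an organ-specific
remodeling rate (a single relaxation constant per organ, not a full
deacylation/re-acylation cycle). Raw counts are then synthesized by the
exact forward of the quantify module — IS ratios, forward ¹³C
spillover, multiplicative technical noise (CV 0.05) — so
quantification inverts the generator up to noise; ground-truth pools
are emitted alongside. The seed fully determines all output.

What passing the end-to-end tests shows — and does not show. The
Monte-Carlo recovery criterion (group means within 2·SE of truth for
≥95% of analyte × organ × time cells over 200 replicates) certifies
that the quantification chain is an unbiased inverse of the forward
model under realistic noise; it does not certify the kinetic model
itself against real animals, whose raw data are unavailable. Real data
differ in ways the generator does not emulate: peak-integration error
structure, batch effects, litter correlations, and isotope effects on
ionization.

**Transfer-rate estimation.** `fit_transfer_rate` fits the
four-parameter model S(t) = S₀e^(−λt), T(t) = T₀ + k·S₀(1−e^(−λt))/λ
jointly to a donor and recipient series by least squares (the donor's
total turnover λ and the specific transfer rate k coincide only for a
pure two-compartment transfer, where the fit is exact). The simulation
study uses six sampling times over 0.75–24 h with 10% lognormal noise;
with only three times the problem is exactly determined and the
estimate is noise-limited but still median-unbiased.

## Problem sizes in the test and acceptance runs

Deterministic checks are instantaneous. The two simulation studies use
200 replicates each (full pipeline at n = 9 × 3 times; transfer-rate
fitting at 6 time points), sized to estimate a 95% coverage fraction
and a median bias to well under their tolerance while keeping the whole
suite around a minute on one CPU.

## Degenerate inputs and tie-breaks

Zero internal-standard counts, empty tables, unknown organ/analyte
names, negative counts and sub-unity dilution factors are hard errors
naming the offending rows. p13 = 0 yields the identity correction.
A hematocrit of 1 yields zero plasma volume. Lavage fluid rows for
water-soluble analytes are rejected (the lavage dilution makes the
water phase unquantifiable). In `group_species`, species tagged `n/a`
are excluded from sub-group sums but retained in the class total, with
the coverage fraction reported.
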