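# cholinetrace

Quantitative analysis of deuterated-choline (D9-choline) tracer
kinetics in the neonatal rat — liver, plasma, lung, lung lavage fluid
(surfactant), cerebrum and cerebellum.

Choline is an essential nutrient in rapidly growing neonates: it
supplies phosphatidylcholine (PC) synthesis for parenchymal growth and,
through betaine, feeds the one-carbon methylation pool. Pulse-labeling
with choline carrying three trideuteromethyl groups (D9) lets the two
fates be separated *in vivo*: de-novo CDP-choline-pathway products keep
all three labeled methyls (D9-PC, D9-betaine, …), betaine demethylation
leaves D6-dimethylglycine and hands one methyl to methionine, and
PE-methylation (PEMT) products carry a single labeled methyl (D3-PC,
D3-choline). `cholinetrace` implements the complete downstream
computation for such a study, for analysts working from integrated
SRM (selected-reaction-monitoring) ion counts:

- **core_io** — analyte/transition registry (packaged default panel:
  the water-soluble choline metabolome plus PC/lyso-PC/SPH/PE species
  ladders in unlabeled/D9/D3 states), typed readers/writers for
  measurement, animal and pool tables.
- **quantify** — natural-abundance ¹³C correction (the M+2
  isotopologue of a species with one more double bond spills into its
  neighbour's SRM channel; the spillover matrix is inverted),
  internal-standard ratio quantification with an optional chain-length
  response model, and acyl sub-group aggregation
  (sat/C18:1/C18:2/C20:4/C22:6).
- **pools** — whole-compartment pool sizes: `pool = c × W` for
  tissues (nmol/mg × mg) and `pool = c × V_p` for plasma, with
  `V_p = BW · 0.125 · (1 − Hct)/ρ` (blood 12.5% of body weight,
  hematocrit 0.40, plasma density 1.025 g/mL); descriptive organ
  fractions against the 10 µmol/g whole-body choline-phospholipid
  reference.
- **label_accounting** — dose arithmetic (50 mg/kg D9-choline
  chloride, M = 148.68 g/mol ⇒ 336 nmol/g), methyl-corrected dose
  fractions `100 · pool · (n_CD₃/3) / dose`, enrichment
  `100 · labeled/(labeled+unlabeled)`, and label balance with the
  unobserved residual.
- **kinetics_stats** — time contrasts (percent change, fold ratios),
  PC sub-group profiles vs. the equilibrium (unlabeled) composition,
  two-tailed t tests, Tukey's range test within analyte families with
  Bonferroni correction across families, and an advisory normality
  screen.
- **simulator** — a first-order compartmental model of the whole
  tracer network (absorption, uptake, CDP-choline pathway, betaine/
  one-carbon branch with exact per-methyl label bookkeeping, VLDL/HDL
  PC trafficking, bile and surfactant secretion) that generates
  synthetic per-animal studies — ground-truth pools *and* raw SRM
  counts — so the entire pipeline is testable end to end.
- **pipeline / CLI** — `cholinetrace {validate, pools, fractions,
  simulate, run-all}` orchestration with a serializable run config.

## Worked example

```python
from cholinetrace import (DoseSpec, compute_dose, default_network,
                          dose_fractions, estimate_plasma_volume, simulate)
from cholinetrace.pipeline import descriptive_fractions
from cholinetrace.core_io import reference_pools

dose = compute_dose(28.2)              # nmol for a 28.2 g pup
vol = estimate_plasma_volume(28.2)     # uL
desc = descriptive_fractions(reference_pools())
traj = simulate(default_network(), dose, [1.5, 6.0, 24.0])
print(dose_fractions(traj, dose).pivot(index="category",
                                       columns="time_point_h",
                                       values="percent_of_dose").round(1))
```

prints

```
dose for a 28.2 g pup:  9484 nmol (336.3 nmol/g)
plasma volume:          2063 uL
liver: 2.9% of body mass, 8.1% of body choline lipids
time_point_h              1.5   6.0   24.0
D3_phospholipid            0.8   2.1   2.3
D9_phospholipid           14.8  11.7  10.9
water_soluble_D9_derived  12.3   2.2   1.0
```

Reading: a 28.2 g pup receives 9.5 µmol of tracer. Its liver is 2.9%
of body mass but holds 8.1% of the body's choline phospholipids. At
1.5 h after injection roughly a quarter of the administered label sits
in the analyzed compartments — ~12% still water-soluble (mostly
D9-betaine) and ~15% already esterified into D9-phospholipids; by 24 h
the water-soluble label is gone while the phospholipid label persists
and redistributes from the liver to the lung and brain. The slowly
rising D3-phospholipid row is endogenous PC synthesis using labeled
methyl groups via the PEMT pathway.

To generate a full synthetic study (animal table, ground-truth pools
and raw SRM counts) and analyze it:

```sh
cholinetrace simulate --seed 7 --out study/
cholinetrace run-all --animals study/animals.csv \
    --measurements study/measurements.csv --out report/
```

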