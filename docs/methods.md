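# Methods

## System and assumptions

The body is modelled as an open thermodynamic system at 310.15 K in
quasi-steady state: no entropy accumulates in the tissues, so the entropy
balance reduces to generation = outgoing flows − incoming flows + exported
heat over temperature.  Everything is driven by the daily diet composition;
there is no time-of-day resolution (a 16:8 fasting schedule matters only
through which diet table is consumed), no storage partitioning, and no
evaporative water loss (drinking water passes through without contributing
to generation).  Sulfur, present only in the composite amino acid at an S:C
ratio of 0.01, is dropped from all balances.

## Fuels and stoichiometry

Carbohydrate, protein and fat are represented by glucose, an average of 20
amino acids (C4.57 H9.03 N1.27 O2.25 S0.046) and palmitic acid.  Only the
utilized share of each macronutrient is oxidized: healthy digestibilities
0.99/0.92/0.95 (carbohydrate/protein/fat), replaced wholesale in liver
disease by Child–Pugh oxidation fractions (A: 0.88/0.28/0.46, B:
0.86/0.31/0.55, C: 0.88/0.24/0.59).  The three oxidation reactions route all
amino-acid nitrogen to urea (0.635 mol per mol of fuel).  Elemental C/H/O/N
and mass conservation of the reactions are verified programmatically at
import time and in the test suite, to a relative tolerance of 0.3% (the
amino-acid coefficients are rounded to three decimals); mass closure is
checked with formula-derived masses excluding S, which balance to <0.05% —
the rounded working masses (119 g/mol for the amino acid) would alone
introduce ~0.5%.

Working molar masses are deliberately the rounded values 180/256/119 (fuels)
and 32/44/18/60 (O2/CO2/H2O/urea): these reproduce the reference exchange
columns exactly (898 g O2/day for the 3100 kcal obese plan; 613.2 g for the
2210 kcal fasting plan), whereas exact IUPAC masses shift results by ~0.3%.
Urine mass assumes 65% of produced urea is excreted at 20 g/L and unit
density; feces are the unabsorbed dry matter Σ(1−fraction)·intake.  (The
reference material prints feces values exceeding total diet mass; those are
not reproducible from any absorption model and the package's unabsorbed-mass
definition is the contract.)

## Thermodynamic properties and heat release

The shipped property set (`entroage/data/species.json`) carries formation
enthalpies and absolute entropies per kmol.  Reactants enter at 298 K;
products leave at 310 K, CO2 and water as ideal gases, with
h(T) = h_form,298 + [h_sens(T) − h_sens(298)] for the gases and the
formation enthalpy alone for condensed species (fuels, urea — their sensible
enthalpy over 12 K is neglected, matching the structure of the source
property table).  Gaps in the source table are filled with standard
thermochemical values (CO2: −393,520 kJ/kmol, sensible 9364→9807; H2O(g):
−241,820, sensible 9904→10,302; urea: −333,100, s = 104.6 kJ/(kmol K)); the
average amino acid's entropy is its specific entropy 1.401 kJ/(kg K) times
119 g/mol.  Every value is overridable through a key-wise-merged config, so
alternative conventions (liquid-phase water, exact masses) are one file away.

Under this gas-phase convention the reaction enthalpies are −2547 (glucose),
−9317 (palmitate) and −2157 (amino) kJ/mol.  Metabolic efficiencies η =
0.346/0.322/0.104 give the ATP-captured share; the remainder leaves as heat,
Q = Σ(1−η)|ΔH_R|ṅ ≈ 8.5 MJ/day for the 3100 kcal plan.  ATP yields
(32/106/8 mol/mol) are reported but not used in the heat path.

## Entropy balance and sign convention

Daily generation is Δs_gen = (Σns)_out − (Σns)_in + Q/T.  Q is the positive
magnitude of the heat leaving the body; exporting heat raises the entropy of
the surroundings, so the term adds to the generation attributed to the
subject.  With the shipped constants Δs_gen > 0 for every shipped diet under
every utilization profile (a tested invariant), and the Q/T term dominates
the net flow term by a factor of ~6.  The annual specific rate divides by a
fixed body-mass basis — the weight at diet onset (100 kg for the obese
plans, 80 kg for the fasting plans) — and is *not* updated as weight
changes; 365 days per year.

The full pipeline yields 115.4 kJ/(kg K yr) for the healthy obese plan
(reference value 119.9, 3.8% apart) and 98.7 for the 2210 kcal fasting plan
(reference 102.4, 3.6%).  The residual reflects the under-specified portions
of the source property table; both land inside the ±5% band the analysis
supports, and the rate targets are treated as bands, not point anchors.

## Entropic age and scenarios

Lifespan projection walks contiguous constant-rate segments from an (age,
accumulated entropy) state until the 11,404 kJ/(kg K) budget is reached; a
single open-ended segment reduces to age + (limit − accumulated)/rate.
Reported lifespans are rounded to the nearest integer with full precision
retained.  Disease scenarios divide a healthy annual rate by the one-year
survival fraction of the Child–Pugh class (0.95/0.80/0.44) — the source's
multi-year horizon formula collapsed to its one-year form, implemented
exactly so.  The autophagy effect of sustained fasting is an explicit,
optional rate reduction in [0.10, 0.25]; whether the reference weight-loss
rates already include it is not stated, so it is never applied implicitly.

Known reference inconsistencies, excluded from exact checks and asserted
*as* discrepancies in the suite: the initial BMR values at 80 kg (the
regression yields 1874/1730, not 1885/1618), the 25-year-old fasting-plan
lifespans (closed form gives 111.4/134.0/144.4 vs printed 110/133/143), the
"+29 years" summary figure for Child–Pugh A (the closed form gives ~35 =
127 − 92), and a remaining-budget figure printed as 6604 where the
subtraction gives 11,404 − 4796 = 6608.  One published exchange table also
swaps two row labels relative to the diet-composition table; everything here
is keyed to composition, never to row label.

## Synthetic diet generator

The generator emulates guideline-constrained diet tables: a calorie target,
a macronutrient calorie split validated against the acceptable ranges
(protein 10–35%, carbohydrate 45–65%, fat 20–35%), Atwater factors 4/4/9
kcal/g, and optional multiplicative lognormal noise parameterized by a
coefficient of variation (mean-1 multiplier keeps masses positive and
unbiased; one integer seed gives reproducibility).  It reproduces the shape
of the published plans — e.g. the 3100 kcal obese plan's split recovers
430/150/98 g within the rounding of the printed grams (~3%) — but not food
items, micronutrients, fibre fermentation or meal timing, so passing tests
demonstrate correctness of the pipeline arithmetic on realistic inputs, not
nutritional fidelity of any real menu.

## Numerical and design choices

* All arithmetic is full precision; rounding (1 decimal for exchange grams,
  integers for kcal and years) happens only at the reporting edge.
* kcal ↔ kJ uses 4.184 throughout.
* Degenerate inputs: zero diets produce all-zero exchanges and flow terms;
  an exhausted budget projects lifespan = current age; a survival fraction
  of zero is rejected rather than producing an infinite rate.
* The BMR module exposes exactly one equation and one activity multiplier
  (1.2); alternative regressions are out of scope.
* Problem sizes everywhere are desk-scale (single diets, ≤1000 synthetic
  plans in the statistical test), so the whole suite runs in a few seconds.

## Limitations

The lifetime entropy budget, survival-fraction device and autophagy
reduction are modelling postulates, not physiology; projections assume no
other disease, a fixed diet per segment, and a constant body-mass basis.
Property values for the composite amino acid and urea carry the largest
uncertainty in the heat and flow terms, which is why pipeline-level rates
are validated as ±5% bands while the stoichiometric layer is validated to
printed precision.
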