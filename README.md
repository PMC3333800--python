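# cellpkpd

Cell-level pharmacokinetic/pharmacodynamic modelling of receptor-targeting
monoclonal antibodies, illustrated with anti-EGFR antibodies (zalutumumab
and comparators) in cynomolgus monkeys.

## The problem

Antagonistic antibodies against cell-surface receptors such as the EGF
receptor have a two-way relationship with their target: the drug inhibits
receptor activation, and the receptor system eliminates the drug through
receptor-mediated endocytosis (target-mediated drug disposition). Classical
compartment PK models capture the nonlinearity with an apparent
Michaelis–Menten binding term, but its parameters (B_max,PK, K_M,PK) are
drug-specific hybrids — they cannot say what happens *at the cell*, or what
would change if the antibody's affinity or internalization rate changed.

`cellpkpd` links the two levels mechanistically. It is aimed at modellers
in systems pharmacology and antibody engineering who want to ask: given a
receptor-trafficking model validated in vitro and a compartment PK model
fitted in vivo, what is the transient inhibitory effect of an antibody per
cell — and how does it depend on affinity, downregulation, and dose? No
parameter is fitted anywhere; everything follows from printed parameter
tables.

## The model

**Single cell.** Free surface receptors R are synthesized at rate k_synR,
internalized (k_degR) into a pool R_i that is recycled (k_recyRi) or
degraded (k_degRi). Ligand L (constant) forms signalling complexes RL
(k_onL, k_offL) that are internalized at k_degRL. Antibody C binds free
receptors (k_onC, k_offC → K_D = k_offC/k_onC) and the complex RC is
internalized and degraded at k_degRC, consuming drug.

**Quasi-steady-state reduction.** With receptor species fast relative to
drug disposition, one cell acts on the drug like a Michaelis–Menten site:

    B_max,cell = SF_unit · k_synR / k_degRC
    K_M,cell   = (k_degRC + k_offC)/(k_degRC · k_onC)
                 · [ k_degRi·k_degR/(k_degRi + k_recyRi)
                   + L·k_onL·k_degRL/(k_offL + k_degRL) ]

**Linking.** Equating N_cell · B_max,cell to the whole-body capacity
B_max,PK of the fitted compartment model gives the number of relevant
target-expressing cells

    N_cell = k_degRC · B_max,PK / (k_synR · SF_unit)

and the ratio of half-maximal binding concentrations defines a
dimensionless in vitro–in vivo scaling factor SF_iviv, subsequently applied
to antibody affinities (K_D,in vivo = SF_iviv · K_D,in vitro).

**Combined model.** The apparent binding term of the compartment model
(plasma, interstitium, linear clearance CL_lin) is replaced by the
mechanistic cell model scaled by N_cell; the cells see the interstitial
concentration C_int. A two-population variant simulates normal and tumor
cells (elevated receptor levels via 10× synthesis or 10× slower
internalization) competing for the same drug.

**Effect measures.** Receptor saturation RC/(R+RL+RC), residual activity
RL/RL*, and three transient-inhibition measures: the integral
E = ∫(RL* − RL(t))dt, the peak (RL* − min RL)/RL*, and the duration until
recovery to 75% of RL*; tumor-to-normal ratios of these give the
specificity S_E, S_p, S_d.

## Worked example

```python
from cellpkpd.experiments import run_linking_report, run_dose_response

link, report = run_linking_report()
print(report)
```

```
Cell-to-body linking report (zalutumumab_monkey)
==============================================
B_max,cell = 2.591e-09 nmol/cell   [SF_unit * k_synR / k_degRC]
K_M,cell   = 7.076 nM   [(k_degRC+k_offC)/(k_degRC*k_onC) * drug-independent loss]
K_M,PK     = 3.378 nM   [fitted in vivo]
N_cell     = 5.215e+09 cells/kg   [k_degRC * B_max,PK / (k_synR * SF_unit)]
SF_iviv    = 2.095   [K_M,cell / K_M,PK]
  (inverse ratio K_M,PK/K_M,cell = 0.4774)
```

About 5.2·10⁹ EGFR-expressing cells per kg account for the whole-body
binding capacity, and the in vivo half-maximal binding concentration is
within a factor ~2 of the in vitro prediction — the cell model transfers to
the animal almost unchanged.

```python
trajectories, summary = run_dose_response((2.0, 20.0, 40.0))
print(summary.round(3).to_string(index=False))
```

```
 dose_mg_per_kg  max_saturation_pct  max_saturation_pct_rounded  peak_inhibition_pct  duration_day  duration_censored  window_below_10pct_day  integral_of_inhibition
            2.0              59.376                          59               58.708        11.383              False                   0.000                4929.852
           20.0              98.989                          99               98.961        39.000              False                  21.861               23655.056
           40.0              99.531                         100               99.518        48.947              False                  32.197               30849.737
```

A 2 mg/kg bolus only ever occupies ~59% of surface receptors and cuts
receptor activation by the same fraction at its peak; 20 mg/kg saturates
the receptor pool and abolishes activation (residual activity below 10%)
for about 22 days, recovering as the pharmacokinetics leave the saturated
regime. The integral of inhibition is in molecules·cell⁻¹·day.

The same pipeline is available from the shell:

```sh
cellpkpd link --out results/
cellpkpd dose-response --doses 2,20,40 --out results/
cellpkpd sweep --doses 2,20 --out results/      # affinity × downregulation grid
cellpkpd tumor --out results/                   # tumor-vs-normal specificity
```

The affinity sweep reproduces the *effect plateau*: across the five
marketed/clinical anti-EGFR antibodies (K_D from 0.05 to 7 nM, a 140-fold
range) the integral of inhibition varies by less than ~6%, while a
hypothetical 1 µM binder loses most of the effect — increasing affinity
beyond the plateau buys almost no additional F(ab)-mediated inhibition.

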