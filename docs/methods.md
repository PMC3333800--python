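# Methods

## Model family and assumptions

The package implements one model family at three levels of description:

1. **Trafficking cell model.** Four receptor species per cell (free surface
   receptors R, internal pool R_i, ligand complexes RL, drug complexes RC),
   mass-action kinetics, constant synthesis. The free EGF concentration L
   is an environmental constant (2.36·10⁻³ nM by default): ligand secretion
   and depletion are outside the model family, so L has no dynamics. RL is
   the signalling-competent species; downstream signal transduction is not
   modelled — the predicted endpoint is receptor activation, not cellular
   response.
2. **Reduced cell model.** A quasi-steady-state collapse of the receptor
   species onto an apparent Michaelis–Menten binding site (B_max,cell,
   K_M,cell). Valid when binding and trafficking are fast relative to drug
   depletion; the test suite probes the approach to this limit explicitly
   by scaling k_onC and k_offC jointly.
3. **Whole-body models.** A two-compartment PK skeleton (plasma,
   interstitium, linear clearance) closed either by the apparent
   Michaelis–Menten term with relaxation constant k_b (reference
   compartment model) or by N_cell copies of the mechanistic cell model
   driven by C_int (combined model; single- and two-population variants).
   Drug distribution to the cells is a reversible linear process — no
   convection, lymphatics, or tumor-penetration gradients — so tumor-cell
   predictions apply only to cells exposed to near-normal interstitial
   concentrations.

The system is assumed to be at its drug-free steady state before dosing;
the closed-form steady state (R*, R_i*, RL*, RC* = 0) is used for initial
conditions and as the reference level for all effect measures.

## Units and parameters

Canonical units: minutes, nM, nmol, litres (per kg body weight for
whole-body quantities), molecules/cell for receptor counts. The
molecules→nmol factor is SF_unit = 10⁹/(6.02·10²³). Whole-body volumes are
per kg, so mg/kg doses convert to initial plasma concentrations without a
body-weight input: C_pla(0) = dose/V_pla · 10⁶/MW (≈193 nM for 2 mg/kg).

Parameter fixtures (YAML, `src/cellpkpd/fixtures/`) store values in their
originally reported units and are converted on load. Two deliberate
interpretation choices are recorded in the fixture itself:

* **B_max,PK is an amount (mg/kg).** The source table prints "mg/h/kg",
  but the linking relation B_max,PK = N_cell·B_max,cell only closes for an
  amount, and the resulting N_cell ≈ 5.2·10⁹ matches the reported value.
* **CL_lin = V_pla·k_el** is derived, as tabulated.

The trafficking constants were measured in human fibroblasts; for
cynomolgus monkey, k_recyRi is multiplied by 4 and k_degR by 1/4. The
adjustment is not idempotent, so parameter containers carry a species
marker and re-adjusting raises.

`V_ex`, the extracellular volume per cell, has no reported value; the
default is 4·10⁻¹⁰ ml/cell (a few thousand cell volumes, a typical sparse
culture). It only enters the standalone in vitro simulator and the reduced
model and cancels out of the linked whole-body model, where V_int and
N_cell take its place.

## The in vitro–in vivo scaling factor

With the tabulated parameters, K_M,cell (unscaled zalutumumab affinity,
monkey-adjusted cell) is 7.08 nM against a fitted K_M,PK of 3.38 nM. The
package defines SF_iviv = K_M,cell/K_M,PK = 2.09, which reproduces the
reported value of 2.1 and matches its subsequent use (in vitro K_D values
are scaled *up* for in vivo simulation: K_D,in vivo = SF_iviv·K_D). The
defining relation could equally be read in the other direction
(K_M,PK = SF_iviv·K_M,cell would give 0.48); both ratios are recorded in
`LinkResult`, and the package does not guess intent beyond reproducing the
reported factor. Note the consequence: scaling K_D up moves the combined
model's effective K_M (≈14.8 nM) *away* from K_M,PK, which is why the
combined and compartment plasma curves agree closely only while binding is
saturated (see Limitations). The scaling is a flag (`apply_scaling`,
default on); SF_iviv itself is always computed from the unscaled affinity
to avoid circularity.

## Numerical choices

* Stiff integration (LSODA), rtol 1e-8, absolute tolerances scaled per
  state class (1e-10 for concentrations and amounts, 1e-6 for
  molecules/cell); identical across models for comparability. Rate
  constants span five orders of magnitude, with binding equilibrating in
  minutes and the PK tail stretching over weeks.
* Output grid: a point at t = 0, ~400 geometrically spaced points from
  1 min to the horizon, plus daily points. Default horizon 100 days —
  long enough that residual activity has recovered to >99.9% of RL* in all
  shipped scenarios (the remaining deficit at the horizon is reported as
  `tail_deficit` with every effect metric, so truncation of the inhibition
  integral is visible).
* Every whole-body state vector carries cumulative-elimination
  accumulators; `mass_balance_audit` checks total tracked drug against the
  administered amount (≲1e-13 relative at default tolerances, degrading
  monotonically as tolerances are loosened).
* The reduced model's free-concentration quadratic is evaluated with the
  cancellation-free conjugate root when C_D < 0 (the
  capacity-dominated regime), keeping the mass closure below 1e-10
  relative for extreme parameter ratios.
* Duration of inhibition uses the first grid time at which residual
  activity re-crosses the recovery fraction (default 0.75); if it never
  recovers within the horizon the duration is reported as the horizon with
  a censoring flag rather than silently underestimated.
* The near-complete-inhibition window is reported as the contiguous time
  with residual activity below 10%. The 10% threshold is the package's
  diagnostic choice for "essentially abolished activation"; no printed
  threshold exists for this quantity.

## Shipped experiments

`experiments.py` fixes the study conditions: doses 2/20/40 mg/kg (bolus
only), the five-antibody affinity catalog (0.05–7 nM), a log-spaced K_D
grid 10⁻¹¹–10⁻⁶ M, k_degRC multipliers {1, 5, 10}, tumor variants with
10× synthesis or 10× slower internalization (free and bound receptor), and
tumor cells at 1% of the normal-cell number so they leave the PK
essentially unperturbed. Target-independent PK is held fixed across
antibodies (same isotype class, hence same linear clearance), and only
k_offC varies with affinity (diffusion-limited association). All outputs
are deterministic and byte-stable: there is no randomness anywhere in the
package.

## Known limitations and documented discrepancies

* **Peak inhibition at 2 mg/kg.** The model predicts a peak reduction of
  activated receptors of ≈59%, essentially equal to the maximum receptor
  saturation (≈59%). This equality is structural: RL is slaved to R on a
  ~3-minute time scale, so residual activity ≈ (1 − saturation) × (surface
  pool/R*), and the surface pool cannot deviate from R* by more than a few
  percent during the ~3-day saturation window (its turnover time is ~8
  days). A reported peak of ~35% alongside ~60% saturation is therefore
  not reproducible by any parameterization of this model family; the
  package reports the model's own value.
* **Combined vs compartment plasma curves.** Agreement is excellent in the
  saturated regime (<1% at day 1–3 for high doses, <4% over 4 weeks at
  40 mg/kg) but degrades in the tail, for two parameter-level reasons: the
  affinity scaling direction above (effective K_M 14.8 nM vs 3.38 nM), and
  k_degRC (0.005/h) differing from k_el (0.0055/h) — a 10% drain-rate
  mismatch that compounds over weeks. A uniform 15% agreement across all
  doses and all times is not attainable with the tabulated constants.
* Fc-mediated effects (ADCC/CDC), downstream signalling, ligand dynamics,
  multiple-dose regimens, and physiologically based distribution are out
  of scope.
* The 20 mg/kg maximum saturation is 98.99% with the default affinity
  scaling (the equilibrium cap C_int/(C_int + K_D,in vivo) at the peak
  interstitial concentration); it rounds to 99%, not 100%.
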