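# Parameter fixture: zalutumumab / cynomolgus monkey.
#
# Whole-body PK parameters were determined in vivo in cynomolgus monkeys
# (3-compartment model fitted to plasma data); receptor-trafficking rate
# constants were determined in vitro in human fibroblast cells and must be
# species-adjusted (apply_species_adjustment) before in vivo use; the
# affinity is the reported in vitro value for zalutumumab.
#
# Values are stored in their originally reported units; the loader converts
# to the package's canonical unit system (min, nM, nmol, L).
fixture: zalutumumab_monkey

pk:  # whole-body pharmacokinetic parameters (in vivo, cynomolgus monkey)
  V_pla:    {value: 70,      unit: ml/kg}   # plasma volume
  V_int:    {value: 35,      unit: ml/kg}   # interstitial volume
  k_pi:     {value: 0.043,   unit: 1/h}     # plasma -> interstitial transport
  k_ip:     {value: 0.043,   unit: 1/h}     # interstitial -> plasma transport
  k_b:      {value: 0.069,   unit: 1/h}     # artificial equilibration constant
  B_max_PK: {value: 2,       unit: mg/kg, printed_unit: mg/h/kg}
    # Whole-body binding capacity. The source table prints the unit as
    # mg/h/kg, but the quantity enters the model as an amount: the linking
    # arithmetic (B_max_PK = N_cell * B_max_cell) only closes for mg/kg.
  K_M_PK:   {value: 0.5e-3,  unit: mg/ml}   # half-maximal binding concentration
  k_el:     {value: 0.0055,  unit: 1/h}     # receptor-route elimination
  # CL_lin (target-independent clearance) is defined as V_pla * k_el and is
  # derived by the loader.

cell:  # EGF receptor trafficking constants (in vitro, human fibroblasts)
  k_onL:    {value: 7.2e-2,  unit: 1/(nM*min)}  # ligand-receptor binding
  k_offL:   {value: 0.34,    unit: 1/min}       # ligand-receptor unbinding
  k_degR:   {value: 0.03,    unit: 1/min}       # free receptor internalization
  k_degRL:  {value: 0.03,    unit: 1/min}       # ligand-receptor complex internalization
  k_synR:   {value: 130,     unit: molecules/(cell*min)}  # receptor expression rate
  k_recyRi: {value: 5.8e-2,  unit: 1/min}       # free receptor recycling
  k_degRi:  {value: 2.2e-3,  unit: 1/min}       # free receptor degradation
  V_ex:     {value: 4e-10,   unit: ml}          # extracellular volume per cell
    # V_ex has no reported value; it is only used by the standalone in vitro
    # simulator and the reduced model, and cancels out of the linked
    # whole-body model.

drug:  # zalutumumab
  name: zalutumumab
  K_D:      {value: 7.0e-9,  unit: M}           # in vitro affinity
  k_onC:    {value: 7.2e-2,  unit: 1/(nM*min)}  # drug-receptor binding (= k_onL,
    # diffusion-limited association)
  k_degRC:  {value: 0.005,   unit: 1/h}         # drug-receptor complex internalization
  MW:       {value: 148000,  unit: g/mol}       # antibody molecular weight

environment:
  L: {value: 2.36e-3, unit: nM}  # free extracellular EGF concentration
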