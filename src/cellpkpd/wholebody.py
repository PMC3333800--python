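"""Whole-body simulators.

Three deterministic ODE models of an antibody bolus in cynomolgus monkeys:

* :func:`simulate_compartment_pk` -- the reference semi-mechanistic
  compartment model (plasma, interstitium, and an apparent Michaelis-Menten
  receptor-binding pool with first-order elimination).
* :func:`simulate_cell_level_pkpd` -- the combined model in which the
  apparent binding term is replaced by the mechanistic single-cell receptor
  model scaled up by the number of relevant cells ``N_cell``.
* :func:`simulate_two_populations` -- the combined model with separate
  normal and tumor cell populations competing for the same interstitial
  drug.

All models carry cumulative-elimination accumulator states so that the drug
mass balance can be audited to solver precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .cell import CellState, pretreatment_steady_state
from .params import (
    CellParameters,
    DrugParameters,
    LigandEnvironment,
    PKParameters,
)
from .reduction import LinkResult
from .trajectory import Trajectory, output_grid
from .units import MINUTES_PER_DAY, SF_UNIT, mg_to_nmol

__all__ = [
    "DoseScenario",
    "dose_to_plasma_concentration",
    "simulate_compartment_pk",
    "simulate_cell_level_pkpd",
    "simulate_two_populations",
    "mass_balance_audit",
]

# Shared stiff-solver settings; identical across models for comparability.
DEFAULT_RTOL = 1e-8
ATOL_CONC = 1e-10   # nM states
ATOL_COUNT = 1e-6   # molecules/cell states
ATOL_AMOUNT = 1e-10  # nmol/kg accumulators


@dataclass(frozen=True)
class DoseScenario:
    """A bolus dose scenario.

    ``populations`` lists ``(label, CellParameters, count_per_kg)`` for the
    cell-level models; the compartment model takes none.
    """

    dose: float                  # bolus [mg/kg]
    horizon: float = 100.0       # [days]
    n_log: int = 400             # geometric grid points
    populations: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")

    @property
    def horizon_min(self) -> float:
        return self.horizon * MINUTES_PER_DAY

    def grid(self) -> np.ndarray:
        return output_grid(self.horizon_min, n_log=self.n_log)


def dose_to_plasma_concentration(dose_mg_per_kg: float, pk: PKParameters) -> float:
    """Initial plasma concentration [nM] of a bolus dose [mg/kg].

    The dose is converted to nmol/kg through the antibody molecular weight
    and distributed instantaneously in the plasma volume [L/kg]; body
    weight cancels because both are per kg.
    """
    return mg_to_nmol(dose_mg_per_kg, pk.MW) / pk.V_pla


def _solve(rhs, y0, scenario: DoseScenario, atol, rtol: float):
    sol = solve_ivp(
        rhs,
        (0.0, scenario.horizon_min),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=scenario.grid(),
    )
    if not sol.success:
        raise RuntimeError(
            f"whole-body solver failed (rtol={rtol}, atol={atol}): {sol.message}"
        )
    return sol


def simulate_compartment_pk(
    pk: PKParameters, scenario: DoseScenario, rtol: float = DEFAULT_RTOL
) -> Trajectory:
    """Reference compartment PK model with apparent receptor binding.

    The receptor-bound amount ``A_RS`` [nmol/kg] relaxes at rate ``k_b``
    toward the Michaelis-Menten isotherm ``B_max_PK*C_int/(K_M_PK+C_int)``
    and is eliminated at rate ``k_el``; drug in plasma is cleared linearly.
    """
    if scenario.populations:
        raise ValueError("the compartment model has no cell populations")
    dose_nmol = mg_to_nmol(scenario.dose, pk.MW)

    def rhs(t, y):
        C_pla, C_int, A_RS = y[0], y[1], y[2]
        bind = pk.k_b * (pk.B_max_PK * C_int / (pk.K_M_PK + C_int) - A_RS)
        return [
            (-pk.q_pi * C_pla + pk.q_ip * C_int - pk.CL_lin * C_pla) / pk.V_pla,
            (pk.q_pi * C_pla - pk.q_ip * C_int - bind) / pk.V_int,
            bind - pk.k_el * A_RS,
            pk.CL_lin * C_pla,   # cumulative linear clearance [nmol/kg]
            pk.k_el * A_RS,      # cumulative receptor-route elimination
        ]

    y0 = [dose_to_plasma_concentration(scenario.dose, pk), 0.0, 0.0, 0.0, 0.0]
    atol = [ATOL_CONC, ATOL_CONC, ATOL_AMOUNT, ATOL_AMOUNT, ATOL_AMOUNT]
    sol = _solve(rhs, y0, scenario, atol, rtol)
    names = ["C_pla", "C_int", "A_RS", "A_cl", "A_el"]
    return Trajectory(
        t=sol.t,
        states={n: sol.y[i] for i, n in enumerate(names)},
        units={
            "C_pla": "nM", "C_int": "nM", "A_RS": "nmol/kg",
            "A_cl": "nmol/kg", "A_el": "nmol/kg",
        },
        metadata={
            "model": "compartment_pk",
            "dose_mg_per_kg": scenario.dose,
            "dose_nmol_per_kg": dose_nmol,
            "V_pla": pk.V_pla, "V_int": pk.V_int,
            "rtol": rtol,
        },
    )


def simulate_cell_level_pkpd(
    pk: PKParameters,
    cell: CellParameters,
    drug: DrugParameters,
    link: LinkResult,
    env: LigandEnvironment,
    scenario: DoseScenario,
    rtol: float = DEFAULT_RTOL,
) -> Trajectory:
    """Combined cell-level PK/PD model with a single cell population.

    Receptors start at their pretreatment steady state, drug starts entirely
    in plasma; the interstitial drug seen by the cells is ``C_int``. The
    number of cells is ``link.N_cell`` unless the scenario provides exactly
    one explicit population.
    """
    if len(scenario.populations) > 1:
        raise ValueError("use simulate_two_populations for multiple populations")
    if scenario.populations:
        _, cell, n_cells = scenario.populations[0]
    else:
        n_cells = link.N_cell
    ss = pretreatment_steady_state(cell, env)
    dose_nmol = mg_to_nmol(scenario.dose, pk.MW)

    def rhs(t, y):
        C_pla, C_int = y[0], y[1]
        R, R_i, RL, RC = y[2], y[3], y[4], y[5]
        exchange = n_cells * SF_UNIT * (
            drug.k_offC * RC - drug.k_onC * R * C_int
        )
        return [
            (-pk.q_pi * C_pla + pk.q_ip * C_int - pk.CL_lin * C_pla) / pk.V_pla,
            (pk.q_pi * C_pla - pk.q_ip * C_int + exchange) / pk.V_int,
            cell.k_synR - cell.k_onL * R * env.L - drug.k_onC * R * C_int
            + cell.k_offL * RL + drug.k_offC * RC - cell.k_degR * R
            + cell.k_recyRi * R_i,
            cell.k_degR * R - cell.k_recyRi * R_i - cell.k_degRi * R_i,
            cell.k_onL * env.L * R - cell.k_offL * RL - cell.k_degRL * RL,
            drug.k_onC * C_int * R - drug.k_offC * RC - drug.k_degRC * RC,
            pk.CL_lin * C_pla,
            n_cells * SF_UNIT * drug.k_degRC * RC,  # receptor-route elimination
        ]

    y0 = [
        dose_to_plasma_concentration(scenario.dose, pk), 0.0,
        ss.R, ss.R_i, ss.RL, 0.0, 0.0, 0.0,
    ]
    atol = [ATOL_CONC] * 2 + [ATOL_COUNT] * 4 + [ATOL_AMOUNT] * 2
    sol = _solve(rhs, y0, scenario, atol, rtol)
    names = ["C_pla", "C_int", "R", "R_i", "RL", "RC", "A_cl", "A_deg"]
    return Trajectory(
        t=sol.t,
        states={n: sol.y[i] for i, n in enumerate(names)},
        units={
            "C_pla": "nM", "C_int": "nM",
            "R": "molecules/cell", "R_i": "molecules/cell",
            "RL": "molecules/cell", "RC": "molecules/cell",
            "A_cl": "nmol/kg", "A_deg": "nmol/kg",
        },
        metadata={
            "model": "cell_level_pkpd",
            "dose_mg_per_kg": scenario.dose,
            "dose_nmol_per_kg": dose_nmol,
            "N_cell": n_cells,
            "R_star": ss.R, "R_i_star": ss.R_i, "RL_star": ss.RL,
            "K_D_nM": drug.K_D if drug.k_onC > 0 else None,
            "drug": drug.name,
            "V_pla": pk.V_pla, "V_int": pk.V_int,
            "rtol": rtol,
        },
    )


def simulate_two_populations(
    pk: PKParameters,
    normal: tuple[CellParameters, float],
    tumor: tuple[CellParameters, float],
    drug: DrugParameters,
    env: LigandEnvironment,
    scenario: DoseScenario,
    rtol: float = DEFAULT_RTOL,
) -> Trajectory:
    """Combined model with normal (``_N``) and tumor (``_T``) populations.

    Both populations start at their own pretreatment steady states and
    exchange drug with the same interstitial compartment, each scaled by its
    cell count [cells/kg].
    """
    cell_N, n_N = normal
    cell_T, n_T = tumor
    ss_N = pretreatment_steady_state(cell_N, env)
    ss_T = pretreatment_steady_state(cell_T, env)
    dose_nmol = mg_to_nmol(scenario.dose, pk.MW)

    def pop_rhs(cell: CellParameters, y, C_int):
        R, R_i, RL, RC = y
        return [
            cell.k_synR - cell.k_onL * R * env.L - drug.k_onC * R * C_int
            + cell.k_offL * RL + drug.k_offC * RC - cell.k_degR * R
            + cell.k_recyRi * R_i,
            cell.k_degR * R - cell.k_recyRi * R_i - cell.k_degRi * R_i,
            cell.k_onL * env.L * R - cell.k_offL * RL - cell.k_degRL * RL,
            drug.k_onC * C_int * R - drug.k_offC * RC - drug.k_degRC * RC,
        ]

    def rhs(t, y):
        C_pla, C_int = y[0], y[1]
        yN, yT = y[2:6], y[6:10]
        ex_N = n_N * SF_UNIT * (drug.k_offC * yN[3] - drug.k_onC * yN[0] * C_int)
        ex_T = n_T * SF_UNIT * (drug.k_offC * yT[3] - drug.k_onC * yT[0] * C_int)
        return [
            (-pk.q_pi * C_pla + pk.q_ip * C_int - pk.CL_lin * C_pla) / pk.V_pla,
            (pk.q_pi * C_pla - pk.q_ip * C_int + ex_N + ex_T) / pk.V_int,
            *pop_rhs(cell_N, yN, C_int),
            *pop_rhs(cell_T, yT, C_int),
            pk.CL_lin * C_pla,
            SF_UNIT * drug.k_degRC * (n_N * yN[3] + n_T * yT[3]),
        ]

    y0 = [
        dose_to_plasma_concentration(scenario.dose, pk), 0.0,
        ss_N.R, ss_N.R_i, ss_N.RL, 0.0,
        ss_T.R, ss_T.R_i, ss_T.RL, 0.0,
        0.0, 0.0,
    ]
    atol = [ATOL_CONC] * 2 + [ATOL_COUNT] * 8 + [ATOL_AMOUNT] * 2
    sol = _solve(rhs, y0, scenario, atol, rtol)
    names = [
        "C_pla", "C_int",
        "R_N", "R_i_N", "RL_N", "RC_N",
        "R_T", "R_i_T", "RL_T", "RC_T",
        "A_cl", "A_deg",
    ]
    units = {"C_pla": "nM", "C_int": "nM", "A_cl": "nmol/kg", "A_deg": "nmol/kg"}
    units.update({n: "molecules/cell" for n in names[2:10]})
    return Trajectory(
        t=sol.t,
        states={n: sol.y[i] for i, n in enumerate(names)},
        units=units,
        metadata={
            "model": "two_population_pkpd",
            "dose_mg_per_kg": scenario.dose,
            "dose_nmol_per_kg": dose_nmol,
            "N_N": n_N, "N_T": n_T,
            "RL_star_N": ss_N.RL, "RL_star_T": ss_T.RL,
            "R_star_N": ss_N.R, "R_star_T": ss_T.R,
            "drug": drug.name,
            "V_pla": pk.V_pla, "V_int": pk.V_int,
            "rtol": rtol,
        },
    )


def mass_balance_audit(traj: Trajectory) -> float:
    """Worst-case relative drug-mass error over a whole-body trajectory.

    Sums free drug in both compartments, receptor-bound drug, and the
    cumulative-elimination accumulators, and compares against the
    administered amount. Returns 0 for a zero-dose run.
    """
    meta = traj.metadata
    dose = meta["dose_nmol_per_kg"]
    total = meta["V_pla"] * traj["C_pla"] + meta["V_int"] * traj["C_int"]
    model = meta["model"]
    if model == "compartment_pk":
        total = total + traj["A_RS"] + traj["A_cl"] + traj["A_el"]
    elif model == "cell_level_pkpd":
        total = total + meta["N_cell"] * SF_UNIT * traj["RC"]
        total = total + traj["A_cl"] + traj["A_deg"]
    elif model == "two_population_pkpd":
        total = total + SF_UNIT * (
            meta["N_N"] * traj["RC_N"] + meta["N_T"] * traj["RC_T"]
        )
        total = total + traj["A_cl"] + traj["A_deg"]
    else:
        raise ValueError(f"cannot audit trajectory of model {model!r}")
    if dose == 0:
        return float(np.max(np.abs(total)))
    return float(np.max(np.abs(total - dose)) / dose)
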