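"""Single-cell receptor trafficking kinetics, with and without drug.

The model tracks four receptor species per cell: free surface receptors
``R``, internalized receptors ``R_i``, signalling-competent ligand-receptor
complexes ``RL``, and antibody-receptor complexes ``RC`` (all in molecules
per cell). Receptors are synthesized at a constant rate, internalized from
the surface, and either recycled or degraded from the internal pool. The
free EGF ligand concentration is an environmental constant. An antibody in
the extracellular medium binds free receptors competitively; the bound
complex is internalized and degraded, which removes both receptor and drug
(receptor-mediated drug elimination).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import CellParameters, DrugParameters, LigandEnvironment
from .trajectory import Trajectory, output_grid
from .units import SF_UNIT

__all__ = [
    "CellState",
    "rhs_ligand_receptor",
    "rhs_cell_with_drug",
    "pretreatment_steady_state",
    "simulate_in_vitro",
]


@dataclass(frozen=True)
class CellState:
    """Receptor species of one cell [molecules/cell]."""

    R: float
    R_i: float
    RL: float
    RC: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.R_i, self.RL, self.RC], dtype=float)

    @classmethod
    def from_array(cls, y) -> "CellState":
        return cls(R=y[0], R_i=y[1], RL=y[2], RC=y[3])


def rhs_ligand_receptor(
    state: CellState, cell: CellParameters, env: LigandEnvironment
) -> CellState:
    """Time derivative of the drug-free trafficking model [molecules/cell/min].

    The RC component of the result is identically zero.
    """
    R, R_i, RL = state.R, state.R_i, state.RL
    L = env.L
    dR = (
        cell.k_synR
        - cell.k_onL * R * L
        + cell.k_offL * RL
        - cell.k_degR * R
        + cell.k_recyRi * R_i
    )
    dRi = cell.k_degR * R - cell.k_recyRi * R_i - cell.k_degRi * R_i
    dRL = cell.k_onL * R * L - cell.k_offL * RL - cell.k_degRL * RL
    return CellState(R=dR, R_i=dRi, RL=dRL, RC=0.0)


def rhs_cell_with_drug(
    state: CellState,
    C_ex: float,
    cell: CellParameters,
    drug: DrugParameters,
    env: LigandEnvironment,
) -> tuple[CellState, float]:
    """Time derivative with drug at extracellular concentration ``C_ex`` [nM].

    Returns ``(dstate/dt, drug_exchange_flux)`` where the flux
    ``SF_unit * (k_offC*RC - k_onC*R*C_ex)`` [nmol/min] is the net rate at
    which drug is returned to the extracellular medium by one cell (negative
    while net binding). Dividing by the relevant extracellular volume turns
    it into a concentration derivative.
    """
    R, R_i, RL, RC = state.R, state.R_i, state.RL, state.RC
    L = env.L
    dR = (
        cell.k_synR
        - cell.k_onL * R * L
        - drug.k_onC * R * C_ex
        + cell.k_offL * RL
        + drug.k_offC * RC
        - cell.k_degR * R
        + cell.k_recyRi * R_i
    )
    dRi = cell.k_degR * R - cell.k_recyRi * R_i - cell.k_degRi * R_i
    dRL = cell.k_onL * L * R - cell.k_offL * RL - cell.k_degRL * RL
    dRC = drug.k_onC * C_ex * R - drug.k_offC * RC - drug.k_degRC * RC
    flux = SF_UNIT * (drug.k_offC * RC - drug.k_onC * R * C_ex)
    return CellState(R=dR, R_i=dRi, RL=dRL, RC=dRC), flux


def drug_independent_loss(cell: CellParameters, env: LigandEnvironment) -> float:
    """Effective first-order loss rate of free surface receptors [1/min].

    Sum of the net internalization-degradation route (internalization
    discounted by recycling) and the net ligand-induced removal route. This
    factor sets the pretreatment receptor level and is the drug-independent
    part of the cell-level Michaelis constant.
    """
    if cell.k_recyRi + cell.k_degRi <= 0:
        raise ValueError("k_recyRi + k_degRi must be > 0")
    if cell.k_offL + cell.k_degRL <= 0:
        raise ValueError("k_offL + k_degRL must be > 0")
    return cell.k_degR * cell.k_degRi / (cell.k_recyRi + cell.k_degRi) + (
        env.L * cell.k_onL * cell.k_degRL / (cell.k_offL + cell.k_degRL)
    )


def pretreatment_steady_state(
    cell: CellParameters, env: LigandEnvironment
) -> CellState:
    """Closed-form drug-free steady state (RC = 0).

    Setting the trafficking derivatives to zero and eliminating ``R_i`` and
    ``RL`` gives ``R* = k_synR / loss`` with the drug-independent loss
    factor above, then ``RL* = k_onL L R*/(k_offL + k_degRL)`` and
    ``R_i* = k_degR R*/(k_recyRi + k_degRi)``.
    """
    loss = drug_independent_loss(cell, env)
    if loss <= 0:
        raise ValueError(
            "degenerate trafficking parameters: drug-independent loss factor "
            f"is {loss}; the receptor pool has no steady state"
        )
    R = cell.k_synR / loss
    RL = cell.k_onL * env.L * R / (cell.k_offL + cell.k_degRL)
    R_i = cell.k_degR * R / (cell.k_recyRi + cell.k_degRi)
    return CellState(R=R, R_i=R_i, RL=RL, RC=0.0)


def simulate_in_vitro(
    initial: CellState,
    C_ex0: float,
    cell: CellParameters,
    drug: DrugParameters,
    env: LigandEnvironment,
    horizon: float,
    n_points: int = 400,
    rtol: float = 1e-8,
    atol_conc: float = 1e-10,
    atol_count: float = 1e-6,
) -> Trajectory:
    """Integrate the closed in vitro system (drug depletes from ``V_ex``).

    One cell sits in a fixed extracellular volume ``cell.V_ex`` [L] with
    initial drug concentration ``C_ex0`` [nM]; bound drug that is
    internalized is tracked in a cumulative accumulator so that total drug
    mass is conserved exactly. ``horizon`` is in minutes.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    V_ex = cell.V_ex

    def rhs(t, y):
        state = CellState.from_array(y[1:5])
        dstate, flux = rhs_cell_with_drug(state, y[0], cell, drug, env)
        return [
            flux / V_ex,
            dstate.R,
            dstate.R_i,
            dstate.RL,
            dstate.RC,
            SF_UNIT * drug.k_degRC * state.RC,  # cumulative internalized drug [nmol]
        ]

    y0 = [C_ex0, initial.R, initial.R_i, initial.RL, initial.RC, 0.0]
    grid = output_grid(horizon, n_log=n_points, daily=False)
    atol = [atol_conc] + [atol_count] * 4 + [atol_conc]
    sol = solve_ivp(
        rhs, (0.0, horizon), y0, method="LSODA", rtol=rtol, atol=atol, t_eval=grid
    )
    if not sol.success:
        raise RuntimeError(
            f"in vitro solver failed (rtol={rtol}, atol={atol}): {sol.message}"
        )
    names = ["C_ex", "R", "R_i", "RL", "RC", "A_deg"]
    unit_of = {
        "C_ex": "nM",
        "R": "molecules/cell",
        "R_i": "molecules/cell",
        "RL": "molecules/cell",
        "RC": "molecules/cell",
        "A_deg": "nmol",
    }
    return Trajectory(
        t=sol.t,
        states={name: sol.y[i] for i, name in enumerate(names)},
        units=unit_of,
        metadata={
            "model": "in_vitro_cell",
            "C_ex0_nM": C_ex0,
            "V_ex_L": V_ex,
            "rtol": rtol,
            "drug": drug.name,
        },
    )


def in_vitro_drug_mass(traj: Trajectory) -> np.ndarray:
    """Total tracked drug [nmol] over an in vitro trajectory (free + bound +
    cumulatively internalized); constant up to solver error."""
    V_ex = traj.metadata["V_ex_L"]
    return V_ex * traj["C_ex"] + SF_UNIT * traj["RC"] + traj["A_deg"]
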