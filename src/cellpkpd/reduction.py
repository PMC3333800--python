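"""Quasi-steady-state reduction and in vitro - in vivo linking.

Under the quasi-steady-state assumption the four receptor species
equilibrate fast relative to drug disposition, and the cell acts on the
drug like a single Michaelis-Menten binding site with capacity
``B_max_cell = SF_unit * k_synR / k_degRC`` [nmol/cell] and half-maximal
concentration ``K_M_cell`` [nM] that factorizes into a drug-specific and a
drug-independent part. Matching the single-cell capacity to the whole-body
binding capacity fitted in vivo yields the number of relevant
target-expressing cells ``N_cell``, and the ratio of half-maximal binding
concentrations defines a dimensionless in vitro - in vivo scaling factor
``SF_iviv`` applied to antibody affinities for in vivo simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.integrate import solve_ivp

from .cell import drug_independent_loss
from .params import (
    CellParameters,
    DrugParameters,
    LigandEnvironment,
    PKParameters,
    as_dict,
)
from .trajectory import Trajectory, output_grid
from .units import SF_UNIT

__all__ = [
    "ReducedCellParameters",
    "LinkResult",
    "effective_bmax",
    "effective_km",
    "reduced_free_concentration",
    "reduced_rhs",
    "simulate_reduced",
    "compute_link",
]


@dataclass(frozen=True)
class ReducedCellParameters:
    """Apparent Michaelis-Menten drug binding parameters of a single cell."""

    B_max_cell: float  # maximal bound drug per cell [nmol/cell]
    K_M_cell: float    # half-maximal binding concentration [nM]

    def __post_init__(self) -> None:
        if self.B_max_cell <= 0 or self.K_M_cell <= 0:
            raise ValueError("B_max_cell and K_M_cell must be > 0")


@dataclass(frozen=True)
class LinkResult:
    """Linking constants between the single-cell and whole-body levels.

    ``sf_iviv`` is reported as the ratio K_M_cell / K_M_PK. The inverse
    ratio is recorded alongside because the defining relation can be read in
    either direction; the forward ratio is the one that is subsequently used
    to scale in vitro affinities up to in vivo conditions.
    """

    N_cell: float          # number of relevant target-expressing cells [1/kg]
    SF_iviv: float         # in vitro - in vivo scaling factor [-]
    B_max_cell: float      # [nmol/cell]
    K_M_cell: float        # [nM] (computed with the unscaled in vitro K_D)
    K_M_PK: float          # [nM]
    SF_iviv_inverse: float # K_M_PK / K_M_cell, recorded for transparency
    provenance: dict[str, Any] = field(default_factory=dict, compare=False)

    def to_json(self, **kwargs) -> str:
        data = {
            "N_cell": self.N_cell,
            "SF_iviv": self.SF_iviv,
            "B_max_cell": self.B_max_cell,
            "K_M_cell": self.K_M_cell,
            "K_M_PK": self.K_M_PK,
            "SF_iviv_inverse": self.SF_iviv_inverse,
            "provenance": self.provenance,
        }
        return json.dumps(data, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "LinkResult":
        return cls(**json.loads(text))


def effective_bmax(cell: CellParameters, drug: DrugParameters) -> float:
    """Maximal drug binding capacity of one cell [nmol/cell].

    ``B_max_cell = SF_unit * k_synR / k_degRC``: at saturation every newly
    synthesized receptor is eventually drug-bound and internalized, so the
    standing bound pool is synthesis divided by complex turnover. Depends
    only on the receptor system and the complex internalization rate, not on
    binding kinetics.
    """
    if drug.k_degRC <= 0:
        raise ValueError(
            "k_degRC must be > 0: without complex internalization the "
            "binding capacity is unbounded"
        )
    return SF_UNIT * cell.k_synR / drug.k_degRC


def effective_km(
    cell: CellParameters, drug: DrugParameters, env: LigandEnvironment
) -> float:
    """Half-maximal binding concentration of one cell [nM].

    Product of a drug-specific factor ``(k_degRC + k_offC)/(k_degRC *
    k_onC)`` and the drug-independent free-receptor loss rate (see
    :func:`cellpkpd.cell.drug_independent_loss`).
    """
    if drug.k_degRC <= 0 or drug.k_onC <= 0:
        raise ValueError("k_degRC and k_onC must be > 0 for a finite K_M_cell")
    drug_specific = (drug.k_degRC + drug.k_offC) / (drug.k_degRC * drug.k_onC)
    return drug_specific * drug_independent_loss(cell, env)


def reduced_cell_parameters(
    cell: CellParameters, drug: DrugParameters, env: LigandEnvironment
) -> ReducedCellParameters:
    return ReducedCellParameters(
        B_max_cell=effective_bmax(cell, drug),
        K_M_cell=effective_km(cell, drug, env),
    )


def reduced_free_concentration(
    C_tot, reduced: ReducedCellParameters, V_ex: float
):
    """Free drug concentration [nM] given the total concentration [nM].

    Solves ``C_tot = C_ex + A_RS/V_ex`` with the bound amount
    ``A_RS = B_max_cell * C_ex/(K_M_cell + C_ex)`` for ``C_ex``; the
    positive root of the resulting quadratic is
    ``C_ex = (C_D + sqrt(C_D^2 + 4 K_M_cell C_tot))/2`` with
    ``C_D = C_tot - B_max_cell/V_ex - K_M_cell``.
    """
    C_tot = np.asarray(C_tot, dtype=float)
    if np.any(C_tot < 0):
        raise ValueError("C_tot must be >= 0")
    K_M = reduced.K_M_cell
    C_D = C_tot - reduced.B_max_cell / V_ex - K_M
    root = np.sqrt(C_D * C_D + 4.0 * K_M * C_tot)
    # cancellation-free branch: for C_D < 0 the textbook root subtracts two
    # nearly equal numbers, so use the conjugate form there
    with np.errstate(divide="ignore", invalid="ignore"):
        C_ex = np.where(
            C_D >= 0,
            0.5 * (C_D + root),
            np.where(root - C_D > 0, 2.0 * K_M * C_tot / (root - C_D), 0.0),
        )
    return np.clip(C_ex, 0.0, C_tot)[()]


def reduced_rhs(
    C_tot: float,
    reduced: ReducedCellParameters,
    drug: DrugParameters,
    V_ex: float,
) -> float:
    """dC_tot/dt [nM/min] of the reduced single-cell depletion model.

    ``V_ex dC_tot/dt = -k_degRC * B_max_cell * C_ex/(K_M_cell + C_ex)``:
    the only drug sink is internalization of the (quasi-equilibrated) bound
    pool.
    """
    C_ex = reduced_free_concentration(C_tot, reduced, V_ex)
    A_RS = reduced.B_max_cell * C_ex / (reduced.K_M_cell + C_ex)
    return -drug.k_degRC * A_RS / V_ex


def simulate_reduced(
    C_tot0: float,
    cell: CellParameters,
    drug: DrugParameters,
    env: LigandEnvironment,
    horizon: float,
    n_points: int = 400,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the reduced depletion model from total concentration
    ``C_tot0`` [nM] over ``horizon`` minutes (V_ex from ``cell``)."""
    reduced = reduced_cell_parameters(cell, drug, env)
    V_ex = cell.V_ex

    def rhs(t, y):
        return [reduced_rhs(max(y[0], 0.0), reduced, drug, V_ex)]

    grid = output_grid(horizon, n_log=n_points, daily=False)
    sol = solve_ivp(
        rhs, (0.0, horizon), [C_tot0], method="LSODA", rtol=rtol, atol=atol,
        t_eval=grid,
    )
    if not sol.success:
        raise RuntimeError(f"reduced-model solver failed: {sol.message}")
    C_tot = sol.y[0]
    C_ex = reduced_free_concentration(C_tot, reduced, V_ex)
    return Trajectory(
        t=sol.t,
        states={"C_tot": C_tot, "C_ex": np.asarray(C_ex)},
        units={"C_tot": "nM", "C_ex": "nM"},
        metadata={
            "model": "reduced_cell",
            "B_max_cell": reduced.B_max_cell,
            "K_M_cell": reduced.K_M_cell,
            "V_ex_L": V_ex,
        },
    )


def compute_link(
    pk: PKParameters,
    cell: CellParameters,
    drug: DrugParameters,
    env: LigandEnvironment,
    fixture_id: str | None = None,
) -> LinkResult:
    """Compute the cell-to-body linking constants.

    ``N_cell = k_degRC * B_max_PK / (k_synR * SF_unit)`` scales the
    single-cell capacity to the whole-body capacity (so that
    ``N_cell * B_max_cell = B_max_PK`` holds by construction, asserted
    here), and ``SF_iviv = K_M_cell / K_M_PK`` with ``K_M_cell`` evaluated
    at the *unscaled* in vitro affinity, avoiding circularity.
    """
    if cell.k_synR <= 0:
        raise ValueError("k_synR must be > 0 to determine N_cell")
    B_max_cell = effective_bmax(cell, drug)
    K_M_cell = effective_km(cell, drug, env)
    N_cell = drug.k_degRC * pk.B_max_PK / (cell.k_synR * SF_UNIT)
    closure = N_cell * B_max_cell
    if not np.isclose(closure, pk.B_max_PK, rtol=1e-9):
        raise AssertionError(
            f"capacity closure violated: N_cell*B_max_cell = {closure} "
            f"!= B_max_PK = {pk.B_max_PK}"
        )
    if pk.K_M_PK <= 0:
        raise ValueError("K_M_PK must be > 0 to determine SF_iviv")
    return LinkResult(
        N_cell=N_cell,
        SF_iviv=K_M_cell / pk.K_M_PK,
        B_max_cell=B_max_cell,
        K_M_cell=K_M_cell,
        K_M_PK=pk.K_M_PK,
        SF_iviv_inverse=pk.K_M_PK / K_M_cell,
        provenance={
            "fixture": fixture_id,
            "cell": as_dict(cell),
            "drug": as_dict(drug),
            "pk": as_dict(pk),
            "L_nM": env.L,
            "formulas": {
                "B_max_cell": "SF_unit * k_synR / k_degRC",
                "K_M_cell": "(k_degRC + k_offC)/(k_degRC*k_onC) * "
                            "(k_degRi*k_degR/(k_degRi+k_recyRi) + "
                            "L*k_onL*k_degRL/(k_offL+k_degRL))",
                "N_cell": "k_degRC * B_max_PK / (k_synR * SF_unit)",
                "SF_iviv": "K_M_cell / K_M_PK",
            },
        },
    )
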