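"""Receptor saturation, residual activity, and transient-inhibition metrics.

The inhibitory effect of an antagonistic antibody is transient: activated
receptor complexes ``RL`` dip below their pretreatment steady-state level
``RL*`` and recover as the drug is eliminated. Three summary measures
quantify the transient:

* the *integral of inhibition* ``E = integral of (RL* - RL(t)) dt``
  [molecules/cell * day] -- cumulative loss of receptor activation,
* the *peak inhibition* ``(RL* - min RL)/RL*`` [-] -- maximal fractional
  reduction,
* the *duration of inhibition* [day] -- time until activation recovers to a
  given fraction (default 75%) of ``RL*``.

For two cell populations, tumor-to-normal ratios of the three measures give
the specificity of the antibody for tumor cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "EffectMetrics",
    "SpecificityMetrics",
    "receptor_saturation",
    "residual_activity",
    "inhibition_metrics",
    "time_below_residual",
    "specificity",
]


@dataclass(frozen=True)
class EffectMetrics:
    """Transient-inhibition summary of one cell population."""

    E: float               # integral of inhibition [molecules/cell * day]
    peak: float            # peak inhibition, fraction of RL* [-]
    duration: float        # duration of inhibition [day]
    max_saturation: float  # max receptor saturation over the run [-]
    RL_star: float         # pretreatment activated receptors [molecules/cell]
    duration_censored: bool = False  # RL had not recovered by the horizon
    tail_deficit: float = 0.0        # (RL* - RL)/RL* at the horizon

    def __post_init__(self) -> None:
        if not (0.0 <= self.peak <= 1.0 + 1e-12):
            raise ValueError(f"peak must be in [0, 1], got {self.peak}")
        if self.E < -1e-9 or self.duration < 0:
            raise ValueError("E and duration must be >= 0")


@dataclass(frozen=True)
class SpecificityMetrics:
    """Tumor-to-normal ratios of the inhibition measures."""

    S_E: float
    S_p: float
    S_d: float


def receptor_saturation(R, RL, RC):
    """Fraction of surface receptors occupied by drug: RC/(R + RL + RC)."""
    R, RL, RC = np.asarray(R, float), np.asarray(RL, float), np.asarray(RC, float)
    total = R + RL + RC
    if np.any(total <= 0):
        raise ValueError("receptor saturation undefined: no surface receptors")
    return (RC / total)[()]


def residual_activity(RL, RL_star: float):
    """Activated receptors relative to the pretreatment level: RL/RL*."""
    if RL_star <= 0:
        raise ValueError("RL_star must be > 0")
    return (np.asarray(RL, float) / RL_star)[()]


def _population_suffix(traj: Trajectory, population_label: str | None) -> str:
    if population_label is None:
        if "RL" in traj:
            return ""
        raise ValueError(
            "trajectory has multiple populations; pass population_label"
        )
    suffix = f"_{population_label}"
    if f"RL{suffix}" not in traj:
        raise KeyError(f"no population {population_label!r} in trajectory")
    return suffix


def inhibition_metrics(
    traj: Trajectory,
    population_label: str | None = None,
    recovery_fraction: float = 0.75,
    start_tolerance: float = 1e-6,
) -> EffectMetrics:
    """Compute the transient-inhibition measures from a trajectory.

    The trajectory must begin at the pretreatment steady state (checked to
    ``start_tolerance`` relative). The integral is evaluated by trapezoidal
    quadrature on the trajectory's grid and truncated at the horizon; the
    remaining deficit at the horizon is reported as ``tail_deficit`` so a
    truncation bias is visible. A duration that has not completed by the
    horizon is reported as the horizon with ``duration_censored=True``.
    """
    suffix = _population_suffix(traj, population_label)
    RL = traj[f"RL{suffix}"]
    star_key = f"RL_star{suffix}"
    RL_star = traj.metadata.get(star_key, traj.metadata.get("RL_star"))
    if RL_star is None:
        raise KeyError("trajectory metadata lacks the pretreatment RL level")
    if abs(RL[0] - RL_star) > start_tolerance * RL_star:
        raise ValueError(
            "trajectory does not start at the pretreatment steady state: "
            f"RL(0) = {RL[0]}, RL* = {RL_star}"
        )
    t_day = traj.t_days
    resid = residual_activity(RL, RL_star)

    E = float(np.trapezoid(np.maximum(RL_star - RL, 0.0), t_day))
    peak = float(min(max((RL_star - RL.min()) / RL_star, 0.0), 1.0))
    tail_deficit = float(max((RL_star - RL[-1]) / RL_star, 0.0))

    below = resid < recovery_fraction
    duration = 0.0
    censored = False
    if below.any():
        i0 = int(np.argmax(below))
        recovered = np.nonzero(resid[i0:] >= recovery_fraction)[0]
        if recovered.size:
            duration = float(t_day[i0 + recovered[0]])
        else:
            duration = float(t_day[-1])
            censored = True

    sat_args = (traj[f"R{suffix}"], RL, traj[f"RC{suffix}"])
    max_sat = float(np.max(receptor_saturation(*sat_args)))
    return EffectMetrics(
        E=E,
        peak=peak,
        duration=duration,
        max_saturation=max_sat,
        RL_star=float(RL_star),
        duration_censored=censored,
        tail_deficit=tail_deficit,
    )


def time_below_residual(
    traj: Trajectory,
    threshold: float = 0.10,
    population_label: str | None = None,
) -> float:
    """Length [day] of the contiguous window with residual activity below
    ``threshold``.

    Reported as a diagnostic for near-complete inhibition; the default 10%
    threshold marks the window in which receptor activation is essentially
    abolished.
    """
    suffix = _population_suffix(traj, population_label)
    RL = traj[f"RL{suffix}"]
    RL_star = traj.metadata.get(f"RL_star{suffix}", traj.metadata.get("RL_star"))
    resid = residual_activity(RL, RL_star)
    below = resid < threshold
    if not below.any():
        return 0.0
    t_day = traj.t_days
    i0 = int(np.argmax(below))
    after = np.nonzero(~below[i0:])[0]
    i1 = i0 + (int(after[0]) - 1 if after.size else len(below) - 1 - i0)
    return float(t_day[i1] - t_day[i0])


def specificity(tumor: EffectMetrics, normal: EffectMetrics) -> SpecificityMetrics:
    """Tumor-to-normal ratios S_E, S_p, S_d of the inhibition measures."""
    for name, value in (("E", normal.E), ("peak", normal.peak),
                        ("duration", normal.duration)):
        if value <= 0:
            raise ZeroDivisionError(
                f"normal-cell {name} is zero; specificity undefined"
            )
    return SpecificityMetrics(
        S_E=tumor.E / normal.E,
        S_p=tumor.peak / normal.peak,
        S_d=tumor.duration / normal.duration,
    )
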