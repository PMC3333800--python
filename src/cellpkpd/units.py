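"""Canonical unit system and conversions.

Everything inside the package runs in one consistent unit system chosen so
that receptor-trafficking rate constants (printed per minute) need no
conversion and drug amounts stay O(1)-O(1e3):

====================  =========================
quantity              canonical unit
====================  =========================
time                  min
amount of drug        nmol (per kg body weight)
concentration         nM
receptor counts       molecules per cell
volume                L (per kg body weight)
====================  =========================

With volumes in litres, ``amount [nmol] = volume [L] * concentration [nM]``
holds without extra factors, which keeps the whole-body mass balance exact.
Parameter fixtures store values in the units they were originally reported
in (ml/kg, 1/h, mg/ml, M); :mod:`cellpkpd.params` converts on load through
the registry below.
"""

from __future__ import annotations

N_AVOGADRO = 6.02e23
"""Avogadro's number [1/mol], at the precision used throughout the model."""

SF_UNIT = 1e9 / N_AVOGADRO
"""Scaling factor from molecule counts to nmol: 1 molecule = SF_UNIT nmol."""

MINUTES_PER_HOUR = 60.0
MINUTES_PER_DAY = 1440.0


def per_hour_to_per_minute(value: float) -> float:
    return value / MINUTES_PER_HOUR


def per_minute_to_per_hour(value: float) -> float:
    return value * MINUTES_PER_HOUR


def mg_to_nmol(mass_mg: float, mw_g_per_mol: float) -> float:
    """Convert a protein mass [mg] to [nmol] given its molecular weight.

    1 mg of a compound with molecular weight MW [g/mol] is 1e6/MW nmol.
    """
    if mw_g_per_mol <= 0:
        raise ValueError("molecular weight must be positive")
    return mass_mg * 1e6 / mw_g_per_mol


def nmol_to_mg(amount_nmol: float, mw_g_per_mol: float) -> float:
    if mw_g_per_mol <= 0:
        raise ValueError("molecular weight must be positive")
    return amount_nmol * mw_g_per_mol / 1e6


def mg_per_ml_to_nM(conc_mg_per_ml: float, mw_g_per_mol: float) -> float:
    """Convert a mass concentration [mg/ml] to a molar concentration [nM]."""
    # mg/ml -> nmol/ml, and 1 nmol/ml = 1 umol/L = 1000 nM
    return mg_to_nmol(conc_mg_per_ml, mw_g_per_mol) * 1000.0


def nM_to_mg_per_ml(conc_nM: float, mw_g_per_mol: float) -> float:
    return nmol_to_mg(conc_nM / 1000.0, mw_g_per_mol)


def molecules_to_nmol(count: float) -> float:
    return count * SF_UNIT


def nmol_to_molecules(amount_nmol: float) -> float:
    return amount_nmol / SF_UNIT


def ml_to_l(volume_ml: float) -> float:
    return volume_ml * 1e-3


# Unit registry used by the fixture loader: maps the unit string found in a
# fixture file to (canonical unit, conversion). Conversions that need the
# drug molecular weight are resolved at load time.
_SIMPLE_UNITS = {
    "min": ("min", 1.0),
    "1/min": ("1/min", 1.0),
    "1/(nM*min)": ("1/(nM*min)", 1.0),
    "molecules/(cell*min)": ("molecules/(cell*min)", 1.0),
    "1/h": ("1/min", 1.0 / MINUTES_PER_HOUR),
    "ml/kg": ("L/kg", 1e-3),
    "ml": ("L", 1e-3),
    "nM": ("nM", 1.0),
    "M": ("nM", 1e9),
    "g/mol": ("g/mol", 1.0),
    "dimensionless": ("dimensionless", 1.0),
}

_MW_UNITS = {
    # unit string -> (canonical unit, conversion function of (value, MW))
    "mg/ml": ("nM", mg_per_ml_to_nM),
    "mg/kg": ("nmol/kg", mg_to_nmol),
}


def convert(value: float, unit: str, mw_g_per_mol: float | None = None) -> tuple[float, str]:
    """Convert ``value`` in ``unit`` to canonical units.

    Returns ``(canonical_value, canonical_unit)``. Mass-based units require
    ``mw_g_per_mol``. Unknown unit strings raise ``ValueError``.
    """
    if unit in _SIMPLE_UNITS:
        canonical, factor = _SIMPLE_UNITS[unit]
        return value * factor, canonical
    if unit in _MW_UNITS:
        if mw_g_per_mol is None:
            raise ValueError(f"unit {unit!r} requires a molecular weight")
        canonical, func = _MW_UNITS[unit]
        return func(value, mw_g_per_mol), canonical
    raise ValueError(f"unknown unit string: {unit!r}")
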