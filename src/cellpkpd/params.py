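"""Parameter containers, fixture loading, and species adjustment.

Three parameter sets drive the model:

* :class:`CellParameters` -- receptor-trafficking rate constants of one cell
  type (synthesis, ligand binding, internalization, recycling, degradation),
  experimentally determined in human fibroblasts in vitro.
* :class:`DrugParameters` -- antibody binding/internalization constants and
  molecular weight. The dissociation constant ``K_D = k_offC/k_onC`` is
  always derived, never stored.
* :class:`PKParameters` -- whole-body compartment volumes, transfer flows,
  clearances and the apparent Michaelis-Menten binding parameters fitted to
  monkey plasma data.

Fixtures ship the values in their originally reported units; everything is
converted to the canonical system of :mod:`cellpkpd.units` on load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from . import units

__all__ = [
    "CellParameters",
    "DrugParameters",
    "PKParameters",
    "LigandEnvironment",
    "Species",
    "load_parameters",
    "load_environment",
    "load_fixture",
    "apply_species_adjustment",
    "drug_from_affinity",
]

# Factors applied to translate the human in vitro trafficking constants to
# cynomolgus monkey: recycling is 4-fold faster, free-receptor
# internalization 4-fold slower.
CYNOMOLGUS_RECYCLING_FACTOR = 4.0
CYNOMOLGUS_INTERNALIZATION_FACTOR = 0.25


class Species(str, Enum):
    HUMAN_INVITRO = "human_invitro"
    CYNOMOLGUS = "cynomolgus"


@dataclass(frozen=True)
class CellParameters:
    """Receptor-trafficking rate constants for one cell type.

    All rates are in canonical units (per minute); ``k_synR`` is in
    molecules per cell per minute. ``V_ex`` [L] is the extracellular volume
    associated with a single cell and is only used by the standalone
    in vitro simulator and the reduced model -- it cancels out of the linked
    whole-body model.
    """

    k_synR: float        # receptor synthesis [molecules/cell/min]
    k_onL: float         # ligand association [1/(nM*min)]
    k_offL: float        # ligand dissociation [1/min]
    k_degR: float        # free surface receptor internalization [1/min]
    k_degRL: float       # ligand-receptor complex internalization [1/min]
    k_recyRi: float      # internal receptor recycling [1/min]
    k_degRi: float       # internal receptor degradation [1/min]
    V_ex: float = 4e-13  # extracellular volume per cell [L]
    species: Species = Species.HUMAN_INVITRO

    def __post_init__(self) -> None:
        for name in ("k_synR", "k_onL", "k_offL", "k_degR", "k_degRL",
                     "k_recyRi", "k_degRi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.V_ex <= 0:
            raise ValueError(f"V_ex must be > 0, got {self.V_ex}")


@dataclass(frozen=True)
class DrugParameters:
    """Antibody binding and internalization constants (canonical units)."""

    k_onC: float    # drug-receptor association [1/(nM*min)]
    k_offC: float   # drug-receptor dissociation [1/min]
    k_degRC: float  # drug-receptor complex internalization [1/min]
    MW: float       # molecular weight [g/mol]
    name: str = "antibody"

    def __post_init__(self) -> None:
        for field in ("k_onC", "k_offC", "k_degRC"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")
        if self.MW <= 0:
            raise ValueError("MW must be > 0")

    @property
    def K_D(self) -> float:
        """Dissociation constant k_offC/k_onC [nM] (derived, never stored)."""
        if self.k_onC == 0:
            raise ZeroDivisionError("K_D undefined for k_onC = 0")
        return self.k_offC / self.k_onC


@dataclass(frozen=True)
class PKParameters:
    """Whole-body compartment PK parameters (canonical units).

    Volumes are per kg body weight, so bolus doses in mg/kg need no
    body-weight input. ``q_pi = V_pla*k_pi`` and ``q_ip = V_int*k_ip`` are
    derived on construction and hold exactly.
    """

    V_pla: float      # plasma volume [L/kg]
    V_int: float      # interstitial volume [L/kg]
    k_pi: float       # plasma -> interstitial transfer [1/min]
    k_ip: float       # interstitial -> plasma transfer [1/min]
    CL_lin: float     # linear (target-independent) clearance [L/min/kg]
    k_b: float        # artificial equilibration rate constant [1/min]
    k_el: float       # receptor-route elimination rate constant [1/min]
    B_max_PK: float   # whole-body binding capacity [nmol/kg]
    K_M_PK: float     # half-maximal binding concentration [nM]
    MW: float = 148000.0  # antibody molecular weight used for conversions

    def __post_init__(self) -> None:
        if self.V_pla <= 0 or self.V_int <= 0:
            raise ValueError("compartment volumes must be > 0")
        for field in ("k_pi", "k_ip", "CL_lin", "k_b", "k_el", "B_max_PK", "K_M_PK"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")

    @property
    def q_pi(self) -> float:
        """Plasma -> interstitial transfer flow [L/min/kg]."""
        return self.V_pla * self.k_pi

    @property
    def q_ip(self) -> float:
        """Interstitial -> plasma transfer flow [L/min/kg]."""
        return self.V_int * self.k_ip


@dataclass(frozen=True)
class LigandEnvironment:
    """Free extracellular EGF concentration [nM], held constant.

    The ligand has no dynamics of its own in this model family; it enters
    the receptor balance only through the constant activation pressure
    ``k_onL * L``.
    """

    L: float = 2.36e-3

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError("ligand concentration must be >= 0")


# ---------------------------------------------------------------------------
# Fixture loading


def _fixture_path(fixture_id: str | Path) -> Path:
    path = Path(fixture_id)
    if path.suffix in (".yaml", ".yml") and path.exists():
        return path
    packaged = resources.files("cellpkpd") / "fixtures" / f"{fixture_id}.yaml"
    with resources.as_file(packaged) as p:
        if p.exists():
            return Path(p)
    raise FileNotFoundError(f"no such parameter fixture: {fixture_id!r}")


def _get(entry: dict, section: str, key: str, mw: float | None = None) -> float:
    try:
        spec = entry[section][key]
    except KeyError as exc:
        raise KeyError(f"fixture is missing required key {section}.{key}") from exc
    try:
        value, unit = float(spec["value"]), str(spec["unit"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(
            f"fixture entry {section}.{key} must be a mapping with "
            f"'value' and 'unit'"
        ) from exc
    converted, _ = units.convert(value, unit, mw_g_per_mol=mw)
    return converted


def load_fixture(fixture_id: str | Path) -> dict[str, Any]:
    """Return the raw (unconverted) fixture document."""
    with open(_fixture_path(fixture_id)) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"fixture {fixture_id!r} did not parse to a mapping")
    return doc


def load_parameters(
    fixture_id: str | Path = "zalutumumab_monkey",
) -> tuple[CellParameters, DrugParameters, PKParameters]:
    """Load a parameter fixture and return canonical-unit containers.

    The returned :class:`CellParameters` carry the in vitro values as
    reported (species marker ``human_invitro``); apply
    :func:`apply_species_adjustment` explicitly for in vivo use. The drug's
    ``k_offC`` is derived from the fixture's in vitro affinity without any
    in vitro - in vivo scaling; see :func:`drug_from_affinity`.
    """
    doc = load_fixture(fixture_id)
    mw = _get(doc, "drug", "MW")

    cell = CellParameters(
        k_synR=_get(doc, "cell", "k_synR"),
        k_onL=_get(doc, "cell", "k_onL"),
        k_offL=_get(doc, "cell", "k_offL"),
        k_degR=_get(doc, "cell", "k_degR"),
        k_degRL=_get(doc, "cell", "k_degRL"),
        k_recyRi=_get(doc, "cell", "k_recyRi"),
        k_degRi=_get(doc, "cell", "k_degRi"),
        V_ex=_get(doc, "cell", "V_ex"),
    )
    k_onC = _get(doc, "drug", "k_onC")
    drug = drug_from_affinity(
        K_D_invitro=_get(doc, "drug", "K_D") * 1e-9,  # back to molar
        k_onC=k_onC,
        k_degRC=_get(doc, "drug", "k_degRC"),
        MW=mw,
        name=str(doc.get("drug", {}).get("name", "antibody")),
    )
    pk = PKParameters(
        V_pla=_get(doc, "pk", "V_pla"),
        V_int=_get(doc, "pk", "V_int"),
        k_pi=_get(doc, "pk", "k_pi"),
        k_ip=_get(doc, "pk", "k_ip"),
        CL_lin=_load_cl(doc),
        k_b=_get(doc, "pk", "k_b"),
        k_el=_get(doc, "pk", "k_el"),
        B_max_PK=_get(doc, "pk", "B_max_PK", mw),
        K_M_PK=_get(doc, "pk", "K_M_PK", mw),
        MW=mw,
    )
    return cell, drug, pk


def _load_cl(doc: dict) -> float:
    """CL_lin may be given directly (ml/h/kg) or derived as V_pla*k_el."""
    pk = doc.get("pk", {})
    if "CL_lin" in pk:
        spec = pk["CL_lin"]
        value, unit = float(spec["value"]), str(spec["unit"])
        if unit == "ml/h/kg":
            return value * 1e-3 / units.MINUTES_PER_HOUR  # -> L/min/kg
        raise ValueError(f"unknown unit string: {unit!r}")
    v_pla = _get(doc, "pk", "V_pla")
    k_el = _get(doc, "pk", "k_el")
    return v_pla * k_el


def load_environment(fixture_id: str | Path = "zalutumumab_monkey") -> LigandEnvironment:
    """Load the fixed ligand environment recorded in a fixture."""
    doc = load_fixture(fixture_id)
    return LigandEnvironment(L=_get(doc, "environment", "L"))


# ---------------------------------------------------------------------------
# Parameter transformations


def apply_species_adjustment(cell: CellParameters, species: Species | str) -> CellParameters:
    """Translate in vitro trafficking constants to another species.

    For cynomolgus monkey, recycling ``k_recyRi`` is multiplied by 4 and
    free-receptor internalization ``k_degR`` by 1/4; all other constants are
    unchanged. The operation is *not* idempotent, so the returned container
    carries a species marker and re-adjusting an already adjusted parameter
    set raises.
    """
    species = Species(species)
    if species is Species.HUMAN_INVITRO:
        return cell
    if species is Species.CYNOMOLGUS:
        if cell.species is not Species.HUMAN_INVITRO:
            raise ValueError(
                "species adjustment is not idempotent: parameters are "
                f"already adjusted to {cell.species.value!r}"
            )
        return replace(
            cell,
            k_recyRi=cell.k_recyRi * CYNOMOLGUS_RECYCLING_FACTOR,
            k_degR=cell.k_degR * CYNOMOLGUS_INTERNALIZATION_FACTOR,
            species=Species.CYNOMOLGUS,
        )
    raise ValueError(f"unknown species: {species!r}")  # pragma: no cover


def drug_from_affinity(
    K_D_invitro: float,
    k_onC: float,
    k_degRC: float,
    MW: float = 148000.0,
    sf_iviv: float = 1.0,
    apply_scaling: bool = False,
    name: str = "antibody",
) -> DrugParameters:
    """Build :class:`DrugParameters` from a molar in vitro affinity.

    The association rate constant is diffusion-limited and therefore left at
    the given (ligand-like) value; affinity differences are realized purely
    through the dissociation rate ``k_offC = K_D * k_onC``. With
    ``apply_scaling`` the in vitro affinity is first multiplied by the
    in vitro - in vivo scaling factor, ``K_D(in vivo) = sf_iviv * K_D``.

    Parameters
    ----------
    K_D_invitro : dissociation constant [M] (molar, as reported in affinity
        tables); converted to nM internally.
    k_onC : association rate [1/(nM*min)].
    k_degRC : complex internalization rate [1/min] (convert hourly values
        before calling).
    """
    if K_D_invitro < 0:
        raise ValueError("K_D must be >= 0")
    K_D_nM = K_D_invitro * 1e9
    if apply_scaling:
        K_D_nM *= sf_iviv
    return DrugParameters(
        k_onC=k_onC, k_offC=K_D_nM * k_onC, k_degRC=k_degRC, MW=MW, name=name
    )


def as_dict(params) -> dict[str, Any]:
    """Serialize any parameter container to a plain dict (for provenance)."""
    d = dataclasses.asdict(params)
    for key, value in d.items():
        if isinstance(value, Enum):
            d[key] = value.value
    return d
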