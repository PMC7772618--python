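"""Morphometric bioenergetics: body mass, lean mass, storage energy, energy density.

The chain is: straight-line body length and axillary girth -> estimated
body mass (class-specific log-linear allometry) -> lean (structural)
mass from length (cubic allometry) -> storage mass = body - lean ->
storage energy from the lipid/protein composition of storage tissue ->
energy density = storage energy / lean mass.

All constants live in :class:`EnergeticsParams`, loadable from YAML, so
published coefficient sets can be dropped in without code changes.  The
shipped defaults are synthetic (structure-faithful but not
field-calibrated); see the config provenance field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd
import yaml

from .demography import AgeSexClass, classify_bear
from .types import CaptureRecord, EnergyProfile

logger = logging.getLogger(__name__)

__all__ = [
    "EnergeticsParams",
    "MassCoefficients",
    "MissingCoefficients",
    "NonPositiveLeanMass",
    "default_params",
    "load_params",
    "estimate_body_mass",
    "lean_mass_from_length",
    "storage_energy_per_kg",
    "energy_from_mass",
    "profile_captures",
]


class MissingCoefficients(KeyError):
    """No mass-regression coefficient set exists for a class."""


class NonPositiveLeanMass(ValueError):
    """Derived lean mass was not positive (bad length or constants)."""


@dataclass(frozen=True)
class MassCoefficients:
    """Log-scale body-mass regression: ln(mass) = b0 + bg·ln(girth) + bl·ln(length)."""

    intercept: float
    girth: float
    length: float


@dataclass(frozen=True)
class EnergeticsParams:
    """All constants of the morphometrics -> energy chain.

    Attributes
    ----------
    mass_coefs
        Per-class :class:`MassCoefficients` (cm -> kg on the log scale).
    structural_coeff_kg_per_m3
        Lean (structural) mass = coeff × (length in m)³.  Structural mass
        scales isometrically with length in mammalian body-composition
        models.
    storage_lipid_fraction / storage_protein_fraction
        Per-class mass fractions of storage tissue that are lipid and
        protein (the remainder is water, which carries no energy).
    lipid_energy_MJ_per_kg / protein_energy_MJ_per_kg
        Combustion energy contents of the two storage components.
    provenance
        Free-text record of where the constants came from.
    """

    mass_coefs: dict[AgeSexClass, MassCoefficients]
    structural_coeff_kg_per_m3: float = 14.9
    storage_lipid_fraction: dict[AgeSexClass, float] = field(default_factory=dict)
    storage_protein_fraction: dict[AgeSexClass, float] = field(default_factory=dict)
    lipid_energy_MJ_per_kg: float = 39.3
    protein_energy_MJ_per_kg: float = 17.8
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.lipid_energy_MJ_per_kg > 0 or not self.protein_energy_MJ_per_kg > 0:
            raise ValueError("energy-content constants must be > 0")
        if not self.structural_coeff_kg_per_m3 > 0:
            raise ValueError("structural coefficient must be > 0")

    def coefs_for(self, cls: AgeSexClass) -> MassCoefficients:
        try:
            return self.mass_coefs[cls]
        except KeyError as exc:
            raise MissingCoefficients(f"no mass coefficients for class {cls.value}") from exc


def _params_from_dict(raw: dict) -> EnergeticsParams:
    coefs = {
        AgeSexClass(name): MassCoefficients(**vals)
        for name, vals in raw["mass_coefs"].items()
    }
    lip = {AgeSexClass(k): float(v) for k, v in raw.get("storage_lipid_fraction", {}).items()}
    pro = {AgeSexClass(k): float(v) for k, v in raw.get("storage_protein_fraction", {}).items()}
    return EnergeticsParams(
        mass_coefs=coefs,
        structural_coeff_kg_per_m3=float(raw.get("structural_coeff_kg_per_m3", 14.9)),
        storage_lipid_fraction=lip,
        storage_protein_fraction=pro,
        lipid_energy_MJ_per_kg=float(raw.get("lipid_energy_MJ_per_kg", 39.3)),
        protein_energy_MJ_per_kg=float(raw.get("protein_energy_MJ_per_kg", 17.8)),
        provenance=str(raw.get("provenance", "")),
    )


def load_params(path) -> EnergeticsParams:
    """Load an energetics parameter set from a YAML file."""
    with open(path) as fh:
        return _params_from_dict(yaml.safe_load(fh))


def default_params() -> EnergeticsParams:
    """The packaged default parameter set (synthetic, documented)."""
    raw = yaml.safe_load(
        resources.files("popenergy.data").joinpath("energetics_params.yaml").read_text()
    )
    return _params_from_dict(raw)


def estimate_body_mass(record: CaptureRecord, params: EnergeticsParams) -> float:
    """Estimate body mass (kg) from length and girth.

    Uses the class-specific log-linear allometry
    ``ln M = b0 + bg ln(girth_cm) + bl ln(length_cm)``; strictly
    increasing in girth at fixed length whenever bg > 0.
    """
    if record.length_cm is None or record.girth_cm is None:
        raise ValueError(f"record {record.bear_id!r} is missing morphometrics")
    cls = classify_bear(record)
    c = params.coefs_for(cls)
    return math.exp(c.intercept + c.girth * math.log(record.girth_cm)
                    + c.length * math.log(record.length_cm))


def lean_mass_from_length(length_cm: float, params: EnergeticsParams) -> float:
    """Lean (structural) body mass in kg from straight-line length."""
    if not length_cm > 0:
        raise ValueError(f"length_cm must be > 0, got {length_cm}")
    lean = params.structural_coeff_kg_per_m3 * (length_cm / 100.0) ** 3
    if not lean > 0:
        raise NonPositiveLeanMass(f"lean mass {lean} from length {length_cm} cm")
    return lean


def storage_energy_per_kg(params: EnergeticsParams, cls: AgeSexClass) -> float:
    """Energy content (MJ) of one kg of storage tissue for a class."""
    lip = params.storage_lipid_fraction.get(cls)
    pro = params.storage_protein_fraction.get(cls)
    if lip is None or pro is None:
        raise MissingCoefficients(f"no storage composition for class {cls.value}")
    return lip * params.lipid_energy_MJ_per_kg + pro * params.protein_energy_MJ_per_kg


def energy_from_mass(body_mass_kg: float, length_cm: float,
                     params: EnergeticsParams, cls: AgeSexClass) -> EnergyProfile:
    """Derive the full energy profile from body mass and length.

    Storage mass is body mass minus lean mass; an emaciated bear whose
    estimated mass falls below structural mass gets storage floored at 0
    (logged) rather than a negative reserve.
    """
    if not body_mass_kg > 0:
        raise ValueError(f"body_mass_kg must be > 0, got {body_mass_kg}")
    lean = lean_mass_from_length(length_cm, params)
    storage = body_mass_kg - lean
    if storage < 0:
        logger.warning("storage mass floored at 0 (body %.1f kg < lean %.1f kg)",
                       body_mass_kg, lean)
        storage = 0.0
    e_per_kg = storage_energy_per_kg(params, cls)
    storage_energy = storage * e_per_kg
    return EnergyProfile(
        body_mass_kg=body_mass_kg,
        lean_mass_kg=lean,
        storage_mass_kg=storage,
        storage_energy_MJ=storage_energy,
        energy_density_MJ_per_kg=storage_energy / lean,
    )


def profile_captures(records: Iterable[CaptureRecord],
                     params: EnergeticsParams) -> pd.DataFrame:
    """Profile every measurable capture; skip (and count) unmeasurable ones.

    Returns a DataFrame with one row per capture:
    bear_id, year, class, body_mass_kg, lean_mass_kg, storage_mass_kg,
    storage_energy_MJ, energy_density_MJ_per_kg.
    """
    rows = []
    skipped = 0
    for rec in records:
        if rec.length_cm is None or rec.girth_cm is None:
            skipped += 1
            continue
        cls = classify_bear(rec)
        mass = estimate_body_mass(rec, params)
        prof = energy_from_mass(mass, rec.length_cm, params, cls)
        rows.append({
            "bear_id": rec.bear_id,
            "year": rec.year,
            "class": cls.value,
            "body_mass_kg": prof.body_mass_kg,
            "lean_mass_kg": prof.lean_mass_kg,
            "storage_mass_kg": prof.storage_mass_kg,
            "storage_energy_MJ": prof.storage_energy_MJ,
            "energy_density_MJ_per_kg": prof.energy_density_MJ_per_kg,
        })
    if skipped:
        logger.warning("profile_captures: skipped %d record(s) with missing morphometrics",
                       skipped)
    cols = ["bear_id", "year", "class", "body_mass_kg", "lean_mass_kg",
            "storage_mass_kg", "storage_energy_MJ", "energy_density_MJ_per_kg"]
    return pd.DataFrame(rows, columns=cols)
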