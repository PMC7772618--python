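"""Core record types shared across modules."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field


@dataclass(frozen=True)
class CaptureRecord:
    """One capture event with morphometrics and demographic attributes.

    Attributes
    ----------
    bear_id : str
        Stable individual identifier (ear tag / tattoo number).
    date : datetime.date
        Capture date (autumn on-land sampling).
    sex : str or None
        "M" or "F"; may be missing for dependent offspring.
    age_years : int
        Age in whole years at capture (0 = cub-of-the-year).
    with_offspring : bool
        For adult females, whether offspring accompanied the bear.
    length_cm : float or None
        Straight-line body length in cm.
    girth_cm : float or None
        Axillary girth in cm.
    """

    bear_id: str
    date: _dt.date
    sex: str | None
    age_years: int
    with_offspring: bool = False
    length_cm: float | None = None
    girth_cm: float | None = None

    def __post_init__(self) -> None:
        if self.length_cm is not None and not self.length_cm > 0:
            raise ValueError(f"length_cm must be > 0, got {self.length_cm}")
        if self.girth_cm is not None and not self.girth_cm > 0:
            raise ValueError(f"girth_cm must be > 0, got {self.girth_cm}")
        if self.age_years < 0:
            raise ValueError(f"age_years must be >= 0, got {self.age_years}")

    @property
    def year(self) -> int:
        return self.date.year


@dataclass(frozen=True)
class AbundanceEstimate:
    """Annual estimate of bears onshore with its standard error.

    Produced externally by open-population capture-recapture models;
    consumed here as Normal(n_mean, n_se) uncertainty on the count.
    """

    year: int
    n_mean: float
    n_se: float

    def __post_init__(self) -> None:
        if not self.n_mean > 0:
            raise ValueError(f"n_mean must be > 0, got {self.n_mean}")
        if self.n_se < 0:
            raise ValueError(f"n_se must be >= 0, got {self.n_se}")


@dataclass(frozen=True)
class EnergyProfile:
    """Derived per-capture masses and energy quantities.

    ``energy_density_MJ_per_kg`` is storage energy divided by lean body
    mass — the energy content of reserves per unit of tissue that must be
    maintained while fasting.
    """

    body_mass_kg: float
    lean_mass_kg: float
    storage_mass_kg: float
    storage_energy_MJ: float
    energy_density_MJ_per_kg: float
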