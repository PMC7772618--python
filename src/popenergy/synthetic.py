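"""Synthetic capture, sea-ice, abundance and climate data with known truth.

The generator emulates the four input streams of the Western Hudson Bay
population-energy analysis — autumn capture records, daily sea-ice
concentration, onshore abundance estimates and monthly winter climate
indices — with fully configurable trends so every downstream stage can
be validated against a known ground truth.

Morphometrics are generated *backwards* from energy: each bear gets a
target storage energy drawn from its class distribution (plus any
per-decade drift), a length from its class length distribution, and a
girth obtained by inverting the body-mass allometry so that the
energetics chain recovers the target exactly.  The seasonal ice curve is
a double logistic whose midpoints are back-solved so the 50%/10%
three-consecutive-day rules fire exactly on the configured dates when
noise is zero.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import CLASS_ORDER, AgeSexClass
from .energetics import (EnergeticsParams, default_params, lean_mass_from_length,
                         storage_energy_per_kg)
from .types import AbundanceEstimate, CaptureRecord

__all__ = [
    "ScenarioConfig",
    "SyntheticBundle",
    "generate_captures",
    "generate_ice_series",
    "generate_abundance",
    "generate_climate",
    "generate_bundle",
    "write_bundle",
]

# Observed capture-class shares of the 1985-2018 monitoring program
# (4346 captures): adult male, solitary adult female, adult female with
# offspring, subadult male, subadult female, yearling, cub.
_DEFAULT_MIX = np.array([1159, 540, 807, 296, 331, 393, 820], dtype=float)
_DEFAULT_MIX /= _DEFAULT_MIX.sum()

# Synthetic per-class distributions (cm; MJ).  Chosen so adult males have
# the largest reserves, solitary adult females the highest energy
# density, and dependent young the smallest reserves.  Not
# field-calibrated; see docs/methods.md.
_DEFAULT_LENGTH_MEAN = {
    AgeSexClass.ADULT_MALE: 240.0,
    AgeSexClass.SOLITARY_ADULT_FEMALE: 195.0,
    AgeSexClass.ADULT_FEMALE_WITH_OFFSPRING: 195.0,
    AgeSexClass.SUBADULT_MALE: 190.0,
    AgeSexClass.SUBADULT_FEMALE: 180.0,
    AgeSexClass.YEARLING: 150.0,
    AgeSexClass.CUB: 120.0,
}
_DEFAULT_LENGTH_SD = {cls: 7.0 for cls in CLASS_ORDER}
_DEFAULT_STORAGE_MEAN = {
    AgeSexClass.ADULT_MALE: 4000.0,
    AgeSexClass.SOLITARY_ADULT_FEMALE: 3000.0,
    AgeSexClass.ADULT_FEMALE_WITH_OFFSPRING: 2200.0,
    AgeSexClass.SUBADULT_MALE: 1800.0,
    AgeSexClass.SUBADULT_FEMALE: 1500.0,
    AgeSexClass.YEARLING: 800.0,
    AgeSexClass.CUB: 300.0,
}
_DEFAULT_STORAGE_SD = {
    AgeSexClass.ADULT_MALE: 900.0,
    AgeSexClass.SOLITARY_ADULT_FEMALE: 800.0,
    AgeSexClass.ADULT_FEMALE_WITH_OFFSPRING: 600.0,
    AgeSexClass.SUBADULT_MALE: 500.0,
    AgeSexClass.SUBADULT_FEMALE: 450.0,
    AgeSexClass.YEARLING: 250.0,
    AgeSexClass.CUB: 120.0,
}
# Printed solitary-adult-female decadal storage decline; other classes
# default to zero drift so the ground truth stays interpretable.
_DEFAULT_TREND = {cls: 0.0 for cls in CLASS_ORDER}
_DEFAULT_TREND[AgeSexClass.SOLITARY_ADULT_FEMALE] = -232.0


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic study system.

    Defaults reproduce the study conditions of the 1985-2018 Western
    Hudson Bay program: ~128 captures/year, the observed class mix,
    ~1.7 captures per individual, breakup advancing 5.5 days/decade,
    freeze-up retreating 4.3 days/decade (open water 105 days in 1985),
    and an onshore population declining from ~1200 bears.
    """

    years: tuple[int, int] = (1985, 2018)
    n_captures_per_year: float = 128.0
    class_mix: dict[AgeSexClass, float] = field(
        default_factory=lambda: dict(zip(CLASS_ORDER, _DEFAULT_MIX)))
    class_length_mean: dict[AgeSexClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_LENGTH_MEAN))
    class_length_sd: dict[AgeSexClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_LENGTH_SD))
    class_storage_mean: dict[AgeSexClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_STORAGE_MEAN))
    class_storage_sd: dict[AgeSexClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_STORAGE_SD))
    energy_trend_per_decade: dict[AgeSexClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_TREND))
    repeat_capture_prob: float = 0.41  # 1/(1-p) ~ 1.7 captures/individual
    breakup_doy_start: float = 183.0
    breakup_trend_days_per_decade: float = -5.5
    freezeup_doy_start: float = 313.0
    freezeup_trend_days_per_decade: float = 4.3
    ice_noise_sd: float = 2.0
    ice_steepness: float = 1.5
    abundance_start: float = 1200.0
    abundance_trend_per_year: float = -11.5
    abundance_se: float = 150.0
    ao_winter_mean: float = -0.2
    nao_winter_mean: float = 0.1
    climate_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 - y0 + 1 < 6:
            raise ValueError("year range must span at least 6 years")
        mix = np.array([self.class_mix.get(c, 0.0) for c in CLASS_ORDER])
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {mix.sum():.12f}")
        if (mix < 0).any():
            raise ValueError("class_mix entries must be >= 0")
        for d in (self.class_length_sd, self.class_storage_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("all SDs must be >= 0")
        if self.abundance_se < 0:
            raise ValueError("abundance_se must be >= 0")
        if self.ice_noise_sd < 0 or self.climate_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class SyntheticBundle:
    """The four generated input streams plus the generating truth."""

    captures: list[CaptureRecord]
    abundance: pd.DataFrame
    ice: pd.DataFrame
    climate: pd.DataFrame
    truth: dict


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.rng_seed, spawn_key=(stream,)))


def _invert_mass_for_girth(body_mass_kg: float, length_cm: float,
                           cls: AgeSexClass, params: EnergeticsParams) -> float:
    """Closed-form inversion of the log-linear mass allometry for girth."""
    c = params.coefs_for(cls)
    ln_g = (math.log(body_mass_kg) - c.intercept
            - c.length * math.log(length_cm)) / c.girth
    return math.exp(ln_g)


def generate_captures(config: ScenarioConfig,
                      params: EnergeticsParams | None = None) -> list[CaptureRecord]:
    """Draw capture records whose implied energetics follow the scenario truth.

    Per year the capture count is Poisson around the configured mean;
    classes are multinomial draws from ``class_mix``; ages are consistent
    with class (cub 0, yearling 1, subadult 2-4, adult 5+).  With
    probability ``repeat_capture_prob`` a capture reuses an existing
    individual ID from the same class pool (re-encounter structure only;
    no family links are simulated).
    """
    params = params or default_params()
    rng = _rng(config, 0)
    mix = np.array([config.class_mix.get(c, 0.0) for c in CLASS_ORDER])
    y0 = config.years[0]
    records: list[CaptureRecord] = []
    id_pools: dict[AgeSexClass, list[str]] = {c: [] for c in CLASS_ORDER}
    counter = 0
    for year in config.year_list:
        n = int(rng.poisson(config.n_captures_per_year))
        cls_idx = rng.choice(len(CLASS_ORDER), size=n, p=mix)
        for k in cls_idx:
            cls = CLASS_ORDER[k]
            if cls is AgeSexClass.CUB:
                age, sex = 0, ("M" if rng.random() < 0.5 else "F")
            elif cls is AgeSexClass.YEARLING:
                age, sex = 1, ("M" if rng.random() < 0.5 else "F")
            elif cls in (AgeSexClass.SUBADULT_MALE, AgeSexClass.SUBADULT_FEMALE):
                age = int(rng.integers(2, 5))
                sex = "M" if cls is AgeSexClass.SUBADULT_MALE else "F"
            else:
                age = int(rng.integers(5, 21))
                sex = "M" if cls is AgeSexClass.ADULT_MALE else "F"
            with_off = cls is AgeSexClass.ADULT_FEMALE_WITH_OFFSPRING

            pool = id_pools[cls]
            if pool and rng.random() < config.repeat_capture_prob:
                bear_id = pool[int(rng.integers(len(pool)))]
            else:
                counter += 1
                bear_id = f"X{counter:05d}"
                pool.append(bear_id)

            length = float(rng.normal(config.class_length_mean[cls],
                                      config.class_length_sd[cls]))
            length = max(length, 30.0)
            drift = config.energy_trend_per_decade.get(cls, 0.0)
            e_target = float(rng.normal(
                config.class_storage_mean[cls] + drift * (year - y0) / 10.0,
                config.class_storage_sd[cls]))
            e_target = max(e_target, 0.0)
            lean = lean_mass_from_length(length, params)
            body = lean + e_target / storage_energy_per_kg(params, cls)
            girth = _invert_mass_for_girth(body, length, cls, params)
            date = _dt.date(year, 9, 18) + _dt.timedelta(
                days=int(rng.integers(-14, 15)))
            records.append(CaptureRecord(
                bear_id=bear_id, date=date, sex=sex, age_years=age,
                with_offspring=with_off, length_cm=length, girth_cm=girth))
    return records


def true_breakup_doy(config: ScenarioConfig, year: int) -> float:
    y0 = config.years[0]
    return (config.breakup_doy_start
            + config.breakup_trend_days_per_decade * (year - y0) / 10.0)


def true_freezeup_doy(config: ScenarioConfig, year: int) -> float:
    y0 = config.years[0]
    return (config.freezeup_doy_start
            + config.freezeup_trend_days_per_decade * (year - y0) / 10.0)


def generate_ice_series(config: ScenarioConfig) -> pd.DataFrame:
    """Daily region-mean concentration series per year (doy 1-365).

    The seasonal shape is a double logistic — winter plateau near 100%,
    summer plateau near 0% — whose midpoints are solved so that with zero
    noise the 50%-for-3-days breakup rule fires on the first ordinal day
    >= the true breakup date, and the 10% freeze-up rule on the first day
    >= the true freeze-up date.
    """
    rng = _rng(config, 1)
    k = config.ice_steepness
    days = np.arange(1, 366)
    frames = []
    for year in config.year_list:
        b = true_breakup_doy(config, year)
        f = true_freezeup_doy(config, year)
        m1 = b                           # conc <= 50  <=>  doy >= m1
        m2 = f + math.log(9.0) / k       # conc >= 10  <=>  doy >= f
        conc = (100.0 / (1.0 + np.exp(np.clip(k * (days - m1), -500, 500)))
                + 100.0 / (1.0 + np.exp(np.clip(-k * (days - m2), -500, 500))))
        if config.ice_noise_sd > 0:
            conc = conc + rng.normal(0.0, config.ice_noise_sd, size=days.size)
        conc = np.clip(conc, 0.0, 100.0)
        frames.append(pd.DataFrame({"year": year, "doy": days,
                                    "concentration_pct": conc}))
    return pd.concat(frames, ignore_index=True)


def generate_abundance(config: ScenarioConfig) -> pd.DataFrame:
    """Linear-trend onshore abundance means with constant SE."""
    y0 = config.years[0]
    rows = [{"year": y,
             "n_mean": config.abundance_start
             + config.abundance_trend_per_year * (y - y0),
             "n_se": config.abundance_se}
            for y in config.year_list]
    df = pd.DataFrame(rows)
    if (df["n_mean"] <= 0).any():
        raise ValueError("abundance trend drives n_mean <= 0 within the year range")
    return df


def generate_climate(config: ScenarioConfig) -> pd.DataFrame:
    """Monthly AO/NAO indices (white noise around configured means).

    Includes the year before the range start so the December-anchored
    NAO winter index is defined for the first study year.
    """
    rng = _rng(config, 2)
    years = [config.years[0] - 1] + config.year_list
    rows = []
    for y in years:
        for m in range(1, 13):
            rows.append({"year": y, "month": m,
                         "ao": float(rng.normal(config.ao_winter_mean,
                                                config.climate_sd)),
                         "nao": float(rng.normal(config.nao_winter_mean,
                                                 config.climate_sd))})
    return pd.DataFrame(rows)


def generate_bundle(config: ScenarioConfig,
                    params: EnergeticsParams | None = None) -> SyntheticBundle:
    """Generate all four input streams plus the truth record."""
    captures = generate_captures(config, params)
    truth = {
        "years": list(config.years),
        "class_mix": {c.value: config.class_mix.get(c, 0.0) for c in CLASS_ORDER},
        "class_storage_mean": {c.value: config.class_storage_mean[c]
                               for c in CLASS_ORDER},
        "energy_trend_per_decade": {c.value: config.energy_trend_per_decade.get(c, 0.0)
                                    for c in CLASS_ORDER},
        "breakup_doy": {y: true_breakup_doy(config, y) for y in config.year_list},
        "freezeup_doy": {y: true_freezeup_doy(config, y) for y in config.year_list},
        "abundance_start": config.abundance_start,
        "abundance_trend_per_year": config.abundance_trend_per_year,
        "rng_seed": config.rng_seed,
    }
    return SyntheticBundle(
        captures=captures,
        abundance=generate_abundance(config),
        ice=generate_ice_series(config),
        climate=generate_climate(config),
        truth=truth,
    )


def captures_to_frame(captures: list[CaptureRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "bear_id": r.bear_id, "date": r.date.isoformat(), "sex": r.sex,
        "age_years": r.age_years, "with_offspring": r.with_offspring,
        "length_cm": r.length_cm, "girth_cm": r.girth_cm,
    } for r in captures])


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write the bundle as the four standard CSVs plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "captures": outdir / "captures.csv",
        "ice": outdir / "ice_daily.csv",
        "abundance": outdir / "abundance.csv",
        "climate": outdir / "climate_monthly.csv",
        "truth": outdir / "truth.json",
    }
    captures_to_frame(bundle.captures).to_csv(paths["captures"], index=False)
    bundle.ice.to_csv(paths["ice"], index=False)
    bundle.abundance.to_csv(paths["abundance"], index=False)
    bundle.climate.to_csv(paths["climate"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump({k: (v if not isinstance(v, dict)
                       else {str(kk): vv for kk, vv in v.items()})
                   for k, v in bundle.truth.items()}, fh, indent=2)
    return paths
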