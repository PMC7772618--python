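"""Age/sex/reproductive classification and annual population composition.

Western Hudson Bay capture programs assign every bear to one of seven
demographic classes defined by age, sex and (for adult females)
reproductive status.  The class structure is the backbone of the
population-energy estimator: per-class energy means are scaled by the
class share of the onshore population.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import CaptureRecord

__all__ = [
    "AgeSexClass",
    "UnclassifiableRecord",
    "classify_bear",
    "annual_composition",
    "CLASS_ORDER",
]


class AgeSexClass(enum.Enum):
    """The seven demographic classes used for Western Hudson Bay bears.

    Adults are >= 5 years, subadults 2-4 years, yearlings ~20-22 months
    (age 1 at autumn capture) and cubs-of-the-year ~8-10 months (age 0).
    Adult females split on whether offspring accompany them.
    """

    ADULT_MALE = "adult_male"
    SOLITARY_ADULT_FEMALE = "solitary_adult_female"
    ADULT_FEMALE_WITH_OFFSPRING = "adult_female_with_offspring"
    SUBADULT_MALE = "subadult_male"
    SUBADULT_FEMALE = "subadult_female"
    YEARLING = "yearling"
    CUB = "cub"


#: Canonical ordering used for vectors/tables keyed by class.
CLASS_ORDER: tuple[AgeSexClass, ...] = (
    AgeSexClass.ADULT_MALE,
    AgeSexClass.SOLITARY_ADULT_FEMALE,
    AgeSexClass.ADULT_FEMALE_WITH_OFFSPRING,
    AgeSexClass.SUBADULT_MALE,
    AgeSexClass.SUBADULT_FEMALE,
    AgeSexClass.YEARLING,
    AgeSexClass.CUB,
)


class UnclassifiableRecord(ValueError):
    """Raised when a capture record cannot be mapped to a class."""


def classify_bear(record: CaptureRecord) -> AgeSexClass:
    """Map a capture record to its demographic class.

    Cubs (age 0) and yearlings (age 1) classify regardless of sex.  From
    age 2 on, sex is required; adult females (>= 5) additionally split on
    ``with_offspring``.  Ages are taken as recorded at autumn capture —
    no birthday correction is applied.

    Raises
    ------
    UnclassifiableRecord
        If age is negative, or sex is missing/invalid for a bear aged >= 2.
    """
    age = record.age_years
    if age is None or age < 0:
        raise UnclassifiableRecord(f"invalid age {age!r} for bear {record.bear_id!r}")
    if age == 0:
        return AgeSexClass.CUB
    if age == 1:
        return AgeSexClass.YEARLING
    sex = (record.sex or "").upper()
    if sex not in ("M", "F"):
        raise UnclassifiableRecord(
            f"missing or invalid sex {record.sex!r} for bear {record.bear_id!r} aged {age}"
        )
    if 2 <= age <= 4:
        return AgeSexClass.SUBADULT_MALE if sex == "M" else AgeSexClass.SUBADULT_FEMALE
    # age >= 5
    if sex == "M":
        return AgeSexClass.ADULT_MALE
    if record.with_offspring:
        return AgeSexClass.ADULT_FEMALE_WITH_OFFSPRING
    return AgeSexClass.SOLITARY_ADULT_FEMALE


@dataclass(frozen=True)
class AnnualComposition:
    """Class counts and proportions for one capture year."""

    year: int
    counts: dict[AgeSexClass, int]
    proportions: dict[AgeSexClass, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def annual_composition(records: Iterable[CaptureRecord],
                       years: Sequence[int] | None = None) -> pd.DataFrame:
    """Tabulate per-year class counts and proportions.

    Parameters
    ----------
    records
        Capture records; each contributes one count to its capture year.
    years
        Optional explicit year range.  Years with zero captures get zero
        counts and NaN proportions (flagged by the NaN itself).

    Returns
    -------
    DataFrame indexed by year with ``n_<class>`` count columns,
    ``p_<class>`` proportion columns and an ``n_total`` column.
    Proportions within a year sum to 1 when the year has captures.
    """
    rows: dict[int, np.ndarray] = {}
    for rec in records:
        cls = classify_bear(rec)
        y = rec.year
        if y not in rows:
            rows[y] = np.zeros(len(CLASS_ORDER), dtype=int)
        rows[y][CLASS_ORDER.index(cls)] += 1

    if years is None:
        years = sorted(rows)
    out = []
    for y in years:
        counts = rows.get(y, np.zeros(len(CLASS_ORDER), dtype=int))
        total = int(counts.sum())
        props = counts / total if total > 0 else np.full(len(CLASS_ORDER), np.nan)
        row: dict[str, float] = {"year": y, "n_total": total}
        for cls, c, p in zip(CLASS_ORDER, counts, props):
            row[f"n_{cls.value}"] = int(c)
            row[f"p_{cls.value}"] = p
        out.append(row)
    df = pd.DataFrame(out)
    if not df.empty:
        df = df.sort_values("year").reset_index(drop=True)
    return df
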