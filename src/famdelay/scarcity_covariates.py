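"""Coding of economic-scarcity indicators and demographic covariates.

Income is split into low / median / high bands at one sample standard
deviation below and above the sample *median*.  Insurance is dichotomized
as Medicaid vs everything else; minority status defaults to "race other
than White, or Hispanic/Latino ethnicity"; sex is coded male=1, female=2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, List, Mapping, Optional, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "RACES",
    "ETHNICITIES",
    "INSURANCE_TYPES",
    "CodedCovariates",
    "categorize_income",
    "encode_covariates",
    "default_minority_predicate",
]

logger = logging.getLogger(__name__)

RACES = frozenset(
    {"Asian", "Black", "Multiracial", "Native", "Other", "Refused", "White"}
)
ETHNICITIES = frozenset({"Hispanic/Latino", "Not Hispanic/Latino"})
INSURANCE_TYPES = frozenset(
    {
        "Private",
        "Medicare",
        "Medicaid",
        "Veterans",
        "Universal Health Care (Canada)",
        "Supplementary",
        "Other",
        "None",
    }
)
SEXES = frozenset({"male", "female"})


@dataclass(frozen=True)
class CodedCovariates:
    income: Optional[float]
    income_category: Optional[str]  # low | median | high, None when income missing
    education_years: Optional[float]
    medicaid: int
    minority: Optional[int]  # None when race was refused
    sex_code: int  # male=1, female=2
    family_size: Optional[int]
    age: Optional[float]


def categorize_income(incomes: Sequence[float]) -> List[Optional[str]]:
    """Band each income as low / median / high around the sample median.

    low iff income < median - SD; high iff income > median + SD; otherwise
    median (boundaries inclusive of the middle band).  The median and the
    ordinary (n-1) standard deviation are computed from the finite entries
    of the supplied vector; NaN entries yield None.
    """
    arr = np.asarray(list(incomes), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot categorize an empty income vector")
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValidationError("no finite incomes to categorize")
    center = float(np.median(finite))
    sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    if sd == 0.0:
        logger.warning(
            "income vector has zero spread; assigning every income to 'median'"
        )
        return [None if not math.isfinite(v) else "median" for v in arr]
    out: List[Optional[str]] = []
    for v in arr:
        if not math.isfinite(v):
            out.append(None)
        elif v < center - sd:
            out.append("low")
        elif v > center + sd:
            out.append("high")
        else:
            out.append("median")
    return out


def default_minority_predicate(race: str, ethnicity: str) -> Optional[int]:
    """1 iff race is not White or ethnicity is Hispanic/Latino; None if refused."""
    if race == "Refused":
        return None
    return int(race != "White" or ethnicity == "Hispanic/Latino")


def encode_covariates(
    raw: Mapping[str, object],
    *,
    minority_predicate: Callable[[str, str], Optional[int]] = default_minority_predicate,
    income_category: Optional[str] = None,
) -> CodedCovariates:
    """Validate one demographic record and emit analysis-ready codes.

    ``raw`` must provide race, ethnicity, insurance and sex drawn from the
    documented vocabularies; income, education_years, family_size and age
    are optional and propagate as missing (None) when absent or NaN.
    ``income_category`` is supplied by the caller because the band depends
    on the whole sample (see :func:`categorize_income`).
    """
    race = str(raw["race"])
    ethnicity = str(raw["ethnicity"])
    insurance = str(raw["insurance"])
    sex = str(raw["sex"]).lower()
    if race not in RACES:
        raise ValidationError(f"race {race!r} not in allowed set {sorted(RACES)}")
    if ethnicity not in ETHNICITIES:
        raise ValidationError(
            f"ethnicity {ethnicity!r} not in allowed set {sorted(ETHNICITIES)}"
        )
    if insurance not in INSURANCE_TYPES:
        raise ValidationError(
            f"insurance {insurance!r} not in allowed set {sorted(INSURANCE_TYPES)}"
        )
    if sex not in SEXES:
        raise ValidationError(f"sex {sex!r} not in allowed set {sorted(SEXES)}")

    def _num(key: str) -> Optional[float]:
        v = raw.get(key)
        if v is None:
            return None
        v = float(v)
        return v if math.isfinite(v) else None

    income = _num("income")
    family_size = _num("family_size")
    return CodedCovariates(
        income=income,
        income_category=income_category if income is not None else None,
        education_years=_num("education_years"),
        medicaid=int(insurance == "Medicaid"),
        minority=minority_predicate(race, ethnicity),
        sex_code=1 if sex == "male" else 2,
        family_size=int(family_size) if family_size is not None else None,
        age=_num("age"),
    )
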