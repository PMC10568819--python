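"""BMI, percent over reference median BMI, and LMS z-scores.

The module is generic over a user-supplied LMS reference table (sex,
age_months, L, M, S); no external growth reference is bundled.  Adults are
scored against the terminal age-20 (240-month) row of the reference for
their sex, a standard proxy when a pediatric reference is extended to
parents.  ``make_synthetic_reference`` builds a smooth, clearly synthetic
table with valid-shaped rows for simulation and testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ReferenceLookupError, ValidationError

__all__ = [
    "LMSRow",
    "AnthroResult",
    "ADULT_PROXY_AGE_MONTHS",
    "compute_bmi",
    "percent_over_median_bmi",
    "lookup_reference",
    "lms_z",
    "lms_inverse",
    "make_synthetic_reference",
    "reference_from_frame",
]

ADULT_PROXY_AGE_MONTHS = 240.0
_SEXES = ("male", "female")


@dataclass(frozen=True)
class LMSRow:
    sex: str
    age_months: float
    L: float
    M: float
    S: float

    def __post_init__(self):
        if self.sex not in _SEXES:
            raise ValidationError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.M <= 0:
            raise ValidationError("M (median) must be positive")
        if self.S <= 0:
            raise ValidationError("S must be positive")


@dataclass(frozen=True)
class AnthroResult:
    bmi: float
    pct_over_median: float
    zbmi: float


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise DomainError("weight and height must be positive")
    height_m = height_cm / 100.0
    return weight_kg / height_m**2


def percent_over_median_bmi(bmi: float, median_bmi: float) -> float:
    """100 * (bmi - median) / median; negative below the reference median."""
    if median_bmi <= 0:
        raise DomainError("median BMI must be positive")
    return 100.0 * (bmi - median_bmi) / median_bmi


def lookup_reference(
    sex: str,
    age_months: float,
    role: str,
    table: Sequence[LMSRow],
) -> LMSRow:
    """Find the applicable LMS row.

    Parents always map to the age-240-month row for their sex regardless of
    actual age; children map to the nearest tabulated month, erroring when
    the requested age falls outside the table's coverage.
    """
    if role not in ("parent", "child"):
        raise ValidationError("role must be 'parent' or 'child'")
    if sex not in _SEXES:
        raise ValidationError(f"sex must be one of {_SEXES}, got {sex!r}")
    rows = [r for r in table if r.sex == sex]
    if not rows:
        raise ReferenceLookupError(f"reference table has no rows for sex {sex!r}")
    if role == "parent":
        target = ADULT_PROXY_AGE_MONTHS
        exact = [r for r in rows if r.age_months == target]
        if not exact:
            raise ReferenceLookupError(
                f"reference table lacks the age-{target:.0f}-month adult proxy row"
            )
        return exact[0]
    ages = np.array([r.age_months for r in rows], dtype=float)
    if age_months < ages.min() - 0.5 or age_months > ages.max() + 0.5:
        raise ReferenceLookupError(
            f"age {age_months} months outside reference coverage "
            f"[{ages.min():.0f}, {ages.max():.0f}] for sex {sex!r}"
        )
    return rows[int(np.argmin(np.abs(ages - age_months)))]


_LMS_L_EPS = 1e-5  # below this the power branch is numerically the log branch


def lms_z(bmi: float, row: LMSRow) -> float:
    """LMS z-score ((bmi/M)^L - 1) / (L*S); log branch when L ~ 0.

    The log branch is the analytic limit of the power branch, and is used
    for |L| < 1e-5 so the transform is continuous in L to high precision.
    """
    if bmi <= 0:
        raise DomainError("bmi must be positive")
    log_ratio = math.log(bmi / row.M)
    if abs(row.L) < _LMS_L_EPS:
        return log_ratio / row.S
    return math.expm1(row.L * log_ratio) / (row.L * row.S)


def lms_inverse(z: float, row: LMSRow) -> float:
    """BMI whose LMS z-score equals ``z`` under ``row`` (generator helper)."""
    if row.L == 0:
        return row.M * math.exp(row.S * z)
    base = 1.0 + row.L * row.S * z
    if base <= 0:
        raise DomainError("z outside the invertible range for this row")
    return row.M * base ** (1.0 / row.L)


def make_synthetic_reference(
    age_min_months: int = 24,
    age_max_months: int = 240,
    step_months: int = 1,
) -> List[LMSRow]:
    """Smooth synthetic LMS table covering both sexes.

    Median BMI rises from ~16 in early childhood to ~22 at the 240-month
    adult-proxy row; L is negative (right-skewed BMI) and S grows with age.
    The values are plausible in shape only — this is not a population
    reference.
    """
    rows: List[LMSRow] = []
    for sex, m_shift in (("male", 0.0), ("female", -0.2)):
        for age in range(age_min_months, age_max_months + 1, step_months):
            t = (age - age_min_months) / (age_max_months - age_min_months)
            m = 16.0 - 1.2 * math.sin(math.pi * min(t, 0.35) / 0.7) + 7.0 * t**1.6
            rows.append(
                LMSRow(
                    sex=sex,
                    age_months=float(age),
                    L=-2.0 + 0.8 * t,
                    M=m + m_shift,
                    S=0.08 + 0.06 * t,
                )
            )
    return rows


def reference_from_frame(frame: pd.DataFrame) -> List[LMSRow]:
    """Parse a reference CSV frame with columns sex, age_months, L, M, S."""
    required = {"sex", "age_months", "L", "M", "S"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"reference table missing columns {sorted(missing)}")
    return [
        LMSRow(
            sex=str(r.sex),
            age_months=float(r.age_months),
            L=float(r.L),
            M=float(r.M),
            S=float(r.S),
        )
        for r in frame.itertuples()
    ]


def reference_to_frame(table: Iterable[LMSRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sex": r.sex, "age_months": r.age_months, "L": r.L, "M": r.M, "S": r.S}
            for r in table
        ]
    )
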