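"""Systematic vs non-systematic classification of indifference profiles.

Two consistency criteria are applied to the delay-ordered profile:

* criterion 1 — no indifference point may exceed the preceding one by more
  than ``c1_frac`` (default 20%) of the larger-later reward;
* criterion 2 — the last indifference point must sit below the first by at
  least ``c2_frac`` (default 10%) of the larger-later reward.

A profile is systematic iff every enabled criterion passes.  Both
inequalities are strict, so a rise of exactly 20% of the llr or a
first-to-last drop of exactly 10% of the llr still counts as systematic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

from .exceptions import DomainError, ValidationError
from .task_engine import IndifferenceProfile

__all__ = ["QCResult", "classify_systematic"]


@dataclass(frozen=True)
class QCResult:
    participant_id: str
    systematic: bool
    criterion1_violations: Tuple[Tuple[int, int], ...] = ()
    criterion2_violation: bool = False

    def violation_labels(self) -> str:
        """Semicolon-joined adjacent-pair labels for CSV reports."""
        return ";".join(f"{a}-{b}" for a, b in self.criterion1_violations)


def classify_systematic(
    profile: IndifferenceProfile,
    c1_frac: float = 0.20,
    c2_frac: float = 0.10,
    *,
    check_c1: bool = True,
    check_c2: bool = True,
) -> QCResult:
    """Classify one profile as systematic or non-systematic.

    Parameters
    ----------
    profile : IndifferenceProfile
        Complete profile over at least two delays.
    c1_frac, c2_frac : float
        Criterion thresholds as fractions of the larger-later reward.
    check_c1, check_c2 : bool
        Disable a criterion to reproduce single-criterion variants.
    """
    if c1_frac < 0 or c2_frac < 0:
        raise DomainError("criterion fractions must be non-negative")
    delays = profile.delays
    if len(delays) < 2:
        raise ValidationError("profile must cover at least two delays")
    llr = profile.llr_amount
    pts = profile.ordered_points()

    c1_violations: List[Tuple[int, int]] = []
    if check_c1:
        for (d_prev, p_prev), (d_next, p_next) in zip(
            zip(delays, pts), zip(delays[1:], pts[1:])
        ):
            if p_next - p_prev > c1_frac * llr:
                c1_violations.append((d_prev, d_next))
    c2_violation = bool(check_c2 and (pts[0] - pts[-1] < c2_frac * llr))

    return QCResult(
        participant_id=profile.participant_id,
        systematic=not c1_violations and not c2_violation,
        criterion1_violations=tuple(c1_violations),
        criterion2_violation=c2_violation,
    )
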