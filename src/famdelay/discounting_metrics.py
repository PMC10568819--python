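"""Discounting summary measures computed from indifference profiles.

The primary measure is the ordinal area under the curve: indifference
points, normalized by the larger-later reward, are plotted against equally
spaced ordinal delay ranks and integrated by the trapezoid rule.  Because
the x-axis uses ranks rather than day counts, the measure does not weight
long delays more heavily than short ones, and is invariant to the numeric
delay values given their order.  It ranges from 0 (maximal discounting) to
1 (no discounting).

A conventional delay-weighted AUC is provided for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ValidationError
from .task_engine import IndifferenceProfile

__all__ = ["AucResult", "auc_ordinal", "auc_traditional"]


@dataclass(frozen=True)
class AucResult:
    participant_id: str
    auc_ord: float
    n_delays: int
    include_origin: bool


def _validated_points(profile: IndifferenceProfile) -> np.ndarray:
    if profile.llr_amount <= 0:
        raise DomainError("llr_amount must be positive")
    pts = profile.ordered_points()
    if pts.size < 2:
        raise ValidationError("profile must cover at least two delays")
    if np.any(pts < 0) or np.any(pts > profile.llr_amount):
        raise DomainError("indifference points must lie in [0, llr_amount]")
    return pts


def auc_ordinal(profile: IndifferenceProfile, include_origin: bool = False) -> AucResult:
    """Ordinal (rank-spaced) area under the normalized discounting curve.

    With ``include_origin=False`` (default) the n observed delays are placed
    at ranks 0, 1/(n-1), ..., 1 and the attainable range is exactly [0, 1].
    With ``include_origin=True`` the point (0, 1) is prepended and ranks are
    mapped to i/n, the alternative convention in the AUC literature.
    """
    pts = _validated_points(profile)
    y = pts / profile.llr_amount
    n = y.size
    if include_origin:
        y = np.concatenate([[1.0], y])
        x = np.arange(n + 1) / n
    else:
        x = np.arange(n) / (n - 1)
    auc = float(np.trapezoid(y, x))
    return AucResult(
        participant_id=profile.participant_id,
        auc_ord=auc,
        n_delays=n,
        include_origin=include_origin,
    )


def auc_traditional(profile: IndifferenceProfile, include_origin: bool = True) -> float:
    """Delay-weighted AUC (x normalized by the maximum delay).

    Secondary, for contrast with :func:`auc_ordinal`; weights long delays
    in proportion to their span on the day axis.
    """
    pts = _validated_points(profile)
    y = pts / profile.llr_amount
    x = np.asarray(profile.delays, dtype=float)
    if include_origin:
        y = np.concatenate([[1.0], y])
        x = np.concatenate([[0.0], x])
    x = x / x.max()
    return float(np.trapezoid(y, x))
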