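"""Deterministic responder banks for end-to-end validation.

Two mechanistic responder families exercise the full task -> scoring -> QC
path with known classification outcomes:

* graded hyperbolic discounters (zero choice noise) across a k range wide
  enough that every profile is monotone with an adequate first-to-last
  drop — always classified systematic;
* preference-reversal responders that take the immediate reward at short
  delays but wait at long delays, producing a large mid-profile rise —
  always classified non-systematic.

Each profile is produced by administering staircases, recording the trial
log, and re-scoring the log, so the whole measurement chain is in play.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .response_qc import classify_systematic
from .task_engine import (
    Agent,
    IndifferenceProfile,
    TaskConfig,
    run_adjusting_staircase,
    score_choice_log,
)

__all__ = [
    "deterministic_discounter_profiles",
    "preference_reversal_profiles",
    "systematic_percentage",
]


def _profile_via_log(agents_by_delay, config: TaskConfig, pid: str) -> IndifferenceProfile:
    trials = []
    for delay in config.delays:
        block, _ = run_adjusting_staircase(
            agents_by_delay(delay), delay, config, participant_id=pid
        )
        trials.extend(block)
    return score_choice_log(trials, config)


def deterministic_discounter_profiles(
    n: int,
    config: Optional[TaskConfig] = None,
    k_min: float = 0.002,
    k_max: float = 1.0,
    seed: Optional[int] = None,
) -> List[IndifferenceProfile]:
    """n zero-noise hyperbolic discounters with log-spaced rates.

    The k range guarantees monotone profiles whose first-to-last drop
    clears the 10%-of-llr consistency bound, so every profile classifies
    as systematic.  ``seed`` only shuffles the rate order.
    """
    config = config or TaskConfig()
    ks = np.logspace(np.log10(k_min), np.log10(k_max), n)
    if seed is not None:
        np.random.default_rng(seed).shuffle(ks)
    return [
        _profile_via_log(lambda d, k=k: Agent(k=k), config, f"sys{i:04d}")
        for i, k in enumerate(ks)
    ]


def preference_reversal_profiles(
    n: int,
    config: Optional[TaskConfig] = None,
    reversal_after_days: float = 10.0,
) -> List[IndifferenceProfile]:
    """n responders who take the money now at short delays but wait at
    long ones — a canonical non-systematic pattern (large rise mid-profile)."""
    config = config or TaskConfig()

    def agent_for(delay: float) -> Agent:
        return Agent(k=1e12) if delay <= reversal_after_days else Agent(k=0.0)

    return [
        _profile_via_log(agent_for, config, f"rev{i:04d}") for i in range(n)
    ]


def systematic_percentage(profiles: List[IndifferenceProfile]) -> tuple:
    """(count systematic, percentage to one decimal) over a profile bank."""
    n_sys = sum(classify_systematic(p).systematic for p in profiles)
    return n_sys, round(100.0 * n_sys / len(profiles), 1)
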