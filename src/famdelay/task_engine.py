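"""Adjusting-amount delay-discounting task: simulation and scoring.

The task offers a fixed larger-later reward (``llr_amount``) against an
immediate amount that is titrated by a halving staircase: the first offer is
``start_fraction * llr``, and after each choice the offer moves down (if the
immediate reward was taken) or up (if the delayed reward was taken) by a step
that starts at half the first offer and halves after every trial.  The
indifference point for a delay is the offer that *would* have been made after
the final adjustment, i.e. the midpoint of the final bisection bracket.

Synthetic responders are hyperbolic agents with optional logistic choice
noise; the hyperbolic form is a modelling choice of the generator, not a
quantity estimated anywhere downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .exceptions import ChoiceLogError, DomainError, ValidationError

__all__ = [
    "TaskConfig",
    "ChoiceTrial",
    "IndifferenceProfile",
    "Agent",
    "hyperbolic_value",
    "simulate_choice",
    "run_adjusting_staircase",
    "run_full_task",
    "score_choice_log",
]

DEFAULT_DELAYS: Tuple[int, ...] = (1, 7, 30, 182, 365)


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the adjusting-amount task.

    Defaults: $100 larger-later reward, delays of 1, 7, 30, 182 and 365
    days, six trials per delay, first offer at half the delayed amount.
    """

    llr_amount: float = 100.0
    delays: Tuple[int, ...] = DEFAULT_DELAYS
    trials_per_delay: int = 6
    start_fraction: float = 0.5
    tie_rule: str = "prefer_delayed"
    delay_order: str = "ascending"

    def __post_init__(self):
        if self.llr_amount <= 0:
            raise ValidationError("llr_amount must be positive")
        delays = tuple(self.delays)
        if len(delays) < 1:
            raise ValidationError("at least one delay is required")
        if any(d <= 0 for d in delays):
            raise ValidationError("delays must be positive")
        if any(b <= a for a, b in zip(delays, delays[1:])):
            raise ValidationError("delays must be strictly increasing")
        object.__setattr__(self, "delays", delays)
        if not 0 < self.start_fraction < 1:
            raise ValidationError("start_fraction must be in (0, 1)")
        if self.trials_per_delay < 1:
            raise ValidationError("trials_per_delay must be >= 1")
        if self.tie_rule not in ("prefer_delayed", "prefer_immediate"):
            raise ValidationError(
                "tie_rule must be 'prefer_delayed' or 'prefer_immediate'"
            )
        if self.delay_order not in ("ascending", "descending"):
            raise ValidationError("delay_order must be 'ascending' or 'descending'")

    @property
    def final_step(self) -> float:
        """Size of the last staircase adjustment (the bracket half-width)."""
        return self.start_fraction * self.llr_amount * 2.0 ** (-self.trials_per_delay)

    def ordered_delays(self) -> Tuple[int, ...]:
        if self.delay_order == "descending":
            return tuple(reversed(self.delays))
        return self.delays


@dataclass(frozen=True)
class ChoiceTrial:
    """One binary choice between an immediate amount and the delayed llr."""

    participant_id: str
    delay_days: int
    immediate_amount: float
    chose_immediate: bool
    trial_index: int


@dataclass(frozen=True)
class IndifferenceProfile:
    """Per-participant indifference points keyed by delay (days)."""

    participant_id: str
    points: Mapping[int, float]
    llr_amount: float

    def __post_init__(self):
        points = dict(self.points)
        for d, p in points.items():
            if not 0 <= p <= self.llr_amount:
                raise ValidationError(
                    f"indifference point {p} at delay {d} outside [0, {self.llr_amount}]"
                )
        object.__setattr__(self, "points", points)

    @property
    def delays(self) -> List[int]:
        return sorted(self.points)

    def ordered_points(self) -> np.ndarray:
        return np.array([self.points[d] for d in self.delays], dtype=float)


@dataclass(frozen=True)
class Agent:
    """Hyperbolic discounter with logistic choice noise.

    ``noise_temperature == 0`` gives a deterministic threshold responder;
    larger temperatures flatten the choice curve toward coin flips.
    """

    k: float
    noise_temperature: float = 0.0

    def __post_init__(self):
        if self.k < 0:
            raise DomainError("discount rate k must be >= 0")
        if self.noise_temperature < 0:
            raise DomainError("noise_temperature must be >= 0")


def hyperbolic_value(amount: float, k: float, delay: float) -> float:
    """Present value A / (1 + k * D) of ``amount`` delayed by ``delay`` days."""
    if amount < 0 or k < 0 or delay < 0:
        raise DomainError("amount, k and delay must be non-negative")
    return amount / (1.0 + k * delay)


def simulate_choice(
    agent: Agent,
    immediate: float,
    delay: float,
    config: TaskConfig,
    rng: np.random.Generator | None = None,
) -> bool:
    """Return True iff the agent takes the immediate amount.

    With zero temperature the agent compares ``immediate`` against the
    discounted value of the llr, breaking exact ties by ``config.tie_rule``;
    otherwise it chooses the immediate option with probability
    ``logistic((immediate - value) / temperature)``.
    """
    if not 0 < immediate < config.llr_amount:
        raise DomainError(
            f"immediate amount {immediate} must lie in (0, {config.llr_amount})"
        )
    value = hyperbolic_value(config.llr_amount, agent.k, delay)
    diff = immediate - value
    if agent.noise_temperature == 0:
        if diff == 0:
            return config.tie_rule == "prefer_immediate"
        return diff > 0
    if rng is None:
        raise ValidationError("a seeded rng is required for noisy agents")
    p_immediate = 1.0 / (1.0 + math.exp(-diff / agent.noise_temperature))
    return bool(rng.random() < p_immediate)


def run_adjusting_staircase(
    agent: Agent,
    delay: float,
    config: TaskConfig,
    rng: np.random.Generator | None = None,
    participant_id: str = "agent",
) -> Tuple[List[ChoiceTrial], float]:
    """Administer one staircase and return (trials, indifference point).

    The indifference point is the offer after the final adjustment; offers
    never leave (0, llr) because every step halves the remaining bracket.
    """
    offer = config.start_fraction * config.llr_amount
    step = offer / 2.0
    trials: List[ChoiceTrial] = []
    for t in range(1, config.trials_per_delay + 1):
        chose_immediate = simulate_choice(agent, offer, delay, config, rng)
        trials.append(
            ChoiceTrial(
                participant_id=participant_id,
                delay_days=int(delay),
                immediate_amount=offer,
                chose_immediate=chose_immediate,
                trial_index=t,
            )
        )
        offer = offer - step if chose_immediate else offer + step
        step /= 2.0
    return trials, offer


def run_full_task(
    agent: Agent,
    config: TaskConfig,
    rng: np.random.Generator | None = None,
    participant_id: str = "agent",
) -> IndifferenceProfile:
    """Run one staircase per configured delay and collect the profile."""
    points: Dict[int, float] = {}
    for delay in config.ordered_delays():
        _, ip = run_adjusting_staircase(agent, delay, config, rng, participant_id)
        points[int(delay)] = ip
    return IndifferenceProfile(
        participant_id=participant_id, points=points, llr_amount=config.llr_amount
    )


def replay_offers(choices: Sequence[bool], config: TaskConfig) -> Tuple[List[float], float]:
    """Recompute the offer sequence implied by a choice sequence.

    Returns (offers presented at each trial, indifference point).
    """
    offer = config.start_fraction * config.llr_amount
    step = offer / 2.0
    offers = []
    for chose_immediate in choices:
        offers.append(offer)
        offer = offer - step if chose_immediate else offer + step
        step /= 2.0
    return offers, offer


def score_choice_log(
    trials: Iterable[ChoiceTrial],
    config: TaskConfig,
    *,
    offer_tol: float = 1e-9,
) -> IndifferenceProfile:
    """Re-derive indifference points from a recorded log for one participant.

    The log must contain exactly ``trials_per_delay`` trials for every
    configured delay; each recorded offer is checked against the offer the
    adjustment rule would have produced, so corrupted or reordered logs fail
    with a :class:`ChoiceLogError` naming the delay and trial.
    """
    by_delay: Dict[int, List[ChoiceTrial]] = {}
    participant_ids = set()
    for tr in trials:
        by_delay.setdefault(int(tr.delay_days), []).append(tr)
        participant_ids.add(tr.participant_id)
    if not by_delay:
        raise ChoiceLogError("empty choice log")
    if len(participant_ids) > 1:
        raise ChoiceLogError(
            f"choice log mixes participants: {sorted(participant_ids)}"
        )
    expected_delays = set(int(d) for d in config.delays)
    missing = expected_delays - set(by_delay)
    extra = set(by_delay) - expected_delays
    if missing:
        raise ChoiceLogError(
            f"missing delays {sorted(missing)}", delay_days=sorted(missing)[0]
        )
    if extra:
        raise ChoiceLogError(
            f"unexpected delays {sorted(extra)}", delay_days=sorted(extra)[0]
        )

    points: Dict[int, float] = {}
    for delay in sorted(by_delay):
        block = sorted(by_delay[delay], key=lambda tr: tr.trial_index)
        indices = [tr.trial_index for tr in block]
        if indices != list(range(1, config.trials_per_delay + 1)):
            raise ChoiceLogError(
                f"delay {delay}: expected trials 1..{config.trials_per_delay}, "
                f"got indices {indices}",
                delay_days=delay,
            )
        offers, ip = replay_offers([tr.chose_immediate for tr in block], config)
        for tr, expected in zip(block, offers):
            if abs(tr.immediate_amount - expected) > offer_tol:
                raise ChoiceLogError(
                    f"delay {delay}, trial {tr.trial_index}: recorded offer "
                    f"{tr.immediate_amount} != replayed offer {expected}",
                    delay_days=delay,
                    trial_index=tr.trial_index,
                )
        points[delay] = ip
    return IndifferenceProfile(
        participant_id=participant_ids.pop(), points=points, llr_amount=config.llr_amount
    )
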