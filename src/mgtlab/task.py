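"""Maastricht Gambling Task (MGT) engine.

The MGT is a binary lottery: six boxes, each pink or blue, one of which
hides a token. The participant guesses the token's color. A correct guess
(hit) pays the points attached to that color; a miss pays zero. The pink
count ranges over 1..5 (the remainder blue) and each color's reward is one
of {5, 25, 50, 75, 100} points, giving 5 x 5 x 5 = 125 unique trial types.
Every type is presented twice per run, so a run holds 250 trials; a session
holds three runs, one per stimulation condition (sham, SPL, VMPFC).

This module enumerates the trial space, builds seeded randomized session
plans, resolves choices into outcomes, and applies the end-of-session
payment rule (one eligible trial, 1 point = EUR 0.10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "N_BOXES",
    "REWARDS",
    "STIMULATIONS",
    "COLORS",
    "TrialType",
    "TrialInstance",
    "SessionPlan",
    "Outcome",
    "PaymentRecord",
    "enumerate_trial_types",
    "build_session_plan",
    "resolve_choice",
    "select_payment_trial",
    "session_streams",
]

N_BOXES = 6
REWARDS = (5, 25, 50, 75, 100)
STIMULATIONS = ("sham", "SPL", "VMPFC")
COLORS = ("pink", "blue")

N_PRACTICE_TRIALS = 10
N_VALID_TRIALS = 250
POINT_VALUE_EUR = 0.10


@dataclass(frozen=True)
class TrialType:
    """One of the 125 unique lottery configurations."""

    n_pink: int
    reward_pink: int
    reward_blue: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_pink <= 5:
            raise ValueError(f"n_pink must be in 1..5, got {self.n_pink}")
        for r in (self.reward_pink, self.reward_blue):
            if r not in REWARDS:
                raise ValueError(f"reward {r} not in {REWARDS}")

    @property
    def n_blue(self) -> int:
        return N_BOXES - self.n_pink

    @property
    def trial_code(self) -> str:
        """Stable identifier, unique within the 125-type space."""
        return f"P{self.n_pink}-{self.reward_pink:03d}-{self.reward_blue:03d}"

    def n_boxes(self, color: str) -> int:
        _check_color(color)
        return self.n_pink if color == "pink" else self.n_blue

    def reward(self, color: str) -> int:
        _check_color(color)
        return self.reward_pink if color == "pink" else self.reward_blue


@dataclass(frozen=True)
class TrialInstance:
    """A single presentation of a trial type within a run.

    ``token_box`` is resolved at plan-build time (uniform over the six
    boxes); ``box_coloring`` maps each box position to its color and is
    re-randomized per presentation — only color counts and rewards matter
    for scoring.
    """

    trial_type: TrialType
    presentation_index: int  # 1 or 2
    position_in_run: int  # 1..250
    token_box: int  # 1..6
    box_coloring: tuple[str, ...]  # length 6

    @property
    def token_color(self) -> str:
        return self.box_coloring[self.token_box - 1]


@dataclass(frozen=True)
class Outcome:
    hit: bool
    points: int


@dataclass(frozen=True)
class PaymentRecord:
    block_index: int
    trial_index: int
    points: int
    euros: float


@dataclass
class SessionPlan:
    """Three runs of 250 trial presentations, one run per stimulation."""

    session: int
    stimulation_order: tuple[str, ...]
    runs: list[list[TrialInstance]] = field(repr=False)
    rng_seed: int

    def run_for(self, stimulation: str) -> list[TrialInstance]:
        return self.runs[self.stimulation_order.index(stimulation)]


def _check_color(color: str) -> None:
    if color not in COLORS:
        raise ValueError(f"color must be one of {COLORS}, got {color!r}")


def enumerate_trial_types() -> list[TrialType]:
    """All 125 trial types, deterministically ordered.

    Order is lexicographic in (n_pink, reward_pink, reward_blue), so the
    enumeration (and therefore every trial_code) is stable across calls,
    runs and sessions.
    """
    return [
        TrialType(n_pink=k, reward_pink=rp, reward_blue=rb)
        for k in range(1, 6)
        for rp in REWARDS
        for rb in REWARDS
    ]


def session_streams(seed: int) -> dict[str, np.random.Generator]:
    """Named RNG substreams for one participant-session.

    A single root seed fans out into independent substreams so that, e.g.,
    changing how many agent-noise draws are consumed cannot perturb trial
    ordering. Streams: ``order`` (trial permutation), ``token`` (token box
    and box coloring), ``agent`` (choice/RT noise for simulated agents).
    """
    root = np.random.SeedSequence(seed)
    order_ss, token_ss, agent_ss = root.spawn(3)
    return {
        "order": np.random.default_rng(order_ss),
        "token": np.random.default_rng(token_ss),
        "agent": np.random.default_rng(agent_ss),
    }


def _build_run(order_rng: np.random.Generator,
               token_rng: np.random.Generator) -> list[TrialInstance]:
    types = enumerate_trial_types()
    # two presentations of every type, uniform random order
    slots = [(t, 1) for t in types] + [(t, 2) for t in types]
    perm = order_rng.permutation(len(slots))
    run: list[TrialInstance] = []
    for pos, idx in enumerate(perm, start=1):
        ttype, pres = slots[idx]
        coloring = ["blue"] * N_BOXES
        pink_positions = token_rng.choice(N_BOXES, size=ttype.n_pink,
                                          replace=False)
        for p in pink_positions:
            coloring[p] = "pink"
        token_box = int(token_rng.integers(1, N_BOXES + 1))
        run.append(TrialInstance(
            trial_type=ttype,
            presentation_index=pres,
            position_in_run=pos,
            token_box=token_box,
            box_coloring=tuple(coloring),
        ))
    return run


def build_session_plan(session: int, stimulation_order: Sequence[str],
                       seed: int) -> SessionPlan:
    """Build a full session: three seeded, randomized 250-trial runs.

    The trial *composition* of a run is fixed (each of the 125 types twice);
    only ordering, box coloring and token placement are random. Identical
    (session, order, seed) inputs reproduce the plan exactly.
    """
    if session not in (1, 2):
        raise ValueError(f"session must be 1 or 2, got {session}")
    if sorted(stimulation_order) != sorted(STIMULATIONS):
        raise ValueError(
            f"stimulation_order must be a permutation of {STIMULATIONS}, "
            f"got {tuple(stimulation_order)}")
    streams = session_streams(seed)
    runs = [_build_run(streams["order"], streams["token"]) for _ in range(3)]
    return SessionPlan(session=session,
                       stimulation_order=tuple(stimulation_order),
                       runs=runs, rng_seed=seed)


def resolve_choice(instance: TrialInstance, chosen_color: str) -> Outcome:
    """Resolve a color choice against the pre-placed token.

    Hit iff the token's box carries the chosen color; a hit pays the chosen
    color's reward, a miss pays zero.
    """
    _check_color(chosen_color)
    hit = instance.token_color == chosen_color
    points = instance.trial_type.reward(chosen_color) if hit else 0
    return Outcome(hit=hit, points=points)


def select_payment_trial(blocks: Sequence[Sequence[Outcome]],
                         block_index: int, trial_index: int) -> PaymentRecord:
    """Apply the end-of-session payment rule.

    The participant draws a block number (1..3) and a trial number; the
    first 10 trials of each block are practice and ineligible, so eligible
    trial numbers are 11..260 (mapping to valid trials 1..250). The selected
    trial's points convert at EUR 0.10 per point.
    """
    if not 1 <= block_index <= 3:
        raise ValueError(f"block_index must be in 1..3, got {block_index}")
    lo = N_PRACTICE_TRIALS + 1
    hi = N_PRACTICE_TRIALS + N_VALID_TRIALS
    if not lo <= trial_index <= hi:
        raise ValueError(
            f"trial_index must be in {lo}..{hi} (practice trials 1..10 are "
            f"ineligible), got {trial_index}")
    run = blocks[block_index - 1]
    if len(run) != N_VALID_TRIALS:
        raise ValueError(
            f"block {block_index} has {len(run)} outcomes, expected "
            f"{N_VALID_TRIALS}")
    outcome = run[trial_index - N_PRACTICE_TRIALS - 1]
    return PaymentRecord(block_index=block_index, trial_index=trial_index,
                         points=outcome.points,
                         euros=round(outcome.points * POINT_VALUE_EUR, 2))
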