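"""Synthetic cohorts with known ground truth.

Two generative routes, serving different verification purposes:

1. **Agent level** (`simulate_cohort`): softmax agents play the actual task
   engine trial by trial. Each agent values an option at
   U = EV + b * Risk (b is the risk appetite) and chooses pink with
   probability sigmoid(lambda * (U_pink - U_blue)); response times are
   lognormal with additive condition effects on the log scale. The study
   specifies no behavioral choice process, so this agent is an explicit
   stand-in that produces task-consistent behavior; it exercises the full
   engine -> scoring path and reproduces the design's cardinalities
   (250 trials/run, 750/session, 44,375 scored rows with 5 dropped runs).
2. **Mixed-model level** (`simulate_lmm_dataset`): scored observations are
   drawn directly from the generative mirror of the fitted model —
   grand mean + treatment-coded fixed effects + participant intercept
   + trial-type-within-participant intercept + residual noise — with the
   published variance components as defaults. This is the route used for
   parameter recovery, where the estimand is known exactly.

The default cohort layout mirrors the study: 60 participants (31 placebo /
29 probiotics, 36 women), 2 sessions x 3 stimulation conditions in
randomized order, and 5 unrecorded runs belonging to distinct participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import task
from .task import N_BOXES, STIMULATIONS, enumerate_trial_types

__all__ = [
    "AgentParams",
    "CohortDesign",
    "EffectSpec",
    "simulate_agent_choice",
    "simulate_cohort",
    "simulate_lmm_dataset",
]

REPETITIONS = ("A", "B", "C")
GROUPS = ("placebo", "probiotics")


@dataclass(frozen=True)
class AgentParams:
    """Softmax mean-variance agent.

    ``risk_appetite`` (b) weighs the option's risk score into its utility;
    ``choice_temperature`` (lambda > 0) is the inverse temperature of the
    softmax — large lambda approaches the deterministic utility maximizer,
    lambda -> 0 approaches coin-flip choice. Response times are lognormal:
    log RT ~ Normal(rt_location + condition shifts, rt_scale^2).

    Defaults are calibrated so the baseline agent's mean type-averaged risk
    (~25.9) and choice optimality (~0.85) sit at the levels a mildly
    risk-averse human cohort shows on this task; the condition modifiers
    inject a session-2 speed-up and a post-intervention probiotics shift
    (riskier, slower) so simulated effects have the observed directions.
    All modifiers are plain config, not empirical claims.
    """

    risk_appetite: float = -0.5
    choice_temperature: float = 0.15
    rt_location: float = -0.18  # log-seconds; mean RT ~0.89 s at baseline
    rt_scale: float = 0.35
    # additive shifts on risk_appetite
    b_session2: float = 0.0
    b_session2_probiotics: float = 0.05
    b_stimulation: dict[str, float] = field(default_factory=dict)
    # additive shifts on rt_location (log scale)
    rt_session2: float = -0.25  # practice speed-up, ~ -0.19 s on the mean
    rt_session2_probiotics: float = 0.07
    rt_stimulation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.choice_temperature <= 0:
            raise ValueError("choice_temperature must be > 0")
        if self.rt_scale <= 0:
            raise ValueError("rt_scale must be > 0")
        if not np.isfinite(self.risk_appetite):
            raise ValueError("risk_appetite must be finite")

    def condition(self, session: int, group: str,
                  stimulation: str) -> "AgentParams":
        """Agent with the (session, group, stimulation) shifts applied."""
        b = self.risk_appetite
        mu = self.rt_location
        if session == 2:
            b += self.b_session2
            mu += self.rt_session2
            if group == "probiotics":
                b += self.b_session2_probiotics
                mu += self.rt_session2_probiotics
        b += self.b_stimulation.get(stimulation, 0.0)
        mu += self.rt_stimulation.get(stimulation, 0.0)
        return replace(self, risk_appetite=b, rt_location=mu,
                       b_session2=0.0, b_session2_probiotics=0.0,
                       b_stimulation={}, rt_session2=0.0,
                       rt_session2_probiotics=0.0, rt_stimulation={})


@dataclass(frozen=True)
class CohortDesign:
    """Study layout: group sizes, factorial structure, unrecorded runs."""

    n_placebo: int = 31
    n_probiotics: int = 29
    n_sessions: int = 2
    stimulations: tuple[str, ...] = STIMULATIONS
    n_dropped_runs: int = 5
    n_women: int = 36
    n_trial_types: int = 125

    def __post_init__(self) -> None:
        if self.n_placebo < 0 or self.n_probiotics < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.n_dropped_runs > self.n_participants:
            raise ValueError("dropped runs must belong to distinct "
                             "participants")
        if not 1 <= self.n_trial_types <= 125:
            raise ValueError("n_trial_types must be in 1..125")

    @property
    def n_participants(self) -> int:
        return self.n_placebo + self.n_probiotics

    @property
    def n_runs(self) -> int:
        return (self.n_participants * self.n_sessions
                * len(self.stimulations) - self.n_dropped_runs)

    @property
    def n_scored_rows(self) -> int:
        return self.n_runs * self.n_trial_types

    def participants(self) -> pd.DataFrame:
        ids = [f"S{i + 1:02d}" for i in range(self.n_participants)]
        group = (["placebo"] * self.n_placebo
                 + ["probiotics"] * self.n_probiotics)
        gender = (["F"] * min(self.n_women, self.n_participants)
                  + ["M"] * max(0, self.n_participants - self.n_women))
        return pd.DataFrame({"participant": ids, "group": group,
                             "gender": gender[: self.n_participants]})


@dataclass(frozen=True)
class EffectSpec:
    """Generative fixed effects and variance components on the risk scale.

    Coefficients use treatment coding with reference cell (session 1,
    placebo, sham); keys of ``coefficients`` are term names such as
    ``"session2"``, ``"probiotics"``, ``"SPL"``, ``"session2:probiotics"``,
    ``"session2:probiotics:VMPFC"``. Unlisted terms are zero. Defaults set
    only the grand intercept (25.33) and the session x group interaction
    (0.27); variance components default to the study's fitted
    decomposition: residual 16.88, trial-type-within-participant 192.99,
    participant 1.56.
    """

    intercept: float = 25.33
    coefficients: dict[str, float] = field(
        default_factory=lambda: {"session2:probiotics": 0.27})
    sigma2_residual: float = 16.88
    tau_trialtype_participant: float = 192.99
    tau_participant: float = 1.56

    def __post_init__(self) -> None:
        for v in (self.sigma2_residual, self.tau_trialtype_participant,
                  self.tau_participant):
            if v < 0:
                raise ValueError("variances must be nonnegative")

    @classmethod
    def published(cls) -> "EffectSpec":
        """The full fitted coefficient set of the risk model."""
        return cls(coefficients={
            "session2": 0.0,
            "probiotics": 1.32,
            "SPL": -0.03,
            "VMPFC": 0.08,
            "session2:probiotics": 0.27,
            "session2:SPL": -0.28,
            "session2:VMPFC": -0.19,
            "probiotics:SPL": 0.14,
            "probiotics:VMPFC": -0.15,
            "session2:probiotics:SPL": 0.13,
            "session2:probiotics:VMPFC": -0.03,
        })

    @property
    def icc(self) -> float:
        tau = self.tau_trialtype_participant + self.tau_participant
        total = tau + self.sigma2_residual
        return tau / total if total > 0 else 0.0

    def cell_mean(self, session: int, group: str, stimulation: str) -> float:
        """Fixed-effects mean of one design cell (treatment coding)."""
        mu = self.intercept
        names: set[str] = set()
        if session == 2:
            names.add("session2")
        if group == "probiotics":
            names.add("probiotics")
        if session == 2 and group == "probiotics":
            names.add("session2:probiotics")
        if stimulation != "sham":
            names.add(stimulation)
            if session == 2:
                names.add(f"session2:{stimulation}")
            if group == "probiotics":
                names.add(f"probiotics:{stimulation}")
            if session == 2 and group == "probiotics":
                names.add(f"session2:probiotics:{stimulation}")
        for n in names:
            mu += self.coefficients.get(n, 0.0)
        return mu


def simulate_agent_choice(agent: AgentParams, trial: task.TrialType,
                          rng: np.random.Generator) -> str:
    """Draw one color choice from the softmax over mean-variance utility."""
    lam = agent.choice_temperature
    b = agent.risk_appetite
    pp = trial.n_pink / N_BOXES
    sd = np.sqrt(pp * (1 - pp))
    u_pink = trial.reward_pink * pp + b * trial.reward_pink * sd
    u_blue = trial.reward_blue * (1 - pp) + b * trial.reward_blue * sd
    p_pink = 1.0 / (1.0 + np.exp(-lam * (u_pink - u_blue)))
    return "pink" if rng.random() < p_pink else "blue"


def _stimulation_orders(design: CohortDesign, rng: np.random.Generator,
                        n_sessions: int) -> list[tuple[str, ...]]:
    return [tuple(rng.permutation(design.stimulations))
            for _ in range(n_sessions)]


def _simulate_run(agent: AgentParams, trial_types: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Vectorized 2x-presentation run for one conditioned agent."""
    two = pd.concat([trial_types, trial_types], ignore_index=True)
    n = len(two)
    order = rng.permutation(n)
    two = two.iloc[order].reset_index(drop=True)
    k = two["n_pink"].to_numpy(float)
    pp = k / N_BOXES
    sd = np.sqrt(pp * (1 - pp))
    rp = two["reward_pink"].to_numpy(float)
    rb = two["reward_blue"].to_numpy(float)
    b, lam = agent.risk_appetite, agent.choice_temperature
    u_pink = rp * pp + b * rp * sd
    u_blue = rb * (1 - pp) + b * rb * sd
    p_pink = 1.0 / (1.0 + np.exp(-lam * (u_pink - u_blue)))
    pink = rng.random(n) < p_pink
    # token box uniform over 6; hit iff its color matches the choice,
    # i.e. hit probability = (#boxes of chosen color)/6
    token = rng.integers(0, N_BOXES, size=n)
    k_chosen = np.where(pink, k, N_BOXES - k)
    hit = token < k_chosen  # uniform token over a random coloring
    points = np.where(hit, np.where(pink, rp, rb), 0.0).astype(int)
    rt = np.exp(agent.rt_location
                + agent.rt_scale * rng.standard_normal(n))
    out = two.copy()
    out["run_position"] = np.arange(1, n + 1)
    out["chosen_color"] = np.where(pink, "pink", "blue")
    out["hit"] = hit
    out["points"] = points
    out["rt_seconds"] = rt
    return out


def simulate_cohort(design: CohortDesign | None = None,
                    agent: AgentParams | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Play the full study with softmax agents; return trial-level records.

    One root seed fans out into independent per-participant-session
    substreams (ordering, token placement and agent noise all derive from
    them), so the table is a pure function of (design, agent, seed).
    Dropped runs are assigned to distinct participants and removed wholesale
    (all 250 trial rows of the affected run).
    """
    design = design or CohortDesign()
    agent = agent or AgentParams()
    root = np.random.SeedSequence(seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    participants = design.participants()

    types = pd.DataFrame(
        [{"trial_code": t.trial_code, "n_pink": t.n_pink,
          "reward_pink": t.reward_pink, "reward_blue": t.reward_blue}
         for t in enumerate_trial_types()[: design.n_trial_types]])

    # unrecorded runs: distinct participants, random session x stimulation
    dropped: set[tuple[str, int, str]] = set()
    if design.n_dropped_runs:
        who = meta_rng.choice(design.n_participants,
                              size=design.n_dropped_runs, replace=False)
        for w in who:
            s = int(meta_rng.integers(1, design.n_sessions + 1))
            st = str(meta_rng.choice(design.stimulations))
            dropped.add((participants["participant"].iloc[w], s, st))

    frames = []
    child_seeds = root.spawn(design.n_participants * design.n_sessions)
    idx = 0
    for _, prow in participants.iterrows():
        pid, group = prow["participant"], prow["group"]
        for session in range(1, design.n_sessions + 1):
            rng = np.random.default_rng(child_seeds[idx]); idx += 1
            order = tuple(rng.permutation(design.stimulations))
            for block, stim in enumerate(order):
                if (pid, session, stim) in dropped:
                    continue
                conditioned = agent.condition(session, group, stim)
                run = _simulate_run(conditioned, types, rng)
                run.insert(0, "participant", pid)
                run.insert(1, "group", group)
                run.insert(2, "session", session)
                run.insert(3, "stimulation", stim)
                run.insert(4, "repetition", REPETITIONS[block])
                frames.append(run)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["dropped_runs"] = sorted(dropped)
    return out


def simulate_lmm_dataset(effects: EffectSpec | None = None,
                         design: CohortDesign | None = None,
                         seed: int = 0
                         ) -> tuple[pd.DataFrame, dict]:
    """Draw scored observations straight from the mixed-model mirror.

    risk = cell mean + u_participant + u_(trial type : participant) + eps,
    with u_participant ~ N(0, tau_participant), the nested intercept
    ~ N(0, tau_trialtype_participant) drawn per participant x trial code,
    and eps ~ N(0, sigma2_residual) per row. Returns (table, ground_truth);
    the truth dict records every generative value for recovery checks.
    """
    effects = effects or EffectSpec()
    design = design or CohortDesign()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    participants = design.participants()
    n_p = design.n_participants
    n_t = design.n_trial_types
    codes = [t.trial_code for t in enumerate_trial_types()[:n_t]]

    u_p = rng.normal(0.0, np.sqrt(effects.tau_participant), n_p)
    u_pt = rng.normal(0.0, np.sqrt(effects.tau_trialtype_participant),
                      (n_p, n_t))

    dropped: set[tuple[int, int, str]] = set()
    if design.n_dropped_runs:
        who = rng.choice(n_p, size=design.n_dropped_runs, replace=False)
        for w in who:
            s = int(rng.integers(1, design.n_sessions + 1))
            st = str(rng.choice(design.stimulations))
            dropped.add((int(w), s, st))

    rows = []
    for i in range(n_p):
        pid = participants["participant"].iloc[i]
        group = participants["group"].iloc[i]
        for session in range(1, design.n_sessions + 1):
            order = rng.permutation(design.stimulations)
            for block, stim in enumerate(order):
                if (i, session, stim) in dropped:
                    continue
                mu = effects.cell_mean(session, group, stim)
                eps = rng.normal(0.0, np.sqrt(effects.sigma2_residual), n_t)
                risk = mu + u_p[i] + u_pt[i] + eps
                rows.append(pd.DataFrame({
                    "participant": pid, "group": group, "session": session,
                    "stimulation": stim, "repetition": REPETITIONS[block],
                    "trial_code": codes, "risk": risk}))
    table = pd.concat(rows, ignore_index=True)
    truth = {
        "intercept": effects.intercept,
        "coefficients": dict(effects.coefficients),
        "sigma2_residual": effects.sigma2_residual,
        "tau_trialtype_participant": effects.tau_trialtype_participant,
        "tau_participant": effects.tau_participant,
        "icc": effects.icc,
        "n_dropped_runs": len(dropped),
        "seed": seed,
    }
    return table, truth
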