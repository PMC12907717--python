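"""Dependent-variable scoring for the MGT.

Three per-trial measures are derived from a choice record and then averaged
over the two presentations of each trial type:

* **Risk** — the standard deviation of the chosen option's payoff lottery.
  With success probability p = k/6 (k boxes of the chosen color) and reward
  x, the payoff X is x with probability p and 0 otherwise, so
  Var(X) = p(x - E[X])^2 + (1-p)(0 - E[X])^2 and Risk = sqrt(Var(X)),
  which simplifies to x*sqrt(p(1-p)).
* **Choice optimality (CO)** — 1 if the chosen color has the strictly
  higher expected value, 0 if strictly lower. When the two colors tie in
  expected value (which happens in the enumerated space, e.g. 25 * 1/6 =
  5 * 5/6) neither option is suboptimal, so either choice scores 1; tie
  trials are flagged for sensitivity analyses.
* **Response time (RT)** — seconds from trial onset to the key press.

Averaging the two presentations of each type yields 125 scored
observations per run — the unit of analysis for the mixed models.
Response-time outliers are removed with a 1.5 x IQR fence computed on the
type-averaged values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import N_BOXES, TrialType, _check_color

__all__ = [
    "LotteryStats",
    "lottery_stats",
    "risk_score",
    "choice_optimality",
    "is_tie_trial",
    "response_time",
    "score_trials",
    "aggregate_run",
    "aggregate_trials",
    "iqr_filter",
    "filter_response_times",
]

#: columns identifying one run (participant x session x stimulation block)
RUN_KEYS = ["participant", "session", "stimulation"]


@dataclass(frozen=True)
class LotteryStats:
    """Moments of the chosen option's payoff lottery."""

    p: float
    x: float
    ev: float
    variance: float
    risk: float


def lottery_stats(trial: TrialType, chosen_color: str) -> LotteryStats:
    """Expected value, variance and risk of choosing ``chosen_color``.

    The variance is evaluated as the two-outcome sum
    p(x - EV)^2 + (1-p)(0 - EV)^2; the closed form x^2 p (1-p) is the same
    quantity and is used as an independent identity in the test suite.
    """
    _check_color(chosen_color)
    k = trial.n_boxes(chosen_color)
    if k == 0:
        raise ValueError("chosen color has zero boxes")
    p = k / N_BOXES
    x = float(trial.reward(chosen_color))
    ev = x * p
    variance = p * (x - ev) ** 2 + (1.0 - p) * (0.0 - ev) ** 2
    return LotteryStats(p=p, x=x, ev=ev, variance=variance,
                        risk=float(np.sqrt(variance)))


def risk_score(trial: TrialType, chosen_color: str) -> float:
    """Risk (payoff SD) of the chosen option."""
    return lottery_stats(trial, chosen_color).risk


def is_tie_trial(trial: TrialType) -> bool:
    """True when both colors carry the same expected value."""
    ev_pink = trial.reward_pink * trial.n_pink
    ev_blue = trial.reward_blue * trial.n_blue
    return ev_pink == ev_blue


def choice_optimality(trial: TrialType, chosen_color: str) -> int:
    """Binary score: did the choice have the (weakly) higher expected value?

    Strictly higher -> 1, strictly lower -> 0. On an expected-value tie
    there is no higher-EV option, so either choice scores 1.
    """
    _check_color(chosen_color)
    ev_chosen = trial.reward(chosen_color) * trial.n_boxes(chosen_color)
    other = "blue" if chosen_color == "pink" else "pink"
    ev_other = trial.reward(other) * trial.n_boxes(other)
    return 1 if ev_chosen >= ev_other else 0


def response_time(trial_start: float, keypress: float,
                  unit: str = "s") -> float:
    """Seconds from trial onset to key press.

    ``unit`` gives the timestamps' unit ("s" or "ms"); the result is always
    seconds.
    """
    if unit not in ("s", "ms"):
        raise ValueError(f"unit must be 's' or 'ms', got {unit!r}")
    delta = keypress - trial_start
    if delta < 0:
        raise ValueError(f"keypress precedes trial start by {-delta}")
    return delta / 1000.0 if unit == "ms" else float(delta)


# --------------------------------------------------------------------------
# table-level scoring

def score_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach per-trial ``risk``, ``co`` and ``tie`` columns.

    Expects the trial-level long format with columns n_pink, reward_pink,
    reward_blue and chosen_color. Vectorized over the whole table.
    """
    out = trials.copy()
    pink = out["chosen_color"].to_numpy() == "pink"
    k = np.where(pink, out["n_pink"], N_BOXES - out["n_pink"]).astype(float)
    x = np.where(pink, out["reward_pink"], out["reward_blue"]).astype(float)
    p = k / N_BOXES
    ev = x * p
    out["risk"] = np.sqrt(p * (x - ev) ** 2 + (1.0 - p) * ev**2)
    ev_pink = out["reward_pink"] * out["n_pink"]
    ev_blue = out["reward_blue"] * (N_BOXES - out["n_pink"])
    ev_chosen = np.where(pink, ev_pink, ev_blue)
    ev_other = np.where(pink, ev_blue, ev_pink)
    out["co"] = (ev_chosen >= ev_other).astype(float)
    out["tie"] = (ev_pink == ev_blue).astype(bool)
    return out


def aggregate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Average scored trials by trial type within each run.

    Produces one row per participant x session x stimulation x trial_code
    with risk, co and rt averaged over the available presentations
    (normally two; a single recorded presentation is averaged over itself
    rather than dropped). Carries through any constant run-level labels
    (group, repetition).
    """
    scored = trials if "risk" in trials.columns else score_trials(trials)
    keys = RUN_KEYS + ["trial_code"]
    carry = [c for c in ("group", "repetition") if c in scored.columns]
    agg: dict[str, str] = {"risk": "mean", "co": "mean"}
    if "rt_seconds" in scored.columns:
        agg["rt_seconds"] = "mean"
    if "tie" in scored.columns:
        agg["tie"] = "first"
    for c in carry:
        agg[c] = "first"
    out = (scored.groupby(keys, sort=True, observed=True)
           .agg(agg).reset_index()
           .rename(columns={"rt_seconds": "rt"}))
    cols = (RUN_KEYS + carry + ["trial_code", "risk", "co"]
            + (["rt"] if "rt" in out.columns else [])
            + (["tie"] if "tie" in out.columns else []))
    return out[cols]


def aggregate_run(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a single run's trial records into 125 scored observations.

    Raises if the records span more than one run or if any trial code has
    no presentations.
    """
    present = [k for k in RUN_KEYS if k in records.columns]
    if present and len(records.drop_duplicates(subset=present)) > 1:
        raise ValueError("records span multiple runs; "
                         "aggregate_trials handles full tables")
    if records.empty:
        raise ValueError("no records to aggregate")
    if present:
        return aggregate_trials(records)
    tmp = records.copy()
    for k in RUN_KEYS:  # synthesize constant keys for a bare run
        if k not in tmp.columns:
            tmp[k] = "-"
    return aggregate_trials(tmp).drop(
        columns=[k for k in RUN_KEYS if k not in records.columns])


# --------------------------------------------------------------------------
# response-time outlier fence

def iqr_filter(values: np.ndarray, factor: float = 1.5
               ) -> tuple[np.ndarray, int]:
    """Tukey fence: retain v with Q1 - f*IQR <= v <= Q3 + f*IQR.

    Quartiles use linear interpolation between order statistics (the
    removal count depends on this choice, so it is fixed and documented).
    Returns (boolean retain mask, number removed). NaNs are not retained
    and do not enter the quartiles.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("iqr_filter needs at least 4 finite values")
    q1, q3 = np.percentile(v[finite], [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    mask = finite & (v >= lo) & (v <= hi)
    return mask, int((~mask & finite).sum())


def filter_response_times(scored: pd.DataFrame, scope: str = "global",
                          factor: float = 1.5
                          ) -> tuple[pd.DataFrame, dict]:
    """Flag RT outliers on the type-averaged table.

    ``scope='global'`` (default) computes one fence over the whole table,
    matching a single study-wide removal count; ``scope='participant'``
    fences within each participant. Adds a boolean ``rt_retained`` column
    and returns an audit dict (n_total, n_removed, n_retained, scope).
    Rows with rt_retained=False keep their risk/co values — the fence only
    gates the response-time analysis.
    """
    if scope not in ("global", "participant"):
        raise ValueError(f"scope must be 'global' or 'participant', "
                         f"got {scope!r}")
    out = scored.copy()
    if scope == "global":
        mask, removed = iqr_filter(out["rt"].to_numpy(), factor=factor)
        out["rt_retained"] = mask
    else:
        out["rt_retained"] = False
        for _, idx in out.groupby("participant").groups.items():
            mask, _ = iqr_filter(out.loc[idx, "rt"].to_numpy(), factor=factor)
            out.loc[idx, "rt_retained"] = mask
        removed = int((~out["rt_retained"]).sum())
    audit = {"n_total": int(len(out)), "n_removed": removed,
             "n_retained": int(out["rt_retained"].sum()),
             "scope": scope, "factor": factor}
    return out, audit
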