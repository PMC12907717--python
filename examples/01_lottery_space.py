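"""The MGT lottery space and the risk score of a single choice.

Enumerates the 125 unique trial configurations (pink-box count x two
rewards) and evaluates the payoff moments of one choice: picking pink on a
1-pink/100-point trial is a long shot (p = 1/6) whose payoff SD — the
study's risk score — is about 37.3 points.
"""

from mgtlab import choice_optimality, enumerate_trial_types, lottery_stats

types = enumerate_trial_types()
print(f"trial space: {len(types)} unique configurations")
print(f"with exactly one pink box: "
      f"{sum(t.n_pink == 1 for t in types)} (5 x 5 reward grid)")

trial = next(t for t in types
             if (t.n_pink, t.reward_pink, t.reward_blue) == (1, 100, 5))
for color in ("pink", "blue"):
    ls = lottery_stats(trial, color)
    co = choice_optimality(trial, color)
    print(f"choose {color:4s}: p={ls.p:.3f} x={ls.x:5.0f} "
          f"EV={ls.ev:6.2f} risk={ls.risk:6.2f} optimal={co}")
# The pink option has the higher EV (16.67 vs 4.17) *and* ~9x the risk:
# risk-seeking and EV-maximizing choices often coincide in this task,
# which is why risk and choice optimality are analyzed separately.
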