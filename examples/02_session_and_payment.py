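"""A seeded session plan, choice resolution and the payment rule.

Builds one two-session participant's worth of runs, plays a simple
EV-maximizing strategy against run 1, and applies the end-of-session
payment draw (eligible trial numbers 11..260; 1 point = EUR 0.10).
"""

from mgtlab import build_session_plan, resolve_choice, select_payment_trial

plan = build_session_plan(session=1, stimulation_order=("sham", "SPL",
                                                        "VMPFC"), seed=7)
print(f"session {plan.session}: {len(plan.runs)} runs of "
      f"{len(plan.runs[0])} trials, order {plan.stimulation_order}")

blocks = []
for run in plan.runs:
    outcomes = []
    for inst in run:
        t = inst.trial_type
        ev_pink = t.reward_pink * t.n_pink
        ev_blue = t.reward_blue * t.n_blue
        color = "pink" if ev_pink >= ev_blue else "blue"
        outcomes.append(resolve_choice(inst, color))
    blocks.append(outcomes)
    hits = sum(o.hit for o in outcomes)
    points = sum(o.points for o in outcomes)
    print(f"  run: {hits}/250 hits, {points} points")

record = select_payment_trial(blocks, block_index=2, trial_index=42)
print(f"payment draw (block 2, trial 42): {record.points} points "
      f"-> EUR {record.euros:.2f}")
# Trial numbers 1..10 are practice and ineligible; 261 is out of range.
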