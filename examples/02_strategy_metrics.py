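"""Win-stay / lose-shift strategy profile of a simulated player.

Rates are split by the feedback trial's deck class (rich vs poor): a
well-calibrated player stays after rich-deck wins and shifts after
poor-deck losses.
"""

import numpy as np

import affectbandit as ab

rng = np.random.default_rng(7)
schedule = ab.make_block_schedule(ab.TaskConfig(), rng)
records, _ = ab.simulate_subject(ab.SubjectParams(alpha=0.3, beta=5.0), schedule, rng)

events = ab.classify_strategy_events(records)
summary = ab.strategy_rates(events)

for name in ("win_stay", "win_stay_rich", "win_stay_poor",
             "lose_shift", "lose_shift_rich", "lose_shift_poor"):
    rate = getattr(summary, name)
    shown = f"{100 * rate.value:5.1f}%" if rate.defined else "undefined"
    print(f"{name:<16} {shown}  ({rate.numerator}/{rate.denominator})")

print("\nEach rate = qualifying (feedback, action) events / qualifying feedback")
print("events with a successor trial; empty denominators stay undefined (NaN).")
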