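"""Simulate one session of the probabilistic gambling task.

Builds the default 480-trial schedule (six 70-90-trial blocks, deck pairs
at 6:1/1:6/3:1/1:3 ratios totalling 60% reward probability), plays it with
a delta-rule/softmax agent, and prints the schedule and the total score.
"""

import numpy as np

import affectbandit as ab

rng = np.random.default_rng(2024)
config = ab.TaskConfig()
schedule = ab.make_block_schedule(config, rng)

print("block  length  ratio   rich deck  p_rich  p_poor")
for i, block in enumerate(schedule.blocks):
    print(
        f"{i:>5}  {block.length:>6}  {block.ratio[0]:.0f}:{block.ratio[1]:.0f}"
        f"{'':>4}{'AB'[block.rich_deck]:>6}"
        f"  {block.decks.p_rich:.3f}   {block.decks.p_poor:.3f}"
    )
print(f"total trials: {schedule.n_trials}")

params = ab.SubjectParams(alpha=0.30, beta=4.0, subject_id="demo")
records, trace = ab.simulate_subject(params, schedule, rng)
score = ab.total_score(records)
print(f"\nagent (alpha={params.alpha}, beta={params.beta}) earned {score} points "
      f"of {schedule.n_trials} possible")
print("Higher beta concentrates choices on the deck with the larger expectation;")
print("alpha sets how fast expectations chase the binary feedback.")
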