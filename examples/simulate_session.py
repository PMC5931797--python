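"""Generate a synthetic figure-8 session and write it to disk.

Builds a small session (12 units, 3 blocks of 16 trials) with the standard
task schedule: 10 forced-alternation trials then 6 free-choice trials per
block, reward volumes of 30/120 uL and three barrier levels.  Prints the
session summary and the free-choice bias per block.
"""

import numpy as np

import accdecode as ad

cfg = ad.SimulatorConfig()
cfg.schedule.blocks = cfg.schedule.blocks[:3]
cfg.tuning.n_units = 12

session = ad.make_session(cfg, seed=1)
ad.write_session(session, "scratch/example_session")

rates = session.spikes.rates()
print(f"{session.spikes.n_units} units, {len(session.trials)} trials, "
      f"{session.spikes.duration:.0f} s")
print(f"mean firing rates {min(rates.values()):.2f}-{max(rates.values()):.2f} Hz "
      "(all above the 0.5 Hz inclusion threshold)")
print(f"{len(session.ground_truth.injections)} excursion episodes injected\n")

print("block  options(L,R)  free choices to R")
for b, block in enumerate(cfg.schedule.blocks):
    free = [t for t in session.trials if t.block_index == b and t.mode == "free"]
    frac = np.mean([t.direction == "right" for t in free])
    print(f"  {b}     {block}   {frac:.2f}")
print("\nThe choice bias tracks the effort-discounted reward utility of each "
      "side; it is the 'revealed preference' used in the excursion analysis.")
print("Session written to scratch/example_session/ (plain CSV + JSON).")
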