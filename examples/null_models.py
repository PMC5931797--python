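"""Spike-timing null models: jitter and inter-spike-interval shuffling.

The three-feeder pattern classifier (the position decoder's trunk with a
3-way softmax head) is trained on clean data and tested on (a) the
original spikes, (b) spikes jittered by a Gaussian with variance 25% of
each cell's ISI variance, and (c) spikes whose ISIs are randomly permuted.
Jitter should barely matter; the shuffle should drop accuracy to chance.
"""

import accdecode as ad
from accdecode.nets import TrainConfig

cfg = ad.SimulatorConfig()
cfg.tuning.n_units = 24
cfg.excursions.mode = "none"
session = ad.make_session(cfg, seed=2)

mats = ad.feeder_classifier_all(session, seed=9, n_reps=4,
                                train_config=TrainConfig(epochs=60))
print("variant    accuracy   (chance = 0.33)")
for v in ("original", "noisy", "shuffled"):
    print(f"{v:<10} {mats[v].accuracy:8.3f}")
print("\nrow-normalized confusion matrix, original data (rows = true L/R/C):")
for row in mats["original"].matrix:
    print("   " + "  ".join(f"{p:.2f}" for p in row))

print("\nModerate spike jitter (~tens of ms) preserves the feeder-specific "
      "ensemble patterns, while destroying the spike-time structure via the "
      "ISI shuffle removes all discriminability.")
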