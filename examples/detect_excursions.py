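"""Detect excursion events and compare them with the injected ground truth.

Excursions are brief episodes in which the decoded position shifts to the
remote target feeder while the rat sits at a feeder after reward.  The
generator injects them with known trials, onsets and durations; the
detector flags trials whose post-reward window shows a > 70 cm decode
error at fine temporal resolution (120 ms kernel, 20 ms bins).
"""

import numpy as np

import accdecode as ad
from accdecode.nets import TrainConfig

cfg = ad.SimulatorConfig()
cfg.tuning.n_units = 24
cfg.excursions.mode = "fixed_count"
cfg.excursions.n_fixed = 10
session = ad.make_session(cfg, seed=5)
injected = {i.trial_index for i in session.ground_truth.injections}
print(f"injected excursions on trials {sorted(injected)}")

det = ad.detect_excursion_trials(session, seed=17, n_sets=4,
                                 train_config=TrainConfig(epochs=60))
flagged = {i for i, f in det["flags"].items() if f}
tested = {i for i, n in det["tested"].items() if n > 0}
print(f"flagged trials           {sorted(flagged)}")
print(f"recall                   "
      f"{len(flagged & injected) / len(injected & tested):.2f}")
print(f"false-positive rate      "
      f"{len(flagged - injected) / len(tested - injected):.3f}")

durs = [e.duration_ms for e in det["events"]]
inj_durs = [i.duration_ms for i in session.ground_truth.injections]
print(f"median episode duration  {np.median(durs):.0f} ms "
      f"(injected {np.median(inj_durs):.0f} ms)")

chi = ad.endpoint_concentration_test(det["events"], session.geometry)
print(f"endpoint concentration   chi2({chi['df']}) = {chi['chi2']:.0f}, "
      f"p = {chi['p']:.2g}")
print("\nEndpoints cluster at the remote target feeder, far beyond what a "
      "uniform spread over the track would produce.")
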