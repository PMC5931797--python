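"""Which cells carry reward information at the feeders?

Plants two reward-modulated cells in an otherwise unmodulated ensemble and
runs the L1-logistic-regression selection: over 50 balanced trial sets, the
cells receiving nonzero weights in the best cross-validated sparse model
are logged; selection frequency is categorized at the 30% / 70% thresholds.
"""

import accdecode as ad

cfg = ad.SimulatorConfig()
cfg.tuning.n_units = 16
cfg.tuning.peak_hz = (0.0, 0.0)        # flat spatial tuning
cfg.tuning.baseline_hz = (2.0, 4.0)
cfg.tuning.reward_frac = 0.0
cfg.tuning.choice_frac = 0.0
cfg.excursions.mode = "none"
session = ad.make_session(cfg, seed=3)

planted = (2, 9)
for i in planted:
    session.ground_truth.tuning[i].reward_gain = 2.0   # 3x rate on big reward
session.spikes = ad.generate_spikes(session.trajectory, session.trials,
                                    session.ground_truth, session.geometry,
                                    seed=10)

prof = ad.informative_cells(session, target="reward", seed=7)
print(f"mean held-out accuracy of selected models: "
      f"{prof.test_accuracy['reward']:.2f}\n")
print("unit   selection freq  category            planted")
for i, u in enumerate(prof.unit_ids):
    f = prof.frequency["reward"][i]
    mark = "  *" if i in planted else ""
    print(f"{u}   {f:14.2f}  {prof.category['reward'][i]:<22}{mark}")
print("\nThe planted cells are selected in essentially every set ('very "
      "informative'); unmodulated cells stay below the 30% threshold.")
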