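import numpy as np
import pytest

import accdecode as ad
from accdecode.decoders import (
    DecodedPath, ErrorSummary, InsufficientDataError, _fit_eval,
    balanced_trial_sets, bayes_log_posterior,
)
from accdecode.nets import MLP, TrainConfig, train_mlp
from accdecode.preprocessing import BinnedEnsemble


def _toy_ensemble(rng, n_units=3, n_bins=400, tile_w=4.0, tile_h=3.0):
    """Random activity with positions confined to a handful of tiles."""
    centers = np.arange(n_bins) * 0.05 + 0.025
    counts = rng.poisson(1.0, size=(n_units, n_bins))
    pos = np.column_stack([
        rng.choice([2.0, 6.0, 10.0, 14.0, 18.0], n_bins),
        np.full(n_bins, 1.5),
    ])
    return BinnedEnsemble(
        unit_ids=[f"u{i}" for i in range(n_units)], bin_centers=centers,
        bin_width_ms=50.0, kernel_std_ms=150.0,
        activity=counts.astype(float) / 0.05, counts=counts, pos=pos,
        trial_index=np.zeros(n_bins, int),
        zone=np.array(["track"] * n_bins, object),
    )


class TestNetwork:
    def test_default_hyperparameters_recorded(self, rng):
        X = rng.normal(size=(150, 4))
        y = rng.normal(size=(150, 2))
        m = train_mlp(X, y, seed=0, config=TrainConfig(epochs=2))
        assert m.config.batch_size == 100
        assert TrainConfig().epochs == 100
        assert m.config.hidden == (100, 50, 25)
        assert m.seed == 0

    def test_training_is_deterministic(self, rng):
        X = rng.normal(size=(200, 3))
        y = rng.normal(size=(200, 2))
        m1 = train_mlp(X, y, seed=5, config=TrainConfig(epochs=3))
        m2 = train_mlp(X, y, seed=5, config=TrainConfig(epochs=3))
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_constant_target_learned_to_subcentimetre(self, rng):
        X = rng.normal(size=(200, 5))
        y = np.tile([40.0, 60.0], (200, 1))
        m = train_mlp(X, y, seed=1)
        rmse = np.sqrt(((m.predict(X) - y) ** 2).sum(axis=1).mean())
        assert rmse < 1.0

    def test_memoryless_duplicate_bins(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=(50, 2)) * 30
        m = train_mlp(X, y, seed=2, config=TrainConfig(epochs=2))
        X2 = np.vstack([X, X[:5]])
        p = m.predict(X2)
        # identical inputs give identical outputs (up to BLAS blocking noise)
        assert np.allclose(p[:5], p[50:], atol=1e-10)

    def test_zero_output_weights_give_constant_bias(self):
        m = _hand_model()
        m.weights[-1][:] = 0.0
        m.biases[-1][:] = [3.0, -2.0]
        p = m.predict(np.array([[0.3, -1.2], [5.0, 2.0]]))
        assert np.allclose(p, [[3.0, -2.0], [3.0, -2.0]])

    def test_forward_pass_matches_hand_computation(self):
        m = _hand_model()
        x = np.array([[0.5, -1.0]])
        h1 = np.maximum(x @ m.weights[0] + m.biases[0], 0)
        h2 = np.maximum(h1 @ m.weights[1] + m.biases[1], 0)
        h3 = np.tanh(h2 @ m.weights[2] + m.biases[2])
        out = h3 @ m.weights[3] + m.biases[3]
        assert np.allclose(m.predict(x), out, atol=1e-9)
        assert np.allclose(m.hidden_activations(x), h3, atol=1e-9)

    def test_hidden_activations_strictly_inside_tanh_range(self, rng):
        X = rng.normal(size=(100, 3))
        y = rng.normal(size=(100, 2))
        m = train_mlp(X, y, seed=3, config=TrainConfig(epochs=2))
        h = m.hidden_activations(rng.normal(size=(40, 3)))
        assert h.shape == (40, 25)
        assert np.all(np.abs(h) < 1.0)
        # extreme inputs saturate but never exceed the tanh range
        h_big = m.hidden_activations(rng.normal(size=(10, 3)) * 1e3)
        assert np.all(np.abs(h_big) <= 1.0)

    def test_unit_permutation_equivariance(self, rng):
        X = rng.normal(size=(80, 6))
        y = rng.normal(size=(80, 2)) * 20
        m = train_mlp(X, y, seed=4, config=TrainConfig(epochs=3))
        perm = rng.permutation(6)
        m2 = MLP(weights=[m.weights[0][perm]] + [w.copy() for w in m.weights[1:]],
                 biases=[b.copy() for b in m.biases], task="regression",
                 config=m.config, y_mean=m.y_mean, y_scale=m.y_scale)
        assert np.allclose(m.predict(X), m2.predict(X[:, perm]), atol=1e-12)

    def test_shape_mismatch_raises(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=(50, 2))
        m = train_mlp(X, y, seed=0, config=TrainConfig(epochs=1))
        with pytest.raises(ValueError, match="units"):
            m.predict(rng.normal(size=(5, 7)))


def _hand_model():
    rng = np.random.default_rng(0)
    dims = [2, 3, 3, 2, 2]
    return MLP(
        weights=[rng.normal(size=(dims[i], dims[i + 1])) for i in range(4)],
        biases=[rng.normal(size=dims[i + 1]) for i in range(4)],
        task="regression", config=TrainConfig(hidden=(3, 3, 2)),
    )


class TestBayes:
    def test_single_visited_tile_gets_full_prior(self, rng):
        ens = _toy_ensemble(rng)
        ens.pos[:] = [2.0, 1.5]
        model = ad.fit_bayesian(ens, bounds=(20.0, 3.0))
        assert len(model.tiles) == 1
        assert model.prior[0] == 1.0

    def test_silent_unit_floored(self, rng):
        ens = _toy_ensemble(rng)
        ens.counts[1] = 0
        model = ad.fit_bayesian(ens, bounds=(20.0, 3.0))
        assert np.all(model.rates[1] == 1e-3)

    def test_rate_maps_equal_hand_means(self):
        counts = np.array([[2, 4, 0, 6], [1, 1, 1, 1]])
        pos = np.array([[2.0, 1.5], [2.0, 1.5], [6.0, 1.5], [6.0, 1.5]])
        ens = BinnedEnsemble(
            unit_ids=["a", "b"], bin_centers=np.arange(4) * 0.05,
            bin_width_ms=50.0, kernel_std_ms=150.0,
            activity=counts / 0.05, counts=counts, pos=pos,
            trial_index=np.zeros(4, int), zone=np.array(["track"] * 4, object),
        )
        model = ad.fit_bayesian(ens, bounds=(8.0, 3.0))
        # tile 0: bins 0,1 -> unit a mean count 3 -> 60 Hz; tile 1: bins 2,3 -> 3 -> 60
        assert model.rates[0, 0] == pytest.approx(3 / 0.05)
        assert model.rates[0, 1] == pytest.approx(3 / 0.05)
        assert model.rates[1, 0] == pytest.approx(1 / 0.05)
        assert np.allclose(model.prior, [0.5, 0.5])

    def test_zero_spikes_prefer_low_rate_tile(self):
        model = ad.BayesDecoder(
            tile_cm=(4.0, 3.0), origin=(0.0, 0.0), shape=(2, 1),
            tiles=np.array([0, 1]),
            centers=np.array([[2.0, 1.5], [6.0, 1.5]]),
            rates=np.array([[1.0, 3.0]]), prior=np.array([0.5, 0.5]), dt=1.0,
        )
        ens = BinnedEnsemble(
            unit_ids=["a"], bin_centers=np.array([0.5]), bin_width_ms=1000.0,
            kernel_std_ms=150.0, activity=np.zeros((1, 1)),
            counts=np.zeros((1, 1), int), pos=np.array([[2.0, 1.5]]),
            trial_index=np.zeros(1, int), zone=np.array(["track"], object),
        )
        path = ad.decode_bayesian(model, ens)
        assert np.allclose(path.pred[0], [2.0, 1.5])   # e^-1 beats e^-3

    def test_identical_rates_fall_back_to_prior(self):
        model = ad.BayesDecoder(
            tile_cm=(4.0, 3.0), origin=(0.0, 0.0), shape=(2, 1),
            tiles=np.array([0, 1]),
            centers=np.array([[2.0, 1.5], [6.0, 1.5]]),
            rates=np.array([[2.0, 2.0]]), prior=np.array([0.3, 0.7]), dt=0.05,
        )
        ens = BinnedEnsemble(
            unit_ids=["a"], bin_centers=np.array([0.5]), bin_width_ms=50.0,
            kernel_std_ms=150.0, activity=np.zeros((1, 1)),
            counts=np.array([[2]]), pos=np.array([[2.0, 1.5]]),
            trial_index=np.zeros(1, int), zone=np.array(["track"], object),
        )
        path = ad.decode_bayesian(model, ens)
        assert np.allclose(path.pred[0], [6.0, 1.5])

    def test_tie_breaks_to_lowest_row_major_tile(self):
        model = ad.BayesDecoder(
            tile_cm=(4.0, 3.0), origin=(0.0, 0.0), shape=(2, 1),
            tiles=np.array([0, 1]),
            centers=np.array([[2.0, 1.5], [6.0, 1.5]]),
            rates=np.array([[2.0, 2.0]]), prior=np.array([0.5, 0.5]), dt=0.05,
        )
        ens = BinnedEnsemble(
            unit_ids=["a"], bin_centers=np.array([0.5]), bin_width_ms=50.0,
            kernel_std_ms=150.0, activity=np.zeros((1, 1)),
            counts=np.array([[1]]), pos=np.array([[6.0, 1.5]]),
            trial_index=np.zeros(1, int), zone=np.array(["track"], object),
        )
        path = ad.decode_bayesian(model, ens)
        assert np.allclose(path.pred[0], [2.0, 1.5])

    def test_matches_exhaustive_enumeration(self, rng):
        # 5-tile, 3-unit toy against a brute-force log-posterior oracle
        ens = _toy_ensemble(rng, n_units=3, n_bins=100)
        model = ad.fit_bayesian(ens, bounds=(20.0, 3.0))
        test = _toy_ensemble(np.random.default_rng(1), n_units=3, n_bins=100)
        path = ad.decode_bayesian(model, test)
        for b in range(100):
            scores = []
            for j in range(len(model.tiles)):
                lp = np.log(model.prior[j])
                for u in range(3):
                    lam = model.rates[u, j]
                    lp += test.counts[u, b] * np.log(lam) - lam * model.dt
                scores.append(lp)
            best = int(np.argmax(scores))
            assert np.allclose(path.pred[b], model.centers[best])


class TestErrorSummary:
    def test_printed_formulas(self):
        pred = np.array([[0.0, 0.0], [3.0, 4.0]])
        actual = np.zeros((2, 2))
        s = ErrorSummary.from_path(DecodedPath(t=np.arange(2), pred=pred,
                                               actual=actual))
        assert s.mse == pytest.approx(25.0 / 4.0)     # (1/2N) sum ||e||^2
        assert s.rmse == pytest.approx(np.sqrt(12.5))
        assert s.median == pytest.approx(2.5)


class TestCrossValidation:
    def test_balanced_sets_have_equal_sides(self, tiny_session):
        trials = tiny_session.trials
        sets = balanced_trial_sets(trials, 10, seed=3)
        by_index = {t.index: t for t in trials}
        for s in sets:
            for key in ("train", "test"):
                dirs = [by_index[i].direction for i in s[key]]
                assert dirs.count("left") == dirs.count("right")

    def test_insufficient_trials_raise(self, tiny_session):
        few = [t for t in tiny_session.trials if t.direction == "right"][:3] + \
              [t for t in tiny_session.trials if t.direction == "left"][:6]
        with pytest.raises(InsufficientDataError):
            balanced_trial_sets(few, 5, seed=1)

    def test_ten_summaries_by_default(self, tiny_session, tiny_coarse):
        cv = ad.crossvalidate(tiny_session, method="bayes", seed=4,
                              ensemble=tiny_coarse)
        assert len(cv["summaries"]) == 10
        assert len(cv["sets"]) == 10

    def test_training_on_test_data_is_no_harder(self, tiny_session, tiny_coarse):
        # degenerate override: same test bins, with vs without leakage
        ens = tiny_coarse
        mask = ens.trial_index >= 0
        held = ens.bins_in_trials([t.index for t in tiny_session.trials[::2]])
        path_tt = _fit_eval(ens, mask, mask & held, "bayes", 1,
                            bounds=tiny_session.geometry.bounds)
        path_ho = _fit_eval(ens, mask & ~held, mask & held, "bayes", 1,
                            bounds=tiny_session.geometry.bounds)
        assert ErrorSummary.from_path(path_tt).rmse <= \
            ErrorSummary.from_path(path_ho).rmse + 0.5


class TestGreedyAndDownsampling:
    def test_strong_unit_chosen_first(self, geometry):
        cfg = ad.SimulatorConfig()
        cfg.schedule.blocks = cfg.schedule.blocks[:2]
        cfg.tuning.n_units = 5
        cfg.tuning.peak_hz = (0.0, 0.0)
        cfg.tuning.baseline_hz = (0.6, 0.8)     # near-silent units
        cfg.excursions.mode = "none"
        s = ad.make_session(cfg, seed=31)
        strong = ad.UnitTuning(unit_id="u002", center_vertex=100, width_cm=30.0,
                               baseline_hz=1.0, peak_hz=25.0)
        s.ground_truth.tuning[2] = strong
        s.spikes = ad.generate_spikes(s.trajectory, s.trials, s.ground_truth,
                                      s.geometry, seed=32)
        res = ad.greedy_select(s, k=1, seed=7, method="bayes", n_sets=4)
        assert res["units"][0] == "u002"

    def test_k_equals_all_units(self, tiny_session):
        res = ad.greedy_select(tiny_session, k=8, seed=9, method="bayes", n_sets=3)
        assert sorted(res["units"]) == sorted(tiny_session.spikes.unit_ids)
        assert len(res["error_per_step"]) == 8

    def test_oversized_subset_skipped_with_warning(self, tiny_session):
        with pytest.warns(UserWarning, match="exceeds unit count"):
            rows = ad.downsampling_curve(tiny_session, sizes=(4, 99), reps=1,
                                         seed=2, method="bayes", n_sets=2)
        assert {r["size"] for r in rows} == {4}


class TestJitterRobustness:
    def test_zero_jitter_is_a_point_mass_at_zero(self, tiny_session):
        res = ad.jitter_robustness(tiny_session, seed=13, jitter_fraction=0.0,
                                   train_config=TrainConfig(epochs=10))
        assert np.allclose(res["deviation"], 0.0, atol=1e-9)
        assert res["rmse_delta_mean"] == pytest.approx(0.0, abs=1e-9)

    def test_deviations_nonnegative_and_rmse_reported(self, tiny_session):
        res = ad.jitter_robustness(tiny_session, seed=14,
                                   train_config=TrainConfig(epochs=10))
        assert np.all(res["deviation"] >= 0)
        assert np.isfinite(res["rmse_delta_mean"])


def test_downsampling_more_units_decode_better(tiny_session):
    rows = ad.downsampling_curve(tiny_session, sizes=(2, 8), reps=3, seed=6,
                                 method="bayes", n_sets=4)
    med = {size: np.median([r["rmse_mean"] for r in rows if r["size"] == size])
           for size in (2, 8)}
    assert med[8] <= med[2]


class TestErrorMap:
    def test_perfect_decoder_gives_zero_maps(self):
        pos = np.array([[2.0, 1.5], [6.0, 1.5], [6.0, 1.5]])
        path = DecodedPath(t=np.arange(3), pred=pos.copy(), actual=pos,
                           trial_index=np.array([0, 0, 1]))
        maps = ad.error_map(results=[{"paths": [path]}], bounds=(8.0, 3.0))
        visited = ~np.isnan(maps["max"])
        assert visited.sum() == 2
        assert np.nanmax(maps["max"]) == 0.0
        assert np.nanmax(maps["mean"]) == 0.0

    def test_single_tile_max_is_five(self):
        actual = np.tile([2.0, 1.5], (3, 1))
        pred = actual + np.array([[1.0, 0], [5.0, 0], [2.0, 0]])
        path = DecodedPath(t=np.arange(3), pred=pred, actual=actual,
                           trial_index=np.zeros(3, int))
        maps = ad.error_map(results=[{"paths": [path]}], bounds=(4.0, 3.0))
        assert maps["max"][0, 0] == pytest.approx(5.0)
        assert maps["mean"][0, 0] == pytest.approx(8.0 / 3.0)

    def test_matches_groupby_oracle(self, rng):
        actual = np.column_stack([rng.choice([2.0, 6.0], 60),
                                  np.full(60, 1.5)])
        pred = actual + rng.normal(0, 5, size=(60, 2))
        trial = rng.integers(0, 3, 60)
        path = DecodedPath(t=np.arange(60), pred=pred, actual=actual,
                           trial_index=trial)
        maps = ad.error_map(results=[{"paths": [path]}], bounds=(8.0, 3.0))
        err = np.hypot(*(pred - actual).T)
        for k, x in enumerate([2.0, 6.0]):
            sel = actual[:, 0] == x
            per_trial = [err[sel & (trial == t)].max()
                         for t in np.unique(trial[sel])]
            assert maps["max"][0, k] == pytest.approx(np.mean(per_trial))


class TestStability:
    def test_drifting_tuning_hurts_half_split(self, geometry):
        # second-half spikes drawn from different tuning: the half split
        # trains on the old code and tests on the new one
        cfg = ad.ScheduleConfig(blocks=[("S0", "B0")] * 2)
        traj, trials = ad.simulate_trajectory(geometry, cfg, seed=11)
        t_a = ad.make_tuning(geometry, ad.TuningConfig(n_units=10), seed=1)
        t_b = ad.make_tuning(geometry, ad.TuningConfig(n_units=10), seed=2)
        sp_a = ad.generate_spikes(traj, trials, t_a, geometry, seed=3)
        sp_b = ad.generate_spikes(traj, trials, t_b, geometry, seed=4)
        half_t = trials[len(trials) // 2].t_start
        spikes = {}
        for u in sp_a.unit_ids:
            spikes[u] = np.concatenate([
                sp_a.spikes[u][sp_a.spikes[u] < half_t],
                sp_b.spikes[u][sp_b.spikes[u] >= half_t],
            ])
        s = ad.SessionBundle(
            geometry=geometry,
            spikes=ad.SpikeTrainSet(unit_ids=sp_a.unit_ids, spikes=spikes,
                                    duration=sp_a.duration),
            trajectory=traj, trials=trials, ground_truth=t_a,
        )
        res = ad.stability_test(s, seed=5, method="bayes")
        assert res["half"].rmse > res["alternating"].rmse

    def test_paired_ttest_wrapper(self):
        t, p = ad.stability_ttest([0.1, -0.2, 0.05, 0.0, -0.1])
        assert np.isfinite(t) and 0 <= p <= 1
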