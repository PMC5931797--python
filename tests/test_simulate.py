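import numpy as np
import pytest
from scipy import stats

import accdecode as ad
from accdecode._rand import MissingSeedError
from accdecode.simulate import (
    ExcursionConfig, ScheduleConfig, preference_p_right, rate_series,
)


def test_schedule_produces_96_trials(geometry):
    traj, trials = ad.simulate_trajectory(geometry, ScheduleConfig(), seed=1)
    assert len(trials) == 96
    for b in range(6):
        block = [t for t in trials if t.block_index == b]
        assert [t.mode for t in block] == ["forced"] * 10 + ["free"] * 6
        forced_dirs = [t.direction for t in block[:10]]
        assert all(a != b_ for a, b_ in zip(forced_dirs, forced_dirs[1:]))


def test_missing_seed_rejected(geometry):
    with pytest.raises(MissingSeedError):
        ad.simulate_trajectory(geometry, ScheduleConfig(), seed=None)


def test_deterministic_preference_always_big_reward(geometry):
    cfg = ScheduleConfig(preference_mode="max_reward")
    _, trials = ad.simulate_trajectory(geometry, cfg, seed=3)
    big = {"S": 30, "B": 120}
    for t in trials:
        if t.mode == "free":
            block = cfg.blocks[t.block_index]
            big_side = "right" if big[block[1][0]] >= big[block[0][0]] else "left"
            assert t.direction == big_side
    assert sum(t.mode == "free" for t in trials) == 36


def test_softmax_choice_fraction_matches_probability(geometry):
    # 1000 free trials in one block: empirical fraction within 3 SE
    cfg = ScheduleConfig(blocks=[("S0", "B1")], n_forced=0, n_free=1000)
    _, trials = ad.simulate_trajectory(geometry, cfg, seed=7)
    p = preference_p_right(cfg, ("S0", "B1"))
    frac = np.mean([t.direction == "right" for t in trials])
    se = np.sqrt(p * (1 - p) / 1000)
    assert abs(frac - p) < 3 * se


def test_trajectory_dwells_and_speed(tiny_session):
    traj = tiny_session.trajectory
    speed = np.hypot(np.diff(traj.x), np.diff(traj.y)) / traj.dt
    cfg = ad.ScheduleConfig()
    assert speed.max() <= cfg.run_speed_cm_s + 1e-6
    for tr in tiny_session.trials[:4]:
        dwell = (traj.t >= tr.t_target_feeder_on + 0.1) & \
                (traj.t <= tr.t_target_feeder_on + 2.4)
        assert np.allclose(speed[dwell[:-1]], 0.0, atol=1e-9)


def test_trial_windows_tile_session(tiny_session):
    trials = tiny_session.trials
    for a, b in zip(trials, trials[1:]):
        assert b.t_start == pytest.approx(a.t_end)
    assert trials[0].t_start == 0.0
    assert tiny_session.spikes.duration >= trials[-1].t_end


def test_homogeneous_poisson_total_count(geometry):
    # flat tuning at 2 Hz for 1000 s: count within 4 * sqrt(2000) of 2000
    t = np.arange(0, 1000.0, 1 / 30.0)
    traj = ad.TrajectorySeries(t=t, x=np.full_like(t, 51.0), y=np.full_like(t, 62.7))
    trial = ad.TrialRecord(
        index=0, block_index=0, direction="left", mode="forced",
        reward_volume=30, barrier_level=0, t_start=0.0, t_end=1000.0,
        t_center_feeder_on=1.0, t_center_feeder_off=1.5,
        t_target_feeder_on=2.0, t_target_feeder_off=2.5,
    )
    truth = ad.GroundTruth(tuning=[ad.UnitTuning(
        unit_id="u0", center_vertex=0, width_cm=30.0, baseline_hz=2.0, peak_hz=0.0,
    )])
    spikes = ad.generate_spikes(traj, [trial], truth, geometry, seed=5)
    n = len(spikes.spikes["u0"])
    assert abs(n - 2000) < 4 * np.sqrt(2000)


def test_spike_counts_follow_poisson_distribution(geometry):
    # count distribution over 10 000 bins against the Poisson pmf
    t = np.arange(0, 1000.0, 1 / 30.0)
    traj = ad.TrajectorySeries(t=t, x=np.full_like(t, 51.0), y=np.full_like(t, 62.7))
    trial = ad.TrialRecord(
        index=0, block_index=0, direction="left", mode="forced",
        reward_volume=30, barrier_level=0, t_start=0.0, t_end=1000.0,
        t_center_feeder_on=1.0, t_center_feeder_off=1.5,
        t_target_feeder_on=2.0, t_target_feeder_off=2.5,
    )
    truth = ad.GroundTruth(tuning=[ad.UnitTuning(
        unit_id="u0", center_vertex=0, width_cm=30.0, baseline_hz=4.0, peak_hz=0.0,
    )])
    spikes = ad.generate_spikes(traj, [trial], truth, geometry, seed=11)
    counts = np.histogram(spikes.spikes["u0"], bins=np.arange(0, 1000.01, 0.1))[0]
    lam = 0.4
    kmax = 4
    observed = np.array([np.sum(counts == k) for k in range(kmax)]
                        + [np.sum(counts >= kmax)], float)
    pmf = [stats.poisson.pmf(k, lam) for k in range(kmax)]
    expected = np.array(pmf + [1 - sum(pmf)]) * len(counts)
    p = stats.chisquare(observed, expected).pvalue
    assert p > 0.01


def test_counts_in_disjoint_windows_uncorrelated(geometry):
    # Poisson independence: correlation of counts in adjacent windows ~ 0
    t = np.arange(0, 2000.0, 1 / 30.0)
    traj = ad.TrajectorySeries(t=t, x=np.full_like(t, 51.0), y=np.full_like(t, 62.7))
    trial = ad.TrialRecord(
        index=0, block_index=0, direction="left", mode="forced",
        reward_volume=30, barrier_level=0, t_start=0.0, t_end=2000.0,
        t_center_feeder_on=1.0, t_center_feeder_off=1.5,
        t_target_feeder_on=2.0, t_target_feeder_off=2.5,
    )
    truth = ad.GroundTruth(tuning=[ad.UnitTuning(
        unit_id="u0", center_vertex=0, width_cm=30.0, baseline_hz=5.0, peak_hz=0.0,
    )])
    spikes = ad.generate_spikes(traj, [trial], truth, geometry, seed=2)
    counts = np.histogram(spikes.spikes["u0"], bins=np.arange(0, 2000.01, 0.5))[0]
    r = np.corrcoef(counts[:-1], counts[1:])[0, 1]
    assert abs(r) < 0.05


def test_tuned_unit_fires_more_at_its_field(geometry):
    r_vertex = geometry.feeder_vertex("R")
    tuning = [ad.UnitTuning(unit_id="u0", center_vertex=r_vertex, width_cm=30.0,
                            baseline_hz=1.0, peak_hz=8.0)]
    t = np.arange(0, 10.0, 1 / 30.0)
    half = len(t) // 2
    x = np.where(np.arange(len(t)) < half, geometry.feeders["R"][0],
                 geometry.feeders["C"][0])
    y = np.where(np.arange(len(t)) < half, geometry.feeders["R"][1],
                 geometry.feeders["C"][1])
    traj = ad.TrajectorySeries(t=t, x=x, y=y)
    trial = ad.TrialRecord(
        index=0, block_index=0, direction="right", mode="forced",
        reward_volume=30, barrier_level=0, t_start=0.0, t_end=10.0,
        t_center_feeder_on=1.0, t_center_feeder_off=1.5,
        t_target_feeder_on=2.0, t_target_feeder_off=2.5,
    )
    rates = rate_series(geometry, tuning, traj, [trial])
    assert rates[0, :half].mean() > rates[0, half:].mean() * 2


def test_injection_preserves_spikes_outside_windows(tiny_session):
    cfg = ExcursionConfig(mode="fixed_count", n_fixed=3)
    new, log = ad.inject_excursions(tiny_session.spikes, tiny_session, cfg, seed=9)
    assert len(log) == 3
    wins = [(i.onset, i.onset + i.duration_ms / 1000.0) for i in log]
    for u in tiny_session.spikes.unit_ids:
        old = tiny_session.spikes.spikes[u]
        out = np.ones(len(old), bool)
        for a, b in wins:
            out &= (old < a) | (old >= b)
        nw = new.spikes[u]
        keep = np.ones(len(nw), bool)
        for a, b in wins:
            keep &= (nw < a) | (nw >= b)
        assert np.array_equal(old[out], nw[keep])


def test_full_blend_window_rate_matches_remote_feeder(geometry):
    # w=1 and a unit tuned only to the remote feeder: expected in-window
    # count equals that unit's remote-feeder rate times the window length
    cfg = ad.SimulatorConfig()
    cfg.schedule.blocks = cfg.schedule.blocks[:2]
    cfg.tuning.n_units = 2
    cfg.excursions = ExcursionConfig(mode="fixed_count", n_fixed=20,
                                     blend_weight=1.0)
    s = ad.make_session(cfg, seed=13)
    l_vertex = s.geometry.feeder_vertex("L")
    unit = ad.UnitTuning(unit_id="u0", center_vertex=l_vertex, width_cm=10.0,
                         baseline_hz=0.0, peak_hz=20.0)
    s.ground_truth.tuning[0] = unit
    s.spikes = ad.generate_spikes(s.trajectory, s.trials, s.ground_truth,
                                  s.geometry, seed=14)
    new, log = ad.inject_excursions(s.spikes, s, cfg.excursions, seed=15)
    right_logs = [i for i in log if i.occupied_feeder == "R"]
    assert right_logs
    total_t = sum(i.duration_ms for i in right_logs) / 1000.0
    count = 0
    for i in right_logs:
        sp = new.spikes["u0"]
        count += np.sum((sp >= i.onset) & (sp < i.onset + i.duration_ms / 1000.0))
    gains = [1.0 + unit.reward_gain, 1.0]  # no gains planted: factor 1
    expected = 20.0 * total_t
    assert abs(count - expected) < 4 * np.sqrt(expected) + 2


def test_injection_frequency_matches_probability_model():
    # p = 0.6 - 0.5 * preference over 7 small sessions, seeds 1..7
    total, expected_total = 0, 0.0
    for seed in range(1, 8):
        cfg = ad.SimulatorConfig()
        cfg.schedule.blocks = cfg.schedule.blocks[:3]
        cfg.tuning.n_units = 4
        s = ad.make_session(cfg, seed=seed)
        total += len(s.ground_truth.injections)
        for t in s.trials:
            p_r = preference_p_right(cfg.schedule, cfg.schedule.blocks[t.block_index])
            pref = p_r if t.direction == "right" else 1 - p_r
            expected_total += np.clip(0.6 - 0.5 * pref, 0, 1)
    sd = np.sqrt(expected_total)  # binomial-ish
    assert abs(total - expected_total) < 4 * sd


def test_mean_rates_exceed_half_hertz(tiny_session):
    assert min(tiny_session.spikes.rates().values()) > 0.5


def test_counterbalanced_study_spreads_preference():
    sessions = ad.counterbalanced_study(4, seed=2, n_repeats=1)
    prefs = []
    for s in sessions:
        free = [t for t in s.trials if t.mode == "free"]
        prefs.append(np.mean([t.direction == "right" for t in free]))
    assert np.ptp(prefs) > 0.15
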