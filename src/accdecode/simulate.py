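"""Synthetic figure-8 sessions with known ground truth.

The generator emulates the structure of the recorded sessions: a 6-block x
16-trial schedule (10 forced-alternation trials then 6 free-choice trials per
block), a video-tracker trajectory that laps the track and pauses at the
centre feeder and the chosen target feeder, and an ensemble of >= 40 units
with broad spatial tuning (> 50 cm fields), baseline rates above 0.5 Hz and
optional reward/choice rate modulation.

Excursion episodes — brief (~300-500 ms) shifts of the population pattern
toward the remote target feeder while the rat sits at a target feeder — are
injected by regenerating spikes inside a short window from a blended rate,
with per-trial injection probability decreasing in the preference for the
occupied feeder.  The injection log is the ground truth against which the
detector is scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from ._rand import require_seed, rng_from, spawn_seeds
from .geometry import TrackGeometry, build_track_geometry
from .session import (
    GroundTruth, InjectionRecord, SessionBundle, SpikeTrainSet,
    TrajectorySeries, TrialRecord, UnitTuning,
)

__all__ = [
    "ScheduleConfig", "TuningConfig", "ExcursionConfig", "SimulatorConfig",
    "preference_p_right", "simulate_trajectory", "make_tuning",
    "generate_spikes", "inject_excursions", "make_session", "reference_session",
]

# block order as run in the task: (left option, right option); letter = reward
# volume (S small 30 uL, B big 120 uL), digit = barrier level
DEFAULT_BLOCKS = [
    ("S0", "B0"), ("S0", "B1"), ("S0", "B2"),
    ("S2", "B2"), ("B0", "S0"), ("B2", "S0"),
]
REWARD_UL = {"S": 30, "B": 120}
BARRIER_HEIGHT_CM = {0: 0.0, 1: 23.0, 2: 46.0}


class InvalidTuningError(ValueError):
    pass


@dataclass
class ScheduleConfig:
    """Block schedule, locomotion and choice-preference parameters."""
    blocks: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_BLOCKS))
    n_repeats: int = 1                # the block sequence restarts upon completion
    n_forced: int = 10
    n_free: int = 6
    run_speed_cm_s: float = 60.0      # locomotion speed between feeders
    dwell_center_s: float = 1.0       # pause at the centre feeder
    dwell_target_s: float = 3.0       # pause at the chosen target feeder
    reward_s: float = 0.5             # feeder-activation to feeder-off interval
    tracker_hz: float = 30.0
    # softmax preference over effort-discounted reward utility
    preference_mode: str = "softmax"  # "softmax" | "max_reward"
    w_reward: float = 1.0
    w_effort: float = 0.6
    temperature: float = 0.25

    def utilities(self, block: tuple[str, str]) -> tuple[float, float]:
        out = []
        for code in block:
            reward = REWARD_UL[code[0]] / 120.0
            effort = int(code[1]) / 2.0
            out.append(self.w_reward * reward - self.w_effort * effort)
        return tuple(out)


def preference_p_right(cfg: ScheduleConfig, block: tuple[str, str]) -> float:
    """Model probability of choosing the right feeder on a free trial."""
    u_left, u_right = cfg.utilities(block)
    if cfg.preference_mode == "max_reward":
        return 1.0 if REWARD_UL[block[1][0]] >= REWARD_UL[block[0][0]] else 0.0
    return float(1.0 / (1.0 + np.exp(-(u_right - u_left) / cfg.temperature)))


@dataclass
class TuningConfig:
    n_units: int = 40
    width_cm: tuple[float, float] = (25.0, 45.0)   # Gaussian SD range; fields span > 50 cm
    baseline_hz: tuple[float, float] = (0.8, 1.5)
    peak_hz: tuple[float, float] = (4.0, 12.0)
    reward_frac: float = 0.3          # fraction of units with reward-gain modulation
    choice_frac: float = 0.3
    reward_gain: tuple[float, float] = (0.5, 1.0)
    choice_gain: tuple[float, float] = (0.5, 1.0)


@dataclass
class ExcursionConfig:
    mode: str = "preference"          # "preference" | "fixed_count" | "none"
    p0: float = 0.6                   # p(excursion) = p0 - p1 * preference(occupied)
    p1: float = 0.5
    n_fixed: int = 12                 # used when mode == "fixed_count"
    blend_weight: float = 1.0         # weight toward the remote-feeder pattern
    delay_s: tuple[float, float] = (0.1, 0.5)   # onset delay after feeder off-set
    duration_ms_mean: float = 400.0
    duration_ms_sd: float = 80.0
    duration_ms_range: tuple[float, float] = (300.0, 500.0)


@dataclass
class SimulatorConfig:
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    tuning: TuningConfig = field(default_factory=TuningConfig)
    excursions: ExcursionConfig = field(default_factory=ExcursionConfig)
    track: dict = field(default_factory=dict)   # overrides for build_track_geometry

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"]["blocks"] = [list(b) for b in self.schedule.blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulatorConfig":
        sched = dict(d.get("schedule", {}))
        if "blocks" in sched:
            sched["blocks"] = [tuple(b) for b in sched["blocks"]]
        tun = dict(d.get("tuning", {}))
        for k in ("width_cm", "baseline_hz", "peak_hz", "reward_gain", "choice_gain"):
            if k in tun:
                tun[k] = tuple(tun[k])
        exc = dict(d.get("excursions", {}))
        for k in ("delay_s", "duration_ms_range"):
            if k in exc:
                exc[k] = tuple(exc[k])
        return cls(
            schedule=ScheduleConfig(**sched), tuning=TuningConfig(**tun),
            excursions=ExcursionConfig(**exc), track=dict(d.get("track", {})),
        )


# ---------------------------------------------------------------------------
# trajectory

def _lap_vertices(geometry: TrackGeometry, direction: str) -> np.ndarray:
    """Ordered vertex indices of one lap: arm south->north, then loop back."""
    from .geometry import ARM, LEFT, RIGHT
    arm = np.flatnonzero(geometry.branch == ARM)
    loop = np.flatnonzero(geometry.branch == (LEFT if direction == "left" else RIGHT))
    return np.concatenate([arm, loop])


def simulate_trajectory(
    geometry: TrackGeometry, schedule: ScheduleConfig, seed,
) -> tuple[TrajectorySeries, list[TrialRecord]]:
    """Run the block schedule and lay down the tracker trajectory.

    The rat starts each trial at the base of the central arm, runs north,
    pauses at the centre feeder, turns left or right at the choice point,
    pauses at the chosen target feeder, and returns along the outer edge.
    Dwells have zero speed; runs use the configured constant speed.
    """
    rng = rng_from(seed)
    if schedule.run_speed_cm_s <= 0 or min(
        schedule.dwell_center_s, schedule.dwell_target_s, schedule.reward_s
    ) <= 0:
        raise ValueError("speeds and dwell times must be positive")

    c_vertex = geometry.feeder_vertex("C")
    knot_t, knot_xy = [0.0], [geometry.skeleton[_lap_vertices(geometry, "left")[0]]]
    trials: list[TrialRecord] = []
    t = 0.0
    idx = 0
    sequence = list(schedule.blocks) * schedule.n_repeats
    for b, block in enumerate(sequence):
        p_right = preference_p_right(schedule, block)
        for k in range(schedule.n_forced + schedule.n_free):
            if k < schedule.n_forced:
                mode = "forced"
                direction = ("left", "right")[(k + b) % 2]
            else:
                mode = "free"
                direction = "right" if rng.random() < p_right else "left"
            code = block[0] if direction == "left" else block[1]
            verts = _lap_vertices(geometry, direction)
            f_vertex = geometry.feeder_vertex("L" if direction == "left" else "R")
            pts = geometry.skeleton[verts]
            seg = np.hypot(*np.diff(pts, axis=0).T)
            t_start = t
            events = {}
            for j in range(1, len(verts)):
                t += seg[j - 1] / schedule.run_speed_cm_s
                knot_t.append(t)
                knot_xy.append(pts[j])
                if verts[j] == c_vertex:
                    events["t_center_feeder_on"] = t
                    events["t_center_feeder_off"] = t + schedule.reward_s
                    t += schedule.dwell_center_s
                    knot_t.append(t)
                    knot_xy.append(pts[j])
                elif verts[j] == f_vertex:
                    events["t_target_feeder_on"] = t
                    events["t_target_feeder_off"] = t + schedule.reward_s
                    t += schedule.dwell_target_s
                    knot_t.append(t)
                    knot_xy.append(pts[j])
            trials.append(TrialRecord(
                index=idx, block_index=b, direction=direction, mode=mode,
                reward_volume=REWARD_UL[code[0]], barrier_level=int(code[1]),
                t_start=t_start, t_end=t, **events,
            ))
            idx += 1

    knot_t = np.asarray(knot_t)
    knot_xy = np.asarray(knot_xy)
    ts = np.arange(0.0, t, 1.0 / schedule.tracker_hz)
    traj = TrajectorySeries(
        t=ts,
        x=np.interp(ts, knot_t, knot_xy[:, 0]),
        y=np.interp(ts, knot_t, knot_xy[:, 1]),
    )
    return traj, trials


# ---------------------------------------------------------------------------
# spikes

def make_tuning(geometry: TrackGeometry, cfg: TuningConfig, seed) -> GroundTruth:
    """Draw per-unit tuning: field centres spread over the track skeleton."""
    rng = rng_from(seed)
    n = cfg.n_units
    n_vertices = len(geometry.skeleton)
    centers = (np.linspace(0, n_vertices - 1, n, dtype=int)
               + rng.integers(-5, 6, size=n)) % n_vertices
    rng.shuffle(centers)
    is_reward = rng.random(n) < cfg.reward_frac
    is_choice = rng.random(n) < cfg.choice_frac
    tuning = [
        UnitTuning(
            unit_id=f"u{i:03d}",
            center_vertex=int(centers[i]),
            width_cm=float(rng.uniform(*cfg.width_cm)),
            baseline_hz=float(rng.uniform(*cfg.baseline_hz)),
            peak_hz=float(rng.uniform(*cfg.peak_hz)),
            reward_gain=float(rng.uniform(*cfg.reward_gain)) if is_reward[i] else 0.0,
            choice_gain=float(rng.uniform(*cfg.choice_gain)) if is_choice[i] else 0.0,
        )
        for i in range(n)
    ]
    return GroundTruth(tuning=tuning, injections=[])


def _trial_gains(tuning: list[UnitTuning], trial: TrialRecord) -> np.ndarray:
    big = 1.0 if trial.reward_volume >= 120 else 0.0
    right = 1.0 if trial.direction == "right" else 0.0
    g = np.array(
        [(1.0 + u.reward_gain * big) * (1.0 + u.choice_gain * right) for u in tuning]
    )
    if np.any(g < 0):
        raise InvalidTuningError("rate gains produce a negative firing rate")
    return g


def _spatial_rates(
    geometry: TrackGeometry, tuning: list[UnitTuning], vertex_idx: np.ndarray,
) -> np.ndarray:
    """(units x positions) rate from spatial tuning alone, no trial gains."""
    G = geometry.geodesic
    rates = np.empty((len(tuning), len(vertex_idx)))
    for i, u in enumerate(tuning):
        d = G[u.center_vertex, vertex_idx]
        rates[i] = u.baseline_hz + u.peak_hz * np.exp(-0.5 * (d / u.width_cm) ** 2)
    if np.any(rates < 0):
        raise InvalidTuningError("negative firing rate in tuning model")
    return rates


def rate_series(
    geometry: TrackGeometry, tuning: list[UnitTuning],
    trajectory: TrajectorySeries, trials: list[TrialRecord],
) -> np.ndarray:
    """(units x tracker samples) intended firing rate along the trajectory."""
    verts = geometry.nearest_vertex(trajectory.xy)
    rates = _spatial_rates(geometry, tuning, verts)
    starts = np.array([tr.t_start for tr in trials])
    which = np.clip(np.searchsorted(starts, trajectory.t, side="right") - 1, 0, None)
    gains = np.stack([_trial_gains(tuning, tr) for tr in trials], axis=1)
    return rates * gains[:, which]


def _poisson_spikes(rng, rates: np.ndarray, t0: np.ndarray, dt: float) -> list[np.ndarray]:
    """Draw inhomogeneous Poisson spikes, piecewise-constant on sample bins."""
    out = []
    for r in rates:
        counts = rng.poisson(r * dt)
        starts = np.repeat(t0, counts)
        out.append(np.sort(starts + rng.random(starts.size) * dt))
    return out


def generate_spikes(
    trajectory: TrajectorySeries, trials: list[TrialRecord],
    tuning: GroundTruth, geometry: TrackGeometry, seed,
) -> SpikeTrainSet:
    """Inhomogeneous-Poisson spike trains from the tuned rate model."""
    rng = rng_from(seed)
    rates = rate_series(geometry, tuning.tuning, trajectory, trials)
    dt = trajectory.dt
    duration = float(trajectory.t[-1] + dt)
    trains = _poisson_spikes(rng, rates, trajectory.t, dt)
    return SpikeTrainSet(
        unit_ids=[u.unit_id for u in tuning.tuning],
        spikes={u.unit_id: s for u, s in zip(tuning.tuning, trains)},
        duration=duration,
    )


# ---------------------------------------------------------------------------
# excursion injection

def inject_excursions(
    spikes: SpikeTrainSet, bundle: SessionBundle, cfg: ExcursionConfig, seed,
    schedule: ScheduleConfig | None = None,
) -> tuple[SpikeTrainSet, list[InjectionRecord]]:
    """Inject remote-feeder pattern shifts during target-feeder dwells.

    Inside each injected window the per-unit rate is replaced by
    ``(1 - w) * rate(occupied feeder) + w * rate(remote feeder)`` and spikes
    are regenerated there; spikes outside injected windows are untouched.
    The feeder rates are the units' spatial-tuning rates at the feeder
    locations, i.e. the typical population pattern expressed during visits
    there, so that a full blend (w = 1) plants a pattern the decoder maps
    to the remote feeder.
    """
    rng = rng_from(seed)
    if cfg.mode == "none":
        return spikes.subset(spikes.unit_ids), []
    schedule = schedule or ScheduleConfig()
    geometry = bundle.geometry
    tuning = bundle.ground_truth.tuning
    feeder_v = {k: geometry.feeder_vertex(k) for k in ("L", "R")}
    base_rates = _spatial_rates(
        geometry, tuning, np.array([feeder_v["L"], feeder_v["R"]])
    )  # units x {L, R}

    trials = bundle.trials
    if cfg.mode == "fixed_count":
        chosen = set(rng.choice(len(trials), size=min(cfg.n_fixed, len(trials)),
                                replace=False).tolist())
    new_spikes = {u: spikes.spikes[u] for u in spikes.unit_ids}
    log: list[InjectionRecord] = []
    for i, tr in enumerate(trials):
        if cfg.mode == "preference":
            block = schedule.blocks[tr.block_index % len(schedule.blocks)]
            p_right = preference_p_right(schedule, block)
            pref = p_right if tr.direction == "right" else 1.0 - p_right
            p = float(np.clip(cfg.p0 - cfg.p1 * pref, 0.0, 1.0))
            take = rng.random() < p
        else:
            take = i in chosen
        if not take:
            continue
        occupied = tr.target_feeder
        remote = "R" if occupied == "L" else "L"
        onset = tr.t_target_feeder_off + rng.uniform(*cfg.delay_s)
        dur = float(np.clip(rng.normal(cfg.duration_ms_mean, cfg.duration_ms_sd),
                            *cfg.duration_ms_range)) / 1000.0
        if onset + dur > tr.t_end:
            warnings.warn(f"trial {tr.index}: excursion window clipped at trial end")
            dur = tr.t_end - onset
        offset = onset + dur
        col = {"L": 0, "R": 1}
        blended = (
            (1.0 - cfg.blend_weight) * base_rates[:, col[occupied]]
            + cfg.blend_weight * base_rates[:, col[remote]]
        )
        for u, lam in zip(spikes.unit_ids, blended):
            s = new_spikes[u]
            keep = s[(s < onset) | (s >= offset)]
            k = rng.poisson(lam * dur)
            inj = onset + rng.random(k) * dur
            new_spikes[u] = np.sort(np.concatenate([keep, inj]))
        log.append(InjectionRecord(
            trial_index=tr.index, occupied_feeder=occupied, remote_feeder=remote,
            onset=float(onset), duration_ms=float(dur * 1000.0),
            blend_weight=float(cfg.blend_weight),
        ))
    out = SpikeTrainSet(unit_ids=list(spikes.unit_ids), spikes=new_spikes,
                        duration=spikes.duration)
    return out, log


# ---------------------------------------------------------------------------
# end-to-end session

def make_session(config: SimulatorConfig | None = None, seed=None) -> SessionBundle:
    """Generate one full session: geometry, trajectory, trials, spikes, injections."""
    require_seed(seed)
    config = config or SimulatorConfig()
    s_traj, s_tune, s_spk, s_exc = spawn_seeds(seed, 4)
    geometry = build_track_geometry(**config.track)
    trajectory, trials = simulate_trajectory(geometry, config.schedule, s_traj)
    truth = make_tuning(geometry, config.tuning, s_tune)
    spikes = generate_spikes(trajectory, trials, truth, geometry, s_spk)
    bundle = SessionBundle(
        geometry=geometry, spikes=spikes, trajectory=trajectory,
        trials=trials, ground_truth=truth,
    )
    spikes, log = inject_excursions(
        spikes, bundle, config.excursions, s_exc, schedule=config.schedule
    )
    bundle.spikes = spikes
    truth.injections = log
    return bundle


def reference_session(seed=1, **overrides) -> SessionBundle:
    """The 40-unit reference synthetic session used throughout the tests."""
    cfg = SimulatorConfig()
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return make_session(cfg, seed=seed)


def counterbalanced_study(
    n_sessions: int = 7, seed=None, excursion_p0: float = 0.6,
    excursion_p1: float = 0.5, n_repeats: int = 2,
) -> list[SessionBundle]:
    """Sessions with counterbalanced reward sides and varied effort weighting.

    Mirrors the experimental design across sessions: the side with the
    initially large reward alternates, and the effort weighting / choice
    temperature differ from animal to animal, producing a spread of revealed
    feeder preferences.  ``excursion_p1 = 0`` gives a preference-independent
    injection model (the null generator).
    """
    seeds = spawn_seeds(seed, n_sessions)
    temperatures = [0.12, 0.25, 0.5]
    efforts = [0.3, 0.6, 1.0]
    out = []
    for i in range(n_sessions):
        cfg = SimulatorConfig()
        cfg.schedule.n_repeats = n_repeats
        cfg.schedule.temperature = temperatures[i % len(temperatures)]
        cfg.schedule.w_effort = efforts[(i // 2) % len(efforts)]
        if i % 2 == 1:
            cfg.schedule.blocks = [(r, l) for l, r in cfg.schedule.blocks]
        cfg.excursions.p0 = excursion_p0
        cfg.excursions.p1 = excursion_p1
        out.append(make_session(cfg, seed=seeds[i]))
    return out
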