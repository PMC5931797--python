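"""Session containers and on-disk session bundles.

A session bundle is a directory holding plain-text tables:

* ``spikes.csv`` — unit_id, t_seconds
* ``position.csv`` — t_seconds, x_cm, y_cm
* ``trials.csv`` — one row per trial with block, direction, mode, reward,
  barrier level, trial window and feeder event times
* ``geometry.json`` — track skeleton, feeders, bounds
* ``ground_truth.json`` — optional; per-unit tuning and injected excursions
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import TrackGeometry

__all__ = [
    "TrialRecord",
    "SpikeTrainSet",
    "TrajectorySeries",
    "UnitTuning",
    "InjectionRecord",
    "GroundTruth",
    "SessionBundle",
    "read_session",
    "write_session",
]

TRIAL_COLUMNS = [
    "index", "block", "direction", "mode", "reward_ul", "barrier_level",
    "t_start", "t_end", "t_center_feeder_on", "t_center_feeder_off",
    "t_target_feeder_on", "t_target_feeder_off",
]


class SessionParseError(ValueError):
    pass


@dataclass
class TrialRecord:
    index: int
    block_index: int
    direction: str            # "left" | "right"
    mode: str                 # "forced" | "free"
    reward_volume: int        # µL at the chosen target feeder (30 or 120)
    barrier_level: int        # 0, 1 or 2 at the chosen target feeder
    t_start: float
    t_end: float
    t_center_feeder_on: float
    t_center_feeder_off: float
    t_target_feeder_on: float
    t_target_feeder_off: float

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError(f"trial {self.index}: t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def target_feeder(self) -> str:
        return "L" if self.direction == "left" else "R"


@dataclass
class SpikeTrainSet:
    unit_ids: list[str]
    spikes: dict[str, np.ndarray]   # unit id -> sorted times (s)
    duration: float                 # session length (s)

    def __post_init__(self):
        for u in self.unit_ids:
            t = np.asarray(self.spikes[u], float)
            if t.size and (np.any(np.diff(t) < 0) or t[0] < 0 or t[-1] > self.duration):
                raise ValueError(f"unit {u}: spike times must be sorted within [0, duration]")
            self.spikes[u] = t

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def rates(self) -> dict[str, float]:
        return {u: len(self.spikes[u]) / self.duration for u in self.unit_ids}

    def subset(self, unit_ids) -> "SpikeTrainSet":
        return SpikeTrainSet(
            unit_ids=list(unit_ids),
            spikes={u: self.spikes[u].copy() for u in unit_ids},
            duration=self.duration,
        )


@dataclass
class TrajectorySeries:
    t: np.ndarray    # regularly sampled timestamps (s)
    x: np.ndarray    # cm
    y: np.ndarray    # cm

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if len(self.t) > 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
                raise ValueError("trajectory must be regularly sampled")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class UnitTuning:
    """Broad spatial tuning of one synthetic unit on the linearized track."""
    unit_id: str
    center_vertex: int       # skeleton vertex index of the field centre
    width_cm: float          # Gaussian SD along the track
    baseline_hz: float
    peak_hz: float
    reward_gain: float = 0.0   # multiplicative gain on large-reward trials
    choice_gain: float = 0.0   # multiplicative gain on right-choice trials

    def __post_init__(self):
        if self.width_cm <= 0:
            raise ValueError("field width must be positive")


@dataclass
class InjectionRecord:
    trial_index: int
    occupied_feeder: str     # feeder the rat is at
    remote_feeder: str       # feeder whose pattern is blended in
    onset: float
    duration_ms: float
    blend_weight: float

    def __post_init__(self):
        if not 0.0 < self.blend_weight <= 1.0:
            raise ValueError("blend weight must be in (0, 1]")


@dataclass
class GroundTruth:
    tuning: list[UnitTuning] = field(default_factory=list)
    injections: list[InjectionRecord] = field(default_factory=list)


@dataclass
class SessionBundle:
    geometry: TrackGeometry
    spikes: SpikeTrainSet
    trajectory: TrajectorySeries
    trials: list[TrialRecord]
    ground_truth: GroundTruth | None = None


# ---------------------------------------------------------------------------
# on-disk format

def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = [
        [tr.index, tr.block_index, tr.direction, tr.mode, tr.reward_volume,
         tr.barrier_level, tr.t_start, tr.t_end, tr.t_center_feeder_on,
         tr.t_center_feeder_off, tr.t_target_feeder_on, tr.t_target_feeder_off]
        for tr in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            index=int(r["index"]), block_index=int(r["block"]),
            direction=str(r["direction"]), mode=str(r["mode"]),
            reward_volume=int(r["reward_ul"]), barrier_level=int(r["barrier_level"]),
            t_start=float(r["t_start"]), t_end=float(r["t_end"]),
            t_center_feeder_on=float(r["t_center_feeder_on"]),
            t_center_feeder_off=float(r["t_center_feeder_off"]),
            t_target_feeder_on=float(r["t_target_feeder_on"]),
            t_target_feeder_off=float(r["t_target_feeder_off"]),
        )
        for _, r in df.iterrows()
    ]


def write_session(bundle: SessionBundle, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = [(u, t) for u in bundle.spikes.unit_ids for t in bundle.spikes.spikes[u]]
    pd.DataFrame(rows, columns=["unit_id", "t_seconds"]).to_csv(
        path / "spikes.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(
        {"t_seconds": bundle.trajectory.t, "x_cm": bundle.trajectory.x,
         "y_cm": bundle.trajectory.y}
    ).to_csv(path / "position.csv", index=False, float_format="%.17g")
    trials_to_frame(bundle.trials).to_csv(path / "trials.csv", index=False,
                                          float_format="%.17g")

    geo = bundle.geometry.to_dict()
    geo["duration"] = bundle.spikes.duration
    geo["unit_ids"] = bundle.spikes.unit_ids
    (path / "geometry.json").write_text(json.dumps(geo))

    if bundle.ground_truth is not None:
        gt = {
            "tuning": [asdict(t) for t in bundle.ground_truth.tuning],
            "injections": [asdict(i) for i in bundle.ground_truth.injections],
        }
        (path / "ground_truth.json").write_text(json.dumps(gt))


def read_session(path) -> SessionBundle:
    path = Path(path)
    try:
        geo = json.loads((path / "geometry.json").read_text())
    except json.JSONDecodeError as e:
        raise SessionParseError(f"{path / 'geometry.json'}: line {e.lineno}: {e.msg}")
    geometry = TrackGeometry.from_dict(geo)
    duration = float(geo["duration"])
    unit_ids = [str(u) for u in geo["unit_ids"]]

    sp = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    spikes = {u: np.array([], float) for u in unit_ids}
    for u, grp in sp.groupby("unit_id", sort=False):
        spikes[str(u)] = np.sort(grp["t_seconds"].to_numpy(float))
    spike_set = SpikeTrainSet(unit_ids=unit_ids, spikes=spikes, duration=duration)

    pos = pd.read_csv(path / "position.csv", float_precision="round_trip")
    traj = TrajectorySeries(
        t=pos["t_seconds"].to_numpy(float),
        x=pos["x_cm"].to_numpy(float),
        y=pos["y_cm"].to_numpy(float),
    )
    trials = trials_from_frame(
        pd.read_csv(path / "trials.csv", float_precision="round_trip"))

    ground_truth = None
    gt_path = path / "ground_truth.json"
    if gt_path.exists():
        try:
            g = json.loads(gt_path.read_text())
        except json.JSONDecodeError as e:
            raise SessionParseError(f"{gt_path}: line {e.lineno}: {e.msg}")
        ground_truth = GroundTruth(
            tuning=[UnitTuning(**t) for t in g["tuning"]],
            injections=[InjectionRecord(**i) for i in g["injections"]],
        )
    return SessionBundle(
        geometry=geometry, spikes=spike_set, trajectory=traj,
        trials=trials, ground_truth=ground_truth,
    )
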