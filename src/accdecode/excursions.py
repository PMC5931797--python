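"""Excursion events: detection, episodes, timing, and preference coupling.

An excursion is a brief episode in which the decoded position departs from
the rat's physical location — typically toward the remote target feeder —
while the rat sits at a feeder after reward.  Detection follows the session
protocol at fine temporal resolution (120 ms kernel, 20 ms bins): for each
of 10 balanced trial sets, the decoder is trained on all bins outside the
post-reward windows of the selected trials and evaluated inside them; a
trial is flagged when its window's maximum decode error exceeds 70 cm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._rand import require_seed, spawn_seeds
from .decoders import DecodedPath, _fit_eval, _retained_trials, balanced_trial_sets
from .geometry import TrackGeometry
from .preprocessing import BinnedEnsemble, build_ensemble
from .session import SessionBundle, TrialRecord

__all__ = [
    "ExcursionEvent", "PreferenceRecord", "detect_excursion_trials",
    "extract_episodes", "align_onsets", "endpoint_concentration_test",
    "preference_correlation", "preference_record",
]


@dataclass
class ExcursionEvent:
    trial_index: int
    occupied_feeder: str        # "L" | "R" | "C"
    onset: float                # s
    offset: float               # s
    duration_ms: float
    peak_error_cm: float
    peak_time: float            # s
    endpoint: tuple[float, float]   # decoded (x, y) at peak error
    endpoint_feeder: str | None     # nearest feeder within zone radius, else None
    set_index: int = 0

    def __post_init__(self):
        assert self.offset > self.onset
        assert self.onset <= self.peak_time <= self.offset


@dataclass
class PreferenceRecord:
    session_id: str
    free_counts: dict[int, tuple[int, int]]   # block -> (n_left, n_right) free choices
    preference_right: float                    # fraction of free choices to R
    excursion_freq_right: float                # events at R / all forced-trial events

    def __post_init__(self):
        assert 0.0 <= self.preference_right <= 1.0
        assert 0.0 <= self.excursion_freq_right <= 1.0


# ---------------------------------------------------------------------------
# detection

def _window(trial: TrialRecord, window_s: float, anchor: str) -> tuple[float, float]:
    t0 = (trial.t_target_feeder_on if anchor == "activation"
          else trial.t_target_feeder_off)
    return t0, min(t0 + window_s, trial.t_end)


def detect_excursion_trials(
    session: SessionBundle, seed=None, threshold_cm: float = 70.0,
    window_s: float = 1.5, anchor: str = "activation", profile: str = "fine",
    method: str = "dann", n_sets: int = 10, train_config=None,
    hysteresis_cm: float | None = None, ensemble: BinnedEnsemble | None = None,
) -> dict:
    """Flag trials whose post-reward window contains a > 70 cm decode error.

    Returns per-trial flag fractions over the balanced sets, the final flags
    (a trial is an excursion trial when any tested window showed a
    supra-threshold error), and the extracted :class:`ExcursionEvent` list.
    """
    require_seed(seed)
    if ensemble is None:
        ensemble = build_ensemble(session, profile=profile)
    trials = {t.index: t for t in _retained_trials(session, ensemble)}
    n_side = min(
        sum(t.direction == "left" for t in trials.values()),
        sum(t.direction == "right" for t in trials.values()),
    ) // 2
    set_seed, *fit_seeds = spawn_seeds(seed, n_sets + 1)
    # selected trials of each set are the test group; the 75/25 split is not
    # used here, so request full sets and treat every selected trial as test
    sets = balanced_trial_sets(
        list(trials.values()), n_sets, set_seed, train_fraction=0.0,
        n_per_side=max(n_side, 4),
    )
    hysteresis = threshold_cm / 2.0 if hysteresis_cm is None else hysteresis_cm

    tested = {i: 0 for i in trials}
    hits = {i: 0 for i in trials}
    window_max: dict[int, float] = {}
    events: list[ExcursionEvent] = []
    window_masks: list[np.ndarray] = []
    selected_per_set: list[list[int]] = []
    for si, (s, fseed) in enumerate(zip(sets, fit_seeds)):
        selected = sorted(set(s["train"]) | set(s["test"]))
        windows = {}
        test_mask = np.zeros(ensemble.n_bins, bool)
        for i in selected:
            w0, w1 = _window(trials[i], window_s, anchor)
            if w1 <= w0:
                warnings.warn(f"trial {i}: empty post-reward window; skipped")
                continue
            m = (ensemble.bin_centers >= w0) & (ensemble.bin_centers < w1)
            if not m.any():
                warnings.warn(f"trial {i}: no bins in post-reward window; skipped")
                continue
            windows[i] = m
            test_mask |= m
        window_masks.append(test_mask)
        selected_per_set.append(selected)
        train_mask = ~test_mask & (ensemble.trial_index >= 0)
        path = _fit_eval(ensemble, train_mask, test_mask, method, fseed,
                         train_config=train_config, bounds=session.geometry.bounds)
        err_full = np.full(ensemble.n_bins, np.nan)
        pred_full = np.full((ensemble.n_bins, 2), np.nan)
        err_full[test_mask] = path.error
        pred_full[test_mask] = path.pred
        for i, m in windows.items():
            tested[i] += 1
            e = err_full[m]
            window_max[i] = max(window_max.get(i, 0.0), float(np.nanmax(e)))
            if np.nanmax(e) > threshold_cm:
                hits[i] += 1
                wpath = DecodedPath(
                    t=ensemble.bin_centers[m], pred=pred_full[m],
                    actual=ensemble.pos[m],
                    trial_index=ensemble.trial_index[m],
                )
                events.extend(extract_episodes(
                    wpath, ensemble.bin_width_ms, trials[i].target_feeder,
                    session.geometry, threshold_cm=threshold_cm,
                    hysteresis_cm=hysteresis, set_index=si,
                ))
    frac = {i: (hits[i] / tested[i] if tested[i] else 0.0) for i in trials}
    flags = {i: (tested[i] > 0 and window_max[i] > threshold_cm) for i in trials}
    return {
        "flags": flags, "flag_fraction": frac, "tested": tested,
        "events": events, "threshold_cm": threshold_cm, "n_sets": n_sets,
        "window_masks": window_masks, "selected": selected_per_set,
        "window_max_cm": window_max,
    }


def extract_episodes(
    path: DecodedPath, bin_ms: float, occupied_feeder: str,
    geometry: TrackGeometry, threshold_cm: float = 70.0,
    hysteresis_cm: float = 35.0, set_index: int = 0,
) -> list[ExcursionEvent]:
    """The maximal error run around the window's peak, with endpoint labelling.

    The episode is the contiguous run of bins with error >= the hysteresis
    level (half the 70 cm flag threshold) that contains the peak-error bin;
    other runs crossing the hysteresis level but not the flag threshold are
    not reported.
    """
    err = path.error
    peak = int(np.argmax(err))
    if err[peak] <= threshold_cm:
        return []
    above = err >= hysteresis_cm
    start = peak
    while start > 0 and above[start - 1]:
        start -= 1
    end = peak
    while end + 1 < len(err) and above[end + 1]:
        end += 1
    endpoint = path.pred[peak]
    label = geometry.label_positions(endpoint[None, :])[0]
    trial = int(path.trial_index[peak]) if path.trial_index is not None else -1
    return [ExcursionEvent(
        trial_index=trial, occupied_feeder=occupied_feeder,
        onset=float(path.t[start]), offset=float(path.t[end] + bin_ms / 1000.0),
        duration_ms=float((end - start + 1) * bin_ms),
        peak_error_cm=float(err[peak]), peak_time=float(path.t[peak]),
        endpoint=(float(endpoint[0]), float(endpoint[1])),
        endpoint_feeder=None if label == "track" else str(label),
        set_index=set_index,
    )]


# ---------------------------------------------------------------------------
# onset alignment

def zone_exit_times(session: SessionBundle) -> dict[int, float]:
    """Per trial, the first time after target-feeder arrival when the rat
    leaves the feeder zone."""
    out = {}
    traj = session.trajectory
    for tr in session.trials:
        feeder = session.geometry.feeders[tr.target_feeder]
        after = traj.t >= tr.t_target_feeder_on
        d = np.hypot(traj.x[after] - feeder[0], traj.y[after] - feeder[1])
        outside = np.flatnonzero(d > session.geometry.feeder_zone_radius)
        if outside.size:
            out[tr.index] = float(traj.t[after][outside[0]])
    return out


def align_onsets(
    events: list[ExcursionEvent], session: SessionBundle, hist_bin_s: float = 0.1,
) -> dict:
    """Excursion onsets relative to feeder activation and to feeder-zone exit."""
    trials = {t.index: t for t in session.trials}
    exits = zone_exit_times(session)
    rel_act, rel_exit, excluded = [], [], 0
    for ev in events:
        tr = trials.get(ev.trial_index)
        if tr is None:
            excluded += 1
            continue
        rel_act.append(ev.onset - tr.t_target_feeder_on)
        if ev.trial_index in exits:
            rel_exit.append(ev.onset - exits[ev.trial_index])
    out = {"relative_to_activation": np.array(rel_act),
           "relative_to_zone_exit": np.array(rel_exit),
           "excluded": excluded}
    for key in ("relative_to_activation", "relative_to_zone_exit"):
        v = out[key]
        if v.size:
            lo = np.floor(v.min() / hist_bin_s) * hist_bin_s
            hi = np.ceil(v.max() / hist_bin_s) * hist_bin_s + hist_bin_s
            counts, edges = np.histogram(v, bins=np.arange(lo, hi + 1e-12, hist_bin_s))
            out[key + "_hist"] = (counts, edges)
    return out


# ---------------------------------------------------------------------------
# endpoint concentration

def endpoint_concentration_test(
    events: list[ExcursionEvent], geometry: TrackGeometry,
    n_segments: int | None = None,
) -> dict:
    """Pearson chi-square of endpoint positions against a uniform spread
    over equal-length track segments.

    The track skeleton is cut into ``k`` equal-length segments (by default,
    as many as there are 4 cm x 3 cm tiles touched by the skeleton); each
    endpoint is assigned to the segment of its nearest skeleton vertex.
    """
    if not events:
        raise ValueError("need at least one event")
    if n_segments is None:
        tiles = np.unique(
            np.floor(geometry.skeleton / np.array([4.0, 3.0])).astype(int), axis=0
        )
        n_segments = len(tiles)
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    n_vertices = len(geometry.skeleton)
    pts = np.array([ev.endpoint for ev in events])
    verts = geometry.nearest_vertex(pts)
    seg = np.minimum((verts * n_segments) // n_vertices, n_segments - 1)
    observed = np.bincount(seg, minlength=n_segments)
    res = stats.chisquare(observed)
    return {"chi2": float(res.statistic), "df": n_segments - 1,
            "p": float(res.pvalue), "k": n_segments, "n": len(events)}


# ---------------------------------------------------------------------------
# preference correlation

def events_from_injections(session: SessionBundle) -> list[ExcursionEvent]:
    """Ground-truth excursion events from the generator's injection log.

    Synthetic stand-ins for detected events, used in multi-session
    statistical studies where running the full detector per session is not
    needed; the detector's agreement with the injection log is established
    separately.
    """
    out = []
    for inj in session.ground_truth.injections:
        remote = session.geometry.feeders[inj.remote_feeder]
        out.append(ExcursionEvent(
            trial_index=inj.trial_index, occupied_feeder=inj.occupied_feeder,
            onset=inj.onset, offset=inj.onset + inj.duration_ms / 1000.0,
            duration_ms=inj.duration_ms, peak_error_cm=np.inf,
            peak_time=inj.onset + inj.duration_ms / 2000.0,
            endpoint=(float(remote[0]), float(remote[1])),
            endpoint_feeder=inj.remote_feeder,
        ))
    return out

def preference_record(
    session: SessionBundle, events: list[ExcursionEvent], session_id: str = "",
) -> PreferenceRecord:
    """Revealed preference (free trials) vs excursion frequency (forced trials).

    The excursion frequency at R is the fraction of forced-trial excursion
    events occurring at the right target feeder among forced-trial events at
    either target feeder.
    """
    free = [t for t in session.trials if t.mode == "free"]
    counts: dict[int, tuple[int, int]] = {}
    for t in free:
        l, r = counts.get(t.block_index, (0, 0))
        counts[t.block_index] = (l + (t.direction == "left"), r + (t.direction == "right"))
    n_right = sum(r for _, r in counts.values())
    pref = n_right / len(free) if free else 0.5

    forced = {t.index for t in session.trials if t.mode == "forced"}
    ev = [e for e in events if e.trial_index in forced and e.occupied_feeder in "LR"]
    at_right = sum(e.occupied_feeder == "R" for e in ev)
    freq = at_right / len(ev) if ev else 0.0
    return PreferenceRecord(
        session_id=session_id, free_counts=counts,
        preference_right=float(pref), excursion_freq_right=float(freq),
    )


def preference_correlation(records: list[PreferenceRecord]) -> dict:
    """OLS of excursion frequency at R on revealed preference for R."""
    if len(records) < 3:
        raise ValueError("need at least 3 sessions")
    x = np.array([r.preference_right for r in records])
    y = np.array([r.excursion_freq_right for r in records])
    if np.ptp(x) == 0:
        return {"slope": np.nan, "r2": np.nan, "F": np.nan, "p": np.nan,
                "defined": False}
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue ** 2
    f = (r2 / (1 - r2)) * (n - 2) if r2 < 1 else np.inf
    return {"slope": float(res.slope), "r2": float(r2), "F": float(f),
            "p": float(res.pvalue), "defined": True}
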