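"""Position decoding from the binned ensemble.

Two memoryless decoders over 2-D position:

* ``dann`` — the feedforward network (100/50/25 hidden units) applied to
  sqrt/z-transformed smoothed rates; its output is an unconstrained (x, y)
  in cm.
* ``bayes`` — Bayesian reconstruction over a 4 cm x 3 cm tile grid from raw
  spike counts with a Poisson likelihood and an occupancy prior; the
  prediction is the centre of the maximum-posterior tile.

Evaluation follows the session protocol: 10 trial sets balanced over left
and right choices, 75% of each set's trials for training and 25% for
testing, with the sqrt/z transform fitted on training bins only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rand import require_seed, rng_from, spawn_seeds
from .nets import MLP, TrainConfig, train_mlp
from .preprocessing import (
    BinnedEnsemble, apply_transform, build_ensemble, transform_rates,
)
from .session import SessionBundle, TrialRecord

__all__ = [
    "DecodedPath", "ErrorSummary", "BayesDecoder", "train_dann", "decode",
    "fit_bayesian", "decode_bayesian", "balanced_trial_sets", "crossvalidate",
    "stability_test", "stability_ttest", "downsampling_curve", "greedy_select",
    "error_map", "hidden_activations", "jitter_robustness",
]


class InsufficientDataError(ValueError):
    pass


@dataclass
class DecodedPath:
    t: np.ndarray          # bin centres (s)
    pred: np.ndarray       # n x 2 (cm)
    actual: np.ndarray     # n x 2 (cm)
    trial_index: np.ndarray | None = None

    @property
    def error(self) -> np.ndarray:
        return np.hypot(*(self.pred - self.actual).T)


@dataclass
class ErrorSummary:
    mse: float             # (1/2N) sum ||pred - target||^2
    rmse: float            # sqrt((1/N) sum ||pred - target||^2), cm
    median: float          # median per-bin Euclidean error, cm
    errors: np.ndarray     # per-bin error series, cm

    @classmethod
    def from_path(cls, path: DecodedPath) -> "ErrorSummary":
        sq = np.sum((path.pred - path.actual) ** 2, axis=1)
        return cls(
            mse=float(sq.sum() / (2 * len(sq))),
            rmse=float(np.sqrt(sq.mean())),
            median=float(np.median(np.sqrt(sq))),
            errors=np.sqrt(sq),
        )


# ---------------------------------------------------------------------------
# network decoder

def train_dann(
    ensemble: BinnedEnsemble, config: TrainConfig | None = None,
    seed=None, mask=None,
) -> MLP:
    """Train the network on (transformed) activity -> position pairs."""
    mask = np.ones(ensemble.n_bins, bool) if mask is None else mask
    X = ensemble.activity[:, mask].T
    y = ensemble.pos[mask]
    return train_mlp(X, y, task="regression", config=config, seed=seed)


def decode(model: MLP, ensemble: BinnedEnsemble, mask=None) -> DecodedPath:
    mask = np.ones(ensemble.n_bins, bool) if mask is None else mask
    pred = model.predict(ensemble.activity[:, mask].T)
    return DecodedPath(
        t=ensemble.bin_centers[mask], pred=pred, actual=ensemble.pos[mask],
        trial_index=ensemble.trial_index[mask],
    )


def hidden_activations(model: MLP, ensemble: BinnedEnsemble, mask=None) -> np.ndarray:
    """Last-hidden-layer (tanh) activation per bin; values in (-1, 1)."""
    mask = np.ones(ensemble.n_bins, bool) if mask is None else mask
    return model.hidden_activations(ensemble.activity[:, mask].T)


# ---------------------------------------------------------------------------
# Bayesian reconstruction

@dataclass
class BayesDecoder:
    tile_cm: tuple[float, float]
    origin: tuple[float, float]
    shape: tuple[int, int]          # (nx, ny)
    tiles: np.ndarray               # visited tile flat indices (row-major: iy * nx + ix)
    centers: np.ndarray             # tile centres, len(tiles) x 2
    rates: np.ndarray               # units x len(tiles), expected rate (Hz), floored
    prior: np.ndarray               # len(tiles), sums to 1
    dt: float                       # decoding bin width (s)
    unit_ids: list[str] = field(default_factory=list)


def _tile_of(pos: np.ndarray, origin, tile_cm, shape) -> np.ndarray:
    ix = np.clip(np.floor((pos[:, 0] - origin[0]) / tile_cm[0]).astype(int), 0, shape[0] - 1)
    iy = np.clip(np.floor((pos[:, 1] - origin[1]) / tile_cm[1]).astype(int), 0, shape[1] - 1)
    return iy * shape[0] + ix


def fit_bayesian(
    ensemble: BinnedEnsemble, mask=None, tile_cm: tuple[float, float] = (4.0, 3.0),
    bounds: tuple[float, float] | None = None, epsilon_hz: float = 1e-3,
    uniform_prior: bool = False,
) -> BayesDecoder:
    """Per-tile expected rates and occupancy prior from training bins."""
    mask = np.ones(ensemble.n_bins, bool) if mask is None else mask
    pos = ensemble.pos[mask]
    counts = ensemble.counts[:, mask]
    dt = ensemble.bin_width_ms / 1000.0
    if bounds is None:
        bounds = (float(pos[:, 0].max()) + 1e-9, float(pos[:, 1].max()) + 1e-9)
    origin = (0.0, 0.0)
    shape = (int(np.ceil(bounds[0] / tile_cm[0])), int(np.ceil(bounds[1] / tile_cm[1])))

    flat = _tile_of(pos, origin, tile_cm, shape)
    tiles = np.unique(flat)                       # visited tiles only
    occupancy = np.array([(flat == t).sum() for t in tiles], float)
    rates = np.empty((counts.shape[0], len(tiles)))
    for j, tl in enumerate(tiles):
        sel = flat == tl
        rates[:, j] = counts[:, sel].mean(axis=1) / dt
    rates = np.maximum(rates, epsilon_hz)
    prior = (np.ones(len(tiles)) if uniform_prior else occupancy)
    prior = prior / prior.sum()
    ix = tiles % shape[0]
    iy = tiles // shape[0]
    centers = np.column_stack([
        origin[0] + (ix + 0.5) * tile_cm[0], origin[1] + (iy + 0.5) * tile_cm[1],
    ])
    return BayesDecoder(
        tile_cm=tile_cm, origin=origin, shape=shape, tiles=tiles,
        centers=centers, rates=rates, prior=prior, dt=dt,
        unit_ids=list(ensemble.unit_ids),
    )


def bayes_log_posterior(model: BayesDecoder, counts: np.ndarray) -> np.ndarray:
    """Unnormalized log posterior, bins x tiles (Poisson likelihood)."""
    logr = np.log(model.rates)                    # units x tiles
    return (
        np.log(model.prior)[None, :]
        + counts.T @ logr
        - model.dt * model.rates.sum(axis=0)[None, :]
    )


def decode_bayesian(model: BayesDecoder, ensemble: BinnedEnsemble, mask=None) -> DecodedPath:
    """Maximum-posterior tile centre per bin; ties go to the lowest row-major tile."""
    mask = np.ones(ensemble.n_bins, bool) if mask is None else mask
    logp = bayes_log_posterior(model, ensemble.counts[:, mask])
    best = np.argmax(logp, axis=1)                # tiles sorted row-major: first max wins
    return DecodedPath(
        t=ensemble.bin_centers[mask], pred=model.centers[best],
        actual=ensemble.pos[mask], trial_index=ensemble.trial_index[mask],
    )


# ---------------------------------------------------------------------------
# balanced trial sets and cross-validation

def balanced_trial_sets(
    trials: list[TrialRecord], n_sets: int, seed, train_fraction: float = 0.75,
    n_per_side: int | None = None,
) -> list[dict]:
    """Random trial sets with equal left/right counts, split 75/25.

    Each set dict holds ``train`` and ``test`` trial-index lists plus the
    per-side composition for logging.
    """
    rng = rng_from(seed)
    left = [t.index for t in trials if t.direction == "left"]
    right = [t.index for t in trials if t.direction == "right"]
    n_side = min(len(left), len(right)) if n_per_side is None else n_per_side
    if n_side < 4:
        raise InsufficientDataError(
            f"need >= 4 trials per side, have {len(left)} left / {len(right)} right"
        )
    n_train = int(round(train_fraction * n_side))
    n_train = min(max(n_train, 1), n_side - 1)
    sets = []
    for _ in range(n_sets):
        tr, te = [], []
        for side in (left, right):
            pick = rng.permutation(side)[:n_side]
            tr += pick[:n_train].tolist()
            te += pick[n_train:].tolist()
        sets.append({
            "train": sorted(tr), "test": sorted(te),
            "n_per_side": n_side, "n_train_per_side": n_train,
        })
    return sets


def _fit_eval(
    ensemble: BinnedEnsemble, train_mask, test_mask, method: str, seed,
    train_config=None, tile_cm=(4.0, 3.0), bounds=None,
) -> DecodedPath:
    """Train on one bin mask and decode another, with leakage-free transforms."""
    if method == "dann":
        act, params = transform_rates(ensemble.activity, train_mask)
        kept_units = [u for u, k in zip(ensemble.unit_ids, params.kept) if k]
        train = _with_activity(ensemble, act, kept_units)
        model = train_dann(train, config=train_config, seed=seed, mask=train_mask)
        test_act = apply_transform(ensemble.activity, params)
        test = _with_activity(ensemble, test_act, kept_units)
        return decode(model, test, mask=test_mask)
    if method == "bayes":
        model = fit_bayesian(ensemble, mask=train_mask, tile_cm=tile_cm, bounds=bounds)
        return decode_bayesian(model, ensemble, mask=test_mask)
    raise ValueError(f"unknown method {method!r}")


def _with_activity(ens: BinnedEnsemble, activity, unit_ids) -> BinnedEnsemble:
    return BinnedEnsemble(
        unit_ids=list(unit_ids), bin_centers=ens.bin_centers,
        bin_width_ms=ens.bin_width_ms, kernel_std_ms=ens.kernel_std_ms,
        activity=activity, counts=ens.counts, pos=ens.pos,
        trial_index=ens.trial_index, zone=ens.zone,
    )


def _retained_trials(session: SessionBundle, ensemble: BinnedEnsemble) -> list[TrialRecord]:
    kept = set(np.unique(ensemble.trial_index[ensemble.trial_index >= 0]).tolist())
    return [t for t in session.trials if t.index in kept]


def crossvalidate(
    session: SessionBundle, method: str = "dann", n_sets: int = 10,
    train_fraction: float = 0.75, seed=None, profile: str = "coarse",
    ensemble: BinnedEnsemble | None = None, train_config: TrainConfig | None = None,
    tile_cm: tuple[float, float] = (4.0, 3.0), unit_ids: list[str] | None = None,
) -> dict:
    """Cross-validated decoding over balanced trial sets.

    Returns a dict with per-set ``summaries`` and ``paths``, the set
    composition, and the mean/SD of RMSE and median error over sets.
    """
    require_seed(seed)
    if ensemble is None:
        ensemble = build_ensemble(session, profile=profile)
    if unit_ids is not None:
        ensemble = _subset_units(ensemble, unit_ids)
    trials = _retained_trials(session, ensemble)
    set_seed, *fit_seeds = spawn_seeds(seed, n_sets + 1)
    sets = balanced_trial_sets(trials, n_sets, set_seed, train_fraction)
    bounds = session.geometry.bounds

    summaries, paths = [], []
    for s, fseed in zip(sets, fit_seeds):
        train_mask = ensemble.bins_in_trials(s["train"])
        test_mask = ensemble.bins_in_trials(s["test"])
        path = _fit_eval(ensemble, train_mask, test_mask, method, fseed,
                         train_config=train_config, tile_cm=tile_cm, bounds=bounds)
        summaries.append(ErrorSummary.from_path(path))
        paths.append(path)
    rmse = np.array([s.rmse for s in summaries])
    med = np.array([s.median for s in summaries])
    return {
        "method": method, "sets": sets, "summaries": summaries, "paths": paths,
        "rmse_mean": float(rmse.mean()), "rmse_sd": float(rmse.std()),
        "median_mean": float(med.mean()), "median_sd": float(med.std()),
    }


def _subset_units(ens: BinnedEnsemble, unit_ids) -> BinnedEnsemble:
    idx = [ens.unit_ids.index(u) for u in unit_ids]
    out = _with_activity(ens, ens.activity[idx], list(unit_ids))
    out.counts = ens.counts[idx]
    return out


# ---------------------------------------------------------------------------
# stability

def stability_test(
    session: SessionBundle, seed=None, profile: str = "coarse",
    method: str = "dann", train_config: TrainConfig | None = None,
) -> dict | None:
    """Alternating-trial vs first/second-half splits on the modal configuration.

    Restricts to the (reward, effort, direction) configuration with the most
    trials; if spatial encoding drifts within the session, the half split
    should decode worse than the alternating split.
    """
    require_seed(seed)
    ensemble = build_ensemble(session, profile=profile)
    trials = _retained_trials(session, ensemble)
    groups: dict[tuple, list[TrialRecord]] = {}
    for t in trials:
        groups.setdefault((t.reward_volume, t.barrier_level, t.direction), []).append(t)
    config, best = max(groups.items(), key=lambda kv: len(kv[1]))
    if len(best) < 4:
        warnings.warn("fewer than 4 trials in the modal configuration; skipping")
        return None
    best = sorted(best, key=lambda t: t.t_start)
    idx = [t.index for t in best]
    half = len(idx) // 2
    splits = {
        "alternating": (idx[0::2], idx[1::2]),
        "half": (idx[:half], idx[half:]),
    }
    s_alt, s_half = spawn_seeds(seed, 2)
    out = {"configuration": config, "n_trials": len(idx)}
    for (name, (tr, te)), s in zip(splits.items(), (s_alt, s_half)):
        path = _fit_eval(
            ensemble, ensemble.bins_in_trials(tr), ensemble.bins_in_trials(te),
            method, s, train_config=train_config, bounds=session.geometry.bounds,
        )
        out[name] = ErrorSummary.from_path(path)
    out["delta_rmse"] = out["half"].rmse - out["alternating"].rmse
    return out


def stability_ttest(deltas) -> tuple[float, float]:
    """Paired t test across sessions on (half - alternating) error differences."""
    res = stats.ttest_1samp(np.asarray(deltas, float), 0.0)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# downsampling and greedy selection

def downsampling_curve(
    session: SessionBundle, sizes=tuple(range(4, 41, 4)), reps: int = 5,
    seed=None, method: str = "dann", n_sets: int = 10,
    profile: str = "coarse", train_config: TrainConfig | None = None,
) -> list[dict]:
    """Decoding error vs ensemble size with random unit subsets."""
    require_seed(seed)
    ensemble = build_ensemble(session, profile=profile)
    rng = rng_from(seed)
    cv_seeds = iter(spawn_seeds(seed, len(sizes) * reps))
    rows = []
    for size in sizes:
        if size > len(ensemble.unit_ids):
            warnings.warn(f"size {size} exceeds unit count; skipped")
            continue
        for rep in range(reps):
            units = [ensemble.unit_ids[i] for i in
                     rng.choice(len(ensemble.unit_ids), size=size, replace=False)]
            cv = crossvalidate(
                session, method=method, n_sets=n_sets, seed=next(cv_seeds),
                ensemble=ensemble, unit_ids=units, train_config=train_config,
            )
            rows.append({"size": size, "rep": rep, "units": units,
                         "rmse_mean": cv["rmse_mean"],
                         "median_mean": cv["median_mean"]})
    return rows


def greedy_select(
    session: SessionBundle, k: int = 20, seed=None, method: str = "bayes",
    n_sets: int = 10, profile: str = "coarse",
    train_config: TrainConfig | None = None,
    ensemble: BinnedEnsemble | None = None,
) -> dict:
    """Forward selection of the best decoding unit set.

    Starting from the empty set, each step adds the unit whose inclusion
    minimizes the cross-validated error of the augmented set; every candidate
    evaluation uses the same balanced trial sets and fit seeds so that
    choices are comparable and deterministic.
    """
    require_seed(seed)
    if ensemble is None:
        ensemble = build_ensemble(session, profile=profile)
    if k > len(ensemble.unit_ids):
        raise ValueError("k exceeds unit count")
    eval_seed = spawn_seeds(seed, 1)[0]

    def score(units) -> float:
        cv = crossvalidate(
            session, method=method, n_sets=n_sets, seed=eval_seed,
            ensemble=ensemble, unit_ids=list(units), train_config=train_config,
        )
        return cv["rmse_mean"]

    selected: list[str] = []
    per_step = []
    remaining = list(ensemble.unit_ids)
    for _ in range(k):
        scores = [(score(selected + [u]), u) for u in remaining]
        best_err, best_unit = min(scores, key=lambda p: (p[0], p[1]))
        selected.append(best_unit)
        remaining.remove(best_unit)
        per_step.append(best_err)
    return {"units": selected, "error_per_step": per_step}


# ---------------------------------------------------------------------------
# error maps

def error_map(
    session: SessionBundle | None = None, tile_cm: tuple[float, float] = (4.0, 3.0),
    n_sets: int = 10, seed=None, method: str = "dann",
    results: list[dict] | None = None, bounds=None,
    train_config: TrainConfig | None = None,
) -> dict:
    """Spatial maps of decoding error on a tile grid.

    For each test trial and tile, the error while the rat occupied the tile
    is reduced (max for the "max" map, mean for the "mean" map); tiles are
    then averaged over trials within a session and over sessions.  Pass
    ``results`` (a list of ``crossvalidate`` outputs, one per session) to
    reuse precomputed decoded paths.
    """
    if results is None:
        require_seed(seed)
        results = [crossvalidate(session, method=method, n_sets=n_sets,
                                 seed=seed, train_config=train_config)]
        bounds = session.geometry.bounds
    if bounds is None:
        raise ValueError("bounds required when passing precomputed results")
    shape = (int(np.ceil(bounds[0] / tile_cm[0])), int(np.ceil(bounds[1] / tile_cm[1])))
    n_tiles = shape[0] * shape[1]

    session_maps = {"mean": [], "max": []}
    for cv in results:
        acc = {}
        for path in cv["paths"]:
            tiles = _tile_of(path.actual, (0.0, 0.0), tile_cm, shape)
            err = path.error
            for trial in np.unique(path.trial_index):
                sel = path.trial_index == trial
                for tl in np.unique(tiles[sel]):
                    e = err[sel & (tiles == tl)]
                    acc.setdefault(tl, {"mean": [], "max": []})
                    acc[tl]["mean"].append(e.mean())
                    acc[tl]["max"].append(e.max())
        for kind in ("mean", "max"):
            m = np.full(n_tiles, np.nan)
            for tl, v in acc.items():
                m[tl] = np.mean(v[kind])
            session_maps[kind].append(m)
    out = {}
    for kind in ("mean", "max"):
        stackd = np.stack(session_maps[kind])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[kind] = np.nanmean(stackd, axis=0).reshape(shape[1], shape[0])
    out["shape"] = shape
    out["tile_cm"] = tile_cm
    return out


# ---------------------------------------------------------------------------
# jitter robustness

def jitter_robustness(
    session: SessionBundle, seed=None, profile: str = "coarse",
    jitter_fraction: float = 0.25, train_config: TrainConfig | None = None,
    n_sets: int = 1,
) -> dict:
    """Train on clean trials, test on spike-jittered versions of held-out trials.

    Jitter shifts every spike by a zero-mean Gaussian whose variance is
    ``jitter_fraction`` of the unit's inter-spike-interval variance.  Reports
    the RMSE change and the distribution of per-bin distances between the
    clean-decoded and jitter-decoded positions.
    """
    from .encoding import jitter_spikes

    require_seed(seed)
    s_jit, s_cv = spawn_seeds(seed, 2)
    ensemble = build_ensemble(session, profile=profile)
    jittered = jitter_spikes(session.spikes, seed=s_jit, fraction=jitter_fraction)
    noisy_session = SessionBundle(
        geometry=session.geometry, spikes=jittered, trajectory=session.trajectory,
        trials=session.trials, ground_truth=session.ground_truth,
    )
    noisy_ens = build_ensemble(noisy_session, profile=profile)

    trials = _retained_trials(session, ensemble)
    set_seed, *fit_seeds = spawn_seeds(s_cv, n_sets + 1)
    sets = balanced_trial_sets(trials, n_sets, set_seed)
    deltas, deviations = [], []
    for s, fseed in zip(sets, fit_seeds):
        train_mask = ensemble.bins_in_trials(s["train"])
        test_mask = ensemble.bins_in_trials(s["test"])
        act, params = transform_rates(ensemble.activity, train_mask)
        kept = [u for u, k in zip(ensemble.unit_ids, params.kept) if k]
        model = train_dann(_with_activity(ensemble, act, kept),
                           config=train_config, seed=fseed, mask=train_mask)
        clean = decode(model, _with_activity(
            ensemble, apply_transform(ensemble.activity, params), kept), mask=test_mask)
        noisy = decode(model, _with_activity(
            noisy_ens, apply_transform(noisy_ens.activity, params), kept), mask=test_mask)
        deltas.append(ErrorSummary.from_path(noisy).rmse
                      - ErrorSummary.from_path(clean).rmse)
        deviations.append(np.hypot(*(noisy.pred - clean.pred).T))
    return {
        "rmse_delta_mean": float(np.mean(deltas)),
        "deviation": np.concatenate(deviations),
    }
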