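"""Per-cell information measures and population-pattern analyses.

Covers: L1-logistic-regression selection of reward/choice-encoding cells
(selection frequency over 50 balanced trial sets, categorized at the 30% /
70% thresholds), t-test identification of excursion-active cells, spike
jitter and inter-spike-interval shuffle null models, the three-feeder
pattern classifier with its confusion matrices, ROC-AUC discrimination of
excursion vs non-excursion patterns, and the LDA feeder projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, silhouette_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._rand import require_seed, rng_from, spawn_seeds
from .nets import TrainConfig, train_mlp
from .preprocessing import apply_transform, build_ensemble, transform_rates
from .session import SessionBundle, SpikeTrainSet

__all__ = [
    "CellInfoProfile", "ConfusionMatrix", "DiscriminationResult", "categorize",
    "informative_cells", "excursion_related_cells", "jitter_spikes",
    "shuffle_isis", "feeder_classifier", "feeder_classifier_all",
    "discriminate_excursion_patterns", "lda_feeder_projection",
]

NOT_INFORMATIVE = "not informative"
RELATIVELY_INFORMATIVE = "relatively informative"
VERY_INFORMATIVE = "very informative"


def categorize(frequency: float) -> str:
    """Category from selection frequency: <=30% not, 30-70% relatively, >70% very."""
    if frequency <= 0.30:
        return NOT_INFORMATIVE
    if frequency <= 0.70:
        return RELATIVELY_INFORMATIVE
    return VERY_INFORMATIVE


@dataclass
class CellInfoProfile:
    unit_ids: list[str]
    frequency: dict[str, np.ndarray]        # attribute -> per-unit frequency in [0,1]
    category: dict[str, list[str]] = field(default_factory=dict)
    test_accuracy: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for attr, f in self.frequency.items():
            self.category[attr] = [categorize(x) for x in f]


@dataclass
class ConfusionMatrix:
    matrix: np.ndarray          # 3 x 3 row-normalized, rows = true feeder L/R/C
    accuracy: float             # overall fraction of correctly classified samples
    variant: str                # "original" | "noisy" | "shuffled"
    labels: tuple[str, ...] = ("L", "R", "C")


@dataclass
class DiscriminationResult:
    auc: dict[str, float]       # "A_vs_Ap", "B_vs_Bp", "Ap_vs_Bp"
    counts: dict[str, int]


# ---------------------------------------------------------------------------
# reward / choice encoding cells (Lasso selection frequency)

def _trial_window_rates(session: SessionBundle, window_s: float = 1.5) -> tuple[np.ndarray, list]:
    """Per-trial mean firing rate (Hz) in the post-reward window at the
    target feeder: trials x units."""
    trials = session.trials
    units = session.spikes.unit_ids
    X = np.zeros((len(trials), len(units)))
    for j, u in enumerate(units):
        s = session.spikes.spikes[u]
        for i, tr in enumerate(trials):
            t0 = tr.t_target_feeder_on
            t1 = min(t0 + window_s, tr.t_end)
            X[i, j] = np.searchsorted(s, t1) - np.searchsorted(s, t0)
            X[i, j] /= (t1 - t0)
    return X, trials


def informative_cells(
    session: SessionBundle, target: str = "reward", seed=None,
    n_sets: int = 50, max_df: int = 20, window_s: float = 1.5,
    Cs: np.ndarray | None = None, n_folds: int = 5,
    labels: np.ndarray | None = None, selection_rule: str = "one_se",
) -> CellInfoProfile:
    """Which cells carry reward or choice information at the target feeders.

    Per-trial mean rates in the 1.5 s post-reward window are the features;
    the label is the reward level (30 vs 120 uL) or the chosen side.  For
    each of ``n_sets`` random class-balanced trial sets (75/25 split), an
    L1-regularized logistic regression is selected over a penalty path by
    5-fold cross-validation, keeping only path points with at most
    ``max_df`` nonzero weights; the nonzero-weight cells of the winning
    model are logged.  A cell's frequency is the fraction of sets selecting
    it; categories use the 30% / 70% thresholds.

    ``selection_rule`` picks the path point: ``"one_se"`` (default) takes
    the sparsest model within one standard error of the best
    cross-validated accuracy — the conventional Lasso-path choice, which
    keeps selection sparse when the labels carry no signal — while
    ``"best"`` takes the accuracy argmax.
    """
    require_seed(seed)
    rng = rng_from(seed)
    Cs = np.logspace(-2.5, 1.0, 14) if Cs is None else Cs
    X, trials = _trial_window_rates(session, window_s)
    if labels is not None:
        y = np.asarray(labels, int)   # caller-supplied labels (permutation controls)
    elif target == "reward":
        y = np.array([t.reward_volume >= 120 for t in trials], int)
    elif target == "choice":
        y = np.array([t.direction == "right" for t in trials], int)
    else:
        raise ValueError(f"unknown target {target!r}")

    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n_side = min(len(pos), len(neg))
    n_train = int(round(0.75 * n_side))
    units = session.spikes.unit_ids
    selected = np.zeros(len(units))
    used_sets = 0
    accs = []
    for _ in range(n_sets):
        tr_idx, te_idx = [], []
        for side in (pos, neg):
            pick = rng.permutation(side)[:n_side]
            tr_idx += pick[:n_train].tolist()
            te_idx += pick[n_train:].tolist()
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xte, yte = X[te_idx], y[te_idx]
        # standardize per set (training statistics) so the L1 penalty treats
        # cells with different rate scales evenly
        mu = Xtr.mean(axis=0)
        sd = np.where(Xtr.std(axis=0) > 1e-12, Xtr.std(axis=0), 1.0)
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
        candidates = []
        for C in Cs:
            clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=C,
                                     max_iter=500)
            clf.fit(Xtr, ytr)
            df = int(np.count_nonzero(clf.coef_))
            if df == 0 or df > max_df:
                continue
            cv = StratifiedKFold(n_folds, shuffle=True,
                                 random_state=int(rng.integers(2**31)))
            acc = []
            for a, b in cv.split(Xtr, ytr):
                f = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=C,
                                       max_iter=500).fit(Xtr[a], ytr[a])
                acc.append(f.score(Xtr[b], ytr[b]))
            candidates.append(
                (float(np.mean(acc)), float(np.std(acc) / np.sqrt(len(acc))), df, clf)
            )
        if not candidates:
            continue
        best_mean, best_se, _, best_clf = max(candidates, key=lambda c: c[0])
        if selection_rule == "one_se":
            ok = [c for c in candidates if c[0] >= best_mean - best_se]
            _, _, _, clf = min(ok, key=lambda c: c[2])
        else:
            clf = best_clf
        test_acc = clf.score(Xte, yte)
        if test_acc < 0.5:
            warnings.warn("degenerate fit (test accuracy < 0.5); set discarded")
            continue
        selected += (np.abs(clf.coef_[0]) > 0)
        used_sets += 1
        accs.append(test_acc)
    freq = selected / max(used_sets, 1)
    return CellInfoProfile(
        unit_ids=list(units), frequency={target: freq},
        test_accuracy={target: float(np.mean(accs)) if accs else np.nan},
    )


# ---------------------------------------------------------------------------
# excursion-related cells

def excursion_related_cells(
    session: SessionBundle, detection: dict, ensemble, alpha: float = 0.01,
    peak_window_ms: float = 80.0,
) -> CellInfoProfile:
    """Cells whose firing differs inside the 80 ms excursion-peak windows.

    Per detection set, excursion samples are the bins within the
    peak-centred window of each event; non-excursion samples are all other
    bins of that set's post-reward test windows.  Rates are square-root
    transformed and compared by a two-sided Welch t test at alpha = 0.01
    (strict inequality).  Frequencies are split by the occupied feeder.
    """
    events = detection["events"]
    n_sets = detection["n_sets"]
    window_masks = detection.get("window_masks")
    if window_masks is None:
        raise ValueError("detection result lacks window masks")
    units = ensemble.unit_ids
    half = peak_window_ms / 2000.0
    counts = {"excursion-L": np.zeros(len(units)),
              "excursion-R": np.zeros(len(units))}
    n_eval = {"excursion-L": 0, "excursion-R": 0}
    for si in range(n_sets):
        in_window = window_masks[si]
        for feeder in ("L", "R"):
            evs = [e for e in events if e.set_index == si and e.occupied_feeder == feeder]
            if not evs:
                continue
            exc_mask = np.zeros(ensemble.n_bins, bool)
            for e in evs:
                exc_mask |= np.abs(ensemble.bin_centers - e.peak_time) <= half
            exc_mask &= in_window
            non_mask = in_window & ~exc_mask
            if exc_mask.sum() < 2 or non_mask.sum() < 2:
                continue
            n_eval[f"excursion-{feeder}"] += 1
            a = np.sqrt(ensemble.activity[:, exc_mask])
            b = np.sqrt(ensemble.activity[:, non_mask])
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
            counts[f"excursion-{feeder}"] += (p < alpha)
    freq = {k: counts[k] / max(n_eval[k], 1) for k in counts}
    return CellInfoProfile(unit_ids=list(units), frequency=freq)


# ---------------------------------------------------------------------------
# null models on the spike trains

def _merge_windows(windows) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for a, b in sorted(windows):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


class _WindowMap:
    """Bijection between real time inside a set of disjoint windows and the
    concatenated-window coordinate (gaps between windows excised)."""

    def __init__(self, windows):
        windows = _merge_windows(windows)
        self.starts = np.array([a for a, _ in windows])
        self.ends = np.array([b for _, b in windows])
        lengths = self.ends - self.starts
        self.offsets = np.concatenate([[0.0], np.cumsum(lengths)[:-1]])
        self.span = float(lengths.sum())

    def select(self, t: np.ndarray) -> np.ndarray:
        i = np.searchsorted(self.starts, t, side="right") - 1
        return (i >= 0) & (t < self.ends[np.clip(i, 0, None)])

    def to_concat(self, t: np.ndarray) -> np.ndarray:
        i = np.searchsorted(self.starts, t, side="right") - 1
        return self.offsets[i] + (t - self.starts[i])

    def from_concat(self, c: np.ndarray) -> np.ndarray:
        ends = self.offsets + (self.ends - self.starts)
        i = np.clip(np.searchsorted(ends, c, side="right"), 0, len(self.starts) - 1)
        return self.starts[i] + (c - self.offsets[i])


def jitter_spikes(
    spikes: SpikeTrainSet, seed=None, fraction: float = 0.25,
    windows: dict[str, list[tuple[float, float]]] | None = None,
) -> SpikeTrainSet:
    """Shift each spike by a Gaussian with variance = ``fraction`` of the
    unit's inter-spike-interval variance.

    ``windows`` maps a set label to time windows; the ISI variance is
    computed on the concatenated-window coordinate of each set (gaps
    between windows excised, so that inter-trial gaps do not inflate it)
    and the shifts are applied in that coordinate, keeping every spike
    inside its set.  Without windows the whole session is one set.  Units
    with fewer than 2 spikes in a set are left unjittered; spike counts
    are always preserved.
    """
    rng = rng_from(seed)
    if windows is None:
        windows = {"all": [(0.0, spikes.duration)]}
    maps = {k: _WindowMap(v) for k, v in windows.items()}
    out = {}
    for u in spikes.unit_ids:
        s = spikes.spikes[u].copy()
        for wm in maps.values():
            sel = wm.select(s)
            if sel.sum() < 2:
                continue
            c = wm.to_concat(s[sel])
            var = float(np.var(np.diff(np.sort(c))))
            if var == 0 or fraction == 0:
                continue
            c = c + rng.normal(0.0, np.sqrt(fraction * var), size=sel.sum())
            s[sel] = wm.from_concat(np.clip(c, 0.0, wm.span - 1e-12))
        out[u] = np.sort(np.clip(s, 0.0, spikes.duration))
    return SpikeTrainSet(unit_ids=list(spikes.unit_ids), spikes=out,
                         duration=spikes.duration)


def shuffle_isis(
    spikes: SpikeTrainSet, seed=None,
    windows: list[tuple[float, float]] | None = None,
) -> SpikeTrainSet:
    """Randomly permute each unit's inter-spike intervals.

    Spikes are mapped onto the concatenated window coordinate, the first
    spike time is kept, the intervals are permuted, and times are mapped
    back; the ISI multiset and the total span are preserved exactly.  Units
    with fewer than 3 spikes in the windows are returned unchanged.
    """
    rng = rng_from(seed)
    if windows is None:
        windows = [(0.0, spikes.duration)]
    wm = _WindowMap(windows)
    out = {}
    for u in spikes.unit_ids:
        s = spikes.spikes[u]
        sel = wm.select(s)
        inside = s[sel]
        if len(inside) < 3:
            out[u] = s.copy()
            continue
        c = wm.to_concat(inside)
        isi = np.diff(c)
        new_c = c[0] + np.concatenate([[0.0], np.cumsum(rng.permutation(isi))])
        new_inside = wm.from_concat(new_c)
        out[u] = np.sort(np.concatenate([s[~sel], new_inside]))
    return SpikeTrainSet(unit_ids=list(spikes.unit_ids), spikes=out,
                         duration=spikes.duration)


# ---------------------------------------------------------------------------
# feeder classifier

def _feeder_windows(session: SessionBundle, center_s: float = 0.75,
                    target_s: float = 1.5) -> list[tuple[float, float, str, int]]:
    """Sample windows: 750 ms after centre-feeder off-set (label C) and
    1500 ms after target-feeder off-set (label L/R), per trial."""
    wins = []
    for tr in session.trials:
        wins.append((tr.t_center_feeder_off,
                     min(tr.t_center_feeder_off + center_s, tr.t_end), "C", tr.index))
        wins.append((tr.t_target_feeder_off,
                     min(tr.t_target_feeder_off + target_s, tr.t_end),
                     tr.target_feeder, tr.index))
    return wins


def _variant_spikes(session: SessionBundle, variant: str, seed) -> SpikeTrainSet:
    wins = _feeder_windows(session)
    if variant == "original":
        return session.spikes
    if variant == "noisy":
        by_feeder: dict[str, list] = {}
        for a, b, lab, _ in wins:
            by_feeder.setdefault(lab, []).append((a, b))
        return jitter_spikes(session.spikes, seed=seed, fraction=0.25,
                             windows=by_feeder)
    if variant == "shuffled":
        # extend each window by the smoothing-kernel support so that
        # unshuffled spikes cannot bleed label information into the edge
        # bins of the sample windows through the Gaussian kernel
        halo = 5 * 0.120
        return shuffle_isis(
            session.spikes, seed=seed,
            windows=[(max(a - halo, 0.0), min(b + halo, session.spikes.duration))
                     for a, b, _, _ in wins],
        )
    raise ValueError(f"unknown variant {variant!r}")


def feeder_classifier_all(
    session: SessionBundle, seed=None, n_reps: int = 10,
    variants: tuple[str, ...] = ("original", "noisy", "shuffled"),
    train_config: TrainConfig | None = None, profile: str = "fine",
) -> dict[str, ConfusionMatrix]:
    """Three-feeder pattern classification on original, jittered and
    ISI-shuffled data.

    The classifier shares the position decoder's trunk with a 3-way softmax
    output.  It is always trained on original data from a class-balanced
    trial subset; each variant is tested on the held-out trials of the
    matching corrupted dataset.  Training is shared across variants within a
    repetition.
    """
    require_seed(seed)
    s_var, s_reps = spawn_seeds(seed, 2)
    wins = _feeder_windows(session)
    label_code = {"L": 0, "R": 1, "C": 2}

    ensembles = {}
    for v in variants:
        sp = _variant_spikes(session, v, s_var)
        ensembles[v] = build_ensemble(
            SessionBundle(geometry=session.geometry, spikes=sp,
                          trajectory=session.trajectory, trials=session.trials,
                          ground_truth=session.ground_truth),
            profile=profile,
        )
    ens0 = ensembles["original" if "original" in variants else variants[0]]
    centers = ens0.bin_centers
    sample_mask = np.zeros(ens0.n_bins, bool)
    sample_label = np.full(ens0.n_bins, -1, int)
    sample_trial = np.full(ens0.n_bins, -1, int)
    for a, b, lab, tr in wins:
        m = (centers >= a) & (centers < b)
        sample_mask |= m
        sample_label[m] = label_code[lab]
        sample_trial[m] = tr

    trials = session.trials
    rng = rng_from(s_reps)
    fit_seeds = spawn_seeds(s_reps, n_reps)
    conf = {v: [] for v in variants}
    acc = {v: [] for v in variants}
    left = [t.index for t in trials if t.direction == "left"]
    right = [t.index for t in trials if t.direction == "right"]
    n_side = min(len(left), len(right))
    n_train = max(1, int(round(0.75 * n_side)))
    for rep in range(n_reps):
        tr_trials = (rng.permutation(left)[:n_train].tolist()
                     + rng.permutation(right)[:n_train].tolist())
        train_mask = sample_mask & np.isin(sample_trial, tr_trials)
        test_mask = sample_mask & ~np.isin(sample_trial, tr_trials)
        ytr = sample_label[train_mask]
        if len(np.unique(ytr)) < 3:
            warnings.warn("a feeder class is absent from the training subset; "
                          "repetition skipped")
            continue
        act, params = transform_rates(ens0.activity, train_mask)
        model = train_mlp(act[:, train_mask].T, ytr, task="classification",
                          config=train_config, seed=fit_seeds[rep])
        for v in variants:
            Xte = apply_transform(ensembles[v].activity, params)[:, test_mask].T
            pred = np.argmax(model.predict(Xte), axis=1)
            yte = sample_label[test_mask]
            m = np.zeros((3, 3))
            for i in range(3):
                sel = yte == i
                if sel.any():
                    m[i] = np.bincount(pred[sel], minlength=3) / sel.sum()
            conf[v].append(m)
            acc[v].append(float((pred == yte).mean()))
    return {
        v: ConfusionMatrix(matrix=np.mean(conf[v], axis=0),
                           accuracy=float(np.mean(acc[v])), variant=v)
        for v in variants if conf[v]
    }


def feeder_classifier(session: SessionBundle, variant: str = "original",
                      seed=None, **kw) -> ConfusionMatrix:
    return feeder_classifier_all(session, seed=seed, variants=(variant,), **kw)[variant]


# ---------------------------------------------------------------------------
# excursion pattern discrimination

def discriminate_excursion_patterns(
    session: SessionBundle, detection: dict, ensemble, seed=None,
    peak_window_ms: float = 100.0, window_s: float = 1.5, max_splits: int = 10,
    n_folds: int = 5,
) -> DiscriminationResult:
    """ROC-AUC separability of excursion and non-excursion feeder patterns.

    Classes: A / B are per-trial mean-rate vectors at the left / right
    feeder in the 1.5 s after feeder close on non-excursion trials; A' / B'
    are mean rates in the 100 ms window around the excursion peak.  A vs A'
    and B vs B' use a depth-limited decision tree (at most ``max_splits``
    splits); A' vs B' uses a maximum-margin linear classifier.  Class
    imbalance is left intact; AUC is the metric.
    """
    require_seed(seed)
    flags = detection["flags"]
    events = detection["events"]
    best_event: dict[int, object] = {}
    for e in events:
        if e.trial_index not in best_event or e.peak_error_cm > best_event[e.trial_index].peak_error_cm:
            best_event[e.trial_index] = e
    centers = ensemble.bin_centers
    half = peak_window_ms / 2000.0

    X, y = [], []
    for tr in session.trials:
        if tr.index not in flags:
            continue
        feeder = tr.target_feeder
        if flags[tr.index] and tr.index in best_event:
            e = best_event[tr.index]
            m = np.abs(centers - e.peak_time) <= half
            label = "Ap" if feeder == "L" else "Bp"
        else:
            t0 = tr.t_target_feeder_off
            m = (centers >= t0) & (centers < min(t0 + window_s, tr.t_end))
            label = "A" if feeder == "L" else "B"
        if not m.any():
            continue
        X.append(ensemble.activity[:, m].mean(axis=1))
        y.append(label)
    X = np.array(X)
    y = np.array(y)
    counts = {lab: int((y == lab).sum()) for lab in ("A", "Ap", "B", "Bp")}

    def auc(lab0, lab1, clf) -> float:
        sel = np.isin(y, [lab0, lab1])
        if counts[lab0] < 3 or counts[lab1] < 3:
            return float("nan")
        yy = (y[sel] == lab1).astype(int)
        k = min(n_folds, min(counts[lab0], counts[lab1]))
        cv = StratifiedKFold(k, shuffle=True, random_state=require_seed(seed) % (2**31))
        method = "predict_proba" if hasattr(clf, "predict_proba") else "decision_function"
        scores = cross_val_predict(clf, X[sel], yy, cv=cv, method=method)
        if scores.ndim == 2:
            scores = scores[:, 1]
        return float(roc_auc_score(yy, scores))

    rs = require_seed(seed) % (2**31)
    tree = DecisionTreeClassifier(max_leaf_nodes=max_splits + 1, random_state=rs)
    svm = SVC(kernel="linear")
    return DiscriminationResult(
        auc={
            "A_vs_Ap": auc("A", "Ap", tree),
            "B_vs_Bp": auc("B", "Bp", tree),
            "Ap_vs_Bp": auc("Ap", "Bp", svm),
        },
        counts=counts,
    )


# ---------------------------------------------------------------------------
# LDA feeder projection

def lda_feeder_projection(X: np.ndarray, y: np.ndarray) -> dict:
    """Two-component linear discriminant projection of feeder-window patterns.

    Returns the projected samples and a silhouette cluster-separation
    score.  A singular within-class scatter is handled by refitting with a
    small ridge (logged via a warning).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate input: all samples identical")
    try:
        lda = LinearDiscriminantAnalysis(n_components=2)
        Z = lda.fit_transform(X, y)
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class scatter; refitting with ridge")
        lda = LinearDiscriminantAnalysis(n_components=2, solver="eigen",
                                         shrinkage=1e-3)
        Z = lda.fit_transform(X, y)
    return {"projection": Z, "silhouette": float(silhouette_score(Z, y)),
            "model": lda}
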