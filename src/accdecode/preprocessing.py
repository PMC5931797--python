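"""From raw session to the binned ensemble representation.

Pipeline: drop outlier-duration trials, drop units firing below 0.5 Hz,
smooth each spike train with a Gaussian kernel, bin the smoothed signal,
assign each bin the mean tracker position of its window, and label bins by
feeder zone.  A square-root plus z transform of the binned rates is applied
separately, with its statistics fitted on the training bins only so that
held-out bins see frozen parameters.

Two named profiles are exposed: ``coarse`` (150 ms kernel, 50 ms bins) for
position decoding, and ``fine`` (120 ms kernel, 20 ms bins) for excursion
detection and feeder-pattern analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from .geometry import TrackGeometry
from .session import SessionBundle, SpikeTrainSet, TrajectorySeries, TrialRecord

__all__ = [
    "PROFILES", "BinnedEnsemble", "filter_trials", "filter_cells",
    "smooth_and_bin", "transform_rates", "assign_positions", "label_zones",
    "build_ensemble",
]

PROFILES = {
    "coarse": {"kernel_std_ms": 150.0, "bin_ms": 50.0},
    "fine": {"kernel_std_ms": 120.0, "bin_ms": 20.0},
}


class InvalidConfigError(ValueError):
    pass


@dataclass
class TransformParams:
    mean: np.ndarray   # per-unit mean of sqrt-rate on the fit segment
    std: np.ndarray    # per-unit SD on the fit segment
    kept: np.ndarray   # boolean mask of units retained (nonzero variance)


@dataclass
class BinnedEnsemble:
    """Per-unit activity on a regular time grid with positions and labels."""
    unit_ids: list[str]
    bin_centers: np.ndarray        # s
    bin_width_ms: float
    kernel_std_ms: float
    activity: np.ndarray           # units x bins; smoothed rate (Hz) or transformed
    counts: np.ndarray             # units x bins; raw integer spike counts
    pos: np.ndarray                # bins x 2 (cm)
    trial_index: np.ndarray        # bins; -1 outside retained trials
    zone: np.ndarray               # bins; "L" | "R" | "C" | "track"
    transform: TransformParams | None = None
    interpolated: np.ndarray | None = None   # bins flagged by position interpolation

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    def bins_in_trials(self, trial_indices) -> np.ndarray:
        return np.isin(self.trial_index, np.asarray(list(trial_indices)))


# ---------------------------------------------------------------------------
# filters

def filter_trials(trials: list[TrialRecord], factor: float = 1.5) -> list[TrialRecord]:
    """Drop trials longer than ``factor`` times the median trial duration."""
    if not trials:
        warnings.warn("filter_trials called with no trials")
        return []
    durations = np.array([t.duration for t in trials])
    cutoff = factor * np.median(durations)
    return [t for t, d in zip(trials, durations) if d <= cutoff]


def filter_cells(spikes: SpikeTrainSet, min_rate_hz: float = 0.5) -> SpikeTrainSet:
    """Drop units whose session-average firing rate is below threshold."""
    rates = spikes.rates()
    keep = [u for u in spikes.unit_ids if rates[u] >= min_rate_hz]
    return spikes.subset(keep)


# ---------------------------------------------------------------------------
# smoothing

def smooth_and_bin(
    spikes: SpikeTrainSet, kernel_std_ms: float, bin_ms: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-smoothed firing rate per unit per bin.

    Each spike contributes a unit-mass Gaussian density; a bin's entry is the
    integral of the summed density over the bin window divided by the bin
    width (a rate in Hz).  Bins are half-open ``[t, t + width)`` from time 0.

    Returns ``(rates, counts, bin_centers)`` where ``counts`` holds the raw
    spike counts on the same grid.
    """
    if kernel_std_ms <= 0 or bin_ms <= 0:
        raise InvalidConfigError("kernel std and bin width must be positive")
    if bin_ms / 1000.0 > spikes.duration:
        raise InvalidConfigError("bin width exceeds session duration")
    sigma = kernel_std_ms / 1000.0
    width = bin_ms / 1000.0
    n_bins = int(np.ceil(spikes.duration / width))
    edges = np.arange(n_bins + 1) * width
    centers = edges[:-1] + width / 2.0

    halfspan = 6.0 * sigma
    k = int(np.ceil(2 * halfspan / width)) + 2   # local window of affected bins

    rates = np.zeros((spikes.n_units, n_bins))
    counts = np.zeros((spikes.n_units, n_bins), dtype=np.int64)
    offsets = np.arange(k + 1)
    for i, u in enumerate(spikes.unit_ids):
        s = spikes.spikes[u]
        if s.size == 0:
            continue
        counts[i] = np.histogram(s, bins=edges)[0]
        first = np.searchsorted(edges, s - halfspan) - 1
        first = np.clip(first, 0, n_bins)
        idx = first[:, None] + offsets[None, :]          # edge indices per spike
        idx = np.clip(idx, 0, n_bins)
        cdf = ndtr((edges[idx] - s[:, None]) / sigma)    # mass left of each edge
        mass = np.diff(cdf, axis=1)                      # mass per bin
        bin_idx = np.clip(idx[:, :-1], 0, n_bins - 1)
        np.add.at(rates[i], bin_idx.ravel(), mass.ravel())
    rates /= width
    return rates, counts, centers


def transform_rates(
    rates: np.ndarray, fit_mask: np.ndarray,
) -> tuple[np.ndarray, TransformParams]:
    """Square-root then per-unit z transform, statistics from ``fit_mask`` bins.

    Units with zero variance on the fit segment are dropped (marked in the
    returned parameters) since they carry no decodable signal.
    """
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    root = np.sqrt(rates)
    seg = root[:, fit_mask]
    mean = seg.mean(axis=1)
    std = seg.std(axis=1)
    kept = std > 1e-12
    if not np.all(kept):
        warnings.warn(f"dropping {int((~kept).sum())} zero-variance unit(s)")
    out = (root[kept] - mean[kept, None]) / std[kept, None]
    return out, TransformParams(mean=mean, std=std, kept=kept)


def apply_transform(rates: np.ndarray, params: TransformParams) -> np.ndarray:
    """Re-apply stored sqrt/z parameters (for held-out bins)."""
    root = np.sqrt(rates)
    return (root[params.kept] - params.mean[params.kept, None]) / params.std[params.kept, None]


# ---------------------------------------------------------------------------
# positions and labels

def assign_positions(
    bin_centers: np.ndarray, bin_ms: float, trajectory: TrajectorySeries,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean tracker coordinate per bin window; empty bins interpolated.

    Returns ``(pos, interpolated_flag)``.
    """
    width = bin_ms / 1000.0
    edges = np.concatenate([bin_centers - width / 2.0, [bin_centers[-1] + width / 2.0]])
    which = np.searchsorted(edges, trajectory.t, side="right") - 1
    ok = (which >= 0) & (which < len(bin_centers))
    n = np.bincount(which[ok], minlength=len(bin_centers)).astype(float)
    sx = np.bincount(which[ok], weights=trajectory.x[ok], minlength=len(bin_centers))
    sy = np.bincount(which[ok], weights=trajectory.y[ok], minlength=len(bin_centers))
    empty = n == 0
    with np.errstate(invalid="ignore"):
        pos = np.column_stack([sx / n, sy / n])
    if np.any(empty):
        full = np.flatnonzero(~empty)
        for d in range(2):
            pos[empty, d] = np.interp(bin_centers[empty], bin_centers[full], pos[full, d])
    return pos, empty


def label_zones(pos: np.ndarray, geometry: TrackGeometry) -> np.ndarray:
    return geometry.label_positions(pos)


# ---------------------------------------------------------------------------
# assembled pipeline

def build_ensemble(
    bundle: SessionBundle,
    profile: str = "coarse",
    min_rate_hz: float = 0.5,
    trial_duration_factor: float = 1.5,
    kernel_std_ms: float | None = None,
    bin_ms: float | None = None,
) -> BinnedEnsemble:
    """Filter, smooth, bin and annotate one session (rates left untransformed)."""
    prof = PROFILES[profile]
    kernel_std_ms = kernel_std_ms if kernel_std_ms is not None else prof["kernel_std_ms"]
    bin_ms = bin_ms if bin_ms is not None else prof["bin_ms"]

    trials = filter_trials(bundle.trials, trial_duration_factor)
    spikes = filter_cells(bundle.spikes, min_rate_hz)
    rates, counts, centers = smooth_and_bin(spikes, kernel_std_ms, bin_ms)
    pos, interp = assign_positions(centers, bin_ms, bundle.trajectory)
    zone = label_zones(pos, bundle.geometry)

    trial_index = np.full(len(centers), -1, dtype=int)
    for tr in trials:
        sel = (centers >= tr.t_start) & (centers < tr.t_end)
        trial_index[sel] = tr.index

    return BinnedEnsemble(
        unit_ids=spikes.unit_ids, bin_centers=centers, bin_width_ms=bin_ms,
        kernel_std_ms=kernel_std_ms, activity=rates, counts=counts, pos=pos,
        trial_index=trial_index, zone=zone, interpolated=interp,
    )
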