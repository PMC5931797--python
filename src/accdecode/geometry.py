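"""Figure-8 track geometry.

The track is modelled by its centerline skeleton: a central arm running
south to north, flanked by a left and a right loop that share the arm.  Three
reward feeders sit on the skeleton: the centre feeder C on the central arm and
the two target feeders L and R at the north-west / north-east corners.

Positions are in cm with the origin at the south-west corner of the bounding
box, x pointing east and y pointing north.  Broad one-dimensional tuning
curves are defined on the skeleton through geodesic (along-track) distances
between skeleton vertices, which keeps them well-defined on a track with two
loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

__all__ = ["TrackGeometry", "build_track_geometry"]

ARM, LEFT, RIGHT = 0, 1, 2


class InvalidConfigError(ValueError):
    pass


def _polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample an open polyline at roughly ``spacing`` cm intervals."""
    out = []
    for a, b in zip(points[:-1], points[1:]):
        seg = np.asarray(b, float) - np.asarray(a, float)
        length = float(np.hypot(*seg))
        n = max(1, int(round(length / spacing)))
        t = np.arange(n) / n
        out.append(np.asarray(a, float) + t[:, None] * seg)
    out.append(np.asarray(points[-1], float)[None, :])
    return np.concatenate(out)


@dataclass
class TrackGeometry:
    """Skeleton, feeder locations and bounds of the figure-8 track."""

    skeleton: np.ndarray          # (N, 2) vertex coordinates, cm
    branch: np.ndarray            # (N,) branch id: 0 arm, 1 left loop, 2 right loop
    feeders: dict[str, np.ndarray]  # {"L","R","C"} -> (2,) cm
    feeder_zone_radius: float     # cm
    bounds: tuple[float, float]   # (width, height) cm

    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _geodesic: np.ndarray | None = field(default=None, repr=False, compare=False)

    # -- vertex lookup ---------------------------------------------------
    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.skeleton)
        return self._tree

    def nearest_vertex(self, points) -> np.ndarray:
        """Index of the nearest skeleton vertex for each query point."""
        pts = np.atleast_2d(np.asarray(points, float))
        return self.tree.query(pts)[1]

    # -- geodesic distances ----------------------------------------------
    @property
    def geodesic(self) -> np.ndarray:
        """All-pairs along-track distance between skeleton vertices (cm)."""
        if self._geodesic is None:
            n = len(self.skeleton)
            rows, cols, vals = [], [], []
            for br in (ARM, LEFT, RIGHT):
                idx = np.flatnonzero(self.branch == br)
                d = np.hypot(*(self.skeleton[idx[1:]] - self.skeleton[idx[:-1]]).T)
                rows += [*idx[:-1]]
                cols += [*idx[1:]]
                vals += [*d]
            # join loop branch endpoints to the arm endpoints they touch
            arm = np.flatnonzero(self.branch == ARM)
            for br in (LEFT, RIGHT):
                idx = np.flatnonzero(self.branch == br)
                for end in (idx[0], idx[-1]):
                    j = arm[np.argmin(np.hypot(*(self.skeleton[arm] - self.skeleton[end]).T))]
                    rows.append(end)
                    cols.append(j)
                    vals.append(float(np.hypot(*(self.skeleton[end] - self.skeleton[j]))))
            g = csr_matrix((vals, (rows, cols)), shape=(n, n))
            self._geodesic = dijkstra(g, directed=False)
        return self._geodesic

    def feeder_vertex(self, name: str) -> int:
        return int(self.nearest_vertex(self.feeders[name])[0])

    def label_positions(self, points) -> np.ndarray:
        """Zone label per point: feeder name if inside its zone, else 'track'.

        Ties (a point inside two zones) go to the nearest feeder.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        names = list(self.feeders)
        d = np.stack([np.hypot(*(pts - self.feeders[k]).T) for k in names])
        best = np.argmin(d, axis=0)
        labels = np.array([names[b] for b in best], dtype=object)
        labels[d[best, np.arange(pts.shape[0])] > self.feeder_zone_radius] = "track"
        return labels

    def to_dict(self) -> dict:
        return {
            "skeleton": self.skeleton.tolist(),
            "branch": self.branch.tolist(),
            "feeders": {k: list(map(float, v)) for k, v in self.feeders.items()},
            "feeder_zone_radius": float(self.feeder_zone_radius),
            "bounds": list(map(float, self.bounds)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrackGeometry":
        return cls(
            skeleton=np.asarray(d["skeleton"], float),
            branch=np.asarray(d["branch"], int),
            feeders={k: np.asarray(v, float) for k, v in d["feeders"].items()},
            feeder_zone_radius=float(d["feeder_zone_radius"]),
            bounds=tuple(d["bounds"]),
        )


def build_track_geometry(
    width: float = 102.0,
    height: float = 114.0,
    feeder_zone_radius: float = 10.0,
    center_feeder_frac: float = 0.55,
    spacing: float = 1.0,
) -> TrackGeometry:
    """Construct the default figure-8 geometry.

    Parameters
    ----------
    width, height
        Bounding-box dimensions in cm.
    feeder_zone_radius
        Radius (cm) of the circular zone around each feeder used for zone
        labelling and excursion endpoint attribution.
    center_feeder_frac
        Fractional position of the centre feeder along the central arm
        (0 = south end, 1 = choice point at the north end).
    spacing
        Skeleton resampling interval in cm.
    """
    if width <= 0 or height <= 0 or spacing <= 0 or feeder_zone_radius <= 0:
        raise InvalidConfigError("track dimensions must be positive")

    xm = width / 2.0
    arm = _polyline([(xm, 0.0), (xm, height)], spacing)
    # loops run from the choice point (north end of the arm) back to its base,
    # in the direction of travel
    # drop the first vertex (shared with the arm top); keep the closing
    # vertex at the arm base so laps are gap-free
    left = _polyline(
        [(xm, height), (0.0, height), (0.0, 0.0), (xm, 0.0)], spacing
    )[1:]
    right = _polyline(
        [(xm, height), (width, height), (width, 0.0), (xm, 0.0)], spacing
    )[1:]

    skeleton = np.concatenate([arm, left, right])
    branch = np.concatenate(
        [np.full(len(arm), ARM), np.full(len(left), LEFT), np.full(len(right), RIGHT)]
    )
    feeders = {
        "L": np.array([0.0, height]),
        "R": np.array([width, height]),
        "C": np.array([xm, center_feeder_frac * height]),
    }
    return TrackGeometry(
        skeleton=skeleton,
        branch=branch,
        feeders=feeders,
        feeder_zone_radius=float(feeder_zone_radius),
        bounds=(float(width), float(height)),
    )
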