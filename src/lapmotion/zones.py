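"""Working-area geometry and zone-occupancy metrics.

At the start of each session the participant holds both instruments on the
target object (aorta or incised kidney parenchyma) for ~5 s at its starting and
ending points, roughly 17-18 cm apart. The componentwise medians of these two
dwell clouds define the *working axis*; radial distance from that axis (with
endpoint capping, i.e. point-to-segment distance) defines concentric-cylinder
zones: close [0, 2 cm), near [2, 4 cm), far [4 cm, inf).

Two occupancy views are provided:

* :func:`zone_distribution` — fraction of the *path length* travelled in each
  zone (each inter-frame step assigned to the zone of its midpoint),
* :func:`zone_conditioned_velocity` — within each zone, the frame-count
  velocity-band distribution (tip position of the frame itself decides the
  zone), the sub-analysis that exposes hovering behaviour near the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, UndefinedMetricError, UnstableAnchorError
from .kinematics import KinematicSeries, VelocityBands, band_fractions

__all__ = [
    "WorkingAxis",
    "ZoneEdges",
    "fit_working_axis",
    "distance_to_target",
    "zone_distribution",
    "zone_conditioned_velocity",
]


@dataclass(frozen=True)
class WorkingAxis:
    """Target-object axis between the two anchor points, cm."""

    p_start: tuple[float, float, float]
    p_end: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise UnstableAnchorError("zero-length working axis")

    @property
    def length(self) -> float:
        return float(
            np.linalg.norm(np.asarray(self.p_end) - np.asarray(self.p_start))
        )


@dataclass(frozen=True)
class ZoneEdges:
    """Left-closed right-open radial zones from the working axis, cm."""

    edges: tuple[float, ...] = (0.0, 2.0, 4.0)
    labels: tuple[str, ...] = ("close", "near", "far")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges):
            raise ConfigurationError("need one label per zone")
        if np.any(np.diff(self.edges) <= 0):
            raise ConfigurationError("zone edges must be strictly increasing")


def fit_working_axis(
    window_a: np.ndarray,
    window_b: np.ndarray,
    max_spread: float = 1.0,
) -> WorkingAxis:
    """Estimate the working axis from two anchor dwell recordings.

    Each window is an ``(n, 3)`` array of tip positions (cm) held
    near-stationary on the target; the anchor point is the componentwise
    median, which is robust to brief slips. A window whose maximum pairwise
    positional spread exceeds ``max_spread`` (cm) is rejected as unstable.
    """
    points = []
    for name, w in (("start", window_a), ("end", window_b)):
        w = np.asarray(w, float)
        if w.ndim != 2 or w.shape[1] != 3 or w.shape[0] < 2:
            raise ConfigurationError(f"{name} anchor window must be (n>=2, 3)")
        spread = _max_pairwise_distance(w)
        if spread > max_spread:
            raise UnstableAnchorError(
                f"{name} anchor window spread {spread:.2f} cm exceeds {max_spread} cm"
            )
        points.append(np.median(w, axis=0))
    return WorkingAxis(tuple(points[0]), tuple(points[1]))


def _max_pairwise_distance(w: np.ndarray, cap: int = 2000) -> float:
    if w.shape[0] > cap:  # subsample; dwell clouds are i.i.d.-like in time
        w = w[:: int(np.ceil(w.shape[0] / cap))]
    return float(pdist(w).max())


def distance_to_target(points: np.ndarray, axis: WorkingAxis) -> np.ndarray:
    """Euclidean distance (cm) from each point to the closed axis segment.

    Perpendicular distance where the orthogonal projection falls inside the
    segment, distance to the nearer endpoint otherwise — the radius of the
    concentric working-area cylinder with capped ends.
    """
    p = np.atleast_2d(np.asarray(points, float))
    a = np.asarray(axis.p_start, float)
    b = np.asarray(axis.p_end, float)
    ab = b - a
    tt = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
    closest = a + tt[:, None] * ab
    d = np.linalg.norm(p - closest, axis=1)
    return d if np.asarray(points).ndim == 2 else d[0]


def _zone_index(dist: np.ndarray, zones: ZoneEdges) -> np.ndarray:
    edges = np.asarray(zones.edges)
    return np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, len(edges) - 1)


def zone_distribution(
    series: KinematicSeries,
    axis: WorkingAxis,
    inside: np.ndarray | None = None,
    zones: ZoneEdges = ZoneEdges(),
) -> np.ndarray:
    """Fraction of the in-box path length travelled in each radial zone.

    Each inter-frame step (both endpoints valid and inside) contributes its
    Euclidean length to the zone containing the step midpoint; fractions are
    per-zone length over total length and sum to 1. Raises
    :class:`UndefinedMetricError` when the total path length is zero.
    """
    if inside is None:
        inside = np.ones(series.n_frames, dtype=bool)
    ok = series.valid & np.asarray(inside, bool)
    use = ok[:-1] & ok[1:]
    steps = np.linalg.norm(np.diff(series.pos_s, axis=0), axis=1)
    total = steps[use].sum()
    if total <= 0:
        raise UndefinedMetricError("zero path length; zone distribution undefined")
    mid = 0.5 * (series.pos_s[:-1] + series.pos_s[1:])
    zi = _zone_index(distance_to_target(mid, axis), zones)
    out = np.zeros(len(zones.labels))
    np.add.at(out, zi[use], steps[use])
    return out / total


def zone_conditioned_velocity(
    series: KinematicSeries,
    axis: WorkingAxis,
    zones: ZoneEdges = ZoneEdges(),
    bands: VelocityBands = VelocityBands(),
    inside: np.ndarray | None = None,
) -> dict[str, np.ndarray | None]:
    """Velocity-band distribution of the frames spent in each zone.

    Zone membership uses each frame's own smoothed tip position. Returns a
    mapping ``zone label -> band fractions`` (each summing to 1); a zone the
    tip never visits maps to ``None`` (undefined, not zero).
    """
    if inside is None:
        inside = np.ones(series.n_frames, dtype=bool)
    ok = series.valid & np.asarray(inside, bool)
    if not ok.any():
        raise UndefinedMetricError("no valid frames")
    v = np.linalg.norm(series.d1, axis=1)
    zi = _zone_index(distance_to_target(series.pos_s, axis), zones)
    result: dict[str, np.ndarray | None] = {}
    for k, label in enumerate(zones.labels):
        sel = ok & (zi == k)
        result[label] = band_fractions(v[sel], bands) if sel.any() else None
    return result
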