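"""Savitzky-Golay kinematics of instrument-tip trajectories.

The tip trajectory of each instrument is smoothed by a Savitzky-Golay filter
(local least-squares polynomial fit, order 3 over 31 frames by default) and the
same filter yields the first three time derivatives, from which the scalar
metrics are computed:

* **path length** (m) — sum of Euclidean steps between consecutive in-box
  frames,
* **velocity / acceleration / jerk** (cm/s, cm/s^2, cm/s^3) — mean Euclidean
  norm of the 1st/2nd/3rd derivative over valid frames; mean jerk is the
  (inverse) motion-smoothness measure,
* **velocity-band distribution** — fraction of frames whose speed falls in the
  idle/low/middle/high/very-high bands (edges 0.5, 2, 5, 12 cm/s),
* **operative time** (s) — task duration.

Frames within half a filter window of a segment boundary lack full filter
support and are marked invalid; they are excluded from every mean and
distribution so that edge artifacts never inflate jerk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    ConfigurationError,
    SegmentTooShortError,
    TrackValidationError,
    UndefinedMetricError,
)
from .io import InstrumentTrack

__all__ = [
    "SGConfig",
    "VelocityBands",
    "KinematicSeries",
    "sg_smooth",
    "path_length",
    "mean_kinematic_magnitudes",
    "velocity_band_distribution",
    "operative_time",
    "speed",
]


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay filter settings: cubic fit over 31 frames by default."""

    poly_order: int = 3
    window_frames: int = 31

    def __post_init__(self) -> None:
        if self.window_frames % 2 == 0 or self.window_frames <= self.poly_order:
            raise ConfigurationError(
                f"window_frames must be odd and > poly_order, got "
                f"{self.window_frames} / {self.poly_order}"
            )

    @property
    def half_window(self) -> int:
        return (self.window_frames - 1) // 2


@dataclass(frozen=True)
class VelocityBands:
    """Left-closed right-open speed bands, cm/s.

    Defaults: idle [0, 0.5), low [0.5, 2), middle [2, 5), high [5, 12),
    very_high [12, inf).
    """

    edges: tuple[float, ...] = (0.0, 0.5, 2.0, 5.0, 12.0)
    labels: tuple[str, ...] = ("idle", "low", "middle", "high", "very_high")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges):
            raise ConfigurationError("need one label per band")
        if np.any(np.diff(self.edges) <= 0):
            raise ConfigurationError("band edges must be strictly increasing")


class KinematicMeans(NamedTuple):
    velocity: float  # cm/s
    acceleration: float  # cm/s^2
    jerk: float  # cm/s^3


@dataclass
class KinematicSeries:
    """Smoothed positions and 1st-3rd derivatives, frame-aligned to the track."""

    t: np.ndarray
    pos_s: np.ndarray  # (n, 3) cm
    d1: np.ndarray  # cm/s
    d2: np.ndarray  # cm/s^2
    d3: np.ndarray  # cm/s^3
    valid: np.ndarray  # full-filter-support frames

    @property
    def n_frames(self) -> int:
        return self.t.shape[0]


def _resample_uniform(
    t: np.ndarray, pos: np.ndarray, sample_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    dt = 1.0 / sample_rate
    n = int(round((t[-1] - t[0]) / dt)) + 1
    tu = t[0] + dt * np.arange(n)
    out = np.column_stack([np.interp(tu, t, pos[:, k]) for k in range(3)])
    return tu, out


def sg_smooth(
    segment: InstrumentTrack | np.ndarray,
    cfg: SGConfig = SGConfig(),
    sample_rate: float | None = None,
    t: np.ndarray | None = None,
) -> KinematicSeries:
    """Smooth a track segment and differentiate it up to third order.

    Accepts an :class:`InstrumentTrack` segment (gap-free; run
    :func:`lapmotion.io.fill_gaps` first) or a raw ``(n, 3)`` position array
    with an explicit ``t``. Sampling must be uniform; timestamp jitter above 1%
    of the frame period triggers linear resampling to a uniform grid at
    ``sample_rate`` (required in that case).

    Derivatives are scaled by the sampling interval, so units are cm/s,
    cm/s^2, cm/s^3 when positions are cm. Frames within half a window of
    either end are flagged invalid.
    """
    if isinstance(segment, InstrumentTrack):
        if segment.gap.any():
            raise TrackValidationError("segment contains gaps; fill or split first")
        t_arr, pos = segment.t, segment.pos
    else:
        if t is None:
            raise ConfigurationError("raw position input needs explicit t")
        t_arr, pos = np.asarray(t, float), np.asarray(segment, float)
    n = t_arr.shape[0]
    if n < cfg.window_frames:
        raise SegmentTooShortError(
            f"segment of {n} frames shorter than filter window {cfg.window_frames}"
        )
    dts = np.diff(t_arr)
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > 0.01 * dt:
        if sample_rate is None:
            sample_rate = 1.0 / dt
        t_arr, pos = _resample_uniform(t_arr, pos, sample_rate)
        dt = 1.0 / sample_rate
        n = t_arr.shape[0]
        if n < cfg.window_frames:
            raise SegmentTooShortError("segment too short after resampling")
    derivs = [
        savgol_filter(
            pos, cfg.window_frames, cfg.poly_order, deriv=j, delta=dt, axis=0
        )
        for j in range(4)
    ]
    valid = np.zeros(n, dtype=bool)
    h = cfg.half_window
    valid[h : n - h] = True
    return KinematicSeries(
        t=t_arr, pos_s=derivs[0], d1=derivs[1], d2=derivs[2], d3=derivs[3], valid=valid
    )


def speed(series: KinematicSeries) -> np.ndarray:
    """Per-frame tip speed ||d1||, cm/s (NaN on invalid frames)."""
    v = np.linalg.norm(series.d1, axis=1)
    v = v.copy()
    v[~series.valid] = np.nan
    return v


def path_length(
    series: KinematicSeries, inside: np.ndarray | None = None
) -> float:
    """Total tip path length in metres.

    Sums Euclidean steps over consecutive frame pairs whose both endpoints are
    valid and inside the box trainer; trajectory outside the box is excluded
    from the measurement. Positions are cm, so the sum is divided by 100.
    """
    if inside is None:
        inside = np.ones(series.n_frames, dtype=bool)
    ok = series.valid & np.asarray(inside, bool)
    use = ok[:-1] & ok[1:]
    if not use.any():
        return 0.0
    steps = np.linalg.norm(np.diff(series.pos_s, axis=0), axis=1)
    return float(steps[use].sum() / 100.0)


def mean_kinematic_magnitudes(series: KinematicSeries) -> KinematicMeans:
    """Mean Euclidean norms of the 1st-3rd derivatives over valid frames."""
    if not series.valid.any():
        raise UndefinedMetricError("no valid frames")
    v = np.linalg.norm(series.d1[series.valid], axis=1).mean()
    a = np.linalg.norm(series.d2[series.valid], axis=1).mean()
    j = np.linalg.norm(series.d3[series.valid], axis=1).mean()
    return KinematicMeans(float(v), float(a), float(j))


def velocity_band_distribution(
    series: KinematicSeries, bands: VelocityBands = VelocityBands()
) -> np.ndarray:
    """Fraction of valid frames per speed band (left-closed right-open).

    Returns fractions summing to 1; multiply by 100 to report percentages.
    """
    if not series.valid.any():
        raise UndefinedMetricError("no valid frames")
    v = np.linalg.norm(series.d1[series.valid], axis=1)
    return band_fractions(v, bands)


def band_fractions(values: np.ndarray, bands: VelocityBands) -> np.ndarray:
    """Histogram fractions of ``values`` over left-closed right-open bands."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise UndefinedMetricError("no samples to band")
    edges = np.asarray(bands.edges + (np.inf,))
    counts = np.array(
        [np.count_nonzero((values >= lo) & (values < hi)) for lo, hi in zip(edges[:-1], edges[1:])],
        dtype=float,
    )
    return counts / values.size


def operative_time(
    tracks: Sequence[InstrumentTrack],
    start: float | None = None,
    end: float | None = None,
) -> float:
    """Task completion time in seconds.

    With explicit ``start``/``end`` timestamps (from the manifest) returns
    ``end - start``; otherwise it is inferred as the span from the earliest
    first frame to the latest last frame over all instrument tracks.
    """
    if start is not None and end is not None:
        if end < start:
            raise TrackValidationError(f"end {end} before start {start}")
        return float(end - start)
    if not tracks:
        raise TrackValidationError("no tracks to infer operative time from")
    t0 = min(float(tr.t[0]) for tr in tracks)
    t1 = max(float(tr.t[-1]) for tr in tracks)
    return t1 - t0
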