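"""Discrete event metrics: jaw open/close iterations and insertion episodes.

One *iteration* is a completed open-then-close series of the forceps jaws,
detected with a two-threshold (hysteresis) state machine so that aperture
chatter around a single level is never counted. An *insertion episode* is the
interval between the instrument entering the box trainer through a trocar and
its removal; the average inserting time is the mean episode duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, UndefinedMetricError

__all__ = ["EventCounts", "count_open_close", "insertion_segments"]


@dataclass
class EventCounts:
    open_close_iterations: int | None = None
    insertion_episodes: list[tuple[float, float]] = field(default_factory=list)

    @property
    def average_inserting_time(self) -> float:
        if not self.insertion_episodes:
            raise UndefinedMetricError("no insertion episodes")
        return float(np.mean([b - a for a, b in self.insertion_episodes]))


def count_open_close(
    jaw: np.ndarray, open_thresh: float = 0.6, close_thresh: float = 0.4
) -> int:
    """Count completed open->close jaw cycles with hysteresis.

    The state becomes OPEN when the normalized aperture rises to
    ``open_thresh`` or above; one iteration completes when it then falls to
    ``close_thresh`` or below. Partial cycles at the end of a task are not
    counted.
    """
    if jaw is None:
        raise UndefinedMetricError("instrument has no jaw channel")
    if not open_thresh > close_thresh:
        raise ConfigurationError("open_thresh must exceed close_thresh (hysteresis)")
    jaw = np.asarray(jaw, float)
    count = 0
    is_open = False
    # vectorized run through threshold crossings only
    above = jaw >= open_thresh
    below = jaw <= close_thresh
    crossings = np.flatnonzero(above | below)
    for i in crossings:
        if not is_open and above[i]:
            is_open = True
        elif is_open and below[i]:
            is_open = False
            count += 1
    return count


def insertion_segments(
    inside: np.ndarray, t: np.ndarray, min_episode: float = 0.5
) -> list[tuple[float, float]]:
    """Extract debounced insertion episodes from the inside-box flag.

    Maximal runs of ``inside`` are episodes; first, outside blips shorter than
    ``min_episode`` seconds are merged into their surrounding episode (tracking
    glitches), then inside runs shorter than ``min_episode`` are dropped (a
    trocar passage cannot be that brief). Returns ordered, disjoint
    ``(t_in, t_out)`` pairs in seconds.
    """
    inside = np.asarray(inside, bool).copy()
    t = np.asarray(t, float)
    if inside.shape != t.shape:
        raise ConfigurationError("inside and t must be frame-aligned")
    # merge short outside blips
    for a, b in _runs(~inside):
        interior = a > 0 and b < inside.size
        if interior and (t[b] - t[a - 1]) < min_episode:
            inside[a:b] = True
    episodes = []
    for a, b in _runs(inside):
        t_in, t_out = float(t[a]), float(t[b - 1])
        if t_out - t_in >= min_episode:
            episodes.append((t_in, t_out))
    return episodes


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))
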