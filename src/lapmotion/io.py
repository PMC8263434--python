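"""Trajectory and session I/O.

A tracked-instrument session is stored as plain delimited text: one file per
instrument with columns ``time,x,y,z[,jaw,inside]`` (seconds and centimetres by
default), a YAML manifest naming the track files, their instrument/hand roles,
the sample rate and the two anchor-recording windows, and a participant table
mapping participant ids to laparoscopic case counts.

Occlusions appear as rows with blank coordinates; they are kept as explicitly
flagged gaps on read and are never silently interpolated — :func:`fill_gaps`
makes the imputation/segmentation policy explicit.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, TrackParseError, TrackValidationError

__all__ = [
    "InstrumentTrack",
    "AnchorWindow",
    "SessionManifest",
    "ParticipantMeta",
    "read_track",
    "write_track",
    "fill_gaps",
    "assign_group",
    "read_participant_table",
]

#: number of previous laparoscopic surgeries delimiting the experience groups
GROUP_CUTOFFS = {"intermediate": 10, "expert": 50, "expert_100plus": 100}


@dataclass
class InstrumentTrack:
    """Time-stamped 3D tip positions for one instrument in one task.

    Parameters
    ----------
    instrument_id:
        Free-form label, e.g. ``scissors``, ``clip_applier``, ``grasper``.
    hand:
        ``"right"`` or ``"left"``.
    t:
        Frame timestamps in seconds, strictly increasing.
    pos:
        ``(n, 3)`` tip positions in centimetres. Rows of an occluded frame are
        NaN and flagged in :attr:`gap`.
    jaw:
        Normalized jaw aperture in ``[0, 1]`` per frame, or ``None`` when the
        instrument has no jaw channel.
    inside:
        Per-frame flag: tip inside the box trainer. Frames outside are excluded
        from path-length accumulation downstream.
    gap:
        Per-frame flag marking occluded (missing) coordinates.
    imputed:
        Per-frame flag marking coordinates filled in by :func:`fill_gaps`.
    """

    instrument_id: str
    hand: str
    t: np.ndarray
    pos: np.ndarray
    jaw: np.ndarray | None = None
    inside: np.ndarray | None = None
    gap: np.ndarray | None = None
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        n = self.t.shape[0]
        if n < 2:
            raise TrackValidationError(f"track needs >= 2 frames, got {n}")
        if self.pos.shape != (n, 3):
            raise TrackValidationError(
                f"pos shape {self.pos.shape} does not match {n} frames"
            )
        if np.any(np.diff(self.t) <= 0):
            raise TrackValidationError("timestamps must be strictly increasing")
        if self.inside is None:
            self.inside = np.ones(n, dtype=bool)
        else:
            self.inside = np.asarray(self.inside, dtype=bool)
        if self.gap is None:
            self.gap = np.any(~np.isfinite(self.pos), axis=1)
        else:
            self.gap = np.asarray(self.gap, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros(n, dtype=bool)
        if self.jaw is not None:
            self.jaw = np.asarray(self.jaw, dtype=float)
            if self.jaw.shape[0] != n:
                raise TrackValidationError("jaw channel length mismatch")
        for name in ("inside", "gap", "imputed"):
            if getattr(self, name).shape[0] != n:
                raise TrackValidationError(f"{name} channel length mismatch")
        if np.any(~np.isfinite(self.pos[~self.gap])):
            raise TrackValidationError("non-finite position on a non-gap frame")

    @property
    def n_frames(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class AnchorWindow:
    """Time window of one anchor dwell (instrument held on the target for ~5 s)."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end - self.start < 1.0:
            raise ConfigurationError(
                f"anchor window [{self.start}, {self.end}] shorter than 1 s"
            )


@dataclass
class TrackRef:
    file: str
    instrument: str
    hand: str


@dataclass
class SessionManifest:
    """One participant x task recording session."""

    participant_id: str
    task: str
    sample_rate_hz: float
    tracks: list[TrackRef]
    anchor_file: str
    anchor_windows: list[AnchorWindow]
    units: str = "cm"
    time_units: str = "s"

    def __post_init__(self) -> None:
        if len(self.anchor_windows) != 2:
            raise ConfigurationError(
                f"exactly two anchor windows required, got {len(self.anchor_windows)}"
            )
        if self.units not in ("cm", "mm", "m"):
            raise ConfigurationError(f"unknown position unit {self.units!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionManifest":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            return cls(
                participant_id=str(raw["participant_id"]),
                task=str(raw["task"]),
                sample_rate_hz=float(raw["sample_rate_hz"]),
                tracks=[TrackRef(**tr) for tr in raw["tracks"]],
                anchor_file=str(raw["anchors"]["file"]),
                anchor_windows=[AnchorWindow(**w) for w in raw["anchors"]["windows"]],
                units=str(raw.get("units", "cm")),
                time_units=str(raw.get("time_units", "s")),
            )
        except KeyError as exc:  # pragma: no cover - message clarity only
            raise ConfigurationError(f"manifest {path} missing key {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "participant_id": self.participant_id,
            "task": self.task,
            "sample_rate_hz": self.sample_rate_hz,
            "units": self.units,
            "time_units": self.time_units,
            "tracks": [vars(tr) for tr in self.tracks],
            "anchors": {
                "file": self.anchor_file,
                "windows": [vars(w) for w in self.anchor_windows],
            },
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class ParticipantMeta:
    participant_id: str
    n_surgeries: int
    group: str = field(init=False)
    subgroup: str | None = field(init=False)

    def __post_init__(self) -> None:
        self.group, self.subgroup = assign_group(self.n_surgeries)


def assign_group(n_surgeries: int) -> tuple[str, str | None]:
    """Map a laparoscopic case count to an experience group.

    Cutoffs: 0-9 novice, 10-49 intermediate, >=50 expert; experts are further
    split into ``expert_50_99`` and ``expert_100plus`` subgroups.

    Returns ``(group, subgroup)``; ``subgroup`` is ``None`` outside the expert
    group.
    """
    n = int(n_surgeries)
    if n != n_surgeries or n < 0:
        raise TrackValidationError(f"n_surgeries must be a non-negative integer, got {n_surgeries}")
    if n < GROUP_CUTOFFS["intermediate"]:
        return "novice", None
    if n < GROUP_CUTOFFS["expert"]:
        return "intermediate", None
    if n < GROUP_CUTOFFS["expert_100plus"]:
        return "expert", "expert_50_99"
    return "expert", "expert_100plus"


_UNIT_TO_CM = {"cm": 1.0, "mm": 0.1, "m": 100.0}
_TIME_TO_S = {"s": 1.0, "ms": 1e-3}


def read_track(
    path: str | Path,
    instrument: str = "instrument",
    hand: str = "right",
    units: str = "cm",
    time_units: str = "s",
) -> InstrumentTrack:
    """Read a delimited trajectory file into a validated :class:`InstrumentTrack`.

    The file must have a header row with at least ``time,x,y,z``; ``jaw`` and
    ``inside`` columns are optional (``inside`` defaults to all-true, ``jaw`` to
    absent). Rows with any blank coordinate are kept as gap frames.
    """
    path = Path(path)
    if units not in _UNIT_TO_CM:
        raise ConfigurationError(f"unknown position unit {units!r}")
    if time_units not in _TIME_TO_S:
        raise ConfigurationError(f"unknown time unit {time_units!r}")
    try:
        header = path.open().readline()
        sep = max(",\t;", key=header.count)
        # round_trip float parsing keeps write_track -> read_track bitwise
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, ValueError) as exc:
        raise TrackParseError(f"{path}: {exc}") from exc
    missing = {"time", "x", "y", "z"} - set(df.columns)
    if missing:
        raise TrackParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("time", "x", "y", "z"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise TrackParseError(f"{path}: malformed {col!r} value at line {line}") from exc
    t = df["time"].to_numpy(float) * _TIME_TO_S[time_units]
    if np.any(~np.isfinite(t)):
        raise TrackParseError(f"{path}: missing timestamp")
    pos = df[["x", "y", "z"]].to_numpy(float) * _UNIT_TO_CM[units]
    jaw = df["jaw"].to_numpy(float) if "jaw" in df.columns else None
    inside = (
        df["inside"].astype(bool).to_numpy() if "inside" in df.columns else None
    )
    return InstrumentTrack(
        instrument_id=instrument, hand=hand, t=t, pos=pos, jaw=jaw, inside=inside
    )


def write_track(track: InstrumentTrack, path: str | Path) -> None:
    """Write a track as CSV, preserving float values to full round-trip precision."""
    cols: dict[str, object] = {
        "time": track.t,
        "x": track.pos[:, 0],
        "y": track.pos[:, 1],
        "z": track.pos[:, 2],
    }
    if track.jaw is not None:
        cols["jaw"] = track.jaw
    cols["inside"] = track.inside.astype(int)
    df = pd.DataFrame(cols)
    buf = _io.StringIO()
    # %.17g is lossless for float64, so read_track(write_track(x)) is bitwise.
    df.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def fill_gaps(track: InstrumentTrack, max_gap: float = 0.2) -> list[InstrumentTrack]:
    """Interpolate short occlusions and split the track at long ones.

    Gap runs no longer than ``max_gap`` seconds are linearly interpolated (and
    flagged ``imputed``); longer runs split the track into independent segments
    so that no path length is fabricated across an occlusion. Non-gap samples
    are never modified. Returns the list of segments in time order (length one
    when no long gap exists); segments shorter than two frames are dropped.
    """
    gap = track.gap.copy()
    if not gap.any():
        return [track]
    n = track.n_frames
    idx = np.arange(n)
    runs = _bool_runs(gap)
    long_runs = []
    pos = track.pos.copy()
    imputed = track.imputed.copy()
    for a, b in runs:  # run is frames [a, b)
        t_lo = track.t[a - 1] if a > 0 else track.t[0]
        t_hi = track.t[b] if b < n else track.t[-1]
        interior = a > 0 and b < n
        if interior and (t_hi - t_lo) <= max_gap:
            for k in range(3):
                pos[a:b, k] = np.interp(track.t[a:b], [t_lo, t_hi], [pos[a - 1, k], pos[b, k]])
            imputed[a:b] = True
        else:
            long_runs.append((a, b))
    keep_gap = np.zeros(n, dtype=bool)
    for a, b in long_runs:
        keep_gap[a:b] = True
    segments = []
    for a, b in _bool_runs(~keep_gap):
        if b - a < 2:
            continue
        segments.append(
            InstrumentTrack(
                instrument_id=track.instrument_id,
                hand=track.hand,
                t=track.t[a:b],
                pos=pos[a:b],
                jaw=None if track.jaw is None else track.jaw[a:b],
                inside=track.inside[a:b],
                gap=np.zeros(b - a, dtype=bool),
                imputed=imputed[a:b],
            )
        )
    return segments


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Return half-open [start, stop) index runs where ``mask`` is True."""
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


def read_participant_table(path: str | Path) -> list[ParticipantMeta]:
    """Read ``participant_id,n_surgeries[,qualification]`` delimited text."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"participant_id", "n_surgeries"} - set(df.columns)
    if missing:
        raise TrackParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        ParticipantMeta(str(r.participant_id), int(r.n_surgeries))
        for r in df.itertuples()
    ]
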