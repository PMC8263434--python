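"""Skill-stratified synthetic instrument trajectories with known ground truth.

Real wet-lab recordings are not redistributable, so every pipeline stage is
exercised against simulated sessions whose generative parameters mirror the
qualitative expert/novice contrasts of the study population: experts move less
(shorter path length), faster (higher mean speed, hence higher mean jerk),
pause less (smaller idle fraction), hover closer to the target axis, cycle the
jaws fewer times, and insert/remove the clip applier more quickly.

Motion is a concatenation of idle dwells and minimum-jerk point-to-point
submovements (quintic position profile ``10 s^3 - 15 s^4 + 6 s^5``, the
standard motor-control reach model), with targets drawn around a preferred
radial distance from the working axis and additive Gaussian sensor noise.
Every jaw cycle and insertion episode is scheduled explicitly, so the
generator knows the exact ground truth each detector must recover.

All randomness flows through an explicit integer seed; the same seed yields
bitwise-identical tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import AnchorWindow, InstrumentTrack, ParticipantMeta, SessionManifest, TrackRef, write_track
from .zones import WorkingAxis

__all__ = [
    "SkillProfile",
    "SimulatedSession",
    "default_profiles",
    "simulate_track",
    "simulate_session",
    "simulate_cohort",
    "write_cohort",
    "DEFAULT_GROUP_SIZES",
]

#: cohort composition mirroring the study population (novice/intermediate/expert)
DEFAULT_GROUP_SIZES = {"novice": 18, "intermediate": 12, "expert": 15}

#: anchor separation (cm); the target-object axis is recorded at ~17-18 cm
ANCHOR_SEPARATION = 17.5
ANCHOR_DWELL = 5.0  # seconds the tip is held on each anchor point


@dataclass(frozen=True)
class SkillProfile:
    """Generative motion parameters for one experience level.

    Units: rates in submovements/s, lengths in cm, times in s.
    """

    submovement_rate: float  # reach cycles per second
    submovement_amplitude: float  # mean reach extent, cm
    amplitude_spread: float = 0.35  # lognormal sigma of reach extent
    idle_fraction: float = 0.2  # fraction of time spent dwelling
    hover_radius_bias: float = 2.0  # preferred radial distance from axis, cm
    hover_duration: float = 0.4  # not used directly; dwell scale modifier
    n_open_close: int = 0  # scheduled jaw cycles
    n_insertions: int = 0  # scheduled trocar insertion episodes
    insertion_duration: float = 10.0  # mean episode length, s
    noise_sigma: float = 0.03  # sensor noise, cm
    duration: float = 120.0  # task duration, s

    def __post_init__(self) -> None:
        if not 0 <= self.idle_fraction <= 1:
            raise ConfigurationError("idle_fraction must be in [0, 1]")
        for name in ("submovement_rate", "submovement_amplitude", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")


def default_profiles(instrument: str = "scissors") -> dict[str, SkillProfile]:
    """Group profiles emulating the study's task-1 contrasts, 10x shortened.

    Task durations are the reported group-median operative times scaled down
    tenfold (novice 230 s, intermediate 144 s, expert 96 s) to keep simulated
    cohorts fast; all orderings across groups are preserved.
    """
    base = {
        "novice": SkillProfile(
            submovement_rate=0.72, submovement_amplitude=2.15, idle_fraction=0.30,
            hover_radius_bias=2.6, duration=230.0,
        ),
        "intermediate": SkillProfile(
            submovement_rate=0.88, submovement_amplitude=2.5, idle_fraction=0.22,
            hover_radius_bias=2.2, duration=144.0,
        ),
        "expert": SkillProfile(
            submovement_rate=1.05, submovement_amplitude=2.85, idle_fraction=0.13,
            hover_radius_bias=1.5, duration=96.0,
        ),
    }
    if instrument in ("scissors", "grasper"):
        # jaw-cycle counts mirror the reported iteration contrasts (scaled 10x)
        cycles = {"scissors": (36, 24, 21), "grasper": (9, 5, 4)}[instrument]
        for g, c in zip(("novice", "intermediate", "expert"), cycles):
            base[g] = replace(base[g], n_open_close=c)
    if instrument == "clip_applier":
        ins = {"novice": (5, 17.7), "intermediate": (5, 12.2), "expert": (5, 9.4)}
        for g, (k, d) in ins.items():
            base[g] = replace(
                base[g], n_insertions=k, insertion_duration=d,
                hover_radius_bias=base[g].hover_radius_bias + 2.0, n_open_close=5,
            )
    return base


@dataclass
class SimulatedSession:
    """All tracks of one simulated participant x task, plus ground truth."""

    participant_id: str
    task: str
    tracks: dict[str, InstrumentTrack]
    anchor_track: InstrumentTrack
    anchor_windows: list[AnchorWindow]
    axis: WorkingAxis
    sample_rate_hz: float
    truth: dict[str, dict]  # per-instrument scheduled ground truth


def _draw_target(
    rng: np.random.Generator,
    axis_len: float,
    axial: float,
    amplitude: float,
    radius_bias: float,
    theta: float,
) -> tuple[np.ndarray, float]:
    """Next reach target on the working cylinder, near the current tip.

    The axial coordinate takes a step of scale ``amplitude`` and the azimuth a
    small random-walk step, so consecutive targets are a reach apart rather
    than on opposite sides of the cylinder.
    """
    ax = float(np.clip(axial + rng.normal(0.0, amplitude), -1.0, axis_len + 1.0))
    r = abs(rng.normal(radius_bias, 0.3 * radius_bias + 0.2))
    theta = theta + rng.normal(0.0, 0.5)
    return np.array([ax, r * np.cos(theta), r * np.sin(theta)]), theta


def simulate_track(
    profile: SkillProfile,
    duration: float | None = None,
    sample_rate: float = 100.0,
    seed: int | np.random.Generator = 0,
    instrument: str = "scissors",
    hand: str = "right",
    axis_length: float = ANCHOR_SEPARATION,
    t0: float = 0.0,
) -> tuple[InstrumentTrack, dict]:
    """Simulate one instrument track; returns ``(track, ground_truth)``.

    ``ground_truth`` records the scheduled jaw-cycle count, the scheduled
    insertion episodes (seconds, frame-aligned), the dwell-time fraction and
    the noise-free positions.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    duration = profile.duration if duration is None else duration
    if duration < 10.0:
        raise ConfigurationError("duration must be >= 10 s")
    dt = 1.0 / sample_rate
    n = int(round(duration * sample_rate)) + 1
    t = t0 + dt * np.arange(n)

    # --- build the dwell/move event schedule -------------------------------
    cycle = 1.0 / profile.submovement_rate if profile.submovement_rate > 0 else duration
    ev_t0, ev_T = [], []  # event start, duration
    ev_P, ev_Q = [], []  # start and end points
    move_starts = []  # movement event start times (jaw cycles attach here)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    pos, theta = _draw_target(rng, axis_length, axis_length / 2,
                              profile.submovement_amplitude,
                              profile.hover_radius_bias, theta)
    clock = 0.0
    pure_dwell = profile.submovement_rate == 0 or profile.idle_fraction >= 1
    while clock < duration:
        dwell = profile.idle_fraction * cycle * rng.uniform(0.6, 1.4)
        if pure_dwell:
            dwell = duration + 1.0
        if dwell > 0:
            ev_t0.append(clock); ev_T.append(dwell); ev_P.append(pos); ev_Q.append(pos)
            clock += dwell
        if clock >= duration or pure_dwell:
            break
        move_T = max((1.0 - profile.idle_fraction) * cycle * rng.uniform(0.7, 1.3), 2 * dt)
        amp = rng.lognormal(np.log(profile.submovement_amplitude), profile.amplitude_spread) \
            if profile.submovement_amplitude > 0 else 0.0
        target, theta = _draw_target(rng, axis_length, pos[0], amp,
                                     profile.hover_radius_bias, theta)
        ev_t0.append(clock); ev_T.append(move_T); ev_P.append(pos); ev_Q.append(target)
        move_starts.append((clock, move_T))
        pos = target
        clock += move_T
    ev_t0 = np.asarray(ev_t0); ev_T = np.asarray(ev_T)
    ev_P = np.asarray(ev_P); ev_Q = np.asarray(ev_Q)

    # --- evaluate minimum-jerk profiles vectorized over frames -------------
    tau = t - t0
    k = np.clip(np.searchsorted(ev_t0, tau, side="right") - 1, 0, len(ev_t0) - 1)
    s = np.clip((tau - ev_t0[k]) / ev_T[k], 0.0, 1.0)
    h = s**3 * (10.0 - 15.0 * s + 6.0 * s**2)
    clean = ev_P[k] + h[:, None] * (ev_Q[k] - ev_P[k])
    xyz = clean + rng.normal(0.0, profile.noise_sigma, size=clean.shape)

    # --- jaw schedule ------------------------------------------------------
    jaw = None
    if profile.n_open_close > 0:
        if len(move_starts) < profile.n_open_close:
            raise ConfigurationError(
                f"schedule infeasible: {profile.n_open_close} jaw cycles but only "
                f"{len(move_starts)} movements in {duration} s"
            )
        jaw = np.full(n, 0.1)
        chosen = rng.choice(len(move_starts), size=profile.n_open_close, replace=False)
        for ci in sorted(chosen):
            c0, cT = move_starts[ci]
            width = min(max(0.6 * cT, 4 * dt), cT)
            i0 = int(round((c0 - 0.0) / dt))
            i1 = min(i0 + max(int(round(width / dt)), 3), n)
            ph = np.linspace(0.0, np.pi, i1 - i0)
            jaw[i0:i1] = np.maximum(jaw[i0:i1], 0.1 + 0.8 * np.sin(ph) ** 2)
        jaw = np.clip(jaw + rng.normal(0.0, 0.02, size=n), 0.0, 1.0)

    # --- insertion schedule ------------------------------------------------
    inside = np.ones(n, dtype=bool)
    episodes: list[tuple[float, float]] = []
    if profile.n_insertions > 0:
        k_ins = profile.n_insertions
        ep_dur = np.maximum(
            rng.normal(profile.insertion_duration, 0.08 * profile.insertion_duration, k_ins),
            1.0,
        )
        gap_total = duration - ep_dur.sum()
        if gap_total <= k_ins:  # need >1 s of outside time around episodes
            raise ConfigurationError("schedule infeasible: insertions exceed duration")
        gaps = rng.dirichlet(np.ones(k_ins + 1)) * gap_total
        gaps = np.maximum(gaps, 1.0)
        gaps *= gap_total / gaps.sum()
        inside[:] = False
        clock2 = 0.0
        for i in range(k_ins):
            clock2 += gaps[i]
            a = int(round(clock2 / dt))
            b = min(int(round((clock2 + ep_dur[i]) / dt)), n - 1)
            inside[a : b + 1] = True
            episodes.append((t0 + a * dt, t0 + b * dt))
            clock2 += ep_dur[i]

    track = InstrumentTrack(
        instrument_id=instrument, hand=hand, t=t, pos=xyz, jaw=jaw, inside=inside
    )
    truth = {
        "n_open_close": int(profile.n_open_close),
        "insertion_episodes": episodes,
        "idle_fraction": profile.idle_fraction,
        "clean_pos": clean,
        "profile": profile,
    }
    return track, truth


def simulate_session(
    profiles: dict[str, SkillProfile],
    participant_id: str = "P00",
    task: str = "task1",
    sample_rate: float = 100.0,
    seed: int | np.random.Generator = 0,
    hands: dict[str, str] | None = None,
) -> SimulatedSession:
    """Simulate one session: an anchor recording plus one track per instrument.

    ``profiles`` maps instrument id -> :class:`SkillProfile`. The anchor track
    holds the tip for 5 s on each of the two axis endpoints (0,0,0) and
    (17.5,0,0); task tracks start after the anchor recording.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt = 1.0 / sample_rate
    # anchor recording: two 5-s dwells
    na = int(round(2 * ANCHOR_DWELL * sample_rate)) + 1
    ta = dt * np.arange(na)
    pa = np.zeros((na, 3))
    p_end = np.array([ANCHOR_SEPARATION, 0.0, 0.0])
    pa[ta >= ANCHOR_DWELL] = p_end
    pa += rng.normal(0.0, 0.05, size=pa.shape)
    anchor_track = InstrumentTrack("anchor", "right", ta, pa)
    windows = [
        AnchorWindow(0.2, ANCHOR_DWELL - 0.2),
        AnchorWindow(ANCHOR_DWELL + 0.2, 2 * ANCHOR_DWELL - 0.2),
    ]
    axis = WorkingAxis((0.0, 0.0, 0.0), tuple(p_end))

    t_task0 = 2 * ANCHOR_DWELL + 1.0
    tracks, truth = {}, {}
    hands = hands or {}
    for instrument, prof in profiles.items():
        tr, gt = simulate_track(
            prof,
            sample_rate=sample_rate,
            seed=rng,
            instrument=instrument,
            hand=hands.get(instrument, "left" if instrument == "grasper" else "right"),
            t0=t_task0,
        )
        tracks[instrument] = tr
        truth[instrument] = gt
    return SimulatedSession(
        participant_id=participant_id,
        task=task,
        tracks=tracks,
        anchor_track=anchor_track,
        anchor_windows=windows,
        axis=axis,
        sample_rate_hz=sample_rate,
        truth=truth,
    )


def _jitter_profile(
    profile: SkillProfile, rng: np.random.Generator, sigma: float
) -> SkillProfile:
    """Lognormal multiplicative between-participant variation.

    Movement tempo and reach extent vary less between participants of one
    skill level (0.5 sigma) than pausing and hovering behaviour (full sigma).
    """
    if sigma == 0:
        return profile
    f = lambda s=1.0: float(rng.lognormal(0.0, sigma * s))  # noqa: E731
    return replace(
        profile,
        submovement_rate=profile.submovement_rate * f(0.5),
        submovement_amplitude=profile.submovement_amplitude * f(0.5),
        idle_fraction=min(profile.idle_fraction * f(), 0.9),
        hover_radius_bias=profile.hover_radius_bias * f(),
        insertion_duration=profile.insertion_duration * f(),
    )


def simulate_cohort(
    n_per_group: dict[str, int] | None = None,
    profiles: dict[str, dict[str, SkillProfile]] | None = None,
    seed: int = 0,
    jitter_sigma: float = 0.15,
    instruments: tuple[str, ...] = ("scissors",),
    sample_rate: float = 100.0,
    task: str = "task1",
) -> tuple[list[SimulatedSession], list[ParticipantMeta]]:
    """Simulate a full skill-stratified cohort.

    Defaults to the study composition (18 novices, 12 intermediates, 15
    experts), the task-1-like group profiles of :func:`default_profiles`, and
    multiplicative lognormal per-participant jitter (sigma 0.15) around the
    group profile. Returns sessions plus participant metadata whose case
    counts are drawn inside each group's defining range.
    """
    n_per_group = dict(DEFAULT_GROUP_SIZES if n_per_group is None else n_per_group)
    if profiles is None:
        profiles = {ins: default_profiles(ins) for ins in instruments}
    rng = np.random.default_rng(seed)
    case_ranges = {"novice": (0, 10), "intermediate": (10, 50), "expert": (50, 400)}
    sessions, meta = [], []
    pid = 0
    for group in ("novice", "intermediate", "expert"):
        for _ in range(n_per_group.get(group, 0)):
            pid += 1
            participant = f"P{pid:03d}"
            per_instrument = {
                ins: _jitter_profile(profiles[ins][group], rng, jitter_sigma)
                for ins in instruments
            }
            sessions.append(
                simulate_session(
                    per_instrument,
                    participant_id=participant,
                    task=task,
                    sample_rate=sample_rate,
                    seed=rng,
                )
            )
            lo, hi = case_ranges[group]
            meta.append(ParticipantMeta(participant, int(rng.integers(lo, hi))))
    return sessions, meta


def write_cohort(
    sessions: list[SimulatedSession],
    meta: list[ParticipantMeta],
    out_dir: str | Path,
) -> None:
    """Write a cohort to disk in the standard session layout.

    One directory per participant with track CSVs, the anchor CSV and a YAML
    manifest, plus a cohort-level ``participants.csv`` — byte-identical in
    format to a real ingested session, so the pipeline is agnostic to origin.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in sessions:
        d = out_dir / s.participant_id
        d.mkdir(exist_ok=True)
        refs = []
        for ins, tr in s.tracks.items():
            fname = f"{s.task}_{ins}.csv"
            write_track(tr, d / fname)
            refs.append(TrackRef(file=fname, instrument=ins, hand=tr.hand))
        write_track(s.anchor_track, d / f"{s.task}_anchors.csv")
        SessionManifest(
            participant_id=s.participant_id,
            task=s.task,
            sample_rate_hz=s.sample_rate_hz,
            tracks=refs,
            anchor_file=f"{s.task}_anchors.csv",
            anchor_windows=s.anchor_windows,
        ).to_yaml(d / f"{s.task}_manifest.yaml")
    pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in meta],
            "n_surgeries": [m.n_surgeries for m in meta],
        }
    ).to_csv(out_dir / "participants.csv", index=False)
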