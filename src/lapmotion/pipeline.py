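"""End-to-end orchestration: ingest -> kinematics -> zones -> events -> stats.

A single :class:`PipelineConfig` carries every tunable constant (filter
settings, band and zone edges, event thresholds, significance level); the
defaults are the study values, and identical inputs plus an identical config
always produce identical outputs. Sessions failing validation are reported in
the run log and skipped, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortResult,
    assemble_metric_table,
    metric_table_to_wide,
    select_and_project,
)
from .errors import LapMotionError, UndefinedMetricError
from .events import count_open_close, insertion_segments
from .io import (
    InstrumentTrack,
    SessionManifest,
    fill_gaps,
    read_participant_table,
    read_track,
)
from .kinematics import (
    SGConfig,
    VelocityBands,
    operative_time,
    path_length,
    sg_smooth,
)
from .zones import WorkingAxis, ZoneEdges, fit_working_axis, zone_distribution

__all__ = ["PipelineConfig", "process_session", "run_pipeline", "session_metrics"]


@dataclass
class PipelineConfig:
    """All pipeline constants; defaults are the study's stated values."""

    sg_poly_order: int = 3
    sg_window_frames: int = 31
    band_edges: tuple[float, ...] = (0.0, 0.5, 2.0, 5.0, 12.0)
    band_labels: tuple[str, ...] = ("idle", "low", "middle", "high", "very_high")
    zone_edges: tuple[float, ...] = (0.0, 2.0, 4.0)
    zone_labels: tuple[str, ...] = ("close", "near", "far")
    jaw_open_thresh: float = 0.6
    jaw_close_thresh: float = 0.4
    min_episode: float = 0.5
    max_gap: float = 0.2
    alpha: float = 0.05
    pca_exclusions: tuple[str, ...] = ()
    seed: int = 0

    @property
    def sg(self) -> SGConfig:
        return SGConfig(self.sg_poly_order, self.sg_window_frames)

    @property
    def bands(self) -> VelocityBands:
        return VelocityBands(tuple(self.band_edges), tuple(self.band_labels))

    @property
    def zones(self) -> ZoneEdges:
        return ZoneEdges(tuple(self.zone_edges), tuple(self.zone_labels))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        raw = {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def session_metrics(
    tracks: dict[str, InstrumentTrack],
    axis: WorkingAxis,
    cfg: PipelineConfig = PipelineConfig(),
    sample_rate: float | None = None,
) -> tuple[dict[str, dict[str, float | None]], list[str]]:
    """Compute the full metric set for one session.

    Returns ``(metrics, warnings)`` where ``metrics`` maps instrument ->
    metric name -> value (``None`` for undefined metrics, e.g. a jaw count on
    an instrument without a jaw channel). Percentages are on the 0-100 scale;
    path length is metres; the session-level operative time is attached under
    the pseudo-instrument ``"task"``.
    """
    notes: list[str] = []
    out: dict[str, dict[str, float | None]] = {}
    out["task"] = {"operative_time_s": operative_time(list(tracks.values()))}
    for name, track in tracks.items():
        m: dict[str, float | None] = {}
        segments = fill_gaps(track, cfg.max_gap)
        if len(segments) > 1:
            notes.append(f"{name}: split into {len(segments)} segments at long gaps")
        usable = []
        for seg in segments:
            if seg.n_frames < cfg.sg_window_frames:
                notes.append(f"{name}: dropped segment of {seg.n_frames} frames (< window)")
                continue
            series = sg_smooth(seg, cfg.sg, sample_rate=sample_rate)
            usable.append((seg, series))
        if not usable:
            notes.append(f"{name}: no segment long enough; kinematics undefined")
            out[name] = {}
            continue

        m["path_length_m"] = sum(path_length(s, seg.inside) for seg, s in usable)

        norms = [
            (np.linalg.norm(s.d1[s.valid], axis=1),
             np.linalg.norm(s.d2[s.valid], axis=1),
             np.linalg.norm(s.d3[s.valid], axis=1))
            for _, s in usable
        ]
        v = np.concatenate([x[0] for x in norms])
        a = np.concatenate([x[1] for x in norms])
        j = np.concatenate([x[2] for x in norms])
        m["velocity_cm_s"] = float(v.mean())
        m["acceleration_cm_s2"] = float(a.mean())
        m["jerk_cm_s3"] = float(j.mean())

        edges = np.asarray(cfg.band_edges + (np.inf,))
        counts = np.array(
            [np.count_nonzero((v >= lo) & (v < hi)) for lo, hi in zip(edges[:-1], edges[1:])],
            float,
        )
        for lab, c in zip(cfg.band_labels, counts / v.size):
            m[f"{lab}_velocity_pct"] = float(100.0 * c)

        # zone distribution aggregated over segments by path length
        zl = np.zeros(len(cfg.zone_labels))
        any_path = False
        for seg, s in usable:
            try:
                frac = zone_distribution(s, axis, seg.inside, cfg.zones)
            except UndefinedMetricError:
                continue
            zl += frac * path_length(s, seg.inside)
            any_path = True
        if any_path and zl.sum() > 0:
            for lab, c in zip(cfg.zone_labels, zl / zl.sum()):
                m[f"{lab}_zone_pct"] = float(100.0 * c)
        else:
            for lab in cfg.zone_labels:
                m[f"{lab}_zone_pct"] = None
            notes.append(f"{name}: zero in-box path length; zone metrics undefined")

        if track.jaw is not None:
            m["open_close_count"] = float(
                count_open_close(track.jaw, cfg.jaw_open_thresh, cfg.jaw_close_thresh)
            )
        else:
            m["open_close_count"] = None

        episodes = insertion_segments(track.inside, track.t, cfg.min_episode)
        if not track.inside.all() and episodes:
            m["avg_inserting_time_s"] = float(np.mean([b - a for a, b in episodes]))
        else:
            m["avg_inserting_time_s"] = None
        out[name] = m
    return out, notes


def process_session(
    manifest: SessionManifest, root: str | Path, cfg: PipelineConfig = PipelineConfig()
) -> tuple[dict[str, dict[str, float | None]], list[str]]:
    """Load a session from disk per its manifest and compute all metrics."""
    root = Path(root)
    anchor = read_track(root / manifest.anchor_file, "anchor", "right",
                        manifest.units, manifest.time_units)
    wa, wb = manifest.anchor_windows
    win_a = anchor.pos[(anchor.t >= wa.start) & (anchor.t <= wa.end)]
    win_b = anchor.pos[(anchor.t >= wb.start) & (anchor.t <= wb.end)]
    axis = fit_working_axis(win_a, win_b)
    tracks = {
        ref.instrument: read_track(
            root / ref.file, ref.instrument, ref.hand, manifest.units, manifest.time_units
        )
        for ref in manifest.tracks
    }
    return session_metrics(tracks, axis, cfg, sample_rate=manifest.sample_rate_hz)


def run_pipeline(
    data_root: str | Path,
    out_dir: str | Path,
    cfg: PipelineConfig = PipelineConfig(),
) -> CohortResult | None:
    """Run the full analysis over a cohort directory and write the report.

    ``data_root`` holds one directory per participant (track CSVs + a
    ``*_manifest.yaml``) and a ``participants.csv``. Writes ``metrics.csv``
    (long format), ``stats.csv`` (per-metric KW and pairwise p-values),
    ``loadings.csv``/``scores.csv``/``variance.csv`` (PCA) and ``run_log.json``.
    Returns the :class:`~lapmotion.cohort.CohortResult` (``None`` when the
    statistical layer could not run).
    """
    data_root, out_dir = Path(data_root), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = read_participant_table(data_root / "participants.csv")
    groups = pd.Series({m.participant_id: m.group for m in meta})

    records, log_sessions = [], []
    for mpath in sorted(data_root.glob("*/*_manifest.yaml")):
        manifest = SessionManifest.from_yaml(mpath)
        entry = {"participant_id": manifest.participant_id, "task": manifest.task,
                 "manifest": str(mpath.relative_to(data_root)), "warnings": []}
        try:
            metrics, notes = process_session(manifest, mpath.parent, cfg)
        except LapMotionError as exc:
            entry["error"] = f"{type(exc).__name__}: {exc}"
            log_sessions.append(entry)
            warnings.warn(f"session {mpath} skipped: {exc}")
            continue
        entry["warnings"] = notes
        log_sessions.append(entry)
        for instrument, md in metrics.items():
            for metric, value in md.items():
                records.append(
                    dict(participant_id=manifest.participant_id, task=manifest.task,
                         instrument=instrument, metric=metric, value=value)
                )
    table = assemble_metric_table(records)
    table.to_csv(out_dir / "metrics.csv", index=False)

    result = None
    stats_err = None
    try:
        wide = metric_table_to_wide(table).dropna(axis=1, how="any")
        result = select_and_project(
            wide, groups, alpha=cfg.alpha, exclusions=cfg.pca_exclusions
        )
        stats_df = pd.DataFrame({"kw_p": result.kw_p}).join(result.pairwise_p)
        stats_df.to_csv(out_dir / "stats.csv", index_label="metric")
        result.loadings.to_csv(out_dir / "loadings.csv", index_label="metric")
        result.scores.join(groups.rename("group")).to_csv(
            out_dir / "scores.csv", index_label="participant_id"
        )
        pd.DataFrame(
            {"component": [f"PC{i+1}" for i in range(len(result.var_explained))],
             "var_explained": result.var_explained}
        ).to_csv(out_dir / "variance.csv", index=False)
    except LapMotionError as exc:
        stats_err = f"{type(exc).__name__}: {exc}"
        warnings.warn(f"cohort statistics unavailable: {exc}")

    log = {
        "package_version": __version__,
        "config": asdict(cfg),
        "config_digest": cfg.digest(),
        "n_participants": len(meta),
        "n_sessions": len(log_sessions),
        "sessions": log_sessions,
        "stats_error": stats_err,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=list))
    return result
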