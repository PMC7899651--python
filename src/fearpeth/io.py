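"""CSV/YAML file formats and run manifests.

All tables are plain CSV with a header row, times in seconds with a
decimal point.  Schemas (also in ``FORMATS.md`` at the repository root):

=================  ==========================================================
file               columns
=================  ==========================================================
spikes             ``unit_id, time_s`` (sorted per unit)
events             ``label, time_s`` (stimulus or freeze events)
bouts              ``start_s, end_s`` (freezing bouts, sorted, disjoint)
freezing summary   ``epoch, n_obs, percent_freezing`` (blank when undefined)
classification     ``unit_id, label, responsive, direction, supra_bins``
group summary      ``group, label, n_responsive, n_total, percent``
comparisons        ``group_a, group_b, a, b, c, d, p_two_sided``
=================  ==========================================================

Configuration is YAML; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import BehaviorTrace, FreezeEventSeries, FreezingSummary
from .perievent import ResponsivenessCall, SpikeTrain
from .protocol import (
    EventLabel,
    ProtocolKind,
    SessionProtocol,
    SessionTimeline,
    StimulusEvent,
)

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_events",
    "write_events",
    "read_bouts",
    "write_bouts",
    "read_timeline",
    "write_timeline",
    "write_freezing_summary",
    "write_freeze_events",
    "write_classification",
    "read_classification",
    "RunManifest",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending row."""


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _check_times(path, df: pd.DataFrame, col: str) -> None:
    bad = df.index[df[col].isna() | (df[col] < 0)]
    if len(bad):
        # +2: header row plus 1-based numbering
        raise FormatError(f"{path}: invalid {col} at line {bad[0] + 2}")


def _roundtrip_str(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Render float columns with shortest round-trip repr (to_csv truncates)."""
    df = df.copy()
    for c in cols:
        df[c] = df[c].map(lambda v: repr(float(v)))
    return df


def read_spikes(path, session_dur: float | None = None) -> dict[str, SpikeTrain]:
    """Read a spikes CSV into per-unit trains.

    ``session_dur`` defaults to just past the last spike; pass the
    timeline's ``total_dur`` for real sessions.  Timestamps must be sorted
    within each unit.
    """
    df = _read_csv(path, ["unit_id", "time_s"])
    _check_times(path, df, "time_s")
    if session_dur is None:
        session_dur = float(df["time_s"].max()) + 1e-9 if len(df) else 1.0
    out: dict[str, SpikeTrain] = {}
    for uid, sub in df.groupby("unit_id", sort=False):
        ts = sub["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(ts) < 0):
            row = sub.index[np.flatnonzero(np.diff(ts) < 0)[0] + 1]
            raise FormatError(f"{path}: unsorted timestamps for unit {uid} at line {row + 2}")
        out[str(uid)] = SpikeTrain(unit_id=str(uid), timestamps=ts, session_dur=session_dur)
    return out


def write_spikes(path, trains: dict[str, SpikeTrain]) -> None:
    rows = [
        {"unit_id": uid, "time_s": t}
        for uid, tr in trains.items()
        for t in tr.timestamps
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "time_s"])
    if len(df):
        df = _roundtrip_str(df, ["time_s"])
    df.to_csv(path, index=False)


def read_events(path) -> list[tuple[str, float]]:
    """Read an events CSV as ordered (label, time_s) tuples."""
    df = _read_csv(path, ["label", "time_s"])
    _check_times(path, df, "time_s")
    return [(str(r.label), float(r.time_s)) for r in df.itertuples()]


def write_events(path, events: list[tuple[str, float]]) -> None:
    df = pd.DataFrame(events, columns=["label", "time_s"])
    if len(df):
        df = _roundtrip_str(df, ["time_s"])
    df.to_csv(path, index=False)


def read_bouts(path, session_dur: float) -> BehaviorTrace:
    df = _read_csv(path, ["start_s", "end_s"])
    _check_times(path, df, "start_s")
    _check_times(path, df, "end_s")
    bouts = tuple((float(r.start_s), float(r.end_s)) for r in df.itertuples())
    return BehaviorTrace(bouts=bouts, session_dur=session_dur)


def write_bouts(path, trace: BehaviorTrace) -> None:
    df = pd.DataFrame(trace.bouts, columns=["start_s", "end_s"])
    if len(df):
        df = _roundtrip_str(df, ["start_s", "end_s"])
    df.to_csv(path, index=False)


def write_timeline(csv_path, timeline: SessionTimeline, config_path=None) -> None:
    """Write a timeline events CSV plus an optional protocol YAML sidecar."""
    write_events(csv_path, [(e.label.value, e.time) for e in timeline.events])
    if config_path is not None:
        p = timeline.protocol
        doc = asdict(p)
        doc["kind"] = p.kind.value
        doc["us_flags"] = list(p.us_flags)
        doc["interval_range"] = list(p.interval_range)
        doc["total_dur"] = timeline.total_dur
        Path(config_path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_timeline(csv_path, config_path) -> SessionTimeline:
    """Rebuild a timeline from its events CSV and protocol sidecar."""
    doc = yaml.safe_load(Path(config_path).read_text())
    total_dur = doc.pop("total_dur")
    doc["kind"] = ProtocolKind(doc["kind"])
    doc["us_flags"] = tuple(doc["us_flags"])
    doc["interval_range"] = tuple(doc["interval_range"])
    protocol = SessionProtocol(**doc)
    events = tuple(
        StimulusEvent(time=t, label=EventLabel(lbl)) for lbl, t in read_events(csv_path)
    )
    return SessionTimeline(protocol=protocol, events=events, total_dur=total_dur)


def write_freezing_summary(path, summary: FreezingSummary) -> None:
    rows = [
        {
            "epoch": ep,
            "n_obs": summary.n_obs[ep],
            "percent_freezing": "" if summary.percent[ep] is None else summary.percent[ep],
        }
        for ep in summary.percent
    ]
    pd.DataFrame(rows, columns=["epoch", "n_obs", "percent_freezing"]).to_csv(path, index=False)


def write_freeze_events(path, series: FreezeEventSeries) -> None:
    rows = [("onset", t) for t in series.onsets] + [("cessation", t) for t in series.cessations]
    rows.sort(key=lambda r: r[1])
    pd.DataFrame(rows, columns=["type", "time_s"]).to_csv(path, index=False)


def write_classification(path, calls: dict[str, ResponsivenessCall]) -> None:
    """Write per-unit, per-alignment calls; skipped labels get responsive=''."""
    rows = []
    for uid in sorted(calls):
        call = calls[uid]
        for label in ("CS_ON", "FREEZE_ON", "FREEZE_OFF"):
            if label in call.calls:
                lc = call.calls[label]
                rows.append(
                    {
                        "unit_id": uid,
                        "label": label,
                        "responsive": lc.responsive,
                        "direction": lc.direction,
                        "supra_bins": ";".join(str(b) for b in lc.supra_bins),
                    }
                )
            else:
                rows.append(
                    {
                        "unit_id": uid,
                        "label": label,
                        "responsive": "",
                        "direction": call.skipped.get(label, "skipped"),
                        "supra_bins": "",
                    }
                )
    pd.DataFrame(rows, columns=["unit_id", "label", "responsive", "direction", "supra_bins"]).to_csv(
        path, index=False
    )


def read_classification(path) -> pd.DataFrame:
    return _read_csv(path, ["unit_id", "label", "responsive", "direction"])


@dataclass
class RunManifest:
    """Provenance record sufficient to re-run a pipeline bit-identically."""

    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict]  # stage -> {"inputs": [...], "outputs": [...]}
    exclusions: dict[str, list[str]]

    @staticmethod
    def config_digest(config: dict) -> str:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def new(cls, config: dict, seed: int) -> "RunManifest":
        return cls(
            config_hash=cls.config_digest(config),
            seed=seed,
            version=__version__,
            stages={},
            exclusions={},
        )

    def add_stage(self, name: str, inputs: list[str], outputs: list[str]) -> None:
        self.stages[name] = {"inputs": sorted(inputs), "outputs": sorted(outputs)}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
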