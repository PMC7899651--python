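"""Freezing-behavior scoring and freeze-event extraction.

Freezing (no visible movement except breathing) is represented as sorted,
disjoint, half-open bout intervals ``[start_s, end_s)`` over a session.
Two analyses consume a trace:

* epoch-wise freezing percentage, sampled instantaneously every 5 s,
  ``100 × n_frozen_observations / n_observations`` — the behavioral fear
  readout; and
* freeze onset (movement→freezing) and cessation (freezing→movement)
  event times, used downstream to align single-unit activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import SessionTimeline

__all__ = [
    "BehaviorTrace",
    "FreezingSummary",
    "FreezeEventSeries",
    "score_freezing",
    "extract_freeze_events",
    "DEFAULT_SAMPLE_INTERVAL",
]

#: manual-scoring cadence (seconds)
DEFAULT_SAMPLE_INTERVAL = 5.0


@dataclass(frozen=True)
class BehaviorTrace:
    """Freezing bouts over one session.

    ``bouts`` are half-open ``[start, end)`` intervals of freezing, sorted
    and pairwise disjoint; everything outside them is movement.
    """

    bouts: tuple[tuple[float, float], ...]
    session_dur: float

    def __post_init__(self) -> None:
        prev_end = 0.0
        for i, (s, e) in enumerate(self.bouts):
            if not (0.0 <= s < e <= self.session_dur):
                raise ValueError(f"bout {i} [{s}, {e}) outside [0, {self.session_dur}]")
            if s < prev_end:
                raise ValueError(f"bout {i} overlaps or is unsorted (starts at {s} < {prev_end})")
            prev_end = e

    def is_frozen(self, t: float | np.ndarray) -> np.ndarray:
        """Instantaneous freezing state at time(s) ``t`` (half-open bouts)."""
        t = np.asarray(t, dtype=float)
        starts = np.array([b[0] for b in self.bouts])
        ends = np.array([b[1] for b in self.bouts])
        if starts.size == 0:
            return np.zeros(t.shape, dtype=bool)
        idx = np.searchsorted(starts, t, side="right") - 1
        inside = idx >= 0
        idx = np.clip(idx, 0, None)
        return inside & (t < ends[idx])

    def was_frozen_at(self, t: float | np.ndarray) -> np.ndarray:
        """Left-limit freezing state: True iff some bout ``(s, e]`` contains ``t``.

        This is the state during the instant immediately before ``t`` — the
        reading a periodic observer reports at a scoring tick, so a bout
        running exactly up to the tick still counts as frozen there.
        """
        t = np.asarray(t, dtype=float)
        starts = np.array([b[0] for b in self.bouts])
        ends = np.array([b[1] for b in self.bouts])
        if starts.size == 0:
            return np.zeros(t.shape, dtype=bool)
        idx = np.searchsorted(starts, t, side="left") - 1
        inside = idx >= 0
        idx = np.clip(idx, 0, None)
        return inside & (t <= ends[idx])

    @property
    def total_frozen(self) -> float:
        return float(sum(e - s for s, e in self.bouts))


@dataclass(frozen=True)
class FreezingSummary:
    """Per-epoch freezing percentages.

    ``percent[label]`` is ``None`` when the epoch is shorter than one
    sample interval (zero observations: the percentage is undefined, not 0).
    """

    percent: dict[str, float | None]
    n_obs: dict[str, int]
    n_frozen: dict[str, int]
    sample_interval: float


@dataclass(frozen=True)
class FreezeEventSeries:
    """Freeze onsets/cessations retained for peri-event alignment."""

    onsets: tuple[float, ...]
    cessations: tuple[float, ...]
    exclusion_log: tuple[str, ...] = ()


def _epochs(timeline: SessionTimeline) -> list[tuple[str, float, float]]:
    """Scoring epochs: pre-CS baseline and each CS period."""
    eps = [("baseline", 0.0, timeline.protocol.baseline_dur)]
    for i, (on, off) in enumerate(timeline.cs_periods, start=1):
        eps.append((f"CS{i}", on, off))
    return eps


def score_freezing(
    trace: BehaviorTrace,
    timeline: SessionTimeline,
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
) -> FreezingSummary:
    """Score percentage freezing per epoch by periodic instantaneous sampling.

    For each epoch (pre-CS baseline, each CS period, and the pooled CS
    epoch) the freezing state is read at ``epoch_start + k * sample_interval``
    for ``k = 1 .. floor(epoch_dur / sample_interval)`` — i.e. at the end of
    each scoring interval, taking the left-limit state so a bout running
    exactly up to a tick counts as frozen there — and the percentage is
    ``100 * n_frozen / n_observations``.
    """
    if sample_interval <= 0:
        raise ValueError("sample_interval must be > 0")
    percent: dict[str, float | None] = {}
    n_obs: dict[str, int] = {}
    n_frozen: dict[str, int] = {}
    cs_frozen = 0
    cs_total = 0
    for label, start, end in _epochs(timeline):
        k = int(np.floor((end - start) / sample_interval + 1e-9))
        n_obs[label] = k
        if k == 0:
            percent[label] = None
            n_frozen[label] = 0
            continue
        times = start + sample_interval * np.arange(1, k + 1)
        frozen = int(trace.was_frozen_at(times).sum())
        n_frozen[label] = frozen
        percent[label] = 100.0 * frozen / k
        if label.startswith("CS"):
            cs_frozen += frozen
            cs_total += k
    n_obs["CS_pooled"] = cs_total
    n_frozen["CS_pooled"] = cs_frozen
    percent["CS_pooled"] = 100.0 * cs_frozen / cs_total if cs_total else None
    return FreezingSummary(
        percent=percent, n_obs=n_obs, n_frozen=n_frozen, sample_interval=sample_interval
    )


def extract_freeze_events(
    trace: BehaviorTrace,
    timeline: SessionTimeline,
    pre_window: float = 2.0,
    min_separation: float = 0.0,
) -> FreezeEventSeries:
    """Extract freeze onset and cessation times for peri-event alignment.

    Onsets are bout starts, cessations bout ends.  Events with less than
    ``pre_window`` seconds of session before them cannot carry the shifted
    baseline window and are excluded (and logged); so are events closer
    than ``min_separation`` to the previous retained event of the same
    type.  Exclusions never shift the remaining event times.
    """
    log: list[str] = []

    def _filter(times: list[float], kind: str) -> tuple[float, ...]:
        kept: list[float] = []
        for t in times:
            if t < pre_window:
                log.append(f"{kind} at t={t:g}s excluded: < {pre_window:g}s of session before event")
                continue
            if kept and t - kept[-1] < min_separation:
                log.append(
                    f"{kind} at t={t:g}s excluded: within {min_separation:g}s of previous {kind}"
                )
                continue
            kept.append(t)
        return tuple(kept)

    onsets = _filter([s for s, _ in trace.bouts], "onset")
    cessations = _filter([e for _, e in trace.bouts], "cessation")
    return FreezeEventSeries(onsets=onsets, cessations=cessations, exclusion_log=tuple(log))
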