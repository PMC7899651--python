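"""Conditioning and retrieval session protocols.

A session is a timed sequence of conditioned-stimulus (CS, 30 s white-noise
tone) presentations, a subset of which co-terminate with an unconditioned
stimulus (US, 2 s footshock).  Four standard designs are supported:

``FRF``
    Fully reinforced fear: 3 CS, all paired with the US, 60-90 s variable
    inter-CS interval.
``PRF``
    Partially reinforced fear: 6 CS of which trials 1, 2 and 5 are paired
    (order CS+US, CS+US, CS-noUS, CS-noUS, CS+US, CS-noUS), 15-60 s
    inter-stimulus interval.  PRF and FRF deliver the same number (3) of
    CS-US pairings.
``CS_ONLY``
    6 unpaired CS on the PRF schedule (tone-alone control).
``RETRIEVAL``
    6 unpaired CS, 20-60 s interval, 20 s post period (test session in a
    novel context).

All sessions open with a 180 s stimulus-free baseline.  Times are
real-valued seconds from session start; every interval in the package is
half-open ``[on, off)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProtocolKind",
    "EventLabel",
    "SessionProtocol",
    "StimulusEvent",
    "SessionTimeline",
    "default_protocol",
    "build_timeline",
    "validate_timeline",
]


class ProtocolKind(str, enum.Enum):
    PRF = "PRF"
    FRF = "FRF"
    CS_ONLY = "CS_ONLY"
    RETRIEVAL = "RETRIEVAL"


class EventLabel(str, enum.Enum):
    CS_ON = "CS_ON"
    CS_OFF = "CS_OFF"
    US_ON = "US_ON"
    US_OFF = "US_OFF"


#: canonical order of coincident events (shock offset precedes tone offset so
#: that sorting is deterministic for co-terminating trials)
_TIE_ORDER = {
    EventLabel.CS_ON: 0,
    EventLabel.US_ON: 1,
    EventLabel.US_OFF: 2,
    EventLabel.CS_OFF: 3,
}


@dataclass(frozen=True)
class SessionProtocol:
    """Parameterization of one conditioning or retrieval session."""

    kind: ProtocolKind
    baseline_dur: float = 180.0
    cs_dur: float = 30.0
    cs_count: int = 6
    us_flags: tuple[bool, ...] = ()
    us_dur: float = 2.0
    interval_range: tuple[float, float] = (15.0, 60.0)
    post_dur: float = 120.0
    us_amp_mA: float = 0.6  # metadata only
    cs_level_dB: float = 75.0  # metadata only

    def __post_init__(self) -> None:
        if len(self.us_flags) != self.cs_count:
            raise ValueError(
                f"us_flags has {len(self.us_flags)} entries for cs_count={self.cs_count}"
            )
        lo, hi = self.interval_range
        if lo > hi:
            raise ValueError(f"interval_range min {lo} exceeds max {hi}")
        for name in ("baseline_dur", "cs_dur", "us_dur", "post_dur"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cs_count < 1:
            raise ValueError("cs_count must be >= 1")

    @property
    def n_pairings(self) -> int:
        return sum(self.us_flags)


@dataclass(frozen=True, order=True)
class StimulusEvent:
    """One stimulus edge (tone/shock on or off) at a time in seconds."""

    time: float
    label: EventLabel = field(compare=False)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"event time must be >= 0, got {self.time}")


@dataclass(frozen=True)
class SessionTimeline:
    """Validated realization of a protocol: ordered stimulus events."""

    protocol: SessionProtocol
    events: tuple[StimulusEvent, ...]
    total_dur: float

    def times(self, label: EventLabel | str) -> np.ndarray:
        """Times (s) of all events with the given label, in order."""
        label = EventLabel(label)
        return np.array([e.time for e in self.events if e.label == label])

    @property
    def cs_periods(self) -> list[tuple[float, float]]:
        """Half-open [on, off) intervals of each CS presentation."""
        return list(zip(self.times(EventLabel.CS_ON), self.times(EventLabel.CS_OFF)))


def default_protocol(kind: ProtocolKind | str) -> SessionProtocol:
    """Return the standard parameterization for a session kind.

    Parameters are the behavioral procedure's values: 180 s baseline, 30 s /
    75 dB CS, 2 s / 0.6 mA US co-terminating with reinforced trials, 120 s
    post period after conditioning and 20 s after retrieval.
    """
    kind = ProtocolKind(kind)
    if kind is ProtocolKind.FRF:
        return SessionProtocol(
            kind=kind,
            cs_count=3,
            us_flags=(True, True, True),
            interval_range=(60.0, 90.0),
        )
    if kind is ProtocolKind.PRF:
        return SessionProtocol(
            kind=kind,
            cs_count=6,
            us_flags=(True, True, False, False, True, False),
            interval_range=(15.0, 60.0),
        )
    if kind is ProtocolKind.CS_ONLY:
        # tone-alone control on the PRF schedule, no shocks
        return SessionProtocol(
            kind=kind,
            cs_count=6,
            us_flags=(False,) * 6,
            interval_range=(15.0, 60.0),
        )
    if kind is ProtocolKind.RETRIEVAL:
        return SessionProtocol(
            kind=kind,
            cs_count=6,
            us_flags=(False,) * 6,
            interval_range=(20.0, 60.0),
            post_dur=20.0,
        )
    raise ValueError(f"unknown protocol kind: {kind!r}")  # pragma: no cover


def build_timeline(protocol: SessionProtocol, seed: int) -> SessionTimeline:
    """Realize a protocol as a concrete event schedule.

    Inter-trial intervals (CS offset to next CS onset) are drawn i.i.d.
    uniform on ``interval_range`` from a generator seeded with ``seed``, so
    identical ``(protocol, seed)`` gives an identical timeline.
    """
    rng = np.random.default_rng(seed)
    events: list[StimulusEvent] = []
    cs_on = protocol.baseline_dur
    for i in range(protocol.cs_count):
        cs_off = cs_on + protocol.cs_dur
        events.append(StimulusEvent(cs_on, EventLabel.CS_ON))
        if protocol.us_flags[i]:
            # shock co-terminates with the tone
            events.append(StimulusEvent(cs_off - protocol.us_dur, EventLabel.US_ON))
            events.append(StimulusEvent(cs_off, EventLabel.US_OFF))
        events.append(StimulusEvent(cs_off, EventLabel.CS_OFF))
        if i + 1 < protocol.cs_count:
            cs_on = cs_off + rng.uniform(*protocol.interval_range)
    events.sort(key=lambda e: (e.time, _TIE_ORDER[e.label]))
    total_dur = events[-1].time + protocol.post_dur
    return SessionTimeline(protocol=protocol, events=tuple(events), total_dur=total_dur)


def validate_timeline(timeline: SessionTimeline, atol: float = 1e-9) -> list[str]:
    """Check every timeline invariant; return human-readable violations.

    An empty list means the timeline is internally consistent with its
    protocol: events sorted, CS on/off paired at ``cs_dur`` spacing,
    reinforced trials co-terminated, first CS at the end of baseline,
    inter-trial gaps inside ``interval_range``, and ``total_dur`` equal to
    the last event time plus ``post_dur``.
    """
    p = timeline.protocol
    out: list[str] = []
    ev = timeline.events
    for i in range(1, len(ev)):
        if ev[i].time < ev[i - 1].time - atol:
            out.append(f"ordering: event {i} at t={ev[i].time} precedes event {i - 1}")
    cs_on = timeline.times(EventLabel.CS_ON)
    cs_off = timeline.times(EventLabel.CS_OFF)
    us_on = timeline.times(EventLabel.US_ON)
    us_off = timeline.times(EventLabel.US_OFF)
    if len(cs_on) != p.cs_count or len(cs_off) != p.cs_count:
        out.append(
            f"cs_count: expected {p.cs_count} CS_ON/CS_OFF pairs, "
            f"found {len(cs_on)}/{len(cs_off)}"
        )
    n_pair = min(len(cs_on), len(cs_off))
    for i in range(n_pair):
        if abs(cs_off[i] - cs_on[i] - p.cs_dur) > atol:
            out.append(f"cs_duration: trial {i} CS lasts {cs_off[i] - cs_on[i]} != {p.cs_dur}")
    if len(cs_on) and abs(cs_on[0] - p.baseline_dur) > atol:
        out.append(f"baseline: first CS_ON at {cs_on[0]} != baseline_dur {p.baseline_dur}")
    lo, hi = p.interval_range
    for i in range(1, n_pair):
        gap = cs_on[i] - cs_off[i - 1]
        if not (lo - atol <= gap <= hi + atol):
            out.append(f"interval: gap before trial {i} is {gap}, outside [{lo}, {hi}]")
    flagged = [i for i, f in enumerate(p.us_flags) if f]
    if len(us_on) != len(flagged) or len(us_off) != len(flagged):
        out.append(
            f"us_count: expected {len(flagged)} US_ON/US_OFF, "
            f"found {len(us_on)}/{len(us_off)}"
        )
    else:
        for j, i in enumerate(flagged):
            if i >= n_pair:
                continue
            if abs(us_off[j] - cs_off[i]) > atol:
                out.append(
                    f"co-termination: trial {i} US_OFF at {us_off[j]} != CS_OFF {cs_off[i]}"
                )
            if abs(us_off[j] - us_on[j] - p.us_dur) > atol:
                out.append(f"us_duration: trial {i} US lasts {us_off[j] - us_on[j]} != {p.us_dur}")
    if ev and abs(timeline.total_dur - (ev[-1].time + p.post_dur)) > atol:
        out.append(
            f"total_dur: {timeline.total_dur} != last event {ev[-1].time} + post {p.post_dur}"
        )
    return out
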