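"""Seeded synthetic sessions: spike trains and freeze/move behavior.

The generator stands in for recorded infralimbic (IL) single units.  Each
unit fires as an inhomogeneous Poisson process whose rate is a baseline
(cortical-like, log-normal across units, ~1-5 Hz) multiplied by boxcar
modulations locked to events — CS onset, freeze onset, or freeze
cessation.  Behavior is a two-state (move/freeze) continuous-time Markov
chain whose transition rates switch when the CS is on, producing
CS-evoked freezing.

Spike realizations use thinning against the maximum rate, which is exact
for the piecewise-constant rate functions used here.  Everything is
reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import BehaviorTrace
from .protocol import (
    EventLabel,
    ProtocolKind,
    SessionTimeline,
    build_timeline,
    default_protocol,
)

__all__ = [
    "RateModulation",
    "UnitSpec",
    "BehaviorModelParams",
    "GroupDesign",
    "CohortDesign",
    "CohortData",
    "simulate_spike_train",
    "simulate_behavior",
    "simulate_cohort",
]

#: alignment labels a modulation (and the classifier) can target
MOD_LABELS = ("CS_ON", "FREEZE_ON", "FREEZE_OFF")


@dataclass(frozen=True)
class RateModulation:
    """Boxcar rate change locked to an event type.

    During ``[event + latency, event + latency + duration)`` the unit's
    rate is multiplied by ``multiplier`` (>1 excites, <1 suppresses).
    """

    event_label: str
    multiplier: float
    latency: float = 0.0
    duration: float = 0.5

    def __post_init__(self) -> None:
        if self.event_label not in MOD_LABELS:
            raise ValueError(f"event_label must be one of {MOD_LABELS}")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.latency < 0:
            raise ValueError("latency must be >= 0")


@dataclass(frozen=True)
class UnitSpec:
    """One synthetic unit: baseline rate plus event-locked modulations."""

    unit_id: str
    baseline_rate: float
    modulations: tuple[RateModulation, ...] = ()

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")


@dataclass(frozen=True)
class BehaviorModelParams:
    """Two-state freeze/move chain rates (per second), CS-conditional.

    Defaults give modest spontaneous freezing outside the CS and a strong
    CS-driven shift toward freezing, with bouts a few seconds long.
    """

    move_to_freeze_cs: float = 0.30
    freeze_to_move_cs: float = 0.05
    move_to_freeze_off: float = 0.02
    freeze_to_move_off: float = 0.25
    min_bout: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "move_to_freeze_cs",
            "freeze_to_move_cs",
            "move_to_freeze_off",
            "freeze_to_move_off",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_bout < 0:
            raise ValueError("min_bout must be >= 0")


def _modulation_event_times(
    mod: RateModulation, timeline: SessionTimeline, behavior: BehaviorTrace | None
) -> np.ndarray:
    if mod.event_label == "CS_ON":
        return timeline.times(EventLabel.CS_ON)
    if behavior is None:
        raise ValueError(f"{mod.event_label} modulation requires a behavior trace")
    if mod.event_label == "FREEZE_ON":
        return np.array([s for s, _ in behavior.bouts])
    return np.array([e for _, e in behavior.bouts])


def _rate_function(
    unit: UnitSpec, timeline: SessionTimeline, behavior: BehaviorTrace | None
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant rate λ(t) as (breakpoints, rates).

    ``rates[i]`` applies on ``[breakpoints[i], breakpoints[i+1])``; the
    final rate applies to the end of the session.
    """
    T = timeline.total_dur
    # accumulate log-multiplier edges so overlapping boxcars compose by product
    edges: list[tuple[float, float]] = [(0.0, 0.0)]
    for mod in unit.modulations:
        for t0 in _modulation_event_times(mod, timeline, behavior):
            a = t0 + mod.latency
            b = a + mod.duration
            if a >= T or b <= 0:
                continue
            edges.append((max(a, 0.0), np.log(mod.multiplier)))
            if b < T:
                edges.append((min(b, T), -np.log(mod.multiplier)))
    edges.sort()
    times = np.array([t for t, _ in edges])
    logm = np.cumsum([dl for _, dl in edges])
    bps, idx = np.unique(times, return_index=True)
    # at a repeated breakpoint the last cumulative value wins
    last_idx = np.append(idx[1:], len(times)) - 1
    rates = unit.baseline_rate * np.exp(logm[last_idx])
    return bps, rates


@dataclass(frozen=True)
class SpikeTrainData:
    """Sorted spike timestamps for one unit (seconds from session start)."""

    unit_id: str
    timestamps: np.ndarray
    session_dur: float


def simulate_spike_train(
    unit: UnitSpec,
    timeline: SessionTimeline,
    behavior: BehaviorTrace | None,
    seed: int,
) -> SpikeTrainData:
    """Realize an inhomogeneous Poisson spike train by thinning.

    λ(t) = baseline_rate × ∏ active boxcar multipliers.  A homogeneous
    candidate process at λ_max is thinned with acceptance probability
    λ(t)/λ_max — exact for the piecewise-constant λ used here.  Identical
    inputs and seed give identical output.
    """
    rng = np.random.default_rng(seed)
    bps, rates = _rate_function(unit, timeline, behavior)
    T = timeline.total_dur
    lam_max = float(rates.max())
    n = rng.poisson(lam_max * T)
    cand = np.sort(rng.uniform(0.0, T, size=n))
    lam_at = rates[np.searchsorted(bps, cand, side="right") - 1]
    keep = rng.uniform(0.0, lam_max, size=n) < lam_at
    return SpikeTrainData(unit_id=unit.unit_id, timestamps=cand[keep], session_dur=T)


def simulate_behavior(
    timeline: SessionTimeline, params: BehaviorModelParams, seed: int
) -> BehaviorTrace:
    """Realize freeze/move behavior as a CS-conditional two-state chain.

    Within each span where the CS status is constant the chain is
    homogeneous, so holding times are exponential; at a CS boundary the
    clock is simply re-drawn (valid by memorylessness).  Afterwards, any
    freeze or move segment shorter than ``min_bout`` is absorbed into its
    surrounding state, shortest first.
    """
    rng = np.random.default_rng(seed)
    T = timeline.total_dur
    cs = timeline.cs_periods

    def in_cs(t: float) -> bool:
        return any(on <= t < off for on, off in cs)

    boundaries = sorted({b for p in cs for b in p if 0.0 < b < T} | {T})
    # segments of (state, start, end); state 0 = move, 1 = freeze
    state = 0
    t = 0.0
    seg_states: list[int] = []
    seg_edges: list[float] = [0.0]
    bi = 0
    while t < T:
        while bi < len(boundaries) and boundaries[bi] <= t:
            bi += 1
        t_next = boundaries[bi] if bi < len(boundaries) else T
        if state == 0:
            rate = params.move_to_freeze_cs if in_cs(t) else params.move_to_freeze_off
        else:
            rate = params.freeze_to_move_cs if in_cs(t) else params.freeze_to_move_off
        dwell = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        if t + dwell < t_next:
            t = t + dwell
            seg_states.append(state)
            seg_edges.append(t)
            state = 1 - state
        else:
            t = t_next
    seg_states.append(state)
    seg_edges.append(T)

    segs = [
        [seg_states[i], seg_edges[i], seg_edges[i + 1]]
        for i in range(len(seg_states))
        if seg_edges[i + 1] > seg_edges[i]
    ]
    # merge sub-min_bout segments (shortest first) into the surrounding state
    while len(segs) > 1:
        durs = [s[2] - s[1] for s in segs]
        j = int(np.argmin(durs))
        if durs[j] >= params.min_bout:
            break
        if j == 0:
            segs[1][1] = segs[0][1]
            del segs[0]
        elif j == len(segs) - 1:
            segs[-2][2] = segs[-1][2]
            del segs[-1]
        else:
            # absorbing an interior segment fuses its two same-state neighbors
            segs[j - 1][2] = segs[j + 1][2]
            del segs[j : j + 2]
    bouts = tuple((s[1], s[2]) for s in segs if s[0] == 1)
    return BehaviorTrace(bouts=bouts, session_dur=T)


@dataclass(frozen=True)
class GroupDesign:
    """One experimental group of synthetic units.

    ``fraction_cs_on`` / ``fraction_freeze_off`` of the units (floor rule)
    carry a CS-onset / freeze-cessation boxcar with ``effect_multiplier``;
    freeze-onset-modulated units (rate decrease) can be requested via
    ``fraction_freeze_on`` with ``freeze_on_multiplier`` < 1.
    """

    group_label: str
    n_units: int
    mean_rate_hz: float = 3.0
    rate_sigma_log: float = 0.4
    fraction_cs_on: float = 0.0
    fraction_freeze_off: float = 0.0
    fraction_freeze_on: float = 0.0
    effect_multiplier: float = 3.0
    freeze_on_multiplier: float = 0.33

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for name in ("fraction_cs_on", "fraction_freeze_off", "fraction_freeze_on"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class CohortDesign:
    """Full synthetic experiment: groups, behavior model, session, seed."""

    groups: tuple[GroupDesign, ...]
    behavior_params: BehaviorModelParams = BehaviorModelParams()
    protocol_kind: ProtocolKind = ProtocolKind.RETRIEVAL
    seed: int = 0


@dataclass(frozen=True)
class GroupData:
    group_label: str
    timeline: SessionTimeline
    behavior: BehaviorTrace
    units: tuple[UnitSpec, ...]
    spikes: tuple[SpikeTrainData, ...]
    truth: dict[str, tuple[str, ...]]  # unit_id -> ground-truth modulation labels


@dataclass(frozen=True)
class CohortData:
    design: CohortDesign
    groups: tuple[GroupData, ...]


def _draw_baseline_rates(
    rng: np.random.Generator, n: int, mean_hz: float, sigma_log: float
) -> np.ndarray:
    """Log-normal rates with arithmetic mean ``mean_hz``."""
    mu = np.log(mean_hz) - 0.5 * sigma_log**2
    return rng.lognormal(mean=mu, sigma=sigma_log, size=n)


def simulate_cohort(design: CohortDesign) -> CohortData:
    """Generate every group's timeline, behavior, units and spike trains.

    Exactly ``floor(fraction * n_units)`` units per group carry each
    requested modulation (CS-modulated units assigned from the front of
    the roster, freeze-modulated from the back).  Ground-truth labels are
    kept for recovery tests.  Fully reproducible from ``design.seed``.
    """
    def derive(*key: int) -> int:
        # SeedSequence keyed on the full path; single-word truncation of
        # spawned children produces correlated streams, keying does not
        return int(np.random.SeedSequence(list(key)).generate_state(1)[0] % 2**31)

    out: list[GroupData] = []
    for gi, g in enumerate(design.groups):
        tl_seed = derive(design.seed, gi, 0)
        timeline = build_timeline(default_protocol(design.protocol_kind), tl_seed)
        bh_seed = derive(design.seed, gi, 1)
        behavior = simulate_behavior(timeline, design.behavior_params, bh_seed)
        rng = np.random.default_rng(derive(design.seed, gi, 2))
        rates = _draw_baseline_rates(rng, g.n_units, g.mean_rate_hz, g.rate_sigma_log)
        n_cs = int(np.floor(g.fraction_cs_on * g.n_units))
        n_foff = int(np.floor(g.fraction_freeze_off * g.n_units))
        n_fon = int(np.floor(g.fraction_freeze_on * g.n_units))
        units: list[UnitSpec] = []
        truth: dict[str, tuple[str, ...]] = {}
        for i in range(g.n_units):
            uid = f"{g.group_label}_u{i:03d}"
            mods: list[RateModulation] = []
            labels: list[str] = []
            if i < n_cs:
                mods.append(RateModulation("CS_ON", g.effect_multiplier))
                labels.append("CS_ON")
            if i >= g.n_units - n_foff:
                mods.append(RateModulation("FREEZE_OFF", g.effect_multiplier))
                labels.append("FREEZE_OFF")
            if n_cs <= i < n_cs + n_fon:
                mods.append(RateModulation("FREEZE_ON", g.freeze_on_multiplier))
                labels.append("FREEZE_ON")
            units.append(
                UnitSpec(unit_id=uid, baseline_rate=float(rates[i]), modulations=tuple(mods))
            )
            truth[uid] = tuple(labels)
        spikes = tuple(
            simulate_spike_train(u, timeline, behavior, derive(design.seed, gi, 3 + i))
            for i, u in enumerate(units)
        )
        out.append(
            GroupData(
                group_label=g.group_label,
                timeline=timeline,
                behavior=behavior,
                units=tuple(units),
                spikes=spikes,
                truth=truth,
            )
        )
    return CohortData(design=design, groups=tuple(out))
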