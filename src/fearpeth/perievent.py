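"""Peri-event spike analysis and unit responsiveness classification.

The core analysis: spikes are aligned to repeated events (CS onset,
freeze onset, freeze cessation), binned in 100 ms bins, trial-averaged,
and z-normalized to a 1 s (10-bin) baseline ending just before the event.
A unit is responsive to an event type when at least two 100 ms bins of
the same sign within the 500 ms following the event exceed ±1.96 z.

For CS alignment the baseline is the 1 s immediately before onset
(−1..0 s); for freeze onset/cessation it is shifted one second earlier
(−2..−1 s) so that the movement transition itself does not contaminate
the baseline.  Units with zero baseline variance are excluded from
classification rather than assigned infinite z scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import FreezeEventSeries
from .protocol import EventLabel, SessionTimeline

__all__ = [
    "SpikeTrain",
    "ClassifierParams",
    "PerieventMatrix",
    "ZScoreProfile",
    "ResponsivenessCall",
    "LabelCall",
    "align_and_bin",
    "zscore_profile",
    "classify_unit",
    "classify_all",
    "mean_rate",
    "peak_response_bin",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike timestamps (seconds from session start) for one unit."""

    unit_id: str
    timestamps: np.ndarray
    session_dur: float

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if ts.size and (np.any(np.diff(ts) < 0) or ts[0] < 0 or ts[-1] >= self.session_dur):
            raise ValueError(
                f"unit {self.unit_id}: timestamps must be sorted within [0, {self.session_dur})"
            )


@dataclass(frozen=True)
class ClassifierParams:
    """Binning and thresholding parameters for the responsiveness rule.

    Defaults implement the standard rule: Δ = 100 ms bins, a 500 ms
    (5-bin) response window, a 10-bin (1 s) baseline, |z| > 1.96 strict,
    and ≥ 2 qualifying same-sign bins.  ``baseline_offset`` is the gap (s)
    between the end of the baseline window and the event: 0 for CS
    alignment, 1 for freeze-aligned events.  ``sd_ddof`` selects the SD
    denominator over baseline bins (1 → n−1, the default).
    """

    bin_width: float = 0.1
    response_window: float = 0.5
    n_baseline_bins: int = 10
    z_threshold: float = 1.96
    min_supra_bins: int = 2
    baseline_offset: float = 0.0
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.response_window <= 0:
            raise ValueError("bin_width and response_window must be > 0")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        n_resp = self.response_window / self.bin_width
        if abs(n_resp - round(n_resp)) > 1e-9:
            raise ValueError("response_window must be an integer multiple of bin_width")
        if self.baseline_offset < 0:
            raise ValueError("baseline_offset must be >= 0")

    @property
    def n_response_bins(self) -> int:
        return round(self.response_window / self.bin_width)

    @property
    def window(self) -> tuple[float, float]:
        """Full analysis window relative to the event: [left, right)."""
        left = -(self.baseline_offset + self.n_baseline_bins * self.bin_width)
        return (left, self.response_window)

    @property
    def bin_edges(self) -> np.ndarray:
        left, right = self.window
        n = round((right - left) / self.bin_width)
        return left + self.bin_width * np.arange(n + 1)

    @property
    def baseline_bins(self) -> np.ndarray:
        """Indices of the 10 baseline bins (the first bins of the window)."""
        return np.arange(self.n_baseline_bins)

    @property
    def response_bins(self) -> np.ndarray:
        """Indices of the response-window bins (the last bins of the window)."""
        n_total = len(self.bin_edges) - 1
        return np.arange(n_total - self.n_response_bins, n_total)


@dataclass(frozen=True)
class PerieventMatrix:
    """Spike counts per retained event × time bin around an event type."""

    unit_id: str
    event_label: str
    counts: np.ndarray  # shape (n_events, n_bins), ints
    bin_edges: np.ndarray  # relative to event, len n_bins + 1
    dropped_events: tuple[str, ...] = ()


@dataclass(frozen=True)
class ZScoreProfile:
    """Trial-averaged, baseline-normalized activity for one unit/event type."""

    unit_id: str
    event_label: str
    mean_counts: np.ndarray  # x̄ per bin (spikes/bin, averaged over events)
    baseline_mean: float
    baseline_sd: float
    z: np.ndarray  # per bin; NaN everywhere when degenerate
    n_events: int

    @property
    def degenerate(self) -> bool:
        return not self.baseline_sd > 0


@dataclass(frozen=True)
class LabelCall:
    """Classification outcome for one unit under one alignment."""

    responsive: bool
    direction: str  # "excited" | "inhibited" | "none"
    supra_bins: tuple[int, ...]  # response-window bin indices (0-based)


@dataclass(frozen=True)
class ResponsivenessCall:
    """Per-alignment calls for a unit; absent labels are in ``skipped``."""

    unit_id: str
    calls: dict[str, LabelCall]
    skipped: dict[str, str] = field(default_factory=dict)  # label -> reason


def align_and_bin(
    spikes: SpikeTrain, event_times, params: ClassifierParams
) -> PerieventMatrix:
    """Count spikes in half-open bins around each event.

    ``counts[i, b]`` is the number of spikes in
    ``[event_i + edge_b, event_i + edge_{b+1})``; the window spans
    ``[−(baseline_offset + 1 s), +response_window)`` relative to the event.
    Events whose window is not fully inside the session are dropped (and
    logged), not truncated.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("empty event list")
    edges = params.bin_edges
    left, right = params.window
    kept: list[float] = []
    dropped: list[str] = []
    for t in event_times:
        if t + left < 0 or t + right > spikes.session_dur:
            dropped.append(
                f"event at t={t:g}s dropped: window [{t + left:g}, {t + right:g}) "
                f"outside session [0, {spikes.session_dur:g})"
            )
        else:
            kept.append(t)
    ts = spikes.timestamps
    counts = np.empty((len(kept), len(edges) - 1), dtype=np.int64)
    for i, t in enumerate(kept):
        idx = np.searchsorted(ts, t + edges, side="left")
        counts[i] = np.diff(idx)
    return PerieventMatrix(
        unit_id=spikes.unit_id,
        event_label="",
        counts=counts,
        bin_edges=edges,
        dropped_events=tuple(dropped),
    )


def zscore_profile(matrix: PerieventMatrix, params: ClassifierParams) -> ZScoreProfile:
    """Trial-average the peri-event matrix and z-normalize to baseline.

    x̄_b is the mean count in bin b across events; μ and σ are the mean and
    SD (``sd_ddof`` denominator, default n−1) of x̄ over the 10 baseline
    bins; z_b = (x̄_b − μ)/σ.  σ = 0 marks the profile degenerate.
    """
    if matrix.counts.shape[0] == 0:
        raise ValueError("no retained events")
    xbar = matrix.counts.mean(axis=0)
    base = xbar[params.baseline_bins]
    mu = float(base.mean())
    sd = float(base.std(ddof=params.sd_ddof))
    z = (xbar - mu) / sd if sd > 0 else np.full_like(xbar, np.nan)
    return ZScoreProfile(
        unit_id=matrix.unit_id,
        event_label=matrix.event_label,
        mean_counts=xbar,
        baseline_mean=mu,
        baseline_sd=sd,
        z=z,
        n_events=matrix.counts.shape[0],
    )


def classify_unit(profile: ZScoreProfile, params: ClassifierParams) -> LabelCall:
    """Apply the threshold-crossing rule to the response window.

    Responsive iff at least ``min_supra_bins`` response bins have
    z > z_threshold (excited) or at least ``min_supra_bins`` have
    z < −z_threshold (inhibited) — strict inequalities, and the qualifying
    bins must all lie on one side.  If both sides qualify, the reported
    direction is that of the bin with the largest |z| (earliest bin on a
    tie); mixed-direction bins never jointly qualify.
    """
    if profile.degenerate:
        raise ValueError(f"unit {profile.unit_id}: degenerate profile (zero baseline SD)")
    zr = profile.z[params.response_bins]
    pos = np.flatnonzero(zr > params.z_threshold)
    neg = np.flatnonzero(zr < -params.z_threshold)
    pos_ok = len(pos) >= params.min_supra_bins
    neg_ok = len(neg) >= params.min_supra_bins
    if not pos_ok and not neg_ok:
        return LabelCall(responsive=False, direction="none", supra_bins=())
    if pos_ok and neg_ok:
        order = np.argsort(-np.abs(zr), kind="stable")
        excited = zr[order[0]] > 0
    else:
        excited = pos_ok
    bins = pos if excited else neg
    return LabelCall(
        responsive=True,
        direction="excited" if excited else "inhibited",
        supra_bins=tuple(int(b) for b in bins),
    )


def classify_all(
    spikes_by_unit: dict[str, SpikeTrain],
    timeline: SessionTimeline,
    freeze_events: FreezeEventSeries,
    params: ClassifierParams | None = None,
) -> dict[str, ResponsivenessCall]:
    """Classify every unit against CS onset, freeze onset and cessation.

    CS alignment uses ``baseline_offset`` 0 (baseline −1..0 s); freeze
    alignments use offset 1 s (baseline −2..−1 s).  The response window is
    [0, 0.5) s after the event in all three.  A unit with no analyzable
    events or a degenerate baseline for a label has that label recorded in
    ``skipped`` with the reason.
    """
    if params is None:
        params = ClassifierParams()
    cs_params = params
    freeze_params = ClassifierParams(
        bin_width=params.bin_width,
        response_window=params.response_window,
        n_baseline_bins=params.n_baseline_bins,
        z_threshold=params.z_threshold,
        min_supra_bins=params.min_supra_bins,
        baseline_offset=1.0,
        sd_ddof=params.sd_ddof,
    )
    alignments = {
        "CS_ON": (timeline.times(EventLabel.CS_ON), cs_params),
        "FREEZE_ON": (np.asarray(freeze_events.onsets), freeze_params),
        "FREEZE_OFF": (np.asarray(freeze_events.cessations), freeze_params),
    }
    out: dict[str, ResponsivenessCall] = {}
    for uid, train in spikes_by_unit.items():
        calls: dict[str, LabelCall] = {}
        skipped: dict[str, str] = {}
        for label, (times, p) in alignments.items():
            if times.size == 0:
                skipped[label] = "no events"
                continue
            mat = align_and_bin(train, times, p)
            if mat.counts.shape[0] == 0:
                skipped[label] = "no events with full window coverage"
                continue
            mat = PerieventMatrix(
                unit_id=mat.unit_id,
                event_label=label,
                counts=mat.counts,
                bin_edges=mat.bin_edges,
                dropped_events=mat.dropped_events,
            )
            prof = zscore_profile(mat, p)
            if prof.degenerate:
                skipped[label] = "degenerate baseline (zero SD)"
                continue
            calls[label] = classify_unit(prof, p)
        out[uid] = ResponsivenessCall(unit_id=uid, calls=calls, skipped=skipped)
    return out


def mean_rate(spikes: SpikeTrain) -> float:
    """Session-wide mean firing rate in Hz."""
    if spikes.session_dur <= 0:
        raise ValueError("session_dur must be > 0")
    return len(spikes.timestamps) / spikes.session_dur


def peak_response_bin(
    profile: ZScoreProfile, params: ClassifierParams | None = None
) -> tuple[int, float, float]:
    """Locate the largest-|z| response bin.

    Returns ``(bin_index, latency_s, z)`` where ``bin_index`` is 0-based
    within the response window, ``latency_s`` is the bin's left edge after
    the event, and ties go to the earliest bin.
    """
    if params is None:
        params = ClassifierParams(baseline_offset=0.0)
    if profile.degenerate:
        raise ValueError("degenerate profile")
    zr = profile.z[params.response_bins]
    b = int(np.argmax(np.abs(zr)))  # argmax returns first maximum: earliest bin
    return b, b * params.bin_width, float(zr[b])
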