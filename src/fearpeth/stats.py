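"""Group-level statistics on responsive-unit counts.

Two operations mirror the unit-level statistics used in this analysis:

* a two-sided Fisher's exact test on 2×2 responsive/non-responsive
  tables, computed by explicit enumeration of the hypergeometric support
  with the probability-ordering convention (the two-sided p is the sum of
  the probabilities of all tables, at fixed margins, no more probable
  than the observed one); and
* a paired t-test for baseline-vs-post-event activity of responsive
  units.

Probabilities are accumulated in log space via ``gammaln``; a relative
tolerance of 1e−12 guards floating-point ties when comparing table
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import t as t_dist

__all__ = [
    "GroupSummary",
    "PairedTResult",
    "fisher_exact_2x2",
    "paired_t",
    "summarize_groups",
    "counts_from_calls",
    "pairwise_comparisons",
]

_REL_TOL = 1e-12


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    event_label: str
    n_responsive: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_responsive <= self.n_total:
            raise ValueError("need 0 <= n_responsive <= n_total")

    @property
    def percent(self) -> float:
        return 100.0 * self.n_responsive / self.n_total


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float | None
    degenerate: bool = False


def _log_hypergeom_pmf(a: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(A = a) for the 2×2 table with row sums r1, r2 and col sum c1."""
    n = r1 + r2

    def lchoose(m, k):
        return gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)

    return lchoose(r1, a) + lchoose(r2, c1 - a) - lchoose(n, c1)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Enumerates every table with the observed margins and sums the
    probabilities of those whose hypergeometric probability does not
    exceed the observed table's (within relative tolerance 1e−12).
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("cell counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, r1, r2, c1)
    logp_obs = float(_log_hypergeom_pmf(np.array([a]), r1, r2, c1)[0])
    # p_k <= p_obs * (1 + tol), compared in log space
    include = logp <= logp_obs + np.log1p(_REL_TOL)
    if include.all():
        return 1.0  # whole support included: the mass sums to 1 exactly
    # log-sum-exp over the included tables
    m = logp[include].max()
    p = float(np.exp(m) * np.exp(logp[include] - m).sum())
    return min(p, 1.0)


def paired_t(baseline, post) -> PairedTResult:
    """Paired t-test on (baseline, post) value pairs.

    t = mean(d) / (sd(d)/√n) with d = post − baseline and the n−1 SD;
    df = n−1; p is two-sided from the t distribution.  Zero-variance
    differences are flagged degenerate and no p is emitted.
    """
    baseline = np.asarray(baseline, dtype=float)
    post = np.asarray(post, dtype=float)
    if baseline.shape != post.shape:
        raise ValueError("baseline and post must be paired (equal length)")
    n = baseline.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = post - baseline
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedTResult(t=np.nan, df=n - 1, p=None, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * t_dist.sf(abs(t), df=n - 1))
    return PairedTResult(t=t, df=n - 1, p=p)


def summarize_groups(
    counts: dict[str, tuple[int, int]], event_label: str = ""
) -> list[GroupSummary]:
    """Build per-group summaries from ``{group: (n_responsive, n_total)}``."""
    out = []
    for g, (k, n) in counts.items():
        if n == 0:
            raise ValueError(f"group {g!r} is empty")
        out.append(GroupSummary(group_label=g, event_label=event_label, n_responsive=k, n_total=n))
    return out


def counts_from_calls(calls_by_group: dict[str, dict], event_label: str) -> dict[str, tuple[int, int]]:
    """Tally (n_responsive, n_classified) per group for one alignment.

    ``calls_by_group`` maps group label to the per-unit
    ``ResponsivenessCall`` mapping from ``perievent.classify_all``.  Units
    whose label was skipped (no events, degenerate baseline) are excluded
    from the denominator.
    """
    out: dict[str, tuple[int, int]] = {}
    for g, calls in calls_by_group.items():
        n = k = 0
        for call in calls.values():
            if event_label in call.calls:
                n += 1
                k += call.calls[event_label].responsive
        out[g] = (k, n)
    return out


def pairwise_comparisons(summaries: list[GroupSummary]) -> list[dict]:
    """All pairwise Fisher tests on responsive-unit proportions.

    Each comparison reports its 2×2 table (responsive / non-responsive ×
    group) and the two-sided exact p.  No multiple-testing correction is
    applied (raw p-values are reported); apply one downstream if desired.
    """
    out = []
    for i in range(len(summaries)):
        for j in range(i + 1, len(summaries)):
            ga, gb = summaries[i], summaries[j]
            a, b = ga.n_responsive, ga.n_total - ga.n_responsive
            c, d = gb.n_responsive, gb.n_total - gb.n_responsive
            out.append(
                {
                    "group_a": ga.group_label,
                    "group_b": gb.group_label,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "p_two_sided": fisher_exact_2x2(a, b, c, d),
                }
            )
    return out
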