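"""Synthetic spike-train and behavior generators."""

import numpy as np
import pytest

from fearpeth import (
    BehaviorModelParams,
    CohortDesign,
    EventLabel,
    GroupDesign,
    ProtocolKind,
    RateModulation,
    SessionProtocol,
    UnitSpec,
    build_timeline,
    simulate_behavior,
    simulate_cohort,
    simulate_spike_train,
)
from conftest import unit_seeds


def long_timeline(dur=1000.0):
    """Single-CS session padded so total_dur == dur exactly."""
    p = SessionProtocol(
        kind=ProtocolKind.CS_ONLY,
        baseline_dur=500.0,
        cs_count=1,
        us_flags=(False,),
        post_dur=dur - 530.0,
    )
    tl = build_timeline(p, seed=0)
    assert tl.total_dur == dur
    return tl


class TestSpikeTrainSimulation:
    def test_homogeneous_poisson_count_mean(self):
        """4 Hz × 1000 s: mean spike count over 500 seeds within 3 SE of 4000."""
        tl = long_timeline(1000.0)
        unit = UnitSpec("u", 4.0)
        counts = [
            len(simulate_spike_train(unit, tl, None, s).timestamps)
            for s in unit_seeds(7, 500)
        ]
        se = np.sqrt(4000.0 / 500)
        assert abs(np.mean(counts) - 4000.0) < 3 * se
        # Poisson: variance ≈ mean (loose factor-2 sanity band)
        assert 0.5 * 4000 < np.var(counts) < 2.0 * 4000

    def test_vanishing_rate_gives_empty_train(self):
        tl = long_timeline(1000.0)
        unit = UnitSpec("u", 1e-4)
        n = sum(
            len(simulate_spike_train(unit, tl, None, s).timestamps) for s in range(10)
        )
        assert n <= 3  # expectation 1.0 over 10 sessions of 0.1 expected spikes

    def test_boxcar_modulation_scales_response_window(self):
        """3× boxcar at CS onset: counts in [CS, CS+0.5) ≈ 3× a flanking window."""
        tl = long_timeline(1000.0)
        cs = tl.times(EventLabel.CS_ON)[0]
        unit = UnitSpec("u", 4.0, (RateModulation("CS_ON", 3.0, 0.0, 0.5),))
        in_win = flank = 0
        for s in unit_seeds(11, 400):
            ts = simulate_spike_train(unit, tl, None, s).timestamps
            in_win += np.sum((ts >= cs) & (ts < cs + 0.5))
            flank += np.sum((ts >= cs - 1.0) & (ts < cs - 0.5))
        # expectations: 400·4·0.5·3 = 2400 vs 400·4·0.5 = 800
        assert abs(in_win - 2400) < 3 * np.sqrt(2400)
        assert abs(flank - 800) < 3 * np.sqrt(800)

    def test_determinism_and_bounds(self):
        tl = long_timeline(1000.0)
        unit = UnitSpec("u", 4.0, (RateModulation("CS_ON", 2.0),))
        a = simulate_spike_train(unit, tl, None, 5)
        b = simulate_spike_train(unit, tl, None, 5)
        np.testing.assert_array_equal(a.timestamps, b.timestamps)
        assert a.timestamps.min() >= 0 and a.timestamps.max() < tl.total_dur
        assert np.all(np.diff(a.timestamps) >= 0)

    def test_freeze_modulation_requires_behavior(self):
        tl = long_timeline(1000.0)
        unit = UnitSpec("u", 4.0, (RateModulation("FREEZE_ON", 0.5),))
        with pytest.raises(ValueError, match="behavior"):
            simulate_spike_train(unit, tl, None, 0)

    def test_thinning_matches_poisson_per_segment(self):
        """Piecewise-constant λ: per-segment counts match Poisson(∫λ) in mean."""
        tl = long_timeline(1000.0)
        cs = tl.times(EventLabel.CS_ON)[0]
        unit = UnitSpec("u", 2.0, (RateModulation("CS_ON", 5.0, 0.0, 30.0),))
        n_rep = 300
        seg_counts = np.zeros((n_rep, 2))
        for i, s in enumerate(unit_seeds(23, n_rep)):
            ts = simulate_spike_train(unit, tl, None, s).timestamps
            seg_counts[i, 0] = np.sum((ts >= cs) & (ts < cs + 30.0))  # λ=10 for 30 s
            seg_counts[i, 1] = np.sum(ts < cs)  # λ=2 for 500 s
        for j, expect in enumerate([300.0, 1000.0]):
            mean = seg_counts[:, j].mean()
            se = np.sqrt(expect / n_rep)
            assert abs(mean - expect) < 3 * se
            assert 0.5 * expect < seg_counts[:, j].var() < 2.0 * expect


class TestBehaviorSimulation:
    def test_zero_rates_no_freezing(self, retrieval_timeline):
        params = BehaviorModelParams(0.0, 0.0, 0.0, 0.0, min_bout=0.0)
        trace = simulate_behavior(retrieval_timeline, params, 1)
        assert trace.bouts == ()

    def test_absorbing_freeze_state(self, retrieval_timeline):
        params = BehaviorModelParams(1000.0, 0.0, 1000.0, 0.0, min_bout=0.0)
        trace = simulate_behavior(retrieval_timeline, params, 1)
        assert len(trace.bouts) == 1
        start, end = trace.bouts[0]
        assert start < 0.1 and end == retrieval_timeline.total_dur

    def test_symmetric_rates_half_freezing(self):
        """Symmetric 2-state chain: stationary freezing fraction ≈ 0.5."""
        tl = long_timeline(1000.0)
        params = BehaviorModelParams(0.2, 0.2, 0.2, 0.2, min_bout=0.0)
        fracs = [
            simulate_behavior(tl, params, s).total_frozen / tl.total_dur
            for s in unit_seeds(31, 50)
        ]
        assert abs(np.mean(fracs) - 0.5) < 0.03

    def test_bouts_within_session_and_min_bout(self, retrieval_timeline):
        params = BehaviorModelParams(min_bout=1.0)
        for s in range(30):
            trace = simulate_behavior(retrieval_timeline, params, s)
            for a, b in trace.bouts:
                assert 0.0 <= a < b <= retrieval_timeline.total_dur
                assert b - a >= 1.0

    def test_cs_increases_freezing(self, retrieval_timeline):
        """Default rates: freezing occupancy is higher inside CS than outside."""
        trace = simulate_behavior(retrieval_timeline, BehaviorModelParams(), 4)
        grid = np.arange(0.0, retrieval_timeline.total_dur, 0.5)
        frozen = trace.is_frozen(grid)
        in_cs = np.zeros_like(grid, dtype=bool)
        for on, off in retrieval_timeline.cs_periods:
            in_cs |= (grid >= on) & (grid < off)
        assert frozen[in_cs].mean() > frozen[~in_cs].mean()


class TestCohortSimulation:
    def design(self, **kw):
        g = [
            GroupDesign("mod", 10, fraction_cs_on=kw.pop("frac", 0.4), effect_multiplier=3.0),
            GroupDesign("ctl", 10),
        ]
        return CohortDesign(groups=tuple(g), seed=kw.pop("seed", 0))

    def test_floor_rule_and_truth_labels(self):
        data = simulate_cohort(self.design(frac=0.4))
        mod = data.groups[0]
        n_mod = sum(1 for labels in mod.truth.values() if "CS_ON" in labels)
        assert n_mod == 4
        ctl = data.groups[1]
        assert all(labels == () for labels in ctl.truth.values())

    def test_zero_fraction_no_modulation(self):
        data = simulate_cohort(self.design(frac=0.0))
        assert all(u.modulations == () for u in data.groups[0].units)

    def test_cohort_determinism(self):
        a = simulate_cohort(self.design(seed=9))
        b = simulate_cohort(self.design(seed=9))
        for ga, gb in zip(a.groups, b.groups):
            assert ga.behavior.bouts == gb.behavior.bouts
            for sa, sb in zip(ga.spikes, gb.spikes):
                np.testing.assert_array_equal(sa.timestamps, sb.timestamps)
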