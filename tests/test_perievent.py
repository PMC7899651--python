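"""Peri-event binning, z-scoring, and the responsiveness rule."""

import numpy as np
import pytest

from fearpeth import (
    ClassifierParams,
    FreezeEventSeries,
    PerieventMatrix,
    RateModulation,
    SpikeTrain,
    UnitSpec,
    ZScoreProfile,
    align_and_bin,
    classify_all,
    classify_unit,
    mean_rate,
    peak_response_bin,
    simulate_spike_train,
    zscore_profile,
)
from conftest import unit_seeds


def naive_align_and_bin(timestamps, event_times, edges):
    """Independent double-loop counter over half-open bins."""
    counts = np.zeros((len(event_times), len(edges) - 1), dtype=int)
    for i, t0 in enumerate(event_times):
        for t in timestamps:
            for b in range(len(edges) - 1):
                if t0 + edges[b] <= t < t0 + edges[b + 1]:
                    counts[i, b] += 1
    return counts


def profile_from_z(z_response, params=None):
    """Build a ZScoreProfile whose response-window z equals ``z_response``."""
    params = params or ClassifierParams()
    n = len(params.bin_edges) - 1
    z = np.zeros(n)
    z[params.response_bins] = z_response
    return ZScoreProfile(
        unit_id="u", event_label="CS_ON", mean_counts=np.zeros(n),
        baseline_mean=0.0, baseline_sd=1.0, z=z, n_events=6,
    )


class TestAlignAndBin:
    def test_matches_naive_counter_on_random_fixtures(self, cs_params):
        rng = np.random.default_rng(0)
        edges = cs_params.bin_edges
        for _ in range(25):
            n_spk = rng.integers(0, 21)
            ts = np.sort(rng.uniform(0, 100, n_spk))
            events = np.sort(rng.uniform(5, 95, rng.integers(1, 4)))
            st_ = SpikeTrain("u", ts, 100.0)
            mat = align_and_bin(st_, events, cs_params)
            np.testing.assert_array_equal(mat.counts, naive_align_and_bin(ts, events, edges))

    def test_spike_on_edge_goes_to_later_bin(self, cs_params):
        # spike exactly at event time -> response bin 0, not the last baseline bin
        st_ = SpikeTrain("u", np.array([50.0]), 100.0)
        mat = align_and_bin(st_, [50.0], cs_params)
        assert mat.counts[0, cs_params.response_bins[0]] == 1
        assert mat.counts.sum() == 1

    def test_no_spikes_zero_matrix(self, cs_params):
        mat = align_and_bin(SpikeTrain("u", np.array([]), 100.0), [10.0, 50.0], cs_params)
        assert mat.counts.shape == (2, 15)
        assert not mat.counts.any()

    def test_deterministic_10hz_train_one_per_bin(self, cs_params):
        ts = np.arange(0.05, 100, 0.1)
        mat = align_and_bin(SpikeTrain("u", ts, 100.0), [20.0, 50.0, 77.3], cs_params)
        assert (mat.counts == 1).all()

    def test_uncovered_events_dropped_and_logged(self, cs_params):
        st_ = SpikeTrain("u", np.array([5.0]), 100.0)
        mat = align_and_bin(st_, [0.5, 50.0, 99.9], cs_params)
        assert mat.counts.shape[0] == 1
        assert len(mat.dropped_events) == 2

    def test_empty_event_list_rejected(self, cs_params):
        with pytest.raises(ValueError, match="empty"):
            align_and_bin(SpikeTrain("u", np.array([1.0]), 10.0), [], cs_params)

    def test_freeze_window_spans_minus2_to_half(self, freeze_params):
        edges = freeze_params.bin_edges
        assert edges[0] == pytest.approx(-2.0)
        assert edges[-1] == pytest.approx(0.5)
        assert len(edges) - 1 == 25
        # baseline bins are −2..−1 s, response bins 0..0.5 s
        assert edges[freeze_params.baseline_bins[-1] + 1] == pytest.approx(-1.0)
        assert edges[freeze_params.response_bins[0]] == pytest.approx(0.0)


class TestZScoreProfile:
    def mk_matrix(self, xbar, params):
        return PerieventMatrix("u", "CS_ON", np.array([xbar]), params.bin_edges)

    def test_alternating_baseline_hand_value(self, cs_params):
        """x̄ baseline (0,1)x5, response bin value 2 → z = 2.84605."""
        xbar = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 2, 0, 0, 0, 0]
        prof = zscore_profile(self.mk_matrix(xbar, cs_params), cs_params)
        assert prof.baseline_mean == pytest.approx(0.5)
        assert prof.baseline_sd == pytest.approx(0.527046, abs=1e-6)
        assert prof.z[10] == pytest.approx(2.84605, abs=1e-5)

    def test_flat_profile_z_zero(self, cs_params):
        xbar = [1] * 15
        prof = zscore_profile(self.mk_matrix(xbar, cs_params), cs_params)
        assert prof.degenerate  # SD of identical baseline bins is 0

    def test_constant_baseline_with_structure(self, cs_params):
        xbar = [0, 1] * 5 + [1, 1, 1, 1, 1]
        prof = zscore_profile(self.mk_matrix(xbar, cs_params), cs_params)
        assert not prof.degenerate
        np.testing.assert_allclose(prof.z[10:], (1 - 0.5) / prof.baseline_sd)

    def test_trial_averaging_before_zscore(self, cs_params):
        counts = np.array([[0] * 15, [2] * 10 + [4] * 5])
        prof = zscore_profile(PerieventMatrix("u", "CS_ON", counts, cs_params.bin_edges),
                              cs_params)
        # x̄ baseline = 1 everywhere -> degenerate despite per-trial structure
        assert prof.degenerate

    def test_permutation_invariance(self, cs_params):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, size=(6, 15))
        a = zscore_profile(PerieventMatrix("u", "CS_ON", counts, cs_params.bin_edges), cs_params)
        b = zscore_profile(
            PerieventMatrix("u", "CS_ON", counts[::-1], cs_params.bin_edges), cs_params
        )
        np.testing.assert_allclose(a.z, b.z)


class TestClassifyUnit:
    @pytest.mark.parametrize(
        "z_resp, responsive, direction",
        [
            ((2.1, 2.3, 0.1, 0.0, -0.5), True, "excited"),
            ((2.1, -2.1, 2.0, -2.0, 0.0), True, "excited"),
            ((1.96, 1.96, 1.96, 1.96, 1.96), False, "none"),
            ((-2.5, -3.0, 0.0, 0.0, 0.0), True, "inhibited"),
            ((2.5, 0.0, 0.0, 0.0, 0.0), False, "none"),  # one bin is not enough
            ((-1.97, -1.97, 1.97, 0.0, 0.0), True, "inhibited"),
        ],
    )
    def test_rule_examples(self, cs_params, z_resp, responsive, direction):
        call = classify_unit(profile_from_z(z_resp), cs_params)
        assert call.responsive is responsive
        assert call.direction == direction

    def test_supra_bins_reported(self, cs_params):
        call = classify_unit(profile_from_z((2.1, 2.3, 0.1, 0.0, -2.5)), cs_params)
        assert call.supra_bins == (0, 1)

    def test_degenerate_profile_rejected(self, cs_params):
        prof = profile_from_z((0, 0, 0, 0, 0))
        bad = ZScoreProfile(
            prof.unit_id, prof.event_label, prof.mean_counts, 0.0, 0.0,
            np.full_like(prof.z, np.nan), prof.n_events,
        )
        with pytest.raises(ValueError, match="degenerate"):
            classify_unit(bad, cs_params)


class TestPeakAndRate:
    def test_peak_simple(self, cs_params):
        assert peak_response_bin(profile_from_z((0, 0, 3, 0, 0)), cs_params) == (2, pytest.approx(0.2), 3.0)

    def test_peak_tie_earliest(self, cs_params):
        b, lat, z = peak_response_bin(profile_from_z((2, 2, 0, 0, 0)), cs_params)
        assert (b, lat, z) == (0, 0.0, 2.0)

    def test_peak_uses_magnitude(self, cs_params):
        b, lat, z = peak_response_bin(profile_from_z((0, 0, 0, 0, -4)), cs_params)
        assert (b, z) == (4, -4.0)
        assert lat == pytest.approx(0.4)

    def test_mean_rate(self):
        assert mean_rate(SpikeTrain("u", np.linspace(0, 24.99, 100), 25.0)) == 4.0
        assert mean_rate(SpikeTrain("u", np.array([]), 10.0)) == 0.0
        ts = np.arange(0.05, 10, 0.1)
        assert mean_rate(SpikeTrain("u", ts, 10.0)) == 10.0


class TestClassifyAll:
    def test_modulated_unit_detected_more_than_null(self, retrieval_timeline):
        """5× CS boxcar at 4 Hz: detection far above the unmodulated rate."""
        freeze = FreezeEventSeries(onsets=(), cessations=())
        hits = {True: 0, False: 0}
        n = 120
        for modulated in (True, False):
            mods = (RateModulation("CS_ON", 5.0),) if modulated else ()
            for s in unit_seeds(17 if modulated else 18, n):
                unit = UnitSpec("u", 4.0, mods)
                train = simulate_spike_train(unit, retrieval_timeline, None, s)
                calls = classify_all(
                    {"u": SpikeTrain("u", train.timestamps, train.session_dur)},
                    retrieval_timeline, freeze,
                )["u"]
                if "CS_ON" in calls.calls and calls.calls["CS_ON"].responsive:
                    hits[modulated] += 1
        assert hits[True] / n > hits[False] / n + 0.3
        assert hits[True] / n > 0.6

    def test_no_freeze_events_label_skipped(self, retrieval_timeline):
        train = SpikeTrain("u", np.arange(0.05, retrieval_timeline.total_dur, 0.25), retrieval_timeline.total_dur)
        calls = classify_all({"u": train}, retrieval_timeline,
                             FreezeEventSeries(onsets=(), cessations=()))["u"]
        assert calls.skipped["FREEZE_ON"] == "no events"
        assert calls.skipped["FREEZE_OFF"] == "no events"

    def test_freeze_alignment_uses_shifted_baseline(self, retrieval_timeline):
        """A unit silenced in [−1, 0) before freeze onsets is unaffected because
        the freeze baseline lives in [−2, −1)."""
        T = retrieval_timeline.total_dur
        onsets = (100.0, 200.0, 300.0, 400.0)
        ts = np.arange(0.025, T, 0.05)  # 20 Hz regular
        # silence [on-1, on-0.5): inside a -1..0 baseline but outside -2..-1
        mask = np.ones(len(ts), bool)
        for on in onsets:
            mask &= ~((ts >= on - 1.0) & (ts < on - 0.5))
        calls = classify_all(
            {"u": SpikeTrain("u", ts[mask], T)}, retrieval_timeline,
            FreezeEventSeries(onsets=onsets, cessations=()),
        )["u"]
        # with the shifted (-2..-1 s) baseline every baseline bin still holds
        # exactly 2 spikes -> zero SD; an unshifted baseline would straddle
        # the silenced half-second and classify instead
        assert calls.skipped.get("FREEZE_ON") == "degenerate baseline (zero SD)"
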