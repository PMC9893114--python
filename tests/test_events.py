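"""Event detection and the synchronization/directionality statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seiznet import (
    DetectionParams,
    EventTrain,
    InsufficientEventsError,
    SeriesTooShortError,
    cumulative_counts,
    delay_scale,
    detect_events,
    pair_counts,
    rate_series,
    sync_causality,
)

from _oracles import (
    brute_cumulative,
    brute_detect,
    brute_pair_counts,
    brute_rate,
    brute_tau,
    random_train,
)
from conftest import make_train


class TestDetectEvents:
    def test_constant_signal_has_no_events(self):
        assert len(detect_events(np.zeros(200))) == 0

    def test_monotone_ramp_has_no_events(self):
        assert len(detect_events(np.arange(200, dtype=float))) == 0

    def test_single_bump_matches_brute_force(self):
        x = np.zeros(1000)
        k = np.arange(-20, 21)
        x[480:521] = 100 * np.exp(-0.5 * (k / 5.0) ** 2)
        params = DetectionParams(M=10, h=30)
        train = detect_events(x, params)
        assert train.times.tolist() == brute_detect(x, 10, 30) == [500]

    def test_noisy_multichannel_matches_brute_force(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 20, size=3000)
        x[1500] += 120  # guarantee at least one strong peak
        params = DetectionParams(M=10, h=30)
        assert detect_events(x, params).times.tolist() == brute_detect(x, 10, 30)

    def test_boundary_indices_are_never_events(self):
        x = np.zeros(50)
        x[3] = 100  # within M of the left edge
        x[47] = 100
        assert len(detect_events(x, DetectionParams(M=10, h=30))) == 0

    def test_too_short_series_raises(self):
        with pytest.raises(SeriesTooShortError):
            detect_events(np.zeros(15), DetectionParams(M=10))

    def test_subthreshold_peak_rejected(self):
        x = np.zeros(200)
        x[100] = 25  # below h=30
        assert len(detect_events(x, DetectionParams(M=10, h=30))) == 0


class TestDelayScale:
    def test_regular_spacing(self, regular_train):
        assert delay_scale(regular_train, regular_train).tau == 100.0

    def test_matches_exhaustive_pair_minimum(self):
        a = make_train([0, 10, 1000])
        b = make_train([5, 500, 990])
        got = delay_scale(a, b, keep_local=True)
        assert got.tau == brute_tau(a.times, b.times) == 5.0
        assert got.tau == min(got.local_taus.values())

    def test_random_trains_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = make_train(random_train(rng, 12, 5000))
            b = make_train(random_train(rng, 9, 5000))
            assert delay_scale(a, b).tau == brute_tau(a.times, b.times)

    def test_insufficient_events_raises(self):
        a = make_train([100, 300])
        b = make_train([50, 250, 450])
        with pytest.raises(InsufficientEventsError):
            delay_scale(a, b)


class TestPairCounts:
    def test_identical_trains_only_coincidences(self, regular_train):
        counts = pair_counts(regular_train, regular_train, tau=100)
        assert counts.e_ab == counts.e_ba == 20.0  # 40 coincidences * 1/2

    def test_lagged_pairing_is_one_sided(self, regular_train, lagged_train):
        counts = pair_counts(regular_train, lagged_train, tau=100)
        assert counts.e_ba == 40.0 and counts.e_ab == 0.0

    def test_random_trains_match_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = make_train(random_train(rng, 20, 10000))
            b = make_train(random_train(rng, 30, 10000))
            tau = delay_scale(a, b).tau
            got = pair_counts(a, b, tau)
            assert (got.e_ab, got.e_ba) == brute_pair_counts(a.times, b.times, tau)

    def test_empty_train_gives_zero_counts(self):
        a = make_train([])
        b = make_train([100, 200])
        counts = pair_counts(a, b, tau=10)
        assert counts.e_ab == counts.e_ba == 0.0


class TestSyncCausality:
    def test_full_coincidence_gives_unit_Q(self, regular_train):
        counts = pair_counts(regular_train, regular_train, tau=100)
        assert sync_causality(counts).Q == 1.0

    def test_perfect_lagged_pairing_gives_unit_q(self, regular_train, lagged_train):
        counts = pair_counts(regular_train, lagged_train, tau=100)
        assert sync_causality(counts).q == 1.0

    def test_far_separated_trains_give_zero(self):
        a = make_train([100, 200, 300])
        b = make_train([5000, 6000, 7000])
        sc = sync_causality(pair_counts(a, b, tau=10))
        assert sc.Q == 0.0 and sc.q == 0.0

    def test_product_normalization_option(self, regular_train):
        counts = pair_counts(regular_train, regular_train, tau=100)
        sc = sync_causality(counts, mode="product_mm")
        assert sc.Q == pytest.approx(40.0 / 1600.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_bounds_on_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        a = make_train(random_train(rng, int(rng.integers(5, 30)), 8000))
        b = make_train(random_train(rng, int(rng.integers(5, 30)), 8000))
        tau = delay_scale(a, b).tau
        fwd = sync_causality(pair_counts(a, b, tau))
        rev = sync_causality(pair_counts(b, a, tau))
        assert fwd.Q == pytest.approx(rev.Q)
        assert fwd.q == pytest.approx(-rev.q)
        assert 0.0 <= fwd.Q <= 1.0
        assert -1.0 <= fwd.q <= 1.0


class TestCumulativeCounts:
    def test_zero_at_origin_and_total_at_end(self, regular_train, lagged_train):
        tau = delay_scale(regular_train, lagged_train).tau
        cum = cumulative_counts(regular_train, lagged_train, tau)
        assert cum.Q(0) == 0.0 and cum.q(0) == 0.0
        totals = pair_counts(regular_train, lagged_train, tau)
        assert cum.Q(10000) == totals.e_ab + totals.e_ba

    def test_midseries_matches_truncated_brute_force(self, regular_train, lagged_train):
        tau = delay_scale(regular_train, lagged_train).tau
        cum = cumulative_counts(regular_train, lagged_train, tau)
        for n in (1, 777, 4000, 4031, 9999):
            Q_n, q_n = brute_cumulative(regular_train.times, lagged_train.times, tau, n)
            assert cum.Q(n) == Q_n and cum.q(n) == q_n

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(5)
        a = make_train(random_train(rng, 25, 10000))
        b = make_train(random_train(rng, 25, 10000))
        tau = delay_scale(a, b).tau
        cum = cumulative_counts(a, b, tau)
        n = np.arange(0, 10001, 97)
        assert np.all(np.diff(cum.Q(n)) >= 0)


class TestRateSeries:
    def test_eventless_window_gives_zero(self):
        a = make_train([100, 150, 200], length=10000)
        b = make_train([110, 160, 210], length=10000)
        tau = delay_scale(a, b).tau
        rs = rate_series(cumulative_counts(a, b, tau), a, b, window=1000, stride=1000)
        assert rs.dQ[-1] == 0.0 and rs.dq[-1] == 0.0  # late windows are empty

    def test_lagged_fixture_has_positive_dq_everywhere(self, regular_train, lagged_train):
        tau = delay_scale(regular_train, lagged_train).tau
        cum = cumulative_counts(regular_train, lagged_train, tau)
        rs = rate_series(cum, regular_train, lagged_train, window=2000, stride=500)
        covered = (rs.dn1 > 0) & (rs.dn2 > 0)
        assert covered.any()
        assert np.all(rs.dq[covered] > 0)

    def test_matches_per_window_brute_force(self):
        rng = np.random.default_rng(13)
        a = make_train(random_train(rng, 30, 10000))
        b = make_train(random_train(rng, 20, 10000))
        tau = delay_scale(a, b).tau
        rs = rate_series(cumulative_counts(a, b, tau), a, b, window=2500, stride=1250)
        for k, n in enumerate(rs.times):
            dQ, dq = brute_rate(a.times, b.times, tau, 2500, int(n))
            assert rs.dQ[k] == dQ and rs.dq[k] == dq

    def test_dQ_nonnegative_always(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            a = make_train(random_train(rng, 15, 8000), length=8000)
            b = make_train(random_train(rng, 25, 8000), length=8000)
            tau = delay_scale(a, b).tau
            rs = rate_series(cumulative_counts(a, b, tau), a, b, window=1000, stride=400)
            assert np.all(rs.dQ >= 0)
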