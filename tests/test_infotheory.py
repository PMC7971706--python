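"""Plug-in estimators against brute-force frequency-table oracles and
closed forms."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scanpath_ais import (
    InsufficientDataError,
    LagSet,
    ScanPath,
    active_information_storage,
    conditional_mutual_information,
    gaze_transition_entropy,
    local_measures,
    plugin_distribution,
    shannon_entropy,
    stationary_gaze_entropy,
)
from scanpath_ais.simulate import build_chain, simulate_scanpath


def brute_tuple_counts(x, lags):
    """Independent tuple counting by explicit iteration."""
    lmax = max(lags)
    c = Counter()
    for t in range(lmax, len(x)):
        c[tuple([x[t]] + [x[t - l] for l in lags])] += 1
    return c


def brute_entropy(counter):
    n = sum(counter.values())
    return -sum((c / n) * math.log2(c / n) for c in counter.values())


# ---------------------------------------------------------------------------
# distributions and entropies
# ---------------------------------------------------------------------------


class TestPluginDistribution:
    def test_alternating_chain(self):
        path = ScanPath(np.array([1, 2, 1, 2, 1, 2, 1]), A=2)
        d = plugin_distribution(path, (1,))
        assert d.prob((1, 2)) == pytest.approx(0.5)
        assert d.prob((2, 1)) == pytest.approx(0.5)
        assert d.prob((1, 1)) == 0.0
        assert d.n_eff == 6

    def test_constant_path_point_mass(self):
        d = plugin_distribution(ScanPath(np.array([3, 3, 3, 3]), A=4), (1,))
        assert d.prob((3, 3)) == 1.0
        assert len(d.probs) == 1

    def test_matches_brute_force_counting(self, rng):
        x = rng.integers(1, 9, 50)
        d = plugin_distribution(ScanPath(x, A=8), (1, 3))
        brute = brute_tuple_counts(x, (1, 3))
        n = sum(brute.values())
        assert d.n_eff == n == 47
        for tup, c in brute.items():
            assert d.prob(tup) == pytest.approx(c / n)
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            plugin_distribution(ScanPath(np.array([1, 2, 3]), A=4), (5,))


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            (np.full(8, 1 / 8), 3.0),
            (np.array([1.0]), 0.0),
            (np.array([0.5, 0.25, 0.25]), 1.5),
        ],
    )
    def test_closed_forms(self, probs, expected):
        assert shannon_entropy(probs) == pytest.approx(expected, abs=1e-12)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.array([0.5, 0.4]))


class TestStationaryGazeEntropy:
    def test_single_aoi_is_zero(self):
        assert stationary_gaze_entropy(ScanPath(np.full(10, 4), A=8)) == 0.0

    def test_uniform_counts(self):
        path = ScanPath(np.tile(np.arange(1, 9), 5), A=8)
        assert stationary_gaze_entropy(path) == pytest.approx(3.0)

    def test_skewed_counts(self):
        x = np.array([1] * 5 + [2] * 3 + [3] * 2)
        expected = shannon_entropy(np.array([0.5, 0.3, 0.2]))
        assert stationary_gaze_entropy(ScanPath(x, A=3)) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# GTE / AIS
# ---------------------------------------------------------------------------


class TestGazeTransitionEntropy:
    def test_deterministic_transitions(self):
        path = ScanPath(np.tile([1, 2], 500), A=2)
        assert gaze_transition_entropy(path) == pytest.approx(0.0, abs=1e-12)

    def test_constant_path(self):
        assert gaze_transition_entropy(ScanPath(np.full(50, 2), A=4)) == 0.0

    def test_matches_brute_force_conditional_entropy(self, rng):
        x = rng.integers(1, 5, 30)
        joint = brute_tuple_counts(x, (1,))
        prev = Counter()
        for (xt, xp), c in joint.items():
            prev[xp] += c
        expected = brute_entropy(joint) - brute_entropy(prev)
        assert gaze_transition_entropy(ScanPath(x, A=4)) == pytest.approx(expected, abs=1e-12)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            gaze_transition_entropy(ScanPath(np.array([1]), A=2))


class TestActiveInformationStorage:
    def test_alternating_forces_one_bit(self):
        # odd length: the eligible targets split exactly evenly
        path = ScanPath(np.tile([1, 2], 500)[:999], A=2)
        assert active_information_storage(path, (1,)) == pytest.approx(1.0, abs=1e-12)

    def test_iid_uniform_bias_level(self):
        rng = np.random.default_rng(7)
        path = ScanPath(rng.integers(1, 5, 100_000), A=4)
        assert active_information_storage(path, (1,)) <= 0.005

    def test_period_two_orbit_selects_lag_two(self):
        # x_t = x_{t-2} on {1,2}: all information is at lag 2, none at lag 1
        path = ScanPath(np.tile([1, 1, 2, 2], 251)[:1002], A=2)
        assert active_information_storage(path, (2,)) == pytest.approx(1.0, abs=1e-12)
        lag1 = active_information_storage(path, (1,))
        assert lag1 == pytest.approx(0.0, abs=1e-2)

    def test_empty_lags_warns_and_returns_zero(self):
        path = ScanPath(np.array([1, 2, 3]), A=3)
        with pytest.warns(UserWarning):
            assert active_information_storage(path, ()) == 0.0

    def test_monotone_in_lag_set_on_common_samples(self, rng):
        x = rng.integers(1, 5, 300)
        path = ScanPath(x, A=4)
        prev = 0.0
        for lags in [(1,), (1, 2), (1, 2, 3)]:
            cur = active_information_storage(path, lags, eligible_from=3)
            assert cur >= prev - 1e-12
            prev = cur


class TestConditionalMutualInformation:
    def test_empty_conditioning_is_plain_mi(self, rng):
        x = rng.integers(1, 5, 200)
        path = ScanPath(x, A=4)
        mi = conditional_mutual_information(path, 2, ())
        assert mi == pytest.approx(active_information_storage(path, (2,)), abs=1e-12)

    def test_markov_property_kills_lag_two(self):
        chain = build_chain(4, (1,), 0.6)
        path = simulate_scanpath(chain, 100_000, seed=3)
        assert conditional_mutual_information(path, 2, (1,)) <= 0.005

    def test_matches_brute_force_three_way_table(self, rng):
        x = rng.integers(1, 4, 15)
        path = ScanPath(x, A=3)
        got = conditional_mutual_information(path, 2, (1,))
        trip = brute_tuple_counts(x, (2, 1))  # (x_t, x_{t-2}, x_{t-1})
        ts, cs, s = Counter(), Counter(), Counter()
        for (xt, xc, xs), c in trip.items():
            ts[(xt, xs)] += c
            cs[(xc, xs)] += c
            s[xs] += c
        expected = (
            brute_entropy(cs) + brute_entropy(ts) - brute_entropy(trip) - brute_entropy(s)
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_candidate_in_conditioning_rejected(self):
        path = ScanPath(np.arange(1, 9), A=8)
        with pytest.raises(ValueError):
            conditional_mutual_information(path, 1, (1, 2))


# ---------------------------------------------------------------------------
# local measures
# ---------------------------------------------------------------------------


class TestLocalMeasures:
    def test_matches_brute_force_log_ratios(self, rng):
        x = rng.integers(1, 4, 20)
        path = ScanPath(x, A=3)
        s = local_measures(path, (1, 2))
        joint = brute_tuple_counts(x, (1, 2))
        past = Counter()
        tgt = Counter()
        n = sum(joint.values())
        for (xt, x1, x2), c in joint.items():
            past[(x1, x2)] += c
            tgt[xt] += c
        for t in range(2, 20):
            tup = (x[t], x[t - 1], x[t - 2])
            p_cond = joint[tup] / past[(x[t - 1], x[t - 2])]
            p_t = tgt[x[t]] / n
            assert s.lais[t] == pytest.approx(math.log2(p_cond / p_t), abs=1e-12)
            assert s.h_local[t] == pytest.approx(-math.log2(p_t), abs=1e-12)
            assert s.h_joint[t] == pytest.approx(-math.log2(joint[tup] / n), abs=1e-12)
        pairs = brute_tuple_counts(x, (1,))
        prev = Counter()
        for (xt, xp), c in pairs.items():
            prev[xp] += c
        for t in range(1, 20):
            p_pair = pairs[(x[t], x[t - 1])] / (20 - 1)
            p_cond = pairs[(x[t], x[t - 1])] / prev[x[t - 1]]
            assert s.lgte[t] == pytest.approx(-math.log2(p_cond), abs=1e-12)
            assert s.h_joint_lag1[t] == pytest.approx(-math.log2(p_pair), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_local_averages_to_global(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(1, 9, 120)
        path = ScanPath(x, A=8)
        s = local_measures(path, (1, 3))
        ais = active_information_storage(path, (1, 3))
        gte = gaze_transition_entropy(path)
        assert np.nanmean(s.lais) == pytest.approx(ais, abs=1e-10)
        assert np.nanmean(s.lgte) == pytest.approx(gte, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_lag_one_complementarity_per_sample(self, seed):
        # LAIS + LGTE = local entropy, pointwise, for the single-lag past
        rng = np.random.default_rng(seed)
        path = ScanPath(rng.integers(1, 9, 80), A=8)
        s = local_measures(path, (1,))
        dev = np.abs(s.lais[1:] + s.lgte[1:] - s.h_local[1:])
        assert np.nanmax(dev) < 1e-10

    def test_local_chain_rule(self, rng):
        path = ScanPath(rng.integers(1, 9, 200), A=8)
        s = local_measures(path, (1,))
        dev = np.abs(s.lgte[1:] - (s.h_joint_lag1[1:] - s.h_past_lag1[1:]))
        assert np.nanmax(dev) < 1e-10

    def test_lgte_nonnegative_lais_signed(self, rng):
        path = ScanPath(rng.integers(1, 9, 500), A=8)
        s = local_measures(path, (1, 2))
        assert np.nanmin(s.lgte) >= 0.0
        assert np.nanmin(s.lais) < 0.0  # misinformative samples exist here

    def test_empty_lag_set_defines_lag_one_block_only(self, rng):
        path = ScanPath(rng.integers(1, 9, 50), A=8)
        s = local_measures(path, ())
        assert np.isnan(s.lais).all()
        assert np.isfinite(s.lgte[1:]).all()
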