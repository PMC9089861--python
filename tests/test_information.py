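"""CTW entropy/MI estimator against exact oracles and analytic sources.

The brute-force oracle builds the full context tree explicitly and evaluates
the weighted probability with rational arithmetic, independently of the
sequential implementation under test.
"""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ca3burst.information import (
    BinarySequence,
    binarize,
    conditional_entropy_rate,
    ctw_log_probability,
    entropy_rate,
    mutual_information,
    poisson_max_entropy_rate,
)
from ca3burst.traces import SpikeTrain


# ---------------------------------------------------------------------------
# Brute-force rational CTW oracle
# ---------------------------------------------------------------------------

def _kt_sequential(symbols) -> Fraction:
    p = Fraction(1)
    a = b = 0
    for s in symbols:
        p *= Fraction(2 * (b if s else a) + 1, 2 * (a + b + 1))
        if s:
            b += 1
        else:
            a += 1
    return p


def brute_force_ctw(bits, depth) -> Fraction:
    """Explicit-tree CTW with KT estimators, exact rational arithmetic."""
    n = len(bits)
    padded = [0] * depth + list(bits)
    contexts = [tuple(padded[depth + t - 1 - k] for k in range(depth))
                for t in range(n)]

    def node_prob(suffix) -> Fraction:
        d = len(suffix)
        symbols = [bits[t] for t in range(n) if contexts[t][:d] == suffix]
        pe = _kt_sequential(symbols)
        if d == depth or not symbols:
            return pe
        # children refine the context by one older symbol (appended, since
        # contexts are stored most-recent-first)
        pw = Fraction(1, 2) * pe + Fraction(1, 2) * (
            node_prob(suffix + (0,)) * node_prob(suffix + (1,))
        )
        return pw

    return node_prob(())


def _bernoulli(p, n, seed):
    rng = np.random.default_rng(seed)
    return BinarySequence((rng.random(n) < p).astype(np.int8))


class TestCTWProbability:
    def test_two_bit_string_depth_zero(self):
        # KT: P(0) = 1/2, then P(1 | one zero seen) = (0+1/2)/(1+1) = 1/4
        logp = ctw_log_probability(BinarySequence([0, 1]), depth=0)
        assert logp == pytest.approx(math.log2(Fraction(1, 8)), abs=1e-12)

    @pytest.mark.parametrize("depth", [0, 1, 2, 3])
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_probabilities_normalize_over_all_strings(self, depth, n):
        total = sum(
            2.0 ** ctw_log_probability(BinarySequence(bits), depth)
            for bits in product((0, 1), repeat=n)
        )
        assert abs(total - 1.0) < 1e-10

    @pytest.mark.parametrize("depth", [0, 1, 2, 3])
    def test_exact_agreement_with_brute_force_tree(self, depth):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(1, 13))
            bits = rng.integers(0, 2, n).tolist()
            got = ctw_log_probability(BinarySequence(bits), depth)
            want = brute_force_ctw(bits, depth)
            assert got == pytest.approx(math.log2(want), abs=1e-9)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40),
           st.integers(0, 4))
    @settings(max_examples=60, deadline=None)
    def test_extension_never_more_probable_than_prefix(self, bits, depth):
        if len(bits) < 2:
            return
        full = ctw_log_probability(BinarySequence(bits), depth)
        prefix = ctw_log_probability(BinarySequence(bits[:-1]), depth)
        assert full <= prefix + 1e-12

    def test_log_probability_nonpositive(self):
        seq = _bernoulli(0.4, 500, 3)
        assert ctw_log_probability(seq, 5) <= 0.0


class TestEntropyRate:
    def test_fair_coin_close_to_one_bit(self):
        h = entropy_rate(_bernoulli(0.5, 16384, 1), depth=8)
        assert abs(h.bits_per_symbol - 1.0) <= 0.05

    def test_all_zeros_is_nearly_deterministic(self):
        h = entropy_rate(BinarySequence(np.zeros(4096, dtype=np.int8)), depth=8)
        assert h.bits_per_symbol <= 0.01

    def test_markov_chain_matches_analytic_entropy_rate(self):
        # order-1 chain: P(1|0) = 0.1, P(0|1) = 0.4
        a, b = 0.1, 0.4
        pi1 = a / (a + b)

        def h2(p):
            return -p * math.log2(p) - (1 - p) * math.log2(1 - p)

        h_true = (1 - pi1) * h2(a) + pi1 * h2(b)
        rng = np.random.default_rng(5)
        bits = np.empty(16384, dtype=np.int8)
        x = 0
        for i in range(bits.size):
            u = rng.random()
            x = (1 if u < a else 0) if x == 0 else (0 if u < b else 1)
            bits[i] = x
        h = entropy_rate(BinarySequence(bits), depth=8)
        assert abs(h.bits_per_symbol - h_true) <= 0.05

    def test_estimates_stabilize_between_depth_8_and_12(self):
        seq = _bernoulli(0.3, 16384, 9)
        h8 = entropy_rate(seq, depth=8).bits_per_symbol
        h12 = entropy_rate(seq, depth=12).bits_per_symbol
        assert abs(h8 - h12) <= 0.02

    def test_value_bounded_by_one_bit(self):
        seq = _bernoulli(0.5, 1024, 11)
        h = entropy_rate(seq, depth=4)
        assert 0.0 <= h.bits_per_symbol <= 1.0

    def test_bits_per_second_conversion(self):
        seq = _bernoulli(0.2, 4096, 13)
        h = entropy_rate(seq, depth=6)
        assert h.bits_per_second == pytest.approx(h.bits_per_symbol / 0.004)


class TestMutualInformation:
    def test_independent_sequences_near_zero(self):
        x = _bernoulli(0.3, 16384, 21)
        y = _bernoulli(0.3, 16384, 22)
        mi = mutual_information(x, y, depth=8)
        assert mi["mi_bits_per_symbol"] <= 0.02

    def test_identical_sequences_give_full_information(self):
        x = _bernoulli(0.3, 16384, 23)
        mi = mutual_information(x, x, depth=8)
        hx = entropy_rate(x, 8).bits_per_symbol
        assert mi["h_x_given_y"].bits_per_symbol <= 0.01
        assert abs(mi["mi_bits_per_symbol"] - hx) <= 0.02

    def test_one_bin_delayed_copy_recovered_at_depth_one(self):
        y = _bernoulli(0.3, 16385, 24)
        x = BinarySequence(np.concatenate([[0], y.bits[:-1]]))
        y = BinarySequence(y.bits[:16384].copy())
        x = BinarySequence(x.bits[:16384].copy())
        hx = entropy_rate(x, 8).bits_per_symbol
        mi = mutual_information(x, y, depth=8)
        assert abs(mi["mi_bits_per_symbol"] - hx) <= 0.05

    def test_symmetry_within_estimator_tolerance(self):
        rng = np.random.default_rng(31)
        z = (rng.random(16384) < 0.25).astype(np.int8)
        x = BinarySequence(np.where(rng.random(16384) < 0.8, z, 1 - z).astype(np.int8))
        y = BinarySequence(z)
        mab = mutual_information(x, y, depth=8)["mi_bits_per_symbol"]
        mba = mutual_information(y, x, depth=8)["mi_bits_per_symbol"]
        assert abs(mab - mba) <= 0.03

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conditional_entropy_rate(_bernoulli(0.5, 100, 1),
                                     _bernoulli(0.5, 101, 2), depth=2)


class TestBinarize:
    def test_empty_train_all_zeros(self):
        seq = binarize(SpikeTrain(np.array([]), duration=100.0), 4.0)
        assert len(seq) == 25
        assert seq.bits.sum() == 0

    def test_shared_bin_collapses_to_one(self):
        st_ = SpikeTrain(np.array([1.0, 5.0, 6.0]), duration=20.0)
        seq = binarize(st_, 4.0)
        assert seq.bits.tolist() == [1, 1, 0, 0, 0]

    def test_set_bits_never_exceed_spike_count(self):
        rng = np.random.default_rng(41)
        times = np.sort(rng.uniform(0, 1000.0, 300))
        seq = binarize(SpikeTrain(times, duration=1000.0), 4.0)
        assert seq.bits.sum() <= 300

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            binarize(SpikeTrain(np.array([-1.0, 2.0]), duration=10.0), 4.0)


class TestPoissonMaximum:
    def test_vanishes_as_rate_goes_to_zero(self):
        assert poisson_max_entropy_rate(1e-9) < 1e-6

    def test_matches_exact_bernoulli_entropy_at_small_occupancy(self):
        r, dt = 5.0, 4.0  # p = 0.02
        p = r * dt * 1e-3
        exact = (-p * math.log2(p) - (1 - p) * math.log2(1 - p)) / (dt * 1e-3)
        approx = poisson_max_entropy_rate(r, dt)
        assert approx == pytest.approx(exact, rel=0.02)

    def test_poisson_train_self_normalizes_to_one(self):
        rng = np.random.default_rng(51)
        rate, duration = 5.0, 400_000.0  # ms
        n = rng.poisson(rate * duration * 1e-3)
        times = np.sort(rng.uniform(0, duration, n))
        train = SpikeTrain(times, duration=duration)
        seq = binarize(train, 4.0, duration)
        h = entropy_rate(seq, depth=8)
        norm = h.bits_per_second / poisson_max_entropy_rate(train.rate, 4.0)
        assert norm == pytest.approx(1.0, abs=0.05)

    def test_saturated_bins_rejected(self):
        with pytest.raises(ValueError):
            poisson_max_entropy_rate(300.0, 4.0)
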