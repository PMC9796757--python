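"""Proposal distributions and the two-block MH sampler."""

import itertools
import math

import numpy as np
import pytest

from lowbmm.mcmc import (
    LowBMMConfig,
    MCMCState,
    accept_rho,
    accept_set,
    leap_and_shift,
    propose_set,
    run_lowbmm,
)
from lowbmm.rankcore import RankMatrix, is_permutation


def enumerate_leap_and_shift(rho, l):
    """Oracle: full transition row of the leap-and-shift kernel.

    Sums (1/m)(1/|S(u)|) over every generating (item, new-rank) pair,
    independent of the closed form used by the implementation.
    """
    rho = np.asarray(rho)
    m = rho.shape[0]
    probs = {}
    for u in range(m):
        pu = rho[u]
        window = [r for r in range(max(1, pu - l), min(m, pu + l) + 1) if r != pu]
        for r in window:
            new = rho.copy()
            if r > pu:
                mask = (rho > pu) & (rho <= r)
                new[mask] -= 1
            else:
                mask = (rho >= r) & (rho < pu)
                new[mask] += 1
            new[u] = r
            key = tuple(new)
            probs[key] = probs.get(key, 0.0) + (1 / m) * (1 / len(window))
    return probs


@pytest.mark.parametrize("m,l", [(3, 1), (4, 1), (4, 2), (5, 1), (5, 2)])
def test_leap_and_shift_rows_sum_to_one(m, l):
    for rho in itertools.permutations(range(1, m + 1)):
        probs = enumerate_leap_and_shift(rho, l)
        assert math.isclose(sum(probs.values()), 1.0, abs_tol=1e-12)


@pytest.mark.parametrize("m,l", [(4, 1), (4, 2), (5, 2)])
def test_leap_and_shift_log_probs_match_enumeration(m, l, rng):
    """The closed-form forward/backward masses equal the pair-enumeration."""
    rho = np.array(rng.permutation(m) + 1)
    fwd_table = enumerate_leap_and_shift(rho, l)
    for _ in range(200):
        rho_prime, log_f, log_b = leap_and_shift(rho, l, rng)
        assert math.isclose(log_f, math.log(fwd_table[tuple(rho_prime)]),
                            rel_tol=1e-12)
        bwd_table = enumerate_leap_and_shift(rho_prime, l)
        assert math.isclose(log_b, math.log(bwd_table[tuple(rho)]),
                            rel_tol=1e-12)


def test_leap_and_shift_changes_between_2_and_lp1_positions(rng):
    rho = np.array(rng.permutation(8) + 1)
    for l in (1, 2, 3):
        for _ in range(50):
            rho_prime, _, _ = leap_and_shift(rho, l, rng)
            assert is_permutation(rho_prime)
            ndiff = int((rho_prime != rho).sum())
            assert 2 <= ndiff <= l + 1


def test_leap_and_shift_rejects_bad_l(rng):
    with pytest.raises(ValueError):
        leap_and_shift(np.array([1, 2, 3]), 3, rng)
    with pytest.raises(ValueError):
        leap_and_shift(np.array([1, 2, 3]), 0, rng)


@pytest.mark.parametrize("delta,alpha,n_star,expected", [
    (0.0, 3.0, 4, 1.0),
    (2.0, 4, 4, math.exp(-2.0)),
    (-5.0, 3.0, 4, 1.0),
])
def test_accept_rho_symmetric_proposal(delta, alpha, n_star, expected):
    assert accept_rho(delta, -1.0, -1.0, alpha, n_star) == pytest.approx(expected)


def test_accept_rho_uses_proposal_correction():
    # backward more likely than forward inflates acceptance
    a = accept_rho(0.0, math.log(0.1), math.log(0.2), 1.0, 2)
    assert a == 1.0
    a = accept_rho(0.0, math.log(0.2), math.log(0.1), 1.0, 2)
    assert a == pytest.approx(0.5)


@pytest.mark.parametrize("delta,alpha,n_star,expected", [
    (0.0, 5.0, 5, 1.0),
    (3.0, 5.0, 5, math.exp(-3.0)),
    (-4.0, 5.0, 5, 1.0),
])
def test_accept_set_closed_form(delta, alpha, n_star, expected):
    assert accept_set(delta, alpha, n_star) == pytest.approx(expected)


class TestProposeSet:
    def test_swaps_exactly_L_items_and_keeps_surviving_ranks(self, rng):
        state = MCMCState(rho=np.array([2, 1, 3]), items=np.array([0, 4, 2]))
        for L in (1, 2, 3):
            items_p, rho_p = propose_set(state, L, 6, rng)
            assert len(np.setdiff1d(items_p, state.items)) == L
            assert len(np.setdiff1d(state.items, items_p)) == L
            surviving = np.isin(state.items, items_p)
            assert np.array_equal(rho_p[surviving], state.rho[surviving])

    def test_pair_frequencies_uniform(self, rng):
        """At n=6, n*=3, L=1 each (out, in) pair has probability 1/9."""
        state = MCMCState(rho=np.array([1, 2, 3]), items=np.array([0, 1, 2]))
        counts = {}
        n_draws = 18000
        for _ in range(n_draws):
            items_p, _ = propose_set(state, 1, 6, rng)
            out = int(np.setdiff1d(state.items, items_p)[0])
            inn = int(np.setdiff1d(items_p, state.items)[0])
            counts[(out, inn)] = counts.get((out, inn), 0) + 1
        assert len(counts) == 9
        se = math.sqrt((1 / 9) * (8 / 9) / n_draws)
        for c in counts.values():
            assert abs(c / n_draws - 1 / 9) < 4 * se

    def test_validation(self, rng):
        state = MCMCState(rho=np.array([1, 2]), items=np.array([0, 1]))
        with pytest.raises(ValueError):
            propose_set(state, 3, 6, rng)
        with pytest.raises(ValueError):
            propose_set(state, 1, 2, rng)


class TestRunLowBMM:
    def test_samples_are_valid_states(self, random_matrix):
        cfg = LowBMMConfig(n_star=3, alpha=2.0, iterations=500, seed=5)
        s = run_lowbmm(random_matrix, cfg)
        for rho in s.rho_samples:
            assert is_permutation(rho)
        for aset in s.aset_samples:
            assert len(set(aset.tolist())) == 3
            assert aset.min() >= 0 and aset.max() < random_matrix.n
        assert 0 < s.accept_rho_rate < 1
        assert 0 < s.accept_set_rate < 1

    def test_full_dimension_reduces_to_plain_consensus_model(self, rng):
        """With n* = n the set update is skipped and rho recovers the
        consensus on strongly concentrated data."""
        rho0 = np.array([3, 1, 2, 5, 4])
        data = RankMatrix(np.tile(rho0, (20, 1)))
        cfg = LowBMMConfig(n_star=5, alpha=8.0, iterations=4000, seed=6)
        s = run_lowbmm(data, cfg)
        assert s.accept_set_rate == 0.0
        assert set(s.aset_samples[-1].tolist()) == set(range(5))
        # posterior mode at the shared ranking (re-align draws to item order)
        from collections import Counter

        def item_ranks(rho, items):
            out = np.empty(5, dtype=int)
            out[items] = rho
            return tuple(out)

        top = Counter(
            item_ranks(r, a) for r, a in zip(s.rho_samples, s.aset_samples)
        ).most_common(1)[0][0]
        assert top == tuple(rho0)

    def test_chains_merge_and_seeds_reproduce(self, random_matrix):
        cfg = LowBMMConfig(n_star=2, alpha=1.0, iterations=400, seed=7, chains=2)
        s1 = run_lowbmm(random_matrix, cfg)
        s2 = run_lowbmm(random_matrix, cfg)
        assert np.array_equal(s1.rho_samples, s2.rho_samples)
        assert np.array_equal(s1.aset_samples, s2.aset_samples)
        assert set(s1.chain_ids.tolist()) == {0, 1}

    def test_config_validation(self, random_matrix):
        with pytest.raises(ValueError):
            LowBMMConfig(n_star=3, alpha=2.0, iterations=0)
        with pytest.raises(ValueError):
            LowBMMConfig(n_star=3, alpha=-1.0, iterations=10)
        with pytest.raises(ValueError):
            LowBMMConfig(n_star=3, alpha=2.0, iterations=10, burnin=10)
        with pytest.raises(ValueError):
            LowBMMConfig(n_star=3, alpha=2.0, iterations=10, swap_L=4)
        cfg = LowBMMConfig(n_star=7, alpha=2.0, iterations=10)
        with pytest.raises(ValueError, match="n_star"):
            run_lowbmm(random_matrix, cfg)

    def test_nonpermutation_row_rejected(self):
        with pytest.raises(ValueError, match="row 0"):
            run_lowbmm(np.array([[1, 1, 2]]),
                       LowBMMConfig(n_star=2, alpha=1.0, iterations=10))

    def test_default_tuning_parameters(self):
        cfg = LowBMMConfig(n_star=10, alpha=1.0, iterations=100)
        assert cfg.leap_l == 2  # round(n*/5)
        assert cfg.swap_L == 1
        assert cfg.burnin == 10
        cfg2 = LowBMMConfig(n_star=2, alpha=1.0, iterations=100)
        assert cfg2.leap_l == 1  # clipped into [1, n*-1]
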