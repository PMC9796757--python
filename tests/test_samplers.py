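"""Mallows sampler and synthetic data generating processes."""

import itertools

import numpy as np
import pytest

from lowbmm.rankcore import footrule, is_permutation, restrict
from lowbmm.samplers import (
    gen_rankconsistency,
    gen_toprank,
    perturb_swap_noise,
    sample_mallows,
)


def exact_mallows_pmf(rho0, alpha):
    """Enumeration oracle: normalized footrule-Mallows pmf at small m."""
    m = len(rho0)
    perms = list(itertools.permutations(range(1, m + 1)))
    w = np.array([np.exp(-(alpha / m) * footrule(p, rho0)) for p in perms])
    return {p: wi / w.sum() for p, wi in zip(perms, w)}


class TestSampleMallows:
    def test_degenerate_alpha_returns_consensus(self):
        rho0 = np.array([3, 1, 4, 2, 5])
        draws = sample_mallows(rho0, 1e6, 5, seed=1)
        assert np.all(draws == rho0)

    def test_alpha_zero_is_uniform(self):
        draws = sample_mallows(np.array([1, 2, 3]), 0.0, 6000, seed=2,
                               burnin=500, thin=3)
        counts = {}
        for d in draws:
            counts[tuple(d)] = counts.get(tuple(d), 0) + 1
        # each of the 6 permutations ~1/6 within 3 binomial MC errors
        se = np.sqrt((1 / 6) * (5 / 6) / 6000)
        assert len(counts) == 6
        for c in counts.values():
            assert abs(c / 6000 - 1 / 6) < 3 * se + 0.01

    def test_pmf_matches_enumeration_at_m4(self):
        rho0 = np.array([1, 2, 3, 4])
        alpha = 3.0
        pmf = exact_mallows_pmf(tuple(rho0), alpha)
        n = 20000
        draws = sample_mallows(rho0, alpha, n, seed=3, burnin=2000, thin=4)
        counts = {}
        for d in draws:
            counts[tuple(d)] = counts.get(tuple(d), 0) + 1
        tv = 0.5 * sum(
            abs(counts.get(p, 0) / n - q) for p, q in pmf.items()
        )
        assert tv < 0.02

    def test_mean_distance_nonincreasing_in_alpha(self):
        rho0 = np.arange(1, 9)
        means = []
        for alpha in (0.5, 2.0, 5.0, 20.0):
            draws = sample_mallows(rho0, alpha, 400, seed=4)
            means.append(np.mean([footrule(d, rho0) for d in draws]))
        assert all(means[i] >= means[i + 1] - 0.8 for i in range(len(means) - 1))

    def test_seed_determinism_and_count_validation(self):
        rho0 = np.arange(1, 6)
        a = sample_mallows(rho0, 2.0, 10, seed=9)
        b = sample_mallows(rho0, 2.0, 10, seed=9)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            sample_mallows(rho0, 2.0, 0, seed=9)
        with pytest.raises(ValueError):
            sample_mallows(rho0, -1.0, 5, seed=9)


class TestTopRank:
    def test_rows_are_permutations_and_relevant_on_top(self):
        data, truth = gen_toprank(20, 8, 30, 5.0, seed=5)
        for row in data.data:
            assert is_permutation(row)
            assert set(row[truth.relevant_items]) == set(range(1, 9))

    def test_restricted_mean_distance_matches_mallows_oracle(self):
        n, n_star, alpha = 20, 8, 10.0
        data, truth = gen_toprank(n, n_star, 400, alpha, seed=6)
        order = np.argsort(truth.consensus)
        items_by_rank = truth.relevant_items[order]
        obs = np.mean([
            footrule(restrict(row, items_by_rank), np.arange(1, n_star + 1))
            for row in data.data
        ])
        ref_draws = sample_mallows(np.arange(1, n_star + 1), alpha, 2000, seed=7)
        ref = np.mean([
            footrule(d, np.arange(1, n_star + 1)) for d in ref_draws
        ])
        assert abs(obs - ref) < 0.4

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            gen_toprank(5, 6, 3, 1.0, seed=0)
        with pytest.raises(ValueError):
            gen_toprank(5, 2, 0, 1.0, seed=0)


class TestRankConsistency:
    def test_rows_are_permutations(self):
        data, _ = gen_rankconsistency(15, 5, 20, 3.0, seed=8)
        for row in data.data:
            assert is_permutation(row)

    def test_degenerate_alpha_preserves_relative_order(self):
        data, truth = gen_rankconsistency(20, 8, 25, 1e6, seed=9)
        order = np.argsort(truth.consensus)
        items_by_rank = truth.relevant_items[order]
        positions = set()
        for row in data.data:
            assert tuple(restrict(row, items_by_rank)) == tuple(range(1, 9))
            positions.add(tuple(row[items_by_rank]))
        # absolute positions vary across assessors
        assert len(positions) > 1

    def test_relative_order_distribution_matches_mallows(self):
        n, n_star, alpha = 12, 4, 3.0
        data, truth = gen_rankconsistency(n, n_star, 4000, alpha, seed=10)
        order = np.argsort(truth.consensus)
        items_by_rank = truth.relevant_items[order]
        pmf = exact_mallows_pmf(tuple(range(1, n_star + 1)), alpha)
        counts = {}
        for row in data.data:
            key = tuple(restrict(row, items_by_rank))
            counts[key] = counts.get(key, 0) + 1
        tv = 0.5 * sum(
            abs(counts.get(p, 0) / 4000 - q) for p, q in pmf.items()
        )
        assert tv < 0.04


class TestSwapNoise:
    def test_zero_levels_is_identity(self):
        data, truth = gen_toprank(20, 8, 10, 5.0, seed=11)
        out = perturb_swap_noise(data, truth, 0, seed=1)
        assert np.array_equal(out.data, data.data)

    def test_level_one_full_fraction_swaps_bottom_item(self):
        data, truth = gen_toprank(20, 8, 10, 5.0, seed=12)
        out = perturb_swap_noise(data, truth, 1, fraction=1.0, seed=2)
        bottom = truth.relevant_items[np.argsort(truth.consensus)][-1]
        changed_cols = {
            c for c in range(20)
            if not np.array_equal(out.data[:, c], data.data[:, c])
        }
        assert bottom in changed_cols
        assert len(changed_cols) == 2
        other = (changed_cols - {bottom}).pop()
        assert np.array_equal(out.data[:, bottom], data.data[:, other])
        assert np.array_equal(out.data[:, other], data.data[:, bottom])

    def test_level_schedule_touches_exactly_that_many_relevant_items(self):
        data, truth = gen_toprank(20, 8, 40, 5.0, seed=13)
        levels = 4
        out = perturb_swap_noise(data, truth, levels, fraction=0.9, seed=3)
        for row in out.data:
            assert is_permutation(row)
        by_rank = truth.relevant_items[np.argsort(truth.consensus)]
        touched = [
            i for i in truth.relevant_items
            if not np.array_equal(out.data[:, i], data.data[:, i])
        ]
        assert sorted(touched) == sorted(by_rank[-levels:])

    def test_levels_validation(self):
        data, truth = gen_toprank(10, 4, 5, 5.0, seed=14)
        with pytest.raises(ValueError):
            perturb_swap_noise(data, truth, 5, seed=0)


def test_generators_are_seed_deterministic():
    for gen in (gen_toprank, gen_rankconsistency):
        d1, t1 = gen(15, 5, 8, 2.0, seed=99)
        d2, t2 = gen(15, 5, 8, 2.0, seed=99)
        d3, _ = gen(15, 5, 8, 2.0, seed=100)
        assert np.array_equal(d1.data, d2.data)
        assert np.array_equal(t1.relevant_items, t2.relevant_items)
        assert not np.array_equal(d1.data, d3.data)
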