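"""Mallows sampling and synthetic rank-data generators.

Two data generating processes are provided for simulation studies:

* **top-rank** — a planted set of n* relevant items always occupies the top
  ranks 1..n*, with their order drawn from a Mallows model around a consensus;
  the remaining items receive a uniformly random permutation of the bottom
  ranks.  This emulates a genome-wide profile in which a block of genes is
  consistently the most expressed.
* **rank-consistency** — the relevant items keep a Mallows-consistent
  *relative* order per assessor, but their absolute rank positions are drawn
  uniformly from all n positions, so they need not be top-ranked.

A swap-noise perturbation is provided for robustness experiments: level by
level, a relevant item (starting from the bottom of the true consensus) has
its ranks exchanged with an item outside the true set for a fraction of the
assessors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .rankcore import RankMatrix

__all__ = [
    "SyntheticTruth",
    "sample_mallows",
    "gen_toprank",
    "gen_rankconsistency",
    "perturb_swap_noise",
]

_SEED_MOD = 2**31 - 1


def _derive_seed(seed, salt: int = 0) -> int:
    """Map (seed, salt) to a positive 31-bit integer seed."""
    ss = np.random.SeedSequence([int(seed) % _SEED_MOD, salt])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % _SEED_MOD)


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic rank dataset.

    ``relevant_items`` lists the planted item indices (0-based) aligned with
    ``consensus``: ``consensus[i]`` is the true consensus rank (1..n*) of item
    ``relevant_items[i]``.
    """

    relevant_items: np.ndarray
    consensus: np.ndarray
    alpha_true: float
    process: str
    noise_level: int = 0

    def __post_init__(self):
        self.relevant_items = np.asarray(self.relevant_items, dtype=np.int64)
        self.consensus = np.asarray(self.consensus, dtype=np.int64)
        if self.relevant_items.shape[0] != self.consensus.shape[0]:
            raise ValueError("relevant set size must equal consensus dimension")

    @property
    def n_star(self) -> int:
        return self.relevant_items.shape[0]


@njit(cache=True)
def _mallows_chain(rho0, alpha, count, l, burnin, thin, seed):  # pragma: no cover
    """Metropolis chain targeting P(R) ∝ exp(-(alpha/m) * footrule(R, rho0)).

    Leap-and-shift moves with window half-width ``l``; returns ``count`` states
    taken every ``thin`` moves after ``burnin`` moves.
    """
    np.random.seed(seed)
    m = rho0.shape[0]
    rho = rho0.copy()
    out = np.empty((count, m), dtype=np.int64)
    total = burnin + count * thin
    kept = 0
    for step in range(1, total + 1):
        if m > 1:
            u = np.random.randint(m)
            pu = rho[u]
            lo = max(1, pu - l)
            hi = min(m, pu + l)
            r = np.random.randint(lo, hi)  # hi - lo values available
            if r >= pu:
                r += 1
            # delta distance to rho0 from moving u to rank r with shifts
            delta = abs(r - rho0[u]) - abs(pu - rho0[u])
            if r > pu:
                for v in range(m):
                    pv = rho[v]
                    if pu < pv <= r:
                        delta += abs(pv - 1 - rho0[v]) - abs(pv - rho0[v])
            else:
                for v in range(m):
                    pv = rho[v]
                    if r <= pv < pu:
                        delta += abs(pv + 1 - rho0[v]) - abs(pv - rho0[v])
            # proposal log-ratio log Pl(rho|rho') - log Pl(rho'|rho):
            # adjacent swaps have two generating pairs and are symmetric;
            # longer leaps have exactly one pair each way, window sizes s(.)
            if abs(r - pu) == 1:
                log_ratio = 0.0
            else:
                s_fwd = min(m, pu + l) - max(1, pu - l)
                s_bwd = min(m, r + l) - max(1, r - l)
                log_ratio = np.log(s_fwd) - np.log(s_bwd)
            if np.log(np.random.random()) < log_ratio - (alpha / m) * delta:
                if r > pu:
                    for v in range(m):
                        if pu < rho[v] <= r:
                            rho[v] -= 1
                else:
                    for v in range(m):
                        if r <= rho[v] < pu:
                            rho[v] += 1
                rho[u] = r
        if step > burnin and (step - burnin) % thin == 0:
            out[kept] = rho
            kept += 1
            if kept == count:
                break
    return out


def sample_mallows(rho0, alpha, count, seed, burnin=None, thin=None, l=None):
    """Approximate draws from the footrule Mallows model.

    Parameters
    ----------
    rho0 : array-like of int
        Consensus rank vector (permutation of 1..m).
    alpha : float
        Non-negative scale (concentration) parameter.
    count : int
        Number of draws to return.
    seed : int
        Seed for the internal Metropolis chain.
    burnin, thin : int, optional
        Moves discarded before sampling and between kept states; defaults are
        1000*m and 20*m moves (the latter chosen so successive draws are
        empirically indistinguishable from independent ones at alpha ~ 0,
        where mixing is slowest for the pairwise-distance statistics).
    l : int, optional
        Leap window half-width; default max(1, round(m/5)).
    """
    rho0 = np.asarray(rho0, dtype=np.int64)
    m = rho0.shape[0]
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if burnin is None:
        burnin = 1000 * m
    if thin is None:
        thin = 20 * m
    if l is None:
        l = max(1, round(m / 5))
    l = int(min(max(1, l), max(1, m - 1)))
    draws = _mallows_chain(
        rho0, float(alpha), int(count), l, int(burnin), int(thin),
        _derive_seed(seed),
    )
    return draws


def _random_relabelling(n, rng):
    """A random permutation of item indices used to scramble generator output."""
    return rng.permutation(n)


def gen_toprank(n, n_star, N, alpha, seed) -> tuple[RankMatrix, SyntheticTruth]:
    """Top-rank data generating process.

    The n* relevant items receive ranks 1..n* per assessor via a Mallows draw
    around the consensus (1, ..., n*); the other items receive a uniformly
    random permutation of ranks n*+1..n.  Item indices are scrambled by a
    seeded relabelling so that the planted set cannot be read off the column
    order.
    """
    n, n_star, N = int(n), int(n_star), int(N)
    if not 1 <= n_star <= n:
        raise ValueError(f"need 1 <= n_star <= n, got n_star={n_star}, n={n}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    rng = np.random.default_rng(_derive_seed(seed, 1))
    rho_star = np.arange(1, n_star + 1)
    top = sample_mallows(rho_star, alpha, N, _derive_seed(seed, 2))
    data = np.empty((N, n), dtype=np.int64)
    data[:, :n_star] = top
    for j in range(N):
        data[j, n_star:] = rng.permutation(np.arange(n_star + 1, n + 1))
    relabel = _random_relabelling(n, rng)  # column i of data becomes item relabel[i]
    full = np.empty((N, n), dtype=np.int64)
    full[:, relabel] = data
    truth = SyntheticTruth(
        relevant_items=relabel[:n_star],
        consensus=rho_star,
        alpha_true=float(alpha),
        process="top_rank",
    )
    return RankMatrix(full), truth


def gen_rankconsistency(n, n_star, N, alpha, seed) -> tuple[RankMatrix, SyntheticTruth]:
    """Rank-consistency data generating process.

    Per assessor, the relative order of the n* relevant items is a Mallows draw
    around the consensus, but the n* absolute rank positions they occupy are
    drawn uniformly without replacement from 1..n; the remaining items fill the
    leftover ranks uniformly at random.
    """
    n, n_star, N = int(n), int(n_star), int(N)
    if not 1 <= n_star <= n:
        raise ValueError(f"need 1 <= n_star <= n, got n_star={n_star}, n={n}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    rng = np.random.default_rng(_derive_seed(seed, 3))
    rho_star = np.arange(1, n_star + 1)
    rel_orders = sample_mallows(rho_star, alpha, N, _derive_seed(seed, 4))
    data = np.empty((N, n), dtype=np.int64)
    all_ranks = np.arange(1, n + 1)
    for j in range(N):
        positions = np.sort(rng.choice(all_ranks, size=n_star, replace=False))
        # item with relative rank k gets the k-th smallest chosen position
        data[j, :n_star] = positions[rel_orders[j] - 1]
        rest = np.setdiff1d(all_ranks, data[j, :n_star], assume_unique=True)
        data[j, n_star:] = rng.permutation(rest)
    relabel = _random_relabelling(n, rng)
    full = np.empty((N, n), dtype=np.int64)
    full[:, relabel] = data
    truth = SyntheticTruth(
        relevant_items=relabel[:n_star],
        consensus=rho_star,
        alpha_true=float(alpha),
        process="rank_consistency",
    )
    return RankMatrix(full), truth


def perturb_swap_noise(data: RankMatrix, truth: SyntheticTruth, levels,
                       fraction=0.9, seed=0) -> RankMatrix:
    """Iterative rank-swap perturbation for robustness experiments.

    At level i (1-based), the relevant item whose true consensus rank is
    n*-i+1 has its rank exchanged with that of one item outside the true set
    (chosen without replacement across levels), for a uniformly chosen
    ceil(fraction*N) subset of assessors.
    """
    levels = int(levels)
    n_star = truth.n_star
    if levels < 0:
        raise ValueError("levels must be non-negative")
    if levels > n_star:
        raise ValueError(f"levels ({levels}) cannot exceed n_star ({n_star})")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    out = data.data.copy()
    if levels == 0:
        return RankMatrix(out, item_labels=data.item_labels)
    rng = np.random.default_rng(_derive_seed(seed, 5))
    outside = np.setdiff1d(np.arange(data.n), truth.relevant_items)
    partners = rng.choice(outside, size=levels, replace=False)
    n_aff = int(np.ceil(fraction * data.N))
    # item order: true consensus rank n*, n*-1, ...
    by_rank = truth.relevant_items[np.argsort(truth.consensus)]
    for i in range(1, levels + 1):
        target = by_rank[n_star - i]
        partner = partners[i - 1]
        rows = rng.choice(data.N, size=n_aff, replace=False)
        tmp = out[rows, target].copy()
        out[rows, target] = out[rows, partner]
        out[rows, partner] = tmp
    return RankMatrix(out, item_labels=data.item_labels)
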