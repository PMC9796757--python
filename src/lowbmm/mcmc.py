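"""Two-block Metropolis-Hastings sampler for the low-dimensional Bayesian
Mallows model (lowBMM).

The target is the joint posterior of the consensus ranking rho (a permutation
of 1..n*) and the relevant item set A* (an n*-subset of the n items), under a
footrule Mallows likelihood on the selected items, uniform priors on both
parameters, and a fixed scale parameter alpha:

    P(rho, A* | R_1..R_N)  ∝  exp( -(alpha/n*) * sum_j d_{A*}(R_j, rho) ),

where d_{A*}(R_j, rho) = sum_{i in A*} |R_ji - rho_i| is the footrule
distance between the consensus ranks (1..n*) and the *observed* ranks of the
selected items.  Selected items are thus rewarded both for agreeing with the
consensus order and for occupying the rank positions 1..n* in the data;
background items enter only through the ranks they occupy.  Because alpha is
fixed the partition function is a constant and cancels from every acceptance
ratio.

Each iteration performs a rho-update (leap-and-shift proposal with its exact
proposal-probability correction) followed by an A*-update sweep: by default
one swap proposal per assessor (swap L items with the complement, vacated
ranks reassigned uniformly to the incoming items; a symmetric joint proposal,
so the acceptance reduces to a likelihood ratio).  The sweep keeps the
item-space exploration rate commensurate with the data size; each individual
proposal is a valid MH move, so any number of attempts leaves the target
invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .rankcore import RankMatrix

__all__ = [
    "LowBMMConfig",
    "MCMCState",
    "PosteriorSamples",
    "leap_and_shift",
    "accept_rho",
    "propose_set",
    "accept_set",
    "run_lowbmm",
]

_SEED_MOD = 2**31 - 1


@dataclass
class LowBMMConfig:
    """Sampler configuration.

    ``leap_l`` defaults to round(n*/5) clipped to [1, n*-1]; ``swap_L``
    defaults to 1; ``burnin`` defaults to iterations//10.
    """

    n_star: int
    alpha: float
    iterations: int
    leap_l: int = None  # type: ignore[assignment]
    swap_L: int = 1
    burnin: int = None  # type: ignore[assignment]
    thin: int = 1
    seed: int = 0
    chains: int = 1
    set_attempts: int = None  # type: ignore[assignment]  # default: one per assessor

    def __post_init__(self):
        self.n_star = int(self.n_star)
        self.iterations = int(self.iterations)
        if self.n_star < 1:
            raise ValueError("n_star must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.leap_l is None:
            self.leap_l = max(1, round(self.n_star / 5))
        self.leap_l = int(min(max(1, self.leap_l), max(1, self.n_star - 1)))
        if self.n_star > 1 and not 1 <= self.leap_l <= self.n_star - 1:
            raise ValueError("leap_l must lie in [1, n_star-1]")
        if not 1 <= self.swap_L <= self.n_star:
            raise ValueError("swap_L must lie in [1, n_star]")
        if self.burnin is None:
            self.burnin = self.iterations // 10
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("burnin must satisfy 0 <= burnin < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.set_attempts is not None and self.set_attempts < 1:
            raise ValueError("set_attempts must be >= 1")


@dataclass
class MCMCState:
    """Chain state: ``items[p]`` is the item (0-based index) holding rank
    ``rho[p]``; rho is a permutation of 1..n*."""

    rho: np.ndarray
    items: np.ndarray


@dataclass
class PosteriorSamples:
    """Post-burn-in, thinned draws from the joint posterior.

    ``rho_samples[m, p]`` is the rank (1..n*) assigned to item
    ``aset_samples[m, p]`` in draw m; the two matrices are column-aligned.
    """

    rho_samples: np.ndarray
    aset_samples: np.ndarray
    accept_rho_rate: float
    accept_set_rate: float
    config: LowBMMConfig
    n_items: int
    chain_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_samples(self) -> int:
        return self.rho_samples.shape[0]


def _window_size(p: int, l: int, m: int) -> int:
    """|S(p)|: ranks reachable from rank p with a leap of at most l."""
    return min(m, p + l) - max(1, p - l)


def leap_and_shift(rho: np.ndarray, l: int, rng: np.random.Generator):
    """One leap-and-shift proposal.

    Picks an item u uniformly, draws a new rank r uniformly from the window
    {max(1, rho_u-l), ..., min(m, rho_u+l)} \\ {rho_u}, moves u to rank r and
    shifts the intervening items by one toward rho_u.  Returns the proposal
    together with log P_l(rho'|rho) and log P_l(rho|rho'), each being the sum
    of (1/m)(1/|S|) over all generating (item, rank) pairs: exactly one pair
    in each direction for a leap of length >= 2, exactly two for an adjacent
    swap.
    """
    rho = np.asarray(rho, dtype=np.int64)
    m = rho.shape[0]
    if not 1 <= l <= m - 1:
        raise ValueError(f"leap size l={l} out of range [1, {m - 1}]")
    u = int(rng.integers(m))
    pu = int(rho[u])
    lo, hi = max(1, pu - l), min(m, pu + l)
    r = int(rng.integers(lo, hi))
    if r >= pu:
        r += 1
    rho_prime = rho.copy()
    if r > pu:
        mask = (rho > pu) & (rho <= r)
        rho_prime[mask] -= 1
    else:
        mask = (rho >= r) & (rho < pu)
        rho_prime[mask] += 1
    rho_prime[u] = r
    s_fwd = _window_size(pu, l, m)
    s_bwd = _window_size(r, l, m)
    if abs(r - pu) == 1:
        # adjacent swap: generated by (u -> r) and by the displaced item
        # moving back; both directions carry both pairs
        p_fwd = (1.0 / m) * (1.0 / s_fwd) + (1.0 / m) * (1.0 / s_bwd)
        log_forward = math.log(p_fwd)
        log_backward = log_forward
    else:
        log_forward = -math.log(m) - math.log(s_fwd)
        log_backward = -math.log(m) - math.log(s_bwd)
    return rho_prime, log_forward, log_backward


def accept_rho(delta_d, log_forward, log_backward, alpha, n_star) -> float:
    """MH acceptance probability for the consensus update."""
    log_a = log_backward - log_forward - (alpha / n_star) * delta_d
    return min(1.0, math.exp(min(log_a, 0.0)))


def accept_set(delta_d, alpha, n_star) -> float:
    """MH acceptance probability for the item-set update (symmetric joint
    proposal, so only the likelihood ratio remains)."""
    log_a = -(alpha / n_star) * delta_d
    return min(1.0, math.exp(min(log_a, 0.0)))


def propose_set(state: MCMCState, L: int, n: int, rng: np.random.Generator):
    """Propose a new item set by swapping L members with L outsiders.

    The ranks vacated by the outgoing items are reassigned uniformly at random
    to the incoming items; ranks of surviving items are untouched.  Returns
    (items_prime, rho_prime) in the same column-aligned representation as the
    state.
    """
    n_star = state.items.shape[0]
    if not 1 <= L <= n_star:
        raise ValueError(f"swap size L={L} out of range [1, {n_star}]")
    if n_star >= n:
        raise ValueError("set update requires n_star < n")
    in_set = np.zeros(n, dtype=bool)
    in_set[state.items] = True
    complement = np.nonzero(~in_set)[0]
    pos_out = rng.choice(n_star, size=L, replace=False)
    items_in = rng.choice(complement, size=L, replace=False)
    items_prime = state.items.copy()
    # random assignment of the vacated ranks to the incoming items
    items_prime[pos_out] = rng.permutation(items_in)
    return items_prime, state.rho.copy()


@njit(cache=True)
def _lowbmm_chain(data, n_star, alpha, leap_l, swap_L, iterations, burnin,
                  thin, attempts, seed):  # pragma: no cover - exercised via run_lowbmm
    """One chain of the two-block sampler (compiled hot path).

    Mirrors ``leap_and_shift`` / ``propose_set`` / the acceptance rules; the
    stationary distribution is cross-validated against exhaustive enumeration
    of the posterior in the test suite.
    """
    np.random.seed(seed)
    N, n = data.shape
    # uniform random initial state
    perm = np.arange(n)
    for i in range(n - 1, 0, -1):
        j = np.random.randint(i + 1)
        tmp = perm[i]; perm[i] = perm[j]; perm[j] = tmp
    items = perm[:n_star].copy()
    outside = perm[n_star:].copy()
    rho = np.arange(1, n_star + 1)
    for i in range(n_star - 1, 0, -1):
        j = np.random.randint(i + 1)
        tmp = rho[i]; rho[i] = rho[j]; rho[j] = tmp
    r_sub = np.empty((N, n_star), dtype=np.int64)
    for p in range(n_star):
        r_sub[:, p] = data[:, items[p]]

    keep = (iterations - burnin) // thin
    rho_out = np.empty((keep, n_star), dtype=np.int64)
    set_out = np.empty((keep, n_star), dtype=np.int64)
    kept = 0
    acc_rho = 0
    acc_set = 0
    do_set = n_star < n
    # scratch for general-L swaps
    pos_buf = np.empty(swap_L, dtype=np.int64)
    out_buf = np.empty(swap_L, dtype=np.int64)
    for it in range(1, iterations + 1):
        # --- rho update: leap-and-shift with exact proposal correction ---
        if n_star > 1:
            u = np.random.randint(n_star)
            pu = rho[u]
            lo = max(1, pu - leap_l)
            hi = min(n_star, pu + leap_l)
            r = np.random.randint(lo, hi)
            if r >= pu:
                r += 1
            delta = 0.0
            for j in range(N):
                delta += abs(r_sub[j, u] - r) - abs(r_sub[j, u] - pu)
            if r > pu:
                for p in range(n_star):
                    pv = rho[p]
                    if pu < pv <= r:
                        for j in range(N):
                            delta += (abs(r_sub[j, p] - (pv - 1))
                                      - abs(r_sub[j, p] - pv))
            else:
                for p in range(n_star):
                    pv = rho[p]
                    if r <= pv < pu:
                        for j in range(N):
                            delta += (abs(r_sub[j, p] - (pv + 1))
                                      - abs(r_sub[j, p] - pv))
            if abs(r - pu) == 1:
                log_ratio = 0.0
            else:
                s_fwd = min(n_star, pu + leap_l) - max(1, pu - leap_l)
                s_bwd = min(n_star, r + leap_l) - max(1, r - leap_l)
                log_ratio = np.log(s_fwd) - np.log(s_bwd)
            if np.log(np.random.random()) < log_ratio - (alpha / n_star) * delta:
                if r > pu:
                    for p in range(n_star):
                        if pu < rho[p] <= r:
                            rho[p] -= 1
                else:
                    for p in range(n_star):
                        if r <= rho[p] < pu:
                            rho[p] += 1
                rho[u] = r
                acc_rho += 1
        else:
            acc_rho += 1
        # --- set update: sweep of single swap proposals ---
        if do_set:
            n_out = n - n_star
            for _a in range(attempts):
                if swap_L == 1:
                    pos = np.random.randint(n_star)
                    oidx = np.random.randint(n_out)
                    new_item = outside[oidx]
                    k = rho[pos]
                    delta = 0.0
                    for j in range(N):
                        delta += abs(data[j, new_item] - k) - abs(r_sub[j, pos] - k)
                    if np.log(np.random.random()) < -(alpha / n_star) * delta:
                        outside[oidx] = items[pos]
                        items[pos] = new_item
                        r_sub[:, pos] = data[:, new_item]
                        acc_set += 1
                else:
                    # L distinct positions out, L distinct outsiders in
                    c = 0
                    while c < swap_L:
                        cand = np.random.randint(n_star)
                        dup = False
                        for q in range(c):
                            if pos_buf[q] == cand:
                                dup = True
                        if not dup:
                            pos_buf[c] = cand
                            c += 1
                    c = 0
                    while c < swap_L:
                        cand = np.random.randint(n_out)
                        dup = False
                        for q in range(c):
                            if out_buf[q] == cand:
                                dup = True
                        if not dup:
                            out_buf[c] = cand
                            c += 1
                    # uniform random assignment of vacated ranks to incomers
                    for i in range(swap_L - 1, 0, -1):
                        j2 = np.random.randint(i + 1)
                        tmp = out_buf[i]; out_buf[i] = out_buf[j2]; out_buf[j2] = tmp
                    delta = 0.0
                    for q in range(swap_L):
                        pos = pos_buf[q]
                        new_item = outside[out_buf[q]]
                        k = rho[pos]
                        for j in range(N):
                            delta += (abs(data[j, new_item] - k)
                                      - abs(r_sub[j, pos] - k))
                    if np.log(np.random.random()) < -(alpha / n_star) * delta:
                        for q in range(swap_L):
                            pos = pos_buf[q]
                            new_item = outside[out_buf[q]]
                            outside[out_buf[q]] = items[pos]
                            items[pos] = new_item
                            r_sub[:, pos] = data[:, new_item]
                        acc_set += 1
        if it > burnin and (it - burnin) % thin == 0 and kept < keep:
            rho_out[kept] = rho
            set_out[kept] = items
            kept += 1
    return (rho_out[:kept], set_out[:kept], acc_rho, acc_set)


def _run_single_chain(data: RankMatrix, config: LowBMMConfig, seed: int):
    attempts = config.set_attempts if config.set_attempts is not None else data.N
    rho_out, set_out, acc_rho, acc_set = _lowbmm_chain(
        data.data, config.n_star, float(config.alpha), config.leap_l,
        config.swap_L, config.iterations, config.burnin, config.thin,
        attempts, seed,
    )
    do_set = config.n_star < data.n
    return (rho_out, set_out,
            acc_rho / config.iterations,
            acc_set / (config.iterations * attempts) if do_set else 0.0)


def run_lowbmm(data: RankMatrix, config: LowBMMConfig) -> PosteriorSamples:
    """Run the two-block MH sampler and collect posterior draws.

    Multiple chains are run with deterministically offset seeds and merged
    after per-chain burn-in removal.
    """
    if not isinstance(data, RankMatrix):
        data = RankMatrix(np.asarray(data))
    if config.n_star > data.n:
        raise ValueError(
            f"n_star={config.n_star} exceeds the number of items n={data.n}"
        )
    rho_all, set_all, ids = [], [], []
    rates_rho, rates_set = [], []
    for c in range(config.chains):
        seed = int(
            np.random.SeedSequence([int(config.seed) % _SEED_MOD, c])
            .generate_state(1, dtype=np.uint32)[0] % _SEED_MOD
        )
        r, s, ar, as_ = _run_single_chain(data, config, seed)
        rho_all.append(r)
        set_all.append(s)
        ids.append(np.full(r.shape[0], c, dtype=np.int64))
        rates_rho.append(ar)
        rates_set.append(as_)
    return PosteriorSamples(
        rho_samples=np.concatenate(rho_all),
        aset_samples=np.concatenate(set_all),
        accept_rho_rate=float(np.mean(rates_rho)),
        accept_set_rate=float(np.mean(rates_set)),
        config=config,
        n_items=data.n,
        chain_ids=np.concatenate(ids),
    )
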