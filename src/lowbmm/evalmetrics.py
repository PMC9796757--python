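"""Performance measures for simulation studies.

Given a true (consensus, relevant-set) pair and an estimate of the same
shape, three measures are computed:

* coverage  p-hat = ncorr / n*, the fraction of truly relevant items found;
* d_norm — footrule distance between the two consensus rank vectors on the
  shared items, divided by ncorr (infinite when no item is shared);
* d_R — Kendall distance between the relative orders of the shared items
  plus the penalty (n* - ncorr) * (n + n* + 1) / 2 for each missed item.

When the estimated set differs from the truth, both distances are evaluated
on the intersection only: the footrule uses each consensus's own rank values
for a shared item, the Kendall uses the relative orders the two consensuses
induce on the shared items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rankcore import kendall, rank_vector

__all__ = ["EvalMetrics", "coverage", "dnorm", "recovery_distance", "evaluate"]


@dataclass
class EvalMetrics:
    n_corr: int
    coverage: float
    d_norm: float
    d_recovery: float
    d_tau: int


def _aligned(consensus, items):
    """Map item -> rank for a consensus aligned with its item array."""
    items = np.asarray(items, dtype=np.int64)
    consensus = np.asarray(consensus, dtype=np.int64)
    if items.shape[0] != consensus.shape[0]:
        raise ValueError("consensus dimension must equal its item-set size")
    return dict(zip(items.tolist(), consensus.tolist()))


def coverage(true_set, est_set) -> float:
    """Fraction of truly relevant items present in the estimate."""
    true_set = np.asarray(true_set, dtype=np.int64)
    est_set = np.asarray(est_set, dtype=np.int64)
    if true_set.shape[0] != est_set.shape[0]:
        raise ValueError(
            f"set sizes differ: {true_set.shape[0]} vs {est_set.shape[0]}"
        )
    n_star = true_set.shape[0]
    return len(np.intersect1d(true_set, est_set)) / n_star


def dnorm(true_consensus, true_set, est_consensus, est_set) -> float:
    """Footrule on shared items divided by their count; inf when disjoint."""
    tmap = _aligned(true_consensus, true_set)
    emap = _aligned(est_consensus, est_set)
    shared = sorted(set(tmap) & set(emap))
    if not shared:
        return float("inf")
    d = sum(abs(tmap[i] - emap[i]) for i in shared)
    return d / len(shared)


def recovery_distance(true_consensus, true_set, est_consensus, est_set, n) -> float:
    """Kendall on shared items' relative orders plus the missed-item penalty."""
    tmap = _aligned(true_consensus, true_set)
    emap = _aligned(est_consensus, est_set)
    n_star = len(tmap)
    shared = sorted(set(tmap) & set(emap))
    n_corr = len(shared)
    if n_corr >= 2:
        t_rel = rank_vector([tmap[i] for i in shared])
        e_rel = rank_vector([emap[i] for i in shared])
        d_tau = kendall(t_rel, e_rel)
    else:
        d_tau = 0
    return d_tau + (n_star - n_corr) * (n + n_star + 1) / 2


def evaluate(true_consensus, true_set, est_consensus, est_set, n) -> EvalMetrics:
    """All three measures in one pass."""
    tmap = _aligned(true_consensus, true_set)
    emap = _aligned(est_consensus, est_set)
    n_star = len(tmap)
    shared = sorted(set(tmap) & set(emap))
    n_corr = len(shared)
    if n_corr:
        d_n = sum(abs(tmap[i] - emap[i]) for i in shared) / n_corr
    else:
        d_n = float("inf")
    if n_corr >= 2:
        d_tau = kendall(
            rank_vector([tmap[i] for i in shared]),
            rank_vector([emap[i] for i in shared]),
        )
    else:
        d_tau = 0
    d_r = d_tau + (n_star - n_corr) * (n + n_star + 1) / 2
    return EvalMetrics(
        n_corr=n_corr, coverage=n_corr / n_star, d_norm=d_n,
        d_recovery=d_r, d_tau=int(d_tau),
    )
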