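"""Posterior summaries of the lowBMM draws.

From the joint draws {(rho_m, A*_m)} the module computes:

* the selection-indicator matrix W (W_mi = 1 if item i is in A*_m) and the
  per-item selection frequencies w-bar;
* the highest probability set (HPS) A' — the k items most frequently
  selected;
* mean posterior ranks x-bar over the draws in which each HPS item was
  selected, from which the point estimates A-hat (the n* items with the
  smallest mean rank) and rho-hat (their rank order) are derived;
* top-K probabilities P(item ranked <= K | item selected), and the refined
  "top probability selection" above a probability cut-off c.

Note on direction: ranks are 1-best, so an item is *good* when its mean
posterior rank x-bar is small, and *frequently selected* when w-bar is large.
The HPS therefore takes the k items with the largest w-bar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples

__all__ = [
    "SelectionSummary",
    "selection_frequencies",
    "hps",
    "summarize",
    "topk_probabilities",
    "top_selection",
    "export_summaries",
]


@dataclass
class SelectionSummary:
    """Container for all posterior selection summaries."""

    w_bar: np.ndarray
    hps_items: np.ndarray
    x_bar: dict
    a_hat: np.ndarray
    rho_hat: np.ndarray
    k: int
    n_star: int
    topk_prob: dict = field(default_factory=dict)
    K: int = None  # type: ignore[assignment]
    cutoff_c: float = None  # type: ignore[assignment]
    a_top: np.ndarray = None  # type: ignore[assignment]


def selection_frequencies(samples: PosteriorSamples, n: int = None):
    """Selection indicator matrix W (M' x n) and its column means w-bar."""
    if samples.n_samples == 0:
        raise ValueError("no posterior samples to summarize")
    if n is None:
        n = samples.n_items
    M = samples.n_samples
    W = np.zeros((M, n), dtype=np.int8)
    rows = np.repeat(np.arange(M), samples.aset_samples.shape[1])
    W[rows, samples.aset_samples.ravel()] = 1
    return W, W.mean(axis=0)


def hps(w_bar: np.ndarray, k: int) -> np.ndarray:
    """Highest probability set: the k items with largest selection frequency.

    Ties at the boundary are broken in favour of the lower item index.
    Returns item indices sorted by decreasing w-bar (then index).
    """
    w_bar = np.asarray(w_bar, dtype=float)
    n = w_bar.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    order = np.lexsort((np.arange(n), -w_bar))
    return order[:k]


def summarize(samples: PosteriorSamples, n: int = None, k: int = None) -> SelectionSummary:
    """Compute the point estimates A-hat and rho-hat.

    ``k`` is the HPS size (defaults to n*, ie the point estimate of the set
    is the n* most frequently selected items; a larger k widens the pool of
    candidates ranked by mean posterior rank).  For each HPS item the
    mean posterior rank x-bar is averaged over the draws in which the item was
    selected; the n* items with the smallest x-bar form A-hat, ranked 1..n* by
    increasing x-bar (boundary ties broken by higher selection frequency, then
    lower item index).
    """
    if n is None:
        n = samples.n_items
    n_star = samples.config.n_star
    if k is None:
        k = n_star
    if k < n_star:
        raise ValueError(f"HPS size k={k} must be >= n_star={n_star}")
    _, w_bar = selection_frequencies(samples, n)
    hset = hps(w_bar, k)
    # mean posterior rank of each HPS item over the draws selecting it
    x_bar: dict[int, float] = {}
    kept = []
    for item in hset:
        mask = samples.aset_samples == item
        count = int(mask.sum())
        if count == 0:
            warnings.warn(
                f"HPS item {item} was never selected in any sample; excluded "
                "from the consensus estimate"
            )
            continue
        x_bar[int(item)] = float(samples.rho_samples[mask].sum() / count)
        kept.append(int(item))
    kept = np.asarray(kept, dtype=np.int64)
    if kept.shape[0] < n_star:
        raise ValueError(
            "fewer HPS items with posterior support than n_star; increase k "
            "or run a longer chain"
        )
    xb = np.array([x_bar[i] for i in kept])
    wb = w_bar[kept]
    # order by mean rank; ties by higher selection frequency, then lower index
    order = np.lexsort((kept, -wb, xb))
    a_hat = kept[order[:n_star]]
    # a_hat is sorted by increasing mean rank, so its rank vector is 1..n*
    # (this realises rank_vector(x_bar) restricted to A-hat, with the stated
    # tie-breaking applied through the sort keys)
    rho_hat = np.arange(1, n_star + 1, dtype=np.int64)
    return SelectionSummary(
        w_bar=w_bar, hps_items=hset, x_bar=x_bar, a_hat=a_hat,
        rho_hat=rho_hat, k=int(k), n_star=int(n_star),
    )


def topk_probabilities(samples: PosteriorSamples, a_hat, K: int) -> dict:
    """P(item ranked <= K | item selected) for each item of A-hat."""
    n_star = samples.config.n_star
    if not 1 <= K <= n_star:
        raise ValueError(f"K={K} out of range [1, {n_star}]")
    out: dict[int, float] = {}
    for item in np.asarray(a_hat, dtype=np.int64):
        mask = samples.aset_samples == item
        count = int(mask.sum())
        if count == 0:
            warnings.warn(f"item {item} never selected; top-K probability set to 0")
            out[int(item)] = 0.0
            continue
        out[int(item)] = float((samples.rho_samples[mask] <= K).sum() / count)
    return out


def top_selection(topk_prob: dict, cutoff_c: float) -> np.ndarray:
    """Items whose top-K probability strictly exceeds the cut-off c."""
    if not 0.0 <= cutoff_c <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff_c}")
    return np.array(
        sorted(i for i, p in topk_prob.items() if p > cutoff_c), dtype=np.int64
    )


def rank_probability_table(samples: PosteriorSamples, items=None) -> pd.DataFrame:
    """Long-format marginal posterior P(item has rank r), heatplot-ready.

    For each item, the probabilities over ranks sum to its selection
    frequency w-bar (an item contributes no mass in draws where it is not
    selected).
    """
    M = samples.n_samples
    n_star = samples.config.n_star
    if items is None:
        items = np.unique(samples.aset_samples)
    rows = []
    for item in np.asarray(items, dtype=np.int64):
        mask = samples.aset_samples == item
        ranks = samples.rho_samples[mask]
        counts = np.bincount(ranks, minlength=n_star + 1)[1:]
        for r in range(1, n_star + 1):
            if counts[r - 1]:
                rows.append((int(item), r, counts[r - 1] / M))
    return pd.DataFrame(rows, columns=["item", "rank", "probability"])


def export_summaries(samples: PosteriorSamples, summary: SelectionSummary,
                     out_prefix: str, item_labels=None) -> dict:
    """Write plot-ready tables; returns the mapping of table name to path.

    Tables: marginal rank probabilities (heatplot), selection frequencies
    (bar plot), rank traces of the estimated items, and top-K probabilities
    (violin/histogram) when computed.
    """
    def lab(i):
        return item_labels[i] if item_labels is not None else f"item{i + 1}"

    paths = {}
    rp = rank_probability_table(samples, summary.hps_items)
    rp.insert(0, "label", [lab(i) for i in rp["item"]])
    paths["rank_probabilities"] = f"{out_prefix}.rank_probabilities.tsv"
    rp.to_csv(paths["rank_probabilities"], sep="\t", index=False)

    sel = pd.DataFrame({
        "item": np.arange(summary.w_bar.shape[0]),
        "label": [lab(i) for i in range(summary.w_bar.shape[0])],
        "selection_frequency": summary.w_bar,
    })
    paths["selection_frequencies"] = f"{out_prefix}.selection_frequencies.tsv"
    sel.to_csv(paths["selection_frequencies"], sep="\t", index=False)

    # trace of the rank of each estimated item along the kept iterations
    M = samples.n_samples
    trace = np.zeros((M, summary.a_hat.shape[0]), dtype=np.int64)
    for j, item in enumerate(summary.a_hat):
        mask = samples.aset_samples == item
        sel_rows = mask.any(axis=1)
        trace[sel_rows, j] = samples.rho_samples[mask]
    tr = pd.DataFrame(trace, columns=[lab(i) for i in summary.a_hat])
    tr.insert(0, "draw", np.arange(M))
    paths["trace"] = f"{out_prefix}.trace.tsv"
    tr.to_csv(paths["trace"], sep="\t", index=False)

    if summary.topk_prob:
        tk = pd.DataFrame({
            "item": list(summary.topk_prob),
            "label": [lab(i) for i in summary.topk_prob],
            "topk_probability": list(summary.topk_prob.values()),
        })
        tk["K"] = summary.K
        paths["topk_probabilities"] = f"{out_prefix}.topk_probabilities.tsv"
        tk.to_csv(paths["topk_probabilities"], sep="\t", index=False)
    return paths
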