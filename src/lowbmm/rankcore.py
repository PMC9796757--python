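"""Permutation and rank-distance primitives.

Ranks are 1-based throughout: rank 1 is the most preferred item (the one with
the largest feature value when rankings are derived from continuous data).
Item *indices* are 0-based internally; item labels attach only at I/O
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RankMatrix",
    "is_permutation",
    "footrule",
    "kendall",
    "max_footrule",
    "rank_vector",
    "restrict",
]


def is_permutation(r: np.ndarray) -> bool:
    """True iff ``r`` is a bijection onto {1, ..., len(r)}."""
    r = np.asarray(r)
    m = r.shape[0]
    if m == 0 or r.ndim != 1:
        return False
    if not np.issubdtype(r.dtype, np.integer):
        if not np.all(r == np.floor(r)):
            return False
        r = r.astype(np.int64)
    return bool(np.array_equal(np.sort(r), np.arange(1, m + 1)))


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError(
            f"rankings have mismatched dimensions: {a.shape[0]} vs {b.shape[0]}"
        )
    return a, b


def footrule(a, b) -> int:
    """Footrule (L1) distance sum_i |a_i - b_i| between two rank vectors."""
    a, b = _check_pair(a, b)
    return int(np.abs(a - b).sum())


def kendall(a, b) -> int:
    """Kendall distance: the number of discordant item pairs.

    A pair of items (i, j) is discordant when the two rankings order them
    oppositely.
    """
    a, b = _check_pair(a, b)
    # O(m^2) pair enumeration; fine for the consensus dimensions in use.
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    return int(((da * db) < 0).sum() // 2)


def max_footrule(m: int) -> int:
    """Maximum attainable footrule distance between two rankings of length m.

    Equals floor(m^2 / 2), attained by rank reversal.
    """
    m = int(m)
    if m < 1:
        raise ValueError(f"dimension must be >= 1, got {m}")
    return m * m // 2


def rank_vector(x) -> np.ndarray:
    """Rank vector of a real vector: r_i = #{j : x_i >= x_j}.

    The smallest value receives rank 1; tied values receive equal (tied)
    counts, in which case the result is not a permutation.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot rank an empty vector")
    if np.any(~np.isfinite(x)):
        raise ValueError("rank_vector requires finite entries (found NaN/inf)")
    return (x[:, None] >= x[None, :]).sum(axis=1).astype(np.int64)


def restrict(R, S) -> np.ndarray:
    """Restrict a full ranking to an item subset, re-labelled to 1..|S|.

    ``R`` is a rank vector over n items; ``S`` is a collection of 0-based item
    indices. The result is the permutation of 1..|S| preserving the relative
    order of the selected items' ranks.
    """
    R = np.asarray(R, dtype=np.int64)
    S = np.asarray(S, dtype=np.int64)
    if S.ndim != 1 or len(np.unique(S)) != S.shape[0]:
        raise ValueError("item subset contains duplicate indices")
    if S.size and (S.min() < 0 or S.max() >= R.shape[0]):
        raise ValueError(
            f"item subset out of range for a ranking of {R.shape[0]} items"
        )
    sub = R[S]
    return rank_vector(sub)


@dataclass
class RankMatrix:
    """Complete rankings from N assessors over n items.

    Rows are assessors; every row must be a permutation of 1..n. ``data`` is
    stored as int64.
    """

    data: np.ndarray
    item_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2:
            raise ValueError("rank matrix must be 2-dimensional")
        n = self.data.shape[1]
        for j, row in enumerate(self.data):
            if not is_permutation(row):
                raise ValueError(
                    f"row {j} is not a permutation of 1..{n}: {row.tolist()}"
                )
        if self.item_labels is None:
            self.item_labels = [f"item{i + 1}" for i in range(n)]
        self.item_labels = list(self.item_labels)
        if len(self.item_labels) != n:
            raise ValueError(
                f"{len(self.item_labels)} labels for {n} items"
            )
        if len(set(self.item_labels)) != n:
            raise ValueError("item labels must be unique")

    @property
    def N(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    def restricted(self, S) -> np.ndarray:
        """All rows restricted to the item subset S (N x |S| matrix)."""
        S = np.asarray(S, dtype=np.int64)
        sub = self.data[:, S]
        # relative ranks per row via double argsort (rows have distinct ranks)
        order = np.argsort(sub, axis=1, kind="stable")
        out = np.empty_like(sub)
        np.put_along_axis(out, order, np.arange(1, S.shape[0] + 1)[None, :], axis=1)
        return out
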