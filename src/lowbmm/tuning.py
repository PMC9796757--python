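"""Off-line estimation of the Mallows scale parameter alpha.

The sampler keeps alpha fixed so that the partition function cancels from all
acceptance ratios; its value is instead tuned before fitting.  The idea: a
larger alpha concentrates rankings around the consensus, hence lowers the
mean pairwise footrule distance between assessors.  We simulate full
Mallows(rho0, alpha0) datasets of the same shape (N, n) as the data over a
grid of alpha0 values, record the simulated mean pairwise distances, and take
the alpha0 at which the simulated curve crosses the observed mean pairwise
distance (piecewise-linear interpolation).  The choice of rho0 is irrelevant
by right-invariance; the identity is used.

Because that estimate lives in dimension n while the low-dimensional model
works in dimension n*, it is rescaled to the lower dimension as

    alpha_n* = alpha_n * (n/n*) * (maxd_n* / maxd_n)  ~  alpha_n * (n*/n),

where maxd_m = floor(m^2/2) is the maximal footrule distance in dimension m:
the scale parameter shrinks roughly proportionally to the dimension, keeping
the per-distance-unit weight alpha/(m * maxd_m) comparable across dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rankcore import RankMatrix, max_footrule
from .samplers import sample_mallows, _derive_seed

__all__ = [
    "AlphaTuneResult",
    "mean_pairwise_distance",
    "estimate_alpha",
    "rescale_alpha",
    "default_grid",
]


@dataclass
class AlphaTuneResult:
    """Grid, simulated distance curve, and the matched estimates."""

    grid: np.ndarray
    mean_dist_curve: np.ndarray
    data_mean_dist: float
    alpha_hat_n: float
    alpha_hat_nstar: float = None  # type: ignore[assignment]
    maxd_n: int = None  # type: ignore[assignment]
    maxd_nstar: int = None  # type: ignore[assignment]


def mean_pairwise_distance(data) -> float:
    """Mean footrule distance over all ordered assessor pairs."""
    mat = data.data if isinstance(data, RankMatrix) else np.asarray(data)
    N = mat.shape[0]
    if N < 2:
        raise ValueError("need at least 2 assessors for a pairwise distance")
    # sum_{j != k} |R_j - R_k| via pairwise broadcast; N is small in practice
    total = np.abs(mat[:, None, :] - mat[None, :, :]).sum()
    return float(total / (N * (N - 1)))


def default_grid(lo: float = 0.01, hi: float = 100.0, num: int = 12) -> np.ndarray:
    """Geometric alpha0 grid spanning several orders of magnitude."""
    return np.geomspace(lo, hi, num)


def estimate_alpha(data: RankMatrix, grid=None, reps_per_point: int = 10,
                   seed: int = 0, n_star: int = None) -> AlphaTuneResult:
    """Estimate alpha by matching mean pairwise distances on a grid.

    For each grid value alpha0, ``reps_per_point`` datasets of the data's
    shape are simulated from Mallows(identity, alpha0) and their mean pairwise
    distances averaged.  The estimate alpha_hat_n is the abscissa where the
    (decreasing) simulated curve crosses the observed distance, by linear
    interpolation between the bracketing grid points.  When ``n_star`` is
    given the rescaled alpha_hat_nstar is filled in as well.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.shape[0] < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    N, n = data.N, data.n
    d_obs = mean_pairwise_distance(data)
    rho0 = np.arange(1, n + 1)
    curve = np.empty_like(grid)
    for g, a0 in enumerate(grid):
        dists = []
        for rep in range(reps_per_point):
            draws = sample_mallows(
                rho0, a0, N, _derive_seed(seed, 1000 * g + rep)
            )
            dists.append(mean_pairwise_distance(RankMatrix(draws)))
        curve[g] = np.mean(dists)

    lo, hi = float(curve.min()), float(curve.max())
    if not lo <= d_obs <= hi:
        raise ValueError(
            f"observed mean distance {d_obs:.2f} lies outside the simulated "
            f"curve range [{lo:.2f}, {hi:.2f}]; extend the alpha grid"
        )
    # first crossing, scanning from small alpha (curve decreasing in alpha)
    alpha_hat = None
    for g in range(grid.shape[0] - 1):
        y0, y1 = curve[g], curve[g + 1]
        if (y0 - d_obs) * (y1 - d_obs) <= 0:
            if y0 == y1:
                alpha_hat = float(grid[g])
            else:
                t = (y0 - d_obs) / (y0 - y1)
                alpha_hat = float(grid[g] + t * (grid[g + 1] - grid[g]))
            break
    if alpha_hat is None:  # pragma: no cover - guarded by the range check
        raise ValueError("no crossing found; extend the alpha grid")
    result = AlphaTuneResult(
        grid=grid, mean_dist_curve=curve, data_mean_dist=d_obs,
        alpha_hat_n=alpha_hat, maxd_n=max_footrule(n),
    )
    if n_star is not None:
        result.alpha_hat_nstar = rescale_alpha(alpha_hat, n, n_star)
        result.maxd_nstar = max_footrule(n_star)
    return result


def rescale_alpha(alpha_hat_n: float, n: int, n_star: int) -> float:
    """Rescale a dimension-n alpha estimate to dimension n*.

    alpha* = alpha * (n/n*) * (maxd_n* / maxd_n), approximately
    alpha * n*/n since maxd_m grows like m^2/2.
    """
    if not 1 <= n_star <= n:
        raise ValueError(f"need 1 <= n_star <= n, got n_star={n_star}, n={n}")
    return float(
        alpha_hat_n * (n / n_star) * (max_footrule(n_star) / max_footrule(n))
    )
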