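"""Model/Results interface to the low-dimensional Bayesian Mallows model.

``LowBMM`` is built from a rank matrix (or a continuous feature matrix via
:meth:`LowBMM.from_expression`); :meth:`LowBMM.fit` runs the two-block MH
sampler and returns a :class:`LowBMMResults` carrying the posterior draws,
point estimates, acceptance diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import posterior as _post
from .io import expression_to_ranks
from .mcmc import LowBMMConfig, PosteriorSamples, run_lowbmm
from .rankcore import RankMatrix

__all__ = ["LowBMM", "LowBMMResults"]


class LowBMM:
    """Bayesian Mallows model with unsupervised item selection.

    Parameters
    ----------
    data : RankMatrix or array-like
        N complete rankings over n items (each row a permutation of 1..n).
    n_star : int
        Number of relevant items to select (fixed model dimension).
    alpha : float
        Fixed Mallows scale parameter (see :mod:`lowbmm.tuning` for the
        off-line estimation procedure).
    leap_l, swap_L : int, optional
        Proposal tuning parameters: leap window for the consensus update
        (default round(n*/5), clipped to [1, n*-1]) and number of items
        exchanged per set update (default 1, recommended).
    """

    def __init__(self, data, n_star, alpha, leap_l=None, swap_L=1):
        if not isinstance(data, RankMatrix):
            data = RankMatrix(np.asarray(data))
        if n_star > data.n:
            raise ValueError(f"n_star={n_star} exceeds n={data.n}")
        self.data = data
        self.n_star = int(n_star)
        self.alpha = float(alpha)
        self.leap_l = leap_l
        self.swap_L = int(swap_L)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_star, alpha, **kwargs) -> "LowBMM":
        """Build from a DataFrame of rankings (columns = item labels)."""
        data = RankMatrix(df.to_numpy(dtype=np.int64), item_labels=list(df.columns))
        return cls(data, n_star, alpha, **kwargs)

    @classmethod
    def from_expression(cls, matrix, n_star, alpha, seed=0, **kwargs) -> "LowBMM":
        """Build from continuous samples x features data (largest value gets
        rank 1; ties broken uniformly at random with ``seed``)."""
        return cls(expression_to_ranks(matrix, seed=seed), n_star, alpha, **kwargs)

    def fit(self, iterations, burnin=None, thin=1, chains=1, seed=0) -> "LowBMMResults":
        """Run the MH-MCMC sampler and return the results object."""
        config = LowBMMConfig(
            n_star=self.n_star, alpha=self.alpha, iterations=iterations,
            leap_l=self.leap_l, swap_L=self.swap_L, burnin=burnin,
            thin=thin, seed=seed, chains=chains,
        )
        samples = run_lowbmm(self.data, config)
        return LowBMMResults(self, samples)


class LowBMMResults:
    """Posterior draws and summaries of a fitted lowBMM."""

    def __init__(self, model: LowBMM, samples: PosteriorSamples):
        self.model = model
        self.samples = samples
        self._summary = None

    # -- selection summaries ------------------------------------------------

    @property
    def selection_frequencies(self) -> np.ndarray:
        """Per-item posterior selection frequency w-bar."""
        return self.selection_summary().w_bar

    def selection_summary(self, k=None) -> _post.SelectionSummary:
        """Point estimates (A-hat, rho-hat) via the HPS of size k."""
        if self._summary is None or (k is not None and k != self._summary.k):
            self._summary = _post.summarize(self.samples, k=k)
        return self._summary

    @property
    def selected_items(self) -> np.ndarray:
        """Estimated relevant item indices A-hat, ordered by estimated rank."""
        return self.selection_summary().a_hat

    @property
    def consensus_estimate(self) -> np.ndarray:
        """Estimated consensus ranks rho-hat aligned with ``selected_items``."""
        return self.selection_summary().rho_hat

    @property
    def selected_labels(self) -> list:
        return [self.model.data.item_labels[i] for i in self.selected_items]

    def topk_probabilities(self, K) -> dict:
        """P(rank <= K | selected) per estimated item."""
        return _post.topk_probabilities(self.samples, self.selected_items, K)

    def top_selection(self, K, cutoff_c) -> np.ndarray:
        """Refined selection: items whose top-K probability exceeds c."""
        summary = self.selection_summary()
        probs = self.topk_probabilities(K)
        summary.topk_prob, summary.K, summary.cutoff_c = probs, K, cutoff_c
        summary.a_top = _post.top_selection(probs, cutoff_c)
        return summary.a_top

    def export(self, out_prefix) -> dict:
        """Write plot-ready TSV tables; returns name -> path."""
        return _post.export_summaries(
            self.samples, self.selection_summary(), out_prefix,
            item_labels=self.model.data.item_labels,
        )

    # -- diagnostics --------------------------------------------------------

    @property
    def accept_rho_rate(self) -> float:
        return self.samples.accept_rho_rate

    @property
    def accept_set_rate(self) -> float:
        return self.samples.accept_set_rate

    def summary(self, k=None) -> str:
        """Human-readable fit summary table."""
        s = self.selection_summary(k=k)
        cfg = self.samples.config
        lines = [
            "Low-dimensional Bayesian Mallows model",
            "=" * 54,
            f"Items (n):            {self.model.data.n}",
            f"Assessors (N):        {self.model.data.N}",
            f"Selected items (n*):  {cfg.n_star}",
            f"alpha (fixed):        {cfg.alpha:g}",
            f"MCMC iterations:      {cfg.iterations} "
            f"(burn-in {cfg.burnin}, thin {cfg.thin}, chains {cfg.chains})",
            f"Posterior draws:      {self.samples.n_samples}",
            f"Acceptance rho:       {self.accept_rho_rate:.3f}",
            f"Acceptance set:       {self.accept_set_rate:.3f}",
            "-" * 54,
            f"{'rank':>4}  {'item':<20} {'sel.freq':>8}  {'mean rank':>9}",
        ]
        for rank, item in zip(s.rho_hat, s.a_hat):
            lines.append(
                f"{rank:>4}  {self.model.data.item_labels[item]:<20} "
                f"{s.w_bar[item]:>8.3f}  {s.x_bar[int(item)]:>9.2f}"
            )
        return "\n".join(lines)
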