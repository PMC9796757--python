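"""Reading and writing rank matrices, posterior samples, and run artifacts.

Rank matrices are stored as TSV/CSV with a header of item labels and one row
per assessor; rank values in files are 1-based, internal item indices are
0-based.  Posterior samples use a portable wide TSV (chain, draw, then the
selected item labels and their ranks).  Truth, config, and summary objects
are JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .mcmc import LowBMMConfig, PosteriorSamples
from .rankcore import RankMatrix
from .samplers import SyntheticTruth, _derive_seed

__all__ = [
    "read_rank_matrix",
    "write_rank_matrix",
    "expression_to_ranks",
    "write_truth",
    "read_truth",
    "write_samples",
    "read_samples",
]


def read_rank_matrix(path) -> RankMatrix:
    """Read and validate a rank matrix from TSV/CSV (header = item labels)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"{path}: empty rank matrix")
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing values")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(values != np.floor(values)):
        raise ValueError(f"{path}: non-integer rank values")
    return RankMatrix(values.astype(np.int64), item_labels=list(df.columns))


def write_rank_matrix(data: RankMatrix, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(data.data, columns=data.item_labels).to_csv(
        path, sep=sep, index=False
    )


def expression_to_ranks(matrix, seed: int = 0, item_labels=None) -> RankMatrix:
    """Convert a continuous samples x features matrix to per-sample rankings.

    The largest value in a row receives rank 1.  Ties are broken uniformly at
    random (seeded) so every row is a proper permutation.  Missing values are
    rejected: imputation belongs upstream.
    """
    if isinstance(matrix, pd.DataFrame):
        if item_labels is None:
            item_labels = list(matrix.columns)
        matrix = matrix.to_numpy()
    x = np.asarray(matrix, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError(
            "expression matrix contains NaN/inf; impute missing values first"
        )
    rng = np.random.default_rng(_derive_seed(seed, 7))
    N, n = x.shape
    out = np.empty((N, n), dtype=np.int64)
    for j in range(N):
        jitter = rng.permutation(n)  # random tie-break, rank-preserving
        order = np.lexsort((jitter, -x[j]))  # descending: largest first
        out[j, order] = np.arange(1, n + 1)
    return RankMatrix(out, item_labels=item_labels)


def write_truth(truth: SyntheticTruth, path, item_labels=None) -> None:
    def lab(i):
        return item_labels[i] if item_labels is not None else int(i)

    obj = {
        "relevant_items": [lab(i) for i in truth.relevant_items],
        "relevant_indices": truth.relevant_items.tolist(),
        "consensus": truth.consensus.tolist(),
        "alpha_true": truth.alpha_true,
        "process": truth.process,
        "noise_level": truth.noise_level,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        obj = json.load(fh)
    return SyntheticTruth(
        relevant_items=np.asarray(obj["relevant_indices"], dtype=np.int64),
        consensus=np.asarray(obj["consensus"], dtype=np.int64),
        alpha_true=float(obj["alpha_true"]),
        process=obj["process"],
        noise_level=int(obj.get("noise_level", 0)),
    )


def write_samples(samples: PosteriorSamples, path) -> None:
    """Persist draws as wide TSV: chain, draw, item_p columns, rank_p columns."""
    M, n_star = samples.rho_samples.shape
    cols = {"chain": samples.chain_ids if samples.chain_ids is not None
            else np.zeros(M, dtype=np.int64),
            "draw": np.arange(M)}
    for p in range(n_star):
        cols[f"item_{p + 1}"] = samples.aset_samples[:, p]
    for p in range(n_star):
        cols[f"rank_{p + 1}"] = samples.rho_samples[:, p]
    header = (f"# n_items={samples.n_items} n_star={n_star} "
              f"alpha={samples.config.alpha} "
              f"accept_rho={samples.accept_rho_rate:.6f} "
              f"accept_set={samples.accept_set_rate:.6f}\n")
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False)


def read_samples(path) -> PosteriorSamples:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(
            kv.split("=") for kv in header.lstrip("# ").strip().split()
        )
        df = pd.read_csv(fh, sep="\t")
    n_star = int(meta["n_star"])
    aset = df[[f"item_{p + 1}" for p in range(n_star)]].to_numpy(dtype=np.int64)
    rho = df[[f"rank_{p + 1}" for p in range(n_star)]].to_numpy(dtype=np.int64)
    config = LowBMMConfig(
        n_star=n_star, alpha=float(meta["alpha"]),
        iterations=max(2, len(df)), burnin=0,
    )
    return PosteriorSamples(
        rho_samples=rho, aset_samples=aset,
        accept_rho_rate=float(meta["accept_rho"]),
        accept_set_rate=float(meta["accept_set"]),
        config=config, n_items=int(meta["n_items"]),
        chain_ids=df["chain"].to_numpy(dtype=np.int64),
    )
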