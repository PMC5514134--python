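"""Partial-correlation (graphical Gaussian model) co-expression networks.

The estimator is the Schaefer-Strimmer shrinkage estimator: the sample
correlation matrix is shrunk toward the identity with the analytic
unbiased-risk intensity, inverted, and standardized to partial
correlations.  Gene pairs with pcor at or above a cutoff (default 0.04)
become network edges; an empirical FDR for the cutoff is obtained by
permuting each gene's sample labels independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("motifnet")

#: edge-selection cutoff used for the human network configuration
DEFAULT_PCOR_CUTOFF = 0.04


class NetworkError(ValueError):
    pass


@dataclass
class PcorResult:
    """Symmetric partial-correlation estimates plus estimator metadata.

    ``pcor[i, j]`` is the estimate for gene pair (i, j); the diagonal is 1
    by convention and never becomes an edge.  ``coverage`` (subsampled
    estimator only) counts the iterations in which both genes of a pair
    co-occurred; pairs under the coverage floor are NaN (missing).
    """

    genes: list[str]
    pcor: np.ndarray
    shrinkage: float
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = len(self.genes)
        if self.pcor.shape != (p, p):
            raise NetworkError("pcor matrix shape mismatch")
        self._index = {g: k for k, g in enumerate(self.genes)}

    def get(self, a: str, b: str) -> float:
        return float(self.pcor[self._index[a], self._index[b]])

    def pairs(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.genes), k=1)
        return pd.DataFrame(
            {
                "gene_a": [self.genes[i] for i in iu],
                "gene_b": [self.genes[j] for j in ju],
                "pcor": self.pcor[iu, ju],
            }
        )


def _standardize(X: pd.DataFrame) -> np.ndarray:
    vals = X.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise NetworkError("expression matrix contains missing values; impute upstream")
    sd = vals.std(axis=1, ddof=1)
    constant = [g for g, s in zip(X.index, sd) if s == 0 or not np.isfinite(s)]
    if constant:
        raise NetworkError(f"constant (zero-variance) genes: {constant}")
    return (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]


def shrinkage_intensity(Z: np.ndarray) -> float:
    """Analytic shrinkage weight toward the identity correlation target.

    lambda* = sum_{i<j} Var-hat(r_ij) / sum_{i<j} r_ij^2, clamped to [0, 1],
    with Var-hat(r_ij) = n/(n-1)^3 * sum_k (w_kij - w-bar_ij)^2 for
    w_kij = z_ik z_jk on standardized data.
    """
    p, n = Z.shape
    C = Z @ Z.T  # sum_k z_ik z_jk
    R = C / (n - 1)
    S2 = (Z**2) @ (Z**2).T  # sum_k (z_ik z_jk)^2
    var_r = n / (n - 1) ** 3 * (S2 - C**2 / n)
    iu = np.triu_indices(p, k=1)
    denom = float((R[iu] ** 2).sum())
    if denom == 0.0:
        return 1.0
    lam = float(var_r[iu].sum()) / denom
    return float(min(1.0, max(0.0, lam)))


def estimate_pcor(X: pd.DataFrame) -> PcorResult:
    """Shrinkage partial correlations for a genes x samples expression matrix.

    Rows are standardized internally; requires at least 3 samples and no
    constant genes.  Deterministic (no randomness).
    """
    if X.shape[1] < 3:
        raise NetworkError("need at least 3 samples to estimate partial correlations")
    Z = _standardize(X)
    p, n = Z.shape
    R = Z @ Z.T / (n - 1)
    lam = shrinkage_intensity(Z)
    R_star = (1.0 - lam) * R
    np.fill_diagonal(R_star, 1.0)
    omega = np.linalg.inv(R_star)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip((pcor + pcor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pcor, 1.0)
    return PcorResult(list(X.index), pcor, shrinkage=lam)


def estimate_pcor_subsampled(
    X: pd.DataFrame,
    subset_size: int,
    iterations: int,
    min_pair_coverage: int = 1,
    seed: int = 0,
) -> PcorResult:
    """Average shrinkage pcor over random gene subsets (for large gene panels).

    Each iteration draws ``subset_size`` genes without replacement and runs
    :func:`estimate_pcor` on the sub-matrix; a pair's estimate is the mean
    over iterations where both genes co-occurred.  Pairs seen fewer than
    ``min_pair_coverage`` times are NaN.
    """
    p = X.shape[0]
    if subset_size > p:
        raise NetworkError("subset_size exceeds the number of genes")
    if subset_size < 3 or iterations < 1:
        raise NetworkError("need subset_size >= 3 and iterations >= 1")
    rng = np.random.default_rng(seed)
    logger.info("estimate_pcor_subsampled: p=%d subset=%d iters=%d seed=%d",
                p, subset_size, iterations, seed)
    acc = np.zeros((p, p))
    cov = np.zeros((p, p), dtype=int)
    lams = []
    for _ in range(iterations):
        idx = np.sort(rng.choice(p, size=subset_size, replace=False))
        sub = estimate_pcor(X.iloc[idx])
        lams.append(sub.shrinkage)
        acc[np.ix_(idx, idx)] += sub.pcor
        cov[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cov > 0, acc / np.maximum(cov, 1), np.nan)
    mean[cov < min_pair_coverage] = np.nan
    np.fill_diagonal(mean, 1.0)
    return PcorResult(list(X.index), mean, shrinkage=float(np.mean(lams)), coverage=cov)


@dataclass
class CoexpressionNetwork:
    """Undirected gene network with pcor edge weights at or above the cutoff."""

    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def to_tsv(self, path) -> None:
        rows = [
            {"gene_a": a, "gene_b": b, "pcor": w}
            for a, b, w in sorted(self.graph.edges(data="weight"))
        ]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcor"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, cutoff: float = 0.0) -> "CoexpressionNetwork":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for a, b, w in df.itertuples(index=False):
            g.add_edge(str(a), str(b), weight=float(w))
        return cls(g, cutoff)


def build_network(
    pcor: PcorResult, cutoff: float = DEFAULT_PCOR_CUTOFF, absolute: bool = False
) -> CoexpressionNetwork:
    """Threshold pcor estimates into a network; only nodes with >= 1 edge are kept.

    By default the rule is signed (pcor >= cutoff); ``absolute`` keeps
    |pcor| >= cutoff instead.  NaN pairs (insufficient subsample coverage)
    never become edges.
    """
    vals = np.abs(pcor.pcor) if absolute else pcor.pcor
    iu, ju = np.triu_indices(len(pcor.genes), k=1)
    with np.errstate(invalid="ignore"):
        keep = vals[iu, ju] >= cutoff
    keep &= ~np.isnan(pcor.pcor[iu, ju])
    g = nx.Graph()
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(pcor.genes[i], pcor.genes[j], weight=float(pcor.pcor[i, j]))
    net = CoexpressionNetwork(g, cutoff)
    logger.info("build_network: cutoff=%.4g -> %d nodes, %d edges",
                cutoff, g.number_of_nodes(), g.number_of_edges())
    return net


def edge_fdr(
    X: pd.DataFrame,
    cutoff: float = DEFAULT_PCOR_CUTOFF,
    n_perm: int = 10,
    seed: int = 0,
    absolute: bool = False,
) -> dict:
    """Empirical FDR of the pcor edge cutoff by per-gene sample permutation.

    Each permutation shuffles every gene's sample labels independently
    (destroying all co-expression while keeping marginals), re-estimates
    pcor, and counts null pairs passing the cutoff.  FDR = mean null count /
    observed count (0 when both are 0; NaN if nothing is observed but the
    null still produces edges).
    """
    if n_perm < 1:
        raise NetworkError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def _count(frame: pd.DataFrame) -> int:
        r = estimate_pcor(frame)
        vals = np.abs(r.pcor) if absolute else r.pcor
        iu, ju = np.triu_indices(len(r.genes), k=1)
        return int((vals[iu, ju] >= cutoff).sum())

    observed = _count(X)
    null_counts = []
    vals = X.to_numpy(dtype=float)
    for _ in range(n_perm):
        perm = np.array([row[rng.permutation(vals.shape[1])] for row in vals])
        null_counts.append(_count(pd.DataFrame(perm, index=X.index, columns=X.columns)))
    mean_null = float(np.mean(null_counts))
    if observed == 0:
        fdr = 0.0 if mean_null == 0 else float("nan")
    else:
        fdr = mean_null / observed
    logger.info("edge_fdr: observed=%d mean_null=%.2f fdr=%.4g (%d perms, seed=%d)",
                observed, mean_null, fdr, n_perm, seed)
    return {
        "fdr": fdr,
        "observed_edges": observed,
        "mean_null_edges": mean_null,
        "null_counts": null_counts,
    }
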