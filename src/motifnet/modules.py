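"""Sub-network extraction and Markov clustering into co-expression modules.

The target-gene sub-network is partitioned with the Markov Cluster
algorithm (MCL): random-walk flow on the weighted graph is alternately
expanded (matrix power) and inflated (entrywise power + column
renormalization) until it converges to a set of attractors, whose basins
are the modules.  Edge weights (partial correlations, non-negative under
the signed edge rule) are used directly as similarities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import CoexpressionNetwork

logger = logging.getLogger("motifnet")

DEFAULT_INFLATION = 2.0
DEFAULT_EXPANSION = 2
DEFAULT_PRUNE = 1e-5


class ClusterError(ValueError):
    pass


def extract_subnetwork(
    network: CoexpressionNetwork, genes
) -> CoexpressionNetwork:
    """Induced subgraph on the given genes, edge weights preserved."""
    genes = set(genes)
    keep = genes & set(network.graph.nodes)
    if not keep:
        warnings.warn("no requested genes occur in the network; empty sub-network",
                      stacklevel=2)
    sub = network.graph.subgraph(keep).copy()
    logger.info("extract_subnetwork: %d/%d genes present, %d edges",
                len(keep), len(genes), sub.number_of_edges())
    return CoexpressionNetwork(sub, network.cutoff)


@dataclass
class ModulePartition:
    """MCL modules, 1-based ids ordered by descending size; module 1 is largest.

    Clusters of a single gene are reported as ``singletons`` rather than
    modules.  ``converged`` is False when the flow matrix hit max_iter.
    """

    modules: dict[int, list[str]]
    singletons: list[str] = field(default_factory=list)
    converged: bool = True
    n_iterations: int = 0

    def labels(self) -> dict[str, int]:
        out = {}
        for mid, genes in self.modules.items():
            for g in genes:
                out[g] = mid
        return out

    def to_tsv(self, path) -> None:
        rows = [{"gene": g, "module": m} for m, gs in self.modules.items() for g in gs]
        rows += [{"gene": g, "module": 0} for g in self.singletons]
        pd.DataFrame(rows, columns=["gene", "module"]).to_csv(path, sep="\t", index=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"module": list(self.modules), "size": [len(v) for v in self.modules.values()]}
        )


def mcl_cluster(
    network: CoexpressionNetwork,
    inflation: float = DEFAULT_INFLATION,
    expansion: int = DEFAULT_EXPANSION,
    prune_below: float = DEFAULT_PRUNE,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ModulePartition:
    """Markov clustering of a weighted co-expression (sub-)network.

    Self-loops are added with weight equal to the node's maximum incident
    edge weight (a standard regularization keeping attractors stable), the
    matrix is made column-stochastic, then expansion and inflation
    alternate with pruning of entries below ``prune_below`` until the
    largest entry change falls under ``tol``.  Nodes attracted to several
    attractor systems go to the larger cluster (ties: lower module id).
    Deterministic: nodes are canonically sorted before anything else.
    """
    if inflation <= 1.0:
        raise ClusterError("inflation must be > 1")
    if expansion < 2:
        raise ClusterError("expansion must be >= 2")
    nodes = sorted(network.graph.nodes)
    if not nodes:
        return ModulePartition(modules={}, singletons=[])
    A = nx.to_numpy_array(network.graph, nodelist=nodes, weight="weight")
    A = np.abs(A)
    loop = A.max(axis=1)
    loop[loop == 0] = 1.0
    np.fill_diagonal(A, loop)
    M = A / A.sum(axis=0, keepdims=True)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M[M < prune_below] = 0.0
        col = M.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        M = M / col
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations", stacklevel=2)

    # attractors: rows with (numerically) positive diagonal mass
    eps = max(prune_below, 1e-9)
    attractors = np.nonzero(np.diag(M) > eps)[0]
    # attractor systems: attractors flowing into each other share a cluster
    parent = {int(a): int(a) for a in attractors}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in attractors:
        for b in attractors:
            if a < b and (M[a, b] > eps or M[b, a] > eps):
                ra, rb = find(int(a)), find(int(b))
                if ra != rb:
                    parent[rb] = ra
    systems: dict[int, set[int]] = {}
    for a in attractors:
        systems.setdefault(find(int(a)), set()).add(int(a))

    raw: list[set[int]] = []
    for members in systems.values():
        basin = set(members)
        for a in members:
            basin |= set(np.nonzero(M[a] > eps)[0].tolist())
        raw.append(basin)
    # resolve overlaps: a node claimed by several basins goes to the largest
    raw.sort(key=lambda s: (-len(s), min(s) if s else 0))
    assigned: dict[int, int] = {}
    for cid, basin in enumerate(raw):
        for node in basin:
            if node not in assigned:
                assigned[node] = cid
    leftovers = [j for j in range(len(nodes)) if j not in assigned]
    clusters: dict[int, list[str]] = {}
    for node, cid in assigned.items():
        clusters.setdefault(cid, []).append(nodes[node])
    cluster_lists = [sorted(v) for v in clusters.values()] + [[nodes[j]] for j in leftovers]
    cluster_lists.sort(key=lambda gs: (-len(gs), gs[0]))

    modules = {}
    singletons = []
    mid = 0
    for gs in cluster_lists:
        if len(gs) >= 2:
            mid += 1
            modules[mid] = gs
        else:
            singletons.extend(gs)
    logger.info("mcl_cluster: inflation=%.2g -> %d modules, %d singletons (%d iterations)",
                inflation, len(modules), len(singletons), it)
    return ModulePartition(modules=modules, singletons=sorted(singletons),
                           converged=converged, n_iterations=it)
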