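"""Synthetic promoters, expression matrices, and binding tables with known truth.

Everything downstream of this module — scanning, network estimation, target
calling, clustering, enrichment — is exercised against data generated here,
where the planted signal (motif positions, co-expression blocks, bound
fractions) is recorded exactly.  All generators are bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .promoters import PWM, PromoterSet

logger = logging.getLogger("motifnet")

#: mean length (bp) of masked repeat/transposon-like runs
MASK_RUN_MEAN = 150.0


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators.

    planted_positions maps gene -> TSS-relative anchors of planted motif
    words; module_labels maps gene -> planted co-expression block id;
    bound_genes is the set flagged bound by :func:`generate_binding_table`.
    """

    planted_target_genes: set[str] = field(default_factory=set)
    planted_positions: dict[str, list[int]] = field(default_factory=dict)
    module_labels: dict[str, int] = field(default_factory=dict)
    bound_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not set(self.planted_positions) <= self.planted_target_genes:
            raise SyntheticError("planted_positions keys must be planted target genes")
        sizes: dict[int, int] = {}
        for m in self.module_labels.values():
            sizes[m] = sizes.get(m, 0) + 1
        if any(v < 2 for v in sizes.values()):
            raise SyntheticError("every module id must label at least 2 genes")

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        pos = {g: list(v) for g, v in self.planted_positions.items()}
        for g, v in other.planted_positions.items():
            pos.setdefault(g, []).extend(v)
        return SyntheticTruth(
            self.planted_target_genes | other.planted_target_genes,
            pos,
            {**self.module_labels, **other.module_labels},
            self.bound_genes | other.bound_genes,
        )

    def to_tsv(self, path) -> None:
        rows = []
        genes = (
            self.planted_target_genes
            | set(self.module_labels)
            | self.bound_genes
        )
        for g in sorted(genes):
            rows.append(
                {
                    "gene": g,
                    "planted_target": int(g in self.planted_target_genes),
                    "positions": ",".join(map(str, self.planted_positions.get(g, []))),
                    "module": self.module_labels.get(g, -1),
                    "bound": int(g in self.bound_genes),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- promoters ---------------------------------------------------------------


def generate_promoters(
    n_genes: int,
    upstream: int,
    downstream: int,
    mask_fraction: float,
    seed: int,
    gene_prefix: str = "g",
    gene_ids: Sequence[str] | None = None,
) -> PromoterSet:
    """Random i.i.d.-uniform A/C/G/T promoters with repeat-like masked runs.

    Masked intervals are laid down as geometric-length runs (mean
    ``MASK_RUN_MEAN`` bp) at uniform start points until at least
    ``mask_fraction`` of each promoter's positions are masked — emulating
    repeat/transposon blocks rather than salt-and-pepper masking.
    """
    if upstream < 0 or downstream < 0 or upstream + downstream < 1:
        raise SyntheticError("need upstream >= 0, downstream >= 0, upstream+downstream >= 1")
    if not 0.0 <= mask_fraction <= 1.0:
        raise SyntheticError("mask_fraction must be in [0, 1]")
    if n_genes < 1:
        raise SyntheticError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    logger.info("generate_promoters: n=%d geometry=(-%d,+%d) mask=%.3f seed=%d",
                n_genes, upstream, downstream, mask_fraction, seed)
    L = upstream + downstream + 1
    if gene_ids is None:
        width = len(str(n_genes))
        gene_ids = [f"{gene_prefix}{k:0{width}d}" for k in range(1, n_genes + 1)]
    else:
        gene_ids = list(gene_ids)
        if len(gene_ids) != n_genes:
            raise SyntheticError("gene_ids length must equal n_genes")
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, L)]) for _ in range(n_genes)]
    free = np.ones((n_genes, L), dtype=bool)
    target = int(round(mask_fraction * L))
    for g in range(n_genes):
        if target == 0:
            continue
        if target >= L:
            free[g, :] = False
            continue
        while (~free[g]).sum() < target:
            start = rng.integers(0, L)
            run = rng.geometric(1.0 / MASK_RUN_MEAN)
            span = np.arange(start, min(L, start + run))
            newly = span[free[g, span]]
            # trim the final run so the masked count lands on the target
            room = target - (~free[g]).sum()
            free[g, newly[:room]] = False
    return PromoterSet(gene_ids, seqs, free, upstream, downstream)


def _eligible_anchors(free: np.ndarray, w: int, occupied: np.ndarray) -> np.ndarray:
    """Window start columns whose full w-window is free and unoccupied."""
    ok = free & ~occupied
    run = np.convolve(ok.astype(int), np.ones(w, dtype=int), "valid") == w
    return np.nonzero(run)[0]


def plant_motif(
    promoters: PromoterSet,
    pwm: PWM,
    genes: Iterable[str],
    placement: str = "uniform",
    per_gene_count: int = 1,
    seed: int = 0,
    scale: float = 50.0,
    max_attempts: int = 10_000,
) -> tuple[PromoterSet, SyntheticTruth]:
    """Write the PWM's max-scoring word into selected promoters and record truth.

    placement 'uniform' samples anchors uniformly over eligible (fully free,
    non-overlapping) window starts; 'tss_biased' draws the anchor's distance
    from the TSS from a geometric law with the given mean ``scale`` (bp) and
    rejects it onto eligible positions, producing the TSS-ward pile-up that
    distinguishes functional motifs from background matches.
    """
    genes = list(genes)
    unknown = [g for g in genes if g not in promoters]
    if unknown:
        raise SyntheticError(f"genes not in promoter set: {unknown}")
    if placement not in ("uniform", "tss_biased"):
        raise SyntheticError(f"unknown placement {placement!r}")
    w = pwm.width
    if w > promoters.length:
        raise SyntheticError("motif wider than promoter")
    rng = np.random.default_rng(seed)
    logger.info("plant_motif: %d genes placement=%s count=%d seed=%d",
                len(genes), placement, per_gene_count, seed)
    word = pwm.consensus
    seqs = list(promoters.sequences)
    positions: dict[str, list[int]] = {}
    for gene in genes:
        g = promoters.index(gene)
        occupied = np.zeros(promoters.length, dtype=bool)
        planted: list[int] = []
        for _ in range(per_gene_count):
            anchors = _eligible_anchors(promoters.free_mask[g], w, occupied)
            if anchors.size == 0:
                raise SyntheticError(f"no free window available for gene {gene!r}")
            if placement == "uniform":
                col = int(rng.choice(anchors))
            else:
                col = None
                for _try in range(max_attempts):
                    d = int(rng.geometric(1.0 / scale)) - 1
                    side = rng.integers(0, 2)
                    pos = -d if (side == 0 or promoters.downstream == 0) else d
                    if promoters.upstream == 0:
                        pos = d
                    if not -promoters.upstream <= pos <= promoters.downstream:
                        continue
                    c = pos + promoters.upstream
                    if c in anchors:
                        col = c
                        break
                if col is None:
                    # fall back on the eligible anchor nearest the TSS
                    col = int(anchors[np.argmin(np.abs(anchors - promoters.upstream))])
            s = seqs[g]
            seqs[g] = s[:col] + word + s[col + w :]
            occupied[max(0, col - w + 1) : col + w] = True
            planted.append(col - promoters.upstream)
        positions[gene] = sorted(planted)
    out = PromoterSet(
        list(promoters.gene_ids), seqs, promoters.free_mask.copy(),
        promoters.upstream, promoters.downstream, truncated=list(promoters.truncated),
    )
    truth = SyntheticTruth(planted_target_genes=set(genes), planted_positions=positions)
    return out, truth


# -- expression --------------------------------------------------------------


def block_precision_matrix(
    module_sizes: Sequence[int], n_background_genes: int, within_pcor: float
) -> np.ndarray:
    """Block-diagonal precision matrix with constant within-block partial correlation.

    Within a block, the precision matrix is I - r(J - I), whose implied
    pairwise partial correlation is exactly r.  Positive definiteness
    requires r < 1/(m-1) for block size m.
    """
    p = int(sum(module_sizes)) + n_background_genes
    omega = np.eye(p)
    start = 0
    for m in module_sizes:
        if m < 2:
            raise SyntheticError("module sizes must be >= 2")
        if within_pcor * (m - 1) >= 1.0:
            raise SyntheticError(
                f"within_pcor={within_pcor} makes a size-{m} block non-positive-definite "
                f"(need within_pcor < 1/{m - 1})"
            )
        block = slice(start, start + m)
        omega[block, block] = np.eye(m) - within_pcor * (np.ones((m, m)) - np.eye(m))
        start += m
    return omega


def generate_expression(
    module_sizes: Sequence[int],
    n_background_genes: int,
    n_samples: int,
    within_pcor: float,
    seed: int,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Sample a genes x samples matrix from a block-structured Gaussian graphical model.

    Module genes (named ``m<k>_g<j>``) share pairwise partial correlation
    ``within_pcor``; background genes (``bg_g<j>``) are independent.  Samples
    are exact zero-mean multivariate-normal draws from the inverse of the
    block precision matrix — no array-noise model is layered on top.
    """
    if n_samples < 1:
        raise SyntheticError("n_samples must be >= 1")
    if n_background_genes < 0:
        raise SyntheticError("n_background_genes must be >= 0")
    if not 0.0 < within_pcor < 1.0 and module_sizes:
        raise SyntheticError("within_pcor must be in (0, 1)")
    omega = block_precision_matrix(module_sizes, n_background_genes, within_pcor)
    sigma = np.linalg.inv(omega)
    rng = np.random.default_rng(seed)
    logger.info("generate_expression: modules=%s bg=%d n=%d pcor=%.3f seed=%d",
                list(module_sizes), n_background_genes, n_samples, within_pcor, seed)
    X = rng.multivariate_normal(np.zeros(omega.shape[0]), sigma, size=n_samples,
                                method="cholesky").T
    gene_ids: list[str] = []
    labels: dict[str, int] = {}
    for k, m in enumerate(module_sizes, start=1):
        for j in range(1, m + 1):
            gid = f"m{k}_g{j:02d}"
            gene_ids.append(gid)
            labels[gid] = k
    gene_ids += [f"bg_g{j:03d}" for j in range(1, n_background_genes + 1)]
    df = pd.DataFrame(X, index=gene_ids,
                      columns=[f"s{j}" for j in range(1, n_samples + 1)])
    df.index.name = "gene"
    truth = SyntheticTruth(
        planted_target_genes=set(labels), module_labels=labels,
        planted_positions={},
    )
    return df, truth


# -- binding -----------------------------------------------------------------


def generate_binding_table(
    genes: Iterable[str],
    bound_fraction_by_group: Mapping[str, float],
    seed: int,
    group_by: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Flag each gene bound with its group's probability (independent Bernoulli).

    With ``group_by`` None, ``bound_fraction_by_group`` must hold a single
    entry applied to every gene; otherwise each gene's group must appear in
    the fraction map.  Returns a two-column gene/bound table plus truth.
    """
    genes = sorted(genes)
    for grp, frac in bound_fraction_by_group.items():
        if not 0.0 <= frac <= 1.0:
            raise SyntheticError(f"bound fraction for group {grp!r} outside [0, 1]")
    if group_by is None:
        if len(bound_fraction_by_group) != 1:
            raise SyntheticError("without group_by, exactly one group fraction is required")
        only = next(iter(bound_fraction_by_group))
        group_by = {g: only for g in genes}
    unknown = sorted({group_by.get(g) for g in genes} - set(bound_fraction_by_group))
    if unknown:
        raise SyntheticError(f"unknown group keys: {unknown}")
    rng = np.random.default_rng(seed)
    logger.info("generate_binding_table: %d genes, %d groups, seed=%d",
                len(genes), len(bound_fraction_by_group), seed)
    flags = [int(rng.random() < bound_fraction_by_group[group_by[g]]) for g in genes]
    table = pd.DataFrame({"gene": genes, "bound": flags})
    truth = SyntheticTruth(bound_genes={g for g, f in zip(genes, flags) if f})
    return table, truth
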