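"""Motif target identification: TSS position bias, enrichment, and permutation FDR.

The central idea: a motif that arose by chance in a group of promoters is
equally likely to sit at any free (non-repeat) position, so its distance
from the TSS follows a known discrete distribution; a functional motif
piles up near the TSS.  For a group of promoters spanning M bp upstream to
N bp downstream of the TSS, with k_i of them free at position i and
K = sum k_i free positions in total, the null distance moments are

    E(d) = sum_i (k_i / K) |i|
    V(d) = sum_i (k_i / K) i^2 - E(d)^2

and a motif observed n times in the group with mean distance mean|x| gets

    Z = (E(d) - mean|x|) / sqrt(V(d) / n).

Large Z means the motif sits closer to the TSS than chance allows.  Target
calling walks every network gene as a seed: the seed plus its direct
neighbors form a group; if the seed's own promoter contains the motif and
the group shows either hypergeometric motif enrichment or significant
position bias, every motif-containing group member is called a target.
The procedure's false discovery rate comes from re-running it on
within-promoter shuffled sequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import CoexpressionNetwork
from .promoters import PWM, MotifHit, PromoterSet, scan_promoters

logger = logging.getLogger("motifnet")

#: minimum motif occurrences in a group before the normal-approximation Z is used
DEFAULT_MIN_OCCURRENCES = 5
#: target-calling cutoffs for the NF-Y-style configuration
DEFAULT_Z_CUTOFF = 3.5
DEFAULT_P_CUTOFF = 1e-5


class BiasError(ValueError):
    pass


@dataclass
class BiasBackground:
    """Null distance-from-TSS moments for a group of promoters."""

    M: int
    N: int
    k_i: np.ndarray  # free-promoter count per position, length M+N+1
    K: int
    E_d: float
    V_d: float

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.M, self.N + 1)


@dataclass
class BiasStat:
    """Observed position-bias statistic for a motif in a group."""

    n: int
    mean_abs_x: float
    z: float


@dataclass
class NeighborhoodResult:
    seed: str
    group: frozenset[str]
    seed_has_motif: bool
    n_occurrences: int
    enrichment_p: float
    bias: BiasStat | None
    called: bool


@dataclass
class TargetSet:
    """Union of called motif targets over all seeds, with per-gene provenance."""

    motif_id: str
    targets: set[str]
    provenance: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    neighborhoods: list[NeighborhoodResult] = field(default_factory=list)

    def genes_by_method(self) -> dict[str, set[str]]:
        """Targets split by the evidence that called them (bias / enrichment / both)."""
        by_bias, by_enrich = set(), set()
        for gene, entries in self.provenance.items():
            for _seed, method in entries:
                if "bias" in method:
                    by_bias.add(gene)
                if "enrichment" in method:
                    by_enrich.add(gene)
        return {"bias": by_bias, "enrichment": by_enrich, "both": by_bias & by_enrich}

    def to_tsv(self, path) -> None:
        rows = []
        for gene in sorted(self.targets):
            entries = self.provenance.get(gene, [])
            rows.append(
                {
                    "gene": gene,
                    "motif": self.motif_id,
                    "n_seeds": len({s for s, _ in entries}),
                    "seeds": ",".join(sorted({s for s, _ in entries})),
                    "methods": ",".join(sorted({m for _, m in entries})),
                }
            )
        pd.DataFrame(rows, columns=["gene", "motif", "n_seeds", "seeds", "methods"]).to_csv(
            path, sep="\t", index=False
        )

    def neighborhoods_to_tsv(self, path) -> None:
        rows = []
        for nb in self.neighborhoods:
            rows.append(
                {
                    "seed": nb.seed,
                    "group_size": len(nb.group),
                    "seed_has_motif": int(nb.seed_has_motif),
                    "n_occurrences": nb.n_occurrences,
                    "mean_abs_x": nb.bias.mean_abs_x if nb.bias else np.nan,
                    "z": nb.bias.z if nb.bias else np.nan,
                    "enrichment_p": nb.enrichment_p,
                    "called": int(nb.called),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


# -- background and statistic ------------------------------------------------


def bias_background(promoters: PromoterSet, group: Iterable[str]) -> BiasBackground:
    """Per-position free counts and null distance moments for a promoter group.

    k_i counts group promoters free at single position i, exactly as the
    background model defines it (window-level eligibility used in scanning
    is a second-order refinement for motif widths much smaller than the
    promoter).
    """
    group = list(group)
    if not group:
        raise BiasError("group must be non-empty")
    idx = [promoters.index(g) for g in group]
    k_i = promoters.free_mask[idx].sum(axis=0).astype(int)
    K = int(k_i.sum())
    if K == 0:
        raise BiasError("all positions masked in the group (K = 0)")
    pos = promoters.positions
    w = k_i / K
    e_d = float(w @ np.abs(pos))
    v_d = float(w @ (pos.astype(float) ** 2) - e_d**2)
    return BiasBackground(promoters.upstream, promoters.downstream, k_i, K, e_d, max(v_d, 0.0))


def unmasked_expected_distance(M: int, N: int) -> float:
    """Closed form of E(d) with no masking: (M(M+1) + N(N+1)) / (2(M+N+1))."""
    return (M * (M + 1) + N * (N + 1)) / (2.0 * (M + N + 1))


def bias_z(
    bg: BiasBackground,
    hits: Sequence[MotifHit],
    min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
) -> BiasStat:
    """Position-bias Z for the motif occurrences observed in a group.

    Every occurrence counts (multiple hits per promoter and both strands
    pooled); the distance |x| is the absolute TSS-relative anchor.  Raises
    if there are fewer than ``min_occurrences`` hits or the background is
    degenerate (V(d) = 0).
    """
    n = len(hits)
    if n == 0:
        raise BiasError("Z undefined with zero occurrences")
    if min_occurrences < DEFAULT_MIN_OCCURRENCES:
        warnings.warn(
            f"min_occurrences={min_occurrences} < {DEFAULT_MIN_OCCURRENCES}: the normal "
            "approximation behind Z is unreliable for very small n",
            stacklevel=2,
        )
    if n < min_occurrences:
        raise BiasError(f"only {n} occurrences; min_occurrences={min_occurrences}")
    if bg.V_d <= 0:
        raise BiasError("V(d) = 0: background distance distribution is degenerate")
    mean_abs_x = float(np.mean([h.distance for h in hits]))
    z = (bg.E_d - mean_abs_x) / np.sqrt(bg.V_d / n)
    return BiasStat(n=n, mean_abs_x=mean_abs_x, z=float(z))


def neighborhood_enrichment(
    group: Iterable[str], motif_genes: Iterable[str], population: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p for motif-gene enrichment in a group.

    P(X >= k) for k = |group ∩ motif genes| when |group| genes are drawn
    from the population containing |motif genes| successes.
    """
    population = set(population)
    group = set(group)
    motif_genes = set(motif_genes)
    if not population:
        raise BiasError("empty population")
    if not group <= population:
        raise BiasError("group must be a subset of the population")
    if not motif_genes <= population:
        raise BiasError("motif genes must be a subset of the population")
    k = len(group & motif_genes)
    return float(stats.hypergeom.sf(k - 1, len(population), len(motif_genes), len(group)))


# -- target calling ----------------------------------------------------------


def call_targets(
    network: CoexpressionNetwork,
    promoters: PromoterSet,
    hits: Sequence[MotifHit],
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
    motif_id: str = "motif",
) -> TargetSet:
    """Seeded-group target calling over the co-expression network.

    For every network gene as seed, the group is the seed plus its direct
    neighbors.  The seed contributes calls only if its own promoter
    contains the motif and the group passes either test (enrichment_p <=
    p_cutoff, or Z >= z_cutoff; both cutoffs inclusive); then every
    motif-containing group member is added to the target set.  Groups with
    fewer than ``min_occurrences`` hits are tested by enrichment only.
    The result is a set union, independent of seed iteration order.
    """
    missing = [g for g in network.nodes if g not in promoters]
    if missing:
        raise BiasError(f"network genes without promoters: {missing[:10]}")
    hits_by_gene: dict[str, list[MotifHit]] = {}
    for h in hits:
        hits_by_gene.setdefault(h.gene_id, []).append(h)
    motif_genes = {g for g in hits_by_gene if g in promoters}
    population = set(network.nodes)
    motif_in_pop = motif_genes & population

    targets: set[str] = set()
    provenance: dict[str, list[tuple[str, str]]] = {}
    neighborhoods: list[NeighborhoodResult] = []
    for seed in network.nodes:
        group = {seed} | network.neighbors(seed)
        seed_has_motif = seed in motif_genes
        p = neighborhood_enrichment(group, motif_in_pop, population)
        group_hits = [h for g in group for h in hits_by_gene.get(g, [])]
        bias = None
        if len(group_hits) >= min_occurrences:
            bg = bias_background(promoters, group)
            if bg.V_d > 0:
                bias = bias_z(bg, group_hits, min_occurrences)
        by_enrich = p <= p_cutoff
        by_bias = bias is not None and bias.z >= z_cutoff
        called = seed_has_motif and (by_enrich or by_bias)
        neighborhoods.append(
            NeighborhoodResult(seed, frozenset(group), seed_has_motif,
                               len(group_hits), p, bias, called)
        )
        if called:
            method = "+".join(
                m for m, on in (("enrichment", by_enrich), ("bias", by_bias)) if on
            )
            for gene in group & motif_genes:
                targets.add(gene)
                provenance.setdefault(gene, []).append((seed, method))
    logger.info("call_targets: %d motif genes, %d targets called (z>=%.3g or p<=%.3g)",
                len(motif_genes), len(targets), z_cutoff, p_cutoff)
    return TargetSet(motif_id, targets, provenance, neighborhoods)


# -- promoter randomization FDR ----------------------------------------------


def shuffle_promoters(
    promoters: PromoterSet,
    rng: np.random.Generator,
    preserve_mask: bool = True,
    dinucleotide: bool = False,
) -> PromoterSet:
    """Randomize promoter sequences for the permutation null.

    With ``preserve_mask`` (default) only the letters at free positions are
    permuted, within each promoter, keeping masked blocks in place; without
    it all positions are permuted while the mask geometry stays where it
    was.  ``dinucleotide`` shuffles non-overlapping 2-mers within each free
    run instead of single bases, approximately preserving dinucleotide
    content.
    """
    seqs = []
    for g in range(len(promoters)):
        chars = np.array(list(promoters.sequences[g]))
        idx = np.nonzero(promoters.free_mask[g])[0] if preserve_mask else np.arange(chars.size)
        if dinucleotide:
            runs = np.split(idx, np.nonzero(np.diff(idx) != 1)[0] + 1) if idx.size else []
            duos: list[str] = []
            duo_slots: list[np.ndarray] = []
            single_slots: list[int] = []
            for run in runs:
                for s in range(0, run.size - 1, 2):
                    duos.append("".join(chars[run[s : s + 2]]))
                    duo_slots.append(run[s : s + 2])
                if run.size % 2:
                    single_slots.append(int(run[-1]))
            # permute 2-mers among 2-mer slots, leftover bases among themselves
            for k, j in enumerate(rng.permutation(len(duos))):
                chars[duo_slots[k]] = list(duos[j])
            singles = np.asarray(single_slots, dtype=int)
            chars[singles] = chars[rng.permutation(singles)]
        else:
            chars[idx] = chars[rng.permutation(idx)]
        seqs.append("".join(chars))
    return PromoterSet(
        list(promoters.gene_ids), seqs, promoters.free_mask.copy(),
        promoters.upstream, promoters.downstream,
    )


@dataclass
class PermutationFDR:
    fdr: float
    observed_count: int
    perm_counts: list[int]

    @property
    def mean_perm_count(self) -> float:
        return float(np.mean(self.perm_counts))

    @classmethod
    def from_counts(cls, observed_count: int, perm_counts: Sequence[int]) -> "PermutationFDR":
        """FDR = mean permutation target count / observed target count."""
        if observed_count < 1:
            raise BiasError("observed target count must be >= 1")
        if len(perm_counts) < 1:
            raise BiasError("need at least one permutation count")
        return cls(
            fdr=float(np.mean(perm_counts)) / observed_count,
            observed_count=int(observed_count),
            perm_counts=list(perm_counts),
        )


def permutation_fdr(
    network: CoexpressionNetwork,
    promoters: PromoterSet,
    pwm: PWM,
    threshold: float,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
    n_perm: int = 10,
    seed: int = 0,
    preserve_mask: bool = True,
    dinucleotide: bool = False,
) -> PermutationFDR:
    """FDR of target calling from shuffled-promoter reruns.

    Each permutation shuffles every promoter's (free) nucleotides, rescans
    with the same PWM and threshold, and recalls targets with the same
    cutoffs.  FDR = mean permutation target count / observed target count.
    """
    if n_perm < 1:
        raise BiasError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def _count(ps: PromoterSet) -> int:
        hits = scan_promoters(ps, pwm, threshold)
        ts = call_targets(network, ps, hits, z_cutoff, p_cutoff, min_occurrences)
        return len(ts.targets)

    observed = _count(promoters)
    if observed < 1:
        raise BiasError("no observed targets; FDR undefined")
    counts = []
    for k in range(n_perm):
        shuffled = shuffle_promoters(promoters, rng, preserve_mask, dinucleotide)
        counts.append(_count(shuffled))
        logger.info("permutation_fdr: perm %d/%d -> %d targets", k + 1, n_perm, counts[-1])
    result = PermutationFDR.from_counts(observed, counts)
    logger.info("permutation_fdr: observed=%d mean_perm=%.2f fdr=%.4g (seed=%d)",
                observed, result.mean_perm_count, result.fdr, seed)
    return result
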