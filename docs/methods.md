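# Methods

## Model and procedure

`motifnet` treats promoter motif occurrences as draws from a discrete null
and asks whether their placement is compatible with chance. Promoters span
*M* bp upstream through *N* bp downstream of the transcription start site
(TSS), indexed by signed position *i* ∈ [−M, N] with *i* = 0 at the TSS
base (the position range deliberately includes 0, so a promoter holds
M + N + 1 positions).
Repeat and transposon intervals are masked; masked positions contribute
neither to scanning nor to the null.

**Position-bias null.** For a group of promoters, let *k<sub>i</sub>* be
the number of group promoters whose position *i* is free, and
*K* = Σ *k<sub>i</sub>*. A non-functional motif is uniform over the *K*
free base pairs, giving

    E(d) = sum_i (k_i / K) |i|
    V(d) = sum_i (k_i / K) i^2 - E(d)^2

With no masking this reduces to the closed form
E(d) = (M(M+1) + N(N+1)) / (2(M+N+1)), which the tests assert for random
geometries. A motif observed *n* times with mean absolute anchor distance
|x̄| is scored with Z = (E(d) − |x̄|) / √(V(d)/n). Because E(d) and V(d)
are the exact first two moments of |i| under the null, Z has exact mean 0
and standard deviation 1 for any *n*; normality of its tail is a
central-limit approximation that the calibration suite checks at
*n* = 20 occurrences (10,000 simulated groups: mean within ±0.05, sd
within [0.9, 1.1], P(Z ≥ 3.5) consistent with the normal tail).

**Seeded-group target calling.** Each network gene in turn is a seed; its
group is the seed plus its distance-1 neighbors. The group is tested for
(a) motif enrichment — the exact hypergeometric upper tail of the number
of motif-containing group members drawn from the population of all network
genes possessing a promoter — and (b) position bias via Z over all pooled
occurrences in the group. If the seed's own promoter contains the motif
and either test passes its (inclusive) cutoff, every motif-containing
group member becomes a target. The final target set is the union over
seeds, hence invariant to iteration order.

**Permutation FDR.** The observed target count is compared with reruns on
randomized promoters: by default each promoter's free-position letters are
permuted within that promoter, leaving masked blocks in place, so the
mask geometry and mononucleotide composition of the scanable sequence are
both preserved. FDR = mean permuted target count / observed count. A
chunked dinucleotide shuffle (non-overlapping 2-mers permuted within free
runs, approximately preserving dinucleotide content) and a variant that
also permutes masked letters are available behind flags, since the choice
of randomization granularity is a genuinely open design point.

## PWM scanning

PFMs are read in JASPAR text format (via Biopython), normalized per column
with a pseudocount (default 0.5), and converted to log-odds in bits
against a background (default uniform 0.25; configurable to promoter
composition). The scan threshold for a per-window p-value (default 4⁻⁸,
POSSUM-style) is computed by exact dynamic programming: each column's
log-odds values are discretized to 0.01-bit bins (configurable) and
convolved under the background; the threshold is the smallest binned score
whose upper-tail mass is at most the requested p-value. Scores of
impossible bases (probability zero without pseudocount) are floored at
−50 bits inside the DP and −∞ during scanning. If the requested p-value is
below the most extreme achievable mass, the function warns and returns the
maximum score plus one bin, so nothing passes. Both strands are scanned; a
window is eligible only when all *w* positions are inside the promoter and
free; the hit anchor is the leftmost promoter-coordinate base of the
window on either strand. The window-level eligibility rule is stricter
than the per-position *k<sub>i</sub>* used in the null (a hit cannot
overlap a masked base, but *k<sub>i</sub>* is defined per single
position); for motif widths ≪ promoter length this mismatch is
second-order, and the null deliberately keeps the literal per-position
definition.

## Network estimation

Partial correlations come from the Schäfer–Strimmer shrinkage estimator:
rows are standardized, the sample correlation matrix is shrunk towards the
identity with the analytic unbiased-risk intensity
λ* = Σ Var̂(r<sub>ij</sub>) / Σ r<sub>ij</sub>², inverted, and scaled to
partial correlations. The estimator is deterministic, refuses missing
values and constant genes, and matches the unshrunk sample partial
correlation in the n ≫ p limit (asserted at p = 5, n = 100,000, tolerance
0.01). Edges keep **signed** pcor ≥ cutoff (default 0.04) — negative
partial correlations are excluded by default, with an `absolute` flag —
because the module structure of interest is positive co-expression. For
gene panels too large to invert at once, a subsampling variant averages
the estimator over random gene subsets and reports per-pair coverage;
pairs under a coverage floor are returned missing rather than guessed.
An empirical FDR for the edge cutoff permutes each gene's sample labels
independently and compares null and observed edge counts. Note that
shrinkage itself is strongly adaptive: on pure-noise data λ* → 1 and all
estimates collapse to zero, so at any positive cutoff both observed and
null counts are typically zero (FDR defined as 0 in the 0/0 case).

## Markov clustering

The target sub-network (induced subgraph, weights preserved) is clustered
with MCL on the dense column-stochastic flow matrix: self-loops with
weight equal to each node's maximum incident edge weight, expansion =
matrix power 2, inflation = entrywise power (default 2.0, the usual
default in the absence of a reported value) followed by column
renormalization, pruning of entries below 1e-5, convergence when the
largest entry change drops under 1e-6 (hard cap 200 iterations, returning
the current interpretation with a warning if hit). Attractors are rows
with positive diagonal mass; attractors that flow into each other form one
cluster; a node attracted to several clusters is assigned to the largest
(ties to the lower module id). Nodes are canonically sorted first, so the
partition is invariant under relabeling. Modules are numbered from 1 by
descending size; single-gene clusters are reported separately as
singletons.

## Enrichment statistics

One hypergeometric kernel serves both the neighborhood enrichment test and
module-level over-representation (the tests assert they agree on identical
inputs). Both tails include the observed count (so
p_enrich + p_deplete ≥ 1), and fold change is
(k/m) / (K_pop/N_pop), reported to two decimals in tabular output. Raw
p-values with fixed thresholds are the default reporting mode; a
Benjamini–Hochberg column is optional. Per-module summaries of per-gene
genomic values (expression, H3K4me3, promoter methylation, …) are medians
or means over genes with available values; modules with none are flagged
NaN.

## Synthetic data: what it emulates and what it does not

The generators provide ground truth for every stage:

- **Promoters** are i.i.d. uniform A/C/G/T with masked intervals laid down
  as geometric-length runs (mean 150 bp, final run trimmed to land on the
  requested masked fraction) — mimicking repeat/transposon blocks rather
  than salt-and-pepper masking. Real promoter base composition (GC skew,
  CpG islands) is *not* modeled, so scanning specificity on real sequence
  will differ from the uniform-background expectation.
- **Planted motifs** write the PWM's consensus word into eligible free
  windows, either uniformly or with distance from the TSS drawn from a
  geometric law (mean `scale` bp, default 50) rejected onto free
  positions; the truth records exact anchors. Any monotone-decaying law
  would do for the TSS-ward pile-up; geometric was chosen as a
  one-parameter knob.
- **Expression** is sampled exactly from a block-diagonal precision matrix
  in which within-module off-diagonal entries are set so the implied
  pairwise partial correlation equals `within_pcor` (positive-definiteness
  requires within_pcor < 1/(block size − 1), checked before sampling).
  No microarray noise model, normalization artifacts, probe effects, or
  batch structure are simulated — the generators test the estimator, not
  preprocessing — so passing tests demonstrate statistical correctness of
  the chain, not robustness to array-specific artifacts.
- **Binding tables** flag genes bound by independent Bernoulli draws with
  per-group probabilities.

All generators are bit-reproducible for a fixed seed and log their seeds.

## Study conditions and problem sizes

The end-to-end synthetic study uses 200 genes — 4 planted modules of 10
plus 160 background genes — with 1,500 samples, within-module partial
correlation 0.09, 10% masked promoter positions on a −1000..0 bp geometry,
an 8-bp planted motif at 2 copies per module gene (TSS-biased, scale
50 bp), and 10 shuffled-promoter permutations; module size 10 requires
within_pcor below 1/9, and 0.09 with n = 1,500 puts planted edges well
clear of the 0.04 cutoff. Calibration suites use 10,000 groups of 20
occurrences for the null Z, 100,000 samples for closed-form partial
correlation checks, exhaustive enumeration up to population 25 for the
hypergeometric kernel, and p = 60 / n = 500 for pair-ranking recovery.
These sizes make the whole suite run in well under a minute while keeping
every statistical band comfortably testable.

## Known limitations

- The position-bias Z is a normal approximation; groups with fewer than
  `min_occurrences` (default 5, values below warn) occurrences are tested
  by enrichment only.
- Only distance-1 network neighborhoods are considered; distal/enhancer
  regulation beyond the promoter window is out of scope by design.
- The MCL inflation default (2.0) is a convention, not a fitted value;
  module counts depend on it and on the edge cutoff.
- The hit anchor is the leftmost window base (not the motif center); for
  wide motifs this shifts |x| by up to w−1 bp relative to a center
  convention. Strand hits are pooled.
- Higher-order background models for scanning (composition-matched or
  Markov backgrounds) are not implemented; the per-window p-value is
  computed under a zero-order background.
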