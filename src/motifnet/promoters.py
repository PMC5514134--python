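"""Promoter sequences, position weight matrices, and motif scanning.

Coordinate convention used throughout the package: each promoter spans
``M`` bp upstream through ``N`` bp downstream of the transcription start
site (TSS), with signed position ``i`` running from ``-M`` to ``+N`` and
``i = 0`` at the TSS base.  Sequences are stored 5'->3' on the promoter
sense strand, so minus-strand genes are reverse-complemented at
extraction time.  Repeat/transposon positions (lowercase or ``N`` in the
source FASTA) are flagged not-free and excluded from scanning and from
the position-bias background.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq

logger = logging.getLogger("motifnet")

# -- defaults ----------------------------------------------------------------

#: POSSUM-style per-window p-value cutoff for motif scanning.
DEFAULT_SCAN_PVALUE = 4.0 ** -8
#: Score-distribution discretization bin, in bits.
DEFAULT_SCORE_BIN = 0.01
#: Uniform nucleotide background.
UNIFORM_BACKGROUND = np.full(4, 0.25)

_ALPHABET = "ACGT"
_CODE = {c: k for k, c in enumerate(_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
# effectively-impossible log-odds used in place of -inf inside the DP
_NEG_BITS = -50.0


class PromoterError(ValueError):
    """Invalid promoter geometry, missing genes, or malformed input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else (N) as 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, k in _CODE.items():
        out[arr == ord(base)] = k
    return out


# -- promoter container ------------------------------------------------------


@dataclass
class PromoterSet:
    """Promoters for a set of genes sharing the same (upstream, downstream) geometry.

    ``free_mask[g, j]`` is True where position ``j`` of gene ``g`` is free
    (not repeat/transposon-masked); column ``j`` corresponds to signed
    TSS-relative position ``j - upstream``.
    """

    gene_ids: list[str]
    sequences: list[str]
    free_mask: np.ndarray
    upstream: int
    downstream: int
    truncated: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = self.length
        if any(len(s) != L for s in self.sequences):
            raise PromoterError("all promoter sequences must have length upstream+downstream+1")
        self.free_mask = np.asarray(self.free_mask, dtype=bool)
        if self.free_mask.shape != (len(self.gene_ids), L):
            raise PromoterError("free_mask shape must be (n_genes, promoter length)")
        self._index = {g: k for k, g in enumerate(self.gene_ids)}
        if len(self._index) != len(self.gene_ids):
            raise PromoterError("duplicate gene ids in promoter set")

    @property
    def length(self) -> int:
        return self.upstream + self.downstream + 1

    @property
    def positions(self) -> np.ndarray:
        """Signed TSS-relative positions, -upstream..+downstream."""
        return np.arange(-self.upstream, self.downstream + 1)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def index(self, gene_id: str) -> int:
        try:
            return self._index[gene_id]
        except KeyError:
            raise PromoterError(f"gene {gene_id!r} not in promoter set") from None

    def column(self, position: int) -> int:
        """Array column for a signed TSS-relative position."""
        if not -self.upstream <= position <= self.downstream:
            raise PromoterError(f"position {position} outside [-{self.upstream}, {self.downstream}]")
        return position + self.upstream

    def subset(self, genes: Iterable[str]) -> "PromoterSet":
        idx = [self.index(g) for g in genes]
        return PromoterSet(
            [self.gene_ids[k] for k in idx],
            [self.sequences[k] for k in idx],
            self.free_mask[idx],
            self.upstream,
            self.downstream,
        )

    # masked FASTA round-trip: masked positions lowercase

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for k, gene in enumerate(self.gene_ids):
                seq = "".join(
                    c.upper() if free else c.lower()
                    for c, free in zip(self.sequences[k], self.free_mask[k])
                )
                fh.write(f">{gene}\n{seq}\n")

    @classmethod
    def from_fasta(cls, path, upstream: int, downstream: int) -> "PromoterSet":
        """Read a masked FASTA (lowercase or N = masked) with known geometry."""
        gene_ids, seqs, masks = [], [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            raw = str(rec.seq)
            arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
            lower = (arr >= ord("a")) & (arr <= ord("z"))
            is_n = (arr == ord("N")) | (arr == ord("n"))
            gene_ids.append(rec.id)
            seqs.append(raw.upper())
            masks.append(~(lower | is_n))
        if not gene_ids:
            raise PromoterError(f"no promoter records parsed from {path}")
        return cls(gene_ids, seqs, np.array(masks), upstream, downstream)


# -- PWM ---------------------------------------------------------------------


@dataclass
class PWM:
    """Motif model: per-column base probabilities and log-odds (bits) vs background."""

    name: str
    probabilities: np.ndarray  # (4, w), rows A,C,G,T; columns sum to 1
    background: np.ndarray  # (4,)

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[0] != 4:
            raise ValueError("probabilities must be a 4 x w matrix")
        if self.width < 1:
            raise ValueError("motif width must be >= 1")
        if not np.allclose(self.probabilities.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("each probability column must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self.probabilities / self.background[:, None])

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[k] for k in self.probabilities.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(np.max(self.log_odds, axis=0).sum())

    @property
    def min_score(self) -> float:
        finite = np.where(np.isfinite(self.log_odds), self.log_odds, _NEG_BITS)
        return float(np.min(finite, axis=0).sum())

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        name: str = "",
        pseudocount: float = 0.5,
        background: np.ndarray | None = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x w matrix")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        col = counts.sum(axis=0)
        if pseudocount == 0 and np.any(col == 0):
            raise ValueError("zero column sum requires a positive pseudocount")
        probs = (counts + pseudocount) / (col + 4 * pseudocount)
        bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
        return cls(name, probs, bg)

    @classmethod
    def from_consensus(cls, word: str, name: str | None = None) -> "PWM":
        """Degenerate PWM putting probability 1 on each consensus base."""
        word = word.upper()
        if not word or any(c not in _CODE for c in word):
            raise ValueError("consensus must be a non-empty A/C/G/T string")
        probs = np.zeros((4, len(word)))
        for j, c in enumerate(word):
            probs[_CODE[c], j] = 1.0
        return cls(name or word, probs, UNIFORM_BACKGROUND.copy())


def load_jaspar_pwm(
    source,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    motif_id: str | None = None,
) -> PWM:
    """Load a position frequency matrix in JASPAR format into a :class:`PWM`.

    ``source`` may be a path or an open text handle holding one or more
    JASPAR-format records; ``motif_id`` selects among several.
    """
    if hasattr(source, "read"):
        records = bio_motifs.parse(source, "jaspar")
    else:
        with open(source) as fh:
            records = bio_motifs.parse(fh, "jaspar")
    records = list(records)
    if not records:
        raise ValueError("no JASPAR motifs parsed")
    if motif_id is not None:
        matches = [m for m in records if motif_id in {m.matrix_id, m.name}]
        if not matches:
            raise ValueError(f"motif {motif_id!r} not found")
        record = matches[0]
    else:
        record = records[0]
    counts = np.array([record.counts[b] for b in _ALPHABET], dtype=float)
    if np.any(counts.sum(axis=0) == 0) and pseudocount == 0:
        raise ValueError("JASPAR matrix has a zero column sum; use pseudocount > 0")
    name = record.matrix_id or record.name or "motif"
    return PWM.from_counts(counts, name=name, pseudocount=pseudocount, background=background)


def pwm_score_threshold(
    pwm: PWM,
    pvalue: float = DEFAULT_SCAN_PVALUE,
    bin_width: float = DEFAULT_SCORE_BIN,
) -> float:
    """Smallest score ``t`` with ``P(score(W) >= t) <= pvalue`` for background words.

    The null score distribution is computed exactly by dynamic programming:
    each column's log-odds values are discretized to ``bin_width``-bit bins
    and convolved column by column under the background base probabilities.
    """
    if not 0.0 < pvalue <= 1.0:
        raise ValueError("pvalue must be in (0, 1]")
    lo = np.where(np.isfinite(pwm.log_odds), pwm.log_odds, _NEG_BITS)
    bins = np.round(lo / bin_width).astype(np.int64)  # (4, w)

    dist = np.array([1.0])
    offset = 0  # bin index of dist[0]
    for j in range(pwm.width):
        col_bins = bins[:, j]
        lo_b, hi_b = int(col_bins.min()), int(col_bins.max())
        col = np.zeros(hi_b - lo_b + 1)
        for base in range(4):
            col[col_bins[base] - lo_b] += pwm.background[base]
        dist = np.convolve(dist, col)
        offset += lo_b

    # upper-tail mass from the top score down
    tail = np.cumsum(dist[::-1])[::-1]
    ok = np.nonzero(tail <= pvalue)[0]
    if ok.size == 0:
        warnings.warn(
            f"requested p-value {pvalue:g} is below the most extreme achievable "
            f"tail mass {tail[-1]:g}; returning max score + epsilon (no word passes)",
            stacklevel=2,
        )
        return pwm.max_score + bin_width
    return float((offset + ok[0]) * bin_width)


# -- scanning ----------------------------------------------------------------


@dataclass(frozen=True)
class MotifHit:
    """One motif match: anchor = TSS-relative position of the window's leftmost base."""

    gene_id: str
    position: int
    strand: str  # '+' or '-'
    score: float

    @property
    def distance(self) -> int:
        """Absolute distance of the anchor from the TSS."""
        return abs(self.position)


def _window_scores(codes: np.ndarray, lo5: np.ndarray) -> np.ndarray:
    """Sliding-window log-odds sums; lo5 is (5, w) with row 4 for N."""
    w = lo5.shape[1]
    n_win = codes.size - w + 1
    if n_win <= 0:
        return np.empty(0)
    out = np.zeros(n_win)
    for k in range(w):
        out += lo5[codes[k : k + n_win], k]
    return out


def scan_promoters(
    promoters: PromoterSet, pwm: PWM, threshold: float
) -> list[MotifHit]:
    """Scan both strands of every promoter for windows scoring >= threshold.

    A window is eligible only when all ``w`` of its positions lie inside the
    promoter and are free (unmasked).  The hit anchor is always the leftmost
    promoter-coordinate base of the window, for both strands; overlapping
    hits are all reported.
    """
    w = pwm.width
    if w > promoters.length:
        warnings.warn("PWM wider than promoters; no hits possible", stacklevel=2)
        return []
    lo = np.where(np.isfinite(pwm.log_odds), pwm.log_odds, -np.inf)
    lo5_fwd = np.vstack([lo, np.full((1, w), -np.inf)])
    # minus-strand: the reverse complement of the window matches the motif
    lo5_rev = np.vstack([lo[::-1, ::-1], np.full((1, w), -np.inf)])

    hits: list[MotifHit] = []
    kernel = np.ones(w, dtype=int)
    for g, gene in enumerate(promoters.gene_ids):
        codes = encode(promoters.sequences[g])
        free_run = np.convolve(promoters.free_mask[g].astype(int), kernel, "valid") == w
        for strand, lo5 in (("+", lo5_fwd), ("-", lo5_rev)):
            scores = _window_scores(codes, lo5)
            keep = np.nonzero(free_run & (scores >= threshold))[0]
            for j in keep:
                hits.append(MotifHit(gene, int(j) - promoters.upstream, strand, float(scores[j])))
    return hits


def hits_to_frame(hits: Sequence[MotifHit]):
    """Hits as a tidy table: gene, anchor, strand, score, distance."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene": [h.gene_id for h in hits],
            "anchor": [h.position for h in hits],
            "strand": [h.strand for h in hits],
            "score": [h.score for h in hits],
            "distance": [h.distance for h in hits],
        }
    )


# -- promoter extraction from genome + gene models ---------------------------


def _parse_bed6(path) -> list[tuple[str, int, str, str]]:
    """Return (gene_id, tss, strand, chrom) tuples from a BED6 file."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise PromoterError(f"BED6 line with {len(f)} fields: {line!r}")
            chrom, start, end, name, _score, strand = f[:6]
            start, end = int(start), int(end)
            tss = start if strand == "+" else end - 1
            genes.append((name, tss, strand, chrom))
    return genes


def _parse_gtf(path) -> list[tuple[str, int, str, str]]:
    """TSS per gene_id from a GTF: 5'-most coordinate over the gene's rows."""
    span: dict[str, tuple[str, str, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise PromoterError(f"GTF line with {len(f)} fields")
            chrom, _src, _feat, start, end, _score, strand, _frame, attrs = f[:9]
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                continue
            s, e = int(start) - 1, int(end)  # GTF is 1-based inclusive
            if gene_id in span:
                c, st, s0, e0 = span[gene_id]
                span[gene_id] = (c, st, min(s0, s), max(e0, e))
            else:
                span[gene_id] = (chrom, strand, s, e)
    return [
        (g, s if st == "+" else e - 1, st, c) for g, (c, st, s, e) in span.items()
    ]


def extract_promoters(
    genome_fasta,
    gene_models,
    upstream: int,
    downstream: int,
    fmt: str | None = None,
) -> PromoterSet:
    """Extract TSS-anchored promoters from a genome FASTA and BED6/GTF gene models.

    Minus-strand promoters are reverse-complemented so positions always read
    -upstream..+downstream 5'->3' through the TSS.  Lowercase and ``N``
    source bases (RepeatMasker convention) are flagged not-free.  Intervals
    running off a chromosome end are N-padded, masked, and recorded in
    ``PromoterSet.truncated``.
    """
    from pyfaidx import Fasta

    if upstream < 0 or downstream < 0 or upstream + downstream < 1:
        raise PromoterError("need upstream >= 0, downstream >= 0, upstream+downstream >= 1")
    path = str(gene_models)
    if fmt is None:
        fmt = "gtf" if path.endswith((".gtf", ".gff")) else "bed"
    genes = _parse_gtf(path) if fmt == "gtf" else _parse_bed6(path)
    if not genes:
        raise PromoterError(f"zero genes parsed from {gene_models}")

    genome = Fasta(str(genome_fasta), rebuild=False)
    missing = sorted({c for _, _, _, c in genes if c not in genome})
    if missing:
        bad = [g for g, _, _, c in genes if c in set(missing)]
        raise PromoterError(f"chromosomes {missing} not in genome (genes: {bad})")

    ids, seqs, masks, truncated = [], [], [], []
    L = upstream + downstream + 1
    for gene_id, tss, strand, chrom in genes:
        chrom_len = len(genome[chrom])
        if strand == "+":
            lo, hi = tss - upstream, tss + downstream + 1
        else:
            lo, hi = tss - downstream, tss + upstream + 1
        clip_lo, clip_hi = max(lo, 0), min(hi, chrom_len)
        raw = str(genome[chrom][clip_lo:clip_hi])
        pad_left, pad_right = clip_lo - lo, hi - clip_hi
        raw = "N" * pad_left + raw + "N" * pad_right
        if pad_left or pad_right:
            truncated.append(gene_id)
        if strand == "-":
            raw = reverse_complement(raw)
        arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
        lower = (arr >= ord("a")) & (arr <= ord("z"))
        is_n = (arr == ord("N")) | (arr == ord("n"))
        ids.append(gene_id)
        seqs.append(raw.upper())
        masks.append(~(lower | is_n))
        assert len(raw) == L
    ps = PromoterSet(ids, seqs, np.array(masks), upstream, downstream, truncated=truncated)
    if truncated:
        logger.warning("promoters truncated at chromosome ends: %s", truncated)
    return ps
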