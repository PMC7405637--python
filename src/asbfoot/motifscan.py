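"""PSSM motif scanning of both haplotypes and allelic disruption scoring.

A position count matrix is turned into a log2 log-odds PSSM; both haplotype
sequences (reference, and the sequence with the focal SNP substituted) are
scanned on both strands.  For every motif match containing a heterozygous
SNP, the disruption score is delta = PSSM(ref window) - PSSM(alt window):
positive delta means the variant weakens the predicted motif, negative delta
means it strengthens it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .cutsites import HetSNP

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Pssm:
    """Log-odds scoring matrix (log2 units) over A/C/G/T columns."""

    motif_id: str
    matrix: np.ndarray  # shape (4, L)
    background: np.ndarray  # shape (4,)
    pseudocount: float

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("matrix must be 4 x L with L >= 1")
        if not np.isfinite(self.matrix).all():
            raise ValueError("matrix must be finite everywhere")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[1]

    def score_threshold(self, pvalue: float = 1e-4, precision: int = 1000) -> float:
        """Smallest score whose exceedance probability under the background
        model is <= *pvalue*, by exact enumeration of the score distribution.

        The per-column score distribution is convolved over columns on an
        integer grid (matrix entries rounded to 1/precision), the standard
        exact approach for PWM score p-values.
        """
        grid = np.rint(self.matrix * precision).astype(np.int64)
        dist = np.array([1.0])
        offset = 0  # current minimum of the support
        for j in range(len(self)):
            col = grid[:, j]
            cmin, cmax = int(col.min()), int(col.max())
            new = np.zeros(len(dist) + cmax - cmin)
            for b in range(4):
                w = self.background[b]
                sh = int(col[b]) - cmin
                new[sh:sh + len(dist)] += w * dist
            dist = new
            offset += cmin
        tail = np.cumsum(dist[::-1])[::-1]  # P(score_int >= offset + i)
        idx = np.searchsorted(-tail, -pvalue, side="left")
        if idx >= len(dist):
            idx = len(dist) - 1
        return (offset + idx) / precision


@dataclass(frozen=True)
class MotifMatch:
    motif_id: str
    chrom: str
    start: int
    end: int  # 0-based half-open, forward-strand coordinates
    strand: str
    score: float
    haplotype: str  # "REF" or "ALT"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class MotifDisruption:
    """Allelic motif-score change for one (SNP, motif match) pair."""

    snp: HetSNP
    motif_id: str
    pssm_ref: float
    pssm_alt: float
    strand: str = "+"
    match_start: int = -1
    match_end: int = -1

    @property
    def delta(self) -> float:
        return self.pssm_ref - self.pssm_alt


def pssm_from_counts(counts, pseudocount: float = 0.8,
                     background: Sequence[float] | None = None,
                     motif_id: str = "motif") -> Pssm:
    """Build a log2 log-odds PSSM from a 4 x L position count matrix.

    entry(b, j) = log2( ((counts[b,j] + pc) / (colsum_j + 4*pc)) / background[b] )

    with *pseudocount* pc added per base.  Default background is uniform;
    pass regional base composition to override.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 4:
        raise ValueError("counts must have 4 rows (A, C, G, T)")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    colsum = counts.sum(axis=0)
    if pseudocount == 0 and (colsum == 0).any():
        raise ValueError("degenerate column: all-zero counts with pseudocount 0")
    probs = (counts + pseudocount) / (colsum + 4 * pseudocount)
    matrix = np.log2(probs / bg[:, None])
    return Pssm(motif_id=motif_id, matrix=matrix, background=bg,
                pseudocount=pseudocount)


def score_window(pssm: Pssm, seq: str) -> float | None:
    """Sum of matrix entries for *seq*; None for unscorable (non-ACGT) windows."""
    if len(seq) != len(pssm):
        raise ValueError(f"sequence length {len(seq)} != motif length {len(pssm)}")
    seq = seq.upper()
    try:
        idx = [_BASE_INDEX[b] for b in seq]
    except KeyError:
        return None
    return float(pssm.matrix[idx, range(len(seq))].sum())


def scan_one_haplotype(pssm: Pssm, seq: str, threshold: float, chrom: str,
                       region_start: int, haplotype: str) -> list[MotifMatch]:
    """All matches of *pssm* in *seq* (both strands) with score >= threshold.

    When both strands match at the same window the higher-scoring strand is
    kept (ties go to +) so one physical site is not double-counted.
    """
    L = len(pssm)
    matches = []
    for off in range(len(seq) - L + 1):
        window = seq[off:off + L]
        fwd = score_window(pssm, window)
        rev = score_window(pssm, reverse_complement(window))
        best: list[tuple[str, float]] = []
        if fwd is not None and fwd >= threshold:
            best.append(("+", fwd))
        if rev is not None and rev >= threshold:
            best.append(("-", rev))
        if not best:
            continue
        strand, score = max(best, key=lambda t: (t[1], t[0] == "+"))
        matches.append(MotifMatch(
            motif_id=pssm.motif_id, chrom=chrom,
            start=region_start + off, end=region_start + off + L,
            strand=strand, score=score, haplotype=haplotype))
    return matches


def scan_sequences(pssm: Pssm, region_seq_ref: str, region_seq_alt: str,
                   score_threshold: float, chrom: str = ".",
                   region_start: int = 0) -> list[MotifMatch]:
    """Scan reference and alternative haplotypes of one region."""
    if len(region_seq_ref) != len(region_seq_alt):
        raise ValueError("haplotype sequences must have equal length")
    out = scan_one_haplotype(pssm, region_seq_ref, score_threshold, chrom,
                             region_start, "REF")
    out += scan_one_haplotype(pssm, region_seq_alt, score_threshold, chrom,
                              region_start, "ALT")
    return out


def substitute(seq: str, offset: int, base: str) -> str:
    return seq[:offset] + base + seq[offset + 1:]


def delta_pssm(pssm: Pssm, ref_window: str, alt_window: str, snp: HetSNP,
               strand: str = "+", match_start: int = -1,
               match_end: int = -1) -> MotifDisruption | None:
    """Disruption score for one candidate; None if either window is unscorable.

    Windows must already be motif-aligned (reverse-complemented for '-'
    strand matches).
    """
    s_ref = score_window(pssm, ref_window)
    s_alt = score_window(pssm, alt_window)
    if s_ref is None or s_alt is None:
        logger.warning("unscorable window at %s:%d for motif %s; candidate dropped",
                       snp.chrom, snp.pos, pssm.motif_id)
        return None
    return MotifDisruption(snp=snp, motif_id=pssm.motif_id, pssm_ref=s_ref,
                           pssm_alt=s_alt, strand=strand,
                           match_start=match_start, match_end=match_end)


def call_candidate_sites(matches: Sequence[MotifMatch], snps: Sequence[HetSNP],
                         pssms: dict[str, Pssm], ref_seq: str,
                         region_start: int = 0) -> list[MotifDisruption]:
    """Intersect motif matches with het SNPs and score allelic disruption.

    One candidate per (SNP, motif locus) pair with the SNP inside the match
    span.  A locus matched on only one haplotype still yields a candidate:
    both haplotype windows are scored at the same coordinates.  *ref_seq* is
    the reference sequence of the scanned region starting at *region_start*.
    """
    candidates: dict[tuple, MotifDisruption] = {}
    for m in matches:
        for snp in snps:
            if snp.chrom != m.chrom and m.chrom != ".":
                continue
            if not m.contains(snp.pos):
                continue
            key = (snp.chrom, snp.pos, snp.ref_base, snp.alt_base,
                   m.motif_id, m.start, m.strand)
            if key in candidates:
                continue
            off = m.start - region_start
            ref_window = ref_seq[off:off + (m.end - m.start)]
            alt_window = substitute(ref_window, snp.pos - m.start, snp.alt_base)
            # guard: the reference sequence must carry the ref allele
            if ref_window[snp.pos - m.start].upper() != snp.ref_base:
                ref_window = substitute(ref_window, snp.pos - m.start,
                                        snp.ref_base)
            if m.strand == "-":
                ref_window = reverse_complement(ref_window)
                alt_window = reverse_complement(alt_window)
            dis = delta_pssm(pssms[m.motif_id], ref_window, alt_window, snp,
                             strand=m.strand, match_start=m.start,
                             match_end=m.end)
            if dis is not None:
                candidates[key] = dis
    return list(candidates.values())


# ---------------------------------------------------------------------------
# Motif file parsing (JASPAR pfm / MEME minimal), via Bio.motifs


def load_motifs(path: str, fmt: str | None = None, pseudocount: float = 0.8,
                background: Sequence[float] | None = None) -> list[Pssm]:
    """Load count matrices from a JASPAR or MEME-minimal file as PSSMs."""
    if fmt is None:
        with open(path) as fh:
            head = fh.read(2048)
        fmt = "minimal" if "MEME version" in head else "jaspar"
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, fmt)
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        if fmt == "minimal":
            # MEME minimal stores probabilities; rescale by nsites
            counts = counts * (m.num_occurrences or 20)
        ident = getattr(m, "matrix_id", None) or m.name or "motif"
        out.append(pssm_from_counts(counts, pseudocount=pseudocount,
                                    background=background, motif_id=str(ident)))
    return out
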