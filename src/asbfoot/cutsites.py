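"""Tn5 cut-site extraction and per-region counting around candidate sites.

ATAC-seq reads report transposase insertion events.  The insertion centre is
recovered by shifting the 5' alignment end (+4 bp on the forward strand,
-5 bp on the reverse strand).  Around each candidate binding site we use a
three-band layout: the footprint ``a`` (the motif-match span), shoulders
``b`` on each side (ignored by the model to absorb motif-length
variability), and flanks ``c`` beyond the shoulders.  Counts of
allele-assigned cut sites in ``a`` and ``c`` are the response data of the
allele-specific binding GLM.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

FORWARD_SHIFT = 4
REVERSE_SHIFT = 5


class Allele(str, Enum):
    REF = "REF"
    ALT = "ALT"
    UNASSIGNED = "UNASSIGNED"


class Region(str, Enum):
    FOOTPRINT = "footprint"  # band a
    SHOULDER = "shoulder"    # band b, excluded from the model
    FLANK = "flank"          # band c


@dataclass(frozen=True)
class CutSite:
    """A single transposase insertion centre, optionally allele-tagged."""

    chrom: str
    pos: int  # 0-based genomic coordinate
    strand: str
    allele: Allele = Allele.UNASSIGNED
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("cut site position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.replicate < 1:
            raise ValueError("replicate ids are 1-based")


@dataclass
class Peak:
    """An open-chromatin interval (0-based half-open) with its cut tally."""

    chrom: str
    start: int
    end: int
    cut_count: int = 0
    name: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("peak requires start < end")
        if self.cut_count < 0:
            raise ValueError("cut_count must be >= 0")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class HetSNP:
    """A heterozygous single-nucleotide variant, 0-based internally."""

    chrom: str
    pos: int  # 0-based; VCF POS - 1
    ref_base: str
    alt_base: str
    dp: int = 0
    mq: float = 0.0
    id: str = "."

    def __post_init__(self) -> None:
        valid = {"A", "C", "G", "T"}
        if self.ref_base not in valid or self.alt_base not in valid:
            raise ValueError("alleles must be single A/C/G/T bases")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt alleles must differ")
        if self.dp < 0 or self.mq < 0:
            raise ValueError("DP and MQ must be >= 0")

    @property
    def vcf_pos(self) -> int:
        """1-based position as printed in a VCF."""
        return self.pos + 1

    @classmethod
    def from_vcf_pos(cls, chrom: str, vcf_pos: int, ref_base: str,
                     alt_base: str, **kw) -> "HetSNP":
        return cls(chrom, vcf_pos - 1, ref_base, alt_base, **kw)


@dataclass(frozen=True)
class Interval:
    start: int
    end: int  # half-open

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("interval requires start < end")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SiteLayout:
    """The a/b/c band partition around one motif match holding a het SNP.

    Bands are contiguous and ordered
    ``flank_left < shoulder_left < footprint < shoulder_right < flank_right``;
    the SNP lies inside the footprint.
    """

    chrom: str
    footprint: Interval
    shoulders: tuple[Interval, Interval]
    flanks: tuple[Interval, Interval]
    snp: HetSNP

    def __post_init__(self) -> None:
        fl, fr = self.flanks
        sl, sr = self.shoulders
        order = (fl.start, fl.end, sl.start, sl.end, self.footprint.start,
                 self.footprint.end, sr.start, sr.end, fr.start, fr.end)
        if any(a > b for a, b in zip(order, order[1:])):
            raise ValueError("layout bands must be disjoint and ordered")
        if not self.footprint.contains(self.snp.pos):
            raise ValueError("SNP must lie inside the footprint band")
        if self.snp.chrom != self.chrom:
            raise ValueError("SNP chromosome does not match layout")

    @classmethod
    def around_motif(cls, chrom: str, start: int, end: int, snp: HetSNP,
                     shoulder: int = 10, flank: int = 50) -> "SiteLayout":
        """Build the layout for a motif match [start, end) containing *snp*."""
        if shoulder < 1 or flank < 1:
            raise ValueError("shoulder and flank widths must be >= 1")
        a = Interval(start, end)
        sl = Interval(start - shoulder, start)
        sr = Interval(end, end + shoulder)
        fl = Interval(sl.start - flank, sl.start)
        fr = Interval(sr.end, sr.end + flank)
        return cls(chrom, a, (sl, sr), (fl, fr), snp)

    @property
    def window(self) -> Interval:
        return Interval(self.flanks[0].start, self.flanks[1].end)

    def region_of(self, pos: int) -> Region | None:
        if self.footprint.contains(pos):
            return Region.FOOTPRINT
        if any(s.contains(pos) for s in self.shoulders):
            return Region.SHOULDER
        if any(f.contains(pos) for f in self.flanks):
            return Region.FLANK
        return None


@dataclass
class CountTable:
    """Cut-site counts indexed by (allele, region, replicate).

    Only footprint and flank cells enter the model; shoulder and
    unassigned-allele cuts are tallied separately so totals are conserved.
    """

    replicates: tuple[int, ...]
    counts: dict = field(default_factory=dict)
    shoulder_tally: int = 0
    unassigned_tally: int = 0

    def __post_init__(self) -> None:
        for rep in self.replicates:
            for allele in (Allele.REF, Allele.ALT):
                for region in (Region.FOOTPRINT, Region.FLANK):
                    self.counts.setdefault((allele, region, rep), 0)

    def y(self, allele: Allele, region: Region, replicate: int) -> int:
        return self.counts[(allele, region, replicate)]

    def _sum(self, allele: Allele, region: Region) -> int:
        return sum(self.y(allele, region, r) for r in self.replicates)

    @property
    def a_ref(self) -> int:
        return self._sum(Allele.REF, Region.FOOTPRINT)

    @property
    def a_alt(self) -> int:
        return self._sum(Allele.ALT, Region.FOOTPRINT)

    @property
    def c_ref(self) -> int:
        return self._sum(Allele.REF, Region.FLANK)

    @property
    def c_alt(self) -> int:
        return self._sum(Allele.ALT, Region.FLANK)

    def total(self) -> int:
        return sum(self.counts.values()) + self.shoulder_tally + self.unassigned_tally


def shift_cut_site(alignment_start: int, alignment_end: int, strand: str) -> int:
    """Shift an aligned read end to the Tn5 insertion centre.

    Forward-strand reads: 5' end (``alignment_start``) + 4.  Reverse-strand
    reads: 5' end (last aligned base, ``alignment_end - 1``) - 5.  A negative
    result (read at a contig edge) is the caller's cue to discard the cut.
    """
    if strand == "+":
        return alignment_start + FORWARD_SHIFT
    if strand == "-":
        return (alignment_end - 1) - REVERSE_SHIFT
    raise ValueError(f"invalid strand {strand!r}")


def assign_allele(base: str | None, base_quality: float, snp: HetSNP,
                  min_base_quality: int = 20) -> Allele:
    """Phase a read to an allele from its base at the SNP position.

    Reads not covering the SNP (``base is None``), low-quality calls, and
    third alleles are all UNASSIGNED.
    """
    if base is None or base_quality < min_base_quality:
        return Allele.UNASSIGNED
    base = base.upper()
    if base == snp.ref_base:
        return Allele.REF
    if base == snp.alt_base:
        return Allele.ALT
    return Allele.UNASSIGNED


def filter_peaks(peaks: Sequence[Peak], min_cuts: int = 200) -> list[Peak]:
    """Keep peaks with at least *min_cuts* cut sites (strict '< removed')."""
    return [p for p in peaks if p.cut_count >= min_cuts]


def filter_variants(records: Iterable, peaks: Sequence[Peak],
                    min_dp: int = 10, min_mq: float = 20.0) -> tuple[list[HetSNP], dict]:
    """Select heterozygous SNVs with DP > min_dp and MQ > min_mq inside peaks.

    *records* are :class:`pysam.VariantRecord` objects (or duck-typed
    equivalents with chrom/pos/ref/alts/info/samples).  Returns the kept
    SNPs plus a tally of rejection reasons; records missing DP or MQ are
    counted under ``missing_field``.
    """
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)

    kept: list[HetSNP] = []
    stats = {"kept": 0, "not_het": 0, "not_snv": 0, "low_dp": 0,
             "low_mq": 0, "missing_field": 0, "outside_peak": 0}
    for rec in records:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1 \
                or rec.ref not in "ACGT" or alts[0] not in "ACGT":
            stats["not_snv"] += 1
            continue
        gts = {tuple(sorted(s["GT"])) for s in rec.samples.values()
               if s.get("GT") is not None}
        if (0, 1) not in gts:
            stats["not_het"] += 1
            continue
        dp = rec.info.get("DP")
        mq = rec.info.get("MQ")
        if dp is None or mq is None:
            stats["missing_field"] += 1
            continue
        if dp <= min_dp:
            stats["low_dp"] += 1
            continue
        if mq <= min_mq:
            stats["low_mq"] += 1
            continue
        pos0 = rec.pos - 1  # pysam .pos is 1-based for VariantRecord
        tree = trees.get(rec.chrom)
        if tree is None or not tree.overlaps(pos0):
            stats["outside_peak"] += 1
            continue
        kept.append(HetSNP(rec.chrom, pos0, rec.ref, alts[0],
                           dp=int(dp), mq=float(mq), id=rec.id or "."))
        stats["kept"] += 1
    return kept, stats


def count_cuts_by_region(cuts: Iterable[CutSite], layout: SiteLayout,
                         replicates: Sequence[int] | None = None) -> CountTable:
    """Tabulate allele-assigned cuts into the (allele, region, replicate) grid.

    Shoulder-band cuts and UNASSIGNED cuts inside the window are excluded
    from the model cells but tallied so that totals are conserved.
    """
    cuts = [c for c in cuts if c.chrom == layout.chrom
            and layout.window.contains(c.pos)]
    reps = tuple(sorted(replicates)) if replicates else \
        tuple(sorted({c.replicate for c in cuts})) or (1,)
    table = CountTable(replicates=reps)
    for c in cuts:
        region = layout.region_of(c.pos)
        if region is None:  # cannot happen: bands tile the window
            continue
        if c.allele is Allele.UNASSIGNED:
            table.unassigned_tally += 1
        elif region is Region.SHOULDER:
            table.shoulder_tally += 1
        else:
            table.counts[(c.allele, region, c.replicate)] += 1
    return table


# ---------------------------------------------------------------------------
# SAM/BAM plumbing


def _replicate_of(read: pysam.AlignedSegment) -> int:
    """Replicate id from the RG tag ('rep3' or '3' -> 3); default 1."""
    try:
        rg = read.get_tag("RG")
    except KeyError:
        return 1
    digits = "".join(ch for ch in str(rg) if ch.isdigit())
    return int(digits) if digits else 1


def _usable(read: pysam.AlignedSegment) -> bool:
    return not (read.is_unmapped or read.is_duplicate or read.is_secondary
                or read.is_supplementary or read.mapping_quality == 0)


def read_cut_position(read: pysam.AlignedSegment) -> int | None:
    """Shifted cut site of one alignment, or None if it falls off the contig."""
    strand = "-" if read.is_reverse else "+"
    pos = shift_cut_site(read.reference_start, read.reference_end, strand)
    if pos < 0:
        logger.warning("cut site before contig start for read %s; discarded",
                       read.query_name)
        return None
    return pos


def _base_at(read: pysam.AlignedSegment, ref_pos: int) -> tuple[str | None, float]:
    """Query base and quality aligned to *ref_pos*; (None, 0) if not covered."""
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == ref_pos:
            qual = read.query_qualities[qpos] if read.query_qualities is not None else 60
            return read.query_sequence[qpos], qual
    return None, 0.0


def iter_cut_positions(path: str) -> Iterable[tuple[str, int, int]]:
    """Yield (chrom, cut_pos, replicate) for every usable alignment."""
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if not _usable(read):
                continue
            pos = read_cut_position(read)
            if pos is not None:
                yield read.reference_name, pos, _replicate_of(read)


def count_cuts_in_peaks(path: str, peaks: Sequence[Peak]) -> list[Peak]:
    """Populate Peak.cut_count from the shifted cuts of all replicates."""
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        p.cut_count = 0
        by_chrom.setdefault(p.chrom, []).append(p)
    starts = {c: sorted(ps, key=lambda p: p.start) for c, ps in by_chrom.items()}
    start_keys = {c: [p.start for p in ps] for c, ps in starts.items()}
    for chrom, pos, _rep in iter_cut_positions(path):
        ps = starts.get(chrom)
        if not ps:
            continue
        i = bisect_right(start_keys[chrom], pos) - 1
        # peaks may abut; walk left while still overlapping
        while i >= 0 and ps[i].end > pos:
            if ps[i].contains(pos):
                ps[i].cut_count += 1
            i -= 1
    return list(peaks)


def collect_site_cuts(path: str, layouts: Sequence[SiteLayout],
                      min_base_quality: int = 20) -> list[list[CutSite]]:
    """One pass over a SAM/BAM collecting allele-tagged cuts per layout.

    A cut is attributed to every layout whose window contains it; the allele
    comes from the read's base at that layout's SNP.
    """
    trees: dict[str, IntervalTree] = {}
    for i, lay in enumerate(layouts):
        trees.setdefault(lay.chrom, IntervalTree()).addi(
            lay.window.start, lay.window.end, i)
    out: list[list[CutSite]] = [[] for _ in layouts]
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if not _usable(read):
                continue
            pos = read_cut_position(read)
            if pos is None:
                continue
            tree = trees.get(read.reference_name)
            if tree is None:
                continue
            for hit in tree.at(pos):
                lay = layouts[hit.data]
                base, qual = _base_at(read, lay.snp.pos)
                allele = assign_allele(base, qual, lay.snp, min_base_quality)
                out[hit.data].append(CutSite(
                    chrom=read.reference_name, pos=pos,
                    strand="-" if read.is_reverse else "+",
                    allele=allele, replicate=_replicate_of(read)))
    return out


def load_peaks(path: str) -> list[Peak]:
    """Read peaks from BED or narrowPeak (first three columns used)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            name = fields[3] if len(fields) > 3 else "."
            peaks.append(Peak(fields[0], int(fields[1]), int(fields[2]),
                              name=name))
    return peaks


def load_het_snps(vcf_path: str, peaks: Sequence[Peak],
                  min_dp: int = 10, min_mq: float = 20.0) -> tuple[list[HetSNP], dict]:
    with pysam.VariantFile(vcf_path) as vf:
        return filter_variants(vf.fetch(), peaks, min_dp=min_dp, min_mq=min_mq)
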