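"""Target-gene assignment, eQTL overlap and enrichment for regulatory SNPs.

SNPs within 1 kb of a transcription start site are promoter variants and
take the closest gene as target; the rest are enhancer candidates whose
targets come from chromatin-interaction pairs (genes resident in the paired
anchor of any interaction overlapping the SNP).  eQTL overlap is an exact
rsID match, falling back to chrom+pos, and enrichment of regulatory SNPs
among eQTLs is a Pearson chi-square on the 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import chi2_contingency

from .cutsites import HetSNP


@dataclass(frozen=True)
class InteractionRecord:
    """One chromatin-interaction pair with the genes resident in each anchor."""

    chrom1: str
    start1: int
    end1: int
    genes1: tuple[str, ...]
    chrom2: str
    start2: int
    end2: int
    genes2: tuple[str, ...]

    def anchor1_contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom1 and self.start1 <= pos < self.end1

    def anchor2_contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom2 and self.start2 <= pos < self.end2


@dataclass(frozen=True)
class EqtlRecord:
    rsid: str = ""
    chrom: str = ""
    pos: int = -1  # 1-based, as printed in GTEx-style tables
    gene: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        if not self.rsid and self.pos < 0:
            raise ValueError("eQTL record needs an rsID or a position")


def classify_snp_location(snp: HetSNP, tss_table: pd.DataFrame,
                          window: int = 1000) -> tuple[str, str | None]:
    """Promoter vs enhancer-candidate classification by TSS distance.

    Returns (class, target_gene): promoter iff some TSS lies within
    *window* bp (inclusive) of the SNP, in which case the closest gene is
    the target (ties broken lexicographically).  Distance ignores gene
    strand.
    """
    if tss_table.empty:
        raise ValueError("empty TSS table")
    same = tss_table[tss_table["chrom"] == snp.chrom]
    if same.empty:
        return "enhancer_candidate", None
    dist = (same["tss"] - snp.pos).abs()
    best = dist.min()
    if best > window:
        return "enhancer_candidate", None
    genes = sorted(same.loc[dist == best, "gene_id"])
    return "promoter", genes[0]


def map_enhancer_targets(snps: Sequence[HetSNP],
                         interactions: Sequence[InteractionRecord]) -> dict[str, set[str]]:
    """Union of genes in the paired anchor of every interaction hit per SNP."""
    out: dict[str, set[str]] = {}
    for snp in snps:
        targets: set[str] = set()
        for rec in interactions:
            if rec.anchor1_contains(snp.chrom, snp.pos):
                targets.update(rec.genes2)
            if rec.anchor2_contains(snp.chrom, snp.pos):
                targets.update(rec.genes1)
        out[snp.id] = targets
    return out


def overlap_eqtl(snps: Sequence[HetSNP],
                 eqtls: Sequence[EqtlRecord]) -> dict[str, bool]:
    """Per-SNP flag: exact rsID match, else exact chrom+pos (1-based) match."""
    by_rsid = {e.rsid for e in eqtls if e.rsid}
    by_pos = {(e.chrom, e.pos) for e in eqtls if e.pos >= 0}
    flags = {}
    for snp in snps:
        hit = (snp.id in by_rsid) or ((snp.chrom, snp.vcf_pos) in by_pos)
        flags[snp.id] = bool(hit)
    return flags


def enrichment_test(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square (df=1) on a 2x2 regulatory-x-eQTL count table."""
    df = pd.DataFrame(table)
    if df.shape != (2, 2) or (df < 0).any().any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if (df.sum(axis=0) == 0).any() or (df.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero margin")
    stat, pvalue, _, _ = chi2_contingency(df.to_numpy(), correction=yates)
    return float(stat), float(pvalue)


# ---------------------------------------------------------------------------
# Flat-file loaders (TSV conventions in the module docstring)


def load_tss_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"gene_id", "chrom", "strand", "tss"} - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    return df


def _split_genes(value) -> tuple[str, ...]:
    if pd.isna(value) or value == "":
        return ()
    return tuple(g for g in str(value).replace(";", ",").split(",") if g)


def load_interactions(path: str) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    if df.empty:
        return []
    return [InteractionRecord(r.chrom1, int(r.start1), int(r.end1),
                              _split_genes(r.genes1), r.chrom2, int(r.start2),
                              int(r.end2), _split_genes(r.genes2))
            for r in df.itertuples()]


def load_eqtls(path: str) -> list[EqtlRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.empty:
        return []
    return [EqtlRecord(rsid=str(r.rsid) if pd.notna(r.rsid) else "",
                       chrom=str(r.chrom), pos=int(r.pos),
                       gene=str(r.gene), tissue=str(getattr(r, "tissue", "")))
            for r in df.itertuples()]


def annotate_snps(snps: Sequence[HetSNP], tss_table: pd.DataFrame,
                  interactions: Sequence[InteractionRecord],
                  eqtls: Sequence[EqtlRecord],
                  window: int = 1000) -> pd.DataFrame:
    """One row per SNP: location class, target genes, eQTL flag."""
    columns = ["snp_id", "chrom", "pos", "location", "target_genes", "eqtl"]
    if not snps:
        return pd.DataFrame(columns=columns)
    enhancer_targets = map_enhancer_targets(snps, interactions)
    eqtl_flags = overlap_eqtl(snps, eqtls)
    rows = []
    for snp in snps:
        cls, promoter_gene = classify_snp_location(snp, tss_table, window)
        if cls == "promoter":
            targets = [promoter_gene]
        else:
            targets = sorted(enhancer_targets.get(snp.id, set()))
        rows.append({"snp_id": snp.id, "chrom": snp.chrom, "pos": snp.vcf_pos,
                     "location": cls, "target_genes": ",".join(targets),
                     "eqtl": eqtl_flags.get(snp.id, False)})
    return pd.DataFrame(rows)
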