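"""Allele-specific expression tests on RNA-seq allelic counts.

Under balanced expression the alternative-allele read count at a coding
heterozygous SNP is Binomial(N, 0.5).  The exact two-sided binomial test
(minimum-likelihood ordering) flags imbalanced SNPs; a gene is called
allele-specifically expressed when any of its coding het SNPs rejects at the
chosen level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .asbmodel import adjust_fdr


@dataclass(frozen=True)
class AllelicCount:
    snp_id: str
    gene_id: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.ref_count + self.alt_count


def ase_binomial_test(ref_count: int, alt_count: int) -> float | None:
    """Exact two-sided p-value against Binomial(N, 0.5); None when N = 0.

    Two-sided mass is the sum of outcome probabilities no larger than the
    observed outcome's probability (the common exact-test convention).
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    n = ref_count + alt_count
    if n == 0:
        return None
    return float(binomtest(ref_count, n, 0.5, alternative="two-sided").pvalue)


def call_ase_genes(counts, alpha: float = 0.05,
                   bh_correct: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP exact tests and per-gene ASE calls.

    *counts* is an iterable of :class:`AllelicCount` or a DataFrame with
    columns gene, snp, ref_count, alt_count.  A gene is ASE-positive iff any
    of its testable SNPs has p (or q with *bh_correct*) below *alpha*; genes
    with no testable SNP are reported as ``untested``.
    """
    if isinstance(counts, pd.DataFrame):
        counts = [AllelicCount(str(r.snp), str(r.gene), int(r.ref_count),
                               int(r.alt_count)) for r in counts.itertuples()]
    rows = []
    for c in counts:
        rows.append({"gene": c.gene_id, "snp": c.snp_id,
                     "ref_count": c.ref_count, "alt_count": c.alt_count,
                     "pvalue": ase_binomial_test(c.ref_count, c.alt_count)})
    snp_df = pd.DataFrame(rows)
    if snp_df.empty:
        return snp_df, pd.DataFrame(columns=["gene", "call", "min_pvalue"])
    testable = snp_df["pvalue"].notna()
    crit = "pvalue"
    if bh_correct and testable.any():
        snp_df.loc[testable, "qvalue"] = adjust_fdr(
            snp_df.loc[testable, "pvalue"].to_numpy())
        crit = "qvalue"
    gene_rows = []
    for gene, grp in snp_df.groupby("gene", sort=True):
        ps = grp[crit].dropna() if crit in grp else pd.Series(dtype=float)
        if ps.empty:
            gene_rows.append({"gene": gene, "call": "untested",
                              "min_pvalue": np.nan})
        else:
            call = "ase" if (ps < alpha).any() else "balanced"
            gene_rows.append({"gene": gene, "call": call,
                              "min_pvalue": float(ps.min())})
    return snp_df, pd.DataFrame(gene_rows)


def load_allelic_counts(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "snp", "ref_count", "alt_count"} - set(df.columns)
    if missing:
        raise ValueError(f"allelic count table missing columns: {sorted(missing)}")
    return df
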