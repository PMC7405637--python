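"""Synthetic data with known ground truth for every pipeline stage.

The generator draws per-cell cut-site counts from the same NB-GLM family the
model fits: log-mean b0 + br*x_r + ba*x_a + bint*x_r*x_a, with bint equal to
the configured effect at allele-specific sites and 0 elsewhere.  At
allele-specific sites ba = -bint so that flank coverage stays balanced
between alleles and the signal lives entirely in the footprint, mirroring a
binding change rather than a copy-number change.  In read-level mode the
drawn counts are realised as SAM alignments whose shifted cut sites
reproduce the counts exactly, plus FASTA/VCF/BED/JASPAR/TSV companions, so
the full pipeline can be exercised end to end against the truth table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cutsites import Allele, CountTable, HetSNP, Interval, Region, SiteLayout
from .motifscan import BASES, pssm_from_counts

SAM_READ_LENGTH = 100


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth generating conditions for a synthetic dataset."""

    n_sites: int = 100
    fraction_asb: float = 0.3
    beta_int_effect: float = 1.5   # true interaction, natural-log scale
    cell_mean: float = 50.0        # expected flank count per cell
    footprint_depth: float = 2.0   # flank/footprint cut-rate ratio under binding
    dispersion: float = 0.1        # NB2 overdispersion alpha
    replicates: int = 3
    seed: int = 0
    motif_length: int = 12
    snp_density: float = 0.0       # extra non-candidate het SNPs per site
    shoulder: int = 10
    flank: int = 50
    site_spacing: int = 400
    margin: int = 300
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_asb <= 1.0:
            raise ValueError("fraction_asb must be in [0, 1]")
        for name in ("n_sites", "cell_mean", "footprint_depth", "replicates",
                     "motif_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None):
    """NB2 draw with Var = mean + dispersion*mean^2 (Poisson when 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def site_betas(config: SimConfig, is_asb: bool) -> dict[str, float]:
    bint = config.beta_int_effect if is_asb else 0.0
    return {
        "beta0": float(np.log(config.cell_mean / config.footprint_depth)),
        "beta_r": float(np.log(config.footprint_depth)),
        "beta_a": -bint,  # keeps flank coverage allele-balanced
        "beta_int": bint,
    }


def simulate_site(config: SimConfig, is_asb: bool,
                  rng: np.random.Generator | None = None) -> tuple[CountTable, dict]:
    """Draw one site's (allele, region, replicate) counts plus its truth record."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    b = site_betas(config, is_asb)
    reps = tuple(range(1, config.replicates + 1))
    table = CountTable(replicates=reps)
    for rep in reps:
        for allele, x_a in ((Allele.REF, 0), (Allele.ALT, 1)):
            for region, x_r in ((Region.FOOTPRINT, 0), (Region.FLANK, 1)):
                mu = np.exp(b["beta0"] + b["beta_r"] * x_r + b["beta_a"] * x_a
                            + b["beta_int"] * x_r * x_a)
                table.counts[(allele, region, rep)] = int(
                    nb_draw(rng, mu, config.dispersion))
    truth = {"is_asb": bool(is_asb), **b}
    return table, truth


@dataclass
class SimDataset:
    """File bundle emitted by :func:`simulate_dataset`."""

    outdir: str
    fasta: str
    vcf: str
    peaks: str
    motifs: str
    sam: str | None
    truth: pd.DataFrame
    tss: str
    interactions: str
    eqtls: str
    ase_counts: str
    layouts: list = field(default_factory=list)
    tables: list = field(default_factory=list)
    snps: list = field(default_factory=list)


def _informative_counts(rng: np.random.Generator, length: int,
                        total: int = 1000) -> tuple[np.ndarray, str]:
    """Strongly-peaked count matrix: one planted motif disrupts hard."""
    consensus = "".join(rng.choice(list(BASES)) for _ in range(length))
    counts = np.ones((4, length))
    for j, base in enumerate(consensus):
        counts[BASES.index(base), j] = total - 3
    return counts, consensus


def _write_jaspar(path: str, motif_id: str, name: str, counts: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(f">{motif_id}\t{name}\n")
        for i, base in enumerate(BASES):
            row = " ".join(f"{int(v):6d}" for v in counts[i])
            fh.write(f"{base}  [ {row} ]\n")


def _write_fasta(path: str, chrom: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def _write_vcf(path: str, chrom: str, chrom_len: int, snps: list[HetSNP]) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={chrom_len}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1",
    ]
    for snp in sorted(snps, key=lambda s: s.pos):
        lines.append(f"{snp.chrom}\t{snp.vcf_pos}\t{snp.id}\t{snp.ref_base}\t"
                     f"{snp.alt_base}\t100\tPASS\tDP={snp.dp};MQ={snp.mq:g}\t"
                     "GT\t0/1")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _cut_to_read(chrom: str, cut: int, snp_pos: int, haplotype: str,
                 name: str, rg: str) -> str:
    """One SAM line whose shifted cut site is exactly *cut* and which covers
    the SNP (forward reads for cuts at/left of the SNP, reverse otherwise)."""
    L = SAM_READ_LENGTH
    if cut <= snp_pos:
        flag, start = 0, cut - 4
    else:
        flag, start = 16, cut + 5 - (L - 1)
    seq = haplotype[start:start + L]
    qual = "I" * L
    return "\t".join([name, str(flag), chrom, str(start + 1), "60", f"{L}M",
                      "*", "0", "0", seq, qual, f"RG:Z:{rg}"])


def simulate_dataset(config: SimConfig, outdir: str,
                     reads: bool = True) -> SimDataset:
    """Emit a complete synthetic input bundle with its truth table.

    One motif is planted per site with a het SNP inside the motif span.  At
    allele-specific sites the favoured allele carries the motif consensus
    base, so the disruption score's sign agrees with the simulated binding
    change (beta_int > 0, gain on ALT, pairs with delta < 0).
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n_asb = int(round(config.n_sites * config.fraction_asb))
    asb_flags = np.array([True] * n_asb + [False] * (config.n_sites - n_asb))

    counts_mat, consensus = _informative_counts(rng, config.motif_length)
    motif_id = "SIM0001.1"
    pssm = pssm_from_counts(counts_mat, motif_id=motif_id)

    chrom_len = 2 * config.margin + config.n_sites * config.site_spacing
    genome = rng.choice(list(BASES), size=chrom_len)

    layouts, tables, snps, truth_rows = [], [], [], []
    sam_reads: list[tuple[int, str]] = []
    half = config.motif_length // 2
    for i in range(config.n_sites):
        center = config.margin + i * config.site_spacing + config.site_spacing // 2
        start = center - half
        end = start + config.motif_length
        # SNP at a central motif column (always at least 1 bp from each edge)
        snp_col = int(rng.integers(1, config.motif_length - 1))
        snp_pos = start + snp_col
        genome[start:end] = list(consensus)

        cons_base = consensus[snp_col]
        others = [b for b in BASES if b != cons_base]
        weak_base = others[int(rng.integers(len(others)))]
        is_asb = bool(asb_flags[i])
        if is_asb and config.beta_int_effect > 0:
            ref_base, alt_base = weak_base, cons_base   # gain on ALT, delta < 0
        else:
            ref_base, alt_base = cons_base, weak_base   # loss on ALT, delta > 0
        genome[snp_pos] = ref_base
        snp = HetSNP(config.chrom, snp_pos, ref_base, alt_base, dp=100,
                     mq=60.0, id=f"snp{i + 1:04d}")
        snps.append(snp)
        layout = SiteLayout.around_motif(config.chrom, start, end, snp,
                                         shoulder=config.shoulder,
                                         flank=config.flank)
        layouts.append(layout)
        table, truth = simulate_site(config, is_asb, rng)
        tables.append(table)
        truth_rows.append({"site": i, "snp_id": snp.id, "chrom": config.chrom,
                           "pos": snp.vcf_pos, "motif_id": motif_id,
                           "motif_start": start, "motif_end": end, **truth})

    genome_str = "".join(genome)
    fasta = os.path.join(outdir, "genome.fa")
    _write_fasta(fasta, config.chrom, genome_str)

    vcf = os.path.join(outdir, "variants.vcf")
    _write_vcf(vcf, config.chrom, chrom_len, snps)

    peaks = os.path.join(outdir, "peaks.bed")
    with open(peaks, "w") as fh:
        for i, lay in enumerate(layouts):
            w = lay.window
            fh.write(f"{config.chrom}\t{w.start - 20}\t{w.end + 20}\tpeak{i + 1}\n")

    motifs_path = os.path.join(outdir, "motif.jaspar")
    _write_jaspar(motifs_path, motif_id, "SIMTF", counts_mat)

    sam = None
    if reads:
        sam = os.path.join(outdir, "reads.sam")
        hap = {Allele.REF: genome_str, Allele.ALT: None}
        rid = 0
        for i, (lay, table) in enumerate(zip(layouts, tables)):
            snp = lay.snp
            alt_genome = (genome_str[:snp.pos] + snp.alt_base
                          + genome_str[snp.pos + 1:])
            hap[Allele.ALT] = alt_genome
            regions = {
                Region.FOOTPRINT: [lay.footprint],
                Region.FLANK: list(lay.flanks),
                Region.SHOULDER: list(lay.shoulders),
            }
            for rep in table.replicates:
                for allele in (Allele.REF, Allele.ALT):
                    for region in (Region.FOOTPRINT, Region.FLANK):
                        k = table.counts[(allele, region, rep)]
                        cuts = _draw_positions(rng, regions[region], k)
                        for cut in cuts:
                            rid += 1
                            sam_reads.append((cut, _cut_to_read(
                                config.chrom, int(cut), snp.pos, hap[allele],
                                f"read{rid:07d}", f"rep{rep}")))
                    # shoulder cuts: present in the library, ignored by the model
                    k = int(nb_draw(rng, config.cell_mean / 5, config.dispersion))
                    for cut in _draw_positions(rng, regions[Region.SHOULDER], k):
                        rid += 1
                        sam_reads.append((cut, _cut_to_read(
                            config.chrom, int(cut), snp.pos, hap[allele],
                            f"read{rid:07d}", f"rep{rep}")))
        sam_reads.sort(key=lambda t: (t[0], t[1]))
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            fh.write(f"@SQ\tSN:{config.chrom}\tLN:{chrom_len}\n")
            for rep in range(1, config.replicates + 1):
                fh.write(f"@RG\tID:rep{rep}\tSM:sample1\n")
            for _, line in sam_reads:
                fh.write(line + "\n")

    truth_df = pd.DataFrame(truth_rows)
    truth_path = os.path.join(outdir, "truth.tsv")
    truth_df.to_csv(truth_path, sep="\t", index=False)

    tss, interactions, eqtls, ase_counts = _write_companions(
        config, outdir, layouts, truth_df, rng)

    return SimDataset(outdir=outdir, fasta=fasta, vcf=vcf, peaks=peaks,
                      motifs=motifs_path, sam=sam, truth=truth_df, tss=tss,
                      interactions=interactions, eqtls=eqtls,
                      ase_counts=ase_counts, layouts=layouts, tables=tables,
                      snps=snps)


def _draw_positions(rng: np.random.Generator, intervals: list[Interval],
                    k: int) -> np.ndarray:
    """k positions uniform over the union of intervals."""
    if k == 0:
        return np.array([], dtype=int)
    lens = np.array([len(iv) for iv in intervals], dtype=float)
    which = rng.choice(len(intervals), size=k, p=lens / lens.sum())
    return np.array([intervals[w].start + rng.integers(len(intervals[w]))
                     for w in which], dtype=int)


def _write_companions(config: SimConfig, outdir: str, layouts, truth_df,
                      rng) -> tuple[str, str, str, str]:
    """Gene TSS, chromatin-interaction, eQTL, and allelic-expression tables
    wired to the planted sites (half promoter-range, half enhancer-range)."""
    tss_rows, inter_rows, eqtl_rows, ase_rows = [], [], [], []
    far_gene_start = 2 * config.margin + config.n_sites * config.site_spacing
    for i, lay in enumerate(layouts):
        snp = lay.snp
        is_asb = bool(truth_df.loc[i, "is_asb"])
        promoter = i % 2 == 0
        gene = f"GENE{i + 1:04d}"
        if promoter:
            tss_pos = snp.pos + 400
        else:
            tss_pos = snp.pos + 5000
            inter_rows.append({
                "chrom1": config.chrom, "start1": lay.window.start,
                "end1": lay.window.end, "genes1": "",
                "chrom2": config.chrom, "start2": tss_pos - 100,
                "end2": tss_pos + 100, "genes2": gene})
        tss_rows.append({"gene_id": gene, "chrom": config.chrom,
                         "strand": "+", "tss": tss_pos})
        if is_asb:
            eqtl_rows.append({"rsid": snp.id, "chrom": config.chrom,
                              "pos": snp.vcf_pos, "gene": gene,
                              "tissue": "simulated"})
        # allelic expression at a coding SNP of the target gene
        frac = 0.85 if is_asb else 0.5
        depth = 60
        alt = int(rng.binomial(depth, frac))
        ase_rows.append({"gene": gene, "snp": f"c{snp.id}",
                         "ref_count": depth - alt, "alt_count": alt})
    paths = {}
    for name, rows in (("tss", tss_rows), ("interactions", inter_rows),
                       ("eqtls", eqtl_rows), ("ase_counts", ase_rows)):
        path = os.path.join(outdir, f"{name}.tsv")
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths["tss"], paths["interactions"], paths["eqtls"], paths["ase_counts"]


def simulate_ase(n_genes: int, imbalance: float, depth: int,
                 seed: int = 0) -> pd.DataFrame:
    """Binomial allelic-count fixtures: alt_count ~ Bin(depth, imbalance)."""
    if not 0.0 < imbalance < 1.0:
        raise ValueError("imbalance must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_genes):
        alt = int(rng.binomial(depth, imbalance)) if depth > 0 else 0
        rows.append({"gene": f"GENE{i + 1:04d}", "snp": f"snp{i + 1:04d}",
                     "ref_count": depth - alt, "alt_count": alt,
                     "true_imbalanced": imbalance != 0.5})
    return pd.DataFrame(rows)
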