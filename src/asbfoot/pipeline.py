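"""End-to-end orchestration: cut sites -> motif scan -> GLM -> annotation -> ASE.

Every stage writes a TSV so any stage can be swapped for an external tool;
the run also emits a filtering-funnel summary (peaks, het SNPs, motif
matches, candidate sites, significant sites, filtered sites, regulatory
SNPs) and a JSON manifest of thresholds and versions.  Outputs are pure
functions of the inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import __version__
from .annotate import annotate_snps, enrichment_test, load_eqtls, \
    load_interactions, load_tss_table
from .ase import call_ase_genes, load_allelic_counts
from .asbmodel import AsbCall, adjust_fdr, build_design, empirical_filter, \
    fit_nb_glm, summarize_snps
from .cutsites import SiteLayout, collect_site_cuts, \
    count_cuts_by_region, count_cuts_in_peaks, filter_peaks, load_het_snps, \
    load_peaks
from .motifscan import call_candidate_sites, load_motifs, scan_sequences

logger = logging.getLogger(__name__)

FUNNEL_COLUMNS = ["open_chromatin_regions", "het_snps",
                  "potential_tf_binding_sites", "candidate_asb_sites",
                  "significant_asb_sites", "filtered_asb_sites",
                  "regulatory_snps"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a run; unknown config keys are rejected."""

    reads: str = ""
    genome: str = ""
    peaks: str = ""
    variants: str = ""
    motifs: str = ""
    tss: str = ""
    interactions: str = ""
    eqtls: str = ""
    ase_counts: str = ""
    out_dir: str = "asbfoot_out"
    min_cuts: int = 200
    min_dp: int = 10
    min_mq: float = 20.0
    min_base_quality: int = 20
    motif_pvalue: float = 1e-4
    pseudocount: float = 0.8
    shoulder: int = 10
    flank: int = 50
    fdr_max: float = 0.05
    min_abs_delta: float = 5.0
    min_abs_log2_magnitude: float = 1.0
    alpha_ase: float = 0.05
    tss_window: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ("min_cuts", "motif_pvalue", "shoulder", "flank",
                    "fdr_max", "alpha_ase", "tss_window")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_dp", "min_mq", "min_base_quality", "pseudocount",
                     "min_abs_delta", "min_abs_log2_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "PipelineConfig":
        """Parse a `key = value` config file; unknown keys are an error."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        values: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = raw
        values.update({k: v for k, v in overrides.items() if v is not None})
        # coerce strings to the declared field types
        coerced = {}
        for f in dataclasses.fields(cls):
            if f.name not in values:
                continue
            v = values[f.name]
            if isinstance(v, str) and f.type in ("int",):
                v = int(v)
            elif isinstance(v, str) and f.type in ("float",):
                v = float(v)
            coerced[f.name] = v
        return cls(**coerced)


@dataclass
class PipelineResult:
    funnel: dict
    calls: list
    asb_table: pd.DataFrame
    annotation: pd.DataFrame | None
    ase_snps: pd.DataFrame | None
    ase_genes: pd.DataFrame | None
    enrichment: tuple[float, float] | None
    out_dir: str


def _require(path: str, stage: str, what: str) -> str:
    if not path:
        raise PipelineError(stage, f"no {what} provided")
    if not os.path.exists(path):
        raise PipelineError(stage, f"{what} not found: {path}")
    return path


def calls_to_frame(calls: list[AsbCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        snp = c.site.snp
        rows.append({
            "snp_id": snp.id, "chrom": snp.chrom, "pos": snp.vcf_pos,
            "ref": snp.ref_base, "alt": snp.alt_base,
            "motif_id": c.disruption.motif_id, "strand": c.disruption.strand,
            "motif_start": c.disruption.match_start,
            "motif_end": c.disruption.match_end,
            "beta0": c.fit.beta0, "beta_r": c.fit.beta_r,
            "beta_a": c.fit.beta_a, "beta_int": c.fit.beta_int,
            "se_int": c.fit.se_int, "dispersion": c.fit.dispersion,
            "pvalue": c.fit.pvalue, "qvalue": c.fit.qvalue,
            "pssm_ref": c.disruption.pssm_ref, "pssm_alt": c.disruption.pssm_alt,
            "delta_pssm": c.disruption.delta,
            "A_ref": c.a_ref, "A_alt": c.a_alt,
            "C_ref": c.c_ref, "C_alt": c.c_alt,
            "verdict": c.verdict, "reasons": ",".join(c.reasons),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the six-stage workflow and write all per-stage outputs."""
    os.makedirs(config.out_dir, exist_ok=True)
    funnel: dict[str, int] = {}

    # Stage 1-2: peaks, cut-site totals, first-round filters
    reads = _require(config.reads, "cutsites", "read alignments")
    peaks = load_peaks(_require(config.peaks, "cutsites", "peak file"))
    count_cuts_in_peaks(reads, peaks)
    peaks = filter_peaks(peaks, min_cuts=config.min_cuts)
    funnel["open_chromatin_regions"] = len(peaks)
    if not peaks:
        raise PipelineError("cutsites", "no peaks pass the cut-site filter")

    snps, vstats = load_het_snps(
        _require(config.variants, "cutsites", "variant file"), peaks,
        min_dp=config.min_dp, min_mq=config.min_mq)
    funnel["het_snps"] = len(snps)
    logger.info("variant filter: %s", vstats)

    # Stage 3: motif scan on both haplotypes around each het SNP
    genome = Fasta(_require(config.genome, "motifscan", "genome FASTA"))
    pssms = {p.motif_id: p
             for p in load_motifs(_require(config.motifs, "motifscan",
                                           "motif file"),
                                  pseudocount=config.pseudocount)}
    thresholds = {mid: p.score_threshold(config.motif_pvalue)
                  for mid, p in pssms.items()}
    n_matches = 0
    candidates = []
    layouts: list[SiteLayout] = []
    max_len = max(len(p) for p in pssms.values())
    for snp in snps:
        contig = genome[snp.chrom]
        lo = max(snp.pos - max_len + 1, 0)
        hi = min(snp.pos + max_len, len(contig))
        ref_seq = str(contig[lo:hi]).upper()
        if ref_seq[snp.pos - lo] != snp.ref_base:
            logger.warning("reference base mismatch at %s:%d; SNP skipped",
                           snp.chrom, snp.vcf_pos)
            continue
        alt_seq = (ref_seq[:snp.pos - lo] + snp.alt_base
                   + ref_seq[snp.pos - lo + 1:])
        for mid, pssm in pssms.items():
            matches = scan_sequences(pssm, ref_seq, alt_seq, thresholds[mid],
                                     chrom=snp.chrom, region_start=lo)
            n_matches += len(matches)
            for dis in call_candidate_sites(matches, [snp], pssms, ref_seq,
                                            region_start=lo):
                try:
                    layout = SiteLayout.around_motif(
                        snp.chrom, dis.match_start, dis.match_end, snp,
                        shoulder=config.shoulder, flank=config.flank)
                except ValueError as exc:
                    logger.warning("layout rejected at %s:%d: %s", snp.chrom,
                                   snp.vcf_pos, exc)
                    continue
                candidates.append(dis)
                layouts.append(layout)
    funnel["potential_tf_binding_sites"] = n_matches
    funnel["candidate_asb_sites"] = len(candidates)

    # Stage 4: per-site counts and GLM fits
    site_cuts = collect_site_cuts(reads, layouts,
                                  min_base_quality=config.min_base_quality)
    calls: list[AsbCall] = []
    counts_rows = []
    for dis, layout, cuts in zip(candidates, layouts, site_cuts):
        table = count_cuts_by_region(cuts, layout)
        for (allele, region, rep), y in sorted(table.counts.items()):
            counts_rows.append({"snp_id": layout.snp.id,
                                "motif_id": dis.motif_id,
                                "motif_start": dis.match_start,
                                "replicate": rep, "allele": allele.value,
                                "region": region.value, "count": y})
        try:
            fit = fit_nb_glm(build_design(table))
        except ValueError as exc:
            raise PipelineError("asbmodel", str(exc))
        calls.append(AsbCall.from_table(layout, dis, fit, table))
    pd.DataFrame(counts_rows).to_csv(
        os.path.join(config.out_dir, "site_counts.tsv"), sep="\t", index=False)

    fitted = [c for c in calls if c.fit.converged and np.isfinite(c.fit.pvalue)]
    if fitted:
        qs = adjust_fdr([c.fit.pvalue for c in fitted])
        for c, q in zip(fitted, qs):
            c.fit.qvalue = float(q)
    funnel["significant_asb_sites"] = sum(
        1 for c in fitted if c.fit.qvalue < config.fdr_max)

    # Stage 5: empirical filters
    retained = empirical_filter(calls, fdr_max=config.fdr_max,
                                min_abs_delta=config.min_abs_delta,
                                min_abs_log2_magnitude=config.min_abs_log2_magnitude)
    funnel["filtered_asb_sites"] = len(retained)
    per_snp = summarize_snps(calls)
    funnel["regulatory_snps"] = len(per_snp)

    asb_table = calls_to_frame(calls)
    asb_table.to_csv(os.path.join(config.out_dir, "asb_calls.tsv"),
                     sep="\t", index=False)

    # Stage 6: target genes, eQTL overlap, enrichment
    annotation = None
    enrichment = None
    if config.tss:
        tss = load_tss_table(config.tss)
        inters = load_interactions(config.interactions) if config.interactions else []
        eqtls = load_eqtls(config.eqtls) if config.eqtls else []
        reg_ids = set(per_snp)
        regulatory = [s for s in snps if s.id in reg_ids]
        annotation = annotate_snps(regulatory, tss, inters, eqtls,
                                   window=config.tss_window)
        if eqtls and regulatory and len(regulatory) < len(snps):
            from .annotate import overlap_eqtl
            other = [s for s in snps if s.id not in reg_ids]
            flags_other = overlap_eqtl(other, eqtls)
            reg_hit = int(annotation["eqtl"].sum())
            oth_hit = sum(flags_other.values())
            table = [[reg_hit, len(regulatory) - reg_hit],
                     [oth_hit, len(other) - oth_hit]]
            try:
                enrichment = enrichment_test(table)
            except ValueError as exc:
                logger.info("enrichment test skipped: %s", exc)
        annotation.to_csv(os.path.join(config.out_dir, "annotation.tsv"),
                          sep="\t", index=False)

    # ASE of target genes
    ase_snps = ase_genes = None
    if config.ase_counts:
        counts = load_allelic_counts(config.ase_counts)
        ase_snps, ase_genes = call_ase_genes(counts, alpha=config.alpha_ase)
        if annotation is not None and not ase_genes.empty \
                and not annotation.empty:
            targets = set()
            for t in annotation["target_genes"]:
                targets.update(g for g in str(t).split(",") if g)
            ase_genes["is_target"] = ase_genes["gene"].isin(targets)
        ase_snps.to_csv(os.path.join(config.out_dir, "ase_snps.tsv"),
                        sep="\t", index=False)
        ase_genes.to_csv(os.path.join(config.out_dir, "ase_genes.tsv"),
                         sep="\t", index=False)

    pd.DataFrame([funnel], columns=FUNNEL_COLUMNS).to_csv(
        os.path.join(config.out_dir, "summary.tsv"), sep="\t", index=False)
    manifest = {
        "package": "asbfoot", "version": __version__,
        "config": {f.name: getattr(config, f.name)
                   for f in dataclasses.fields(config)},
        "funnel": funnel,
    }
    if enrichment is not None:
        manifest["eqtl_enrichment"] = {"chi2": enrichment[0],
                                       "pvalue": enrichment[1]}
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(funnel=funnel, calls=calls, asb_table=asb_table,
                          annotation=annotation, ase_snps=ase_snps,
                          ase_genes=ase_genes, enrichment=enrichment,
                          out_dir=config.out_dir)
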