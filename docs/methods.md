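# Methods

## Signal and model

A TF bound over its motif shields the DNA from Tn5 insertion, so in ATAC-seq
a bound site shows locally depleted cut sites (a footprint) relative to the
accessible flanks. At a heterozygous SNP inside the motif the two alleles of
a diploid sample are an internal contrast: if the factor binds one allele
better, the flanks-to-footprint cut-site ratio differs between alleles,
while library-level confounders (Tn5 sequence preference, the TF's intrinsic
footprint shape, copy-number imbalance between alleles) affect both bands
of the same allele or both alleles equally and largely cancel.

Each candidate site is the span of a motif match containing a het SNP.
Bands around it: footprint *a* = the match span; shoulders *b* = `shoulder`
bp on each side, excluded from the model (they absorb uncertainty about the
true protected width); flanks *c* = `flank` bp beyond the shoulders. Cut
sites are the shifted 5' alignment ends (+4 forward / −5 reverse); a read is
assigned to an allele by its base at the SNP (base quality ≥
`min_base_quality`, third alleles and non-covering reads stay unassigned and
are excluded from the model but tallied for conservation checks).

Counts y per (region, allele, replicate) cell are modelled as NB2 with log
link:

    log E(y) = b0 + br*x_r + ba*x_a + bint*x_r*x_a,

x_r = 0 footprint / 1 flank, x_a = 0 reference / 1 alternative.
`bint` is the allelic change of the flanks/footprint ratio (log scale);
bint > 0 = gain of binding on the variant allele. Technical replicates enter
as independent observations (4 rows per replicate). No library-size offset
is applied by default: both alleles of a site come from the same library, so
depth cancels inside the contrast (an offset hook exists for merged
multi-library designs).

## Estimation and testing

Per site: a Poisson GLM supplies fitted means; the NB2 dispersion alpha is
the Pearson moment estimate solving sum((y-mu)^2/(mu+alpha*mu^2)) = n − p
(0 when the data are under-dispersed); the GLM is refit at that alpha. The
Wald statistic bint/se is referred to a t distribution with n − p residual
degrees of freedom. With 3 replicates this test holds its size at the 5%
level in the package's own calibration simulations, whereas a normal
reference (with any per-site dispersion estimator, including joint maximum
likelihood) is visibly anticonservative at 12 observations; the t reference
is the same small-sample convention R applies to quasi-likelihood count
models. A likelihood-ratio variant (same alpha, F(1, n−p) reference) is
available behind a flag. With one replicate the model is saturated: fitted
means equal the observed cells, bint equals the log cross-ratio of the four
counts, dispersion is not identifiable, and the p-value is exploratory
(normal reference).

Degenerate inputs: a site whose REF or ALT allele has zero phased coverage,
or any (allele, region) cell at zero across all replicates, is excluded with
a reason code rather than fitted to an infinite coefficient. Benjamini–
Hochberg q-values are computed over all sites that reached a converged fit
within one dataset.

## Motif scoring

Count matrices (JASPAR pfm or MEME minimal) become log2 log-odds PSSMs with
a per-base pseudocount (default 0.8) against a background (default uniform,
overridable by regional composition). Both haplotypes of the region around
each SNP are scanned on both strands; the match threshold is the smallest
score whose exceedance probability under the background model is ≤
`motif_pvalue` (default 1e-4), computed by exact convolution of the
discretised per-column score distributions — FIMO-like semantics without its
q-value machinery. When both strands match the same window the higher score
wins (tie → forward) so one physical site is not counted twice. A match on
either haplotype yields a candidate; both haplotype windows are then scored
at the same coordinates and delta = PSSM(ref) − PSSM(alt). Windows with
non-ACGT bases are unscorable and drop the candidate with a logged reason.
Haplotype construction substitutes only the focal SNP; neighbouring het SNPs
inside one window are ignored (a known simplification).

## Second-round filters

Retained calls need q < `fdr_max` (0.05), |delta| > `min_abs_delta` (5),
sign consistency bint*delta < 0 (a footprint gain on ALT must pair with ALT
scoring higher), and an allelic cross-ratio magnitude
|log2((A_ref+1)/(A_alt+1) / ((C_ref+1)/(C_alt+1)))| ≥
`min_abs_log2_magnitude`. The magnitude gate quantifies an otherwise
qualitative "high magnitude difference" requirement; 1.0 (a two-fold allelic
change of the footprint contrast) is the default and the gate can be
disabled by setting it to 0. All verdicts carry reason codes so users can
audit each gate separately.

## Annotation and ASE

Promoter SNPs are those within 1 kb (inclusive) of any TSS, strand ignored;
the closest gene is the target, ties broken by distance then gene id for
determinism. Other SNPs take as targets the union of genes resident in the
paired anchor of every chromatin-interaction record overlapping them. eQTL
overlap is an exact rsID match with a chrom+pos fallback; enrichment of
regulatory vs non-regulatory candidate SNPs among eQTLs is a Pearson
chi-square (df = 1, Yates optional). ASE uses the exact two-sided binomial
test (minimum-likelihood ordering) of allelic counts against p = 0.5; a gene
is ASE-positive when any of its coding het SNPs rejects at `alpha_ase`
(default 0.05, per-test; an optional BH mode exists but is off by default,
matching the plain-threshold convention for this analysis). Counts are
summed across replicate libraries before testing by default.

## Synthetic data

The generator draws cell counts from exactly the model family above, so
parameter recovery is a meaningful validation surface. Defaults: flank cell
mean 50 per replicate per allele, dispersion 0.1, 3 replicates,
footprint/flank depletion ratio 2.0 (published footprinting work shows
roughly 40–70% depletion of insertions over bound motifs; 2.0 is the
mid-range), interaction effect 1.5 at allele-specific sites with
ba = −bint so flank coverage stays allele-balanced (a binding change, not a
copy-number change). One high-information motif (consensus count 997/1000
per column) is planted per site with the SNP at a random interior motif
column; at gain-on-ALT sites the ALT base is the consensus so the disruption
sign matches the binding change. Read-level mode materialises every drawn
count as one SAM alignment whose shifted cut site reproduces the draw
exactly and which always covers its SNP (forward reads for cuts left of the
SNP, reverse for cuts right of it), so extraction is an identity and
byte-level determinism holds for every emitted file under a fixed seed.

What the generator does *not* emulate: Tn5 sequence bias (the method is
insensitive to it by construction, so simulating it would not exercise
anything), mapping/reference bias toward the REF allele, overlapping
peaks, indels, multi-SNP motif windows, and CNV/LOH. Passing tests therefore
demonstrate correctness of the statistics and the plumbing under the model's
own assumptions, not robustness to those artefacts.

## Problem sizes and numerical choices

Calibration and recovery checks run at 2,000 null sites and 500 sites per
effect level; the end-to-end known-answer run uses 100 sites at 30%
allele-specific fraction — sizes at which the Monte-Carlo error of the
checked rates is a few parts in a thousand while a full run stays in the
tens of seconds. PSSM score convolution uses a 1e-3 score grid. The BH
step is statsmodels' `multipletests`; the exact binomial test is scipy's
`binomtest`; the chi-square is scipy's `chi2_contingency` without continuity
correction by default.

## Known limitations

Detection power at the default conditions is materially below 1 for
moderate effects: with dispersion 0.1 and 3 replicates the standard error
of bint cannot fall below sqrt(4·alpha/R) ≈ 0.37 regardless of coverage, so
an effect of 1.5 sits near z ≈ 3 and BH-adjusted recall at realistic
coverage is roughly 40%, with essentially no false calls. Calls at
homozygous loci are impossible by design; TFs with very short residence
times leave no footprint to test; and motif-free TFs are invisible. The
per-site dispersion estimate is noisy at 12 observations — sharing
dispersion across sites would raise power but is deliberately out of scope.
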