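"""Negative-binomial GLM test for allele-specific footprints.

For one candidate site the cut-site count y in each (region, allele,
replicate) cell is modelled as

    log E(y) = b0 + br*x_r + ba*x_a + bint*x_r*x_a

with x_r = 0 for the footprint band and 1 for the flanks, x_a = 0 for the
reference allele and 1 for the alternative allele, and NB-distributed y to
absorb overdispersion.  The interaction coefficient bint compares the
flanks-to-footprint ratio between alleles; H0: bint = 0.  A positive bint is
a gain of binding on the variant allele, a negative bint a loss.  P-values
are two-sided Wald tests; FDR is Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .cutsites import Allele, CountTable, Region, SiteLayout
from .motifscan import MotifDisruption

MIN_DISPERSION = 1e-8


@dataclass(frozen=True)
class DesignRow:
    """One observation cell: count with its region/allele coding."""

    y: int
    x_r: int  # 0 = binding site (footprint), 1 = flanking region
    x_a: int  # 0 = reference allele, 1 = alternative allele
    replicate: int

    def __post_init__(self) -> None:
        if self.x_r not in (0, 1) or self.x_a not in (0, 1):
            raise ValueError("x_r and x_a are binary")
        if self.y < 0:
            raise ValueError("counts are non-negative")


@dataclass
class GlmFit:
    beta0: float = np.nan
    beta_r: float = np.nan
    beta_a: float = np.nan
    beta_int: float = np.nan
    se_int: float = np.nan
    dispersion: float = np.nan
    pvalue: float = np.nan
    qvalue: float = np.nan
    converged: bool = False
    reason: str = ""
    df_resid: int = 0


@dataclass
class AsbCall:
    """A candidate site with its fit, disruption score and filter verdict."""

    site: SiteLayout
    disruption: MotifDisruption
    fit: GlmFit
    a_ref: int
    a_alt: int
    c_ref: int
    c_alt: int
    verdict: str = "pending"
    reasons: list = field(default_factory=list)

    @property
    def magnitude(self) -> float:
        """|log2 allelic cross-ratio| input, with pseudocount 1 per sum."""
        return float(np.log2(((self.a_ref + 1) / (self.a_alt + 1))
                             / ((self.c_ref + 1) / (self.c_alt + 1))))

    @classmethod
    def from_table(cls, site: SiteLayout, disruption: MotifDisruption,
                   fit: GlmFit, table: CountTable) -> "AsbCall":
        return cls(site=site, disruption=disruption, fit=fit,
                   a_ref=table.a_ref, a_alt=table.a_alt,
                   c_ref=table.c_ref, c_alt=table.c_alt)


def build_design(table: CountTable) -> list[DesignRow]:
    """Expand a CountTable into the 4*R design rows of the GLM."""
    if not table.replicates:
        raise ValueError("incomplete design: no replicates")
    rows = []
    for rep in table.replicates:
        for allele, x_a in ((Allele.REF, 0), (Allele.ALT, 1)):
            for region, x_r in ((Region.FOOTPRINT, 0), (Region.FLANK, 1)):
                key = (allele, region, rep)
                if key not in table.counts:
                    raise ValueError(f"incomplete design: missing cell {key}")
                rows.append(DesignRow(y=table.counts[key], x_r=x_r, x_a=x_a,
                                      replicate=rep))
    return rows


def _design_arrays(design: Sequence[DesignRow]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([r.y for r in design], dtype=float)
    X = np.column_stack([
        np.ones(len(design)),
        [r.x_r for r in design],
        [r.x_a for r in design],
        [r.x_r * r.x_a for r in design],
    ])
    return y, X


def _separation_reason(design: Sequence[DesignRow]) -> str | None:
    """Detect cells whose fitted log-mean would be -inf (complete separation)."""
    y = np.array([r.y for r in design])
    xa = np.array([r.x_a for r in design])
    xr = np.array([r.x_r for r in design])
    for a in (0, 1):
        if y[xa == a].sum() == 0:
            return "no phased coverage"
        for r in (0, 1):
            if y[(xa == a) & (xr == r)].sum() == 0:
                return "complete separation"
    return None


def moment_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int = 4) -> float:
    """Pearson moment estimator of the NB2 dispersion alpha.

    Solves sum((y - mu)^2 / (mu + alpha*mu^2)) = n - p on the Poisson fitted
    means (Breslow's estimating equation); returns 0 when the data are at or
    below Poisson variation.
    """
    df = len(y) - n_params
    if df <= 0:
        return 0.0

    def pearson_excess(alpha: float) -> float:
        return float(((y - mu) ** 2 / (mu + alpha * mu * mu)).sum()) - df

    if pearson_excess(0.0) <= 0.0:
        return 0.0
    hi = 1.0
    while pearson_excess(hi) > 0.0 and hi < 1e6:
        hi *= 10.0
    if hi >= 1e6:
        return 1e6
    return float(optimize.brentq(pearson_excess, 0.0, hi))


def _glm_at_alpha(y: np.ndarray, X: np.ndarray, alpha: float):
    fam = sm.families.Poisson() if alpha <= MIN_DISPERSION \
        else sm.families.NegativeBinomial(alpha=alpha)
    return sm.GLM(y, X, family=fam).fit()


def fit_nb_glm(design: Sequence[DesignRow]) -> GlmFit:
    """Fit the footprint-interaction NB GLM for one candidate site.

    A Poisson fit supplies the means for the Pearson moment dispersion
    estimate; the GLM is then refit under NB2 at that dispersion.  Estimated
    dispersion at or below ``MIN_DISPERSION`` collapses to the Poisson
    limit.  With a single replicate the model is saturated, the dispersion
    is not identifiable (taken as 0), and fitted means equal the observed
    cells.  Sites with an allele (or a design cell) at zero total are
    excluded rather than given an infinite coefficient.
    """
    if len(design) < 4:
        return GlmFit(converged=False, reason="fewer than 4 design rows")
    reason = _separation_reason(design)
    if reason is not None:
        return GlmFit(converged=False, reason=reason)
    y, X = _design_arrays(design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            alpha = moment_dispersion(y, pois.mu)
            res = pois if alpha <= MIN_DISPERSION else _glm_at_alpha(y, X, alpha)
        except Exception:
            return GlmFit(converged=False, reason="non-convergence")
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if not (np.isfinite(params).all() and np.isfinite(bse).all()):
        return GlmFit(converged=False, reason="non-convergence")
    fit = GlmFit(beta0=params[0], beta_r=params[1], beta_a=params[2],
                 beta_int=params[3], se_int=float(bse[3]),
                 dispersion=max(alpha, 0.0), converged=True)
    fit.df_resid = len(y) - 4
    fit.pvalue = test_interaction(fit)
    return fit


def test_interaction(fit: GlmFit) -> float:
    """Two-sided Wald p-value for H0: beta_int = 0.

    The statistic beta_int/se_int is referred to a t distribution with the
    model's residual degrees of freedom (the small-sample convention for
    estimated-dispersion count GLMs); with no residual degrees of freedom
    (saturated single-replicate fits) the normal reference is the only
    option left and the p-value is exploratory.
    """
    if not fit.converged:
        raise ValueError("cannot test a non-converged fit")
    if not np.isfinite(fit.se_int) or fit.se_int <= 0:
        return np.nan
    z = abs(fit.beta_int / fit.se_int)
    df = getattr(fit, "df_resid", 0)
    if df and df > 0:
        return float(2.0 * stats.t.sf(z, df=df))
    return float(2.0 * stats.norm.sf(z))


def lr_test_interaction(design: Sequence[DesignRow]) -> float:
    """Likelihood-ratio alternative to the Wald test.

    Dispersion is held at the full-model moment estimate; the statistic is
    referred to F(1, n-p) for the same small-sample reason the Wald test
    uses t.
    """
    y, X = _design_arrays(design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        alpha = moment_dispersion(y, pois.mu)
        full = _glm_at_alpha(y, X, alpha)
        null = _glm_at_alpha(y, X[:, :3], alpha)
    lr = max(2.0 * (full.llf - null.llf), 0.0)
    df = len(y) - 4
    if df > 0:
        return float(stats.f.sf(lr, 1, df))
    return float(stats.chi2.sf(lr, df=1))


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def empirical_filter(calls: Sequence[AsbCall], fdr_max: float = 0.05,
                     min_abs_delta: float = 5.0,
                     min_abs_log2_magnitude: float = 1.0) -> list[AsbCall]:
    """Second-round filters: FDR, motif-disruption size, sign consistency,
    and allelic cross-ratio magnitude.

    Sign consistency requires beta_int * delta < 0: a gain of binding on the
    variant allele (beta_int > 0) must pair with the variant scoring higher
    on the motif (delta = PSSM(ref) - PSSM(alt) < 0), and vice versa.
    Verdicts and reason codes are written onto every call; the retained
    subset is returned.
    """
    retained = []
    for call in calls:
        reasons = []
        if not call.fit.converged or not np.isfinite(call.fit.qvalue):
            reasons.append("no_fit")
        elif call.fit.qvalue >= fdr_max:
            reasons.append("fdr")
        if abs(call.disruption.delta) <= min_abs_delta:
            reasons.append("delta")
        if not (call.fit.beta_int * call.disruption.delta < 0):
            reasons.append("inconsistent")
        if abs(call.magnitude) < min_abs_log2_magnitude:
            reasons.append("magnitude")
        call.reasons = reasons
        if reasons:
            call.verdict = "filtered_out"
        else:
            call.verdict = "significant"
            retained.append(call)
    return retained


def summarize_snps(calls: Sequence[AsbCall]) -> dict[str, dict]:
    """Group retained calls by SNP; distinct disrupted motifs per SNP."""
    report: dict[str, dict] = {}
    for call in calls:
        if call.verdict != "significant":
            continue
        snp = call.site.snp
        key = snp.id if snp.id not in (".", "", None) else \
            f"{snp.chrom}:{snp.vcf_pos}:{snp.ref_base}>{snp.alt_base}"
        entry = report.setdefault(key, {"snp": snp, "motifs": set(), "calls": []})
        entry["motifs"].add(call.disruption.motif_id)
        entry["calls"].append(call)
    for entry in report.values():
        entry["n_motifs"] = len(entry["motifs"])
    return report
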