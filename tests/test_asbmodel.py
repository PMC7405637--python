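"""NB-GLM interaction test, FDR adjustment, and the empirical filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asbfoot.asbmodel import (AsbCall, GlmFit, adjust_fdr, build_design,
                              empirical_filter, fit_nb_glm,
                              lr_test_interaction)
from asbfoot.asbmodel import test_interaction as wald_interaction_p
from asbfoot.cutsites import Allele, CountTable, HetSNP, Region, SiteLayout
from asbfoot.motifscan import MotifDisruption
from asbfoot.simulate import SimConfig, simulate_site


def make_table(a_ref, c_ref, a_alt, c_alt, replicates=(1,)):
    """CountTable with the same four cell values in every replicate."""
    t = CountTable(replicates=tuple(replicates))
    for rep in replicates:
        t.counts[(Allele.REF, Region.FOOTPRINT, rep)] = a_ref
        t.counts[(Allele.REF, Region.FLANK, rep)] = c_ref
        t.counts[(Allele.ALT, Region.FOOTPRINT, rep)] = a_alt
        t.counts[(Allele.ALT, Region.FLANK, rep)] = c_alt
    return t


def cross_ratio_beta_int(a_ref, c_ref, a_alt, c_alt):
    return np.log((c_alt / a_alt) / (c_ref / a_ref))


def test_build_design_coding_and_shape():
    t = make_table(1, 2, 3, 4, replicates=(1, 2, 3))
    rows = build_design(t)
    assert len(rows) == 12
    alt_flank = [r for r in rows if r.x_r == 1 and r.x_a == 1]
    assert {r.y for r in alt_flank} == {4}
    # structurally missing cell -> error
    del t.counts[(Allele.REF, Region.FLANK, 2)]
    with pytest.raises(ValueError, match="incomplete design"):
        build_design(t)


def test_saturated_fit_matches_cross_ratio_closed_form():
    t = make_table(20, 80, 40, 80)
    fit = fit_nb_glm(build_design(t))
    assert fit.converged
    assert fit.beta_int == pytest.approx(np.log((80 / 40) / (80 / 20)), abs=1e-6)
    assert fit.beta_int == pytest.approx(-0.6931, abs=1e-4)
    assert fit.beta0 == pytest.approx(np.log(20), abs=1e-6)


def test_saturated_fit_random_tables_equal_observed_cells(rng):
    """Single-replicate fits are saturated: means == counts, beta_int ==
    ln cross-ratio (20 random tables, all cells >= 5)."""
    for _ in range(20):
        a_ref, c_ref, a_alt, c_alt = rng.integers(5, 200, size=4)
        fit = fit_nb_glm(build_design(make_table(a_ref, c_ref, a_alt, c_alt)))
        assert fit.converged
        expected = cross_ratio_beta_int(a_ref, c_ref, a_alt, c_alt)
        assert fit.beta_int == pytest.approx(expected, abs=1e-6)


def test_symmetric_counts_give_zero_betas():
    fit = fit_nb_glm(build_design(make_table(50, 50, 50, 50)))
    assert fit.beta_int == pytest.approx(0.0, abs=1e-8)
    assert fit.beta_r == pytest.approx(0.0, abs=1e-8)
    assert fit.beta_a == pytest.approx(0.0, abs=1e-8)
    assert fit.beta0 == pytest.approx(np.log(50), abs=1e-8)


def test_zero_allele_or_cell_is_excluded_not_fitted():
    no_alt = make_table(10, 20, 0, 0)
    fit = fit_nb_glm(build_design(no_alt))
    assert not fit.converged and fit.reason == "no phased coverage"
    zero_cell = make_table(10, 20, 0, 15)
    fit = fit_nb_glm(build_design(zero_cell))
    assert not fit.converged and fit.reason == "complete separation"


def test_poisson_limit_of_nb_fit(rng):
    """At (near-)Poisson data the NB path collapses to the Poisson GLM."""
    cfg = SimConfig(cell_mean=40.0, dispersion=0.0, replicates=3,
                    beta_int_effect=0.8, footprint_depth=1.0)
    t, _ = simulate_site(cfg, True, rng)
    fit = fit_nb_glm(build_design(t))
    assert fit.converged
    import statsmodels.api as sm
    from asbfoot.asbmodel import _design_arrays
    y, X = _design_arrays(build_design(t))
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    if fit.dispersion == 0.0:
        assert fit.beta_int == pytest.approx(pois.params[3], abs=1e-10)
    else:  # tiny estimated dispersion: coefficients still at Poisson limit
        assert fit.beta_int == pytest.approx(pois.params[3], abs=1e-3)


def test_wald_p_properties():
    fit = GlmFit(beta_int=0.0, se_int=0.5, converged=True, df_resid=8)
    assert wald_interaction_p(fit) == pytest.approx(1.0)
    ps = [wald_interaction_p(GlmFit(beta_int=b, se_int=0.5, converged=True,
                                  df_resid=8)) for b in (0.1, 0.5, 1.0, 2.0)]
    assert all(a > b for a, b in zip(ps, ps[1:]))  # monotone in |beta_int|
    bad = GlmFit(beta_int=1.0, se_int=0.0, converged=True, df_resid=8)
    assert np.isnan(wald_interaction_p(bad))
    with pytest.raises(ValueError):
        wald_interaction_p(GlmFit(converged=False))


def test_lr_test_agrees_in_direction(rng):
    cfg = SimConfig(cell_mean=50.0, dispersion=0.05, replicates=3,
                    beta_int_effect=1.5, footprint_depth=1.0)
    strong, _ = simulate_site(cfg, True, rng)
    null, _ = simulate_site(cfg, False, rng)
    p_strong = lr_test_interaction(build_design(strong))
    p_null = lr_test_interaction(build_design(null))
    assert p_strong < p_null


def brute_force_bh(pvals):
    """Independent step-up implementation used as the oracle."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        q[i] = val
        prev = val
    return q


def test_bh_printed_example_and_edges():
    assert np.allclose(adjust_fdr([0.01, 0.02, 0.03, 0.04]),
                       [0.04, 0.04, 0.04, 0.04])
    assert np.allclose(adjust_fdr([0.2]), [0.2])
    assert np.allclose(adjust_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
    assert adjust_fdr([]).size == 0
    with pytest.raises(ValueError):
        adjust_fdr([0.5, 1.5])


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=50))
def test_bh_matches_brute_force(pvals):
    assert np.allclose(adjust_fdr(pvals), brute_force_bh(pvals), atol=1e-12)


def _call(q, delta, beta_int, a=(100, 20, 100, 100), name="x"):
    snp = HetSNP("chr1", 505, "A", "G", id=name)
    lay = SiteLayout.around_motif("chr1", 500, 512, snp)
    dis = MotifDisruption(snp=snp, motif_id="m", pssm_ref=delta, pssm_alt=0.0)
    fit = GlmFit(beta_int=beta_int, se_int=0.3, qvalue=q, pvalue=q / 2,
                 converged=True, df_resid=8)
    a_ref, a_alt, c_ref, c_alt = a
    return AsbCall(site=lay, disruption=dis, fit=fit, a_ref=a_ref,
                   a_alt=a_alt, c_ref=c_ref, c_alt=c_alt)


def test_empirical_filter_boundary_grid():
    """Six calls spanning every gate; exactly the all-pass row survives."""
    calls = [
        _call(0.049, -5.1, +0.9, name="pass"),
        _call(0.051, -5.1, +0.9, name="fail_q"),
        _call(0.049, -4.9, +0.9, name="fail_delta"),
        _call(0.049, +5.1, +0.9, name="fail_sign"),
        _call(0.049, -5.1, -0.9, name="fail_sign2"),
        _call(0.049, -5.1, +0.9, a=(50, 50, 50, 50), name="fail_mag"),
    ]
    kept = empirical_filter(calls, fdr_max=0.05, min_abs_delta=5.0,
                            min_abs_log2_magnitude=1.0)
    assert [c.site.snp.id for c in kept] == ["pass"]
    reasons = {c.site.snp.id: c.reasons for c in calls}
    assert reasons["fail_q"] == ["fdr"]
    assert reasons["fail_delta"] == ["delta"]
    assert reasons["fail_sign"] == ["inconsistent"]
    assert reasons["fail_sign2"] == ["inconsistent"]
    assert reasons["fail_mag"] == ["magnitude"]


@given(st.floats(min_value=0.0, max_value=0.1),
       st.floats(min_value=0.0, max_value=10.0),
       st.floats(min_value=0.0, max_value=2.0))
def test_filter_monotone_in_thresholds(fdr, delta_min, mag_min):
    calls = [_call(0.049, -5.1, +0.9), _call(0.01, -8.0, +1.5),
             _call(0.03, -6.0, +0.2, a=(60, 40, 50, 50))]
    base = {id(c) for c in empirical_filter(calls, 0.05, 5.0, 1.0)}
    tighter = {id(c) for c in empirical_filter(
        calls, min(fdr, 0.05), max(delta_min, 5.0), max(mag_min, 1.0))}
    assert tighter <= base


def test_summarize_snps_distinct_motifs():
    from asbfoot.asbmodel import summarize_snps
    c1 = _call(0.01, -6.0, 0.9, name="rsA")
    c2 = _call(0.01, -6.0, 0.9, name="rsA")
    c2.disruption = MotifDisruption(snp=c2.site.snp, motif_id="m2",
                                    pssm_ref=-6.0, pssm_alt=0.0)
    c3 = _call(0.01, -6.0, 0.9, name="rsA")  # same motif as c1, other offset
    for c in (c1, c2, c3):
        c.verdict = "significant"
    report = summarize_snps([c1, c2, c3])
    assert report["rsA"]["n_motifs"] == 2
    assert len(report["rsA"]["calls"]) == 3
    assert summarize_snps([]) == {}
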