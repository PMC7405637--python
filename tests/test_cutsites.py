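"""Cut-site shifting, allele assignment, filters, and region counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asbfoot.cutsites import (Allele, CutSite, HetSNP, Peak, Region,
                              SiteLayout, assign_allele, count_cuts_by_region,
                              filter_peaks, shift_cut_site)

SNP = HetSNP("chr1", 505, "A", "G", dp=30, mq=40.0, id="rs1")


@pytest.mark.parametrize("start,end,strand,expected", [
    (1000, 1050, "+", 1004),   # forward 5' end + 4
    (1950, 2001, "-", 1995),   # reverse 5' end (end-1) - 5
    (0, 36, "+", 4),
    (0, 3, "-", -3),           # contig edge: negative -> caller discards
])
def test_shift_cut_site(start, end, strand, expected):
    assert shift_cut_site(start, end, strand) == expected


def test_shift_rejects_bad_strand():
    with pytest.raises(ValueError):
        shift_cut_site(0, 10, ".")


@pytest.mark.parametrize("base,qual,expected", [
    ("A", 30, Allele.REF),
    ("G", 30, Allele.ALT),
    ("T", 30, Allele.UNASSIGNED),   # third allele
    ("A", 10, Allele.UNASSIGNED),   # below quality floor
    (None, 60, Allele.UNASSIGNED),  # read does not cover the SNP
])
def test_assign_allele(base, qual, expected):
    assert assign_allele(base, qual, SNP, min_base_quality=20) is expected


def test_filter_peaks_boundary_and_order():
    peaks = [Peak("chr1", 0, 100, cut_count=199, name="low"),
             Peak("chr1", 200, 300, cut_count=200, name="edge"),
             Peak("chr1", 400, 500, cut_count=5000, name="high")]
    kept = filter_peaks(peaks, min_cuts=200)
    assert [p.name for p in kept] == ["edge", "high"]
    assert filter_peaks([], min_cuts=200) == []


@given(st.lists(st.integers(min_value=0, max_value=400), max_size=30),
       st.integers(min_value=0, max_value=300))
def test_filter_peaks_monotone_in_threshold(counts, thresh):
    peaks = [Peak("chr1", i * 10, i * 10 + 5, cut_count=c)
             for i, c in enumerate(counts)]
    loose = filter_peaks(peaks, min_cuts=thresh)
    tight = filter_peaks(peaks, min_cuts=thresh + 50)
    assert set(id(p) for p in tight) <= set(id(p) for p in loose)


def test_vcf_coordinate_round_trip():
    snp = HetSNP.from_vcf_pos("chr1", 506, "A", "G")
    assert snp.pos == 505
    assert snp.vcf_pos == 506


def make_layout(snp=SNP, shoulder=10, flank=50):
    # motif span [500, 512) containing the SNP at 505
    return SiteLayout.around_motif("chr1", 500, 512, snp,
                                   shoulder=shoulder, flank=flank)


def test_layout_geometry():
    lay = make_layout()
    assert lay.footprint.start == 500 and lay.footprint.end == 512
    assert lay.shoulders[0].start == 490 and lay.shoulders[1].end == 522
    assert lay.window.start == 440 and lay.window.end == 572
    assert lay.region_of(505) is Region.FOOTPRINT
    assert lay.region_of(495) is Region.SHOULDER
    assert lay.region_of(450) is Region.FLANK
    assert lay.region_of(439) is None


def test_layout_rejects_snp_outside_footprint():
    with pytest.raises(ValueError):
        SiteLayout.around_motif("chr1", 600, 612, SNP)


def test_count_cuts_shoulder_and_unassigned_excluded():
    lay = make_layout()
    cuts = [
        CutSite("chr1", 505, "+", Allele.REF, 1),   # footprint
        CutSite("chr1", 450, "+", Allele.ALT, 1),   # flank left
        CutSite("chr1", 530, "-", Allele.REF, 1),   # flank right
        CutSite("chr1", 495, "+", Allele.REF, 1),   # shoulder -> excluded
        CutSite("chr1", 505, "+", Allele.UNASSIGNED, 1),
        CutSite("chr1", 10, "+", Allele.REF, 1),    # outside window
    ]
    table = count_cuts_by_region(cuts, lay, replicates=[1])
    assert table.y(Allele.REF, Region.FOOTPRINT, 1) == 1
    assert table.y(Allele.ALT, Region.FLANK, 1) == 1
    assert table.y(Allele.REF, Region.FLANK, 1) == 1
    assert table.shoulder_tally == 1
    assert table.unassigned_tally == 1
    assert table.total() == 5  # everything inside the window


@settings(deadline=None)
@given(st.lists(st.tuples(st.integers(min_value=440, max_value=571),
                          st.sampled_from(list(Allele)),
                          st.integers(min_value=1, max_value=3)),
                max_size=60))
def test_count_conservation(random_cuts):
    """Sum of model cells + excluded tallies == cuts inside the window."""
    lay = make_layout()
    cuts = [CutSite("chr1", pos, "+", allele, rep)
            for pos, allele, rep in random_cuts]
    table = count_cuts_by_region(cuts, lay, replicates=[1, 2, 3])
    assert table.total() == len(cuts)
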