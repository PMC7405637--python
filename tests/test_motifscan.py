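"""PSSM construction, window scoring, double-strand scanning, disruption."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asbfoot.cutsites import HetSNP
from asbfoot.motifscan import (Pssm, call_candidate_sites, delta_pssm,
                               pssm_from_counts, reverse_complement,
                               scan_one_haplotype, scan_sequences,
                               score_window)

BASES = "ACGT"


def naive_scan(pssm, seq, threshold):
    """Independent per-window loop: best strand per window, ties to '+'."""
    L = len(pssm)
    out = []
    for off in range(len(seq) - L + 1):
        win = seq[off:off + L]
        fwd = score_window(pssm, win)
        rev = score_window(pssm, reverse_complement(win))
        cand = [(s, sc) for s, sc in (("+", fwd), ("-", rev))
                if sc is not None and sc >= threshold]
        if not cand:
            continue
        strand, score = max(cand, key=lambda t: (t[1], t[0] == "+"))
        out.append((off, off + L, strand, round(score, 9)))
    return out


def test_pssm_entries_hand_arithmetic():
    counts = np.zeros((4, 1))
    counts[0, 0] = 10  # column (10, 0, 0, 0)
    p = pssm_from_counts(counts, pseudocount=1.0)
    assert p.matrix[0, 0] == pytest.approx(np.log2((11 / 14) / 0.25), abs=1e-9)
    assert p.matrix[1, 0] == pytest.approx(np.log2((1 / 14) / 0.25), abs=1e-9)


def test_pssm_uniform_counts_score_zero():
    p = pssm_from_counts(np.full((4, 5), 3.0), pseudocount=1.0)
    assert np.allclose(p.matrix, 0.0)
    assert p.matrix.shape == (4, 5)


def test_pssm_degenerate_column_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        pssm_from_counts(np.zeros((4, 2)), pseudocount=0.0)


def _hand_pssm(cols):
    """Pssm with explicit per-base column entries (no count conversion)."""
    m = np.array(cols, dtype=float).T
    return Pssm(motif_id="hand", matrix=m, background=np.full(4, 0.25),
                pseudocount=0.0)


def test_score_window_manual_sum_and_policies():
    # per column: A=+1, C=-1, G/T=0
    p = _hand_pssm([[1.0, -1.0, 0.0, 0.0]] * 2)
    assert score_window(p, "AC") == pytest.approx(0.0)
    assert score_window(p, "AA") == pytest.approx(2.0)
    assert score_window(p, "AN") is None
    with pytest.raises(ValueError):
        score_window(p, "AAA")


def test_scan_threshold_minus_inf_is_exhaustive():
    p = _hand_pssm([[1.0, -1.0, 0.0, 0.0]] * 3)
    seq = "ACGTACGTAC"
    matches = scan_one_haplotype(p, seq, -np.inf, "chr1", 0, "REF")
    assert len(matches) == len(seq) - 3 + 1


def test_scan_finds_planted_motif_only():
    rng = np.random.default_rng(0)
    motif = "GAA"
    cols = []
    for base in motif:
        col = [-4.0] * 4
        col[BASES.index(base)] = 2.0
        cols.append(col)
    p = _hand_pssm(cols)
    seq = "CCCCCCGAACCCCCCCCCC"  # planted at offset 6
    matches = scan_one_haplotype(p, seq, 5.0, "chr1", 0, "REF")
    assert [(m.start, m.strand) for m in matches] == [(6, "+")]


def test_strand_symmetry_of_best_score():
    rng = np.random.default_rng(3)
    p = pssm_from_counts(rng.integers(0, 20, size=(4, 5)), pseudocount=1.0)
    seq = "".join(rng.choice(list(BASES), size=30))
    rc = reverse_complement(seq)
    best = max(m.score for m in scan_one_haplotype(p, seq, -np.inf, ".", 0, "REF"))
    best_rc = max(m.score for m in scan_one_haplotype(p, rc, -np.inf, ".", 0, "REF"))
    assert best == pytest.approx(best_rc)


@settings(deadline=None, max_examples=50)
@given(st.integers(min_value=0, max_value=10_000))
def test_scanner_matches_naive_loop(seed):
    """Sliding scanner == brute-force per-window loop, both strands."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(3, 9))
    n = int(rng.integers(L, 51))
    p = pssm_from_counts(rng.integers(0, 30, size=(4, L)), pseudocount=0.8)
    seq = "".join(rng.choice(list(BASES), size=n))
    thr = float(rng.uniform(-5, 8))
    got = [(m.start, m.end, m.strand, round(m.score, 9))
           for m in scan_one_haplotype(p, seq, thr, ".", 0, "REF")]
    assert got == naive_scan(p, seq, thr)


def test_score_threshold_enumeration_small_motif():
    """Exact-enumeration threshold reproduces the brute-force tail p-value."""
    rng = np.random.default_rng(5)
    p = pssm_from_counts(rng.integers(0, 12, size=(4, 4)), pseudocount=1.0)
    thr = p.score_threshold(pvalue=0.05)
    # brute force over all 4^4 windows under uniform background
    from itertools import product
    scores = [score_window(p, "".join(w)) for w in product(BASES, repeat=4)]
    tail = np.mean([s >= thr for s in scores])
    below = np.mean([s >= thr - 2e-3 for s in scores])
    assert tail <= 0.05 < below + 0.05  # thr is the smallest grid score at level


def test_delta_pssm_hand_matrix_and_antisymmetry():
    # column 2 scores A=2.0, G=-1.0; other columns identical for both windows
    cols = [[0.5, 0.5, 0.5, 0.5], [2.0, 0.0, -1.0, 0.0], [0.1, 0.1, 0.1, 0.1]]
    p = _hand_pssm(cols)
    snp = HetSNP("chr1", 11, "A", "G", id="rs9")
    dis = delta_pssm(p, "CAT", "CGT", snp)
    assert dis.delta == pytest.approx(3.0)
    swapped = delta_pssm(p, "CGT", "CAT", snp)
    assert swapped.delta == pytest.approx(-3.0)
    assert delta_pssm(p, "CAT", "CAT", snp).delta == 0.0
    assert delta_pssm(p, "CNT", "CGT", snp) is None  # unscorable -> dropped


def test_candidate_sites_intersection_rules():
    rng = np.random.default_rng(8)
    seq = "TTTTTGATTTTTTTTT"
    cols = []
    for base in "GAT":
        col = [-4.0] * 4
        col[BASES.index(base)] = 2.0
        cols.append(col)
    p = _hand_pssm(cols)
    pssms = {"hand": p}
    inside = HetSNP("chr1", 6, "A", "C", id="in")      # inside match [5, 8)
    outside = HetSNP("chr1", 8, "A", "C", id="out")    # 1 bp past the span
    matches = scan_one_haplotype(p, seq, 5.0, "chr1", 0, "REF")
    assert [(m.start, m.end) for m in matches] == [(5, 8)]
    cands = call_candidate_sites(matches, [inside, outside], pssms, seq)
    assert [c.snp.id for c in cands] == ["in"]
    assert cands[0].delta == pytest.approx(2.0 - (-4.0))
    # a second motif over the same SNP yields a second candidate
    pssms2 = {"hand": p, "hand2": Pssm("hand2", p.matrix.copy(),
                                       p.background, 0.0)}
    m2 = [m for m in matches] + [
        type(matches[0])(motif_id="hand2", chrom="chr1", start=5, end=8,
                         strand="+", score=6.0, haplotype="REF")]
    cands2 = call_candidate_sites(m2, [inside], pssms2, seq)
    assert sorted(c.motif_id for c in cands2) == ["hand", "hand2"]


def test_snp_only_on_alt_haplotype_still_candidate():
    """A match present on only one haplotype still yields a candidate."""
    cols = []
    for base in "GAT":
        col = [-6.0] * 4
        col[BASES.index(base)] = 2.0
        cols.append(col)
    p = _hand_pssm(cols)
    ref_seq = "TTTTTGCTTTTTTTTT"   # ref carries C at pos 6: no ref match
    snp = HetSNP("chr1", 6, "C", "A", id="gain")
    alt_seq = ref_seq[:6] + "A" + ref_seq[7:]
    matches = scan_sequences(p, ref_seq, alt_seq, 5.0, chrom="chr1")
    assert {m.haplotype for m in matches} == {"ALT"}
    cands = call_candidate_sites(matches, [snp], {"hand": p}, ref_seq)
    assert len(cands) == 1
    assert cands[0].delta == pytest.approx(-8.0)  # ALT scores higher
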