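"""Secondary-structure oracle, shuffle statistics and duplex hybridization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnidmir._seq import FOLD_PAIRS, random_rna, revcomp
from cnidmir.fold import (
    BULGED,
    PAIRED_GU,
    PAIRED_WC,
    UNPAIRED_END,
    DuplexScoring,
    dinucleotide_counts,
    _dinuc_shuffle,
    duplex_align,
    fold_nussinov,
    pair_table_from_dotbracket,
    shuffle_pvalue,
)
from cnidmir.simulate import make_hairpin

from conftest import SAFE_MATURE

# ---------------------------------------------------------------------------
# base-pair maximization
# ---------------------------------------------------------------------------


def brute_force_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Exhaustive enumeration of nested structures (no memoization)."""

    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        top = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in FOLD_PAIRS:
                top = max(top, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return top

    return best(0, len(seq) - 1)


def test_fold_simple_hairpin():
    res = fold_nussinov("GGGAAACCC")
    assert res.pair_count == 3
    assert res.structure == "(((...)))"


@pytest.mark.parametrize("seq", ["AAAAAAAAAA", "CCCCCC", "ACAC"])
def test_fold_unpairable_sequences(seq):
    res = fold_nussinov(seq)
    assert res.pair_count == 0
    assert res.structure == "." * len(seq)


def test_fold_respects_min_loop():
    # GAAAC could pair G:C only across a 3-nt loop; GAAC cannot.
    assert fold_nussinov("GAAAC").pair_count == 1
    assert fold_nussinov("GAAC").pair_count == 0


def test_fold_matches_exhaustive_enumeration():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = int(rng.integers(4, 13))
        seq = random_rna(rng, n)
        res = fold_nussinov(seq)
        assert res.pair_count == brute_force_max_pairs(seq), seq
        # the reported structure must be internally consistent
        table = pair_table_from_dotbracket(res.structure)
        assert len(table) == 2 * res.pair_count
        assert table == res.pair_table
        for i, j in table.items():
            if i < j:
                assert (seq[i - 1], seq[j - 1]) in FOLD_PAIRS
                assert j - i > 3  # hairpin loop >= 3


def test_fold_deterministic():
    rng = np.random.default_rng(7)
    seq = random_rna(rng, 60)
    assert fold_nussinov(seq).structure == fold_nussinov(seq).structure


# ---------------------------------------------------------------------------
# dinucleotide shuffling and the randomization p-value
# ---------------------------------------------------------------------------


@given(st.integers(min_value=0, max_value=10_000))
def test_dinucleotide_shuffle_preserves_counts(seed):
    rng = np.random.default_rng(seed)
    seq = random_rna(rng, 40)
    shuf = _dinuc_shuffle(seq, rng)
    assert sorted(shuf) == sorted(seq)
    assert dinucleotide_counts(shuf) == dinucleotide_counts(seq)
    assert shuf[0] == seq[0] and shuf[-1] == seq[-1]


def test_shuffle_pvalue_homopolymer_is_one():
    # every shuffle is the sequence itself; ties always count
    assert shuffle_pvalue("A" * 30, n_shuffles=20, seed=0) == 1.0


def test_shuffle_pvalue_bounds():
    rng = np.random.default_rng(99)
    for _ in range(5):
        seq = random_rna(rng, 50)
        p = shuffle_pvalue(seq, n_shuffles=19, seed=3)
        assert 1 / 20 <= p <= 1.0


def test_shuffle_pvalue_real_hairpin_significant():
    cand = make_hairpin(SAFE_MATURE[:21], loop_len=8, star_3p_overhang=2)
    p = shuffle_pvalue(cand.precursor_seq, n_shuffles=99, seed=11)
    assert p == pytest.approx(1 / 100)


def test_shuffle_pvalue_first_order_differs_from_second():
    # order-1 destroys dinucleotide stacking; both remain valid p-values
    seq = make_hairpin(SAFE_MATURE, loop_len=8).precursor_seq
    p2 = shuffle_pvalue(seq, n_shuffles=49, shuffle_order=2, seed=5)
    p1 = shuffle_pvalue(seq, n_shuffles=49, shuffle_order=1, seed=5)
    assert 0 < p1 <= 1 and 0 < p2 <= 1


# ---------------------------------------------------------------------------
# duplex hybridization
# ---------------------------------------------------------------------------


def brute_force_duplex_score(x: str, y_rev: str, sc: DuplexScoring) -> float:
    """Best local alignment score of x vs y_rev by explicit enumeration.

    Enumerates every choice of aligned segments (all four ends free) and
    every internal alignment path with affine gap runs.
    """
    best = [float("-inf")]

    def walk(i, j, score, gap_state):
        # option: stop here, leaving suffixes unaligned
        best[0] = max(best[0], score)
        if i < len(x) and j < len(y_rev):
            a, b = x[i], y_rev[j]
            if (a, b) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
                col = sc.wc
            elif (a, b) in {("G", "U"), ("U", "G")}:
                col = sc.gu
            else:
                col = sc.mismatch
            walk(i + 1, j + 1, score + col, None)
        if i < len(x):  # gap in y (miRNA bulge)
            cost = sc.gap_extend + (sc.gap_open if gap_state != "y" else 0)
            walk(i + 1, j, score + cost, "y")
        if j < len(y_rev):  # gap in x (target insertion)
            cost = sc.gap_extend + (sc.gap_open if gap_state != "x" else 0)
            walk(i, j + 1, score + cost, "x")

    for i0 in range(len(x) + 1):
        for j0 in range(len(y_rev) + 1):
            walk(i0, j0, 0.0, None)
    return best[0]


def test_duplex_perfect_complement():
    mi = SAFE_MATURE
    d = duplex_align(mi, revcomp(mi))
    assert d.score == 2 * len(mi)
    assert d.mirna_states == [PAIRED_WC] * len(mi)
    assert d.target_insertions == 0
    assert d.target_span == (0, len(mi))


def test_duplex_single_gu_wobble():
    mi = SAFE_MATURE
    window = list(revcomp(mi))
    # miRNA position 8 is G; put U opposite it (window index L-8) -> G:U
    pos = 8
    assert mi[pos - 1] == "G"
    window[len(mi) - pos] = "U"
    d = duplex_align(mi, "".join(window))
    assert d.score == 2 * (len(mi) - 1) + 1
    assert d.mirna_states.count(PAIRED_GU) == 1
    assert d.mirna_states[pos - 1] == PAIRED_GU


def test_duplex_target_insertion():
    mi = SAFE_MATURE
    rc = revcomp(mi)
    window = rc[:11] + "A" + rc[11:]  # 1-nt insertion mid-hybrid
    d = duplex_align(mi, window)
    assert d.target_insertions == 1
    assert d.score == 2 * len(mi) - 5  # one gap: open -3, extend -2
    assert BULGED not in d.mirna_states


def test_duplex_free_terminal_overhangs():
    mi = SAFE_MATURE
    window = "GGGG" + revcomp(mi) + "CCCC"
    d = duplex_align(mi, window)
    assert d.score == 2 * len(mi)  # overhangs cost nothing
    assert d.target_span == (4, 4 + len(mi))


def test_duplex_matches_brute_force_on_toys():
    sc = DuplexScoring()
    rng = np.random.default_rng(31)
    for _ in range(30):
        x = random_rna(rng, 8)
        y = random_rna(rng, int(rng.integers(7, 10)))
        d = duplex_align(x, y, sc)
        assert d.score == brute_force_duplex_score(x, y[::-1], sc), (x, y)


@given(st.integers(min_value=0, max_value=5_000))
def test_duplex_reverse_both_strands_invariance(seed):
    # reading both strands backwards describes the same physical duplex
    rng = np.random.default_rng(seed)
    x, y = random_rna(rng, 10), random_rna(rng, 12)
    assert duplex_align(x, y).score == duplex_align(x[::-1], y[::-1]).score


def test_duplex_strand_swap_changes_roles_not_pairing():
    # swapping which strand is "the miRNA" preserves WC pair count on toys
    x, y = "GGAUCCAA", revcomp("GGAUCCAA")
    d1, d2 = duplex_align(x, y), duplex_align(y, x)
    assert d1.score == d2.score == 2 * len(x)


def test_duplex_frayed_end_reported_unpaired():
    mi = SAFE_MATURE
    rc = revcomp(mi)
    # destroy pairing of the final 2 miRNA positions (C:C is no pair)
    window = "CC" + rc[2:]
    d = duplex_align(mi, window)
    assert d.mirna_states[-2:] == [UNPAIRED_END, UNPAIRED_END]
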