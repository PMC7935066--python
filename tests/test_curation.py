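"""Bona fide miRNA criteria: geometry, read evidence and the full factorial."""

from __future__ import annotations

import itertools

import pytest

from cnidmir._seq import revcomp
from cnidmir.curation import (
    CurationThresholds,
    PrecursorCandidate,
    ReadStack,
    blacklist_filter,
    duplex_geometry,
    evaluate_candidate,
    five_prime_consistency,
    quantify_known,
)
from cnidmir.fold import FoldResult, fold_nussinov, pair_table_from_dotbracket
from cnidmir.simulate import make_hairpin, make_read_stack

from conftest import SAFE_MATURE

# ---------------------------------------------------------------------------
# duplex geometry
# ---------------------------------------------------------------------------


def test_duplex_geometry_canonical_overhang(safe_mature):
    cand = make_hairpin(safe_mature[:21], star_3p_overhang=2)
    geom = duplex_geometry(cand, fold_nussinov(cand.precursor_seq))
    assert geom.star_3p_overhang == 2
    assert geom.mature_star_pairs == 19  # 21-nt mature minus the 2-nt overhang


def test_duplex_geometry_blunt_duplex(safe_mature):
    cand = make_hairpin(safe_mature[:21], star_3p_overhang=0)
    geom = duplex_geometry(cand, fold_nussinov(cand.precursor_seq))
    assert geom.star_3p_overhang == 0
    assert geom.mature_star_pairs == 21


def test_duplex_geometry_anchor_scans_past_frayed_end():
    # hand-built toy: mature position 1 unpaired (frayed), positions 2-5
    # paired to star positions 11-14, so the duplex still shows a 2-nt
    # 3' overhang once the anchor scans inward.
    structure = ".((((.....)))).."
    seq = "ACUGGAAAAACCAGAA"  # letters consistent with the pairing
    with pytest.warns(UserWarning):
        cand = PrecursorCandidate(
            id="toy", precursor_seq=seq, mature_interval=(0, 6), star_interval=(10, 16)
        )
    table = pair_table_from_dotbracket(structure)
    fold = FoldResult(structure, len(table) // 2, table)
    geom = duplex_geometry(cand, fold, anchor_scan=2)
    assert geom.star_3p_overhang == 2
    assert geom.mature_star_pairs == 4


def test_duplex_geometry_no_duplex():
    structure = "." * 16
    with pytest.warns(UserWarning):
        cand = PrecursorCandidate(
            id="toy", precursor_seq="A" * 16, mature_interval=(0, 6), star_interval=(10, 16)
        )
    geom = duplex_geometry(cand, FoldResult(structure, 0, {}))
    assert geom.no_duplex
    assert geom.star_3p_overhang is None
    assert geom.mature_star_pairs == 0


# ---------------------------------------------------------------------------
# 5' read consistency
# ---------------------------------------------------------------------------


def test_five_prime_consistency_simple():
    stack = ReadStack([(0, 22, 9), (1, 21, 1)])
    assert five_prime_consistency(stack, (0, 22)) == pytest.approx(0.9)


def test_five_prime_consistency_ignores_star_arm_reads():
    stack = ReadStack([(0, 22, 9), (1, 21, 1), (40, 20, 50)])
    assert five_prime_consistency(stack, (0, 22)) == pytest.approx(0.9)


def test_five_prime_consistency_tie_prefers_annotated_start():
    stack = ReadStack([(0, 22, 5), (2, 22, 5)])
    assert five_prime_consistency(stack, (0, 22)) == pytest.approx(0.5)


def test_five_prime_consistency_tie_prefers_smaller_start():
    # neither tied mode equals the annotated start (3)
    stack = ReadStack([(4, 22, 5), (6, 22, 5)])
    assert five_prime_consistency(stack, (3, 25)) == pytest.approx(0.5)


def test_five_prime_consistency_requires_mature_reads():
    with pytest.raises(ValueError):
        five_prime_consistency(ReadStack([(40, 20, 5)]), (0, 22))


# ---------------------------------------------------------------------------
# full factorial over the six independent criteria
# ---------------------------------------------------------------------------

LOOP = 8
FOLDABLE_BASE = SAFE_MATURE  # dinucleotide shuffles rarely refold this well
UNFOLDABLE_BASE = ("GC" * 12)  # shuffles of GC-alternation fold just as well


def _grid_candidate(score_ok, overhang_ok, five_prime_ok, pairs_ok, reads_ok, fold_ok):
    """One candidate/stack pair whose six criterion outcomes are forced.

    The intended structure is supplied explicitly so the geometric criteria
    (overhang, paired count) are decoupled from the fold p-value, which is
    controlled purely through the sequence composition.
    """
    k = 2 if overhang_ok else 1
    pairs = 16 if pairs_ok else 15
    lm = pairs + k
    base = FOLDABLE_BASE if fold_ok else UNFOLDABLE_BASE
    mature = base[:lm]
    tail = ("C" if fold_ok else "A") * k
    precursor = mature + "A" * LOOP + revcomp(mature[k:]) + tail
    # mature 5' block pairs the star run; star 3' overhang = k by construction
    structure = "(" * (lm - k) + "." * (k + LOOP) + ")" * (lm - k) + "." * k
    cand = PrecursorCandidate(
        id="cell",
        precursor_seq=precursor,
        mature_interval=(0, lm),
        star_interval=(lm + LOOP, len(precursor)),
        structure=structure,
        upstream_score=12.0 if score_ok else 8.0,
    )
    n_reads = 10 if reads_ok else 9
    fraction = 0.95 if five_prime_ok else 0.5
    stack = make_read_stack(cand, n_reads=n_reads, five_prime_fraction=fraction, seed=4)
    return cand, stack


@pytest.mark.parametrize(
    "flags", list(itertools.product([True, False], repeat=6)),
    ids=lambda f: "".join("P" if x else "F" for x in f),
)
def test_factorial_criteria_are_independent(flags):
    score_ok, overhang_ok, five_prime_ok, pairs_ok, reads_ok, fold_ok = flags
    cand, stack = _grid_candidate(*flags)
    ev = evaluate_candidate(cand, stack, n_shuffles=49, seed=11)
    assert ev.score_pass is score_ok
    assert ev.overhang_pass is overhang_ok
    assert ev.five_prime_pass is five_prime_ok
    assert ev.complementarity_pass is pairs_ok
    assert ev.reads_pass is reads_ok
    assert ev.fold_pvalue_pass is fold_ok
    assert ev.bona_fide is all(flags)
    assert bool(ev.failure_reasons) is not all(flags)


def test_boundary_reads_and_pairs(safe_mature):
    # exactly 10 reads and exactly 16 paired positions pass; one less fails
    cand, stack = _grid_candidate(True, True, True, True, True, True)
    ev = evaluate_candidate(cand, stack, n_shuffles=49, seed=11)
    assert ev.measured_reads == 10 and ev.reads_pass
    assert ev.measured_pairs == 16 and ev.complementarity_pass
    cand2, stack2 = _grid_candidate(True, True, True, False, False, True)
    ev2 = evaluate_candidate(cand2, stack2, n_shuffles=49, seed=11)
    assert ev2.measured_reads == 9 and not ev2.reads_pass
    assert ev2.measured_pairs == 15 and not ev2.complementarity_pass


def test_score_criterion_skipped_without_upstream_score(safe_mature):
    cand = make_hairpin(safe_mature, upstream_score=None)
    stack = make_read_stack(cand, n_reads=20, five_prime_fraction=0.95, seed=1)
    ev = evaluate_candidate(cand, stack, n_shuffles=49, seed=11)
    assert ev.score_pass and ev.measured_score is None
    assert ev.bona_fide


def test_optional_loop_size_criterion(safe_mature):
    small_loop = make_hairpin(safe_mature, loop_len=5)
    stack = make_read_stack(small_loop, n_reads=20, five_prime_fraction=0.95, seed=1)
    default = evaluate_candidate(small_loop, stack, n_shuffles=49, seed=11)
    assert default.bona_fide  # loop-size rule is off by default
    strict = CurationThresholds(require_loop_size=True, min_loop_size=8)
    ev = evaluate_candidate(small_loop, stack, thresholds=strict, n_shuffles=49, seed=11)
    assert not ev.bona_fide


# ---------------------------------------------------------------------------
# blacklist filtering
# ---------------------------------------------------------------------------


def _cand(mature: str, cid: str) -> PrecursorCandidate:
    return make_hairpin(mature, candidate_id=cid)


def test_blacklist_removes_exact_match(safe_mature):
    cand = _cand(safe_mature, "c1")
    rrna = {"r1": "GGG" + safe_mature + "CCC"}
    kept, removed = blacklist_filter([cand], {"rRNA": rrna})
    assert kept == [] and removed[0][1] == "rRNA"


def test_blacklist_matches_reverse_complement(safe_mature):
    cand = _cand(safe_mature, "c1")
    trna = {"t1": "AA" + revcomp(safe_mature) + "AA"}
    kept, removed = blacklist_filter([cand], {"tRNA": trna})
    assert kept == [] and removed[0][1] == "tRNA"


def test_blacklist_keeps_unrelated(safe_mature):
    cand = _cand(safe_mature, "c1")
    kept, removed = blacklist_filter([cand], {"rRNA": {"r1": "G" * 60}})
    assert kept == [cand] and removed == []


def test_blacklist_partitions_input(safe_mature):
    cands = [_cand(safe_mature, "a"), _cand("UAUCACAGCCAGCUUUGAUGAG", "b")]
    lists = {"rRNA": {"r1": "GG" + safe_mature + "GG"}}
    kept, removed = blacklist_filter(cands, lists)
    assert sorted(c.id for c in kept) + sorted(c.id for c, _ in removed) == ["b", "a"]
    assert len(kept) + len(removed) == len(cands)


def test_blacklist_mismatch_tolerance(safe_mature):
    near = safe_mature[:10] + "A" + safe_mature[11:]
    lists = {"sym": {"s1": "CC" + near + "CC"}}
    cand = _cand(safe_mature, "c1")
    kept0, _ = blacklist_filter([cand], lists, max_mismatch=0)
    kept1, _ = blacklist_filter([cand], lists, max_mismatch=1)
    assert kept0 == [cand] and kept1 == []


# ---------------------------------------------------------------------------
# genome-less quantification of known miRNAs
# ---------------------------------------------------------------------------

KNOWN = {"mir-100": "AACCCGUAGAUCCGAACUUGUG", "mir-2030": "UAUCGGGUCUGUAGUUAGCUGG"}


def test_quantify_detects_at_threshold():
    reads = [(KNOWN["mir-100"], 12)]
    assert quantify_known(reads, KNOWN) == {"mir-100": 12}


def test_quantify_below_threshold_not_detected():
    assert quantify_known([(KNOWN["mir-100"], 9)], KNOWN) == {}


def test_quantify_rejects_two_mismatches():
    seq = "GG" + KNOWN["mir-100"][2:]
    assert quantify_known([(seq, 50)], KNOWN, max_mismatch=1) == {}


def test_quantify_allows_one_mismatch_and_shift():
    shifted = KNOWN["mir-2030"][1:] + "A"  # 1-nt 5' trim plus a 3' extension
    assert quantify_known([(shifted, 11)], KNOWN) == {"mir-2030": 11}


def test_quantify_each_read_assigned_once():
    # a read matching one mature exactly must not also count for another
    reads = [(KNOWN["mir-100"], 10), (KNOWN["mir-2030"], 10)]
    out = quantify_known(reads, KNOWN)
    assert out == {"mir-100": 10, "mir-2030": 10}
    assert sum(out.values()) == sum(c for _, c in reads)
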