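"""Orthology, site conservation categories, sequence evolution and Dollo."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cnidmir._seq import random_rna
from cnidmir.conservation import (
    TurnoverInput,
    align_orthologs,
    annotate_site_region,
    classify_conservation,
    count_substitutions,
    dollo_reconstruct,
    flag_divergent_members,
    position_bias,
    project_interval,
    reciprocal_best_hits,
    reciprocal_map,
    site_location_conserved,
    turnover_rate,
)
from cnidmir.pipeline import analyze_scenario
from cnidmir.simulate import SimulationConfig, make_ortholog_transcript, make_species_scenario
from cnidmir.targets import TargetSite

from conftest import SAFE_MATURE


def _site(tid: str, start: int, end: int, mirna: str = "m", validated=None) -> TargetSite:
    return TargetSite(
        mirna_id=mirna, transcript_id=tid, start=start, end=end,
        seed_mismatches=0, tail_mismatches=0, pos1_mismatch=False,
        last_nt_unpaired=False, validated=validated,
    )


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------


def test_rbh_identical_transcriptomes():
    rng = np.random.default_rng(1)
    tx = {f"t{i}": random_rna(rng, 150) for i in range(5)}
    pairs = reciprocal_best_hits(tx, tx)
    assert all(p.reciprocal and p.id_A == p.id_B for p in pairs)
    assert reciprocal_map(pairs) == {t: t for t in tx}


def test_rbh_asymmetry_detected():
    rng = np.random.default_rng(2)
    x = random_rna(rng, 120)
    a1 = x[:60] + ("A" if x[60] != "A" else "C") + x[61:]  # one mismatch vs x
    tx_a = {"a1": a1, "a2": x}
    tx_b = {"b1": x}
    by_id = {p.id_A: p for p in reciprocal_best_hits(tx_a, tx_b)}
    assert not by_id["a1"].reciprocal  # b1's best is a2, not a1
    assert by_id["a2"].reciprocal


def test_rbh_recovers_orthologs_at_5pct_divergence():
    rng = np.random.default_rng(3)
    cfg = SimulationConfig(substitution_rate=0.05, indel_rate=0.01)
    tx_a = {f"t{i:02d}": random_rna(rng, 200) for i in range(20)}
    tx_b = {
        tid: make_ortholog_transcript(seq, cfg, seed=int(rng.integers(2**31)))[0]
        for tid, seq in tx_a.items()
    }
    mapping = reciprocal_map(reciprocal_best_hits(tx_a, tx_b))
    assert mapping == {tid: tid for tid in tx_a}


def test_rbh_rejects_empty_input():
    with pytest.raises(ValueError):
        reciprocal_best_hits({}, {"b": "ACGU"})


# ---------------------------------------------------------------------------
# conservation categories
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", [0, 5, 17])
def test_scenario_categories_recovered(seed):
    scen = make_species_scenario(seed=seed)
    res = analyze_scenario(scen)
    got = {(r.ref_mirna, r.ref_target): r.category for r in res["records"]}
    for entry in scen.plan:
        assert got[(entry.ref_mirna, entry.ref_transcript)] == entry.category


def test_classify_none_without_homolog():
    records = classify_conservation([("m", "tA")], rbh=[], other_sites=[], other_repertoire=set())
    assert records[0].category == "none"


def test_classify_category_boundaries():
    from cnidmir.conservation import HomologyPair

    rbh = [HomologyPair("tA", "tB", 100, 100, True)]
    # same family validated on the homolog -> I
    rec = classify_conservation(
        [("m", "tA")], rbh, [_site("tB", 10, 32, "m", validated=True)], {"m"}
    )[0]
    assert rec.category == "I"
    # different family validated, reference miRNA absent from repertoire -> II
    rec = classify_conservation(
        [("m", "tA")], rbh, [_site("tB", 10, 32, "other", validated=True)], {"other"}
    )[0]
    assert rec.category == "II" and rec.other_mirna == "other"
    # candidate exists but failed validation -> III
    rec = classify_conservation(
        [("m", "tA")], rbh, [_site("tB", 10, 32, "m", validated=False)], {"m"}
    )[0]
    assert rec.category == "III"


# ---------------------------------------------------------------------------
# site regions and positional conservation
# ---------------------------------------------------------------------------


def test_annotate_site_region():
    cds = (100, 200)
    assert annotate_site_region(_site("t", 50, 72), cds) == "5'UTR"
    assert annotate_site_region(_site("t", 90, 112), cds) == "CDS"  # any overlap
    assert annotate_site_region(_site("t", 150, 172), cds) == "CDS"
    assert annotate_site_region(_site("t", 210, 232), cds) == "3'UTR"
    assert annotate_site_region(_site("t", 50, 72), None) == "unknown"


def test_site_location_conserved_identical():
    rng = np.random.default_rng(4)
    tx = random_rna(rng, 300)
    check = site_location_conserved(_site("a", 120, 142), _site("b", 120, 142), tx, tx)
    assert check


def test_site_location_conserved_through_indel():
    rng = np.random.default_rng(5)
    tx = random_rna(rng, 300)
    tx_b = tx[:40] + "ACGUA" + tx[40:]  # 5-nt insertion upstream of the site
    check = site_location_conserved(_site("a", 120, 142), _site("b", 125, 147), tx, tx_b)
    assert check
    # the projection itself lands on the shifted window
    assert project_interval(tx, tx_b, (120, 142)) == (125, 147)


def test_site_location_not_conserved_when_distant():
    rng = np.random.default_rng(6)
    tx = random_rna(rng, 400)
    check = site_location_conserved(_site("a", 120, 142), _site("b", 320, 342), tx, tx)
    assert not check
    assert "apart" in check.reason or not check.conserved


# ---------------------------------------------------------------------------
# family alignment, substitutions, nucleotide bias
# ---------------------------------------------------------------------------


def test_align_orthologs_recovers_shift():
    ref = SAFE_MATURE
    trimmed = ref[1:]  # lost one 5' nucleotide
    aln = align_orthologs({"ref": ref, "trim": trimmed}, "ref")
    assert aln.offsets == {"ref": 0, "trim": 1}
    assert aln.identities["trim"] == 1.0


def test_align_orthologs_flags_divergent():
    aln = align_orthologs({"ref": SAFE_MATURE, "junk": "CGCGCGCGCGCGCGCGCGCGCG"}, "ref")
    assert flag_divergent_members(aln) == ["junk"]


def test_count_substitutions_modes_differ():
    # column A,A,G,G: one substitution by distinct-nucleotide counting,
    # two by the non-modal convention (plurality tie -> lexicographic A)
    seqs = ["AU", "AU", "GU", "GU"]
    d = count_substitutions(seqs, mode="distinct_minus_one")
    n = count_substitutions(seqs, mode="non_modal_count")
    assert d.per_position.get(1, 0) == 1 and d.total == 1
    assert n.per_position.get(1, 0) == 2 and n.total == 2
    with pytest.raises(ValueError):
        count_substitutions(seqs, mode="bogus")


def test_count_substitutions_permutation_invariant():
    seqs = ["AUGC", "AUGG", "CUGC"]
    t1 = count_substitutions(seqs).total
    t2 = count_substitutions(list(reversed(seqs))).total
    assert t1 == t2


def test_position_bias_closed_forms():
    pfm, info = position_bias(["AC", "AC", "AC", "AA"])
    # column 1 invariant: 2 bits; column 2 is 3:1 -> 2 - H(3/4, 1/4)
    assert info[0] == pytest.approx(2.0)
    h = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
    assert info[1] == pytest.approx(2.0 - h)
    assert pfm.loc["A", 1] == pytest.approx(1.0)
    assert pfm.loc["C", 2] == pytest.approx(0.75)


def test_position_bias_uniform_column_zero_bits():
    _, info = position_bias(["A", "C", "G", "U"])
    assert info[0] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------

TREE = "((A,B)ab,(C,D)cd)root;"


def _presence(rows: dict[str, list[int]]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=["A", "B", "C", "D"]).T


def test_dollo_gain_at_root_with_one_loss():
    pres = _presence({"m1": [1, 1, 1, 0]})
    res = dollo_reconstruct(pres, TREE)
    assert res.gain_node["m1"] == "root"
    assert res.loss_edges["m1"] == ["D"]
    assert res.shared_per_node == {"root": 1, "ab": 1, "cd": 1}


def test_dollo_gain_on_leaf():
    res = dollo_reconstruct(_presence({"m1": [1, 0, 0, 0]}), TREE)
    assert res.gain_node["m1"] == "A"
    assert res.loss_edges["m1"] == []
    assert res.shared_per_node == {"root": 0, "ab": 0, "cd": 0}


def test_dollo_disjoint_possessors_two_losses():
    # present in A and D only: gained at the root, lost along B and C edges
    res = dollo_reconstruct(_presence({"m1": [1, 0, 0, 1]}), TREE)
    assert res.gain_node["m1"] == "root"
    assert sorted(res.loss_edges["m1"]) == ["B", "C"]
    assert res.presence["m1"] >= {"root", "ab", "A", "cd", "D"}
    assert "B" not in res.presence["m1"] and "C" not in res.presence["m1"]


def test_dollo_each_mirna_gained_exactly_once():
    pres = _presence(
        {"m1": [1, 1, 1, 1], "m2": [1, 1, 0, 0], "m3": [1, 0, 0, 1], "m4": [0, 0, 1, 0]}
    )
    res = dollo_reconstruct(pres, TREE)
    assert sum(res.gains_per_node.values()) == 4
    assert res.gain_node == {"m1": "root", "m2": "ab", "m3": "root", "m4": "C"}
    assert res.shared_per_node == {"root": 2, "ab": 3, "cd": 2}


def test_dollo_skips_absent_everywhere():
    with pytest.warns(UserWarning):
        res = dollo_reconstruct(_presence({"m1": [0, 0, 0, 0]}), TREE)
    assert res.skipped == ["m1"]


def test_dollo_unknown_species_raises():
    with pytest.raises(ValueError):
        dollo_reconstruct(pd.DataFrame({"A": [1], "Z": [1]}, index=["m1"]), TREE)


# ---------------------------------------------------------------------------
# repertoire turnover
# ---------------------------------------------------------------------------


def test_turnover_published_window():
    a = frozenset(f"a{i}" for i in range(8)) | frozenset(f"s{i}" for i in range(5))
    b = frozenset(f"b{i}" for i in range(15)) | frozenset(f"s{i}" for i in range(5))
    inp = TurnoverInput(a, b, (16.2, 35.3))
    low, high = turnover_rate(inp)  # D = 8 + 15 = 23
    assert low == pytest.approx(0.652, abs=5e-4)
    assert high == pytest.approx(1.420, abs=5e-4)


def test_turnover_identical_repertoires():
    r = frozenset({"x", "y"})
    assert turnover_rate(TurnoverInput(r, r, (1.0, 2.0))) == (0.0, 0.0)


def test_turnover_point_estimate_and_per_lineage():
    inp = TurnoverInput(frozenset("abcde"), frozenset("fghij"), (10.0, 10.0))
    assert turnover_rate(inp) == (1.0, 1.0)
    assert turnover_rate(inp, per_lineage=True) == (0.5, 0.5)


def test_turnover_invalid_window():
    with pytest.raises(ValueError):
        TurnoverInput(frozenset("a"), frozenset("b"), (5.0, 2.0))
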