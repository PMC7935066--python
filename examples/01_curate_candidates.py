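"""Curating bona fide miRNAs from hairpin candidates and small-RNA reads.

A candidate precursor qualifies as a bona fide miRNA only when its
processing signature looks Drosha/Dicer-made: a ~2-nt star 3' overhang,
homogeneous read 5' ends, extensive mature/star pairing, enough reads,
and a fold that is more stable than dinucleotide-shuffled versions of
itself. This example builds one good candidate and several deliberately
broken ones and walks through the audit trail.
"""

from cnidmir import evaluate_candidate, make_hairpin, make_read_stack
from cnidmir.curation import CurationThresholds, blacklist_filter

MATURE = "UAAGGUAGUAGGUUGUAUAGCC"  # a let-7-like 22-mer

# --- a well-formed candidate -------------------------------------------------
good = make_hairpin(MATURE, loop_len=8, star_3p_overhang=2, candidate_id="mir-good",
                    upstream_score=14.0)
good_stack = make_read_stack(good, n_reads=25, five_prime_fraction=0.95, seed=1)

ev = evaluate_candidate(good, good_stack, n_shuffles=99, seed=11)
print("== well-formed candidate ==")
print(f"overhang          : {ev.measured_overhang} nt   (pass={ev.overhang_pass})")
print(f"5' consistency    : {ev.measured_five_prime:.2f}   (pass={ev.five_prime_pass})")
print(f"mature/star pairs : {ev.measured_pairs}     (pass={ev.complementarity_pass})")
print(f"mature-arm reads  : {ev.measured_reads}     (pass={ev.reads_pass})")
print(f"fold p-value      : {ev.measured_pvalue}   (pass={ev.fold_pvalue_pass})")
print(f"bona fide         : {ev.bona_fide}")

# --- a ragged candidate: heterogeneous 5' ends -------------------------------
ragged_stack = make_read_stack(good, n_reads=25, five_prime_fraction=0.6, seed=1)
ev2 = evaluate_candidate(good, ragged_stack, n_shuffles=99, seed=11)
print("\n== ragged 5' ends ==")
print(f"5' consistency    : {ev2.measured_five_prime:.2f}")
print(f"failure reasons   : {ev2.failure_reasons}")

# --- an rRNA fragment masquerading as a miRNA --------------------------------
impostor = make_hairpin("UAUCACAGCCAGCUUUGAUGAG", candidate_id="mir-impostor")
rrna = {"rRNA-frag": "GGGG" + "UAUCACAGCCAGCUUUGAUGAG" + "CCCC"}
kept, removed = blacklist_filter([good, impostor], {"rRNA": rrna})
print("\n== blacklist screening ==")
print(f"kept    : {[c.id for c in kept]}")
print(f"removed : {[(c.id, src) for c, src in removed]}")

# --- stricter, plant/bilaterian-style thresholds -----------------------------
strict = CurationThresholds(require_loop_size=True, min_loop_size=10)
ev3 = evaluate_candidate(good, good_stack, thresholds=strict, n_shuffles=99, seed=11)
print("\n== with a loop-size requirement (off by default) ==")
print(f"bona fide under strict thresholds: {ev3.bona_fide} ({ev3.failure_reasons})")
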