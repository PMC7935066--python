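# cnidmir

Annotation and comparative analysis of cnidarian microRNAs: curation of
bona fide miRNA hairpins from small-RNA evidence, prediction of plant-like
highly complementary mRNA target sites, verification of those sites
against degradome (PARE) cleavage signatures, and quantification of
cross-species conservation and turnover of both the miRNAs and their
binding sites.

## The scientific problem

Cnidarian miRNAs are unusual twice over. Unlike bilaterian miRNAs, which
bind short "seed" matches, cnidarian miRNAs act like plant miRNAs: they
require near-perfect complementarity to their targets and direct
endonucleolytic cleavage ("slicing") of the target between the bases
opposite miRNA positions 10 and 11. And unlike the deeply conserved
bilaterian repertoires, cnidarian miRNA repertoires evolve fast — most
families and most target interactions differ even between congeneric
species. Analyzing this regime requires a toolchain built around three
evidential pillars:

1. **Hairpin curation.** A candidate precursor is accepted as a bona fide
   miRNA only when its read signature looks Drosha/Dicer-made: a ~2-nt
   star-strand 3' overhang, ≥90% homogeneous read 5' ends, ≥16 paired
   mature/star positions, ≥10 supporting reads, and a secondary structure
   more stable than dinucleotide-shuffled versions of itself (p < 0.05).
2. **Target prediction + degradome proof.** Sites are found by antisense
   scanning under explicit per-region mismatch budgets (free 5' position 1;
   ≤2 mismatches in seed positions 2–11; ≤2 in the 3' tail; terminal
   position exempt), re-validated at duplex level (G:U allowed, at most one
   bulge, positions 9–12 must pair), and then confirmed by degradome reads
   whose 5' ends fall exactly 10 nt upstream of the site's 3' edge — the
   fingerprint of slicing.
3. **Conservation accounting.** Between two species, each verified
   (miRNA, target) pair is classified as category I (same miRNA, same
   homologous target), II (a different miRNA took over the target), or III
   (the homologous site decayed past validation); miRNA family histories
   are reconstructed by Dollo parsimony and repertoire turnover is
   expressed in gains+losses per million years.

All generators for synthetic data plant their truth *by construction*
(exact mismatch counts per rule region, exact cleavage coordinates, known
ortholog maps), so every pipeline stage can be tested against a known
answer rather than a plausibility argument.

## Worked example

```python
from cnidmir import (evaluate_candidate, make_hairpin, make_read_stack,
                     make_species_scenario)
from cnidmir.pipeline import analyze_scenario

# curate one well-formed candidate
cand = make_hairpin("UAAGGUAGUAGGUUGUAUAGCC", star_3p_overhang=2,
                    upstream_score=14.0)
stack = make_read_stack(cand, n_reads=25, five_prime_fraction=0.95, seed=1)
ev = evaluate_candidate(cand, stack, n_shuffles=99, seed=11)
print(ev.measured_overhang, ev.measured_pairs, ev.measured_pvalue, ev.bona_fide)
# -> 2 20 0.01 True

# run the in-memory pipeline on a two-species scenario with planted fates
scen = make_species_scenario(seed=2024, category_plan=("I", "II", "III"))
res = analyze_scenario(scen)
for r in res["records"]:
    print(r.ref_mirna, r.ref_target, "->", r.category)
# -> mir-1 A_t1 -> I
# -> mir-2 A_t2 -> II
# -> mir-3 A_t3 -> III
```

The `examples/` directory holds five narrative scripts covering curation
(`01`), target prediction and degradome verification (`02`), conservation
categories (`03`), repertoire/sequence evolution statistics (`04`), and the
full file-based pipeline with its TOML config (`05`). Each prints its
results and asserts them against the planted truth; run them with
`python examples/01_curate_candidates.py` etc.

A thin CLI mirrors the pipeline stages:

```bash
cnidmir simulate --seed 8 --out-dir fixtures/
cnidmir find-targets --mirnas m.fasta --transcripts tx.fasta --out sites.tsv
cnidmir degradome-verify --sites sites.tsv --transcripts tx.fasta \
    --degradome reads.fasta --out evidence.tsv
cnidmir run config.toml
```

TSV reports use 1-based inclusive coordinates; BED output is 0-based
half-open. All randomness flows through seeded `numpy` generators, and
pipeline reruns are byte-identical for a fixed seed.

## Reproduction

`scripts/acceptance.py` recomputes the package's headline quantities from
scratch — scanner agreement with an independently written oracle (200
random miRNA/transcript pairs), the exhaustive planted-mismatch budget
grid, degradome verification precision/recall over 50 seeds, the full 2⁶
factorial over the curation criteria, fold agreement with brute-force
structure enumeration, category recovery over 50 two-species scenarios,
reciprocal-best-hit ortholog recovery at 5% divergence, Dollo worked
fixtures, and the closed-form turnover and information-content arithmetic:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

With `--seed 1` this reports, among others: `scanner_oracle_disagreements
= 0/200`, `degradome_precision = degradome_recall = 1.0`,
`curation_factorial_mismatches = 0/64`, `conservation_category_accuracy =
1.0` over 150 planted targets, `turnover_rate_low = 0.652` and
`turnover_rate_high = 1.420` for 23 repertoire differences over a
16.2–35.3 Myr divergence window, and an information content of 1.1887
bits for a 3:1 skewed alignment column.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.
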