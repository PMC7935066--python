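# Methods

This note records the model implemented by `cnidmir`, the default
parameters and why they were chosen, the numerical conventions, what the
synthetic-data generators do and do not capture, and known limitations.

## Hairpin curation

A precursor candidate is evaluated against six independent criteria, each
recorded separately in the audit table so a failure lists every reason:

| criterion | default | rationale |
|---|---|---|
| upstream discovery score | ≥ 10 | prefilter from an external hairpin-discovery tool; skipped (passes) when no score is attached |
| star 3' overhang | exactly 2 nt | the RNase III processing signature; measured on the fold, with the anchor scanning up to 2 nt inward because real hairpin ends fray |
| 5' read consistency | ≥ 0.90 | mature 5' homogeneity distinguishes Dicer products from degradation; only reads overlapping the mature arm count, modal ties prefer the annotated start, then the smaller coordinate |
| mature/star paired positions | ≥ 16 | extensive duplex pairing; counted between the annotated arms on the fold |
| supporting reads | ≥ 10 | by default only mature-arm reads count (`mature_reads_only`); the alternative (all reads) is a documented switch |
| fold randomization p | < 0.05 | `p = (1 + #{shuffles scoring ≥ observed}) / (n+1)` over 99 order-2 shuffles by default, so the minimum attainable p is 0.01 |

Loop-size (≥ 8 nt) and star-read-consistency requirements exist as
switches but default **off**: cnidarian hairpins frequently violate them,
and enforcing them would discard genuine miRNAs.

If a candidate carries a dot-bracket structure, the geometric criteria are
measured on that structure; the randomization p-value is always computed
from the sequence. Candidates whose mature occurs (either strand,
substring with ≤ `max_mismatch` mismatches) in a blacklist — rRNA, tRNA,
or symbiont sequence sets — are removed before evaluation.

## Secondary structure

Folding uses Nussinov-style base-pair maximization over {A:U, G:C, G:U}
with a minimum hairpin loop of 3 nt and a deterministic traceback, **not**
a thermodynamic model. Pair-count maximization preserves the quantity the
criteria actually consume (which positions pair, how many) while keeping
the implementation exact, dependency-free and testable against brute-force
enumeration of all nested structures. A `fold_fn` hook accepts an
energy-model backend (`vienna_fold_fn` adapts the ViennaRNA bindings,
returning −MFE so higher = more stable) wherever stability enters a
decision; results in this package's tests use the pair-count model.

The shuffle test uses the Altschul–Erickson Eulerian-walk algorithm, which
preserves all dinucleotide counts exactly (first and last nucleotide
fixed); order-1 (mononucleotide) shuffling is available but order-2 is the
default because stacking makes fold stability strongly dinucleotide-
dependent.

## Target rules

Scanning slides the miRNA antisense along the transcript and charges
Watson–Crick failures to regions of the miRNA (1-based, 5'→3'):

- position 1: free (flagged, never counted) under `free_5prime`; charged
  to the seed budget otherwise;
- seed, positions 2–11: ≤ 2 mismatches;
- tail, positions 12…L−1: ≤ 2 mismatches;
- the last position (`unpaired_3prime` = 1): always exempt.

G:U is a **mismatch** during scanning and a **match** during validation —
scanning is deliberately the stricter filter. Validation re-hybridizes
the site window ±3 nt flanks with a local affine-gap duplex aligner
(WC +2, G:U +1, mismatch −1, gap open −3, extend −2; terminal overhangs
free), then requires: non-paired states re-satisfy the per-region budgets,
at most one bulge in total, and positions 9–12 all paired — slicing
geometry demands a paired centre.

## Degradome verification

A site occupying 0-based half-open interval [start, end) is sliced
opposite miRNA positions 10/11, so the diagnostic 3' fragment begins at
coordinate `end − 10`. A degradome read supports a site iff its mapped 5'
end equals that coordinate exactly (`require_exact`, the default;
`slop_nt` relaxes this). Multi-mapping reads are discarded as ambiguous by
default. One exact read suffices (`min_supporting_reads = 1`) because the
coordinate test is already stringent; the threshold is configurable.

## Conservation

Orthology is reciprocal best hits under Biopython local alignment
(match 2, mismatch −1, gap open −5, extend −2); a tabular adapter
(`rbh_from_table`) accepts external aligner output for real data.
Verified reference sites are projected onto their homologs through a
global alignment with free end gaps, and the projected windows are duplex-
validated even when scanning would never emit them — this is what makes
decayed sites (category III) observable rather than silent. Categories:
I = same family validated on the reciprocal homolog; II = a different
family validated there *and* the reference family absent from the other
repertoire; III = a candidate window exists but fails validation.

Family histories use Dollo parsimony (each family gained exactly once, at
the MRCA of its possessors; losses wherever presence ends). Repertoire
turnover divides the symmetric difference of two repertoires by the
divergence-time window, reported as a (D/t_max, D/t_min) interval; a
`per_lineage` flag halves it. Substitution counts over ungapped offset
alignments support two conventions — `distinct_minus_one` (default) and
`non_modal_count` — because published counts use both; they differ when a
column carries more than two states or a tied plurality. Position bias
reports a coverage-normalized frequency matrix and information content
`2 − H` bits per column.

## Synthetic data

Generators plant truth by construction: hairpins are built so the star 3'
overhang and pair count are exact (and re-verified on the actual fold
before use); planted sites receive hard (non-WC, non-G:U) mismatches at
seeded positions with exact per-region counts; degradome reads start
exactly at the cleavage coordinate; ortholog transcripts evolve by i.i.d.
substitutions and 1-nt indels that never fall inside planted sites, with
interval maps threaded through the indels. Category III windows are
degraded *until they demonstrably fail duplex validation* (re-checked at
generation time), not merely past the scan budget, because the validator
forgives wobbles and one bulge.

Realism limits, deliberately accepted: transcripts are i.i.d. uniform
RNA (no codon structure, no composition bias beyond the planted 5'-U of
matures); read stacks are three-parameter summaries (start homogeneity,
±1–2 nt jitter, counts), not error-model simulations; degradome noise is
uniform; indels are single-nucleotide. These are the right trade-offs for
truth-by-construction testing but the generators should not be used as a
biological null model.

Two construction corner cases are refused rather than silently mishandled:
a mature whose first `star_3p_overhang` nucleotides contain both G and U
admits no guaranteed-unpairable overhang tail letter (every base pairs
with G or U under max-pairing), and a constructed hairpin whose verified
geometry differs from the request (e.g. self-structure within a short
mature) raises instead of emitting a wrong fixture.

## Numerical conventions

All randomness flows through `numpy.random.default_rng` with explicit
seeds; derived seeds stay below 2³¹. Reports use 1-based inclusive
coordinates in TSV and 0-based half-open in BED; all internal coordinates
are 0-based half-open. Output rows are ordered (transcript id, start,
miRNA id) so pipeline reruns are byte-identical. Rounding uses
round-half-up where read counts are apportioned.

## Limitations

- Base-pair maximization can differ from thermodynamic folds on long or
  GC-poor precursors; use the `fold_fn` hook when energies matter.
- The duplex aligner's score invariance holds under strand-role swap and
  simultaneous reversal of both strands, but **not** under simultaneous
  reverse-complement: G:U wobbles map to C:A non-pairs, so that symmetry
  is mathematically unavailable to any wobble-aware scorer.
- Where the seed window should anchor (5' of the miRNA vs 5' of the
  duplex) is unsettled for the slicing regime; the rule set keeps it a
  parameter (`seed_len`, `free_5prime`) rather than a fixed convention.
- Dollo parsimony by construction cannot represent convergent gain; a
  family truly gained twice is reported as one deep gain plus losses.
- RBH orthology is one-to-one; paralog fan-outs are flagged only via
  lost reciprocity, not resolved.
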