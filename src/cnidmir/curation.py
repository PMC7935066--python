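"""Bona fide miRNA curation.

A hairpin candidate qualifies as a bona fide miRNA when it satisfies the
structural and read-support criteria used for cnidarian annotation:
a miRDeep2-style score prefilter (>= 10, when a score is available), a
2-nt 3' overhang of the star strand, >= 90% of mature-arm reads sharing
one 5' start, >= 16 paired positions between mature and star strand,
>= 10 supporting reads, and a significant fold-randomization p-value.
Terminal-loop size and star-strand read consistency are deliberately NOT
required: cnidarian miRNAs do not follow those bilaterian conventions.

Candidates matching tRNA/rRNA or symbiont blacklists are removed, and
for species without genome assemblies conserved miRNAs are detected
directly from reads (:func:`quantify_known`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from . import fold as _fold
from ._seq import normalize_rna, revcomp
from .fold import FoldResult, pair_table_from_dotbracket


@dataclass
class PrecursorCandidate:
    """A hairpin precursor with annotated mature/star arms (0-based half-open)."""

    id: str
    precursor_seq: str
    mature_interval: tuple[int, int]
    star_interval: tuple[int, int]
    structure: str | None = None
    upstream_score: float | None = None
    species: str = ""

    def __post_init__(self) -> None:
        self.precursor_seq = normalize_rna(self.precursor_seq)
        n = len(self.precursor_seq)
        for name, (a, b) in (("mature", self.mature_interval), ("star", self.star_interval)):
            if not (0 <= a < b <= n):
                raise ValueError(f"{name} interval outside precursor for {self.id}")
        ma, mb = self.mature_interval
        sa, sb = self.star_interval
        if max(ma, sa) < min(mb, sb):
            raise ValueError(f"mature and star intervals overlap for {self.id}")
        mlen = mb - ma
        if not 18 <= mlen <= 26:
            warnings.warn(f"{self.id}: mature length {mlen} outside typical 18-26 nt", stacklevel=2)

    @property
    def mature_seq(self) -> str:
        a, b = self.mature_interval
        return self.precursor_seq[a:b]

    @property
    def star_seq(self) -> str:
        a, b = self.star_interval
        return self.precursor_seq[a:b]


@dataclass
class ReadStack:
    """Aligned small-RNA reads on a precursor: (start, length, count) rows."""

    entries: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        for start, length, count in self.entries:
            if count < 1 or length < 1 or start < 0:
                raise ValueError("read stack entries need start >= 0, length >= 1, count >= 1")

    @property
    def total_reads(self) -> int:
        return sum(c for _, _, c in self.entries)


@dataclass(frozen=True)
class CurationThresholds:
    """Criteria a candidate must pass to qualify as bona fide.

    Loop-size and star-consistency requirements exist as switches but
    default off; cnidarian hairpins violate them.
    """

    min_score: float = 10.0
    overhang_nt: int = 2
    min_five_prime_consistency: float = 0.90
    min_mature_star_pairs: int = 16
    min_reads: int = 10
    fold_alpha: float = 0.05
    require_loop_size: bool = False
    min_loop_size: int = 8
    require_star_consistency: bool = False
    #: count mature-arm reads only toward min_reads (alternative: all reads)
    mature_reads_only: bool = True


@dataclass
class DuplexGeometry:
    """Mature/star pairing geometry measured on a fold."""

    star_3p_overhang: int | None
    mature_star_pairs: int
    no_duplex: bool = False


@dataclass
class CandidateEvaluation:
    """Audit record: one boolean + measured value per criterion."""

    candidate_id: str
    score_pass: bool
    overhang_pass: bool
    five_prime_pass: bool
    complementarity_pass: bool
    reads_pass: bool
    fold_pvalue_pass: bool
    measured_score: float | None
    measured_overhang: int | None
    measured_five_prime: float
    measured_pairs: int
    measured_reads: int
    measured_pvalue: float
    bona_fide: bool
    failure_reasons: list[str]


def duplex_geometry(candidate: PrecursorCandidate, fold: FoldResult, anchor_scan: int = 2) -> DuplexGeometry:
    """Star 3' overhang and mature/star paired-position count from a fold.

    The overhang is the number of star 3'-terminal nucleotides lying
    beyond the pairing partner of the first paired mature 5' nucleotide;
    real hairpin ends fray, so the anchor scans up to ``anchor_scan`` nt
    inward for the first mature position paired to the star.
    """
    ma, mb = candidate.mature_interval
    sa, sb = candidate.star_interval
    mature_pos = set(range(ma + 1, mb + 1))  # 1-based
    star_pos = set(range(sa + 1, sb + 1))
    pairs = sum(1 for i, j in fold.pair_table.items() if i in mature_pos and j in star_pos)
    anchor_partner = None
    for off, i in enumerate(sorted(mature_pos)):
        if off > anchor_scan:
            break
        j = fold.pair_table.get(i)
        if j is not None and j in star_pos:
            anchor_partner = j
            break
    if anchor_partner is None:
        return DuplexGeometry(star_3p_overhang=None, mature_star_pairs=pairs, no_duplex=True)
    overhang = sb - anchor_partner  # star positions 3' of the anchor partner
    return DuplexGeometry(star_3p_overhang=overhang, mature_star_pairs=pairs)


def five_prime_consistency(stack: ReadStack, mature_interval: tuple[int, int]) -> float:
    """Fraction of mature-arm reads sharing the modal 5' start.

    Only reads overlapping the mature arm count. A modal tie prefers the
    annotated mature start, then the smaller coordinate.
    """
    ma, mb = mature_interval
    by_start: dict[int, int] = {}
    total = 0
    for start, length, count in stack.entries:
        if start < mb and start + length > ma:  # overlaps the mature arm
            by_start[start] = by_start.get(start, 0) + count
            total += count
    if total == 0:
        raise ValueError("no reads overlap the mature arm")
    best = max(by_start.values())
    tied = sorted(s for s, c in by_start.items() if c == best)
    modal = ma if ma in tied else tied[0]
    return by_start[modal] / total


def _loop_size(candidate: PrecursorCandidate, fold: FoldResult) -> int:
    """Unpaired span between the innermost mature/star pairing partners."""
    ma, mb = candidate.mature_interval
    sa, sb = candidate.star_interval
    mature_pos = set(range(ma + 1, mb + 1))
    star_pos = set(range(sa + 1, sb + 1))
    inner = [(i, j) for i, j in fold.pair_table.items() if i in mature_pos and j in star_pos]
    if not inner:
        return 0
    i, j = max(inner)  # innermost duplex pair (largest mature position)
    return j - i - 1


def evaluate_candidate(
    candidate: PrecursorCandidate,
    stack: ReadStack,
    thresholds: CurationThresholds | None = None,
    n_shuffles: int = 99,
    seed: int = 0,
    min_loop: int = 3,
    fold_fn=None,
) -> CandidateEvaluation:
    """Apply every bona fide criterion and record all outcomes.

    Criteria are all evaluated even after a failure so audit tables list
    every reason. The score criterion is skipped (passes) when the
    candidate carries no upstream score.
    """
    th = thresholds or CurationThresholds()
    if candidate.structure is not None:
        table = pair_table_from_dotbracket(candidate.structure)
        fold = FoldResult(candidate.structure, len(table) // 2, table)
    else:
        fold = _fold.fold_nussinov(candidate.precursor_seq, min_loop)
    geom = duplex_geometry(candidate, fold)
    consistency = five_prime_consistency(stack, candidate.mature_interval)
    if th.mature_reads_only:
        ma, mb = candidate.mature_interval
        reads = sum(c for s, ln, c in stack.entries if s < mb and s + ln > ma)
    else:
        reads = stack.total_reads
    pvalue = _fold.shuffle_pvalue(
        candidate.precursor_seq, n_shuffles=n_shuffles, seed=seed, min_loop=min_loop, fold_fn=fold_fn
    )
    score_pass = candidate.upstream_score is None or candidate.upstream_score >= th.min_score
    overhang_pass = geom.star_3p_overhang == th.overhang_nt
    five_prime_pass = consistency >= th.min_five_prime_consistency
    compl_pass = geom.mature_star_pairs >= th.min_mature_star_pairs
    reads_pass = reads >= th.min_reads
    fold_pass = pvalue < th.fold_alpha
    flags = {
        "score": score_pass,
        "overhang": overhang_pass,
        "five_prime": five_prime_pass,
        "complementarity": compl_pass,
        "min_reads": reads_pass,
        "fold_pvalue": fold_pass,
    }
    if th.require_loop_size:
        flags["loop_size"] = _loop_size(candidate, fold) >= th.min_loop_size
    if th.require_star_consistency:
        try:
            star_consistency = five_prime_consistency(stack, candidate.star_interval)
        except ValueError:  # no reads on the star arm: no evidence, no pass
            star_consistency = 0.0
        flags["star_consistency"] = star_consistency >= th.min_five_prime_consistency
    failures = [name for name, ok in flags.items() if not ok]
    return CandidateEvaluation(
        candidate_id=candidate.id,
        score_pass=score_pass,
        overhang_pass=overhang_pass,
        five_prime_pass=five_prime_pass,
        complementarity_pass=compl_pass,
        reads_pass=reads_pass,
        fold_pvalue_pass=fold_pass,
        measured_score=candidate.upstream_score,
        measured_overhang=geom.star_3p_overhang,
        measured_five_prime=consistency,
        measured_pairs=geom.mature_star_pairs,
        measured_reads=reads,
        measured_pvalue=pvalue,
        bona_fide=all(flags.values()),
        failure_reasons=failures,
    )


def _matches_with_mismatches(query: str, subject: str, max_mismatch: int) -> bool:
    """True if query occurs as a substring of subject with <= max_mismatch mismatches."""
    m, n = len(query), len(subject)
    if m > n:
        return False
    if max_mismatch == 0:
        return query in subject
    for start in range(n - m + 1):
        mm = 0
        for a, b in zip(query, subject[start : start + m]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return True
    return False


def blacklist_filter(
    candidates: list[PrecursorCandidate],
    blacklists: dict[str, dict[str, str]],
    max_mismatch: int = 0,
) -> tuple[list[PrecursorCandidate], list[tuple[PrecursorCandidate, str]]]:
    """Remove candidates whose mature occurs in any blacklist sequence.

    ``blacklists`` maps a source name (e.g. "tRNA", "rRNA", "symbiont") to
    {sequence id: sequence}. Matching is substring matching on either
    strand with <= ``max_mismatch`` mismatches (0 by default).
    """
    kept: list[PrecursorCandidate] = []
    removed: list[tuple[PrecursorCandidate, str]] = []
    norm_lists = {
        src: [normalize_rna(s) for s in seqs.values()] for src, seqs in blacklists.items()
    }
    for cand in candidates:
        mature = cand.mature_seq
        queries = (mature, revcomp(mature))
        source = None
        for src, seqs in norm_lists.items():
            if any(_matches_with_mismatches(q, s, max_mismatch) for q in queries for s in seqs):
                source = src
                break
        if source is None:
            kept.append(cand)
        else:
            removed.append((cand, source))
    return kept, removed


def _read_vs_mature(read: str, mature: str, max_shift: int, max_mismatch: int):
    """Best ungapped placement of a read on a known mature.

    Returns (mismatches, total end shift) or None if no placement fits the
    shift/mismatch budgets. The 5' offset and the 3' overhang must each be
    <= max_shift in absolute value.
    """
    best = None
    for d5 in range(-max_shift, max_shift + 1):
        d3 = (d5 + len(read)) - len(mature)
        if abs(d3) > max_shift:
            continue
        # overlap region in mature coordinates
        lo = max(0, d5)
        hi = min(len(mature), d5 + len(read))
        if hi <= lo:
            continue
        mm = sum(1 for i in range(lo, hi) if mature[i] != read[i - d5])
        if mm > max_mismatch:
            continue
        key = (mm, abs(d5) + abs(d3))
        if best is None or key < best:
            best = key
    return best


def quantify_known(
    reads: list[tuple[str, int]],
    known_matures: dict[str, str],
    min_reads: int = 10,
    max_shift: int = 2,
    max_mismatch: int = 1,
) -> dict[str, int]:
    """Detect conserved miRNAs directly from reads (no genome required).

    Each read is assigned to at most one known mature (fewest mismatches,
    then fewest end shifts, then lexicographic id); a mature is detected
    when its summed supporting counts reach ``min_reads``. Returns
    {mature id: supporting read count} for detected miRNAs.
    """
    if not known_matures:
        raise ValueError("known_matures must be non-empty")
    matures = {mid: normalize_rna(s) for mid, s in sorted(known_matures.items())}
    support: dict[str, int] = {mid: 0 for mid in matures}
    for seq, count in reads:
        read = normalize_rna(seq)
        best_key = None
        best_id = None
        for mid, mat in matures.items():
            key = _read_vs_mature(read, mat, max_shift, max_mismatch)
            if key is not None and (best_key is None or key < best_key):
                best_key, best_id = key, mid
        if best_id is not None:
            support[best_id] += count
    return {mid: c for mid, c in support.items() if c >= min_reads}
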