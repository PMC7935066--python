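"""Target-site discovery by extensive antisense complementarity.

Cnidarian miRNAs, like plant miRNAs, bind their targets through
near-complete complementarity and direct Argonaute-mediated cleavage.
:func:`scan_transcript` implements the sRNA-mapper-style discovery rules
(free 5' nucleotide, 11-nt seed with a 2-mismatch budget, 2 mismatches
downstream of the seed, last nucleotide may be unpaired), and
:func:`validate_site` re-inspects each hit as a thermodynamic duplex
(RNAhybrid-style) with wobble pairing allowed and a central-pairing
requirement over miRNA positions 9-12, where slicing occurs.

Geometry convention: miRNA position 1 (5' end) pairs the 3'-most
transcript nucleotide of the site window; miRNA position p pairs
transcript coordinate ``start + L - p`` (0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import fold as _fold
from ._seq import GU_PAIRS, WC_PAIRS, normalize_rna
from .fold import BULGED, Duplex, DuplexScoring, MISMATCH, PAIRED_STATES, UNPAIRED_END


@dataclass(frozen=True)
class TargetRuleSet:
    """The five mapper parameters governing site discovery.

    ``free_5prime`` (-c): the miRNA 5' nucleotide need not match;
    ``seed_len`` (-s): seed window, miRNA positions 1..seed_len;
    ``seed_mismatch_max`` (-S) and ``tail_mismatch_max`` (-m): per-region
    mismatch budgets; ``unpaired_3prime`` (-n): number of 3'-terminal
    miRNA nucleotides exempt from pairing.
    """

    free_5prime: bool = True
    seed_len: int = 11
    seed_mismatch_max: int = 2
    tail_mismatch_max: int = 2
    unpaired_3prime: int = 1
    #: treat G:U as a match during scanning (a nucleotide-space mapper does not)
    gu_is_match_scan: bool = False

    def __post_init__(self) -> None:
        if self.seed_len < 1 or self.seed_mismatch_max < 0 or self.tail_mismatch_max < 0:
            raise ValueError("invalid rule set")
        if self.unpaired_3prime < 0:
            raise ValueError("unpaired_3prime must be >= 0")


@dataclass
class TargetSite:
    """An antisense duplex footprint on a transcript.

    ``start``/``end`` are 0-based half-open transcript coordinates
    (length equals the miRNA length at scan stage).
    """

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    seed_mismatches: int
    tail_mismatches: int
    pos1_mismatch: bool
    last_nt_unpaired: bool
    validated: bool | None = None
    duplex: Duplex | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _region_of(pos: int, length: int, rules: TargetRuleSet) -> str:
    """Region of 1-based miRNA position ``pos``: 'pos1', 'seed', 'tail' or 'last'."""
    if pos > length - rules.unpaired_3prime:
        return "last"
    if pos == 1:
        return "pos1"
    if pos <= rules.seed_len:
        return "seed"
    return "tail"


def scan_transcript(
    mirna: str,
    transcript: str,
    rules: TargetRuleSet | None = None,
    mirna_id: str = "mirna",
    transcript_id: str = "transcript",
) -> list[TargetSite]:
    """All windows where the miRNA anneals antisense within the rule budgets.

    Mismatches are Watson-Crick failures (G:U counts as mismatch unless
    ``rules.gu_is_match_scan``); position 1 is exempt under ``free_5prime``
    (charged to the seed budget otherwise) and the last ``unpaired_3prime``
    positions are always exempt. Sites are returned sorted by position.
    """
    rules = rules or TargetRuleSet()
    mi = normalize_rna(mirna)
    tx = normalize_rna(transcript)
    L = len(mi)
    if L <= rules.seed_len:
        raise ValueError("miRNA not longer than the seed window")
    if L < rules.seed_len + rules.unpaired_3prime + 1:
        raise ValueError("miRNA shorter than seed_len + unpaired_3prime + 1")
    if len(tx) < L:
        return []
    matches = WC_PAIRS | GU_PAIRS if rules.gu_is_match_scan else WC_PAIRS
    sites: list[TargetSite] = []
    for start in range(len(tx) - L + 1):
        seed_mm = tail_mm = 0
        pos1_mm = last_unpaired = False
        ok = True
        for p in range(1, L + 1):  # 1-based miRNA position
            t = tx[start + L - p]
            if (mi[p - 1], t) in matches:
                continue
            region = _region_of(p, L, rules)
            if region == "last":
                last_unpaired = True
            elif region == "pos1":
                pos1_mm = True
                if not rules.free_5prime:
                    seed_mm += 1
            elif region == "seed":
                seed_mm += 1
            else:
                tail_mm += 1
            if seed_mm > rules.seed_mismatch_max or tail_mm > rules.tail_mismatch_max:
                ok = False
                break
        if ok:
            sites.append(
                TargetSite(
                    mirna_id=mirna_id,
                    transcript_id=transcript_id,
                    start=start,
                    end=start + L,
                    seed_mismatches=seed_mm,
                    tail_mismatches=tail_mm,
                    pos1_mismatch=pos1_mm,
                    last_nt_unpaired=last_unpaired,
                )
            )
    return sites


def validate_site(
    mirna: str,
    site: TargetSite,
    transcript: str,
    rules: TargetRuleSet | None = None,
    duplex_params: DuplexScoring | None = None,
    flank: int = 3,
    max_bulges: int = 1,
    central_pairing: tuple[int, int] = (9, 12),
    gu_is_match: bool = True,
) -> TargetSite:
    """Duplex-level re-inspection of a candidate site.

    The site window plus ``flank`` nt on each side is hybridized to the
    miRNA; the site is validated iff the duplex states re-satisfy the rule
    budgets (non-paired states charged to their regions, G:U a match by
    default at this stage), carry at most ``max_bulges`` bulged
    nucleotides in total, and miRNA positions ``central_pairing`` (the
    slicer-competent core) are all paired. Returns a copy of the site with
    ``validated`` and ``duplex`` filled in.
    """
    rules = rules or TargetRuleSet()
    mi = normalize_rna(mirna)
    tx = normalize_rna(transcript)
    L = len(mi)
    lo = max(0, site.start - flank)
    hi = min(len(tx), site.end + flank)
    duplex = _fold.duplex_align(mi, tx[lo:hi], duplex_params)
    ok_states = PAIRED_STATES if gu_is_match else frozenset({_fold.PAIRED_WC})
    seed_mm = tail_mm = 0
    bulges = duplex.target_insertions
    valid = True
    for p, state in enumerate(duplex.mirna_states, start=1):
        if state in ok_states:
            continue
        if state == BULGED:
            bulges += 1
        region = _region_of(p, L, rules)
        if region == "last":
            continue
        if region == "pos1":
            if rules.free_5prime:
                continue
            seed_mm += 1
        elif region == "seed":
            seed_mm += 1
        else:
            tail_mm += 1
    if seed_mm > rules.seed_mismatch_max or tail_mm > rules.tail_mismatch_max:
        valid = False
    if bulges > max_bulges:
        valid = False
    c_lo, c_hi = central_pairing
    for p in range(c_lo, c_hi + 1):
        if p <= L and duplex.mirna_states[p - 1] not in PAIRED_STATES:
            valid = False
            break
    return replace(site, validated=valid, duplex=duplex)
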