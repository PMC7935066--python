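"""Degradome (PARE) verification of predicted cleavage targets.

Argonaute-guided slicing cuts the target opposite miRNA positions 10-11,
so the uncapped 3' fragment recovered by degradome sequencing starts at
the transcript nucleotide pairing miRNA position 10. A predicted site is
verified when a degradome read's 5' end maps exactly there: with the site
occupying 0-based half-open ``[start, end)`` and miRNA position 1 pairing
coordinate ``end - 1``, the supporting 5' end is ``end - offset_nt``
(``end - 10`` under the default 10-nt offset).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._seq import normalize_rna
from .targets import TargetSite


@dataclass(frozen=True)
class CleavageRule:
    """Offset rule linking a read 5' end to the site it supports."""

    offset_nt: int = 10
    require_exact: bool = True
    min_supporting_reads: int = 1
    #: tolerance in nt when require_exact is off
    slop_nt: int = 1

    def __post_init__(self) -> None:
        if self.offset_nt < 1:
            raise ValueError("offset_nt must be >= 1")
        if self.min_supporting_reads < 1:
            raise ValueError("min_supporting_reads must be >= 1")


@dataclass
class CleavageEvidence:
    """Degradome support for one site."""

    site: TargetSite
    cleavage_coord: int  # 0-based transcript coordinate of the expected 5' end
    supporting_read_5p_positions: list[int]
    n_supporting: int
    verified: bool


def map_read_5p(read: str, transcript: str, max_mismatch: int = 0) -> list[int]:
    """All sense-strand start coordinates where the read matches the transcript.

    The caller applies a unique-best policy; multi-mapping reads are
    normally discarded as ambiguous.
    """
    r = normalize_rna(read)
    tx = normalize_rna(transcript)
    if len(r) < 10:
        raise ValueError("degradome reads shorter than 10 nt are unreliable")
    hits: list[int] = []
    n, m = len(tx), len(r)
    if max_mismatch == 0:
        start = tx.find(r)
        while start != -1:
            hits.append(start)
            start = tx.find(r, start + 1)
        return hits
    for start in range(n - m + 1):
        mm = 0
        for a, b in zip(r, tx[start : start + m]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append(start)
    return hits


def expected_cleavage_coord(site: TargetSite, rule: CleavageRule | None = None) -> int:
    """Transcript coordinate (0-based) of the 5' end of the sliced 3' fragment."""
    rule = rule or CleavageRule()
    return site.end - rule.offset_nt


def verify_sites(
    sites: list[TargetSite],
    read_5p_positions: dict[str, Counter | dict[int, int] | list[int]],
    rule: CleavageRule | None = None,
) -> list[CleavageEvidence]:
    """Check each site against per-transcript degradome 5'-end positions.

    ``read_5p_positions`` maps transcript id to a multiset of mapped read
    5' ends (list, Counter or {coord: count}). A read supports a site iff
    its 5' end equals the expected cleavage coordinate (within ``slop_nt``
    when ``require_exact`` is off); a site is verified when supporting
    reads reach ``min_supporting_reads``.
    """
    rule = rule or CleavageRule()
    evidence: list[CleavageEvidence] = []
    for site in sites:
        coord = expected_cleavage_coord(site, rule)
        positions = read_5p_positions.get(site.transcript_id, [])
        counts = positions if isinstance(positions, (Counter, dict)) else Counter(positions)
        if rule.require_exact:
            supporting = [coord] * counts.get(coord, 0)
        else:
            supporting = []
            for c in range(coord - rule.slop_nt, coord + rule.slop_nt + 1):
                supporting.extend([c] * counts.get(c, 0))
        n = len(supporting)
        evidence.append(
            CleavageEvidence(
                site=site,
                cleavage_coord=coord,
                supporting_read_5p_positions=supporting,
                n_supporting=n,
                verified=n >= rule.min_supporting_reads,
            )
        )
    return evidence


def map_degradome(
    reads: list[tuple[str, str]],
    transcripts: dict[str, str],
    max_mismatch: int = 0,
    drop_ambiguous: bool = True,
) -> dict[str, Counter]:
    """Map degradome reads to transcripts, returning 5'-end multisets.

    Reads mapping to more than one location (across all transcripts) are
    discarded when ``drop_ambiguous`` (the conservative default);
    otherwise a multi-mapping read is assigned to its first placement
    (transcript insertion order, then smallest coordinate).
    """
    per_tx: dict[str, Counter] = {tid: Counter() for tid in transcripts}
    for _rid, seq in reads:
        placements: list[tuple[str, int]] = []
        for tid, tx in transcripts.items():
            placements.extend((tid, c) for c in map_read_5p(seq, tx, max_mismatch))
        if not placements:
            continue
        if drop_ambiguous and len(placements) > 1:
            continue
        tid, coord = placements[0]
        per_tx[tid][coord] += 1
    return per_tx
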