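"""Cross-species conservation of miRNAs and their target sites.

Covers the comparative layer of the pipeline: reciprocal-best-hit
orthology between transcriptomes, classification of homologous targets
into conserved (category I: same miRNA), shared (category II: different
miRNA, reference miRNA absent from the second repertoire) and
rule-failing (category III) pairs, binding-site region and location
conservation, substitution counting over aligned mature miRNAs,
position-wise nucleotide bias, Dollo-parsimony gain/loss reconstruction
on a species tree, and repertoire turnover rates in genes per million
years.
"""

from __future__ import annotations

import io as _io
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Phylo
from Bio.Align import PairwiseAligner

from ._seq import RNA_LETTERS, normalize_rna
from .targets import TargetRuleSet, TargetSite, validate_site


@dataclass(frozen=True)
class HomologyPair:
    id_A: str
    id_B: str
    score_AB: float
    score_BA: float
    reciprocal: bool
    tie_broken: bool = False


@dataclass
class ConservationRecord:
    ref_target: str
    homolog: str | None
    ref_mirna: str
    other_mirna: str | None
    category: str  # "I", "II", "III" or "none"
    ref_region: str = "unknown"
    other_region: str = "unknown"
    site_location_conserved: bool | None = None
    reason: str = ""


@dataclass
class SubstitutionProfile:
    per_position: dict[int, int]  # 1-based reference position -> count
    total: int
    mode: str
    n_columns: int


@dataclass(frozen=True)
class TurnoverInput:
    repertoire_A: frozenset
    repertoire_B: frozenset
    divergence_window: tuple[float, float]

    def __post_init__(self) -> None:
        t_min, t_max = self.divergence_window
        if not (0 < t_min <= t_max):
            raise ValueError("divergence window must satisfy 0 < t_min <= t_max")


def _local_aligner(match: float = 2, mismatch: float = -1, gap_open: float = -5, gap_extend: float = -2) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    # transcript ends may be ragged between assemblies; do not punish them
    aligner.end_gap_score = 0
    return aligner


def reciprocal_best_hits(
    transcriptome_A: dict[str, str],
    transcriptome_B: dict[str, str],
    aligner: PairwiseAligner | None = None,
) -> list[HomologyPair]:
    """Reciprocal best hits by local-alignment score.

    One pair is reported per A-side query (its best B hit, ties broken by
    lexicographic id and flagged); ``reciprocal`` marks pairs whose bests
    agree both ways.
    """
    if not transcriptome_A or not transcriptome_B:
        raise ValueError("both transcriptomes must be non-empty")
    aligner = aligner or _local_aligner()
    a_seqs = {k: normalize_rna(v) for k, v in transcriptome_A.items()}
    b_seqs = {k: normalize_rna(v) for k, v in transcriptome_B.items()}
    scores: dict[tuple[str, str], float] = {}
    for ida, sa in a_seqs.items():
        for idb, sb in b_seqs.items():
            scores[(ida, idb)] = float(aligner.score(sa, sb))

    def best_of(ids, other_ids, key) -> tuple[dict[str, str], set[str]]:
        best: dict[str, str] = {}
        ties: set[str] = set()
        for q in ids:
            ranked = sorted(other_ids, key=lambda o: (-scores[key(q, o)], o))
            best[q] = ranked[0]
            if len(ranked) > 1 and scores[key(q, ranked[0])] == scores[key(q, ranked[1])]:
                ties.add(q)
        return best, ties

    best_a, ties_a = best_of(sorted(a_seqs), sorted(b_seqs), lambda q, o: (q, o))
    best_b, _ = best_of(sorted(b_seqs), sorted(a_seqs), lambda q, o: (o, q))
    pairs = []
    for ida in sorted(a_seqs):
        idb = best_a[ida]
        pairs.append(
            HomologyPair(
                id_A=ida,
                id_B=idb,
                score_AB=scores[(ida, idb)],
                score_BA=scores[(ida, idb)],
                reciprocal=best_b[idb] == ida,
                tie_broken=ida in ties_a,
            )
        )
    return pairs


def rbh_from_table(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame) -> list[HomologyPair]:
    """RBH from precomputed tabular hits (BLAST outfmt-6-like).

    Expects columns ``query``, ``subject``, ``score``; for real-data use
    where an external aligner produced the hits.
    """
    def best(df: pd.DataFrame) -> dict[str, str]:
        d = df.sort_values(["query", "score", "subject"], ascending=[True, False, True])
        return d.groupby("query", sort=True).first()["subject"].to_dict()

    best_ab, best_ba = best(hits_ab), best(hits_ba)
    score_ab = {(r.query, r.subject): r.score for r in hits_ab.itertuples()}
    pairs = []
    for ida in sorted(best_ab):
        idb = best_ab[ida]
        pairs.append(
            HomologyPair(
                id_A=ida, id_B=idb, score_AB=float(score_ab[(ida, idb)]),
                score_BA=float(score_ab[(ida, idb)]),
                reciprocal=best_ba.get(idb) == ida,
            )
        )
    return pairs


def reciprocal_map(pairs: list[HomologyPair]) -> dict[str, str]:
    """A-side id -> B-side id for reciprocal pairs only."""
    return {p.id_A: p.id_B for p in pairs if p.reciprocal}


def classify_conservation(
    reference_records: list[tuple[str, str]],
    rbh: list[HomologyPair],
    other_sites: list[TargetSite],
    other_repertoire: set[str],
) -> list[ConservationRecord]:
    """Label each verified reference (miRNA, target) pair I / II / III / none.

    Category I: the same miRNA family has a validated site on the
    reciprocal homolog. Category II: a different miRNA has a validated
    site there and the reference miRNA is absent from the other species'
    repertoire. Category III: a candidate site exists on the homolog but
    failed duplex validation.
    """
    homolog_of = reciprocal_map(rbh)
    by_tx: dict[str, list[TargetSite]] = {}
    for s in other_sites:
        by_tx.setdefault(s.transcript_id, []).append(s)
    records = []
    for ref_mirna, ref_target in reference_records:
        homolog = homolog_of.get(ref_target)
        if homolog is None:
            records.append(
                ConservationRecord(
                    ref_target=ref_target, homolog=None, ref_mirna=ref_mirna,
                    other_mirna=None, category="none", reason="no_homolog",
                )
            )
            continue
        sites = by_tx.get(homolog, [])
        same_valid = [s for s in sites if s.mirna_id == ref_mirna and s.validated]
        diff_valid = sorted(
            (s for s in sites if s.mirna_id != ref_mirna and s.validated),
            key=lambda s: (s.mirna_id, s.start),
        )
        if same_valid:
            cat, other_mirna, reason = "I", ref_mirna, ""
        elif diff_valid and ref_mirna not in other_repertoire:
            cat, other_mirna, reason = "II", diff_valid[0].mirna_id, ""
        elif sites:
            cat, other_mirna, reason = "III", None, "candidate_failed_validation"
        else:
            cat, other_mirna, reason = "none", None, "no_candidate_site"
        records.append(
            ConservationRecord(
                ref_target=ref_target, homolog=homolog, ref_mirna=ref_mirna,
                other_mirna=other_mirna, category=cat, reason=reason,
            )
        )
    return records


def annotate_site_region(site: TargetSite, cds: tuple[int, int] | None) -> str:
    """5'UTR / CDS / 3'UTR call for a site given a CDS interval (0-based half-open).

    Any overlap with the CDS annotates as CDS: coding-sequence placement
    is the biologically meaningful case for these sites.
    """
    if cds is None:
        return "unknown"
    cds_start, cds_end = cds
    if site.end <= cds_start:
        return "5'UTR"
    if site.start >= cds_end:
        return "3'UTR"
    return "CDS"


@dataclass
class LocationCheck:
    conserved: bool
    reason: str = ""
    projected_midpoint: int | None = None

    def __bool__(self) -> bool:  # usable directly as the flag
        return self.conserved


def _project_coord(blocks, coord: int) -> int:
    """Map a coordinate on sequence A through aligned blocks to sequence B."""
    prev_b_end = 0
    for (a0, a1), (b0, b1) in blocks:
        if coord < a0:
            return b0  # in a gap before this block: snap to block start
        if coord < a1:
            return b0 + (coord - a0)
        prev_b_end = b1
    return prev_b_end


def project_interval(
    transcript_a: str, transcript_b: str, interval: tuple[int, int],
    aligner: PairwiseAligner | None = None,
) -> tuple[int, int]:
    """Project a 0-based half-open interval from transcript A onto B
    through a global alignment of the two transcripts."""
    aligner = aligner or _global_aligner()
    aln = aligner.align(normalize_rna(transcript_a), normalize_rna(transcript_b))[0]
    blocks = list(zip(aln.aligned[0].tolist(), aln.aligned[1].tolist()))
    a, b = interval
    pa = _project_coord(blocks, a)
    pb = _project_coord(blocks, max(a, b - 1)) + 1
    if pb <= pa:
        pb = pa + (b - a)
    return (pa, min(pb, len(transcript_b)))


def site_location_conserved(
    site_a: TargetSite,
    site_b: TargetSite,
    transcript_a: str,
    transcript_b: str,
    tolerance: int = 30,
    cds_a: tuple[int, int] | None = None,
    cds_b: tuple[int, int] | None = None,
    score_floor_fraction: float = 0.25,
) -> LocationCheck:
    """Do two homologous sites sit in the same place on their transcripts?

    True iff the annotated regions match (when CDS intervals are supplied)
    and the midpoint of site A, projected through a global alignment of
    the transcripts, lies within ``tolerance`` nt of site B's midpoint.
    """
    ta, tb = normalize_rna(transcript_a), normalize_rna(transcript_b)
    aligner = _global_aligner()
    score = float(aligner.score(ta, tb))
    floor = score_floor_fraction * 2 * min(len(ta), len(tb))
    if score < floor:
        return LocationCheck(False, reason="unalignable_pair")
    if cds_a is not None and cds_b is not None:
        if annotate_site_region(site_a, cds_a) != annotate_site_region(site_b, cds_b):
            return LocationCheck(False, reason="region_mismatch")
    mid_a = (site_a.start + site_a.end) // 2
    aln = aligner.align(ta, tb)[0]
    blocks = list(zip(aln.aligned[0].tolist(), aln.aligned[1].tolist()))
    projected = _project_coord(blocks, mid_a)
    mid_b = (site_b.start + site_b.end) // 2
    if abs(projected - mid_b) <= tolerance:
        return LocationCheck(True, projected_midpoint=projected)
    return LocationCheck(False, reason="midpoints_too_far", projected_midpoint=projected)


def candidate_homolog_sites(
    ref_sites: list[TargetSite],
    ref_transcripts: dict[str, str],
    other_transcripts: dict[str, str],
    rbh: list[HomologyPair],
    matures: dict[str, str],
    rules: TargetRuleSet | None = None,
) -> list[TargetSite]:
    """Project each verified reference site onto its homolog and validate it.

    This recovers candidate sites that mutation pushed outside the scan
    budgets: the window homologous to a real site is still inspected as a
    duplex, and a failing one becomes category III feedstock.
    """
    rules = rules or TargetRuleSet()
    homolog_of = reciprocal_map(rbh)
    out = []
    for site in ref_sites:
        homolog = homolog_of.get(site.transcript_id)
        if homolog is None or site.mirna_id not in matures:
            continue
        tx_b = other_transcripts[homolog]
        pa, pb = project_interval(
            ref_transcripts[site.transcript_id], tx_b, site.interval
        )
        L = site.end - site.start
        start = max(0, min(pa, len(tx_b) - L))
        cand = TargetSite(
            mirna_id=site.mirna_id, transcript_id=homolog,
            start=start, end=start + L,
            seed_mismatches=0, tail_mismatches=0,
            pos1_mismatch=False, last_nt_unpaired=False,
        )
        out.append(validate_site(matures[site.mirna_id], cand, tx_b, rules))
    return out


# ---------------------------------------------------------------------------
# Mature-sequence evolution statistics
# ---------------------------------------------------------------------------


@dataclass
class OffsetAlignment:
    """Ungapped offset alignment of mature miRNAs against a reference.

    ``offsets[name]`` is the shift of that sequence relative to the
    reference: reference position r aligns sequence index ``r - offset``.
    """

    reference: str
    seqs: dict[str, str]
    offsets: dict[str, int]
    identities: dict[str, float]

    def columns(self) -> list[tuple[int, list[str]]]:
        """Full-coverage columns: (1-based reference position, column letters)."""
        ref_len = len(self.seqs[self.reference])
        cols = []
        for r in range(ref_len):
            letters = []
            for name, s in self.seqs.items():
                i = r - self.offsets[name]
                if not 0 <= i < len(s):
                    break
                letters.append(s[i])
            else:
                cols.append((r + 1, letters))
        return cols


def align_orthologs(
    matures: dict[str, str], reference: str, max_offset: int = 2
) -> OffsetAlignment:
    """Assign each sequence the integer offset maximizing identity to the reference.

    Ties prefer the smaller |offset|, then the smaller offset. The identity
    achieved is reported so callers can flag dubious family assignments.
    """
    if len(matures) < 2:
        raise ValueError("need at least two sequences")
    if reference not in matures:
        raise ValueError(f"reference {reference!r} not among the sequences")
    seqs = {k: normalize_rna(v) for k, v in matures.items()}
    ref = seqs[reference]
    offsets: dict[str, int] = {}
    identities: dict[str, float] = {}
    for name, s in seqs.items():
        best = None
        for off in range(-max_offset, max_offset + 1):
            matches = overlap = 0
            for r in range(len(ref)):
                i = r - off
                if 0 <= i < len(s):
                    overlap += 1
                    matches += ref[r] == s[i]
            if overlap == 0:
                continue
            key = (-matches, abs(off), off)
            if best is None or key < best[0]:
                best = (key, off, matches / overlap)
        offsets[name] = best[1]
        identities[name] = best[2]
    return OffsetAlignment(reference=reference, seqs=seqs, offsets=offsets, identities=identities)


def flag_divergent_members(alignment: OffsetAlignment, ceiling: float = 0.6) -> list[str]:
    """Names whose identity to the reference falls below the ceiling —
    likely mis-assigned family members."""
    return sorted(n for n, ident in alignment.identities.items() if ident < ceiling)


def count_substitutions(
    alignment: OffsetAlignment | list[str],
    mode: str = "distinct_minus_one",
) -> SubstitutionProfile:
    """Per-column substitution counts over an ortholog alignment.

    ``distinct_minus_one``: number of distinct nucleotides minus one;
    ``non_modal_count``: number of sequences differing from the plurality
    nucleotide (ties broken lexicographically). Only full-coverage columns
    are counted.
    """
    if mode not in ("distinct_minus_one", "non_modal_count"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(alignment, OffsetAlignment):
        cols = alignment.columns()
    else:
        seqs = [normalize_rna(s) for s in alignment]
        if len(seqs) < 2:
            raise ValueError("need at least two sequences")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("plain sequence lists must be pre-aligned to equal length")
        cols = [(r + 1, [s[r] for s in seqs]) for r in range(len(seqs[0]))]
    per_position: dict[int, int] = {}
    for pos, letters in cols:
        if mode == "distinct_minus_one":
            c = len(set(letters)) - 1
        else:
            counts = Counter(letters)
            top = max(counts.values())
            modal = min(b for b, n in counts.items() if n == top)
            c = sum(n for b, n in counts.items() if b != modal)
        per_position[pos] = c
    return SubstitutionProfile(
        per_position=per_position,
        total=sum(per_position.values()),
        mode=mode,
        n_columns=len(per_position),
    )


def position_bias(matures: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-position nucleotide frequency matrix and information content.

    Ragged 3' ends are allowed; each column is normalized by its coverage.
    Information content is ``2 - H`` bits per column (H = Shannon entropy).
    """
    seqs = [normalize_rna(s) for s in matures]
    if not seqs:
        raise ValueError("need at least one sequence")
    L = max(len(s) for s in seqs)
    counts = np.zeros((4, L))
    idx = {b: i for i, b in enumerate(RNA_LETTERS)}
    for s in seqs:
        for p, b in enumerate(s):
            counts[idx[b], p] += 1
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=0)
    pfm = pd.DataFrame(freqs, index=list(RNA_LETTERS), columns=range(1, L + 1))
    return pfm, info


# ---------------------------------------------------------------------------
# Gain/loss reconstruction and turnover
# ---------------------------------------------------------------------------


@dataclass
class DolloResult:
    """Dollo-parsimony reconstruction over a rooted species tree."""

    gain_node: dict[str, str]  # miRNA -> node name where it arose
    loss_edges: dict[str, list[str]]  # miRNA -> child-node names of loss edges
    gains_per_node: dict[str, int]
    losses_per_node: dict[str, int]
    shared_per_node: dict[str, int]  # internal nodes: #miRNAs present
    presence: dict[str, set[str]]  # miRNA -> node names where present
    skipped: list[str]


def _load_tree(tree):
    if isinstance(tree, str):
        handle = _io.StringIO(tree) if tree.lstrip().startswith("(") else open(tree)
        with handle:
            return Phylo.read(handle, "newick")
    return tree


def dollo_reconstruct(presence: pd.DataFrame, tree) -> DolloResult:
    """Single-gain/multiple-loss reconstruction of miRNA family history.

    ``presence`` has miRNA families as rows, species as columns, values
    0/1; ``tree`` is a rooted newick string/path or a Bio.Phylo tree whose
    leaves cover the matrix species. The gain node of a family is the MRCA
    of its possessors; the family is present at every node on a path from
    the gain to a possessor; losses are the edges where presence ends.
    """
    t = _load_tree(tree)
    leaves = {leaf.name for leaf in t.get_terminals()}
    missing = set(presence.columns) - leaves
    if missing:
        raise ValueError(f"species absent from the tree: {sorted(missing)}")
    counter = 0
    for clade in t.find_clades():
        if not clade.name:
            counter += 1
            clade.name = f"node{counter}"
    parents = {}
    for clade in t.find_clades():
        for child in clade.clades:
            parents[child.name] = clade.name
    subtree_leaves = {
        clade.name: {leaf.name for leaf in clade.get_terminals()}
        for clade in t.find_clades()
    }
    descendants = {
        clade.name: {c.name for c in clade.find_clades()} for clade in t.find_clades()
    }
    internal = [c.name for c in t.get_nonterminals()]
    all_nodes = [c.name for c in t.find_clades()]

    gain_node: dict[str, str] = {}
    loss_edges: dict[str, list[str]] = {}
    presence_nodes: dict[str, set[str]] = {}
    skipped: list[str] = []
    for mirna, row in presence.iterrows():
        possessors = {sp for sp in presence.columns if row[sp]}
        if not possessors:
            warnings.warn(f"{mirna}: absent from every species, skipped", stacklevel=2)
            skipped.append(str(mirna))
            continue
        if len(possessors) == 1:
            gain = next(iter(possessors))
        else:
            gain = t.common_ancestor(sorted(possessors)).name
        present = {
            n for n in descendants[gain] if subtree_leaves[n] & possessors
        }
        losses = [
            n for n in all_nodes
            if n not in present and parents.get(n) in present
        ]
        gain_node[str(mirna)] = gain
        loss_edges[str(mirna)] = sorted(losses)
        presence_nodes[str(mirna)] = present
    gains_per_node = Counter(gain_node.values())
    losses_per_node: Counter = Counter()
    for losses in loss_edges.values():
        losses_per_node.update(losses)
    shared = {
        n: sum(1 for pres in presence_nodes.values() if n in pres) for n in internal
    }
    return DolloResult(
        gain_node=gain_node,
        loss_edges=loss_edges,
        gains_per_node={n: gains_per_node.get(n, 0) for n in all_nodes},
        losses_per_node={n: losses_per_node.get(n, 0) for n in all_nodes},
        shared_per_node=shared,
        presence=presence_nodes,
        skipped=skipped,
    )


def turnover_rate(inp: TurnoverInput, per_lineage: bool = False) -> tuple[float, float]:
    """miRNA gain+loss rate window in genes per million years.

    ``D`` = size of the symmetric difference of the two repertoires;
    returns ``(D / t_max, D / t_min)``. ``per_lineage`` halves the rate to
    express it per descending lineage rather than over the summed path.
    """
    a, b = set(inp.repertoire_A), set(inp.repertoire_B)
    d = len(a ^ b)
    if d == 0:
        return (0.0, 0.0)
    t_min, t_max = inp.divergence_window
    scale = 0.5 if per_lineage else 1.0
    return (scale * d / t_max, scale * d / t_min)
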