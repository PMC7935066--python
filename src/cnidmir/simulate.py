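"""Synthetic inputs with ground truth known by construction.

Every input the pipeline consumes can be generated here: hairpin
precursors with configurable duplex overhangs, read stacks with a tunable
5'-homogeneity fraction, transcripts with target sites planted at exact
per-region mismatch budgets, degradome reads whose 5' ends mark planted
cleavage positions, ortholog transcripts under substitution/indel
processes, and mature-miRNA families with per-position substitution
counts known by construction. Identical seeds give byte-identical
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import FOLD_PAIRS, RNA_LETTERS, normalize_rna, random_rna, revcomp
from . import fold as _fold
from .curation import DuplexGeometry, PrecursorCandidate, ReadStack, duplex_geometry
from .targets import TargetRuleSet, TargetSite, validate_site


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs shared by the generators; rates are per-site probabilities."""

    rng_seed: int = 0
    transcript_length: int = 300
    n_transcripts: int = 10
    substitution_rate: float = 0.05
    indel_rate: float = 0.01
    degradome_read_length: int = 20
    noise_reads: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.transcript_length < 1 or self.degradome_read_length < 1:
            raise ValueError("lengths must be positive")
        if self.n_transcripts < 0 or self.noise_reads < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MismatchSpec:
    """Planted mismatch counts per rule region (pos1, seed, tail, last-nt)."""

    pos1: int = 0
    seed: int = 0
    tail: int = 0
    last: int = 0

    def within(self, rules: TargetRuleSet) -> bool:
        """True when a site planted with this spec must be emitted by the scanner."""
        seed_charge = self.seed + (0 if rules.free_5prime else self.pos1)
        return seed_charge <= rules.seed_mismatch_max and self.tail <= rules.tail_mismatch_max


@dataclass
class PlantedSite:
    transcript_id: str
    interval: tuple[int, int]
    mirna_id: str
    mismatch_spec: MismatchSpec


@dataclass
class PlantedTruth:
    """Everything the generators decided, for checking recovery downstream."""

    sites: list[PlantedSite] = field(default_factory=list)
    cleavage_positions: list[tuple[str, int]] = field(default_factory=list)
    ortholog_map: dict[str, str] = field(default_factory=dict)
    per_position_substitutions: dict[int, int] = field(default_factory=dict)

    def intervals_on(self, transcript_id: str) -> list[tuple[int, int]]:
        return [s.interval for s in self.sites if s.transcript_id == transcript_id]


def make_hairpin(
    mature: str,
    loop_len: int = 8,
    star_3p_overhang: int = 2,
    seed: int = 0,
    candidate_id: str = "hairpin",
    upstream_score: float | None = None,
    species: str = "",
) -> PrecursorCandidate:
    """Build a precursor hairpin: 5' arm = mature, loop, 3' arm = star.

    The star strand is the reverse complement of the mature minus its
    first ``star_3p_overhang`` nucleotides, extended by that many
    non-pairing tail nucleotides, so that the folded duplex shows exactly
    the requested star 3' overhang and ``len(mature) - star_3p_overhang``
    mature/star pairs. The construction is verified on the actual fold and
    raises if the mature's 5' end makes a clean overhang impossible.
    """
    mat = normalize_rna(mature)
    if len(mat) < 16:
        raise ValueError("mature must be at least 16 nt")
    if loop_len < 3:
        raise ValueError("loop_len < 3 gives an unfoldable hairpin")
    if star_3p_overhang < 0:
        raise ValueError("star_3p_overhang must be >= 0")
    k = star_3p_overhang
    rng = np.random.default_rng(seed)
    prefix = set(mat[:k])
    tail = []
    for _ in range(k):
        allowed = [
            b for b in RNA_LETTERS if all((b, p) not in FOLD_PAIRS for p in prefix)
        ]
        if not allowed:
            raise ValueError(
                "mature 5' end contains both G and U; no overhang tail letter can "
                "be guaranteed unpaired — use a different mature"
            )
        tail.append(allowed[rng.integers(len(allowed))])
    loop = "A" * loop_len
    star = revcomp(mat[k:]) + "".join(tail)
    precursor = mat + loop + star
    m_iv = (0, len(mat))
    s_iv = (len(mat) + loop_len, len(precursor))
    cand = PrecursorCandidate(
        id=candidate_id,
        precursor_seq=precursor,
        mature_interval=m_iv,
        star_interval=s_iv,
        upstream_score=upstream_score,
        species=species,
    )
    geom = duplex_geometry(cand, _fold.fold_nussinov(precursor), anchor_scan=max(2, k))
    if geom.star_3p_overhang != k or geom.mature_star_pairs != len(mat) - k:
        raise ValueError(
            f"hairpin construction failed geometry check for {candidate_id}: "
            f"got overhang {geom.star_3p_overhang}, pairs {geom.mature_star_pairs}"
        )
    return cand


def make_read_stack(
    candidate: PrecursorCandidate,
    n_reads: int = 20,
    five_prime_fraction: float = 0.9,
    seed: int = 0,
) -> ReadStack:
    """A read stack with the requested 5'-homogeneity fraction.

    ``round_half_up(n_reads * five_prime_fraction)`` reads start at the
    mature 5' position; the remainder are shifted by +-1 or +-2 nt
    (uniform, seeded, restricted to non-negative starts).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= five_prime_fraction <= 1:
        raise ValueError("five_prime_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ms, me = candidate.mature_interval
    length = me - ms
    n_exact = int(np.floor(n_reads * five_prime_fraction + 0.5))
    n_exact = min(n_exact, n_reads)
    counts: dict[tuple[int, int], int] = {}
    if n_exact:
        counts[(ms, length)] = n_exact
    shifts = [s for s in (-2, -1, 1, 2) if ms + s >= 0]
    for _ in range(n_reads - n_exact):
        s = shifts[rng.integers(len(shifts))]
        key = (ms + s, length)
        counts[key] = counts.get(key, 0) + 1
    entries = [(start, ln, c) for (start, ln), c in sorted(counts.items())]
    return ReadStack(entries=entries)


def _region_positions(L: int, rules: TargetRuleSet) -> dict[str, list[int]]:
    """1-based miRNA positions per rule region."""
    n = rules.unpaired_3prime
    return {
        "pos1": [1],
        "seed": list(range(2, rules.seed_len + 1)),
        "tail": list(range(rules.seed_len + 1, L - n + 1)),
        "last": list(range(L - n + 1, L + 1)),
    }


def plant_target_site(
    transcript: str,
    mirna: str,
    mismatch_spec: MismatchSpec = MismatchSpec(),
    position: int = 0,
    seed: int = 0,
    rules: TargetRuleSet | None = None,
    transcript_id: str = "t1",
    mirna_id: str = "mirna",
    truth: PlantedTruth | None = None,
) -> tuple[str, PlantedTruth]:
    """Replace a window with the miRNA's antisense site plus exact mismatches.

    The interval ``[position, position + len(mirna))`` becomes the reverse
    complement of the miRNA, then exactly the requested number of hard
    mismatches (neither Watson-Crick nor wobble) is injected at seeded
    random positions inside each region. Raises if the interval overlaps a
    previously planted site recorded in ``truth``.
    """
    rules = rules or TargetRuleSet()
    tx = list(normalize_rna(transcript))
    mi = normalize_rna(mirna)
    L = len(mi)
    if position < 0 or position + L > len(tx):
        raise ValueError("site does not fit inside the transcript")
    truth = truth if truth is not None else PlantedTruth()
    for a, b in truth.intervals_on(transcript_id):
        if position < b and position + L > a:
            raise ValueError(f"planted site would overlap existing site [{a}, {b})")
    rng = np.random.default_rng(seed)
    tx[position : position + L] = list(revcomp(mi))
    regions = _region_positions(L, rules)
    wanted = {
        "pos1": mismatch_spec.pos1,
        "seed": mismatch_spec.seed,
        "tail": mismatch_spec.tail,
        "last": mismatch_spec.last,
    }
    for region, count in wanted.items():
        pool = regions[region]
        if count > len(pool):
            raise ValueError(f"{count} mismatches requested in region {region!r} of size {len(pool)}")
        if count == 0:
            continue
        chosen = rng.choice(pool, size=count, replace=False)
        for p in sorted(int(q) for q in chosen):
            m_nt = mi[p - 1]
            bad = [b for b in RNA_LETTERS if (m_nt, b) not in FOLD_PAIRS]
            coord = position + L - p
            # avoid silently leaving the complementary letter in place
            bad = [b for b in bad if b != tx[coord]] or bad
            tx[coord] = bad[rng.integers(len(bad))]
    truth.sites.append(
        PlantedSite(
            transcript_id=transcript_id,
            interval=(position, position + L),
            mirna_id=mirna_id,
            mismatch_spec=mismatch_spec,
        )
    )
    return "".join(tx), truth


def make_degradome_reads(
    transcript: str,
    site: TargetSite | PlantedSite,
    n_signal: int = 5,
    n_noise: int = 0,
    read_len: int = 20,
    seed: int = 0,
    offset_nt: int = 10,
    truth: PlantedTruth | None = None,
    read_prefix: str = "read",
) -> tuple[list[tuple[str, str]], PlantedTruth]:
    """Degradome reads marking a planted cleavage position plus uniform noise.

    Signal reads are exact substrings starting at the transcript
    coordinate pairing miRNA position ``offset_nt`` of the site (the
    sliced 3' fragment's 5' end); noise reads start uniformly at random.
    """
    tx = normalize_rna(transcript)
    interval = site.interval if hasattr(site, "interval") else site
    end = interval[1]
    cleavage = end - offset_nt
    if cleavage < 0 or cleavage + read_len > len(tx):
        raise ValueError("read_len exceeds distance from cleavage position to transcript 3' end")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    for i in range(n_signal):
        reads.append((f"{read_prefix}_sig{i}", tx[cleavage : cleavage + read_len]))
    for i in range(n_noise):
        start = int(rng.integers(0, len(tx) - read_len + 1))
        reads.append((f"{read_prefix}_noise{i}", tx[start : start + read_len]))
    truth = truth if truth is not None else PlantedTruth()
    tid = getattr(site, "transcript_id", "t1")
    truth.cleavage_positions.append((tid, cleavage))
    return reads, truth


def make_ortholog_transcript(
    transcript: str,
    config: SimulationConfig,
    preserve_site: bool = True,
    seed: int = 0,
    site_intervals: tuple[tuple[int, int], ...] = (),
) -> tuple[str, list[tuple[int, int]]]:
    """Evolve a transcript by i.i.d. substitutions and 1-nt indels.

    Indels never fall inside planted sites (so mismatch truth stays
    countable); substitutions skip sites only when ``preserve_site``.
    Returns the evolved sequence and the planted intervals mapped through
    the indels.
    """
    tx = normalize_rna(transcript)
    rng = np.random.default_rng(seed)
    in_site = [False] * len(tx)
    for a, b in site_intervals:
        for i in range(a, b):
            in_site[i] = True
    out: list[str] = []
    starts = {a: None for a, _ in site_intervals}
    ends = {b: None for _, b in site_intervals}
    letters = list(RNA_LETTERS)
    for i, ch in enumerate(tx):
        if i in starts:
            starts[i] = len(out)
        if i in ends:
            ends[i] = len(out)
        if not in_site[i] and rng.random() < config.indel_rate:
            if rng.random() < 0.5:  # deletion
                continue
            out.append(letters[rng.integers(4)])  # insertion before i
        if (not preserve_site or not in_site[i]) and rng.random() < config.substitution_rate:
            others = [b for b in letters if b != ch]
            out.append(others[rng.integers(3)])
        else:
            out.append(ch)
    if len(tx) in ends:
        ends[len(tx)] = len(out)
    mapped = [(starts[a], ends[b]) for a, b in site_intervals]
    return "".join(out), mapped


def make_mature_family(
    mature: str,
    n_orthologs: int,
    n_substitutions: int,
    seed: int = 0,
) -> tuple[list[str], dict[int, int]]:
    """An orthologous mature set with known per-position substitution counts.

    Each substitution hits a distinct position (at most one per alignment
    column) in a random non-reference sequence, so both substitution
    counting conventions see exactly one change per hit column.
    Returns (sequences incl. reference first, {1-based position: count}).
    """
    mat = normalize_rna(mature)
    if n_orthologs < 2:
        raise ValueError("need at least two sequences")
    if n_substitutions > len(mat):
        raise ValueError("at most one substitution per position is supported")
    rng = np.random.default_rng(seed)
    seqs = [list(mat) for _ in range(n_orthologs)]
    positions = rng.choice(len(mat), size=n_substitutions, replace=False)
    per_position: dict[int, int] = {}
    for p in sorted(int(q) for q in positions):
        which = int(rng.integers(1, n_orthologs))
        others = [b for b in RNA_LETTERS if b != mat[p]]
        seqs[which][p] = others[rng.integers(3)]
        per_position[p + 1] = 1
    return ["".join(s) for s in seqs], per_position


# ---------------------------------------------------------------------------
# Whole-study scenario
# ---------------------------------------------------------------------------


@dataclass
class TargetPlan:
    """Truth row for one reference target in a species scenario."""

    ref_transcript: str
    other_transcript: str
    ref_mirna: str
    other_mirna: str | None
    category: str  # "I", "II" or "III"


@dataclass
class SpeciesScenario:
    """A full two-species fixture set with truth known by construction."""

    families: list[str]
    matures: dict[str, str]
    repertoires: dict[str, dict[str, str]]  # species -> {family: mature seq}
    precursors: dict[str, dict[str, PrecursorCandidate]]
    read_stacks: dict[str, dict[str, ReadStack]]
    transcripts: dict[str, dict[str, str]]  # species -> {tid: seq}
    cds: dict[str, dict[str, tuple[int, int]]]
    degradome_reads: dict[str, list[tuple[str, str]]]
    plan: list[TargetPlan]
    truth: PlantedTruth
    rules: TargetRuleSet


def _scenario_mature(rng: np.random.Generator, length: int = 22) -> str:
    """A mature with the field's position-1 U bias and a hairpin-safe 5' end."""
    second = "AC"[rng.integers(2)]
    rest = random_rna(rng, length - 2)
    return "U" + second + rest


def make_species_scenario(
    n_mirnas: int = 6,
    n_targets: int = 3,
    category_plan: tuple[str, ...] = ("I", "II", "III"),
    seed: int = 0,
    config: SimulationConfig | None = None,
    n_decoys: int = 3,
    rules: TargetRuleSet | None = None,
    species: tuple[str, str] = ("A", "B"),
    n_signal_reads: int = 3,
) -> SpeciesScenario:
    """Emit a two-species fixture whose pipeline run reproduces ``category_plan``.

    Category I targets carry the same miRNA's intact site in both species;
    category II targets carry a different miRNA's valid site in the second
    species, whose repertoire lacks the reference miRNA; category III
    targets carry a homologous site degraded beyond the duplex rules.
    """
    if len(category_plan) != n_targets:
        raise ValueError("category_plan length must equal n_targets")
    bad = set(category_plan) - {"I", "II", "III"}
    if bad:
        raise ValueError(f"unknown categories in plan: {sorted(bad)}")
    n_cat2 = sum(1 for c in category_plan if c == "II")
    if n_mirnas < n_targets + n_cat2:
        raise ValueError("need n_mirnas >= n_targets + number of category II targets")
    config = config or SimulationConfig()
    rules = rules or TargetRuleSet()
    rng = np.random.default_rng(seed)
    sp_a, sp_b = species

    families = [f"mir-{i + 1}" for i in range(n_mirnas)]
    matures: dict[str, str] = {}
    precursors: dict[str, PrecursorCandidate] = {}
    for fam in families:
        for attempt in range(50):
            cand_mature = _scenario_mature(rng)
            try:
                precursors[fam] = make_hairpin(
                    cand_mature, seed=int(rng.integers(2**31)), candidate_id=fam
                )
            except ValueError:
                continue
            matures[fam] = cand_mature
            break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError(f"could not construct a hairpin for {fam}")

    # assign miRNAs to targets; category II targets get a replacement miRNA
    ref_fams = families[:n_targets]
    spare = iter(families[n_targets:])
    other_fams = {
        i: next(spare) if cat == "II" else ref_fams[i]
        for i, cat in enumerate(category_plan)
    }
    withheld = {ref_fams[i] for i, cat in enumerate(category_plan) if cat == "II"}
    repertoires = {
        sp_a: dict(matures),
        sp_b: {f: s for f, s in matures.items() if f not in withheld},
    }

    L_tx = config.transcript_length
    transcripts: dict[str, dict[str, str]] = {sp_a: {}, sp_b: {}}
    cds: dict[str, dict[str, tuple[int, int]]] = {sp_a: {}, sp_b: {}}
    truth = PlantedTruth()
    plan: list[TargetPlan] = []
    degradome: list[tuple[str, str]] = []

    read_len = config.degradome_read_length
    for i, cat in enumerate(category_plan):
        fam = ref_fams[i]
        mi = matures[fam]
        L = len(mi)
        tid_a = f"{sp_a}_t{i + 1}"
        tid_b = f"{sp_b}_t{i + 1}"
        base = random_rna(rng, L_tx)
        pos = int(rng.integers(60, L_tx - L - read_len - 20))
        seq_a, truth = plant_target_site(
            base, mi, MismatchSpec(), pos, seed=int(rng.integers(2**31)),
            rules=rules, transcript_id=tid_a, mirna_id=fam, truth=truth,
        )
        transcripts[sp_a][tid_a] = seq_a
        cds[sp_a][tid_a] = (30, L_tx - 30)
        site = next(s for s in truth.sites if s.transcript_id == tid_a)
        reads, truth = make_degradome_reads(
            seq_a, site, n_signal=n_signal_reads, n_noise=config.noise_reads,
            read_len=read_len, seed=int(rng.integers(2**31)), truth=truth,
            read_prefix=f"deg_{tid_a}",
        )
        degradome.extend(reads)

        seq_b, mapped = make_ortholog_transcript(
            seq_a, config, preserve_site=True, seed=int(rng.integers(2**31)),
            site_intervals=(site.interval,),
        )
        (b_start, b_end) = mapped[0]
        sb = list(seq_b)
        other_fam: str | None = fam
        if cat == "I":
            truth.sites.append(PlantedSite(tid_b, (b_start, b_end), fam, MismatchSpec()))
        elif cat == "II":
            other_fam = other_fams[i]
            mi2 = matures[other_fam]
            # destroy the inherited site, then plant the replacement elsewhere
            sb[b_start:b_end] = list(random_rna(rng, b_end - b_start))
            seq_b = "".join(sb)
            pos2_lo, pos2_hi = 20, b_start - len(mi2) - 5
            if pos2_hi <= pos2_lo:
                pos2_lo, pos2_hi = b_end + 5, len(seq_b) - len(mi2) - 5
            pos2 = int(rng.integers(pos2_lo, pos2_hi))
            seq_b, truth = plant_target_site(
                seq_b, mi2, MismatchSpec(), pos2, seed=int(rng.integers(2**31)),
                rules=rules, transcript_id=tid_b, mirna_id=other_fam, truth=truth,
            )
            sb = list(seq_b)
        else:  # category III: degrade the site beyond the seed budget
            n_bad = rules.seed_mismatch_max + 1

            def _inject(p: int) -> None:
                coord = b_start + (b_end - b_start) - p
                m_nt = mi[p - 1]
                badletters = [
                    b for b in RNA_LETTERS if (m_nt, b) not in FOLD_PAIRS and b != sb[coord]
                ]
                sb[coord] = badletters[rng.integers(len(badletters))]

            # seed positions first, then central/tail positions: the duplex
            # validator forgives wobbles and a bulge, so keep degrading until
            # the window demonstrably fails validation
            pool = [int(q) for q in rng.permutation(np.arange(2, rules.seed_len + 1))]
            pool += [
                int(q)
                for q in rng.permutation(
                    np.arange(rules.seed_len + 1, L - rules.unpaired_3prime + 1)
                )
            ]
            n_seed_injected = n_tail_injected = 0

            def _bump(p: int) -> None:
                nonlocal n_seed_injected, n_tail_injected
                _inject(p)
                if p <= rules.seed_len:
                    n_seed_injected += 1
                else:
                    n_tail_injected += 1

            for p in pool[:n_bad]:
                _bump(p)
            probe = TargetSite(
                mirna_id=fam, transcript_id=tid_b, start=b_start, end=b_end,
                seed_mismatches=0, tail_mismatches=0,
                pos1_mismatch=False, last_nt_unpaired=False,
            )
            for p in pool[n_bad:]:
                if not validate_site(mi, probe, "".join(sb), rules).validated:
                    break
                _bump(p)
            if validate_site(mi, probe, "".join(sb), rules).validated:  # pragma: no cover
                raise RuntimeError(f"could not degrade the {tid_b} site past validation")
            truth.sites.append(
                PlantedSite(
                    tid_b, (b_start, b_end), fam,
                    MismatchSpec(seed=n_seed_injected, tail=n_tail_injected),
                )
            )
        transcripts[sp_b][tid_b] = "".join(sb)
        cds[sp_b][tid_b] = (30, len(sb) - 30)
        truth.ortholog_map[tid_a] = tid_b
        plan.append(TargetPlan(tid_a, tid_b, fam, other_fam, cat))

    for d in range(n_decoys):
        tid_a = f"{sp_a}_decoy{d + 1}"
        tid_b = f"{sp_b}_decoy{d + 1}"
        seq_a = random_rna(rng, L_tx)
        seq_b, _ = make_ortholog_transcript(
            seq_a, config, preserve_site=False, seed=int(rng.integers(2**31))
        )
        transcripts[sp_a][tid_a] = seq_a
        transcripts[sp_b][tid_b] = seq_b
        cds[sp_a][tid_a] = (30, L_tx - 30)
        cds[sp_b][tid_b] = (30, len(seq_b) - 30)
        truth.ortholog_map[tid_a] = tid_b

    prec_by_species: dict[str, dict[str, PrecursorCandidate]] = {}
    stacks: dict[str, dict[str, ReadStack]] = {}
    for sp in (sp_a, sp_b):
        prec_by_species[sp] = {}
        stacks[sp] = {}
        for fam in repertoires[sp]:
            cand = replace(precursors[fam], id=fam, species=sp)
            prec_by_species[sp][fam] = cand
            stacks[sp][fam] = make_read_stack(
                cand, n_reads=20, five_prime_fraction=0.95, seed=int(rng.integers(2**31))
            )

    return SpeciesScenario(
        families=families,
        matures=matures,
        repertoires=repertoires,
        precursors=prec_by_species,
        read_stacks=stacks,
        transcripts=transcripts,
        cds=cds,
        degradome_reads={sp_a: degradome},
        plan=plan,
        truth=truth,
        rules=rules,
    )
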