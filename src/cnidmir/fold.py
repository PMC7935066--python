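"""Self-contained RNA secondary-structure scoring.

Three primitives back the annotation pipeline:

* :func:`fold_nussinov` — nested base-pair maximization over {AU, GC, GU}
  with a minimum hairpin-loop size, returning one optimal structure. It
  stands in for thermodynamic MFE folding; the fold-significance criterion
  downstream is a randomization test and only needs a stability score that
  ranks a real hairpin above its shuffles. An external folding backend
  (e.g. ViennaRNA) can be plugged in wherever a ``fold_fn`` is accepted.
* :func:`shuffle_pvalue` — randfold-style significance of a fold score
  against mononucleotide or dinucleotide (Altschul–Erickson Eulerian-path)
  shuffles, with an add-one pseudo-count so p is never 0.
* :func:`duplex_align` — optimal antiparallel miRNA:target hybrid under a
  simple pair/gap scoring scheme, the desk-scale analogue of RNAhybrid
  duplex inspection.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._seq import FOLD_PAIRS, GU_PAIRS, WC_PAIRS, normalize_rna

# per-miRNA-position duplex states
PAIRED_WC = "paired-WC"
PAIRED_GU = "paired-GU"
MISMATCH = "mismatch"
BULGED = "bulged"
UNPAIRED_END = "unpaired-end"

PAIRED_STATES = frozenset({PAIRED_WC, PAIRED_GU})


@dataclass(frozen=True)
class FoldResult:
    """A nested secondary structure: dot-bracket, pair count, 1-based pair table."""

    structure: str
    pair_count: int
    pair_table: dict[int, int]

    def __post_init__(self) -> None:
        for i, j in self.pair_table.items():
            assert self.pair_table[j] == i, "pair table must be symmetric"


@dataclass(frozen=True)
class DuplexScoring:
    """Pair/gap parameters for duplex alignment.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """

    wc: int = 2
    gu: int = 1
    mismatch: int = -1
    gap_open: int = -3
    gap_extend: int = -2


@dataclass
class Duplex:
    """An antiparallel miRNA:target hybrid from :func:`duplex_align`.

    ``mirna_states`` has one entry per miRNA position (5'→3');
    ``target_span`` is the 0-based half-open interval of the window that
    takes part in the hybrid; ``target_insertions`` counts target-side
    bulged nucleotides inside the hybrid.
    """

    mirna_states: list[str]
    score: float
    target_span: tuple[int, int]
    target_insertions: int = 0


def pair_table_from_dotbracket(structure: str) -> dict[int, int]:
    """1-based pair table from a dot-bracket string; raises on imbalance."""
    stack: list[int] = []
    table: dict[int, int] = {}
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            table[i] = pos
            table[pos] = i
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return table


def fold_nussinov(seq: str, min_loop: int = 3) -> FoldResult:
    """Maximize nested {AU, GC, GU} pairs with hairpin loops >= ``min_loop``.

    Returns one optimal structure; ties are broken deterministically
    (leave the 3' base unpaired when possible, else pair it with the
    5'-most admissible partner).
    """
    s = normalize_rna(seq)
    n = len(s)
    # dp[i][j] = max pairs in s[i..j] inclusive
    dp = [[0] * n for _ in range(n)]
    can_pair = FOLD_PAIRS.__contains__
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            row_i = dp[i]
            best = row_i[j - 1]
            sj = s[j]
            for k in range(i, j - min_loop):
                if can_pair((s[k], sj)):
                    val = (row_i[k - 1] if k > i else 0) + 1 + dp[k + 1][j - 1]
                    if val > best:
                        best = val
            row_i[j] = best
    structure = ["."] * n
    table: dict[int, int] = {}

    def trace(i: int, j: int) -> None:
        while i < j:
            if dp[i][j] == dp[i][j - 1]:
                j -= 1
                continue
            sj = s[j]
            for k in range(i, j - min_loop):
                if can_pair((s[k], sj)):
                    val = (dp[i][k - 1] if k > i else 0) + 1 + dp[k + 1][j - 1]
                    if val == dp[i][j]:
                        structure[k] = "("
                        structure[j] = ")"
                        table[k + 1] = j + 1
                        table[j + 1] = k + 1
                        if k > i:
                            trace(i, k - 1)
                        i, j = k + 1, j - 1
                        break
            else:  # pragma: no cover - dp/traceback mismatch would be a bug
                raise AssertionError("traceback failed")

    if n:
        trace(0, n - 1)
    count = dp[0][n - 1] if n else 0
    return FoldResult("".join(structure), count, table)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for a, b in zip(seq, seq[1:]):
        counts[a + b] += 1
    return dict(counts)


def _mononuc_shuffle(s: str, rng: np.random.Generator) -> str:
    return "".join(rng.permutation(list(s)))


def _dinuc_shuffle(s: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson Eulerian shuffle: preserves all dinucleotide counts."""
    if len(s) <= 2:
        return s
    first, last = s[0], s[-1]
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    sources = [v for v in edges if v != last]
    # choose a random "last edge" out of every non-terminal vertex such that
    # following last edges always reaches the terminal vertex (arborescence)
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in sources}
        ok = True
        for v in sources:
            seen = set()
            cur = v
            while cur != last and cur in last_edge and cur not in seen:
                seen.add(cur)
                cur = last_edge[cur]
            if cur != last:
                ok = False
                break
        if ok:
            break
    adj: dict[str, list[str]] = {}
    for v, lst in edges.items():
        rest = list(lst)
        if v in last_edge:
            rest.remove(last_edge[v])
        rest = [rest[k] for k in rng.permutation(len(rest))]
        if v in last_edge:
            rest.append(last_edge[v])
        adj[v] = rest
    out = [first]
    ptr: dict[str, int] = defaultdict(int)
    cur = first
    for _ in range(len(s) - 1):
        nxt = adj[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffle_pvalue(
    seq: str,
    n_shuffles: int = 99,
    shuffle_order: int = 2,
    seed: int = 0,
    min_loop: int = 3,
    fold_fn=None,
) -> float:
    """Randomization p-value of a sequence's fold stability.

    ``p = (1 + #{shuffles with score >= observed}) / (n_shuffles + 1)``.
    ``fold_fn(seq) -> stability score`` may replace the default Nussinov
    pair count (e.g. negated free energy from an external folder); higher
    scores mean more stable.
    """
    s = normalize_rna(seq)
    if len(s) < 3:
        raise ValueError("sequence too short to shuffle (< 3 nt)")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if shuffle_order not in (1, 2):
        raise ValueError("shuffle_order must be 1 or 2")
    if fold_fn is None:
        fold_fn = lambda x: fold_nussinov(x, min_loop).pair_count  # noqa: E731
    rng = np.random.default_rng(seed)
    observed = fold_fn(s)
    shuffle = _dinuc_shuffle if shuffle_order == 2 else _mononuc_shuffle
    ge = sum(fold_fn(shuffle(s, rng)) >= observed for _ in range(n_shuffles))
    return (1 + ge) / (n_shuffles + 1)


def vienna_fold_fn(temperature: float = 37.0):
    """Adapter returning a ``fold_fn`` backed by the ViennaRNA Python bindings.

    Returns negated MFE so that higher = more stable, matching the
    convention of :func:`shuffle_pvalue`. Raises ImportError if the
    bindings are unavailable.
    """
    import RNA  # noqa: PLC0415 - optional backend

    md = RNA.md()
    md.temperature = temperature

    def fold(seq: str) -> float:
        fc = RNA.fold_compound(seq.replace("U", "T").replace("T", "U"), md)
        _, mfe = fc.mfe()
        return -mfe

    return fold


def _pair_score(a: str, b: str, sc: DuplexScoring) -> int:
    if (a, b) in WC_PAIRS:
        return sc.wc
    if (a, b) in GU_PAIRS:
        return sc.gu
    return sc.mismatch


def duplex_align(mirna: str, window: str, scoring: DuplexScoring | None = None) -> Duplex:
    """Optimal antiparallel hybrid between a miRNA and a target window.

    The miRNA is read 5'→3' against the window read 3'→5' (miRNA position 1
    faces the window's 3'-most base). Terminal unaligned stretches on either
    strand are free and reported as ``unpaired-end`` states; internal gaps
    appear as ``bulged`` states (miRNA side) or ``target_insertions``.
    """
    sc = scoring or DuplexScoring()
    x = normalize_rna(mirna)
    y = normalize_rna(window)[::-1]  # window 3'->5'
    if not x or not y:
        raise ValueError("empty input to duplex_align")
    m, n = len(x), len(y)
    NEG = float("-inf")
    go, ge = sc.gap_open, sc.gap_extend
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    GX = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in x: consumes y
    GY = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in y: consumes x
    ptrM = [[0] * (n + 1) for _ in range(m + 1)]  # 0=start,1=M,2=GX,3=GY
    ptrX = [[0] * (n + 1) for _ in range(m + 1)]
    ptrY = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        xi = x[i - 1]
        for j in range(1, n + 1):
            p = _pair_score(xi, y[j - 1], sc)
            # M: xi aligned to yj
            best, arg = 0, 0  # free start (terminal overhangs unpenalized)
            for cand, tag in ((M[i - 1][j - 1], 1), (GX[i - 1][j - 1], 2), (GY[i - 1][j - 1], 3)):
                if cand > best:
                    best, arg = cand, tag
            M[i][j] = p + best
            ptrM[i][j] = arg
            # GX: gap in miRNA, consumes y[j-1]
            best, arg = M[i][j - 1] + go + ge, 1
            if GX[i][j - 1] + ge > best:
                best, arg = GX[i][j - 1] + ge, 2
            if GY[i][j - 1] + go + ge > best:
                best, arg = GY[i][j - 1] + go + ge, 3
            GX[i][j] = best
            ptrX[i][j] = arg
            # GY: gap in target, consumes x[i-1]
            best, arg = M[i - 1][j] + go + ge, 1
            if GX[i - 1][j] + go + ge > best:
                best, arg = GX[i - 1][j] + go + ge, 2
            if GY[i - 1][j] + ge > best:
                best, arg = GY[i - 1][j] + ge, 3
            GY[i][j] = best
            ptrY[i][j] = arg
    # hybrid ends on an aligned pair; trailing overhangs are free
    bi = bj = 0
    best = NEG
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    states = [UNPAIRED_END] * m
    insertions = 0
    i, j, state = bi, bj, 1
    j_end = bj
    j0 = bj
    while i > 0 and j > 0:
        if state == 1:
            a, b = x[i - 1], y[j - 1]
            if (a, b) in WC_PAIRS:
                states[i - 1] = PAIRED_WC
            elif (a, b) in GU_PAIRS:
                states[i - 1] = PAIRED_GU
            else:
                states[i - 1] = MISMATCH
            nxt = ptrM[i][j]
            i, j = i - 1, j - 1
            j0 = j + 1
            if nxt == 0:
                break
            state = nxt
        elif state == 2:
            insertions += 1
            nxt = ptrX[i][j]
            j -= 1
            state = nxt
        else:
            states[i - 1] = BULGED
            nxt = ptrY[i][j]
            i -= 1
            state = nxt
    # convert reversed-window coords [j0, j_end] (1-based inclusive) back
    # to original window orientation, 0-based half-open
    span = (n - j_end, n - (j0 - 1))
    return Duplex(mirna_states=states, score=best, target_span=span, target_insertions=insertions)
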