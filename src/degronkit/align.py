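"""Global pairwise protein alignment and binding-residue conservation calls.

The aligner is a Needleman–Wunsch / Gotoh dynamic program with an affine
gap model, configured by default like the EMBOSS Needle web service:
BLOSUM62, gap open 10, gap extension 0.5, end gaps free.  A gap of length
L costs ``open + (L − 1)·extend`` (the opening penalty covers the first
gap residue).

On top of the alignment sit two small analyses used when comparing
ortholog binding regions:

* ``map_position`` — translate a residue number in one protein into the
  ortholog's numbering through the alignment (fragment offsets supported,
  so position 126 of a fragment starting at 70 maps correctly);
* ``conservation_at`` — classify queried positions as identical, similar
  (same physicochemical group), different, or unaligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import AlignmentError

__all__ = [
    "AlignmentConfig",
    "AlignmentResult",
    "ConservationReport",
    "DEFAULT_SIMILARITY_GROUPS",
    "needleman_wunsch",
    "map_position",
    "conservation_at",
    "format_pair",
]

NEG_INF = -1.0e30

#: physicochemical groups used for "similar" calls: aromatic, basic, acidic,
#: hydroxylic, aliphatic, amide, plus singletons for the structurally
#: idiosyncratic cysteine and proline; small A/G grouped together.
DEFAULT_SIMILARITY_GROUPS: tuple[str, ...] = (
    "FYW",
    "KRH",
    "DE",
    "ST",
    "ILVM",
    "NQ",
    "AG",
    "C",
    "P",
)


@dataclass(frozen=True)
class AlignmentConfig:
    """Scoring parameters; defaults mirror the EMBOSS Needle web defaults."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_penalized: bool = False

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise AlignmentError("gap penalties must be non-negative")


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment plus the position bookkeeping downstream code needs.

    ``position_map`` lists 1-based ungapped index pairs (i in a, j in b) for
    every column where both sequences are aligned; it is strictly increasing
    in both coordinates.  ``a_start``/``b_start`` give the full-protein
    number of the first residue of each input fragment, so alignments of
    sub-sequences can report positions in full-protein numbering.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    position_map: tuple[tuple[int, int], ...]
    a_start: int = 1
    b_start: int = 1

    @property
    def a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def b(self) -> str:
        return self.aligned_b.replace("-", "")


@dataclass(frozen=True)
class ConservationReport:
    """Conservation calls for a set of queried positions in sequence a."""

    calls: dict[int, str]  # position (a numbering) -> identical|similar|different|unaligned
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_conserved(self) -> int:
        """Identical + similar — positions with preserved chemistry."""
        return self.counts.get("identical", 0) + self.counts.get("similar", 0)


def load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError as exc:
        available = ", ".join(substitution_matrices.load())
        raise AlignmentError(
            f"unknown substitution matrix {name!r}; available: {available}"
        ) from exc


def _score_lookup(mat, alphabet: str):
    index = {ch: i for i, ch in enumerate(alphabet)}
    fallback = index.get("X")

    def ix(ch: str) -> int:
        i = index.get(ch)
        if i is None:
            if fallback is None:
                raise AlignmentError(f"residue {ch!r} not in matrix alphabet")
            return fallback
        return i

    arr = np.asarray(mat, dtype=float)
    return arr, ix


# state codes
_M, _IX, _IY = 0, 1, 2  # match/mismatch, gap-in-b (consumes a), gap-in-a (consumes b)


def needleman_wunsch(
    a: str, b: str, cfg: AlignmentConfig = AlignmentConfig(), a_start: int = 1, b_start: int = 1
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences (Gotoh algorithm).

    Traceback ties are broken deterministically in the order
    substitution > gap-in-b > gap-in-a.
    """
    a = a.strip().upper()
    b = b.strip().upper()
    if not a or not b:
        raise AlignmentError("sequences must be non-empty")
    mat = load_matrix(cfg.matrix)
    arr, ix = _score_lookup(mat, str(mat.alphabet))
    ai = [ix(ch) for ch in a]
    bi = [ix(ch) for ch in b]
    m, n = len(a), len(b)
    open_, ext = cfg.gap_open, cfg.gap_extend
    free = not cfg.end_gaps_penalized

    # score[state][i][j]; ptr[state][i][j] = predecessor state (or -1 at start)
    score = np.full((3, m + 1, n + 1), NEG_INF)
    ptr = np.full((3, m + 1, n + 1), -1, dtype=np.int8)
    score[_M, 0, 0] = 0.0
    for i in range(1, m + 1):
        score[_IX, i, 0] = 0.0 if free else -(open_ + (i - 1) * ext)
        ptr[_IX, i, 0] = _M if i == 1 else _IX
    for j in range(1, n + 1):
        score[_IY, 0, j] = 0.0 if free else -(open_ + (j - 1) * ext)
        ptr[_IY, 0, j] = _M if j == 1 else _IY

    for i in range(1, m + 1):
        srow = arr[ai[i - 1]]
        for j in range(1, n + 1):
            # substitution: tie order M > IX > IY on predecessors
            prev = (score[_M, i - 1, j - 1], score[_IX, i - 1, j - 1], score[_IY, i - 1, j - 1])
            k = int(np.argmax(prev))
            score[_M, i, j] = srow[bi[j - 1]] + prev[k]
            ptr[_M, i, j] = k
            # gap in b (consumes a_i)
            cand = (
                score[_M, i - 1, j] - open_,
                score[_IX, i - 1, j] - ext,
                score[_IY, i - 1, j] - open_,
            )
            k = int(np.argmax(cand))
            score[_IX, i, j] = cand[k]
            ptr[_IX, i, j] = k
            # gap in a (consumes b_j)
            cand = (
                score[_M, i, j - 1] - open_,
                score[_IX, i, j - 1] - open_,
                score[_IY, i, j - 1] - ext,
            )
            k = int(np.argmax(cand))
            score[_IY, i, j] = cand[k]
            ptr[_IY, i, j] = k

    # choose the alignment end; with free end gaps the best endpoint may sit
    # on the last row/column, with the remainder aligned to an unpenalized gap
    best_score = NEG_INF
    best = (m, n, _M)
    endpoints: list[tuple[int, int]] = [(m, n)]
    if free:
        endpoints += [(i, n) for i in range(m - 1, -1, -1)]
        endpoints += [(m, j) for j in range(n - 1, -1, -1)]
    for (i, j) in endpoints:
        for state in (_M, _IX, _IY):
            s = score[state, i, j]
            if s > best_score + 1e-12:
                best_score = s
                best = (i, j, state)

    # traceback
    i, j, state = best
    cols_a: list[str] = []
    cols_b: list[str] = []
    # trailing free gaps
    for k in range(m, i, -1):
        cols_a.append(a[k - 1])
        cols_b.append("-")
    for k in range(n, j, -1):
        cols_a.append("-")
        cols_b.append(b[k - 1])
    while i > 0 or j > 0:
        prev_state = int(ptr[state, i, j])
        if state == _M:
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == _IX:
            cols_a.append(a[i - 1])
            cols_b.append("-")
            i -= 1
        else:
            cols_a.append("-")
            cols_b.append(b[j - 1])
            j -= 1
        state = prev_state
        if state < 0:
            break
    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))

    pa = pb = 0
    identical = 0
    pairs: list[tuple[int, int]] = []
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-":
            pa += 1
        if cb != "-":
            pb += 1
        if ca != "-" and cb != "-":
            pairs.append((pa, pb))
            if ca == cb:
                identical += 1
    identity = identical / len(aligned_a) if aligned_a else 0.0

    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(best_score),
        identity=identity,
        position_map=tuple(pairs),
        a_start=a_start,
        b_start=b_start,
    )


def map_position(aln: AlignmentResult, pos_a: int) -> int | None:
    """Translate a full-protein position in a to b's numbering, or None if
    the position faces a gap."""
    idx = pos_a - aln.a_start + 1
    if idx < 1 or idx > len(aln.a):
        raise AlignmentError(
            f"position {pos_a} outside the aligned fragment "
            f"[{aln.a_start}, {aln.a_start + len(aln.a) - 1}]"
        )
    for ia, jb in aln.position_map:
        if ia == idx:
            return jb + aln.b_start - 1
    return None


def conservation_at(
    aln: AlignmentResult,
    positions: Sequence[int],
    groups: Sequence[str] = DEFAULT_SIMILARITY_GROUPS,
) -> ConservationReport:
    """Classify queried positions of a (full-protein numbering) against b.

    ``identical`` — the aligned residues are the same amino acid;
    ``similar`` — different residues from the same physicochemical group;
    ``different`` — otherwise; ``unaligned`` — the position faces a gap.
    """
    group_of: dict[str, int] = {}
    for gi, g in enumerate(groups):
        for ch in g:
            group_of[ch] = gi

    a_seq, b_seq = aln.a, aln.b
    calls: dict[int, str] = {}
    counts = {"identical": 0, "similar": 0, "different": 0, "unaligned": 0}
    for pos in positions:
        jb_full = map_position(aln, pos)
        if jb_full is None:
            call = "unaligned"
        else:
            ra = a_seq[pos - aln.a_start]
            rb = b_seq[jb_full - aln.b_start]
            if ra == rb:
                call = "identical"
            elif group_of.get(ra) is not None and group_of.get(ra) == group_of.get(rb):
                call = "similar"
            else:
                call = "different"
        calls[pos] = call
        counts[call] += 1
    return ConservationReport(calls=calls, counts=counts)


def format_pair(aln: AlignmentResult, name_a: str = "a", name_b: str = "b", width: int = 60) -> str:
    """EMBOSS-pair-like plain-text rendering of an alignment."""
    out = [
        f"# 1: {name_a}",
        f"# 2: {name_b}",
        f"# Score: {aln.score:.1f}",
        f"# Identity: {aln.identity * 100:.1f}%",
        "#",
    ]
    pa, pb = aln.a_start, aln.b_start
    for k in range(0, len(aln.aligned_a), width):
        block_a = aln.aligned_a[k : k + width]
        block_b = aln.aligned_b[k : k + width]
        marks = "".join(
            "|" if ca == cb and ca != "-" else (" " if "-" in (ca, cb) else ".")
            for ca, cb in zip(block_a, block_b)
        )
        na = sum(1 for c in block_a if c != "-")
        nb = sum(1 for c in block_b if c != "-")
        out.append(f"{name_a[:10]:>10s} {pa:5d} {block_a} {pa + max(na - 1, 0):5d}")
        out.append(f"{'':10s}       {marks}")
        out.append(f"{name_b[:10]:>10s} {pb:5d} {block_b} {pb + max(nb - 1, 0):5d}")
        out.append("")
        pa += na
        pb += nb
    return "\n".join(out)
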