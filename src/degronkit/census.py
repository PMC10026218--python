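"""C-terminal Arg/C-degron motif grammar and proteome census.

FEM1C-family substrate receptors recognise degrons at a protein's extreme
C-terminus whose defining feature is an arginine at or near the terminus
with a basic residue (R/K) three or four positions upstream.  The grammar
implemented here has six classes, all anchored at the C-terminus:

====================  =================  ==========================================
class                 window (from end)  meaning
====================  =================  ==========================================
``RK_X_X_R``          [RK] X X R         core motif, R terminal, R/K at −4
``RK_X_R``            [RK] X R           core motif, R terminal, R/K at −3
``RK_X_X_R_G``        [RK] X X R G       core followed by a terminal glycine
``RK_X_R_G``          [RK] X R G         ″
``RK_X_X_R_A``        [RK] X X R A       core followed by a terminal alanine
``RK_X_R_A``          [RK] X R A         ″
====================  =================  ==========================================

``X`` stands for any amino acid.  Specified positions ([RK], R, G, A) are
satisfied only by those exact standard residues, so ambiguity/non-standard
letters (X, B, Z, U, O) never satisfy them — but they do satisfy wildcard
positions.  Counts are per protein record: a protein matching several
classes is counted once in each class and once in each union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import SequenceError

__all__ = [
    "MotifGrammar",
    "DegronMatch",
    "CensusSummary",
    "DEFAULT_GRAMMAR",
    "classify_cterm",
    "scan_proteome",
    "scan_records",
    "write_matches_tsv",
]

logger = logging.getLogger(__name__)

# slot vocabulary for C-terminal patterns, listed from the most C-terminal
# position backwards would be confusing; patterns are stored N→C over the
# terminal window instead.
WILD = "X"

CORE_CLASSES = ("RK_X_X_R", "RK_X_R")
G_CLASSES = ("RK_X_X_R_G", "RK_X_R_G")
A_CLASSES = ("RK_X_X_R_A", "RK_X_R_A")


@dataclass(frozen=True)
class MotifGrammar:
    """Named C-terminal patterns.

    Each pattern is a tuple of slots over the terminal window, N→C; a slot
    is either the wildcard ``"X"`` or a string of admissible residues
    (e.g. ``"RK"``).  All patterns are anchored at the C-terminus.
    """

    classes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "RK_X_X_R": ("RK", WILD, WILD, "R"),
            "RK_X_R": ("RK", WILD, "R"),
            "RK_X_X_R_G": ("RK", WILD, WILD, "R", "G"),
            "RK_X_R_G": ("RK", WILD, "R", "G"),
            "RK_X_X_R_A": ("RK", WILD, WILD, "R", "A"),
            "RK_X_R_A": ("RK", WILD, "R", "A"),
        }
    )

    def max_window(self) -> int:
        return max(len(p) for p in self.classes.values())


DEFAULT_GRAMMAR = MotifGrammar()


@dataclass(frozen=True)
class DegronMatch:
    """One protein with at least one matching degron class."""

    protein_id: str
    length: int
    terminal_window: str  # last 5 residues (or fewer for very short proteins)
    classes: frozenset[str]


@dataclass(frozen=True)
class CensusSummary:
    """Per-class and union counts over a proteome scan.

    Unions count distinct proteins: ``union_core`` is the number of proteins
    matching either core class, ``union_g``/``union_a`` likewise for the
    extended classes.  Because the classes differ in their terminal residue,
    the core and extended unions are disjoint protein sets.
    """

    per_class: dict[str, int]
    union_core: int
    union_g: int
    union_a: int
    total_scanned: int

    def as_dict(self) -> dict:
        return {
            "per_class": dict(self.per_class),
            "union_core": self.union_core,
            "union_g": self.union_g,
            "union_a": self.union_a,
            "total_scanned": self.total_scanned,
        }


def _matches_pattern(seq: str, pattern: tuple[str, ...]) -> bool:
    if len(seq) < len(pattern):
        return False
    window = seq[-len(pattern):]
    for res, slot in zip(window, pattern):
        if slot == WILD:
            continue
        if res not in slot:
            return False
    return True


def classify_cterm(seq: str, grammar: MotifGrammar = DEFAULT_GRAMMAR) -> set[str]:
    """Return all degron classes whose C-terminal pattern matches ``seq``.

    A trailing stop symbol ``*`` is stripped before classification.
    Sequences shorter than a pattern cannot match that pattern.
    """
    seq = seq.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise SequenceError("empty sequence after stripping the stop symbol")
    return {name for name, pattern in grammar.classes.items() if _matches_pattern(seq, pattern)}


def _is_canonical(record_id: str) -> bool:
    """Heuristic isoform filter: UniProt-style ids with '-<n>' suffixes dropped."""
    accession = record_id.split("|")[1] if record_id.count("|") >= 2 else record_id
    head, sep, tail = accession.rpartition("-")
    return not (sep and head and tail.isdigit())


def scan_records(
    records: Iterable,
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
    canonical_only: bool = False,
) -> tuple[list[DegronMatch], CensusSummary]:
    """Scan an iterable of Biopython ``SeqRecord``s for C-terminal degrons."""
    matches: list[DegronMatch] = []
    per_class = {name: 0 for name in grammar.classes}
    union_sets: dict[str, set[str]] = {"core": set(), "g": set(), "a": set()}
    seen_ids: set[str] = set()
    total = 0

    for idx, record in enumerate(records):
        rid = record.id
        if rid in seen_ids:
            raise SequenceError(f"duplicate FASTA record id {rid!r} (record {idx + 1})")
        seen_ids.add(rid)
        if canonical_only and not _is_canonical(rid):
            continue
        seq = str(record.seq).strip().upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise SequenceError(f"record {rid!r} (record {idx + 1}) has an empty sequence")
        if "*" in seq:
            logger.warning(
                "record %s contains an internal stop symbol; skipping (likely pseudo-translation)",
                rid,
            )
            continue
        total += 1
        classes = classify_cterm(seq, grammar)
        if not classes:
            continue
        matches.append(
            DegronMatch(
                protein_id=rid,
                length=len(seq),
                terminal_window=seq[-5:],
                classes=frozenset(classes),
            )
        )
        for name in classes:
            per_class[name] += 1
        if classes & set(CORE_CLASSES):
            union_sets["core"].add(rid)
        if classes & set(G_CLASSES):
            union_sets["g"].add(rid)
        if classes & set(A_CLASSES):
            union_sets["a"].add(rid)

    summary = CensusSummary(
        per_class=per_class,
        union_core=len(union_sets["core"]),
        union_g=len(union_sets["g"]),
        union_a=len(union_sets["a"]),
        total_scanned=total,
    )
    return matches, summary


def scan_proteome(
    fasta: str | Path,
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
    canonical_only: bool = False,
) -> tuple[list[DegronMatch], CensusSummary]:
    """Scan a proteome FASTA file for C-terminal degron motifs.

    Returns one :class:`DegronMatch` per protein with ≥ 1 matching class
    (ordered by record appearance) and a :class:`CensusSummary` of per-class
    and union counts.  Duplicate record ids are rejected; records with
    internal stop symbols are skipped with a logged warning.
    """
    fasta = Path(fasta)
    if not fasta.exists():
        raise SequenceError(f"FASTA file not found: {fasta}")
    try:
        records = list(SeqIO.parse(str(fasta), "fasta"))
    except (ValueError, OSError) as exc:
        raise SequenceError(f"failed to parse FASTA {fasta}: {exc}") from exc
    return scan_records(records, grammar=grammar, canonical_only=canonical_only)


def write_matches_tsv(matches: Sequence[DegronMatch], path: str | Path) -> None:
    """Write matches as TSV: protein_id, length, terminal_window, classes."""
    lines = ["protein_id\tlength\tterminal_window\tclasses"]
    for m in matches:
        lines.append(
            f"{m.protein_id}\t{m.length}\t{m.terminal_window}\t{','.join(sorted(m.classes))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
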