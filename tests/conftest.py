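"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written from scratch, by a different
route than the library code they check: a brute-force double loop for
contacts, a recursive enumeration for global alignments, a regex matcher
for the degron grammar.
"""

from __future__ import annotations

import itertools
import re
from functools import lru_cache

import numpy as np
import pytest

from degronkit.structure import Structure


# ---------------------------------------------------------------- contacts

def brute_force_contacts(receptor: Structure, peptide: Structure, cutoff: float) -> set:
    """All-pairs double loop over every heavy atom (the contact oracle)."""
    pairs = set()
    for rres in receptor.residues:
        for pres in peptide.residues:
            hit = False
            for ra in rres.atoms:
                for pa in pres.atoms:
                    d = np.linalg.norm(np.array(ra.coords) - np.array(pa.coords))
                    if d <= cutoff:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                pairs.add((rres.rid, pres.rid))
    return pairs


@pytest.fixture
def toy_complex():
    """Default toy complex with 6 planted contacts (seed 11)."""
    from degronkit.synthetic import ToyComplexSpec, make_toy_complex

    spec = ToyComplexSpec(
        n_receptor=10,
        peptide_len=5,
        planted_pairs=frozenset({(1, 1), (2, 1), (3, 2), (4, 3), (5, 5), (9, 4)}),
        seed=11,
    )
    return make_toy_complex(spec)


# ---------------------------------------------------------------- alignment

@lru_cache(maxsize=4)
def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def enumerate_global_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (aligned_a, aligned_b)."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ta, tb in enumerate_global_alignments(a[1:], b):
            yield (a[0] + ta, "-" + tb)
    if b:
        for ta, tb in enumerate_global_alignments(a, b[1:]):
            yield ("-" + ta, b[0] + tb)
    if a and b:
        for ta, tb in enumerate_global_alignments(a[1:], b[1:]):
            yield (a[0] + ta, b[0] + tb)


def score_alignment(
    aligned_a: str,
    aligned_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    free_end_gaps: bool = True,
) -> float:
    """Score a gapped alignment: BLOSUM62 columns plus affine gap runs.

    A gap run of length L costs open + (L-1)*extend; runs touching either
    end of the alignment are free when ``free_end_gaps``.
    """
    mat = _blosum62()
    total = 0.0
    n = len(aligned_a)
    for seq, other in ((aligned_a, aligned_b), (aligned_b, aligned_a)):
        i = 0
        while i < n:
            if seq[i] == "-":
                j = i
                while j < n and seq[j] == "-":
                    j += 1
                at_end = i == 0 or j == n
                if not (free_end_gaps and at_end):
                    total -= gap_open + (j - i - 1) * gap_extend
                i = j
            else:
                i += 1
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            total += mat[ca, cb]
    return total


def best_alignment_score_bruteforce(a: str, b: str, free_end_gaps: bool = True) -> float:
    return max(
        score_alignment(ta, tb, free_end_gaps=free_end_gaps)
        for ta, tb in enumerate_global_alignments(a, b)
    )


# ---------------------------------------------------------------- census

_ORACLE_PATTERNS = {
    "RK_X_X_R": re.compile(r"[RK]..R\Z"),
    "RK_X_R": re.compile(r"[RK].R\Z"),
    "RK_X_X_R_G": re.compile(r"[RK]..RG\Z"),
    "RK_X_R_G": re.compile(r"[RK].RG\Z"),
    "RK_X_X_R_A": re.compile(r"[RK]..RA\Z"),
    "RK_X_R_A": re.compile(r"[RK].RA\Z"),
}


def regex_classify(seq: str) -> set[str]:
    """Independent regex-based degron classifier (the census oracle)."""
    seq = seq.rstrip("*")
    return {name for name, pat in _ORACLE_PATTERNS.items() if pat.search(seq)}


# ---------------------------------------------------------------- structures

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  HB1 ALA A   1       2.100   1.900   0.900  1.00  0.00           H
ATOM      5  N   GLY A   2       2.000  -1.200   0.000  1.00  0.00           N
ATOM      6  CA AGLY A   2       3.400  -1.300   0.000  0.40  0.00           C
ATOM      7  CA BGLY A   2       3.500  -1.350   0.100  0.60  0.00           C
HETATM    8  O   HOH A 101       8.000   8.000   8.000  1.00  0.00           O
HETATM    9 ZN    ZN A 102       9.000   9.000   9.000  1.00  0.00          ZN
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


def random_toy_spec(rng: np.random.Generator):
    """Random small complex spec for oracle-equivalence sweeps."""
    from degronkit.synthetic import ToyComplexSpec

    n_rec = int(rng.integers(3, 30))
    n_pep = int(rng.integers(1, 8))
    all_pairs = list(itertools.product(range(1, n_rec + 1), range(1, n_pep + 1)))
    k = int(rng.integers(0, min(len(all_pairs), 25) + 1))
    idx = rng.choice(len(all_pairs), size=k, replace=False)
    return ToyComplexSpec(
        n_receptor=n_rec,
        peptide_len=n_pep,
        planted_pairs=frozenset(all_pairs[i] for i in idx),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
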