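"""Seeded generators for every fixture the test surface needs.

These stand in for downloadable inputs (experimental complexes, predicted
models, reference proteomes): each generator is a pure function of its
specification — the seed included — and ships an exact ground-truth ledger
(a contact map, a census summary, a known rigid transform) that downstream
modules must reproduce.

Geometry is deliberately schematic, not physical.  Every residue carries a
pseudo-Cα and a base side-chain pseudo-atom; residues involved in planted
contacts additionally carry one side-chain pseudo-atom per contact, placed
at an isolated "contact site" so that planted pairs sit within the cutoff
while every non-planted receptor–peptide pair stays at least cutoff + 1 Å
apart.  This keeps the planted contact map exactly realizable for any
bipartite contact pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import seq3

from .census import (
    CensusSummary,
    DEFAULT_GRAMMAR,
    MotifGrammar,
    classify_cterm,
)
from .contacts import ContactMap, ContactParams
from .errors import FixtureError
from .structure import Atom, Residue, ResidueID, Structure

__all__ = [
    "ToyComplexSpec",
    "ToyProteomeSpec",
    "make_toy_complex",
    "make_toy_proteome",
    "make_linker_model",
    "perturb_structure",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_NON_RK = "".join(c for c in STANDARD_AA if c not in "RK")

# lattice constants for the schematic geometry (Å)
_CA_SPACING = 20.0
_SITE_SPACING = 50.0
_PEPTIDE_OFFSET = 200.0
_HELIX_RADIUS = 3.0  # keeps pseudo-Cα traces non-collinear for rigid fits


def _backbone(i: int, phase: float = 0.0, z0: float = 0.0) -> np.ndarray:
    ang = 0.7 * i + phase
    return np.array(
        [i * _CA_SPACING, _HELIX_RADIUS * np.sin(ang), z0 + _HELIX_RADIUS * np.cos(ang)]
    )


@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for a receptor+peptide complex with a planted contact map."""

    n_receptor: int = 10
    peptide_len: int = 5
    planted_pairs: frozenset[tuple[int, int]] = frozenset()  # 1-based (receptor, peptide)
    cutoff: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_receptor < 1 or self.peptide_len < 1:
            raise FixtureError("need at least one receptor and one peptide residue")
        if self.cutoff <= 0:
            raise FixtureError("cutoff must be positive")
        for (ri, pj) in self.planted_pairs:
            if not (1 <= ri <= self.n_receptor) or not (1 <= pj <= self.peptide_len):
                raise FixtureError(
                    f"planted pair ({ri}, {pj}) outside "
                    f"{self.n_receptor}×{self.peptide_len} index range"
                )
        max_degree = max(self.n_receptor, self.peptide_len)
        if len(self.planted_pairs) > 90 * max_degree:
            raise FixtureError("too many planted pairs for the atom-naming scheme")


@dataclass(frozen=True)
class ToyProteomeSpec:
    """Recipe for a decoy proteome with planted C-terminal motifs.

    ``planted`` maps census categories to counts: keys ``"core"``, ``"g"``,
    ``"a"`` plant proteins matching the respective union exactly; decoys are
    rejection-sampled to be motif-free.
    """

    n_decoys: int = 500
    planted: dict[str, int] = field(default_factory=dict)
    length_range: tuple[int, int] = (50, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.planted) - {"core", "g", "a"}
        if unknown:
            raise FixtureError(f"unknown planted categories: {sorted(unknown)}")
        if any(v < 0 for v in self.planted.values()):
            raise FixtureError("planted counts must be ≥ 0")
        lo, hi = self.length_range
        if lo < 6 or hi < lo:
            raise FixtureError("length_range must satisfy 6 ≤ lo ≤ hi")


def _residue(
    chain: str, number: int, res_name: str, atoms: list[tuple[str, str, np.ndarray]]
) -> Residue:
    return Residue(
        ResidueID(chain=chain, number=number, icode="", res_name=res_name),
        tuple(Atom(name=n, element=e, coords=(float(c[0]), float(c[1]), float(c[2]))) for n, e, c in atoms),
    )


def _contact_site_atoms(
    pairs: list[tuple[int, int]],
    cutoff: float,
    rng: np.random.Generator,
    origin: np.ndarray,
) -> tuple[dict[int, list[np.ndarray]], dict[int, list[np.ndarray]]]:
    """Place one isolated two-atom gadget per planted pair.

    Returns extra side-chain atom positions keyed by receptor / peptide
    residue index.  Sites are spaced ``_SITE_SPACING`` apart, far from both
    backbone lines, so only the intended pair falls within the cutoff.
    """
    rec_extra: dict[int, list[np.ndarray]] = {}
    pep_extra: dict[int, list[np.ndarray]] = {}
    for k, (ri, pj) in enumerate(sorted(pairs)):
        site = origin + np.array([k * _SITE_SPACING, 0.0, 0.0])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = rng.uniform(2.5, max(cutoff - 0.2, 2.6))
        rec_pos = site
        pep_pos = site + direction * dist
        rec_extra.setdefault(ri, []).append(rec_pos)
        pep_extra.setdefault(pj, []).append(pep_pos)
    return rec_extra, pep_extra


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, Structure, ContactMap]:
    """Generate a receptor+peptide complex whose contact map is known exactly.

    Returns ``(receptor, peptide, truth)`` where ``truth`` is the contact
    map of the generated coordinates at ``spec.cutoff``: exactly the planted
    pairs, nothing else (non-planted pairs are ≥ cutoff + 1 Å apart by
    construction).
    """
    rng = np.random.default_rng(spec.seed)
    rec_extra, pep_extra = _contact_site_atoms(
        sorted(spec.planted_pairs), spec.cutoff, rng, origin=np.array([0.0, 100.0, 100.0])
    )

    receptor_residues = []
    for i in range(1, spec.n_receptor + 1):
        ca = _backbone(i)
        atoms = [("CA", "C", ca), ("CB", "C", ca + np.array([0.0, 1.5, 0.0]))]
        for t, pos in enumerate(rec_extra.get(i, ()), start=1):
            atoms.append((f"C{t}", "C", pos))
        receptor_residues.append(_residue("A", i, "ALA", atoms))

    peptide_residues = []
    for j in range(1, spec.peptide_len + 1):
        ca = _backbone(j, phase=1.0, z0=_PEPTIDE_OFFSET)
        atoms = [("CA", "C", ca), ("CB", "C", ca + np.array([0.0, 1.5, 0.0]))]
        for t, pos in enumerate(pep_extra.get(j, ()), start=1):
            atoms.append((f"C{t}", "C", pos))
        peptide_residues.append(_residue("B", j, "ALA", atoms))

    receptor = Structure(id=f"toy-receptor-{spec.seed}", residues=receptor_residues)
    peptide = Structure(id=f"toy-peptide-{spec.seed}", residues=peptide_residues)
    truth = ContactMap(
        receptor_label=receptor.id,
        peptide_label=peptide.id,
        pairs=frozenset(
            (receptor_residues[ri - 1].rid, peptide_residues[pj - 1].rid)
            for ri, pj in spec.planted_pairs
        ),
        params=ContactParams(cutoff=spec.cutoff),
    )
    return receptor, peptide, truth


def _euler_rotation(angles: tuple[float, float, float]) -> np.ndarray:
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def perturb_structure(
    s: Structure,
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Structure:
    """Rigid-transform a structure (x–y–z Euler angles, radians; translation
    in Å) and add isotropic Gaussian per-atom noise of the given σ."""
    if len(s) == 0:
        raise FixtureError("cannot perturb an empty structure")
    if noise_sigma < 0:
        raise FixtureError("noise_sigma must be ≥ 0")
    rng = np.random.default_rng(seed)
    R = _euler_rotation(rotation)
    coords = s.all_coords() @ R.T + np.asarray(translation, dtype=float)
    if noise_sigma > 0:
        coords = coords + rng.normal(scale=noise_sigma, size=coords.shape)
    return s.with_coords(coords)


# --- toy proteome ----------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=length))


def _plant_window(rng: np.random.Generator, category: str) -> tuple[str, set[str]]:
    """Build a terminal window matching exactly one known class set."""
    rk = rng.choice(list("RK"))
    x1 = rng.choice(list(_NON_RK))
    x2 = rng.choice(list(_NON_RK))
    long_form = bool(rng.integers(0, 2))  # alternate between the two motif arities
    if category == "core":
        window = rk + x1 + x2 + "R" if long_form else rk + x1 + "R"
        classes = {"RK_X_X_R"} if long_form else {"RK_X_R"}
    elif category == "g":
        window = (rk + x1 + x2 + "RG") if long_form else (rk + x1 + "RG")
        classes = {"RK_X_X_R_G"} if long_form else {"RK_X_R_G"}
    elif category == "a":
        window = (rk + x1 + x2 + "RA") if long_form else (rk + x1 + "RA")
        classes = {"RK_X_X_R_A"} if long_form else {"RK_X_R_A"}
    else:  # pragma: no cover
        raise FixtureError(f"unknown category {category!r}")
    return window, classes


def make_toy_proteome(
    spec: ToyProteomeSpec, grammar: MotifGrammar = DEFAULT_GRAMMAR
) -> tuple[list[SeqRecord], CensusSummary]:
    """Generate a decoy proteome with planted motifs and its exact census.

    Decoy C-termini are rejection-sampled until motif-free; planted records
    get a terminal window constructed to match exactly one grammar class,
    preceded by a motif-free prefix.  Scanning the returned records must
    reproduce the returned :class:`CensusSummary` with zero tolerance.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: list[SeqRecord] = []
    per_class = {name: 0 for name in grammar.classes}
    union = {"core": 0, "g": 0, "a": 0}

    for category in ("core", "g", "a"):
        for k in range(spec.planted.get(category, 0)):
            window, classes = _plant_window(rng, category)
            length = int(rng.integers(lo, hi + 1))
            prefix = _random_seq(rng, max(length - len(window), 1))
            if prefix[-1] in "RK":
                # guard the position just upstream of a short-form window so
                # the longer-arity pattern cannot also fire accidentally
                prefix = prefix[:-1] + rng.choice(list(_NON_RK))
            seq = prefix + window
            rid = f"PLANT_{category.upper()}_{k + 1:04d}"
            records.append(SeqRecord(Seq(seq), id=rid, description=""))
            for name in classes:
                per_class[name] += 1
            union[category] += 1

    for k in range(spec.n_decoys):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        while classify_cterm(seq, grammar):
            seq = seq[:-5] + _random_seq(rng, 5)
        records.append(SeqRecord(Seq(seq), id=f"DECOY_{k + 1:05d}", description=""))

    # deterministic interleaving: shuffle record order with the same rng
    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    truth = CensusSummary(
        per_class=per_class,
        union_core=union["core"],
        union_g=union["g"],
        union_a=union["a"],
        total_scanned=len(records),
    )
    return records, truth


# --- linker-threaded single-chain model ------------------------------------

def make_linker_model(
    receptor_len: int,
    linker_len: int,
    peptide_seq: str,
    docked: bool,
    seed: int = 0,
    contacts: frozenset[tuple[int, int]] | set[tuple[int, int]] | None = None,
    cutoff: float = 4.0,
) -> Structure:
    """Generate a single-chain receptor+polyGly-linker+peptide model.

    With ``docked=True``, ``contacts`` gives the (receptor index, peptide
    index) pairs (1-based) the model must realize — the model's contact map
    at ``cutoff`` is then exactly that set.  With ``docked=False`` the
    peptide is placed ≥ 10 Å from every receptor atom.  The linker is
    all-glycine; linker coordinates are routed far from both receptor and
    peptide so they never influence receptor–peptide contacts.
    """
    if receptor_len < 1 or linker_len < 0 or not peptide_seq:
        raise FixtureError("invalid linker-model dimensions")
    peptide_seq = peptide_seq.upper()
    contacts = frozenset(contacts or ())
    if docked and not contacts:
        raise FixtureError("docked=True requires a set of contacts to realize")
    if not docked and contacts:
        raise FixtureError("docked=False cannot realize contacts")
    for ri, pj in contacts:
        if not (1 <= ri <= receptor_len) or not (1 <= pj <= len(peptide_seq)):
            raise FixtureError(f"contact ({ri}, {pj}) outside model index range")

    rng = np.random.default_rng(seed)
    rec_extra, pep_extra = _contact_site_atoms(
        sorted(contacts), cutoff, rng, origin=np.array([0.0, 100.0, 100.0])
    )

    residues: list[Residue] = []
    pos = 0
    for i in range(1, receptor_len + 1):
        pos += 1
        ca = _backbone(i)
        atoms = [("CA", "C", ca), ("CB", "C", ca + np.array([0.0, 1.5, 0.0]))]
        for t, p in enumerate(rec_extra.get(i, ()), start=1):
            atoms.append((f"C{t}", "C", p))
        residues.append(_residue("A", pos, "ALA", atoms))
    for k in range(1, linker_len + 1):
        pos += 1
        ca = np.array([k * 3.8, 500.0, 0.0])  # routed far away; coordinates immaterial
        residues.append(_residue("A", pos, "GLY", [("CA", "C", ca)]))
    pep_z = _PEPTIDE_OFFSET  # ≥ 10 Å from all receptor atoms either way
    for j, aa in enumerate(peptide_seq, start=1):
        pos += 1
        ca = _backbone(j, phase=1.0, z0=pep_z)
        atoms = [("CA", "C", ca), ("CB", "C", ca + np.array([0.0, 1.5, 0.0]))]
        for t, p in enumerate(pep_extra.get(j, ()), start=1):
            atoms.append((f"C{t}", "C", p))
        residues.append(_residue("A", pos, seq3(aa).upper(), atoms))

    return Structure(id=f"linker-model-{'docked' if docked else 'undocked'}-{seed}", residues=residues)
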