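"""Lightweight macromolecular structure model.

Parsing (PDB / mmCIF) is delegated to :mod:`gemmi`; what the rest of the
toolkit consumes is a deliberately small, immutable-ish representation:
chains of residues of heavy atoms with author numbering, which is all the
contact, superposition and model-evaluation code needs.

Reading applies the conventions used throughout the toolkit:

* first model only (predicted models ship a single model; for experimental
  entries the first model holds the deposited coordinates);
* hydrogens (and deuteriums) removed — all distances downstream are
  heavy-atom distances;
* waters and non-polymer ligands removed — the analyses are protein–peptide
  only; modified amino acids inside a polymer chain are kept;
* alternate locations resolved to the highest-occupancy conformer, ties
  broken by file order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

from .errors import SelectionError, StructureParseError

__all__ = [
    "Atom",
    "Residue",
    "ResidueID",
    "Structure",
    "read_structure",
    "select_residues",
    "write_structure",
]

_WATER_NAMES = {"HOH", "DOD", "WAT", "H2O"}
_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True, order=True)
class ResidueID:
    """Identity of a residue: chain, author sequence number, insertion code, name.

    ``(chain, number, icode)`` is unique within a :class:`Structure`; author
    numbering is used throughout so residue ranges match what a structure's
    depositors (and the literature) print.
    """

    chain: str
    number: int
    icode: str = ""
    res_name: str = ""

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    def __str__(self) -> str:
        return f"{self.chain}:{self.number}{self.icode}:{self.res_name}"


@dataclass(frozen=True)
class Atom:
    """A heavy atom: label, element symbol and Cartesian coordinates in Å."""

    name: str
    element: str
    coords: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class Residue:
    """One residue: an id plus an ordered collection of heavy atoms."""

    rid: ResidueID
    atoms: tuple[Atom, ...]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise SelectionError(f"residue {self.rid} has no atom named {name!r}")

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of heavy-atom coordinates."""
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Structure:
    """An ordered collection of residues grouped by chain.

    Residue order within a chain follows file order.  ``source`` records the
    file path and format the structure was read from (empty for structures
    built in memory).
    """

    id: str
    residues: list[Residue] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for res in self.residues:
            out.setdefault(res.rid.chain, []).append(res)
        return out

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residue_ids(self) -> list[ResidueID]:
        return [r.rid for r in self.residues]

    def get(self, key: tuple[str, int, str] | ResidueID) -> Residue:
        if isinstance(key, ResidueID):
            key = key.key()
        for res in self.residues:
            if res.rid.key() == key:
                return res
        raise SelectionError(f"no residue {key} in structure {self.id!r}")

    def all_coords(self) -> np.ndarray:
        """(n_atoms, 3) array over all residues, file order."""
        if not self.residues:
            return np.empty((0, 3), dtype=float)
        return np.concatenate([r.coords() for r in self.residues], axis=0)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with atom coordinates replaced (same layout)."""
        coords = np.asarray(coords, dtype=float)
        n = sum(len(r.atoms) for r in self.residues)
        if coords.shape != (n, 3):
            raise ValueError(f"expected coordinate array of shape ({n}, 3), got {coords.shape}")
        residues: list[Residue] = []
        k = 0
        for res in self.residues:
            atoms = tuple(
                replace(a, coords=tuple(float(x) for x in coords[k + i]))
                for i, a in enumerate(res.atoms)
            )
            k += len(res.atoms)
            residues.append(Residue(res.rid, atoms))
        return Structure(id=self.id, residues=residues, source=self.source)


def _resolve_format(path: Path, fmt: str) -> gemmi.CoorFormat:
    fmt = fmt.lower()
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    if fmt in ("mmcif", "cif"):
        return gemmi.CoorFormat.Mmcif
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in (".cif", ".mmcif"):
            return gemmi.CoorFormat.Mmcif
        if suffix in (".pdb", ".ent"):
            return gemmi.CoorFormat.Pdb
        return gemmi.CoorFormat.Detect
    raise ValueError(f"unknown structure format {fmt!r}; expected pdb, mmcif or auto")


def _is_polymer_residue(name: str) -> bool:
    """Amino-acid residues (standard or modified) are kept; waters/ligands dropped."""
    if name.upper() in _WATER_NAMES:
        return False
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: highest occupancy, ties → first in file."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a heavy-atom :class:`Structure`.

    Only the first model is loaded; hydrogens, waters and non-polymer
    heteroatoms are excluded; alternate locations are resolved to the
    highest-occupancy conformer (ties broken by file order).

    Raises
    ------
    StructureParseError
        If the file cannot be parsed, or contains no polymer residues.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"structure file not found: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_resolve_format(path, format))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no models")

    model = st[0]
    residues: list[Residue] = []
    index: dict[tuple[str, int, str], int] = {}
    for chain in model:
        for res in chain:
            if not _is_polymer_residue(res.name):
                continue
            atoms = []
            for atom in _pick_altlocs(res):
                element = atom.element.name.strip().upper()
                if element in _HYDROGEN_ELEMENTS:
                    continue
                coords = (atom.pos.x, atom.pos.y, atom.pos.z)
                if not all(math.isfinite(c) for c in coords):
                    raise StructureParseError(
                        f"{path}: non-finite coordinates for atom {atom.name} "
                        f"in residue {res.name} {res.seqid.num}"
                    )
                atoms.append(Atom(name=atom.name, element=element, coords=coords))
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            rid = ResidueID(
                chain=chain.name, number=res.seqid.num, icode=icode, res_name=res.name
            )
            if rid.key() in index:
                # residue split across records (e.g. microheterogeneity):
                # keep the first conformation's identity, merge new atom names only
                i = index[rid.key()]
                prev = residues[i]
                have = {a.name for a in prev.atoms}
                extra = tuple(a for a in atoms if a.name not in have)
                residues[i] = Residue(prev.rid, prev.atoms + extra)
                continue
            index[rid.key()] = len(residues)
            residues.append(Residue(rid, tuple(atoms)))

    if not residues:
        raise StructureParseError(f"{path}: no polymer residues after filtering")
    return Structure(id=st.name or path.stem, residues=residues, source=f"{path}")


def select_residues(s: Structure, chain: str, first: int, last: int) -> Structure:
    """Sub-structure of residues with author number in ``[first, last]`` on a chain.

    The range is inclusive and 1-based in author numbering; order is
    preserved and an empty selection is allowed.
    """
    if first > last:
        raise ValueError(f"invalid range [{first}, {last}]: first > last")
    chains = s.chains
    if chain not in chains:
        raise SelectionError(
            f"no chain {chain!r} in structure {s.id!r}; available chains: "
            + ", ".join(repr(c) for c in chains)
        )
    picked = [r for r in chains[chain] if first <= r.rid.number <= last]
    return Structure(id=f"{s.id}[{chain}:{first}-{last}]", residues=picked, source=s.source)


def _format_atom_name(name: str) -> str:
    # PDB columns 13-16: names shorter than 4 chars start in column 14
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a structure as a PDB coordinate file.

    Round trip: ``read_structure(write_structure(s))`` reproduces residue
    identities exactly and coordinates to 3 decimals (the PDB field width).
    """
    if not s.residues:
        raise ValueError("refusing to write an empty structure")
    path = Path(path)
    lines: list[str] = []
    serial = 0
    prev_chain: str | None = None
    for res in s.residues:
        rid = res.rid
        if prev_chain is not None and rid.chain != prev_chain:
            lines.append("TER")
        prev_chain = rid.chain
        for atom in res.atoms:
            serial += 1
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d} {_format_atom_name(atom.name)} "
                f"{rid.res_name:>3s} {rid.chain[:1]:1s}{rid.number:4d}{(rid.icode or ' '):1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise StructureParseError(f"cannot write {path}: {exc}") from exc


def build_structure(
    struct_id: str,
    residues: Iterable[tuple[str, int, str, list[tuple[str, str, tuple[float, float, float]]]]],
) -> Structure:
    """Assemble a Structure in memory.

    Each entry is ``(chain, number, res_name, atoms)`` with atoms given as
    ``(atom_name, element, (x, y, z))``.  Used by the synthetic-fixture
    generators and by tests.
    """
    out: list[Residue] = []
    for chain, number, res_name, atoms in residues:
        rid = ResidueID(chain=chain, number=number, icode="", res_name=res_name)
        out.append(
            Residue(rid, tuple(Atom(name=n, element=e, coords=tuple(c)) for n, e, c in atoms))
        )
    return Structure(id=struct_id, residues=out)
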