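"""Residue-level receptor–peptide contact maps and native-contact recapitulation.

A contact is declared between a receptor residue and a peptide residue when
the minimum distance over all heavy-atom pairs does not exceed the cutoff
(4.0 Å by default).  Contacts are counted at residue-pair level; the number
of atom pairs supporting each residue contact is retained for diagnostics.

Recapitulation scores how many of an experimental complex's contacts a
predicted model reproduces — the fraction of native contacts — after
translating the model's residue identities into the native numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ContactError
from .structure import ResidueID, Structure

__all__ = [
    "ContactParams",
    "ContactMap",
    "RecapReport",
    "heavy_atom_contacts",
    "recapitulation",
    "export_contact_table",
    "read_contact_table",
]

Pair = tuple[ResidueID, ResidueID]


@dataclass(frozen=True)
class ContactParams:
    """Contact definition: heavy-atom distance cutoff in Å (inclusive)."""

    cutoff: float = 4.0

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ContactError(f"cutoff must be positive, got {self.cutoff}")


@dataclass(frozen=True)
class ContactMap:
    """Set of (receptor residue, peptide residue) contacts at a given cutoff."""

    receptor_label: str
    peptide_label: str
    pairs: frozenset[Pair]
    params: ContactParams = ContactParams()
    # diagnostics: number of heavy-atom pairs within cutoff per residue pair
    atom_pair_counts: Mapping[Pair, int] = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.pairs)

    def receptor_residues(self) -> list[ResidueID]:
        return sorted({r for r, _ in self.pairs})

    def peptide_residues(self) -> list[ResidueID]:
        return sorted({p for _, p in self.pairs})

    def transpose(self) -> "ContactMap":
        return ContactMap(
            receptor_label=self.peptide_label,
            peptide_label=self.receptor_label,
            pairs=frozenset((p, r) for r, p in self.pairs),
            params=self.params,
            atom_pair_counts={(p, r): n for (r, p), n in self.atom_pair_counts.items()},
        )


@dataclass(frozen=True)
class RecapReport:
    """Native-contact recapitulation: which native pairs a model reproduces."""

    n_native: int
    n_recapitulated: int
    matched: frozenset[Pair]
    missing: frozenset[Pair]
    extra: frozenset[Pair]

    @property
    def fraction(self) -> float:
        """n_recapitulated / n_native (0.0 when there are no native contacts)."""
        return self.n_recapitulated / self.n_native if self.n_native else 0.0

    def as_dict(self) -> dict:
        return {
            "n_native": self.n_native,
            "n_recapitulated": self.n_recapitulated,
            "fraction": self.fraction,
            "matched": sorted(str(r) + "--" + str(p) for r, p in self.matched),
            "missing": sorted(str(r) + "--" + str(p) for r, p in self.missing),
            "extra": sorted(str(r) + "--" + str(p) for r, p in self.extra),
        }


def heavy_atom_contacts(
    receptor: Structure, peptide: Structure, params: ContactParams = ContactParams()
) -> ContactMap:
    """Compute the residue-level contact map between two structures.

    A residue pair is in contact iff the minimum Euclidean distance over all
    heavy-atom pairs is ≤ ``params.cutoff`` (Å).  Distances are compared
    with plain floating-point ≤ — no boundary tolerance — so the result is
    deterministic for fixed inputs.
    """
    if len(receptor) == 0:
        raise ContactError("receptor structure is empty")
    if len(peptide) == 0:
        raise ContactError("peptide structure is empty")
    shared = set(r.key() for r in receptor.residue_ids()) & set(
        p.key() for p in peptide.residue_ids()
    )
    if shared:
        raise ContactError(
            f"receptor and peptide share residues (e.g. {sorted(shared)[0]}); "
            "they must be disjoint"
        )

    rec_coords = receptor.all_coords()
    pep_coords = peptide.all_coords()
    rec_owner = np.concatenate(
        [np.full(len(res.atoms), i) for i, res in enumerate(receptor.residues)]
    )
    pep_owner = np.concatenate(
        [np.full(len(res.atoms), j) for j, res in enumerate(peptide.residues)]
    )

    dists = cdist(rec_coords, pep_coords)
    within = np.nonzero(dists <= params.cutoff)
    counts: dict[Pair, int] = {}
    for ai, aj in zip(*within):
        pair = (receptor.residues[rec_owner[ai]].rid, peptide.residues[pep_owner[aj]].rid)
        counts[pair] = counts.get(pair, 0) + 1

    return ContactMap(
        receptor_label=receptor.id,
        peptide_label=peptide.id,
        pairs=frozenset(counts),
        params=params,
        atom_pair_counts=counts,
    )


def _as_mapping_fn(
    mapping: Mapping[ResidueID, ResidueID] | Callable[[ResidueID], ResidueID] | None,
) -> Callable[[ResidueID], ResidueID]:
    if mapping is None:
        return lambda rid: rid
    if callable(mapping):
        return mapping
    return lambda rid: mapping.get(rid, rid)


def recapitulation(
    native: ContactMap,
    model: ContactMap,
    mapping: Mapping[ResidueID, ResidueID] | Callable[[ResidueID], ResidueID] | None = None,
) -> RecapReport:
    """Score how many native contacts a model contact map recapitulates.

    ``mapping`` translates model residue identities into native numbering
    (identity when omitted); it must be injective on the residues it is
    applied to, otherwise two distinct model contacts could collapse onto
    one native pair.
    """
    fn = _as_mapping_fn(mapping)

    seen: dict[ResidueID, ResidueID] = {}
    mapped_pairs: set[Pair] = set()
    for r, p in model.pairs:
        mr, mp = fn(r), fn(p)
        for src, dst in ((r, mr), (p, mp)):
            prev_src = seen.get(dst)
            if prev_src is not None and prev_src != src:
                raise ContactError(
                    f"residue mapping is not injective: both {prev_src} and {src} "
                    f"map to {dst}"
                )
            seen[dst] = src
        mapped_pairs.add((mr, mp))

    matched = frozenset(native.pairs & mapped_pairs)
    missing = frozenset(native.pairs - mapped_pairs)
    extra = frozenset(mapped_pairs - native.pairs)
    return RecapReport(
        n_native=len(native.pairs),
        n_recapitulated=len(matched),
        matched=matched,
        missing=missing,
        extra=extra,
    )


def _rid_label(rid: ResidueID) -> str:
    return f"{rid.chain}:{rid.number}{rid.icode}:{rid.res_name}"


def _parse_rid_label(label: str) -> ResidueID:
    chain, numicode, res_name = label.split(":")
    i = len(numicode)
    while i > 0 and not numicode[i - 1].isdigit() and numicode[i - 1] != "-":
        i -= 1
    return ResidueID(chain=chain, number=int(numicode[:i]), icode=numicode[i:], res_name=res_name)


def export_contact_table(cmap: ContactMap, path: str | Path) -> None:
    """Write a contact map as a 0/1 TSV matrix.

    Rows are the receptor residues and columns the peptide residues that
    appear in the map (labelled ``chain:number:resname``), ordered by
    residue number ascending.  An empty map yields a header-only table.
    """
    rows = cmap.receptor_residues()
    cols = cmap.peptide_residues()
    data = np.zeros((len(rows), len(cols)), dtype=int)
    row_ix = {rid: i for i, rid in enumerate(rows)}
    col_ix = {rid: j for j, rid in enumerate(cols)}
    for r, p in cmap.pairs:
        data[row_ix[r], col_ix[p]] = 1
    df = pd.DataFrame(
        data, index=[_rid_label(r) for r in rows], columns=[_rid_label(p) for p in cols]
    )
    df.to_csv(path, sep="\t", index_label="receptor")


def read_contact_table(path: str | Path, params: ContactParams = ContactParams()) -> ContactMap:
    """Read a contact map written by :func:`export_contact_table`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    pairs: set[Pair] = set()
    for row_label, row in df.iterrows():
        for col_label, val in row.items():
            if int(val) == 1:
                pairs.add((_parse_rid_label(str(row_label)), _parse_rid_label(str(col_label))))
    return ContactMap(
        receptor_label=str(Path(path)),
        peptide_label=str(Path(path)),
        pairs=frozenset(pairs),
        params=params,
    )
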