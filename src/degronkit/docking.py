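"""Linker-mediated peptide-docking inputs and predicted-model dissection.

The docking trick evaluated here predicts a receptor–peptide complex by
folding a *single chain*: the receptor fragment, a flexible poly-glycine
linker, and the peptide (for FEM1C: residues 1–390, 30×Gly, then the
LKELR degron — 425 residues in all).  Point mutants of the receptor are
encoded in the input sequence.

This module builds those input sequences, dissects a predicted single-chain
model back into receptor / linker / peptide components, and classifies a
model as *docked* or *undocked* by how many of the experimental complex's
contacts it recapitulates (linker excluded from the contact calculation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.SeqUtils import seq1

from .contacts import ContactMap, ContactParams, RecapReport, heavy_atom_contacts, recapitulation
from .errors import ModelLayoutError, SequenceError
from .structure import ResidueID, Structure

__all__ = [
    "DockingInputSpec",
    "ModelComponents",
    "apply_mutation",
    "build_input",
    "build_inputs",
    "extract_components",
    "classify_docked",
    "write_fasta_inputs",
]

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class DockingInputSpec:
    """Recipe for one docking input: fragment + mutations + linker + peptide."""

    receptor_seq: str
    fragment: tuple[int, int] = (1, 390)
    mutations: tuple[str, ...] = ()
    linker_len: int = 30
    peptide: str = "LKELR"

    def __post_init__(self) -> None:
        first, last = self.fragment
        if not (1 <= first <= last <= len(self.receptor_seq)):
            raise SequenceError(
                f"fragment [{first}, {last}] outside receptor sequence "
                f"(length {len(self.receptor_seq)})"
            )
        if self.linker_len < 0:
            raise SequenceError("linker length must be ≥ 0")
        if not self.peptide:
            raise SequenceError("peptide must be non-empty")

    @property
    def fragment_seq(self) -> str:
        first, last = self.fragment
        return self.receptor_seq[first - 1 : last]

    @property
    def fragment_len(self) -> int:
        return self.fragment[1] - self.fragment[0] + 1

    @property
    def total_len(self) -> int:
        return self.fragment_len + self.linker_len + len(self.peptide)

    def variant_name(self) -> str:
        return "+".join(self.mutations) if self.mutations else "WT"


@dataclass
class ModelComponents:
    """A predicted single-chain model dissected into its three segments."""

    receptor: Structure
    linker: Structure
    peptide: Structure
    numbering_map: dict[int, int] = field(default_factory=dict)  # model position → receptor number


def apply_mutation(seq: str, spec: str) -> str:
    """Apply a one-letter point-mutation spec ``XnY`` (1-based) to a sequence.

    The reference residue ``X`` must match the sequence at position ``n``;
    a mismatch raises with the expected and found residues.
    """
    m = _MUTATION_RE.match(spec.strip().upper())
    if not m:
        raise SequenceError(f"malformed mutation spec {spec!r}; expected e.g. 'D126H'")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if not (1 <= pos <= len(seq)):
        raise SequenceError(f"mutation position {pos} outside sequence of length {len(seq)}")
    found = seq[pos - 1]
    if found != ref:
        raise SequenceError(
            f"reference mismatch for {spec}: expected {ref} at position {pos}, found {found}"
        )
    return seq[: pos - 1] + alt + seq[pos:]


def build_input(spec: DockingInputSpec) -> tuple[str, str]:
    """Build one docking input sequence and its FASTA record text.

    Returns ``(sequence, fasta_text)``.  The sequence is the mutated
    receptor fragment, then ``linker_len`` glycines, then the peptide; the
    FASTA header encodes the variant name and the segment boundaries.
    """
    frag = spec.fragment_seq
    for mut in spec.mutations:
        # mutation positions are in fragment coordinates (= full-protein
        # coordinates when the fragment starts at 1)
        offset_spec = mut
        if spec.fragment[0] != 1:
            m = _MUTATION_RE.match(mut.strip().upper())
            if not m:
                raise SequenceError(f"malformed mutation spec {mut!r}")
            offset_spec = f"{m.group(1)}{int(m.group(2)) - spec.fragment[0] + 1}{m.group(3)}"
        frag = apply_mutation(frag, offset_spec)
    seq = frag + "G" * spec.linker_len + spec.peptide
    first, last = spec.fragment
    header = (
        f">{spec.variant_name()} fragment={first}-{last}"
        f" linker={spec.linker_len}G peptide={spec.peptide}"
    )
    fasta = header + "\n" + "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60)) + "\n"
    return seq, fasta


def build_inputs(
    receptor_seq: str,
    mutations: Sequence[str] = ("D126H", "D126V", "D126A"),
    fragment: tuple[int, int] = (1, 390),
    linker_len: int = 30,
    peptide: str = "LKELR",
    include_wt: bool = True,
) -> list[tuple[DockingInputSpec, str, str]]:
    """Build the wild-type plus single-mutant input set.

    Returns ``(spec, sequence, fasta_text)`` triples, wild type first.
    """
    variant_sets: list[tuple[str, ...]] = [()] if include_wt else []
    variant_sets += [(m,) for m in mutations]
    out = []
    for muts in variant_sets:
        spec = DockingInputSpec(
            receptor_seq=receptor_seq,
            fragment=fragment,
            mutations=muts,
            linker_len=linker_len,
            peptide=peptide,
        )
        seq, fasta = build_input(spec)
        out.append((spec, seq, fasta))
    return out


def write_fasta_inputs(inputs: Sequence[tuple[DockingInputSpec, str, str]], path: str | Path) -> None:
    Path(path).write_text("".join(fasta for _, _, fasta in inputs))


def _one_letter(res_name: str) -> str:
    code = seq1(res_name.capitalize())
    return code.upper() if code else "X"


def extract_components(model: Structure, spec: DockingInputSpec) -> ModelComponents:
    """Dissect a predicted model into receptor, linker and peptide segments.

    Accepts either a single chain with continuous numbering over the whole
    construct, or one chain per segment (matched by segment lengths).  The
    linker segment must be all glycine and the peptide must match the spec's
    peptide sequence; violations raise :class:`ModelLayoutError` naming the
    offending position.
    """
    fl, ll, pl = spec.fragment_len, spec.linker_len, len(spec.peptide)
    chains = model.chains

    if len(chains) == 1:
        residues = next(iter(chains.values()))
        if len(residues) != fl + ll + pl:
            raise ModelLayoutError(
                f"model length mismatch: expected {fl}+{ll}+{pl} = {fl + ll + pl} residues, "
                f"found {len(residues)}"
            )
        rec = residues[:fl]
        link = residues[fl : fl + ll]
        pep = residues[fl + ll :]
    elif len(chains) == 3 and sorted(len(r) for r in chains.values()) == sorted((fl, ll, pl)):
        by_len = {len(v): v for v in chains.values()}
        if len(by_len) < 3:
            raise ModelLayoutError(
                "cannot disambiguate segments: two chains share the same length"
            )
        rec, link, pep = by_len[fl], by_len[ll], by_len[pl]
    else:
        raise ModelLayoutError(
            f"model does not match the {fl}/{ll}/{pl} layout: chains "
            + ", ".join(f"{c} ({len(v)} res)" for c, v in chains.items())
        )

    for k, res in enumerate(link):
        if res.rid.res_name.upper() != "GLY":
            raise ModelLayoutError(
                f"non-glycine residue {res.rid.res_name} at linker position {k + 1} "
                f"(residue {res.rid})"
            )
    pep_seq = "".join(_one_letter(r.rid.res_name) for r in pep)
    if pep_seq != spec.peptide.upper():
        raise ModelLayoutError(
            f"peptide segment reads {pep_seq!r}, expected {spec.peptide.upper()!r}"
        )

    numbering = {i + 1: spec.fragment[0] + i for i in range(fl)}
    return ModelComponents(
        receptor=Structure(id=f"{model.id}:receptor", residues=list(rec), source=model.source),
        linker=Structure(id=f"{model.id}:linker", residues=list(link), source=model.source),
        peptide=Structure(id=f"{model.id}:peptide", residues=list(pep), source=model.source),
        numbering_map=numbering,
    )


def classify_docked(
    components: ModelComponents,
    native: ContactMap,
    params: ContactParams = ContactParams(),
    threshold: float = 0.5,
    native_peptide: Sequence[ResidueID] | None = None,
) -> tuple[str, RecapReport]:
    """Classify a model as docked/undocked by native-contact recapitulation.

    The model's receptor–peptide contact map is computed with the linker
    excluded, translated into the native complex's residue identities
    (receptor by author number, peptide by order), and compared against the
    native map.  Verdict is ``"docked"`` iff the recapitulated fraction is
    ≥ ``threshold``.

    ``native_peptide`` should list the native complex's peptide residues in
    chain order; when omitted, the peptide residues appearing in the native
    contact map are used (sufficient whenever every peptide residue makes at
    least one native contact).
    """
    model_map = heavy_atom_contacts(components.receptor, components.peptide, params)

    native_rec_by_number = {rid.number: rid for rid in native.receptor_residues()}
    native_pep_in_order = (
        list(native_peptide) if native_peptide is not None else native.peptide_residues()
    )
    model_pep_in_order = [r.rid for r in components.peptide.residues]
    # anchor at the C-terminus: the degron grammar is C-terminal, so if the
    # native map lacks an N-terminal peptide residue the pairing stays right
    pep_map = dict(zip(reversed(model_pep_in_order), reversed(native_pep_in_order)))

    def mapping(rid: ResidueID) -> ResidueID:
        if rid in pep_map:
            return pep_map[rid]
        return native_rec_by_number.get(rid.number, rid)

    report = recapitulation(native, model_map, mapping)
    verdict = "docked" if report.fraction >= threshold else "undocked"
    return verdict, report
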