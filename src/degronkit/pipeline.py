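"""End-to-end orchestration: census, model evaluation, ortholog comparison.

Each ``run_*`` function takes a :class:`RunConfig` (whose defaults are the
reference settings used throughout the toolkit: 4 Å contact cutoff, pocket
residues 76–191, receptor fragment 1–390, 30-glycine linker, LKELR peptide,
docked threshold 0.5) and returns a JSON-serializable report that embeds
the fully resolved configuration, so results are reproducible from the
report alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

from .align import AlignmentConfig, conservation_at, format_pair, map_position, needleman_wunsch
from .census import MotifGrammar, DEFAULT_GRAMMAR, scan_proteome
from .contacts import ContactMap, ContactParams, heavy_atom_contacts
from .docking import DockingInputSpec, classify_docked, extract_components
from .errors import DegronkitError
from .structure import Structure, read_structure
from .superpose import PocketSpec, pocket_rmsd

__all__ = ["RunConfig", "binding_positions", "run_evaluate", "run_census", "run_ortholog"]


def binding_positions(native: ContactMap) -> list[int]:
    """Default 'binding residues' query set: the receptor residues of a
    native contact map, as sorted author numbers (published binding-residue
    lists are often not printed in full, so the experimental interface is
    the natural stand-in)."""
    return sorted({rid.number for rid in native.receptor_residues()})


@dataclass(frozen=True)
class RunConfig:
    """Defaults reproduce the reference FEM1C/SIL1 analysis settings."""

    cutoff: float = 4.0
    pocket: tuple[int, int] = (76, 191)
    fragment: tuple[int, int] = (1, 390)
    linker_len: int = 30
    peptide: str = "LKELR"
    threshold: float = 0.5

    def contact_params(self) -> ContactParams:
        return ContactParams(cutoff=self.cutoff)

    def pocket_spec(self) -> PocketSpec:
        return PocketSpec(first=self.pocket[0], last=self.pocket[1])


def _load(source: str | Path | Structure) -> Structure:
    if isinstance(source, Structure):
        return source
    return read_structure(source)


def _one_letter_seq(residues) -> str:
    from Bio.SeqUtils import seq1

    return "".join((seq1(r.rid.res_name.capitalize()) or "X").upper() for r in residues)


def native_contact_map(
    native: str | Path | Structure,
    peptide_chain: str,
    cfg: RunConfig = RunConfig(),
) -> tuple[ContactMap, Structure, Structure]:
    """Split an experimental complex into receptor/peptide and map contacts."""
    complex_ = _load(native)
    chains = complex_.chains
    if peptide_chain not in chains:
        raise DegronkitError(
            f"peptide chain {peptide_chain!r} not in complex; chains: {list(chains)}"
        )
    peptide = Structure(
        id=f"{complex_.id}:{peptide_chain}", residues=chains[peptide_chain], source=complex_.source
    )
    receptor_residues = [r for c, res in chains.items() if c != peptide_chain for r in res]
    receptor = Structure(id=f"{complex_.id}:receptor", residues=receptor_residues, source=complex_.source)
    cmap = heavy_atom_contacts(receptor, peptide, cfg.contact_params())
    return cmap, receptor, peptide


def run_evaluate(
    native: str | Path | Structure,
    peptide_chain: str,
    models: Sequence[tuple[str, str | Path | Structure]],
    cfg: RunConfig = RunConfig(),
) -> dict:
    """Evaluate predicted linker-threaded models against a native complex.

    ``models`` is a sequence of ``(variant_name, source)``; each model is
    dissected into receptor/linker/peptide, scored for native-contact
    recapitulation and pocket RMSD (both superposition modes), and given a
    docked/undocked verdict.  The summary lists the variants with at least
    one docked model.
    """
    if not models:
        raise DegronkitError("no models to evaluate")
    native_map, native_receptor, native_peptide = native_contact_map(native, peptide_chain, cfg)

    rows = []
    docked_variants: set[str] = set()
    for variant, source in models:
        model = _load(source)
        rec_len = len(model) - cfg.linker_len - len(cfg.peptide)
        if rec_len < 1:
            raise DegronkitError(
                f"model {model.id!r} too short for linker {cfg.linker_len} "
                f"+ peptide {cfg.peptide!r}"
            )
        receptor_seq = _one_letter_seq(model.residues[:rec_len])
        spec = DockingInputSpec(
            receptor_seq=receptor_seq,
            fragment=(1, rec_len),
            linker_len=cfg.linker_len,
            peptide=cfg.peptide,
        )
        components = extract_components(model, spec)
        verdict, recap = classify_docked(
            components,
            native_map,
            cfg.contact_params(),
            cfg.threshold,
            native_peptide=[r.rid for r in native_peptide.residues],
        )
        row = {
            "variant": variant,
            "model": model.id,
            "source": model.source,
            "n_native": recap.n_native,
            "n_recapitulated": recap.n_recapitulated,
            "fraction": recap.fraction,
            "verdict": verdict,
        }
        for mode in ("all_pairs", "reject"):
            try:
                sup = pocket_rmsd(
                    components.receptor, native_receptor, cfg.pocket_spec(), mode=mode
                )
                row[f"rmsd_{mode}"] = sup.rmsd
                row[f"n_pairs_{mode}"] = sup.n_pairs
            except DegronkitError as exc:
                row[f"rmsd_{mode}"] = None
                row[f"rmsd_{mode}_error"] = str(exc)
        rows.append(row)
        if verdict == "docked":
            docked_variants.add(variant)

    return {
        "config": asdict(cfg),
        "n_models": len(rows),
        "models": rows,
        "docked_variants": sorted(docked_variants),
    }


def run_census(
    fasta: str | Path,
    cfg: RunConfig = RunConfig(),
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
    canonical_only: bool = False,
) -> dict:
    """Scan a proteome FASTA and summarize per-class / union counts."""
    matches, summary = scan_proteome(fasta, grammar=grammar, canonical_only=canonical_only)
    return {
        "config": {**asdict(cfg), "canonical_only": canonical_only},
        "summary": summary.as_dict(),
        "matches": [
            {
                "protein_id": m.protein_id,
                "length": m.length,
                "terminal_window": m.terminal_window,
                "classes": sorted(m.classes),
            }
            for m in matches
        ],
    }


def run_ortholog(
    seq_a: str,
    seq_b: str,
    a_start: int = 1,
    b_start: int = 1,
    positions: Sequence[int] = (),
    aln_cfg: AlignmentConfig = AlignmentConfig(),
    name_a: str = "a",
    name_b: str = "b",
) -> dict:
    """Align two ortholog fragments and report conservation at queried positions."""
    aln = needleman_wunsch(seq_a, seq_b, aln_cfg, a_start=a_start, b_start=b_start)
    report: dict = {
        "config": asdict(aln_cfg),
        "a_start": a_start,
        "b_start": b_start,
        "score": aln.score,
        "identity": aln.identity,
        "alignment": format_pair(aln, name_a, name_b),
    }
    if positions:
        cons = conservation_at(aln, positions)
        report["positions"] = {
            str(pos): {
                "maps_to": map_position(aln, pos),
                "call": cons.calls[pos],
                "residue_a": aln.a[pos - a_start],
            }
            for pos in positions
        }
        report["conservation_counts"] = cons.counts
        report["n_conserved"] = cons.n_conserved
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
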