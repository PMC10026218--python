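# degronkit

Structural-bioinformatics toolkit for C-degron biology: scan proteomes for
C-terminal Arg/C-degron motifs, measure receptor–peptide contact maps and
native-contact recapitulation in predicted complexes, compute pocket Cα
RMSD by optimal rigid-body superposition, and compare ortholog binding
regions by global alignment with conservation calls.

It is aimed at people assessing missense variants in CRL (cullin-RING
ligase) substrate receptors of the FEM1 family — e.g. FEM1C, whose
degron-binding pocket engages the C-terminal arginine of substrates such
as SIL1 (degron `LKELR`) — and, more generally, at anyone evaluating
linker-mediated peptide-docking models against an experimental complex.

## What it computes

**Degron grammar.** A protein C-terminus matches the core Arg/C-degron
classes `[RK]-X-X-R` or `[RK]-X-R` (X = any amino acid, patterns anchored
at the terminus), or their weaker `-G` / `-A` extended forms
(`[RK]-X-X-R-G`, `[RK]-X-R-G`, `[RK]-X-X-R-A`, `[RK]-X-R-A`). The census
counts proteins (not occurrences) per class and per union.

**Contact maps.** Residues *r* (receptor) and *p* (peptide) are in contact
iff min over heavy-atom pairs of ‖x<sub>i</sub> − x<sub>j</sub>‖ ≤ 4.0 Å
(inclusive). A model's quality against an experimental complex is the
fraction of native contacts recapitulated, f = |C<sub>model</sub> ∩
C<sub>native</sub>| / |C<sub>native</sub>|; a model is *docked* when
f ≥ 0.5 (threshold exposed and recorded).

**Superposition.** Kabsch's closed-form solution (SVD of the
cross-covariance, reflection-corrected to det R = +1) minimizes the Cα
RMSD over a residue range such as a degron pocket (76–191 by default).
An optional reject mode re-fits up to 5 cycles, discarding pairs with
residual > 2 × current RMSD, emulating molecular-viewer `align` commands.

**Ortholog comparison.** Needleman–Wunsch/Gotoh global alignment with
affine gaps (BLOSUM62, open 10, extend 0.5, end gaps free — the EMBOSS
Needle web defaults), a position map between the two numbering schemes,
and per-position conservation calls (identical / similar by
physicochemical group / different / unaligned).

**Docking inputs.** The single-chain trick: receptor fragment (1–390 by
default) + 30×Gly linker + degron peptide, with point mutations (`D126H`
style) applied to the fragment; predicted models are dissected back into
segments for evaluation.

## Worked example

`examples/` holds one short script per capability. For instance:

```
$ python examples/contact_map_recapitulation.py
native complex: 17 residue-level contacts at 4.0 Å
model recapitulates 14/17 native contacts (fraction 0.82) → docked
```

Seventeen receptor–peptide residue pairs sit within the 4 Å heavy-atom
cutoff in the reference complex; the predicted model reproduces 14 of
them (82 %), well above the 0.5 docked threshold, so its peptide occupies
the same pocket engaging the same receptor residues.

```
$ python examples/ortholog_conservation.py
position 126 maps to ortholog position 133
  position 100: similar
  position 126: identical
...
```

The alignment bridges the two proteins' numbering (position 126 of the
receptor pairs with 133 of the ortholog); `similar` marks substitutions
within a physicochemical group (F↔Y aromatic, K↔R basic) that typically
preserve pocket function.

The same operations are available from the shell:

```
degronkit scan --fasta proteome.fasta --out matches.tsv --summary summary.json
degronkit contacts --receptor complex.pdb --peptide-chain B --out contacts.tsv
degronkit evaluate --native-complex complex.pdb --peptide-chain B --model wt_model1.pdb ...
degronkit align --a fem1c.fa --a-range 70:220 --b fem1.fa --b-range 76:227 --positions 126
```

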