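# Methods

## Scope and data model

The toolkit covers the computational side of a C-degron pathogenicity
assessment: motif census, contact-map evaluation of predicted
receptor–peptide complexes, pocket superposition, and ortholog
conservation. Structures are held in a small in-memory model (chains →
residues → heavy atoms, Å coordinates, author numbering); parsing of PDB
and mmCIF is delegated to gemmi, FASTA IO and substitution matrices to
Biopython. The PDB writer is a fixed-column formatter of our own: the
round trip read∘write∘read preserves residue identities exactly and
coordinates to the PDB field width (10⁻³ Å).

Reading applies fixed conventions: first model only; hydrogens and
deuteriums removed (every downstream distance is a heavy-atom distance);
waters and non-polymer ligands removed, while modified amino acids inside
a polymer chain are kept (the analyses are protein–peptide only);
alternate locations resolved to the highest-occupancy conformer with ties
broken by file order. Residue ranges are author-numbered, 1-based and
inclusive, matching how structure depositors and the literature quote
ranges such as 76–191.

## Contact maps and recapitulation

A receptor residue and a peptide residue are in contact iff the minimum
Euclidean distance over all heavy-atom pairs is ≤ the cutoff (default
4.0 Å, inclusive "not exceeding" semantics). Contacts are counted at
residue-pair level — a 5-residue degron against its pocket yields a
residue×residue map of order tens of pairs — while the number of
supporting atom pairs is kept per contact for diagnostics. No spatial
indexing is used: the largest inputs (a few thousand atoms against a few
dozen) need only a dense distance matrix, and the implementation is
checked against a brute-force double loop in the tests.

Recapitulation translates a model's residue identities into the native
complex's numbering (identity, an explicit table, or a function; the
mapping must be injective on the residues it touches) and reports
matched / missing / extra pairs plus the fraction of native contacts
reproduced. The docked/undocked verdict applies a threshold to that
fraction; 0.5 is the default, chosen so that a model must reproduce most
of the experimental interface to count as docked. The threshold is a
reporting convention, not a fitted constant, and is recorded in every
output.

## Superposition and pocket RMSD

`kabsch` implements the closed-form optimal rigid superposition: SVD of
the cross-covariance of centered point sets, with the reflection branch
corrected so det R = +1. Degenerate inputs (fewer than 3 pairs, collinear
points) raise rather than return an ill-determined rotation.

`pocket_rmsd` pairs Cα atoms over an author-numbered range, either by
equal residue number or through an explicit reference→model number map —
for cross-ortholog comparisons that map comes from the sequence
alignment, never from raw numbering. Two modes are reported side by side:

* **all_pairs** — one fit over every paired Cα;
* **reject** — up to 5 cycles, each discarding pairs whose residual
  exceeds 2.0 × the current cycle's RMSD, then re-fitting. These
  constants emulate the default outlier rejection of common viewer
  `align` commands; published cross-ortholog RMSD values are typically
  produced by such tools, and the two modes bracket the ±0.1–0.2 Å
  spread their unstated settings can introduce. A small absolute floor
  (10⁻⁸ Å) on the rejection threshold keeps an exact fit from discarding
  pairs on floating-point noise.

Reject-mode RMSD never increases across cycles and the pair count is
non-increasing; both properties are tested.

For validation the expected post-fit RMSD under isotropic per-atom
Gaussian noise σ on n atoms is taken as σ·√(3·(1 − 7/(2n))): 3n noisy
coordinates minus the fitted rigid-body degrees of freedom. At the pocket
sizes used (n ≈ 100) this is within a percent of the simpler σ√3
asymptote, and Monte-Carlo ensembles must land within 20 % of it.

## Degron grammar and census

The grammar has six C-terminally anchored classes: core `[RK]-X-X-R` and
`[RK]-X-R`, plus `-G` and `-A` extended forms. Specified positions are
satisfied only by the exact standard residues, so ambiguity codes
(X, B, Z, U, O) never satisfy `[RK]`, `R`, `G` or `A` — but they do
satisfy wildcard positions. A trailing `*` is stripped; a record with an
internal stop is skipped with a warning (likely pseudo-translation).
Counts are per protein record: a protein matching both core classes is
counted once in each class and once in the core union. Because the
classes differ in their terminal residue, core and extended unions are
provably disjoint. Isoform policy is left to the caller: every record
counts by default, and `--canonical-only` drops UniProt-style `-N`
isoform suffixes. Absolute counts on a real proteome depend on the
release and that policy, so they are reported, not asserted.

## Ortholog alignment

The aligner is our own Gotoh dynamic program over three states
(substitution, gap-in-b, gap-in-a) with deterministic traceback
(tie order: substitution > gap-in-b > gap-in-a). Defaults mirror the
EMBOSS Needle web service: BLOSUM62, gap open 10, gap extension 0.5, end
gaps free. A gap of length L costs open + (L − 1)·extend — the opening
penalty covers the first gap residue. EMBOSS's printed score charges the
extension on every gap residue instead; at these penalty scales the
optimal alignments coincide and only the printed score differs, and this
convention lets Biopython's `PairwiseAligner` serve as an independent
score oracle in the tests (alongside exhaustive enumeration for short
sequences). Identity is counted per alignment column, EMBOSS-style.

Fragment offsets (`a_start`, `b_start`) carry alignments of sub-sequences
into full-protein numbering, so a query at receptor position 126 can
report the ortholog's position 133. Conservation calls use configurable
physicochemical groups — {FYW}, {KRH}, {DE}, {ST}, {ILVM}, {NQ}, {AG},
{C}, {P} — grounded in the canonical conservative pairs (F/Y aromatic,
K/R basic); `similar` means same group, `unaligned` means the position
faces a gap. The default query set for "binding residues" is the receptor
side of the native contact map, since published binding-residue lists are
often not printed in full.

## Docking inputs and model dissection

Inputs are single chains: receptor fragment (default 1–390) + poly-Gly
linker (default 30) + peptide (default `LKELR`), with point mutations in
`XnY` notation (1-based, reference residue checked against the sequence).
Predicted models are dissected back into segments either by position in a
continuous single chain or by matching one chain per segment; the linker
must be all-glycine and the peptide must read back as the specified
sequence. The linker is excluded from all contact calculations, and the
verdict is invariant to arbitrary linker coordinates (tested).

## Synthetic generators

The generators stand in for downloadable inputs and carry exact ground
truth. Geometry is schematic, not physical: pseudo-Cα atoms lie on a
gentle helix (radius 3 Å, 20 Å spacing — the helix keeps Cα traces
non-collinear so rigid fits are well-posed), each residue carries a base
side-chain pseudo-atom, and each planted contact adds one dedicated
side-chain pseudo-atom per partner at an isolated "contact site" ≥ 46 Å
from every other site and both backbones. Within a site the two atoms sit
2.5–3.8 Å apart; everything else is ≥ cutoff + 1 Å away. This realizes
*any* bipartite contact pattern exactly — a fixed two-atoms-per-residue
layout cannot, once a residue must contact three or more partners, which
is why contact-degree-many side-chain atoms were chosen. Planted proteome
records get terminal windows constructed to match exactly one grammar
class (the position upstream of a short window is forced non-R/K so the
longer-arity pattern cannot also fire); decoy termini are
rejection-sampled until motif-free. All generators are pure functions of
their spec, seed included.

What the fixtures do *not* emulate: real side-chain packing and chemistry
(so no hydrogen-bond or energy statements), realistic amino-acid
composition (decoys are uniform over the 20 standard residues, which
makes accidental motifs more likely than in a real proteome — hence the
rejection step), sequence-structure consistency, and crystallographic
artifacts (altlocs and insertion codes are exercised by hand-written
miniatures instead). Passing tests therefore demonstrate the correctness
of the algorithms and bookkeeping, not agreement with any particular
external database release or deposited model set.

## Problem sizes and reproducibility

The test and acceptance workloads are sized for a laptop-class single
CPU: contact oracles sweep complexes up to ~30×8 residues, Monte-Carlo
RMSD bands use 116–100-residue pockets over 10–20 seeds, the census
oracle battery runs 10⁴ random termini per seed over three seeds, and
alignment enumeration covers all global alignments of sequences up to
length 6. `scripts/acceptance.py` regenerates everything it reports from
its `--seed`; reports embed the resolved configuration, and identical
inputs yield byte-identical outputs.

## Known limitations

* The PDB writer emits single-character chain ids and does not write
  mmCIF; structures with exotic chain naming round-trip through gemmi
  only on the reading side.
* Contact analysis has no notion of symmetry mates or biological
  assemblies; the deposited asymmetric unit is taken as the complex.
* The reject-mode constants are a convention, not a reverse-engineered
  match of any particular viewer; when a published RMSD depends on a
  tool's unstated rejection settings, both modes should be quoted.
* The census treats each FASTA record independently; proteome-level
  absolute counts shift across releases and isoform policies by design.
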