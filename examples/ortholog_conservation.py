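"""Ortholog binding-region alignment and conservation calls.

Aligns two synthetic ortholog binding-region fragments whose numbering
differs (the second protein's fragment starts 6 residues later and carries
a one-residue N-terminal extension, so equivalent positions are offset by
+7 — the FEM1C Asp126 / FEM-1 Asp133 situation), then classifies queried
binding residues as identical / similar / different.
"""

import numpy as np

from degronkit import map_position, needleman_wunsch, conservation_at
from degronkit.align import format_pair
from degronkit.synthetic import STANDARD_AA

rng = np.random.default_rng(11)
a_start, b_start = 70, 76

seq = list("".join(rng.choice(list(STANDARD_AA), size=151)))
seq[126 - a_start] = "D"        # the anchor aspartate, position 126
seq[100 - a_start] = "F"
seq[140 - a_start] = "K"
a_frag = "".join(seq)

b_body = list(a_frag)
b_body[100 - a_start] = "Y"     # F→Y: conserved chemistry (aromatic)
b_body[140 - a_start] = "R"     # K→R: conserved chemistry (basic)
b_frag = "M" + "".join(b_body)  # one-residue N-terminal extension

aln = needleman_wunsch(a_frag, b_frag, a_start=a_start, b_start=b_start)
print(format_pair(aln, "receptor", "ortholog").splitlines()[3], "\n")

print(f"position 126 maps to ortholog position {map_position(aln, 126)}")

positions = [90, 100, 110, 126, 140]
report = conservation_at(aln, positions)
for pos in positions:
    print(f"  position {pos}: {report.calls[pos]}")
print(f"conserved (identical or similar): {report.n_conserved}/{len(positions)}")
# 'similar' means a substitution within the same physicochemical group —
# the kind of change that typically preserves binding-pocket function.
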