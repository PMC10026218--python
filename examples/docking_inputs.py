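"""Build linker-mediated docking inputs for a receptor and its point mutants.

The single-chain trick: receptor fragment + flexible poly-Gly linker +
degron peptide, folded as one sequence by a structure predictor.  This
example builds the four input records (wild type and three Asp126 mutants)
and prints their layout.
"""

import numpy as np

from degronkit import build_inputs
from degronkit.synthetic import STANDARD_AA

# a synthetic stand-in receptor sequence with an aspartate at position 126
rng = np.random.default_rng(0)
receptor = list("".join(rng.choice(list(STANDARD_AA), size=617)))
receptor[125] = "D"
receptor = "".join(receptor)

inputs = build_inputs(
    receptor,
    mutations=("D126H", "D126V", "D126A"),
    fragment=(1, 390),
    linker_len=30,
    peptide="LKELR",
)
for spec, seq, _ in inputs:
    print(
        f"{spec.variant_name():>6s}: {len(seq)} residues "
        f"(fragment {spec.fragment[0]}–{spec.fragment[1]} + {spec.linker_len}×G + "
        f"{spec.peptide}), position 126 = {seq[125]}, tail ...{seq[-8:]}"
    )
# 390 + 30 + 5 = 425 residues per record; the four sequences differ only at
# position 126.  Write them with degronkit.docking.write_fasta_inputs and
# feed them to a structure predictor; evaluate the resulting models with
# `degronkit evaluate`.
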