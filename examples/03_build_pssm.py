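"""Build a motif PSSM from a seed alignment and inspect its scores.

Loads the shipped example seed alignment for motif C (which carries the
GDD catalytic triad), builds the log-odds matrix with the default
0.1-weight background pseudocount, and scores a consensus window versus a
background window.
"""

from pathlib import Path

import numpy as np

from palmprint import MotifAlignment, build_pssm, score_at
from palmprint.simulate import sample_background

msa_path = (Path(__file__).resolve().parents[1]
            / "src/palmprint/data/example_sets/pisuvi-like/C.fasta")
msa = MotifAlignment.from_fasta(msa_path, motif_label="C", group="pisuvi-like")
print(f"seed alignment: {len(msa.rows)} rows x {msa.length} columns")

pssm = build_pssm(msa)   # BLOSUM62 background, pseudocount weight 0.1
print(f"consensus: {pssm.consensus()}  (note the invariant GDD core)")

consensus_score = score_at(pssm, pssm.consensus(), 0)
background = sample_background(pssm.length, np.random.default_rng(3))
print(f"consensus window score:  {consensus_score:6.2f} bits")
print(f"background window score: {score_at(pssm, background, 0):6.2f} bits")
# A strongly positive consensus score and strongly negative background
# score is what makes the motif-score floor (2 bits) so discriminative.
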