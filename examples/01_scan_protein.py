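"""Detect a palmprint in a protein sequence.

Plants the catalytic A/B/C motifs of one example group in a synthetic
polymerase-like protein, then runs the detector and prints where each
motif landed, the variable-segment lengths, and the adjusted score that
decides high vs low confidence (threshold: 20 bits).
"""

import numpy as np

from palmprint import example_sets, make_positive, scan_aa

sets = [s for s in example_sets() if not s.is_rt]
rng = np.random.default_rng(1)

record, truth = make_positive(sets[2], rng, v1_len=40, v2_len=25, order="ABC",
                              record_id="demo_polymerase")
print(f"query: {record.id} ({len(record.seq)} aa), planted group {truth.group}")

hit = scan_aa(record, sets)
print(f"detected group {hit.group}, motif order {hit.order}")
for m in "ABC":
    start, end, score = hit.motifs[m]
    print(f"  motif {m}: {start:>3}-{end:<3} score {score:6.2f} bits")
print(f"V1={hit.v1_len} aa, V2={hit.v2_len} aa, "
      f"palmprint {hit.pp_start}-{hit.pp_end} ({hit.pp_len} aa)")
print(f"raw score {hit.raw_score:.2f}, adjusted {hit.adjusted_score:.2f} "
      f"-> {hit.confidence} confidence")
# The adjusted score equals the raw motif-score sum here because every
# segment length sits inside its expected band, so no penalties apply.
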