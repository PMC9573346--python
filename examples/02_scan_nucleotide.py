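"""Detect a palmprint in a nucleotide sequence via six-frame translation.

Reverse-translates a planted positive into reading frame 2 of the minus
strand, scans all six frames, and shows that the detector reports the
same barcode with forward-strand nucleotide coordinates.
"""

import numpy as np

from palmprint import example_sets, encode_nt, extract_palmprint, make_positive, scan_nt

sets = [s for s in example_sets() if not s.is_rt]
rng = np.random.default_rng(2)

protein, _ = make_positive(sets[0], rng, record_id="demo_contig")
nt = encode_nt(protein, rng, frame=2, strand="-")
print(f"nucleotide query: {len(nt.seq)} nt, protein hidden in frame -2")

hit = scan_nt(nt, sets)
print(f"hit in frame {hit.frame:+d} (strand {hit.strand}), group {hit.group}")
print(f"palmprint: aa {hit.pp_start}-{hit.pp_end} of the frame, "
      f"nt {hit.nt_start}-{hit.nt_end} on the forward strand")
barcode = extract_palmprint(hit)
print(f"barcode record {barcode.id}: {barcode.seq[:30]}... ({len(barcode.seq)} aa)")
# The nt interval is 3x the aa length: each palmprint residue maps back to
# one codon on the original sequence.
assert hit.nt_end - hit.nt_start + 1 == 3 * hit.pp_len
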