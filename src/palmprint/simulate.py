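"""Synthetic test-data generators with known ground truth.

Everything the detector and clusterer can be asked to find can be planted:
motif-bearing positives (canonical ABC and permuted CAB layouts), iid
background decoys, nucleotide encodings targeting any frame and strand,
and labelled multi-species palmprint populations for clustering and
threshold-tuning experiments. Each generator is deterministic under a
fixed seed and returns an explicit truth object where applicable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .cluster import global_align
from .pssm import AA_ORDER, BLOSUM62_BACKGROUND, PSSM
from .scanner import PssmSet, MOTIF_LABELS
from .seqio import SeqRecord, reverse_complement

__all__ = [
    "SyntheticTruth",
    "sample_motif",
    "sample_background",
    "make_positive",
    "make_decoy",
    "encode_nt",
    "make_species_population",
]


@dataclass
class SyntheticTruth:
    """Planted coordinates and labels for one generated record.

    Motif starts/ends are 1-based inclusive amino-acid coordinates in the
    emitted (or encoded) protein sequence.
    """

    record_id: str
    group: str
    order: str
    motif_starts: dict[str, int]
    motif_lengths: dict[str, int]
    v1_len: int
    v2_len: int
    pp_start: int
    pp_end: int
    frame: int | None = None
    strand: str | None = None
    species: str | None = None


def sample_background(length: int, rng: np.random.Generator,
                      background: np.ndarray | None = None) -> str:
    """An iid amino-acid string drawn from the background frequencies."""
    bg = BLOSUM62_BACKGROUND if background is None else np.asarray(background, float)
    idx = rng.choice(20, size=length, p=bg / bg.sum())
    return "".join(AA_ORDER[i] for i in idx)


def sample_motif(pssm: PSSM, rng: np.random.Generator,
                 temperature: float = 1.0) -> str:
    """Sample a motif instance from the probabilities implied by a PSSM.

    ``temperature`` sharpens (<1) or flattens (>1) the per-column
    distributions; temperature 0 returns the deterministic consensus.
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if temperature == 0:
        return pssm.consensus()
    probs = pssm.column_probabilities()
    out = []
    for p in probs:
        p = np.power(np.clip(p, 1e-300, None), 1.0 / temperature)
        p = p / p.sum()
        out.append(AA_ORDER[rng.choice(20, p=p)])
    return "".join(out)


def make_positive(pssm_set: PssmSet, rng: np.random.Generator,
                  v1_len: int = 40, v2_len: int = 25, order: str = "ABC",
                  flank_lens: tuple[int, int] = (10, 10),
                  temperature: float = 0.0,
                  record_id: str = "synthetic_positive"
                  ) -> tuple[SeqRecord, SyntheticTruth]:
    """A motif-bearing protein with background flanks and V segments.

    Motifs are laid out in the requested order (first, V1, second, V2,
    third) between background-sampled flanks; at the default temperature 0
    each motif is the PSSM consensus, giving a strong positive.
    """
    if order not in ("ABC", "CAB"):
        raise ValueError("order must be 'ABC' or 'CAB'")
    if v1_len < 0 or v2_len < 0 or min(flank_lens) < 0:
        raise ValueError("lengths must be non-negative")
    motif_seqs = {m: sample_motif(pssm_set.pssms[m], rng, temperature)
                  for m in MOTIF_LABELS}
    layout = list(order)   # e.g. ["C", "A", "B"]
    parts = [sample_background(flank_lens[0], rng),
             motif_seqs[layout[0]], sample_background(v1_len, rng),
             motif_seqs[layout[1]], sample_background(v2_len, rng),
             motif_seqs[layout[2]], sample_background(flank_lens[1], rng)]
    seq = "".join(parts)
    starts: dict[str, int] = {}
    pos = flank_lens[0]
    for i, label in enumerate(layout):
        starts[label] = pos + 1   # 1-based
        pos += len(motif_seqs[label])
        if i == 0:
            pos += v1_len
        elif i == 1:
            pos += v2_len
    lengths = {m: len(motif_seqs[m]) for m in MOTIF_LABELS}
    pp_start = starts[layout[0]]
    pp_end = starts[layout[2]] + lengths[layout[2]] - 1
    truth = SyntheticTruth(record_id=record_id, group=pssm_set.group, order=order,
                           motif_starts=starts, motif_lengths=lengths,
                           v1_len=v1_len, v2_len=v2_len,
                           pp_start=pp_start, pp_end=pp_end)
    return SeqRecord(id=record_id, seq=seq, alphabet="aa"), truth


def make_decoy(length: int, rng: np.random.Generator,
               background: np.ndarray | None = None,
               record_id: str = "decoy") -> SeqRecord:
    """An iid background-frequency protein with no planted motifs."""
    if length < 1:
        raise ValueError("length must be positive")
    return SeqRecord(id=record_id, seq=sample_background(length, rng, background),
                     alphabet="aa")


_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _STANDARD_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
_AA_TO_CODONS["*"] = sorted(_STANDARD_TABLE.stop_codons)
for _aa in _AA_TO_CODONS:
    _AA_TO_CODONS[_aa].sort()


def encode_nt(aa_record: SeqRecord, rng: np.random.Generator,
              frame: int = 1, strand: str = "+") -> SeqRecord:
    """Reverse-translate a protein into a nucleotide record.

    Synonymous codons are sampled uniformly; ``frame`` - 1 random bases are
    prepended so the protein lands in reading frame +-``frame`` of the
    requested strand. With frame 1 and strand '+', translating the result
    reproduces the protein exactly.
    """
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    codons = []
    for aa in aa_record.seq:
        options = _AA_TO_CODONS.get(aa)
        if options is None:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    prefix = "".join("ACGT"[rng.integers(4)] for _ in range(frame - 1))
    plus = prefix + "".join(codons)
    seq = plus if strand == "+" else reverse_complement(plus)
    return SeqRecord(id=aa_record.id, seq=seq, alphabet="nt",
                     description=f"encoded frame={frame} strand={strand}")


def _mutate(seq: str, n_subs: int, rng: np.random.Generator,
            background: np.ndarray | None = None) -> str:
    """Substitute ``n_subs`` distinct positions with different residues."""
    bg = BLOSUM62_BACKGROUND if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False)
    for p in positions:
        while True:
            alt = AA_ORDER[rng.choice(20, p=bg)]
            if alt != chars[p]:
                break
        chars[p] = alt
    return "".join(chars)


def make_species_population(rng: np.random.Generator, n_species: int = 20,
                            members_per_species: int = 10,
                            within_identity: float = 95.0,
                            between_identity: float = 70.0,
                            pp_len: int = 100,
                            member_tolerance: float = 2.0,
                            centroid_tolerance: float = 8.0,
                            max_tries: int = 500
                            ) -> tuple[list[SeqRecord], dict[str, str]]:
    """A labelled multi-species palmprint population for clustering tests.

    Species centroids descend from a common root so that centroid pairs sit
    near ``between_identity``; members are centroid copies with point
    substitutions near ``within_identity``. Realised identities are
    verified with the global aligner and redrawn until member-to-centroid
    identities fall within ``member_tolerance`` points of the target and
    centroid-to-centroid identities within ``centroid_tolerance`` points
    (pairwise constraints are jointly looser than the single member
    constraint; see the methods note).
    """
    if not (0.0 < between_identity < within_identity <= 100.0):
        raise ValueError("require 0 < between_identity < within_identity <= 100")
    root = sample_background(pp_len, rng)
    # mutating each centroid from the root at identity c gives pairwise
    # centroid identity near c^2
    c_frac = float(np.sqrt(between_identity / 100.0))
    k_centroid = round(pp_len * (1.0 - c_frac))
    k_member = round(pp_len * (1.0 - within_identity / 100.0))

    centroid_seqs: list[str] = []
    for _ in range(n_species):
        best = None
        for _try in range(max_tries):
            cand = _mutate(root, k_centroid, rng)
            pids = [global_align(cand, other).pct_identity for other in centroid_seqs]
            worst = max((abs(p - between_identity) for p in pids), default=0.0)
            if best is None or worst < best[0]:
                best = (worst, cand)
            if worst <= centroid_tolerance:
                break
        centroid_seqs.append(best[1])

    records: list[SeqRecord] = []
    labels: dict[str, str] = {}
    for si, cen in enumerate(centroid_seqs):
        sp = f"species{si + 1:03d}"
        cen_id = f"{sp}_00"
        records.append(SeqRecord(id=cen_id, seq=cen, alphabet="aa"))
        labels[cen_id] = sp
        for mi in range(1, members_per_species):
            for _try in range(max_tries):
                cand = _mutate(cen, k_member, rng)
                pid = global_align(cand, cen).pct_identity
                if abs(pid - within_identity) <= member_tolerance:
                    break
            rid = f"{sp}_{mi:02d}"
            records.append(SeqRecord(id=rid, seq=cand, alphabet="aa"))
            labels[rid] = sp
    return records, labels
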