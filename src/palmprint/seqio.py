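"""Sequence I/O and nucleotide-to-protein machinery.

FASTA reading/writing (via Biopython), IUPAC-aware reverse complement,
six-frame translation with the standard genetic code, and the coordinate
bookkeeping that maps amino-acid positions in a reading frame back to
1-based nucleotide intervals on the forward strand.

Internally all coordinates are 0-based half-open; everything user-facing
is 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq

__all__ = [
    "SeqRecord",
    "FrameTranslation",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "six_frame_translate",
    "frame_aa_to_nt_interval",
    "FRAMES",
]

NT_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
AA_EXTENDED = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZJUO*-")

#: frame order used everywhere: three forward, three reverse
FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV",
    "TGCANYRSWMKVHDB",
)


@dataclass
class SeqRecord:
    """A single sequence with a declared alphabet ('aa' or 'nt').

    Sequences are upper-cased on construction; for nucleotide records U is
    normalised to T, and for amino-acid records alignment gaps '-' are
    stripped (query sequences are unaligned).
    """

    id: str
    seq: str
    alphabet: str = "aa"
    description: str = ""

    def __post_init__(self) -> None:
        if self.alphabet not in ("aa", "nt"):
            raise ValueError(f"alphabet must be 'aa' or 'nt', got {self.alphabet!r}")
        s = self.seq.upper()
        if self.alphabet == "nt":
            s = s.replace("U", "T")
            bad = set(s) - NT_ALPHABET
        else:
            s = s.replace("-", "")
            bad = set(s) - AA_EXTENDED
        if not s:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if bad:
            pos = min(i for i, c in enumerate(s) if c in bad)
            raise ValueError(
                f"record {self.id!r}: residue {s[pos]!r} at position {pos + 1} "
                f"is not in the {self.alphabet} alphabet"
            )
        self.seq = s

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FrameTranslation:
    """One of the six translation frames of a nucleotide sequence.

    ``frame`` is +1/+2/+3 for the forward strand and -1/-2/-3 for the
    reverse complement; ``nt_offset`` is the 0-based offset of the first
    translated base on the strand being read.
    """

    frame: int
    aa_seq: str
    nt_offset: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


def read_fasta(path: str | Path, alphabet: str) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    One record per header, in file order. Raises ``ValueError`` on an empty
    file, on duplicate ids, and on residues outside the declared alphabet.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SeqRecord(id=rec.id, seq=str(rec.seq), alphabet=alphabet,
                      description=rec.description)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                # Bio.SeqIO descriptions repeat the id as first token; avoid doubling
                desc = rec.description
                if desc.startswith(rec.id + " "):
                    desc = desc[len(rec.id) + 1:]
                    header = f"{rec.id} {desc}"
                elif desc != rec.id:
                    header = f"{rec.id} {desc}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def reverse_complement(nt: str) -> str:
    """IUPAC-aware reverse complement of a DNA string (U accepted as T)."""
    s = nt.upper().replace("U", "T")
    bad = set(s) - NT_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide character(s) {sorted(bad)!r}")
    return s.translate(_COMPLEMENT)[::-1]


def _translate(nt: str) -> str:
    """Translate a nucleotide string with the standard code, dropping the
    trailing partial codon; ambiguous codons yield 'X' unless the code is
    unambiguous for that pattern; stops are '*'."""
    usable = len(nt) - (len(nt) % 3)
    if usable == 0:
        return ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return str(_BioSeq(nt[:usable]).translate(table=1))


def six_frame_translate(nt: str) -> list[FrameTranslation]:
    """Translate all six reading frames, in fixed order +1,+2,+3,-1,-2,-3."""
    s = nt.upper().replace("U", "T")
    if len(s) < 3:
        raise ValueError(f"nucleotide sequence of length {len(s)} is too short "
                         "to translate (need >= 3)")
    bad = set(s) - NT_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide character(s) {sorted(bad)!r}")
    rc = reverse_complement(s)
    out = []
    for frame in FRAMES:
        offset = abs(frame) - 1
        strand_seq = s if frame > 0 else rc
        out.append(FrameTranslation(frame=frame,
                                    aa_seq=_translate(strand_seq[offset:]),
                                    nt_offset=offset))
    return out


def frame_aa_to_nt_interval(frame: int, nt_len: int, aa_start: int, aa_end: int
                            ) -> tuple[int, int, str]:
    """Map a 1-based inclusive aa interval in a reading frame to the 1-based
    inclusive nucleotide interval on the *forward* strand.

    Returns ``(nt_start, nt_end, strand)`` with ``nt_start <= nt_end``.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    if not (1 <= aa_start <= aa_end):
        raise ValueError("require 1 <= aa_start <= aa_end")
    offset = abs(frame) - 1
    lo = offset + 3 * (aa_start - 1)      # 0-based on the strand being read
    hi = offset + 3 * aa_end              # exclusive
    if hi > nt_len:
        raise ValueError("aa interval extends past the end of the sequence")
    if frame > 0:
        return lo + 1, hi, "+"
    # positions on the reverse strand map back as p_fwd = nt_len - p_rev + 1
    return nt_len - hi + 1, nt_len - lo, "-"
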