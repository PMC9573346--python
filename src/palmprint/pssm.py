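"""Position-specific scoring matrices for catalytic-motif detection.

A PSSM represents a gap-free motif alignment as per-column log-odds scores
(bits) for each of the 20 amino acids:

    score[i][a] = log2(p_ia / b_a)

where p_ia is the pseudocount-smoothed probability of residue a in column i
and b_a the background frequency. A window of a query sequence is scored
ungapped as the sum of per-column lookups; the best window placement of a
motif is the maximum of this sliding sum.

The background defaults to the BLOSUM62 marginal amino-acid frequencies and
the smoothing to a 0.1-weight mixture with the background:
p = 0.9 * observed + 0.1 * background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AA_ORDER",
    "BLOSUM62_BACKGROUND",
    "MotifAlignment",
    "PSSM",
    "MotifHit",
    "build_pssm",
    "score_at",
    "best_hit",
    "top_hits",
    "window_scores",
    "encode_frame",
    "save_pssm",
    "load_pssm",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(AA_ORDER)}

#: BLOSUM62 marginal amino-acid frequencies (Henikoff & Henikoff), sum = 1.
BLOSUM62_BACKGROUND = np.array([
    0.074,  # A
    0.025,  # C
    0.054,  # D
    0.054,  # E
    0.047,  # F
    0.074,  # G
    0.026,  # H
    0.068,  # I
    0.058,  # K
    0.099,  # L
    0.025,  # M
    0.045,  # N
    0.039,  # P
    0.034,  # Q
    0.052,  # R
    0.057,  # S
    0.051,  # T
    0.073,  # V
    0.013,  # W
    0.032,  # Y
])

SCORE_FLOOR = -20.0   # stands in for log2(0) when pseudocount weight is 0
STOP_SCORE = -100.0   # '*' vetoes any window containing it

# residues scored as neutral (0 bits): unknowns and rare non-standard codes
NEUTRAL_RESIDUES = "XBZJUO"

_N_CODES = 22
_NEUTRAL_CODE = 20
_STOP_CODE = 21

_CHAR_TO_CODE = np.full(128, -1, dtype=np.int16)
for _c, _i in _AA_INDEX.items():
    _CHAR_TO_CODE[ord(_c)] = _i
for _c in NEUTRAL_RESIDUES:
    _CHAR_TO_CODE[ord(_c)] = _NEUTRAL_CODE
_CHAR_TO_CODE[ord("*")] = _STOP_CODE


def encode_frame(frame: str) -> np.ndarray:
    """Encode an amino-acid string as integer codes for fast PSSM scoring.

    Raises ``ValueError`` naming the first offending position if a character
    is not a standard residue, a neutral code (X/B/Z/J/U/O) or '*'.
    """
    raw = np.frombuffer(frame.encode("ascii"), dtype=np.uint8)
    codes = _CHAR_TO_CODE[raw]
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise ValueError(f"invalid residue {frame[pos]!r} at position {pos + 1}")
    return codes


@dataclass
class MotifAlignment:
    """A gap-light seed alignment for one motif (A, B or C) of one group."""

    rows: list[str]
    motif_label: str
    group: str

    def __post_init__(self) -> None:
        if self.motif_label not in ("A", "B", "C"):
            raise ValueError(f"motif_label must be A, B or C, got {self.motif_label!r}")
        if len(self.rows) < 2:
            raise ValueError("motif alignment needs at least 2 rows")
        self.rows = [r.upper() for r in self.rows]
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("ragged motif alignment: rows differ in length")
        if not (1 <= L <= 30):
            raise ValueError(f"motif length {L} outside the supported range 1..30")
        for r in self.rows:
            bad = set(r) - set(AA_ORDER) - {"-"}
            if bad:
                raise ValueError(f"invalid residue(s) {sorted(bad)!r} in motif row")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path: str | Path, motif_label: str, group: str) -> "MotifAlignment":
        from .seqio import read_fasta  # local import to avoid cycle at module load
        from Bio import SeqIO
        rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
        if not rows:
            raise ValueError(f"no rows in motif alignment {path}")
        return cls(rows=rows, motif_label=motif_label, group=group)


@dataclass
class PSSM:
    """An L x 20 log-odds matrix (bits) with its background model."""

    scores: np.ndarray
    motif_label: str
    group: str
    background: np.ndarray
    pseudocount_weight: float

    _ext: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be an L x 20 matrix")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        ext = np.zeros((self.length, _N_CODES), dtype=np.float64)
        ext[:, :20] = self.scores
        ext[:, _NEUTRAL_CODE] = 0.0
        ext[:, _STOP_CODE] = STOP_SCORE
        self._ext = ext

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def column_probabilities(self) -> np.ndarray:
        """Recover the implied per-column residue probabilities b * 2**score."""
        return self.background[None, :] * np.exp2(self.scores)

    def consensus(self) -> str:
        """Highest-scoring residue per column (ties: first in AA_ORDER)."""
        return "".join(AA_ORDER[i] for i in np.argmax(self.scores, axis=1))


@dataclass(frozen=True)
class MotifHit:
    """Best ungapped placement of one PSSM on one frame (start is 0-based)."""

    group: str
    motif_label: str
    start: int
    length: int
    score: float


def build_pssm(msa: MotifAlignment,
               background: Sequence[float] | None = None,
               pseudocount_weight: float = 0.1) -> PSSM:
    """Build a log-odds PSSM from a motif alignment.

    Per column i: observed frequency f_ia over non-gap rows, smoothed
    p_ia = (1 - w) * f_ia + w * b_a, score = log2(p_ia / b_a). A column in
    which every row is a gap is an error; with w = 0, unobserved residues
    are floored at ``SCORE_FLOOR`` rather than -inf.
    """
    bg = BLOSUM62_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (20,) or abs(float(bg.sum()) - 1.0) > 1e-9:
        raise ValueError("background must be 20 frequencies summing to 1")
    if not (0.0 <= pseudocount_weight < 1.0):
        raise ValueError("pseudocount_weight must be in [0, 1)")
    L = msa.length
    w = pseudocount_weight
    scores = np.empty((L, 20), dtype=np.float64)
    for i in range(L):
        col = [r[i] for r in msa.rows if r[i] != "-"]
        if not col:
            raise ValueError(f"column {i + 1} of motif {msa.motif_label} is all gaps")
        counts = np.zeros(20)
        for c in col:
            counts[_AA_INDEX[c]] += 1.0
        p = (1.0 - w) * (counts / len(col)) + w * bg
        with np.errstate(divide="ignore"):
            scores[i] = np.log2(p / bg)
        scores[i] = np.maximum(scores[i], SCORE_FLOOR)
    return PSSM(scores=scores, motif_label=msa.motif_label, group=msa.group,
                background=bg, pseudocount_weight=w)


def score_at(pssm: PSSM, frame: str, s: int) -> float:
    """Ungapped log-odds score of ``pssm`` placed at 0-based start ``s``.

    Neutral residues contribute 0 bits; '*' contributes ``STOP_SCORE``.
    """
    L = pssm.length
    if not (0 <= s <= len(frame) - L):
        raise ValueError(f"start {s} out of range for frame of length {len(frame)}")
    codes = encode_frame(frame[s:s + L])
    total = 0.0
    for i in range(L):
        total += pssm._ext[i, codes[i]]
    return total


def window_scores(pssm: PSSM, frame: str | np.ndarray) -> np.ndarray:
    """Scores of every placement of ``pssm`` along ``frame`` (may be empty)."""
    codes = encode_frame(frame) if isinstance(frame, str) else frame
    L = pssm.length
    m = len(codes) - L + 1
    if m <= 0:
        return np.empty(0, dtype=np.float64)
    total = np.zeros(m, dtype=np.float64)
    ext = pssm._ext
    for i in range(L):
        total += ext[i, codes[i:i + m]]
    return total


def best_hit(pssm: PSSM, frame: str | np.ndarray) -> MotifHit | None:
    """Highest-scoring placement; ties broken by the smallest start.

    Returns ``None`` when the frame is shorter than the motif.
    """
    scores = window_scores(pssm, frame)
    if scores.size == 0:
        return None
    s = int(np.argmax(scores))
    return MotifHit(group=pssm.group, motif_label=pssm.motif_label,
                    start=s, length=pssm.length, score=float(scores[s]))


def top_hits(pssm: PSSM, frame: str | np.ndarray, k: int) -> list[MotifHit]:
    """The ``k`` best placements, score-descending (ties: smaller start)."""
    scores = window_scores(pssm, frame)
    if scores.size == 0:
        return []
    order = np.lexsort((np.arange(scores.size), -scores))[:k]
    return [MotifHit(group=pssm.group, motif_label=pssm.motif_label,
                     start=int(s), length=pssm.length, score=float(scores[s]))
            for s in order]


def save_pssm(pssm: PSSM, path: str | Path) -> None:
    """Serialise a PSSM to a plain-text, round-trippable format."""
    with open(path, "w") as fh:
        fh.write("# palmprint pssm v1\n")
        fh.write(f"group\t{pssm.group}\n")
        fh.write(f"motif\t{pssm.motif_label}\n")
        fh.write(f"L\t{pssm.length}\n")
        fh.write(f"pseudocount_weight\t{pssm.pseudocount_weight!r}\n")
        fh.write("background\t" + "\t".join(repr(float(x)) for x in pssm.background) + "\n")
        fh.write("alphabet\t" + "\t".join(AA_ORDER) + "\n")
        for row in pssm.scores:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def load_pssm(path: str | Path) -> PSSM:
    """Load a PSSM written by :func:`save_pssm`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("# palmprint pssm"):
        raise ValueError(f"{path} is not a palmprint PSSM file")
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    background = None
    for ln in lines[1:]:
        parts = ln.split("\t")
        if parts[0] == "background":
            background = np.array([float(x) for x in parts[1:]])
        elif parts[0] in ("group", "motif", "L", "pseudocount_weight"):
            meta[parts[0]] = parts[1]
        elif parts[0] == "alphabet":
            if "".join(parts[1:]) != AA_ORDER:
                raise ValueError("unexpected alphabet order in PSSM file")
        else:
            rows.append([float(x) for x in parts])
    scores = np.array(rows)
    if scores.shape != (int(meta["L"]), 20):
        raise ValueError("PSSM score matrix shape does not match header")
    return PSSM(scores=scores, motif_label=meta["motif"], group=meta["group"],
                background=background,
                pseudocount_weight=float(meta["pseudocount_weight"]))
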