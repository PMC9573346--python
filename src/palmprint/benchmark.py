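"""Validation harness: sensitivity / PPV / FDR over labelled datasets and
the random-nucleotide decoy experiment.

A prediction is a reported high-confidence, non-RT palmprint. PPV is the
number of correct predictions over all predictions; FDR the number of
incorrect predictions over all predictions; unclassified queries enter
neither. The decoy scan streams seeded random nucleotide sequence through
the detector in overlapping chunks and counts (deduplicated)
high-confidence hits, estimating the false-positive rate per letter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .scanner import HeuristicConfig, PalmprintHit, PssmSet, scan_aa, scan_nt
from .seqio import SeqRecord, read_fasta

__all__ = [
    "DatasetEval",
    "AccuracySummary",
    "DecoyResult",
    "evaluate_datasets",
    "decoy_scan",
]


@dataclass(frozen=True)
class DatasetEval:
    """Hit counts for one labelled dataset (Pos = should contain RdRP)."""

    name: str
    polarity: str                  # "Pos" or "Neg"
    n_sequences: int
    n_palmprints: int              # high-confidence non-RT hits

    @property
    def sensitivity(self) -> float | None:
        if self.polarity != "Pos":
            return None
        return self.n_palmprints / self.n_sequences


@dataclass(frozen=True)
class AccuracySummary:
    tp: int
    fp: int

    @property
    def ppv(self) -> float | None:
        total = self.tp + self.fp
        return self.tp / total if total else None

    @property
    def fdr(self) -> float | None:
        total = self.tp + self.fp
        return self.fp / total if total else None


def _is_prediction(hit: PalmprintHit | None) -> bool:
    return hit is not None and hit.confidence == "high" and not hit.is_rt


def evaluate_datasets(datasets: Sequence[tuple[str, str, object]],
                      sets: Sequence[PssmSet],
                      cfg: HeuristicConfig | None = None,
                      alphabet: str = "aa"
                      ) -> tuple[list[DatasetEval], AccuracySummary]:
    """Scan labelled datasets and summarise accuracy.

    ``datasets`` holds (name, polarity, source) triples where source is a
    FASTA path or a list of :class:`SeqRecord`. Hits on Pos datasets count
    as true positives, hits on Neg datasets as false positives.
    """
    cfg = cfg or HeuristicConfig()
    scan = scan_aa if alphabet == "aa" else scan_nt
    evals: list[DatasetEval] = []
    tp = fp = 0
    for name, polarity, source in datasets:
        if polarity not in ("Pos", "Neg"):
            raise ValueError(f"dataset {name!r}: polarity must be Pos or Neg")
        if isinstance(source, (str, Path)):
            try:
                records = read_fasta(source, alphabet=alphabet)
            except Exception as exc:
                raise ValueError(f"dataset {name!r}: cannot read {source}: {exc}") from exc
        else:
            records = list(source)
        n_hits = sum(_is_prediction(scan(rec, list(sets), cfg)) for rec in records)
        evals.append(DatasetEval(name=name, polarity=polarity,
                                 n_sequences=len(records), n_palmprints=n_hits))
        if polarity == "Pos":
            tp += n_hits
        else:
            fp += n_hits
    return evals, AccuracySummary(tp=tp, fp=fp)


@dataclass
class DecoyResult:
    """High-confidence hits found on a seeded random nucleotide stream."""

    total_nt: int
    fp_count: int
    #: (nt_start, nt_end, strand, adjusted_score) in global 1-based coords
    hits: list[tuple[int, int, str, float]] = field(default_factory=list)

    @property
    def fp_rate_per_nt(self) -> float:
        return self.fp_count / self.total_nt


def decoy_scan(total_nt: int, seed: int, sets: Sequence[PssmSet],
               cfg: HeuristicConfig | None = None,
               chunk_len: int = 1_000_000) -> DecoyResult:
    """Scan ``total_nt`` letters of seeded iid uniform {A,C,G,T} sequence.

    The stream is a pure function of the seed, so results are identical
    across ``chunk_len`` choices: chunks overlap by twice the maximum
    palmprint nucleotide length and duplicate hits in overlaps are removed
    by their global coordinates.
    """
    cfg = cfg or HeuristicConfig()
    if total_nt < chunk_len:
        raise ValueError("total_nt must be >= chunk_len")
    rng = np.random.default_rng(seed)
    stream = rng.integers(0, 4, size=total_nt, dtype=np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    overlap = 2 * 3 * cfg.pp_max_len
    step = chunk_len - overlap
    if step <= 0:
        raise ValueError("chunk_len too small for the configured overlap")
    seen: set[tuple[int, int, str]] = set()
    hits: list[tuple[int, int, str, float]] = []
    start = 0
    while start < total_nt:
        chunk = lut[stream[start:start + chunk_len]].tobytes().decode("ascii")
        if len(chunk) < 3:
            break
        rec = SeqRecord(id=f"decoy_{start}", seq=chunk, alphabet="nt")
        hit = scan_nt(rec, list(sets), cfg)
        if _is_prediction(hit):
            key = (start + hit.nt_start, start + hit.nt_end, hit.strand)
            if key not in seen:
                seen.add(key)
                hits.append((key[0], key[1], hit.strand, hit.adjusted_score))
        if start + chunk_len >= total_nt:
            break
        start += step
    hits.sort()
    return DecoyResult(total_nt=total_nt, fp_count=len(hits), hits=hits)
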