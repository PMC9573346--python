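"""Palmprint detection: place A/B/C motif PSSMs on a query, enforce motif
order and spacing, score the candidate barcode and emit the segment.

The palmprint is the minimal segment of the polymerase palm sub-domain
containing all letters of the catalytic motifs A, B and C. In canonical
(ABC) order it runs from the first letter of A to the last letter of C; in
permuted (CAB) domains from the first letter of C to the last letter of B.
V1 and V2 are the variable segments between the first/second and
second/third motifs respectively.

Scoring starts from the sum of the three motif log-odds scores and is
adjusted by a ledger of heuristics (motif-score floor, V1/V2/palmprint
length bands). A candidate whose adjusted score reaches the
high-confidence threshold (default 20 bits) is reported as 'high'
confidence, otherwise 'low'.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

from . import pssm as _pssm
from .pssm import PSSM, MotifHit, best_hit, top_hits, build_pssm, encode_frame, MotifAlignment
from .seqio import SeqRecord, six_frame_translate, frame_aa_to_nt_interval

__all__ = [
    "PssmSet",
    "HeuristicConfig",
    "PalmprintHit",
    "find_motifs",
    "resolve_order",
    "score_palmprint",
    "scan_aa",
    "scan_nt",
    "extract_palmprint",
    "load_pssm_set",
    "load_pssm_sets",
    "build_pssm_set",
    "example_sets",
    "REPORT_COLUMNS",
    "hit_to_row",
    "write_report",
]

MOTIF_LABELS = ("A", "B", "C")


@dataclass
class PssmSet:
    """The three motif PSSMs (A, B, C) of one polymerase group."""

    group: str
    pssms: dict[str, PSSM]
    is_rt: bool = False

    def __post_init__(self) -> None:
        if set(self.pssms) != set(MOTIF_LABELS):
            raise ValueError(f"set {self.group!r} must have exactly motifs A, B, C")
        for label, p in self.pssms.items():
            if p.group != self.group:
                raise ValueError(f"PSSM group {p.group!r} != set group {self.group!r}")
            if p.motif_label != label:
                raise ValueError(f"PSSM labelled {p.motif_label!r} stored under {label!r}")

    @property
    def min_query_length(self) -> int:
        return max(p.length for p in self.pssms.values())

    @property
    def total_motif_length(self) -> int:
        return sum(p.length for p in self.pssms.values())


@dataclass
class HeuristicConfig:
    """The tunable score-adjustment ledger.

    All scores are in bits, all lengths in amino acids. A motif scoring
    below ``min_motif_score`` rejects the candidate outright; V1 shorter
    than ``v1_min`` costs ``v1_penalty``; V1 above its band, and V2 or the
    palmprint length outside their bands, each cost
    ``out_of_range_penalty``. ``top_k`` > 1 enables the exhaustive mode
    that considers the top-k placements per motif.
    """

    min_motif_score: float = 2.0
    v1_min: int = 35
    v1_max: int = 120
    v1_penalty: float = 5.0
    v2_min: int = 15
    v2_max: int = 90
    pp_min_len: int = 70
    pp_max_len: int = 160
    out_of_range_penalty: float = 5.0
    high_confidence_threshold: float = 20.0
    top_k: int = 1

    def __post_init__(self) -> None:
        if self.v1_min > self.v1_max or self.v2_min > self.v2_max \
                or self.pp_min_len > self.pp_max_len:
            raise ValueError("length-band bounds out of order")
        for name in ("v1_min", "v1_max", "v2_min", "v2_max",
                     "pp_min_len", "pp_max_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class PalmprintHit:
    """A complete palmprint detection on one frame of one query.

    All user-facing coordinates (motifs, palmprint, nucleotide interval)
    are 1-based inclusive; ``frame`` is +1 for amino-acid queries.
    """

    query_id: str
    frame: int
    group: str
    is_rt: bool
    order: str                          # "ABC" or "CAB"
    motifs: dict[str, tuple[int, int, float]]   # label -> (start, end, score)
    v1_len: int
    v2_len: int
    pp_start: int
    pp_end: int
    pp_seq: str
    raw_score: float
    adjusted_score: float
    confidence: str                     # "high" or "low"
    reject_reasons: list[str] = field(default_factory=list)
    strand: str = "."
    nt_start: int | None = None
    nt_end: int | None = None

    @property
    def pp_len(self) -> int:
        return self.pp_end - self.pp_start + 1


def find_motifs(frame: str, pssm_set: PssmSet, top_k: int = 1
                ) -> dict[str, list[MotifHit]]:
    """Best (or top-k) independent placements of each motif PSSM.

    Motifs whose PSSM is longer than the frame are absent from the map.
    """
    codes = encode_frame(frame)
    out: dict[str, list[MotifHit]] = {}
    for label in MOTIF_LABELS:
        hits = top_hits(pssm_set.pssms[label], codes, top_k)
        if hits:
            out[label] = hits
    return out


def resolve_order(hits: dict[str, MotifHit]) -> str:
    """Classify a motif placement triple as 'ABC', 'CAB' or 'rejected'.

    Motifs must be pairwise disjoint and in one of the two biological
    orders; any overlap or other permutation is rejected.
    """
    if set(hits) != set(MOTIF_LABELS):
        return "rejected"
    s = {m: h.start for m, h in hits.items()}
    e = {m: h.start + h.length for m, h in hits.items()}   # exclusive
    if e["A"] <= s["B"] and e["B"] <= s["C"]:
        return "ABC"
    if e["C"] <= s["A"] and e["A"] <= s["B"]:
        return "CAB"
    return "rejected"


def _geometry(hits: dict[str, MotifHit], order: str) -> tuple[int, int, int, int]:
    """(v1_len, v2_len, pp_start0, pp_end0_exclusive) for an ordered triple."""
    s = {m: h.start for m, h in hits.items()}
    e = {m: h.start + h.length for m, h in hits.items()}
    if order == "ABC":
        return s["B"] - e["A"], s["C"] - e["B"], s["A"], e["C"]
    if order == "CAB":
        return s["A"] - e["C"], s["B"] - e["A"], s["C"], e["B"]
    raise ValueError(f"order must be ABC or CAB, got {order!r}")


def score_palmprint(hits: dict[str, MotifHit], order: str,
                    cfg: HeuristicConfig) -> tuple[float, list[str]]:
    """Adjusted palmprint score and machine-readable reject reasons.

    The score starts from the sum of the three motif scores; rejection (any
    motif below the score floor) returns the adjusted score alongside the
    reasons, but a candidate with non-empty reasons is never reported.
    """
    reasons: list[str] = []
    for label in MOTIF_LABELS:
        if label not in hits:
            reasons.append(f"motif_missing:{label}")
    if reasons:
        return 0.0, reasons
    raw = sum(hits[m].score for m in MOTIF_LABELS)
    for label in MOTIF_LABELS:
        if hits[label].score < cfg.min_motif_score:
            reasons.append(f"motif_score_below_min:{label}")
    if order not in ("ABC", "CAB"):
        reasons.append("order_invalid")
        return raw, reasons
    v1, v2, pp_s, pp_e = _geometry(hits, order)
    pp_len = pp_e - pp_s
    adjusted = raw
    if v1 < cfg.v1_min:
        adjusted -= cfg.v1_penalty
    elif v1 > cfg.v1_max:
        adjusted -= cfg.out_of_range_penalty
    if not (cfg.v2_min <= v2 <= cfg.v2_max):
        adjusted -= cfg.out_of_range_penalty
    if not (cfg.pp_min_len <= pp_len <= cfg.pp_max_len):
        adjusted -= cfg.out_of_range_penalty
    return adjusted, reasons


def _best_combination(candidates: dict[str, list[MotifHit]]
                      ) -> tuple[dict[str, MotifHit], str] | None:
    """Highest-raw-score ordered, non-overlapping combination of placements."""
    if set(candidates) != set(MOTIF_LABELS):
        return None
    best = None
    for combo in product(*(candidates[m] for m in MOTIF_LABELS)):
        trip = dict(zip(MOTIF_LABELS, combo))
        order = resolve_order(trip)
        if order == "rejected":
            continue
        raw = sum(h.score for h in trip.values())
        if best is None or raw > best[0]:
            best = (raw, trip, order)
    if best is None:
        return None
    return best[1], best[2]


def _scan_frame(frame: str, query_id: str, sets: list[PssmSet],
                cfg: HeuristicConfig, frame_no: int = 1) -> PalmprintHit | None:
    """Scan one amino-acid frame against all PSSM sets; best raw score wins."""
    winner = None  # (raw, group, hit)
    for pssm_set in sorted(sets, key=lambda s: s.group):
        candidates = find_motifs(frame, pssm_set, top_k=cfg.top_k)
        if cfg.top_k == 1:
            trip = {m: hs[0] for m, hs in candidates.items()}
            order = resolve_order(trip)
        else:
            combo = _best_combination(candidates)
            if combo is None:
                trip = {m: hs[0] for m, hs in candidates.items()}
                order = "rejected"
            else:
                trip, order = combo
        adjusted, reasons = score_palmprint(trip, order, cfg)
        if order == "rejected" or reasons:
            continue
        raw = sum(trip[m].score for m in MOTIF_LABELS)
        if winner is not None and raw <= winner[0]:
            continue
        v1, v2, pp_s, pp_e = _geometry(trip, order)
        hit = PalmprintHit(
            query_id=query_id,
            frame=frame_no,
            group=pssm_set.group,
            is_rt=pssm_set.is_rt,
            order=order,
            motifs={m: (trip[m].start + 1, trip[m].start + trip[m].length,
                        trip[m].score) for m in MOTIF_LABELS},
            v1_len=v1,
            v2_len=v2,
            pp_start=pp_s + 1,
            pp_end=pp_e,
            pp_seq=frame[pp_s:pp_e],
            raw_score=raw,
            adjusted_score=adjusted,
            confidence="high" if adjusted >= cfg.high_confidence_threshold else "low",
        )
        winner = (raw, hit)
    return winner[1] if winner else None


def scan_aa(record: SeqRecord, sets: list[PssmSet],
            cfg: HeuristicConfig | None = None) -> PalmprintHit | None:
    """Scan an amino-acid query; returns the single best palmprint or None."""
    if not sets:
        raise ValueError("no PSSM sets supplied")
    if record.alphabet != "aa":
        raise ValueError(f"record {record.id!r} is not amino-acid")
    cfg = cfg or HeuristicConfig()
    return _scan_frame(record.seq, record.id, sets, cfg, frame_no=1)


def scan_nt(record: SeqRecord, sets: list[PssmSet],
            cfg: HeuristicConfig | None = None) -> PalmprintHit | None:
    """Six-frame translate a nucleotide query and scan every frame.

    The frame with the best adjusted score wins (ties resolved in frame
    order +1,+2,+3,-1,-2,-3); the hit carries 1-based forward-strand
    nucleotide coordinates of the palmprint and the strand sign.
    """
    if not sets:
        raise ValueError("no PSSM sets supplied")
    if record.alphabet != "nt":
        raise ValueError(f"record {record.id!r} is not nucleotide")
    cfg = cfg or HeuristicConfig()
    min_nt = 3 * min(s.total_motif_length for s in sets)
    if len(record.seq) < min_nt:
        raise ValueError(f"nucleotide query of length {len(record.seq)} is "
                         f"shorter than the minimum scannable length {min_nt}")
    best: PalmprintHit | None = None
    for ft in six_frame_translate(record.seq):
        hit = _scan_frame(ft.aa_seq, record.id, sets, cfg, frame_no=ft.frame)
        if hit is None:
            continue
        if best is None or hit.adjusted_score > best.adjusted_score:
            nt_s, nt_e, strand = frame_aa_to_nt_interval(
                ft.frame, len(record.seq), hit.pp_start, hit.pp_end)
            best = replace(hit, strand=strand, nt_start=nt_s, nt_end=nt_e)
    return best


def extract_palmprint(hit: PalmprintHit) -> SeqRecord:
    """The barcode segment of a non-rejected hit as an amino-acid record."""
    if hit.reject_reasons:
        raise ValueError(f"cannot extract a rejected hit: {hit.reject_reasons}")
    return SeqRecord(
        id=f"{hit.query_id}:{hit.pp_start}-{hit.pp_end}:{hit.frame:+d}",
        seq=hit.pp_seq,
        alphabet="aa",
        description=f"palmprint group={hit.group} order={hit.order} "
                    f"score={hit.adjusted_score:.1f}",
    )


# ---------------------------------------------------------------------------
# PSSM set loading

def build_pssm_set(msas: dict[str, MotifAlignment], is_rt: bool | None = None,
                   pseudocount_weight: float = 0.1) -> PssmSet:
    groups = {m.group for m in msas.values()}
    if len(groups) != 1:
        raise ValueError("motif alignments of one set must share a group name")
    group = groups.pop()
    if is_rt is None:
        is_rt = _infer_is_rt(group)
    return PssmSet(group=group,
                   pssms={label: build_pssm(m, pseudocount_weight=pseudocount_weight)
                          for label, m in msas.items()},
                   is_rt=is_rt)


def _infer_is_rt(group: str) -> bool:
    return "RT" in re.split(r"[-_.]", group.upper())


def load_pssm_set(directory: str | Path, is_rt: bool | None = None,
                  pseudocount_weight: float = 0.1) -> PssmSet:
    """Load one group's set from a directory holding A.fasta, B.fasta, C.fasta.

    RT-ness is inferred from an 'RT' token in the directory (group) name
    unless given explicitly.
    """
    directory = Path(directory)
    group = directory.name
    msas = {}
    for label in MOTIF_LABELS:
        path = directory / f"{label}.fasta"
        if not path.exists():
            raise FileNotFoundError(f"missing motif alignment {path}")
        msas[label] = MotifAlignment.from_fasta(path, motif_label=label, group=group)
    return build_pssm_set(msas, is_rt=is_rt, pseudocount_weight=pseudocount_weight)


def load_pssm_sets(root: str | Path, pseudocount_weight: float = 0.1) -> list[PssmSet]:
    """Load every group subdirectory under ``root``, sorted by group name."""
    root = Path(root)
    dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not dirs:
        raise ValueError(f"no PSSM set subdirectories under {root}")
    return [load_pssm_set(d, pseudocount_weight=pseudocount_weight) for d in dirs]


def example_sets(pseudocount_weight: float = 0.1) -> list[PssmSet]:
    """The small synthetic example sets shipped with the package.

    These have the canonical shape of catalytic-motif seed alignments
    (12-14aa motifs, invariant catalytic residues) but are synthetic
    demonstration data, not trained viral PSSMs.
    """
    root = Path(__file__).parent / "data" / "example_sets"
    return load_pssm_sets(root, pseudocount_weight=pseudocount_weight)


# ---------------------------------------------------------------------------
# Reporting

REPORT_COLUMNS = [
    "query_id", "frame", "strand", "group", "is_rt", "order",
    "A_start", "A_end", "A_score", "B_start", "B_end", "B_score",
    "C_start", "C_end", "C_score", "v1_len", "v2_len",
    "pp_start", "pp_end", "pp_len", "raw_score", "adjusted_score",
    "confidence", "reject_reasons",
]

_MISSING = "."


def hit_to_row(hit: PalmprintHit | None, query_id: str | None = None) -> list[str]:
    """One report row; a None hit yields a mostly-missing row for the query."""
    if hit is None:
        row = [query_id or _MISSING] + [_MISSING] * (len(REPORT_COLUMNS) - 1)
        return row
    vals: dict[str, object] = {
        "query_id": hit.query_id, "frame": f"{hit.frame:+d}", "strand": hit.strand,
        "group": hit.group, "is_rt": "yes" if hit.is_rt else "no",
        "order": hit.order, "v1_len": hit.v1_len, "v2_len": hit.v2_len,
        "pp_start": hit.pp_start, "pp_end": hit.pp_end, "pp_len": hit.pp_len,
        "raw_score": f"{hit.raw_score:.4f}",
        "adjusted_score": f"{hit.adjusted_score:.4f}",
        "confidence": hit.confidence,
        "reject_reasons": ";".join(hit.reject_reasons) or _MISSING,
    }
    for m in MOTIF_LABELS:
        s, e, sc = hit.motifs[m]
        vals[f"{m}_start"], vals[f"{m}_end"], vals[f"{m}_score"] = s, e, f"{sc:.4f}"
    return [str(vals[c]) for c in REPORT_COLUMNS]


def write_report(hits: list[tuple[str, PalmprintHit | None]], path: str | Path) -> None:
    """Write a TSV report (header + one row per query, '.' for missing)."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for query_id, hit in hits:
            fh.write("\t".join(hit_to_row(hit, query_id)) + "\n")
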