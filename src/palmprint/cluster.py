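"""Pairwise identity, species-like OTU clustering and threshold tuning.

Palmprints are same-scale (~100 aa) segments, so divergence is measured on
end-gap-penalised global alignments (Needleman-Wunsch, affine gaps,
BLOSUM62). Percent identity uses all alignment columns as the denominator.

Greedy centroid clustering mirrors the classic centroid-search strategy:
records are processed longest-first and join the first centroid (in
founding order) they match at or above the identity threshold, otherwise
they found a new cluster. The species-like threshold defaults to 90%
identity; coarser rank bands classify matches as species-like (>90),
genus-like (70-90], family-like (45-70] or phylum-like (<=45).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import SeqRecord

__all__ = [
    "PairwiseAlignment",
    "Cluster",
    "ThresholdEval",
    "global_align",
    "pct_identity",
    "cluster_greedy",
    "tune_threshold",
    "select_balancing_threshold",
    "rank_of_identity",
    "search_reference",
    "RANK_BANDS",
]

#: lower identity bound (exclusive) for each taxonomic-likeness band
RANK_BANDS = (("species-like", 90.0), ("genus-like", 70.0), ("family-like", 45.0),
              ("phylum-like", 0.0))


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences with its identity summary."""

    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    matches: int
    columns: int

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.matches / self.columns


@dataclass
class Cluster:
    """One species-like OTU: a centroid and its members with identities."""

    otu_id: str
    centroid_id: str
    members: list[tuple[str, float]] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return [m for m, _ in self.members]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ThresholdEval:
    """Species/cluster agreement statistics at one identity threshold."""

    threshold: float
    n_clusters: int
    n_split: int
    n_lumped: int
    n_lumped_and_split: int
    n_pure: int
    cluster_species_delta: int


def _make_aligner(matrix: str = "BLOSUM62", gap_open: float = 11.0,
                  gap_extend: float = 1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aligner.mode = "global"   # end gaps penalised
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def global_align(q: str | SeqRecord, t: str | SeqRecord,
                 matrix: str = "BLOSUM62", gap_open: float = 11.0,
                 gap_extend: float = 1.0) -> PairwiseAlignment:
    """End-gap-penalised global alignment with affine gap costs.

    The aligner's first-reported traceback is used, which is deterministic
    for fixed inputs; percent identity (matches over all columns) does not
    depend on the traceback chosen among co-optimal alignments in the
    populations handled here.
    """
    q_id, q_seq = (q.id, q.seq) if isinstance(q, SeqRecord) else ("query", q)
    t_id, t_seq = (t.id, t.seq) if isinstance(t, SeqRecord) else ("target", t)
    if not q_seq or not t_seq:
        raise ValueError("cannot align an empty sequence")
    if (matrix, gap_open, gap_extend) == ("BLOSUM62", 11.0, 1.0):
        aligner = _DEFAULT_ALIGNER
    else:
        aligner = _make_aligner(matrix, gap_open, gap_extend)
    # align the pair in canonical order so the chosen co-optimal traceback --
    # and hence the match count -- is exactly symmetric in the arguments
    if q_seq <= t_seq:
        aln = aligner.align(q_seq, t_seq)[0]
        a, b = str(aln[0]), str(aln[1])
    else:
        aln = aligner.align(t_seq, q_seq)[0]
        b, a = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return PairwiseAlignment(query_id=q_id, target_id=t_id,
                             aligned_query=a, aligned_target=b,
                             matches=matches, columns=len(a))


def pct_identity(q: str | SeqRecord, t: str | SeqRecord) -> float:
    return global_align(q, t).pct_identity


class _IdentityCache:
    """Memoised pairwise identity, symmetric in its arguments."""

    def __init__(self) -> None:
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, a: SeqRecord, b: SeqRecord) -> float:
        key = (a.id, b.id) if a.id <= b.id else (b.id, a.id)
        if key not in self._cache:
            self._cache[key] = global_align(a, b).pct_identity
        return self._cache[key]


def cluster_greedy(palmprints: Sequence[SeqRecord], threshold: float = 90.0,
                   _identity=None) -> list[Cluster]:
    """Greedy centroid clustering at a percent-identity threshold.

    Records are processed in length-descending order (ties: id
    lexicographic); each joins the first centroid, in founding order, with
    identity >= threshold, else founds a new cluster. The centroid is its
    own first member at 100%.
    """
    if not (0.0 < threshold <= 100.0):
        raise ValueError("threshold must be in (0, 100]")
    for rec in palmprints:
        if rec.alphabet != "aa":
            raise ValueError(f"record {rec.id!r} is not amino-acid")
    identity = _identity or _IdentityCache()
    clusters: list[Cluster] = []
    centroids: list[SeqRecord] = []
    for rec in sorted(palmprints, key=lambda r: (-len(r.seq), r.id)):
        for cl, cen in zip(clusters, centroids):
            pid = identity(rec, cen)
            if pid >= threshold:
                cl.members.append((rec.id, pid))
                break
        else:
            cl = Cluster(otu_id=f"OTU{len(clusters) + 1:04d}", centroid_id=rec.id,
                         members=[(rec.id, 100.0)])
            clusters.append(cl)
            centroids.append(rec)
    return clusters


def tune_threshold(palmprints: Sequence[SeqRecord],
                   species_labels: Mapping[str, str],
                   thresholds: Iterable[float]) -> list[ThresholdEval]:
    """Cluster at each threshold and tally species lumping/splitting.

    A species is *split* if its members occupy more than one cluster,
    *lumped* if any cluster containing it also contains another species,
    and *pure* if neither. ``cluster_species_delta`` = |n_clusters -
    n_species| supports picking the balancing threshold.
    """
    for rec in palmprints:
        if rec.id not in species_labels:
            raise KeyError(f"no species label for record {rec.id!r}")
    n_species = len(set(species_labels[r.id] for r in palmprints))
    identity = _IdentityCache()   # shared across thresholds
    evals = []
    for thr in thresholds:
        clusters = cluster_greedy(palmprints, threshold=thr, _identity=identity)
        species_to_clusters: dict[str, set[str]] = {}
        cluster_to_species: dict[str, set[str]] = {}
        for cl in clusters:
            for member_id in cl.member_ids:
                sp = species_labels[member_id]
                species_to_clusters.setdefault(sp, set()).add(cl.otu_id)
                cluster_to_species.setdefault(cl.otu_id, set()).add(sp)
        n_split = n_lumped = n_both = n_pure = 0
        for sp, otus in species_to_clusters.items():
            split = len(otus) > 1
            lumped = any(len(cluster_to_species[o]) > 1 for o in otus)
            n_split += split
            n_lumped += lumped
            n_both += split and lumped
            n_pure += not split and not lumped
        evals.append(ThresholdEval(
            threshold=float(thr), n_clusters=len(clusters),
            n_split=n_split, n_lumped=n_lumped, n_lumped_and_split=n_both,
            n_pure=n_pure,
            cluster_species_delta=abs(len(clusters) - n_species)))
    return evals


def select_balancing_threshold(evals: Sequence[ThresholdEval]) -> float:
    """The threshold balancing lumping and splitting of species.

    Minimises |n_clusters - n_species|; when several thresholds tie (a
    plateau where the clustering matches the species partition), the median
    of the plateau is returned as the most stable choice.
    """
    if not evals:
        raise ValueError("no threshold evaluations supplied")
    best = min(e.cluster_species_delta for e in evals)
    plateau = sorted(e.threshold for e in evals if e.cluster_species_delta == best)
    return plateau[(len(plateau) - 1) // 2]


def rank_of_identity(pct: float) -> str:
    """Taxonomic-likeness band of a percent identity.

    >90 species-like; (70,90] genus-like; (45,70] family-like; <=45
    phylum-like (band boundaries are assigned to the lower band).
    """
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"percent identity {pct} outside [0, 100]")
    for name, lower in RANK_BANDS:
        if pct > lower:
            return name
    return RANK_BANDS[-1][0]


@dataclass(frozen=True)
class ReferenceHit:
    target_id: str
    pct_identity: float
    rank: str


def search_reference(query_pp: SeqRecord, reference: Sequence[SeqRecord],
                     max_hits: int = 500, min_identity: float = 0.0
                     ) -> list[ReferenceHit]:
    """Align a palmprint against every reference centroid and rank the hits.

    Hits are sorted by identity descending (ties: target id) and truncated
    to ``max_hits``; each carries its taxonomic-likeness band.
    """
    if not reference:
        raise ValueError("reference collection is empty")
    hits = []
    for ref in reference:
        pid = global_align(query_pp, ref).pct_identity
        if pid >= min_identity:
            hits.append(ReferenceHit(target_id=ref.id, pct_identity=pid,
                                     rank=rank_of_identity(pid)))
    hits.sort(key=lambda h: (-h.pct_identity, h.target_id))
    return hits[:max_hits]
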