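# Methods

## The palmprint model

The RdRP palm sub-domain carries three short catalytic motifs that are
strongly conserved across riboviruses: motif A (~12 aa, two essential
aspartates), motif B (~14 aa, a near-invariant glycine) and motif C
(~13 aa, the GDD core; YxDD in reverse transcriptases, ADN in the permuted
birnavirus-like lineage). The palmprint is defined as the minimal segment
containing all letters of the three motifs. In the canonical ABC gene
order it runs from the first letter of A to the last letter of C; in
lineages with a circularly permuted active site (CAB) it runs from the
first letter of C to the last letter of B. The intervening variable
segments are called V1 (between the first and second motif in sequence
order) and V2 (between the second and third). Typical palmprints are
~100 aa.

Because motifs delimit the segment consistently, palmprints from different
viruses are globally homologous, and divergence measured on global
alignments is commensurate across clades — the property that justifies a
single identity threshold for species-like clustering.

## Motif scoring

Each motif of each polymerase group is a position-specific scoring matrix
(PSSM) over the 20 amino acids. From a seed alignment, the per-column
observed frequencies `f_ia` (gaps excluded from the denominator) are
smoothed with a background mixture

    p_ia = (1 - w) f_ia + w b_a,      w = 0.1 by default,

and scored in bits, `P[i][a] = log2(p_ia / b_a)`, with `b` the BLOSUM62
marginal amino-acid frequencies. The pseudocount is interpreted as a
mixture *frequency* (not an added count): it keeps every column a proper
distribution regardless of row count, and `w -> 0` recovers pure observed
log-odds while `w -> 1` flattens all scores to zero. With `w = 0` an
unobserved residue would be `-inf`; scores are floored at -20 bits to keep
arithmetic finite (unreachable at the default `w`). The log base is 2 and
all shipped thresholds (2, 5, 20 bits) are interpreted in these units, so
the system is self-consistent.

A window placement is scored as the ungapped sum of per-column lookups.
Ambiguity codes (X, B, Z, J, U, O) score 0 bits — they neither help nor
hurt — and a stop codon `'*'` scores -100, vetoing any window that crosses
it. Frames are deliberately *not* split at stop codons: metagenomic
contigs contain indel errors, and splitting would silently fragment real
palmprints; the veto confines the damage to windows that actually overlap
the stop.

## Detection and the score ledger

For each group, the best placement of each of the three motif PSSMs is
found independently (ties: leftmost). Independent placement is what makes
permuted-order detection free: the placements are then classified as ABC,
CAB, or rejected (any overlap or other permutation). V1, V2 and palmprint
lengths follow from the placements.

The palmprint score starts from the raw sum of the three motif scores and
is adjusted by a configurable ledger of heuristics:

| rule | default | effect |
|---|---|---|
| motif-score floor | 2 bits | candidate rejected outright |
| V1 short bound | 35 aa | -5 bits when below |
| V1 long bound | 120 aa | -5 bits when above |
| V2 band | 15-90 aa | -5 bits outside |
| palmprint band | 70-160 aa | -5 bits outside |
| high confidence | >= 20 bits adjusted | reported as `high` |

Only the motif floor and the short-V1 rule have published values; the
remaining bands are this package's own defaults chosen to bracket the
~100 aa palmprint and its observed segment-length distributions, and all
are exposed in `HeuristicConfig` rather than hard-coded. V1 below its
lower bound incurs only the short-V1 penalty (not an additional band
penalty): the two rules describe the same boundary.

The winning group is the one with the highest *raw* motif-score sum among
non-rejected candidates (ties: lexicographic group name); the adjusted
score then decides confidence. Candidates passing the structural checks
but scoring below 20 are reported with `confidence=low` rather than
dropped, which makes threshold sweeps cheap without changing the
high-confidence contract. One hit is reported per query (the global
best); multiple RdRPs on one contig are a documented limitation.

Because per-motif optima are chosen independently, a valid ordered
combination can in principle be shadowed by a stray higher-scoring copy of
one motif elsewhere in the query. `HeuristicConfig.top_k > 1` enables an
exhaustive mode that considers the top-k placements per motif and picks
the best-scoring ordered, non-overlapping combination; the default `k = 1`
matches the plain description of the algorithm.

Nucleotide queries are six-frame translated (standard genetic code;
ambiguous codons become X unless unambiguous) and every frame is scanned;
the best adjusted score wins, with ties resolved in frame order
+1,+2,+3,-1,-2,-3. Hits carry 1-based forward-strand nucleotide
coordinates and the strand sign. All user-facing coordinates are 1-based
inclusive; internal arithmetic is 0-based half-open.

## Identity, clustering, banding

Pairwise identity is computed on end-gap-penalised global alignments
(Needleman-Wunsch with affine gaps, BLOSUM62, open 11 / extend 1, via
Biopython's pairwise aligner) with **all alignment columns** in the
denominator. This convention is stricter than dividing by the shorter
sequence length and is appropriate because palmprints are same-scale
segments. Each pair is aligned in a canonical order internally so that
identity is exactly symmetric even when co-optimal tracebacks exist.

Greedy centroid clustering processes records longest-first (ties: id);
each record joins the first centroid, in founding order, at or above the
threshold, else founds a new cluster. The species-like threshold defaults
to 90% identity. `tune_threshold` sweeps thresholds and tallies, per
species: *split* (members in >1 cluster), *lumped* (sharing a cluster with
another species), both, or *pure*. `select_balancing_threshold` picks the
threshold minimising |clusters - species|; when a plateau of thresholds
ties (the planted populations used here produce one), the plateau median
is returned as the most stable choice.

Reference search aligns a query palmprint against every reference centroid
with the same global aligner used for clustering (internal consistency in
place of the original local-alignment search tool; reproduced identities
to published values can therefore differ by small amounts). Matches band
into species-like (>90%), genus-like (70-90%], family-like (45-70%] and
phylum-like (<=45%); the boundaries 90/70/45 are assigned to the lower
band, consistent with the strict inequality of the species band.

## Validation harness

`evaluate_datasets` counts high-confidence, non-RT hits per labelled
dataset; sensitivity is hits/sequences on positive sets, and PPV/FDR are
correct/total and incorrect/total over all predictions (unclassified
queries enter neither). `decoy_scan` streams seeded iid uniform
{A,C,G,T} sequence through the six-frame scanner. The stream is a pure
function of the seed, chunks overlap by twice the maximum palmprint
nucleotide length (2 x 3 x `pp_max_len`) so boundary hits cannot be lost,
and duplicates in overlaps are removed by global coordinate — results are
identical across chunk sizes. The decoy base composition is uniform by
default with GC bias available through the generator's background
argument.

## Synthetic data

The generators in `palmprint.simulate` define the study conditions used by
the tests and the acceptance script:

- **Positives**: motifs sampled from the PSSM-implied column distributions
  (temperature 0 = consensus, the default, modelling a well-conserved
  polymerase), laid out in ABC or CAB order with background-sampled V
  segments and flanks. Defaults V1 = 40 aa and V2 = 25 aa sit mid-band;
  recovery experiments draw V1 from 35-60 and V2 from 15-40, the central
  mass of observed segment-length distributions.
- **Decoys**: iid draws from the BLOSUM62 background; 500 aa matches the
  scale of typical protein database entries.
- **Nucleotide encodings**: uniformly sampled synonymous codons, padded to
  land the protein in any requested frame and strand.
- **Species populations**: 20 species x 10 members, ~95% identity within
  species and ~70% between, palmprint length 100 aa — a deliberately
  well-separated analogue of the recognised-species clustering experiment
  at desk scale. Members are redrawn until their realised
  centroid-identity is within +-2 points of target. Centroid *pairs*
  cannot all be pinned to +-2 points (with ~190 pairs and a per-pair
  standard deviation near 4.6 points at length 100, the joint event is
  vanishingly rare), so centroids accept a +-8 point band; expected values
  still centre on the target and the planted partition remains
  recoverable.

What the synthetic data does **not** model: real motif diversity within a
phylum (the shipped example seed alignments are 8-row synthetic fixtures,
not trained viral PSSMs), homologous non-RdRP palm-like domains, EVEs and
degraded RT fossils, indel sequencing errors inside motifs, and skewed
base composition. Passing tests therefore demonstrate the correctness of
the machinery — exact scoring, recovery of planted structure, specificity
against featureless noise — not sensitivity/PPV on real viromes, whose
published values depend on externally trained PSSMs and curated datasets.

## Problem sizes and numerical choices

Test and acceptance runs use 1,000 planted positives for recovery, 10,000
x 500 aa decoys and 10^6 random nucleotides for specificity, 100 positives
x 6 frames for strand consistency, and a 200-record species population
for clustering — sizes chosen so the whole suite completes in a few
minutes on one core while keeping binomial noise on the reported
percentages well below the assertion margins. Window scoring accumulates
float64 in fixed column order, so vectorised and naive summations agree
bit-for-bit; ties in placement (equal window scores) resolve to the
smallest start, and ties between groups to the lexicographically smallest
name, making every report byte-stable for a fixed input and seed.

## Known limitations

- One palmprint per query; tandem polymerases are not reported.
- Sensitivity to lineages far outside the seed alignments is untested and
  expected to be low; the shipped example sets are demonstration fixtures.
- The greedy clustering depends on input order by design (deterministic,
  but not an optimal partition); it stands in for the referenced
  centroid-clustering tool rather than reproducing its internals.
- The aligner's identity convention (all columns, end gaps penalised)
  differs from local-alignment search tools; identities near band
  boundaries can shift by a point or two relative to other conventions.
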