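# palmprint

Detection, extraction and classification of the **polymerase palmprint** —
the barcode segment of the viral RNA-dependent RNA polymerase (RdRP) palm
sub-domain delimited by the well-conserved catalytic motifs **A**, **B**
and **C**.

RNA viruses discovered in high-throughput sequencing are known mostly from
sequence alone, and their hallmark gene, RdRP, is often buried inside a
longer open reading frame with unclear boundaries. The palmprint solves the
boundary problem: it is the minimal segment containing all letters of the
three catalytic motifs (~100 aa; motifs A and C carry the essential
aspartates, B a near-invariant glycine). Because the segment is globally
homologous across known RdRPs, pairwise global alignments of palmprints
give commensurate divergence estimates, supporting species-like OTU
clustering and rank-banded classification. This package is for
virologists and metagenomics pipelines that need to pull that barcode out
of contigs or protein sets and organise what they find.

## What it implements

- **Motif scanning** (`palmprint.pssm`, `palmprint.scanner`). Each motif of
  each polymerase group is modelled as a position-specific scoring matrix
  with per-column log-odds scores `P[i][a] = log2(p_ia / b_a)` (bits), built
  from a seed alignment with BLOSUM62 background frequencies `b` and a
  0.1-weight background pseudocount. A window starting at `s` in query `Q`
  scores `sum_i P[i][Q_{s+i}]`, ungapped. The best placement of each motif
  is found independently, which also catches the permuted **CAB** motif
  order of some lineages; in canonical order the palmprint runs from the
  first letter of A to the last letter of C, in permuted order from the
  first letter of C to the last letter of B. Nucleotide queries are
  six-frame translated first.
- **Heuristic confidence score**. The raw score (sum of the three motif
  scores) is adjusted by a configurable ledger: any motif below 2 bits
  rejects the candidate; V1 < 35 aa costs 5 bits; V1/V2/palmprint lengths
  outside their expected bands each cost 5 bits. Adjusted score >= 20 bits
  marks a high-confidence hit. Reverse-transcriptase (RT) matches are
  flagged so downstream counts can exclude them.
- **OTU clustering and search** (`palmprint.cluster`). End-gap-penalised
  global alignment (BLOSUM62, affine gaps 11/1) gives percent identity over
  all alignment columns; greedy centroid clustering at 90% identity yields
  species-like OTUs; a threshold sweep with lumping/splitting tallies
  re-derives the balancing threshold; identities band into species-like
  (>90), genus-like (70-90], family-like (45-70] and phylum-like (<=45)
  matches.
- **Validation harness** (`palmprint.benchmark`). Sensitivity on positive
  sets, PPV/FDR over labelled predictions, and streamed random-nucleotide
  decoy scans for the false-positive rate per letter.
- **Synthetic fixtures** (`palmprint.simulate`). Planted positives with
  known truth, decoys, frame/strand nucleotide encodings and labelled
  species populations — everything the test-suite and acceptance script
  generate at run time.

The package ships four small synthetic example PSSM seed alignments
(including one RT-like and one permuted-order group) for tests and demos;
they have the canonical shape of catalytic-motif seeds but are not trained
viral PSSMs.

## Worked example

```sh
python examples/01_scan_protein.py
```

prints

```
query: demo_polymerase (124 aa), planted group pisuvi-like
detected group pisuvi-like, motif order ABC
  motif A:  11-22  score  46.91 bits
  motif B:  63-76  score  51.78 bits
  motif C: 102-114 score  49.64 bits
V1=40 aa, V2=25 aa, palmprint 11-114 (104 aa)
raw score 148.33, adjusted 148.33 -> high confidence
```

Each motif line shows the 1-based placement and its log-odds score; the
palmprint spans first-letter-of-A to last-letter-of-C (12 + 40 + 14 + 25 +
13 = 104 aa here), and the adjusted score equals the raw sum because every
segment length falls inside its expected band — comfortably above the
20-bit high-confidence threshold. The other examples cover nucleotide
queries on the minus strand, PSSM construction, OTU clustering with
threshold tuning (`04_cluster_otus.py` recovers 20 planted species as 20
pure clusters and balances at 90% identity), and the decoy benchmark.

A thin CLI mirrors the library:

```sh
palmprint scan --in contigs.fasta --alphabet nt \
    --sets src/palmprint/data/example_sets --out report.tsv
palmprint cluster --in palmprints.fasta --id 90 --out otus.tsv
palmprint decoy --n 1e6 --seed 1 --sets src/palmprint/data/example_sets --out decoy.tsv
```

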