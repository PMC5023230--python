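# Methods

`c1comp` implements the comparative-genomics workflow used to study
methylotrophy in Gram-positive bacteria: genome-wide relatedness by
average amino acid identity (AAI) over reciprocal best hits, 16S rRNA
identity, a methylotrophy gene inventory with type categorization and
truncated-gene detection, C1 gene-cluster (genomic island) detection,
and lateral-vs-vertical inheritance calls from the contrast between
per-gene amino acid identity (AI) and genome-pair AAI. A synthetic
proteome-evolution generator with full ground truth makes every stage
testable without external data.

## Alignment kernel and conventions

Pairwise alignment is exact affine-gap Needleman–Wunsch / Smith–
Waterman (delegated to Biopython's `PairwiseAligner`); this package
fixes the conventions that all downstream statistics depend on:

- A gap of length *k* costs `gap_open + k·gap_extend`. Protein default:
  BLOSUM62 with gap open 11 / extend 1 (BLAST protein defaults, since
  the identities this workflow reproduces historically came from
  BLAST). Nucleotide default for 16S: match +2 / mismatch −3, gap 5/2.
- Percent identity = `100 · matches / aligned_columns`; gap columns
  count for global alignments, terminal gap columns are excluded, and
  only the optimal local window counts in local mode. This is stated
  explicitly because "AI" has no universal definition; the local
  (BLAST-style) identity is used for hit filtering, the global identity
  for typing and cluster-member comparison.
- `X` residues score 0 against everything: draft genomes contain
  ambiguous translations and they should neither reward nor punish.
- Coverage of a sequence is the fraction of its length inside the
  aligned span.
- Ties in the traceback are resolved by taking the kernel's first
  optimal alignment, which is deterministic for fixed input. Scores are
  tie-free by definition; identity ties are possible in principle but
  do not affect any reported statistic at the precision used.

A brute-force enumeration oracle (in the test suite, fully independent
of the kernel) enumerates every monotone alignment path for short
sequences; the kernel must match it exactly, and the acceptance script
re-measures this agreement on 200 random pairs at every run.

## Best-hit search and AAI

AAI(A, B) is the unweighted arithmetic mean of percent identity over
reciprocal-best-hit (RBH) pairs. Hits must reach 30% local identity
with the alignment covering ≥ 70% of the shorter protein — the classic
AAI filter — and proteins under 50 aa are excluded as fragment noise.
Best hits maximize score, with ties broken by identity and then by
lexicographically smallest subject tag, making the search deterministic.

Exhaustive all-vs-all Smith–Waterman is quadratic in proteome size, so
candidate subjects are pre-ranked per query by normalized edit distance
(edlib, bit-parallel) and exact local alignment is run only on the top
`prescreen_k = 8` candidates. The prescreen is deterministic and can be
disabled (`prescreen_k=None`). In principle an edit-distance ranking
can demote the true best-scoring subject below rank 8; this requires
many near-equidistant subjects and was never observed on simulated
data, where orthologs sit far above the background. A pluggable
external search backend is not provided; the built-in kernel covers the
intended problem sizes.

Because the kernel is symmetric, the identity of an RBH pair is
direction-independent, so one reciprocal search per unordered genome
pair suffices and the AAI matrix is symmetric by construction (the
matrix diagonal is fixed at 100). Pairs with no surviving orthologs are
reported missing with a warning rather than as zero.

16S identity is global nucleotide identity with terminal gaps excluded.
The 16S sequence is taken from rRNA feature rows (product containing
"16S") or supplied directly; the package does not predict rRNA genes.

## Gene inventory

Each predicted protein is searched against a reference panel of
methylotrophy proteins (function labels follow the field vocabulary:
Mao, Tmo, Tmd, EutQ, Gma, MgsA–C, MgdA–D, FolD, Mch, PurU, Fhs, FaDH,
Fdh, Pgi, Zwf, OpcA, Pgl, Gnd, Hps, Hpi, Pfk, Fba, Tkt, Tal, GlpX, Rpe,
Rpi, Tpi, Gap, Pgk, Eda, plus Mdh and candidate labels). A protein is
reported under its single best-scoring function when it reaches 30%
identity and 40% reference coverage; hits covering less than half the
reference (`partial_threshold = 0.5`) are flagged partial. The 0.5
threshold is a design choice: genuinely truncated remnants observed in
this family of genomes cover only a few percent of their reference,
far below any plausible cutoff, while assembly-edge partials cluster
just below full length.

**Typing.** Homologs of one function across genomes are grouped by
single-linkage clustering on pairwise global identity at 50% — chosen
to separate known within-type identities (≥ ~52%) from "unrelated"
between-type pairs — and numbered by decreasing cluster size, ties by
smallest locus tag, so type labels are invariant to input order.
Partial hits carry no type: a fragment's global identity to full-length
homologs is not meaningful, and published inventories list partial
genes without a type. Per-protein single-function assignment keeps the
inventory unambiguous; overlapping candidates are logged as warnings.

**Truncated-gene remnants.** Contigs are translated in six frames and
each frame is locally aligned to the reference protein. A remnant is an
ORF-like run: the aligned window is split at in-frame stop codons and
only the best stop-free segment is kept (an optimal local alignment can
otherwise extend a few residues past a remnant boundary through the
stop on a lucky downstream stretch). Segments of ≥ 25 aligned residues
at ≥ 40% identity covering < 50% of the reference are reported with
span `3 × aligned residues` and forward-strand genomic coordinates.
These permissive thresholds deliberately favour sensitivity; marginal
chance windows (exactly at the floor) occasionally appear and are
distinguished by score and identity.

## Islands and inheritance calls

Cluster detection chains inventory hits left-to-right along each contig
(gene index = rank by start coordinate): consecutive members may be
separated by at most `max_gap = 3` intervening non-member genes, and
runs of ≥ `min_size = 3` members are emitted. The defaults reflect how
real C1 islands look: dense runs of methylotrophy genes with occasional
hypothetical/transposase insertions.

Clusters from two genomes are compared when their function sets overlap
at Jaccard ≥ 0.5; members are paired within matching functions by
descending global identity (each member used once) and the pair's mean
member AI is reported. A cluster is "common" when a Jaccard ≥ 0.5
counterpart exists in every other genome of its user-declared genus
group, else "unique"; groups are never inferred from the data.

Inheritance calls compare each gene pair's AI with the genome-pair AAI:
`delta = AI − AAI`; **lateral** when `delta ≥ 15` points, **vertical**
when `|delta| ≤ 10`, else **ambiguous**. The margins encode the
qualitative field rule (AI > 80% between genomes sharing 50–60% AAI is
a transfer signature; AI tracking AAI is vertical descent); both are
configurable, the delta is always reported so calls can be
re-thresholded without recomputation, and no significance test is
attached — the delta is descriptive. A cluster's aggregate verdict is
the majority of its member calls, ties resolving to ambiguous.

## Synthetic data generator

The generator emulates exactly the observations the pipeline must
recover; its defaults are the study conditions used by the tests.

- **Substitution model**: site-uniform replacement over a uniform
  alphabet (20 letters for proteins, 4 for nucleotides). Expected
  identity after `lam` substitutions per site is
  `1/k + (1 − 1/k)·exp(−(k/(k−1))·lam)`; the closed-form inverse gives
  the load for a target identity, verified against direct Monte-Carlo
  simulation in the tests. No rate heterogeneity and no indels by
  default: the statistics under test are identity-driven, not
  model-sensitive.
- **Pairwise targets**: each genome receives a branch load `d_i` from
  the shared ancestor with `d_i + d_j = lam(target_ij)` (least squares
  for > 2 genomes). Matrices admitting no consistent non-negative
  decomposition are rejected with the offending pair named. Realized
  mean core identities are measured and the divergence deterministically
  re-tuned until they sit within one point of target.
- **Gene complement**: `genes_per_genome = 500` core genes (length
  Normal(300, 75) aa, floored at 50) shared by all genomes, plus
  methylotrophy genes declared as islands (contiguous) or singletons,
  seeded from the generated reference panel (Mao 700 aa, others 300 aa
  by default, matching real protein sizes). Duplications copy a gene
  and diverge the copies to a target within-copy identity; HGT events
  copy a donor island into the recipient as a contiguous run at a
  target island identity; truncations remove the protein and keep an
  internal in-frame fragment of stated length in the contig, flanked by
  in-frame stop codons, exactly as a deletion remnant would read.
- **Contigs**: one contig per genome — genes back-translated with
  uniform synonymous codons, random strand, 200-bp random spacers, and
  a 16S gene (1500 nt, diverged to per-pair marker targets) annotated
  as an rRNA feature. GC content is not emulated.
- **Determinism**: all randomness flows from named child streams of the
  config seed; identical config gives byte-identical output files.

What the generator does *not* emulate — indels and fragmented
assemblies, codon/GC bias, rate heterogeneity across sites, gene loss,
partial islands, contaminating paralog families — bounds what passing
tests show: the pipeline's statistics are validated against an
idealized but fully known evolutionary history, not against annotation
noise or assembly artefacts.

## Problem sizes and numerical choices

The validation suite uses proteome pairs of 500 genes for AAI recovery
(recovered within ±2 points at targets 40/60/80/95), 20 replicates of a
60-core-gene donor/recipient pair at AAI 55 with an 8-gene island
transferred at 85% identity for lateral-call recovery (sensitivity ≥
0.9 at false-positive rate ≤ 0.05), and 200 random length-≤8 pairs for
kernel-vs-oracle exactness. Smaller sizes appear in unit tests where
the property under test does not depend on scale. Identity-like values
are rendered with one decimal in reports; all report writers emit
deterministic row and column orders so reruns are byte-identical.

## Known limitations

- Local-identity AAI carries a small upward bias at deep divergence
  (the optimal local window trims mismatch-rich ends); at 40% target
  identity the bias is under one point at the default gene lengths.
- The edit-distance prescreen trades a theoretical risk of missing the
  true best hit for a ~50× search speed-up (see above).
- Transfer calls are descriptive, not statistical tests; genes whose AI
  falls between the vertical band and the lateral margin remain
  ambiguous by design.
- The "common vs unique" classification depends entirely on the
  user-supplied genome grouping.
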