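# Methods

## Scope and data model

`igscluster` operates on a single replicon at a time (bacterial
chromosomes are the intended input; plasmids are handled by separate
invocations). Internally all coordinates are 0-based half-open on the
forward strand; GenBank/GFF3 1-based inclusive coordinates are converted
at the I/O boundary and strand logic is confined to the extraction module.
The translation start codon (TSC) position of a gene is the first base of
its start codon read on the coding strand. Any annotated start codon is
accepted by default; the `atg_only` flag restricts to ATG for annotations
where that is wanted.

Operon tables group genes into transcription units (TUs); a TU's lead gene
is the strand-wise 5′-most member and owns the unit's single upstream
regulatory region. Genes absent from the table become singleton TUs;
an operon whose members lie on both strands is rejected.

## Region definitions

* **IGR** (intergenic region): from the lead gene's TSC back to the end of
  the previous coding region *on the same strand*. On circular replicons
  the distance is modular, so a strand carrying a single gene wraps to the
  gene's own far side; on linear replicons the region is clipped at the
  edge. IGRs routinely contain reverse complements of opposite-strand
  genes.
* **RIGR** (restricted IGR): the strand-agnostic gap between consecutive
  coding spans, swept in start order with a running maximum end so that
  contained genes cannot create spurious gaps; overlapping genes
  contribute length 0.
* **Window length rule:** the common upstream window is
  `round(mean − sd)` of the RIGR length distribution. The population
  standard deviation is used. The dispersion subtracted here is a length
  in bp, so it is interpreted as the standard deviation (a variance would
  carry bp² units and could not be subtracted from a mean length). The
  pipeline default overrides the rule with a fixed 200 bp, which is the
  value the rule produces on a gene-dense chromosome whose restricted gaps
  average ≈ 250 ± 50 bp. On inputs whose gap distribution is strongly
  bimodal (many near-zero intra-operon gaps next to a broad upstream-gap
  mode) the raw rule can return a small or even negative number; it is
  reported in the manifest for inspection but the override is what the
  pipeline uses.

## Shine–Dalgarno detection and the IGS anchor

The ribosome-binding search region is the last 25 bp of the upstream
window (motif occurrence beyond 25 bp of the TSC is negligible in
gene-dense genomes). Motifs are tried in strictly decreasing length order
— `AGGAGG`; `AGGAG`, `GGAGG`; `GGAG`, `GAGG`, `AGGA`; `GGA`, `GAG`,
`AGG` — and the longest present wins; among equal-length hits the one
closest to the TSC is taken (consistent with the canonical placement of
the motif about 10 bp upstream). The operational transcription start site
(TSS) is the *first* nucleotide of the winning motif, and the IGS is the
`200 − 25 = 175` bp immediately 5′ of the TSS; without a motif the TSS
falls back to the TSC. Position 0 of every downstream coordinate system is
this anchor; the IGS occupies ℓ = −175 … −1. Windows are taken even when
they cross coding sequence — the coding fraction of each IGS (overlap with
any CDS on either strand) is recorded so downstream analyses can stratify
by contamination. Ambiguity codes pass through extraction unchanged: the
alignment scores them through the substitution matrix and composition
profiles count them for no nucleotide.

## Alignment scoring

Scores are exact affine-gap dynamic programming (Biopython's
`PairwiseAligner`), EDNAFULL (`NUC.4.4`) substitution table. A run of k
gaps costs `gap_open + (k − 1)·gap_extend` with defaults 10 and 0.5; in
global mode end gaps are free, so the all-end-gap alignment scores 0 and
global scores of equal-length sequences are bounded below by 0. The high
open/low extend setting deliberately tolerates long indels, which favors
sequences sharing dispersed compositional patches. Scores keep the 0.5
granularity induced by the extension penalty; no banding or heuristic
acceleration is applied (175-bp sequences make exact scoring cheap — an
all-vs-all pass over 150 sequences takes seconds). The similarity matrix
has a zero diagonal by construction: a self-score of 5L per node would
dominate the degree normalization without carrying between-sequence
information.

## Threshold estimation

Two estimators of the background score s\*:

* **whole-set shuffle:** shuffle every sequence, score all pairs, average;
  repeat R times (default 3) and average the iteration means. Each
  iteration is O(N²) alignments; a pair subsample is available for large
  N.
* **self-shuffle (default):** score each sequence against 10 random
  reorderings of itself and average over everything.

Shuffling preserves composition, so the self-shuffle estimate retains each
sequence's compositional self-similarity and is systematically the higher
of the two; for short sequences this sparser graph discriminates clusters
better, which is why it is the default. Thresholding (`s_ij ≥ s*`,
inclusive) happens on the raw score scale; normalization by the maximum
surviving score comes after. Nodes with zero degree after thresholding are
excluded from clustering and reported as unclustered (the normalized
Laplacian is undefined at zero degree).

## Spectral clustering

`L_sym = D^{−1/2}(D − W)D^{−1/2}` is diagonalized with a dense symmetric
eigensolver. Eigenvector sign is canonicalized (largest-magnitude entry
positive) so embeddings are reproducible. The cluster number k is
suggested by the largest gap `λ_{k+1} − λ_k` over 2 ≤ k ≤ 20; ties break
to the largest k with a warning. The suggestion is advisory: the spectrum
and gap table are always written, and k can be fixed by the caller — e.g.
when downstream composition profiles justify a finer split than the
silhouette optimum.

The embedding takes the first k eigenvectors as columns and scales each
row to unit norm; numerically zero rows are replaced by the first basis
vector and flagged. K-means is Lloyd's algorithm with Euclidean metric,
centroid-displacement tolerance 1e−8, initial centroids sampled from the
distinct points, and an emptied cluster reseeded at the point farthest
from its centroid. Ten restarts are run and the lowest
within-cluster-sum-of-squares solution kept; the restart count removes
initialization sensitivity without changing the algorithm. Lloyd's is a
local optimizer, so a finite restart budget does not guarantee the global
optimum (the test suite checks global optimality only on tiny instances
with a widened restart budget).

Silhouettes are computed in the embedding with Euclidean distance. Two
cohesion normalizations are exposed: `cluster_size` divides the intra-cluster
distance sum (excluding the point itself) by the full cluster size N_k;
`standard` divides by N_k − 1, the textbook mean over the other members.
The two differ by a factor (N_k − 1)/N_k; neither is silently "corrected"
to the other. Singleton clusters get s(i) = 0.

## Composition analysis

`ρ_x(ℓ)` is the fraction of sequences carrying nucleotide x at position ℓ.
Smoothing is a centered moving average over ℓ ± a (default a = 15); at
profile boundaries the window truncates to the covered positions and
renormalizes by the true width rather than padding, which preserves the
per-position cross-nucleotide sum exactly everywhere.

Segment statistics count maximal runs of length ≥ 6: pure-A homopolymers,
pure-T homopolymers, and alternating-AT runs (letters in {A, T}, no two
equal neighbours; alternation at length ≥ 2 implies both letters occur).
Strict alternation is required of AT-segments, matching the period-2
character of the motif class. Homopolymer and alternating maximality are
judged independently, so a run such as `AAAAAATATATA` contributes one
A-segment and one AT-segment.

## Association statistics

The interaction network keeps edges whose channel score strictly exceeds
700 ("overtakes", configurable to ≥), discarding weights. For a cluster's
genes the induced subgraph's largest connected component is summarized by
its node count N_LCC and its **total** internal edge count N_link (tie on
size breaks by more edges, then lexicographically; an edgeless induced
graph counts as N_LCC = 1, N_link = 0). The null draws the same number of
IGSs uniformly without replacement from the whole set and expands each to
all its genes — operon structure is preserved per draw — for 1000
resamples (configurable); mean, sample sd (divisor n − 1) and
z = (observed − mean)/sd are reported, with a degenerate flag when sd = 0.

Category enrichment is the exact binomial test of the cluster's category
count k out of its annotated total n against the background proportion p,
two-sided as `min(1, 2·min(lower tail, upper tail))`. Raw p-values are the
primary output; Benjamini–Hochberg adjusted values are reported alongside
because many categories are tested at once.

## Synthetic fixtures

The generator assembles a circular replicon from transcription-unit
blocks written on their coding strand —
`[pad][planted 175-bp class IGS][SDS motif][C/T spacer][genes]` — and
reverse complements minus-strand blocks. Defaults: 60 genes, half of them
in operons of 2–4 genes, upstream gaps ~ Normal(250, 50) bp clipped at
210 bp (so the 200-bp window never crosses a gene), Shine–Dalgarno
consensus planted with probability 0.88 at offsets ~ Normal(10, 4) clipped
to [6, 25]. The C/T spacer between motif and start codon cannot contain or
complete any motif, so a planted consensus is always recovered at its
exact offset, and unplanted units yield no hit.

The three IGS classes mirror the compositional cluster phenotypes the
method is built to separate: T-rich (ρ_T ≈ 0.45) with ~3 planted T-runs
per sequence, A-rich mirrored, and a balanced weak-rich class
(ρ_A ≈ ρ_T ≈ 0.30) carrying ~1.5 A- and T-runs and ~6 alternating-AT
patches (runs 6–12 bp, positions uniform). The balanced class needs its
own planted signature because the self-shuffle threshold is
composition-preserving: a class distinguished only by *uniform*
composition scores below the mixed-set threshold against its own members
and would disconnect; the alternating-AT patches give it the mutual
alignment cohesion that, in real genomes, the corresponding cluster
derives from its regular weak-nucleotide motifs.

What the generator does **not** emulate: codon usage, GC skew,
replication-strand asymmetry, overlapping genes, compound (joined) CDS,
length-175 truncation on linear contigs, and IGSs that cross coding
sequence (all planted coding fractions are 0). Passing tests therefore
demonstrate that the machinery recovers planted compositional structure
under realistic sizes and noise — not that any particular real genome
contains three clusters.

Interaction tables plant the compositional classes as network modules
(within-module edges exceed the 700 threshold with probability 0.9,
between-module 0.05); category tables draw one category per gene,
uniformly in the background and with a boosted first-category probability
in the target class.

## Problem sizes and numerical tolerances

The test suite and the acceptance script run at desk scale, chosen so the
statistics are informative while the whole suite stays fast: planted-class
recovery uses 3 × 50 sequences of 175 bp (≈ 11k alignments per seed, 5
seeds); threshold-ordering checks use 30 sequences over 10 seeds; the
resampling-null calibration uses 40-gene structureless tables over 200
seeded runs with 200 resamples each; planted-module power uses 90-gene
genomes, where each module spans ~10 transcription units (at 40 genes a
module of 4–6 genes is smaller than a typical random draw's gene
expansion and the z-score has no power). Symmetry checks use 1e−8,
eigenvalue-multiplicity checks 1e−6 on a unit-scale spectrum, and exact
formula comparisons 1e−9 to 1e−12.

## Known limitations

* Dense O(N²) alignment and O(N³) diagonalization cap practical inputs at
  a few thousand IGSs — adequate for single bacterial chromosomes.
* Compound-location CDS (programmed frameshifts, origin-spanning joins)
  are skipped with a warning.
* The eigengap suggestion degrades gracefully but uninformatively on flat
  spectra (returns k_max with a warning); it should be reviewed against
  the written spectrum.
* Threshold estimation by plain permutation preserves composition but not
  dinucleotide structure; composition-matched Markov shuffles are out of
  scope.
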