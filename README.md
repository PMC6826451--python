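# igscluster

Structure-based, genome-wide classification of bacterial intergenic
sequences (IGSs).

Bacterial genomes are gene-dense: the short noncoding stretches upstream of
genes and operons concentrate most of the regulatory signal, yet they are
too variable for conservation-based comparison. `igscluster` implements an
alignment-and-spectral-clustering pipeline that classifies these regions by
*global* compositional structure instead of by specific motifs, and then
asks whether the resulting classes correlate with gene-network and
functional-category features. It is aimed at microbial genomics groups who
want a reproducible, desk-scale implementation of this analysis for any
annotated replicon.

## Method

1. **Extraction.** For every transcription unit (single gene or operon,
   from an operon table) the pipeline takes the window of `L = 200` bp
   immediately 5′ of the lead gene's translation start codon (TSC). A
   Shine–Dalgarno sequence (SDS) is sought within the last 25 bp of the
   window, trying the consensus `AGGAGG` first and then its admissible
   subsequences (`AGGAG, GGAGG, GGAG, GAGG, AGGA, GGA, GAG, AGG`) in
   decreasing length order. The transcription start site (TSS) is placed at
   the first SDS nucleotide (or at the TSC when no motif is found) and the
   IGS is the 175 bp immediately upstream of it. The window length itself
   derives from the restricted intergenic gap distribution by the rule
   `round(mean − sd)` (≈ 250 − 50 = 200 bp), with a configurable override.
2. **Alignment.** All N(N−1)/2 IGS pairs are scored with exact affine-gap
   dynamic programming: Needleman–Wunsch global alignment (EDNAFULL
   substitution table, `GAPOPEN = 10`, `GAPEXTEND = 0.5`) with free end
   gaps; Smith–Waterman local alignment is available behind a flag.
3. **Thresholding.** Even random sequences score positively, so a
   background threshold s\* is estimated from shuffled sequences. The
   default estimator aligns each IGS against ten random reorderings of
   itself; because shuffling preserves composition this estimate is higher
   than the whole-set-shuffle alternative and yields the sparser, better
   discriminating graph. Scores ≥ s\* survive as edges and are divided by
   the maximum surviving score: `w_ij = s_ij / max{s_ij}` if
   `s_ij ≥ s*`, else 0.
4. **Spectral clustering.** From the weighted adjacency W and the degree
   matrix D the normalized Laplacian `L_sym = D^{−1/2}(D − W)D^{−1/2}` is
   diagonalized; the number of clusters k is suggested by the largest
   eigengap `λ_{k+1} − λ_k` of the ascending spectrum (advisory — the full
   spectrum is always reported and k may be overridden). The rows of the
   first-k-eigenvector matrix, normalized to unit length, embed each IGS in
   R^k, where Lloyd's k-means (tolerance 1e−8, best of 10 restarts)
   assigns cluster labels. Silhouette values
   `s(i) = (b(i) − a(i)) / max(a(i), b(i))` grade the partition.
5. **Characterization and association.** Each cluster is profiled by base
   composition analysis — positional densities `ρ_x(ℓ)`, ℓ = −175…−1,
   optionally smoothed over a ±15 bp window — and by counts of homogeneous
   A-, T- and alternating-AT segments (≥ 6 bp). Optionally, cluster genes
   are mapped onto an interaction score network (edges where the score
   exceeds 700) and the size and link count of the largest connected
   component are compared with a 1000-resample null of random equal-size
   IGS draws; functional-category enrichment uses the exact two-sided
   binomial test against the genomic background.

A synthetic-fixture generator produces full GenBank genomes with planted
operons, planted SDS motifs at known offsets, three planted compositional
IGS classes (T-rich, A-rich, balanced/AT-alternating), planted network
modules and planted category enrichment, so the whole pipeline is testable
without downloading anything.

## Worked example

```bash
igscluster simulate --n-genes 150 --seed 7 --out demo/fixture
igscluster run-all --genome demo/fixture/genome.gbk \
    --operons demo/fixture/operons.tsv --seed 7 --out demo/run
```

The run prints a stage summary (abridged):

```
"extract":  { "n_tus": 98, "n_igs": 98, "sds_fraction": 0.8367 }
"threshold": { "method": "self_shuffle", "s_star": 211.86, "n_isolated": 2 }
"cluster":  { "suggested_k": 3,
              "cluster_sizes": { "C0": 30, "C1": 31, "C2": 35 },
              "silhouette_means": { "0": 0.940, "1": 0.906, "2": 0.853 } }
```

98 of the 150 genes lead a transcription unit, 84% of the units carry a
detectable Shine–Dalgarno motif, and the eigengap of the Laplacian spectrum
suggests three clusters, which the silhouettes (all ≈ 0.9) confirm as well
separated. The per-cluster segment table (`demo/run/segments.tsv`) shows
the compositional signatures the clusters were recovered from:

```
cluster  A_segments  T_segments  AT_segments
C0       95          1           2
C1       0           91          7
C2       27          38          170
```

C0 is rich in homogeneous A-segments, C1 in T-segments, and C2 in
period-2 alternating-AT segments. `demo/run/` also contains the spectrum,
labels, silhouettes, per-cluster composition profiles (`bca_C*.tsv`) and a
checksum manifest; a rerun with the same seed reproduces the checksums
bit-for-bit.

Individual stages (`extract`, `align`, `threshold`, `cluster`, `bca`,
`segments`, `network`, `enrich`) can be rerun from cached artifacts; see
`igscluster --help`.

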