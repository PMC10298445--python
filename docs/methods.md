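# Methods

## Specificity model

Tissue specificity is defined by thresholds on FPKM, not by a continuous
index (no tau or entropy): a gene is called for tissue *t* iff
FPKM(t) > `high_threshold` and FPKM(u) < `low_threshold` for every other
tissue *u*. Defaults are 100 and 10 FPKM. Because the high threshold
exceeds the low one, at most one call per gene is possible. Both
comparisons are strict: FPKM exactly 100 in the candidate tissue, or
exactly 10 in an off-target tissue, disqualifies the gene.

Two points the threshold rule leaves open were resolved as follows.

* **Silent off-target tissues.** "Unexpressed or weakly expressed" is read
  as 0 ≤ FPKM < 10: a tissue where the gene is fully silent supports
  specificity. Excluding FPKM = 0 would reject exactly the cleanest
  tissue-specific genes. `CallerConfig(strict_zero=True)` restores the
  literal open-interval reading (0 < FPKM < 10) for comparison.
* **Detection floor.** Genes with "minor expression in all tissues" are
  removed before calling. The floor is a configurable
  `detection_threshold`, default 1 FPKM — the conventional bulk RNA-seq
  detection level. A gene is undetected iff its maximum FPKM over all
  tissues is strictly below the floor; a maximum exactly at the floor
  counts as detected.

## Expression bins

Called genes are classed by target FPKM into 100–500, 500–1000, 1000–5000
and >5000. Open intervals cannot tile the positive axis, so the bins are
half-open [a, b) with a boundary value assigned to the upper bin
(FPKM = 500 falls in 500–1000). `bin_share` turns the per-tissue counts of
one class into its percentage of all calls; e.g. 19 + 1 + 1 = 21 calls of
288 in the 1000–5000 class is 7.29%.

## Heatmap preparation

Rows are standardized to Z-scores with the sample standard deviation
(n − 1), matching R's `scale()` convention used by heatmap tooling.
Zero-variance rows map to all-zero with a logged warning rather than NaN.
Row order comes from agglomerative complete-linkage clustering on
Euclidean distances (scipy); equal merge distances resolve by input order,
which yields the smallest-original-index tie-break and a platform-stable
leaf order. The package emits the Z-matrix and leaf order; rendering is
left to external tools.

## Enrichment statistic

The over-representation test is the one-sided hypergeometric upper tail
P(X ≥ k) with N background genes, K of them annotated to the term, and k
of the n study genes annotated — the default statistic of the common
enrichment servers. The significance flag uses the raw p < α rule
(α = 0.05 default) because that is how the upstream analysis defines
significance; BH-adjusted p-values are always reported and can drive the
flag via `flag_on_adjusted`. The default background is the set of genes in
the annotation file; pass an explicit background (e.g. the full expression
matrix's gene set) to widen it. No GO DAG propagation is performed — terms
are opaque labels.

## Promoters

A promoter is the `length`-bp (default 3000) genomic window 5′ of the
translation initiation codon. The anchor is the first base of the first
CDS segment of the representative transcript: the isoform whose id ends in
".1" if present, else the longest total CDS, else the lexicographically
first id. GFF3 coordinates (1-based closed) convert to 0-based half-open
internally and in BED output. On the + strand the window is
[anchor−1−L, anchor−1); on the − strand [anchor, anchor+L),
reverse-complemented, so the reported sequence always reads 5′→3′ toward
the ATG and never includes it. Windows are clipped at chromosome edges and
flagged `truncated`; padding with N was rejected because it would inject
artificial motif-scan context. Ambiguity codes in the genome pass through
unchanged.

## Cis-element scanning

Motifs are IUPAC degenerate consensus strings. Matching is positionwise
set membership; a sequence N is matched only by a consensus N, so unknown
bases (including any introduced upstream of the pipeline) can never create
a hit at an informative position. Every overlapping window is tested
against the consensus and its reverse complement; a window matching both
(palindromic site) is reported once, on the + strand, so strand-ambiguous
sites are never double-counted. Occurrences are counted, not coverage —
overlapping hits of the same motif all count. `--forward-only` restricts
to the given strand. The builtin library is the eleven tissue-specificity
elements used for the soybean promoter analysis; user tables can replace
or extend it.

## qPCR validation

Relative expression per replicate is 2^−ΔCT with
ΔCT = Ct(gene) − Ct(reference) paired by replicate id within a tissue;
the default reference is the housekeeping gene GmActin. Tests run on
log2-transformed relative expression (equivalently −ΔCT), which is the
scale the measurements live on and stabilizes variance. The test is the
classic equal-variance two-sample Student t-test (two-sided);
`equal_var=False` selects Welch. Significance codes are *** (p < 0.001),
** (p < 0.01), n.s. otherwise.

A predicted gene validates as *specific* iff its target-tissue mean
relative expression is strictly highest among detected tissues and every
pairwise comparison against a detected non-target tissue has p < α
(pairwise, not target-vs-pooled, mirroring per-tissue star annotations).
A tissue where the gene was never detected contributes no comparison and
cannot defeat specificity; a gene undetected in its own target tissue is
*not detected*. The consistency percentage is
100 × #specific / #predictions.

## Synthetic data

The generators emit the exact formats the readers consume, plus a truth
table, and are pure functions of their seed (byte-identical reruns; each
generator has its own RNG stream so modules can be tested in isolation).

* **Expression matrices.** Planted specific genes draw target FPKM
  log-uniformly on [150, 20000] — populating all four bins including the
  >5000 tail that seed storage-protein genes produce in real atlases — and
  off-target FPKM uniformly on [0, 8]. Undetected genes draw all tissues
  on [0, 0.5]. Background genes draw i.i.d. log-normal profiles
  (μ = 1.5, σ = 1.5 on the log scale), post-adjusted so none of them
  satisfies the caller rule or falls below the detection floor. The
  margins (150 vs 100, 8 vs 10, 0.5 vs 1) are ≥ 1.25× clear of every
  threshold, so planted truth must be recovered with precision = recall
  = 1; the generator probes bookkeeping, not borderline calibration, and
  the log-normal background is a shape choice, not a claim about the true
  FPKM distribution. The full-catalog scenario is 56,044 genes × 9
  tissues with 3,731 undetected and 288 specific genes
  (117 flower / 99 seed / 40 root / 21 leaf / 6 pod / 3 stem / 2 nodule).
* **Genomes.** A random chromosome with strand-alternating single-CDS
  genes, each CDS stamped to begin ATG on its own strand; the first gene
  sits 400–600 bp from the chromosome edge so that its promoter truncates.
* **Motif planting.** Background bases i.i.d. at a stated GC content;
  placements resolve degenerate positions to a concrete word recorded in
  the truth table, so scanner-vs-truth comparisons are exact.
* **Ct tables.** Reference Ct ~ 20 + N(0, σ) per tissue × replicate; a
  target with planted fold f gets Ct = ref − log2 f + N(0, σ), so at σ = 0
  its 2^−ΔCT equals f exactly; fold 0 emits ND. The validation case study
  uses 12 genes over six tissues (leaf, stem, root, flower, pod, seed), 10
  with a 64-fold excess in the predicted tissue and 2 with the excess in a
  different tissue, σ = 0.2 Ct, 3 replicates — with those margins the
  consistency is 10/12 = 83.33% for essentially every seed.

What the synthetic data does **not** emulate: replicate-level count noise,
correlated expression programs across tissues, realistic genome
composition or intron structure, primer efficiency effects. Passing tests
therefore demonstrate correctness of the algorithms and bookkeeping under
the stated model, not robustness to real-data pathologies.

## Problem sizes and numerics

The test suite runs the full 56,044 × 9 catalog (sub-second), scanner
oracles up to 10 kb, exhaustive hypergeometric enumeration for small
universes (N ≤ 12, tolerance 1e−12), and 200-seed verdict-recovery
sweeps. Floating-point FPKM round-trips use 17-significant-digit
serialization, which is exact for doubles. Degenerate statistical inputs:
zero variance on both t-test sides gives p = 1 for equal means and p = 0
otherwise; fewer than two replicates per side is an error.
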