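# Methods

This note documents the models and procedures implemented in `crelink`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Coordinates and containers

All genomic coordinates are BED-style 0-based half-open `[start, end)`.
GTF input (1-based inclusive) is converted once on read; strand `"."` is
treated as `"+"` when deriving a TSS.  Count matrices are features × cells
(`pandas.DataFrame`); the paired container `OmicsPair` enforces one shared
cell ordering across both modalities.

## Filtering and normalization

Peaks count as *detected* in a cell at ≥ 2 fragments (a single fragment is
treated as noise); genes at ≥ 1 count.  Features detected in at least 10 %
of cells are retained (`min_cell_fraction=0.10`; the boundary is inclusive,
with a flag to flip it, since "at least" versus "more than" is a genuine
convention choice at the exact boundary).  Filtering never drops cells and
is idempotent.

Size factors use pooled deconvolution: cells are placed on a ring ordered
by library size (interleaved from both ends so every pool window mixes
small and large cells); for each pool size in {21, 26, 31, 36, 41} and
each ring offset, the pooled count vector is divided feature-wise by the
average pseudo-cell and the median ratio gives one linear equation
"sum of member factors = pooled ratio".  The stacked system is solved by
least squares together with low-weight (1 %) per-cell library-size anchor
equations that fix the scale and keep the system full rank; the solution
is rescaled to mean 1.  Non-positive solutions are clipped to 1 % of the
smallest positive factor with a warning; fewer cells than the smallest
pool falls back to library-size factors.  On noise-free planted scalings
the estimator is exact to < 1e-3 relative error (tested).

CPM is counts × 1e6 / cell total and errors on zero-total cells.

## Gene activity classes

From overlapping histone marks: *active* = (H3K4me3 ∨ H3K4me1) ∧ H3K27ac ∧
¬H3K27me3; *bivalent* = (H3K4me3 ∨ H3K4me1) ∧ H3K27me3; *inactive* =
H3K27me3 alone; everything else *unclassified*.  Bivalent takes precedence
over inactive when both patterns hold.

## Link inference

**Weighted Spearman.**  Midranks of both vectors, then weighted Pearson of
the rank vectors.  Constant inputs return NaN with a warning.  With equal
weights this equals classic Spearman to 1e-12 (tested).

**Strategies 1–2.**  Promoter peaks overlap TSS ± 2 kb (the promoter
window is not fixed by any convention; ± 2 kb is the common default and is
configurable).  Distal peaks have any base within 1 Mb of the TSS — the
same window strategy 3 uses, adopted for 1–2 as well since nothing pins a
different one.  For each candidate pair the correlation is computed once
per NMF signature with that signature's exposure row as weights; the pair
is linked when the maximum exceeds 0.25 (one-sided: anti-correlated pairs
are never linked).  Strategy 1's exposures come from NMF of the
accessibility matrix, strategy 2's from NMF of the expression matrix —
each strategy weights by the subpopulation structure of its response
modality.  The exposure NMF rank defaults to 3 in the pipeline and is
configurable; the choice only shapes the weights, not the statistic.

**Wilcoxon rank-sum.**  Exact enumeration of all C(n, n1) rank assignments
when the pooled sample is tie-free with n ≤ 12; the two-sided p is twice
the smaller tail, capped at 1.  Otherwise a normal approximation with
midranks, tie-corrected variance and continuity correction.  In the
tie-free case the normal path adds a fourth-cumulant Edgeworth term using
the closed-form excess kurtosis of the rank sum,
g₂ = −6(n₁² + n₂² + n₁n₂ + n) / (5 n₁ n₂ (n+1)); without it the plain
normal approximation deviates from enumeration by up to 0.037 at the
smallest sizes, with it by at most 0.0195 (verified exhaustively).

**Strategy 3.**  For every peak within 1 Mb of a gene's TSS, cells are
partitioned by the peak's active-region mask; both groups need ≥ 3 cells,
otherwise the pair is recorded as untested.  A link requires p < 0.05 with
no multiple-testing correction (Benjamini–Hochberg is available but off by
default, matching the raw-threshold convention of the screen).  The
per-cell on/off state of a link is its peak's mask row; an alternative
definition additionally requiring expression (mask ∧ count > 0) is behind
a flag.  Under a row-permuted mask the link rate matches the nominal
α = 0.05 within sampling error (tested with ≥ 500 permuted tests).

**Pearson screen.**  Candidate (peak, gene) pairs are screened by Pearson
correlation with t-distribution p-values and BH control at FDR 10 %;
significant positive and negative counts are reported separately.

## Regulon activity

Regulons are built by co-expression: candidate targets are genes with
Spearman correlation ≥ 0.3 to the TF's expression across cells, always
including the TF's own gene, optionally pruned to genes whose TSS lies
within 10 kb of a peak carrying that TF's motif; regulons below 10 genes
are dropped.  This is a deliberately simple, documented screen — not a
gradient-boosting GRN — and regulons can be supplied externally to bypass
it.

Per-cell enrichment is the area under the recovery curve: genes ranked by
expression descending (ties broken by stable input order), the cumulative
regulon-gene count summed over the top ⌈0.05 · n⌉ ranks and normalized by
the best achievable packing, so the score lives in [0, 1] and is invariant
to monotone transformations of the expression vector.  The top fraction
follows the common recovery-curve convention and is configurable.

Activity calls fit a two-component Gaussian mixture (EM, 10 restarts,
seeded) to each TF's AUC row; the threshold is the smallest point between
the component means where the posterior flips.  When the components are
indistinct (|μ₁ − μ₂| < 0.5 (σ₁ + σ₂)) the fallback threshold mean + 2 sd
is used, which marks isolated outliers and otherwise calls everything
inactive; constant rows are all-inactive.

## Motif scanning and active regions

PWMs are JASPAR-style counts converted to probabilities after adding the
pseudocount to every cell.  Scores are log₂(p/background) sums; both
strands are scanned (the reverse strand via the reverse-complemented
matrix) and windows containing N are skipped.  The "fraction of the best
possible score" criterion is ill-posed when log-odds scores are negative,
so the default fraction is shift-normalized, (score − min)/(max − min) ≥
0.95, with the literal ratio available behind a flag.  Hit sets equal
brute-force window scoring (tested on random fixtures).

A peak is active in a cell iff some TF has a qualifying hit in the peak
and is called active in that cell, and (by default — configurable) the
peak holds at least one fragment in that cell.  The mask is monotone:
adding an active TF can only switch cells on.

## NMF and rank selection

Multiplicative updates minimize the Frobenius loss; the loss is checked to
be non-increasing every 50 iterations, and iteration stops at max_iter
(default 1000) or when the checked improvement falls below tol (1e-6).
Initialisation is uniform random scaled by √(mean(V)/K); restart r uses
seed + r, so a fixed seed is bitwise reproducible.  All-zero rows/columns
are dropped with a warning.  Per rank, the best of 20 restarts is kept;
restart stability is the mean pairwise Amari distance of the restart W
matrices and consensus stability the cophenetic correlation of the
averaged co-clustering (H-argmax) connectivity matrix.

The Amari distance uses the cross-product pinv(W₁)W₂, which is exactly a
scaled permutation matrix when the column sets match up to permutation and
positive scaling — column-cosine constructions lack this property for
non-orthogonal factors — and is averaged over both directions for
symmetry.

Rank selection scores each K ∈ [2, 6] by three criteria: the *relative
drop* in Frobenius error from the previous rank (the raw error is monotone
in K, so "minimize the error" is read as the elbow; the drop at K_min is
measured against a rank-(K_min−1) baseline), the mean Amari distance
(smaller better) and the cophenetic coefficient (larger better).  Criteria
are converted to ranks after rounding to three decimals — differences
below numerical noise must count as ties, otherwise an exactly-zero Amari
at K=2 can outvote a decisive elbow at the true rank — and the best mean
rank wins, ties toward smaller K.  Signature-exclusive features are rows
whose normalized weight concentrates ≥ 0.75 on one signature; cross-rank
signature similarity regresses each higher-rank signature onto the
lower-rank W by non-negative least squares with coefficient columns
normalized to sum 1.

## Accessibility deviations

Expected counts allocate each cell's total over peaks in proportion to the
pooled peak fractions; a motif's raw deviation is (observed −
expected)/expected over its annotated peaks.  Raw deviations are z-scored
against B = 50 background peak sets matched on mean accessibility
(25 quantile bins; 2-D bins with GC content when supplied; singleton bins
map a peak to itself with a warning).  Variability is the sample standard
deviation of a motif's z row.  Under exact proportionality raw deviations
are identically zero (tested).  Note that background matching absorbs
signal when an enriched peak set monopolises its own accessibility bin;
benchmarks therefore vary baseline peak means so bins mix enriched and
unenriched peaks, as real peak sets do.

## Interaction validation

A link is supported when some interaction places one anchor over the
link's peak and the other over the gene's promoter (TSS ± 2 kb, the
canonical interaction endpoint for a gene; either anchor assignment
counts), with optional symmetric anchor slop.  The supported set grows
monotonically with slop.  Per-strategy proportions and the three-way Venn
of link sets are reported.

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes:

* cells split evenly into `n_cell_types` subpopulations (default 3 of
  300); TFs (default 10) are assigned round-robin to types and are active
  exactly in their type;
* each of the 100 planted links occupies its own 2.4 Mb block: target
  gene TSS at the center, a co-modulated promoter peak over the TSS, and
  one motif-bearing distal peak at an exponential distance (scale 150 kb,
  clipped to [20 kb, 900 kb], random sign — links are proximal-biased);
* accessibility is Poisson with mean 2 fragments, ×3 in cells of the
  link's type for the two link peaks; expression is negative binomial
  (mean 10, dispersion 0.1, var = μ + μ²·disp) with ×2^1 on targets in
  active cells, ×2^2 on TF genes in their type, then 10 % Bernoulli
  dropout.  The NB/Poisson split and the modest dropout reflect deep
  full-length single-cell expression data alongside sparse accessibility
  counts; all values are configurable;
* motifs are length-10 peaked PWMs (consensus probability ≈ 0.83 after
  pseudocount) embedded verbatim in the distal peaks on a random strand.
  At the 95 % shift-normalized threshold only exact consensus windows
  qualify, so spurious hits arise at ≈ 4⁻¹⁰ per window;
* decoy genes and decoy peaks live on separate chromosomes, so the 1 Mb
  window of any motif-bearing peak contains exactly its own target gene.

The last point is a deliberate idealisation: planted-link precision and
recall then measure the statistical power of the inference chain (regulon
→ activity call → motif mask → partition test), not layout confounding.
Real genomes interleave co-regulated genes within 1 Mb of shared
enhancers, where *any* per-cell partition method will report additional
type-associated pairs that are not direct targets; passing the benchmark
therefore does not certify causal specificity on real data.  The generator
also omits doublets, batch effects, GC composition bias and realistic
genomic background sequence.

Benchmark problem sizes used throughout the tests and the acceptance
script are the generator defaults (300 cells, 2000 peaks, 500 genes) or
scaled-down variants (120 cells, 200 peaks) for unit-level checks — sizes
at which every stage runs in seconds on one core while keeping ≥ 30 cells
per subpopulation and ≥ 500 permuted null tests.

## Known limitations

* The regulon builder is a correlation screen; indirect targets of a
  correlated TF pair are not disambiguated (all same-type TFs share one
  regulon on the synthetic data, which is harmless for activity calling
  but wrong as a regulon catalogue).
* Strategy-1/2 exposures require choosing an NMF rank before links exist;
  the default (3) matches the synthetic conditions, and real analyses
  should select it on the omics matrix first.
* The deviation model uses pooled-fraction expectations without the
  bias-corrected k-mer background of full chromVAR.
* Exact Wilcoxon enumeration is limited to n ≤ 12; beyond that the
  Edgeworth-corrected normal path is used even for tie-free data.
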