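# Methods

This note documents the models and procedures implemented in `tescope`, the
defaults they run with, the design choices that were genuinely open, and
what the synthetic-data validation does and does not show.

## Data model and coordinates

All genomic coordinates are 0-based half-open internally; only the GTF
reader/writer shifts by one at the file boundary. This matches BED
semantics and removes a whole class of off-by-one errors from overlap code.
Strand is stored on annotation records but ignored in every overlap
computation: ATAC peaks are strandless, and TE locus overlap with a peak is
a positional question. Feature kind (`gene` vs `te_locus`) travels as a
third column of the features TSV in the 10x-style matrix triplet; a triplet
without that column reads as all-gene, keeping plain 10x outputs loadable.

## QC and normalization

* `filter_cells`: keep cells detecting ≥ 1800 genes (detection = nonzero
  UMI count; TE-locus features never count toward this number). The wording
  "fewer than 1800" is read literally, so exactly 1800 is kept.
* `filter_genes`: keep genes with total count ≥ 10 **and** detected in ≥ 6
  cells ("five or fewer" removed). TE loci are untouched here; they have
  their own detection filter downstream. The filter is applied per loaded
  matrix; whether the original thresholds were per-sample or
  post-aggregation is not recoverable, so per-matrix is the package's rule.
* `normalize`: value = log2(count / cell_total × scale + 1) with scale 10⁶
  (TPM) or 10⁴ (CP10k). "TPM" is length-free counts-per-million: UMI counts
  are 3'-end counts, so no transcript-length division is meaningful. The
  per-cell total runs over **all** features present in the matrix
  (genes + TE loci), mirroring quantification against one combined
  annotation; a switch (`include_te_in_total=False`) and an explicit
  `totals=` argument cover gene-only scaling and submatrix normalization.

Filters are idempotent and monotone in their thresholds; before the log,
per-cell scaled values sum to the scale exactly — all three are property
tests.

## Differential expression

Pairwise DEGs use Welch's unequal-variance t-test per feature on the
normalized log values, Satterthwaite degrees of freedom, two-sided p,
Benjamini–Hochberg across all tested features, and the triple rule:
mean log2(TPM+1) of the higher group > 2 (strict), difference of group
means ≥ log2 4 (non-strict "≥ fourfold"), FDR < 0.01. Fold-change is the
difference of mean log values — the quantity the flanking diagonals of a
mean-vs-mean scatter plot measure — not the log of the ratio of linear
means. Features in which both groups have zero variance get p = 1 rather
than being dropped, so the BH denominator does not depend on the data;
this is conservative and deterministic.

Multi-group markers are one-vs-rest Welch tests with BH across features
within each cluster's comparison; a marker needs FDR < 0.05 and a
cluster-minus-rest mean difference > log2 2, and a feature may mark only
the cluster where its mean is maximal (so a feature cannot mark two
clusters). Marker callers in this role are often negative-binomial GLMs;
the one-vs-rest Welch construction was chosen because it is self-contained
and exactly testable, and its validation is by planted-marker recovery on
synthetic data (sensitivity and observed FDR), not by equivalence to any
particular GLM implementation. On the study-scale synthetic conditions
(6 clusters × 200 cells, 2000 genes, 50 markers at 2–8 fold) both rules
are scored in `tests/test_acceptance.py` and `scripts/acceptance.py`.

Sensitivity definitions: the fourfold pairwise rule is scored over planted
markers whose generative effect is ≥ log2 4 — a rule whose detection floor
is fourfold cannot be expected to recover twofold effects, and planted
effects right at the floor are borderline by construction. The twofold
multi-group rule is scored over all planted markers. Pairwise means are
computed over cells pooled across samples (per-sample-then-average is the
alternative; pooling is the package's rule and is stated here because the
choice is invisible in the output).

Marker-set selections (`select_expressed_panel`, `shared_upregulated`,
`t1lc_specific`) operate on cluster-averaged profiles with strict
inequalities at the stated cutoffs (mean > 1 in at least one cluster;
> 2-fold over every other cluster; male mean > 4 with adjusted female mean
< 2). Features missing from a second dataset's annotation are excluded
before testing, never imputed.

## Cross-platform adjustment

`fit_quadratic` is ordinary least squares on the monomial basis
{x², x, 1}; no weighting, no robust loss, no clamping of predictions. The
fit pairs per-feature pseudo-bulk means of the *same nominal cell type* on
the two platforms by inner join on feature id, and it is performed on the
log scale (log2 of scaled counts + 1): the downstream threshold "adjusted
log2(RPM+1) < 2" only makes sense if the curve maps log to log. A
rank-deficient design (fewer than three distinct x values) raises rather
than returning a pseudo-inverse fit.

## TE expression

TE abundance is quantified per genomic locus against a combined gene+TE
annotation. Reads compatible with zero or ≥ 2 features are discarded
(assigned + discarded = total, an invariant test); fractional or
EM-style multi-assignment is deliberately out of scope — unique assignment
is deterministic and is the behavior of standard unique-mapping counters.
How an upstream counter resolves gene/TE ambiguity in a combined
annotation is generally undocumented; the discard rule is this package's
declared substitute and is confined to `count_assignments`.

Order of operations: detection filter first (locus kept when detected in
≥ 0.5% of cells, inclusive), then aggregation by summing locus counts per
cell up the subfamily → family → class → total hierarchy. Summing after
filtering makes per-cell totals identical across every level — an exact
conservation test — and empty groups are absent from the output rather
than zero rows. Normalization is log2(CP10k+1) using per-cell totals of
the **full combined matrix**, so TE abundances remain comparable to gene
abundances and are not inflated by TE-only library sizes.

`variable_tes` ranks features by variance standardized against a
mean-variance trend: an OLS quadratic of log variance on mean expression
is fitted across features, and each feature is scored by the ratio of its
variance to the trend's prediction at its mean. Raw variance of
log-normalized values is strongly confounded with abundance — sampling
noise of lowly expressed subfamilies dominates, and a genuinely
stage-modulated subfamily at high expression can rank *last* by raw
variance because the log transform compresses its sampling noise. The
trend-standardized score removes this confound while staying free of
smoother hyperparameters; with fewer than three distinct feature means the
trend is undefined and plain variance is the fallback. Ties break
lexicographically by feature id and constant features rank last, so the
ranking is fully deterministic and invariant under duplication of cells.

## Peak–TE fold-enrichment

The observed statistic is the number of peaks overlapping (≥ 1 bp,
half-open) at least one locus of the subfamily; each peak counts at most
once. A base-pair-wise unit is available (`unit="bp"`) but peak-wise is
the default: the question is how many accessible sites sit on the
subfamily, not how much of their width does. The null re-places every peak
uniformly at random on its original chromosome with its length preserved,
placements independent (randomized peaks may overlap one another). This
scheme preserves chromosome and length but not inter-peak spacing, GC or
mappability; it was chosen because it admits an exact enumeration oracle
(every admissible start can be counted) and is the minimal "random
expectation". The randomizer is pluggable.

`fold = observed / mean(null)`; `empirical_p = (1 + #{null ≥ observed}) /
(1 + n_iter)` (add-one form, so p is never zero and is super-uniform under
the null). Degenerate cases: a null mean of 0 with a positive observed
count reports +inf with a logged warning; an empty peak set is an error,
not a zero. Defaults: n_iter = 1000, top_k = 50,000 peaks by score with
ties broken by (chrom, start).

## Synthetic data: what it emulates and what it does not

Counts are negative binomial with mean μ and size r (variance μ + μ²/r),
r = 2 by default — typical droplet-data overdispersion — with a scalar
baseline mean (0.5 by default, giving library sizes of a few hundred to a
few thousand UMIs at desk-scale gene counts) and log-normal per-cell
library factors (σ = 0.35, mean 1) so the per-cell normalizers are
exercised nontrivially. Markers multiply the baseline by 2^effect in one
cluster; TE programs multiply TE-locus means per cluster and subfamily.
TE loci are simulated *per locus* so aggregation conservation is testable
rather than trivially true. Toy genomes place loci non-overlapping and
uniformly; peak sets seed a calculated number of peaks inside enriched
subfamilies so the expected randomization fold equals the target
(n_seeded = n·p₀·(f−1)/(1−p₀), p₀ from the exact enumeration), the rest
placed uniformly.

Study-scale validation conditions: DEG suite at 6 clusters × 200 cells,
2000 genes, 50 markers with log2 effects evenly spread over [1, 3];
variable-TE suite at 100 subfamilies with copy numbers spread over 2–20
loci (real RepeatMasker subfamilies span orders of magnitude in copy
number, and a flat layout would leave the mean-variance trend
unconstrained), one subfamily following a geometric 1→8-fold program
across the six stages, 20 replicates; enrichment suite at 2000 peaks of
200 bp on a 2 × 1 Mb genome with planted folds 3 and 10 and 300
randomizations, plus the exact single-peak enumeration toy at 10,000
randomizations.

Not emulated: doublets, ambient RNA, batch effects, read-level error,
transcript-length bias, mappability structure, GC-matched null placement,
and multi-mapping reads. Passing the planted-recovery suite therefore
shows the statistics are implemented correctly and are calibrated under
the stated generative model — not that the model captures every failure
mode of real droplet data.

## Numerical notes

* BH adjustment is the standard step-up procedure (via statsmodels),
  verified against the direct formula and permutation-invariance property.
* Overlap counting merges loci per chromosome and answers each query by
  binary search over the merged runs; it is verified against a brute-force
  all-pairs oracle (fixed 1000-interval case plus a derandomized property
  test).
* All generators and the randomization null consume a single
  `numpy.random.default_rng(seed)` stream; identical seeds give bitwise
  identical outputs.
* Welch tests require ≥ 2 observations per group; a comparison in which
  both samples are constant is an error at the single-test interface and
  p = 1 in the vectorized matrix path (see above).
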