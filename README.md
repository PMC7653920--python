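# tescope

Single-cell transcriptome and transposable-element (TE) analysis toolkit for
staged germline differentiation studies.

## What it is for

In vitro reconstitution of human male germ-cell development produces a time
course of cell states (hiPSC → incipient mesoderm-like cells → primordial
germ cell-like cells → multiplying and transitional prospermatogonia-like
cells). Characterizing such a time course from droplet scRNA-seq requires a
specific chain of computations that general-purpose frameworks only partly
cover:

* **QC and normalization** — discard cells with < 1800 detected genes and
  genes with < 10 reads or detected in ≤ 5 cells; express abundances as
  log2(TPM+1) (length-free counts-per-million for UMI data) or
  log2(CP10k+1).
* **Differential expression** — pairwise DEGs under the triple rule
  *mean log2(TPM+1) > 2, fold-change ≥ 4, Welch-t BH-FDR < 0.01*, and
  one-vs-rest cluster markers (FDR < 0.05, > 2-fold over the rest); plus the
  marker-set selections built on cluster-averaged profiles (expressed-panel
  filtering, cross-dataset shared/specific marker splits, profile r²).
* **Cross-platform adjustment** — an ordinary least-squares quadratic
  y = a·x² + b·x + c fitted between pseudo-bulk profiles of the same cell
  type measured on two scRNA-seq platforms, used to place both datasets on
  one expression scale.
* **TE expression** — quantification at the individual genomic locus against
  a combined gene+TE annotation, detection filtering (locus seen in ≥ 0.5%
  of cells), exact hierarchical aggregation (locus → subfamily → family →
  class → total), CP10k normalization by combined-matrix totals, and
  trend-standardized variable-TE ranking.
* **Peak–TE enrichment** — for ATAC-seq peaks (top 50,000 by score), the
  fold-enrichment of peak overlaps with a TE subfamily over a randomization
  null in which every peak is re-placed uniformly on its own chromosome with
  length preserved:
  `fold = observed / mean(null)`, `p = (1 + #{null ≥ observed}) / (1 + n_iter)`.

Every stage is exercisable without external downloads through the
`tescope.simulate` generators, which plant known markers, TE programs and
peak enrichments and return the ground truth alongside the data.

## Worked example

```python
import tescope as ts
from tescope.te import te_matrix

layout = {"AluYa5": ("Alu", "SINE", 6, 300), "LTR7": ("ERV1", "LTR", 6, 400)}
cfg = ts.SimConfig(
    cluster_cells={c: 150 for c in ts.DEFAULT_STAGES},
    n_genes=500,
    marker_spec=[("G00042", "T1LC", 3.0)],          # 8-fold in T1LC
    te_layout=layout,
    te_program={"T1LC": {"LTR7": 8.0}},
    seed=1,
)
matrix, truth = ts.simulate_counts(cfg)
norm = ts.normalize(matrix, scheme=ts.TPM_LOG2)

deg = ts.pairwise_deg(norm, "T1LC", "hiPSC")
hits = deg[deg.deg_group == "a"]
print(f"{len(hits)} features >4-fold higher in T1LC")

ann, genome = ts.simulate_genome_annotation(2, 1_000_000, 500, layout, seed=2)
tem = ts.filter_te_loci(te_matrix(matrix))
sub = ts.aggregate_te(tem, ann, "subfamily")
tn = ts.te_normalize(sub, matrix.cell_totals())
print("variable TE ranking:", ts.variable_tes(tn, 2))

peaks, _ = ts.simulate_peaks(genome, ann, 1000, 200, enrich={"LTR7": 5.0}, seed=3)
res = ts.fold_enrichment(peaks, ann.intervals(subfamily="LTR7"),
                         genome, n_iter=1000, seed=4)
print(f"LTR7 fold-enrichment = {res.fold:.2f} (p = {res.empirical_p:.3g})")
```

Output:

```
7 features >4-fold higher in T1LC
variable TE ranking: ['LTR7', 'AluYa5']
LTR7 fold-enrichment = 5.02 (p = 0.000999)
```

The 7 pairwise DEGs are the planted gene marker (`G00042`, observed
Δlog2 = 6.8, FDR ≈ 3e-20) and the six LTR7 loci driven by the planted TE
program; the LTR7 subfamily tops the variable-TE ranking; and the peak set
planted at 5-fold enrichment is estimated at 5.02 with the smallest
empirical p-value attainable at 1000 randomizations.

A `tescope` console script exposes the same stages as subcommands
(`simulate`, `qc`, `deg`, `markers`, `xadjust`, `te-count`, `te-aggregate`,
`te-variable`, `enrich`); run `tescope --help`.

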