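"""Locus-resolution TE quantification, aggregation and variable-TE selection.

TE expression is quantified per genomic locus against a combined gene+TE
annotation; loci detected (nonzero count) in >= 0.5% of cells are retained,
and abundances at the subfamily, family, class and total levels are obtained
by summing locus counts per cell. Aggregation runs on the post-filter locus
set (filter first, then sum), so per-cell totals are conserved exactly across
every level of the hierarchy. Normalization is log2(CP10k+1) using the
per-cell totals of the full combined matrix, not TE-only totals.

Reads compatible with more than one feature of the combined annotation (e.g.
a TE locus inside a gene) are discarded rather than fractionally assigned:
deterministic, and it mirrors unique-assignment counting. The rule is
confined to :func:`count_assignments` and can be swapped out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

from .errors import ConfigError, InputError, IntegrityError
from .io import GENE, TE_LOCUS, CountMatrix, FeatureAnnotation
from .qc import CP10K_LOG2, NormalizedMatrix, normalize

logger = logging.getLogger(__name__)

LEVELS = ("locus", "subfamily", "family", "class", "total")
_LEVEL_COLUMN = {"subfamily": "subfamily", "family": "family", "class": "te_class"}


@dataclass
class TEMatrix:
    """A CountMatrix of TE features tagged with its aggregation level.

    At the locus level feature ids are locus ids; above it they are hierarchy
    names (subfamily/family/class) or the single feature ``"TE_total"``.
    """

    matrix: CountMatrix
    level: str = "locus"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ConfigError(f"unknown aggregation level {self.level!r}")
        if not (self.matrix.feature_kind == TE_LOCUS).all():
            raise IntegrityError("TEMatrix must contain only TE features")

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells


# ---------------------------------------------------------------------------
# Annotation assembly and read assignment
# ---------------------------------------------------------------------------

def build_combined_annotation(genes: FeatureAnnotation,
                              tes: FeatureAnnotation) -> FeatureAnnotation:
    """Union of a gene annotation and a TE-locus annotation.

    Feature-id namespaces must be disjoint; a collision raises rather than
    silently renaming.
    """
    overlap = set(genes.records["feature_id"]) & set(tes.records["feature_id"])
    if overlap:
        raise IntegrityError(f"feature_id collision: {sorted(overlap)[:5]}")
    return FeatureAnnotation(pd.concat([genes.records, tes.records],
                                       ignore_index=True))


def count_assignments(reads: pd.DataFrame, annotation: FeatureAnnotation,
                      cells) -> tuple[CountMatrix, dict]:
    """Accumulate read footprints into a per-(cell, feature) count matrix.

    ``reads`` needs columns barcode/chrom/start/end (0-based half-open).
    A read is counted iff it overlaps exactly one feature of the combined
    annotation; reads overlapping zero or >= 2 features, or on chromosomes
    absent from the annotation, are discarded. Returns the matrix over the
    supplied cell list plus an {assigned, discarded} tally
    (assigned + discarded == number of input reads, always).
    """
    cells = list(cells)
    cell_index = {c: i for i, c in enumerate(cells)}
    if len(cell_index) != len(cells):
        raise InputError("duplicate cell barcodes")
    trees: dict[str, IntervalTree] = {}
    for j, rec in enumerate(annotation.records.itertuples(index=False)):
        trees.setdefault(rec.chrom, IntervalTree())[rec.start:rec.end] = j
    n_features = len(annotation)
    counts = sp.dok_matrix((len(cells), n_features), dtype=np.int64)
    assigned = discarded = 0
    for rec in reads.itertuples(index=False):
        tree = trees.get(rec.chrom)
        hits = tree[rec.start:rec.end] if tree is not None else ()
        if len(hits) != 1 or rec.barcode not in cell_index:
            if tree is None:
                logger.debug("read on unknown chromosome %r discarded", rec.chrom)
            discarded += 1
            continue
        (hit,) = hits
        counts[cell_index[rec.barcode], hit.data] += 1
        assigned += 1
    m = CountMatrix(
        cell_ids=np.array(cells, dtype=object),
        feature_ids=annotation.records["feature_id"].to_numpy(dtype=object),
        feature_kind=annotation.records["kind"].to_numpy(dtype=object),
        counts=counts.tocsr(),
    )
    return m, {"assigned": assigned, "discarded": discarded}


def te_matrix(m: CountMatrix) -> TEMatrix:
    """Restrict a combined matrix to its TE-locus features."""
    return TEMatrix(m.subset(features=m.kind_mask(TE_LOCUS)), level="locus")


# ---------------------------------------------------------------------------
# Detection filter and hierarchical aggregation
# ---------------------------------------------------------------------------

def filter_te_loci(tem: TEMatrix, min_cell_fraction: float = 0.005) -> TEMatrix:
    """Keep loci detected in at least ``min_cell_fraction`` of cells
    (inclusive boundary: detected in exactly 0.5% of cells is kept)."""
    if tem.level != "locus":
        raise InputError("detection filter applies at the locus level")
    if not 0 <= min_cell_fraction <= 1:
        raise ConfigError("min_cell_fraction must be in [0, 1]")
    m = tem.matrix
    frac = np.asarray((m.counts > 0).sum(axis=0)).ravel() / m.n_cells
    return TEMatrix(m.subset(features=frac >= min_cell_fraction), level="locus")


def aggregate_te(tem: TEMatrix, annotation: FeatureAnnotation,
                 level: str) -> TEMatrix:
    """Sum locus counts per cell up the subfamily/family/class hierarchy.

    Groups with no surviving locus are absent from the output (no zero rows);
    ``level="total"`` yields the single feature ``"TE_total"``.
    """
    if tem.level != "locus":
        raise InputError("aggregation starts from the locus level")
    if level not in LEVELS or level == "locus":
        raise ConfigError(f"level must be one of {LEVELS[1:]}")
    m = tem.matrix
    if level == "total":
        totals = np.asarray(m.counts.sum(axis=1))
        agg = CountMatrix(m.cell_ids, np.array(["TE_total"], dtype=object),
                          np.array([TE_LOCUS], dtype=object),
                          sp.csr_matrix(totals),
                          cluster_labels=m.cluster_labels,
                          sample_labels=m.sample_labels)
        return TEMatrix(agg, level="total")
    hier = annotation.hierarchy()
    missing = [f for f in m.feature_ids if f not in hier.index]
    if missing:
        raise IntegrityError(f"loci without hierarchy: {missing[:5]}")
    col = _LEVEL_COLUMN[level]
    groups = hier.loc[list(m.feature_ids), col].to_numpy()
    names = pd.unique(groups)
    # indicator features x groups, then one sparse matmul
    gidx = {g: k for k, g in enumerate(names)}
    ind = sp.csr_matrix(
        (np.ones(len(groups)), (np.arange(len(groups)),
                                [gidx[g] for g in groups])),
        shape=(len(groups), len(names)))
    summed = (m.counts @ ind).astype(np.int64)
    agg = CountMatrix(m.cell_ids, np.array(names, dtype=object),
                      np.full(len(names), TE_LOCUS, dtype=object),
                      sp.csr_matrix(summed),
                      cluster_labels=m.cluster_labels,
                      sample_labels=m.sample_labels)
    return TEMatrix(agg, level=level)


# ---------------------------------------------------------------------------
# Normalization and variable-TE ranking
# ---------------------------------------------------------------------------

def te_normalize(tem: TEMatrix, cell_totals) -> NormalizedMatrix:
    """log2(CP10k+1) using per-cell totals of the full combined matrix.

    ``cell_totals`` may be an array aligned with the TE matrix's cells or a
    mapping/Series keyed by barcode; a missing barcode is an error.
    """
    m = tem.matrix
    if isinstance(cell_totals, (dict, pd.Series)):
        lookup = dict(cell_totals)
        missing = [c for c in m.cell_ids if c not in lookup]
        if missing:
            raise IntegrityError(f"no total for cells {missing[:5]}")
        cell_totals = np.array([lookup[c] for c in m.cell_ids], dtype=float)
    return normalize(m, scheme=CP10K_LOG2, totals=cell_totals)


def variable_tes(norm: NormalizedMatrix, n: int) -> list:
    """The ``n`` most variably expressed TE features, in rank order.

    Raw variance of log-normalized values is confounded with abundance
    (sampling noise of lowly expressed features dominates), so features are
    ranked by variance standardized against a mean-variance trend: an OLS
    quadratic of log variance on mean expression is fit across features, and
    each feature is scored by the ratio of its variance to the trend's
    prediction at its mean. With fewer than three distinct feature means the
    trend is undefined and plain variance is used. Ties are broken
    lexicographically by feature id; constant features rank last.
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    if n > len(norm.feature_ids):
        raise InputError(f"n={n} exceeds the {len(norm.feature_ids)} features")
    mean = norm.values.mean(axis=0)
    var = norm.values.var(axis=0, ddof=0)
    ok = var > 0
    if ok.sum() >= 3 and len(np.unique(mean[ok])) >= 3:
        design = np.vstack([mean ** 2, mean, np.ones_like(mean)]).T
        coef, *_ = np.linalg.lstsq(design[ok], np.log(var[ok]), rcond=None)
        score = np.where(ok, var / np.exp(design @ coef), -np.inf)
    else:
        score = np.where(ok, var, -np.inf)
    order = sorted(range(len(score)),
                   key=lambda j: (-score[j], norm.feature_ids[j]))
    return [norm.feature_ids[j] for j in order[:n]]


def te_stage_dynamics(norm_total: NormalizedMatrix, labels=None,
                      stage_order=None) -> pd.DataFrame:
    """Per-stage mean and dispersion of total TE expression.

    Expects the total-level normalized matrix (single feature). Rows follow
    ``stage_order`` when given, otherwise order of first appearance.
    """
    labels = norm_total.cluster_labels if labels is None \
        else np.asarray(labels, dtype=object)
    if labels is None:
        raise InputError("cluster labels required")
    if norm_total.values.shape[1] != 1:
        raise InputError("expected the total-level matrix (one feature)")
    vals = norm_total.values[:, 0]
    stages = list(stage_order) if stage_order is not None else list(pd.unique(labels))
    rows = []
    for s in stages:
        v = vals[labels == s]
        if v.size == 0:
            raise InputError(f"stage {s!r} has no cells")
        rows.append((s, v.size, float(v.mean()),
                     float(v.std(ddof=1)) if v.size > 1 else 0.0))
    return pd.DataFrame(rows, columns=["stage", "n_cells", "mean", "sd"])
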