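"""Cell/gene quality filters and per-cell normalization.

Filtering follows the conventions of droplet scRNA-seq germline atlases:
cells with fewer than 1800 detected genes are discarded, as are genes with
fewer than 10 total reads or detected in five or fewer cells ("detected"
means a nonzero UMI count). Expression is reported as log2(TPM+1) — for
3'-UMI data TPM is length-free counts-per-million — or as log2(CP10k+1)
(counts per 10,000), the convention used for TE profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError
from .io import GENE, CountMatrix

TPM_LOG2 = "tpm_log2"
CP10K_LOG2 = "cp10k_log2"
_SCALES = {TPM_LOG2: 1e6, CP10K_LOG2: 1e4}


@dataclass
class NormalizedMatrix:
    """Per-cell scaled log2 expression with the same axes as a CountMatrix."""

    cell_ids: np.ndarray
    feature_ids: np.ndarray
    feature_kind: np.ndarray
    values: np.ndarray  # dense cells x features, float
    scheme: str
    cluster_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scheme not in _SCALES:
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.values.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise IntegrityError("values shape does not match axes")
        if self.values.size and self.values.min() < 0:
            raise IntegrityError("negative normalized values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.cell_ids),
                            columns=list(self.feature_ids))


def filter_cells(m: CountMatrix, min_genes: int = 1800) -> CountMatrix:
    """Retain cells detecting at least ``min_genes`` features of kind gene.

    The boundary is inclusive: a cell with exactly ``min_genes`` detected
    genes is kept ("fewer than" removed). Cell order is preserved.
    """
    if min_genes < 0:
        raise ConfigError("min_genes must be >= 0")
    gene_cols = m.kind_mask(GENE)
    detected = np.asarray((m.counts[:, gene_cols] > 0).sum(axis=1)).ravel()
    return m.subset(cells=detected >= min_genes)


def filter_genes(m: CountMatrix, min_total_reads: int = 10,
                 min_cells_detected: int = 6) -> CountMatrix:
    """Drop genes with < ``min_total_reads`` total counts or detected in
    fewer than ``min_cells_detected`` cells. TE-locus features are untouched
    (they have their own detection filter downstream)."""
    if min_total_reads < 0 or min_cells_detected < 0:
        raise ConfigError("thresholds must be >= 0")
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    ncells = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    is_gene = m.kind_mask(GENE)
    keep = ~is_gene | ((totals >= min_total_reads) & (ncells >= min_cells_detected))
    return m.subset(features=keep)


def normalize(m: CountMatrix, scheme: str = TPM_LOG2,
              totals: np.ndarray | None = None,
              include_te_in_total: bool = True) -> NormalizedMatrix:
    """Per-cell scaling to TPM or CP10k followed by log2(x + 1).

    By default the per-cell total runs over every feature present in the
    matrix, mirroring quantification against a single combined gene+TE
    annotation; set ``include_te_in_total=False`` to scale by gene counts
    only, or pass explicit ``totals`` (e.g. totals of the full combined
    matrix when normalizing a TE-only submatrix).
    """
    if scheme not in _SCALES:
        raise ConfigError(f"unknown scheme {scheme!r}; use {sorted(_SCALES)}")
    if totals is None:
        if include_te_in_total:
            totals = m.cell_totals()
        else:
            totals = np.asarray(m.counts[:, m.kind_mask(GENE)].sum(axis=1)).ravel()
    totals = np.asarray(totals, dtype=float).ravel()
    if len(totals) != m.n_cells:
        raise IntegrityError("totals length != number of cells")
    if (totals <= 0).any():
        raise IntegrityError(
            "cell with zero total counts; run filter_cells/filter_genes first")
    dense = np.asarray(m.counts.todense(), dtype=float)
    values = np.log2(dense / totals[:, None] * _SCALES[scheme] + 1.0)
    return NormalizedMatrix(m.cell_ids, m.feature_ids, m.feature_kind,
                            values, scheme, cluster_labels=m.cluster_labels)


def proportions(counts) -> np.ndarray:
    """Percentage composition of a vector of category counts (sums to 100)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ConfigError("total count must be positive")
    return counts / total * 100.0
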