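import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import tescope as ts
from tescope.io import ANNOTATION_COLUMNS


@pytest.fixture
def small_matrix() -> ts.CountMatrix:
    """4 cells x 5 features (3 genes + 2 TE loci) with hand-set counts."""
    counts = np.array([
        [5, 0, 2, 1, 0],
        [0, 3, 0, 0, 4],
        [1, 1, 1, 1, 1],
        [0, 0, 0, 0, 0],
    ])
    return ts.CountMatrix(
        cell_ids=np.array([f"c{i}" for i in range(4)], dtype=object),
        feature_ids=np.array(["g1", "g2", "g3", "te1", "te2"], dtype=object),
        feature_kind=np.array(["gene"] * 3 + ["te_locus"] * 2, dtype=object),
        counts=sp.csr_matrix(counts),
        cluster_labels=np.array(["A", "A", "B", "B"], dtype=object),
    )


@pytest.fixture
def tiny_annotation() -> ts.FeatureAnnotation:
    """2 genes + 3 TE loci in 2 subfamilies on one chromosome."""
    rows = [
        ("g1", "chr1", 100, 300, "+", "gene", None, None, None),
        ("g2", "chr1", 1000, 1400, "-", "gene", None, None, None),
        ("te1", "chr1", 500, 600, "+", "te_locus", "AluYa5", "Alu", "SINE"),
        ("te2", "chr1", 700, 760, "-", "te_locus", "AluYa5", "Alu", "SINE"),
        ("te3", "chr1", 2000, 2500, "+", "te_locus", "LTR7", "ERV1", "LTR"),
    ]
    return ts.FeatureAnnotation(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS))


@pytest.fixture
def te_layout() -> dict:
    return {"AluYa5": ("Alu", "SINE", 3, 300),
            "LTR7": ("ERV1", "LTR", 4, 400)}


def brute_force_overlaps(peaks: ts.IntervalSet, loci: ts.IntervalSet) -> int:
    """All-pairs overlap oracle: number of peaks hitting >= 1 locus."""
    hits = 0
    for p in peaks.intervals.itertuples(index=False):
        for l in loci.intervals.itertuples(index=False):
            if p.chrom == l.chrom and p.start < l.end and l.start < p.end:
                hits += 1
                break
    return hits


def bh_direct(p: np.ndarray) -> np.ndarray:
    """Step-up BH by the textbook formula: q(i) = min_{j>=i} p(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
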