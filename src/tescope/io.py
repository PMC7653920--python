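"""Shared data model and readers/writers for the standard formats the pipeline touches.

In-memory containers:

* :class:`CountMatrix` — cells x features sparse UMI counts, with a per-feature
  flag separating ordinary genes from transposable-element (TE) loci.
* :class:`FeatureAnnotation` — genomic records for genes and TE loci; TE loci
  carry the RepeatMasker subfamily -> family -> class hierarchy.
* :class:`IntervalSet` — strandless genomic intervals (ATAC peaks, TE loci).
* :class:`Genome` — chromosome name -> length map.

All coordinates are 0-based half-open internally; only the GTF reader/writer
shifts by one at the boundary. Strand is stored but never used for overlaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import FormatError, IntegrityError

GENE = "gene"
TE_LOCUS = "te_locus"
_KINDS = (GENE, TE_LOCUS)

ANNOTATION_COLUMNS = [
    "feature_id", "chrom", "start", "end", "strand", "kind",
    "subfamily", "family", "te_class",
]


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Cells x features non-negative integer UMI counts.

    Parameters
    ----------
    cell_ids
        Unique cell barcodes, one per row of ``counts``.
    feature_ids
        Unique feature identifiers, one per column.
    feature_kind
        Per-feature flag, ``"gene"`` or ``"te_locus"``.
    counts
        Sparse (CSR) cells x features matrix of non-negative integers.
    cluster_labels, sample_labels
        Optional per-cell categories (cluster / sample of origin).
    """

    cell_ids: np.ndarray
    feature_ids: np.ndarray
    feature_kind: np.ndarray
    counts: sp.csr_matrix
    cluster_labels: np.ndarray | None = None
    sample_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.feature_kind = np.asarray(self.feature_kind, dtype=object)
        self.counts = sp.csr_matrix(self.counts)
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels, dtype=object)
        if self.sample_labels is not None:
            self.sample_labels = np.asarray(self.sample_labels, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_cells, n_features = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.feature_ids) != n_features:
            raise IntegrityError(
                f"axis lengths ({len(self.cell_ids)} cells, {len(self.feature_ids)} "
                f"features) do not match matrix shape {self.counts.shape}"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise IntegrityError("duplicate cell barcodes")
        if len(set(self.feature_ids)) != n_features:
            raise IntegrityError("duplicate feature ids")
        if len(self.feature_kind) != n_features:
            raise IntegrityError("feature_kind length mismatch")
        bad = set(self.feature_kind) - set(_KINDS)
        if bad:
            raise IntegrityError(f"unknown feature kinds: {sorted(bad)}")
        data = self.counts.data
        if data.size:
            if (data < 0).any():
                raise IntegrityError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise IntegrityError("non-integer counts")
        for name in ("cluster_labels", "sample_labels"):
            lab = getattr(self, name)
            if lab is not None and len(lab) != n_cells:
                raise IntegrityError(f"{name} length != number of cells")

    # -- convenience ------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def kind_mask(self, kind: str) -> np.ndarray:
        return self.feature_kind == kind

    def cell_totals(self) -> np.ndarray:
        """Total UMI count per cell over all features in the matrix."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @staticmethod
    def _as_index(sel: np.ndarray | None, n: int) -> np.ndarray:
        if sel is None:
            return np.arange(n)
        sel = np.asarray(sel)
        return np.flatnonzero(sel) if sel.dtype == bool else sel

    def subset(self, cells: np.ndarray | None = None,
               features: np.ndarray | None = None) -> "CountMatrix":
        """Return a new matrix restricted to the given boolean/index masks."""
        c = self._as_index(cells, self.n_cells)
        f = self._as_index(features, self.n_features)
        return CountMatrix(
            cell_ids=self.cell_ids[c],
            feature_ids=self.feature_ids[f],
            feature_kind=self.feature_kind[f],
            counts=self.counts[c][:, f],
            cluster_labels=None if self.cluster_labels is None else self.cluster_labels[c],
            sample_labels=None if self.sample_labels is None else self.sample_labels[c],
        )


def read_count_matrix(dir_path: str | Path) -> CountMatrix:
    """Read a 10x-style triplet (matrix.mtx + features.tsv + barcodes.tsv).

    The on-disk matrix may be stored either features x barcodes (the 10x
    convention) or barcodes x features; orientation is resolved against the
    TSV line counts and the returned matrix is always cells x features.
    A third features-TSV column, when present, carries the feature kind
    (``te_locus`` or anything else, read as ``gene``); without it all
    features are genes.
    """
    dir_path = Path(dir_path)
    paths = {name: dir_path / name
             for name in ("matrix.mtx", "features.tsv", "barcodes.tsv")}
    for name, p in paths.items():
        if not p.exists():
            raise FormatError(f"missing {name} in {dir_path}")
    try:
        mat = mmread(str(paths["matrix.mtx"]))
    except Exception as exc:  # malformed MatrixMarket header/body
        raise FormatError(f"cannot parse matrix.mtx: {exc}") from exc
    feats = pd.read_csv(paths["features.tsv"], sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(paths["barcodes.tsv"], sep="\t", header=None, dtype=str)[0].tolist()
    feature_ids = feats[0].tolist()
    n_f, n_b = len(feature_ids), len(barcodes)
    if mat.shape == (n_f, n_b):
        counts = sp.csr_matrix(mat.T)
    elif mat.shape == (n_b, n_f):
        counts = sp.csr_matrix(mat)
    else:
        raise IntegrityError(
            f"matrix shape {mat.shape} matches neither ({n_f} features, {n_b} barcodes) "
            "nor its transpose"
        )
    data = counts.data
    if data.size and ((data < 0).any() or not np.allclose(data, np.round(data))):
        raise IntegrityError("matrix.mtx contains negative or non-integer entries")
    counts = counts.astype(np.int64)
    if feats.shape[1] >= 3:
        kind = np.where(feats[2].to_numpy() == TE_LOCUS, TE_LOCUS, GENE)
    else:
        kind = np.full(n_f, GENE, dtype=object)
    return CountMatrix(np.array(barcodes, dtype=object),
                       np.array(feature_ids, dtype=object),
                       np.asarray(kind, dtype=object), counts)


def write_count_matrix(m: CountMatrix, dir_path: str | Path) -> Path:
    """Write the 10x-style triplet (features x barcodes on disk)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    mmwrite(str(dir_path / "matrix.mtx"), sp.coo_matrix(m.counts.T), field="integer")
    feats = pd.DataFrame({0: m.feature_ids, 1: m.feature_ids, 2: m.feature_kind})
    feats.to_csv(dir_path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(dir_path / "barcodes.tsv", sep="\t",
                                 header=False, index=False)
    return dir_path


# ---------------------------------------------------------------------------
# FeatureAnnotation
# ---------------------------------------------------------------------------

@dataclass
class FeatureAnnotation:
    """Genomic records for genes and TE loci (0-based half-open).

    TE loci must carry the full subfamily/family/class hierarchy; genes carry
    none of it.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        for col in ANNOTATION_COLUMNS:
            if col not in df.columns:
                df[col] = None
        self.records = df[ANNOTATION_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.records
        if df["feature_id"].duplicated().any():
            dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise IntegrityError(f"duplicate feature_id {dup!r}")
        if (df["end"] <= df["start"]).any():
            raise IntegrityError("interval with end <= start")
        bad = set(df["kind"]) - set(_KINDS)
        if bad:
            raise IntegrityError(f"unknown feature kinds: {sorted(bad)}")
        te = df[df["kind"] == TE_LOCUS]
        for col in ("subfamily", "family", "te_class"):
            if te[col].isna().any():
                raise IntegrityError(f"TE locus without {col}")

    def __len__(self) -> int:
        return len(self.records)

    def te_loci(self) -> pd.DataFrame:
        return self.records[self.records["kind"] == TE_LOCUS]

    def genes(self) -> pd.DataFrame:
        return self.records[self.records["kind"] == GENE]

    def intervals(self, kind: str | None = None,
                  subfamily: str | None = None) -> "IntervalSet":
        """Project (a subset of) the annotation onto a plain interval set."""
        df = self.records
        if kind is not None:
            df = df[df["kind"] == kind]
        if subfamily is not None:
            df = df[df["subfamily"] == subfamily]
        return IntervalSet(df[["chrom", "start", "end"]].reset_index(drop=True))

    def hierarchy(self) -> pd.DataFrame:
        """feature_id -> (subfamily, family, te_class) for TE loci."""
        return self.te_loci()[["feature_id", "subfamily", "family", "te_class"]] \
            .set_index("feature_id")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path) -> FeatureAnnotation:
    """Parse a combined gene/TE GTF into a FeatureAnnotation.

    GTF coordinates (1-based inclusive) are shifted to 0-based half-open.
    The feature column distinguishes ``gene`` from ``te_locus``; records whose
    attributes include ``te_subfamily`` are TE loci regardless. Exactly one
    record per ``gene_id`` is required.
    """
    rows = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {ln}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr:
                raise FormatError(f"line {ln}: missing gene_id attribute")
            fid = attr["gene_id"]
            if fid in seen:
                raise FormatError(f"line {ln}: duplicate feature_id {fid!r}")
            seen.add(fid)
            start0, end0 = int(start) - 1, int(end)
            if end0 <= start0:
                raise FormatError(f"line {ln}: empty interval after conversion")
            is_te = feature == TE_LOCUS or "te_subfamily" in attr
            if is_te:
                missing = [k for k in ("te_subfamily", "te_family", "te_class")
                           if k not in attr]
                if missing:
                    raise FormatError(
                        f"line {ln}: TE record lacking attributes {missing}")
            rows.append({
                "feature_id": fid, "chrom": chrom, "start": start0, "end": end0,
                "strand": strand if strand in "+-" else ".",
                "kind": TE_LOCUS if is_te else GENE,
                "subfamily": attr.get("te_subfamily"),
                "family": attr.get("te_family"),
                "te_class": attr.get("te_class"),
            })
    return FeatureAnnotation(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS))


def write_gtf(annotation: FeatureAnnotation, path: str | Path) -> Path:
    """Write the annotation back to GTF (shifting to 1-based inclusive)."""
    with open(path, "w") as fh:
        for rec in annotation.records.itertuples(index=False):
            attrs = f'gene_id "{rec.feature_id}";'
            if rec.kind == TE_LOCUS:
                attrs += (f' te_subfamily "{rec.subfamily}";'
                          f' te_family "{rec.family}";'
                          f' te_class "{rec.te_class}";')
            fh.write("\t".join([
                rec.chrom, "tescope", rec.kind, str(rec.start + 1), str(rec.end),
                ".", rec.strand, ".", attrs,
            ]) + "\n")
    return Path(path)


# ---------------------------------------------------------------------------
# IntervalSet / Genome
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """Strand-agnostic 0-based half-open intervals with an optional score."""

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals).copy()
        if "score" not in df.columns:
            df["score"] = np.nan
        self.intervals = df[["chrom", "start", "end", "score"]].reset_index(drop=True)
        if len(df) and (self.intervals["end"] <= self.intervals["start"]).any():
            raise IntegrityError("interval with end <= start")

    def __len__(self) -> int:
        return len(self.intervals)

    def validate_against(self, genome: "Genome") -> None:
        for rec in self.intervals.itertuples(index=False):
            if rec.chrom not in genome.sizes:
                raise IntegrityError(f"chromosome {rec.chrom!r} absent from genome")
            if rec.end > genome.sizes[rec.chrom]:
                raise IntegrityError(
                    f"interval end {rec.end} beyond {rec.chrom} "
                    f"length {genome.sizes[rec.chrom]}")


@dataclass
class Genome:
    """Chromosome name -> length (bases)."""

    sizes: dict

    def __post_init__(self) -> None:
        self.sizes = dict(self.sizes)
        for chrom, length in self.sizes.items():
            if int(length) <= 0:
                raise IntegrityError(f"non-positive length for {chrom!r}")
            self.sizes[chrom] = int(length)

    @property
    def total_length(self) -> int:
        return sum(self.sizes.values())


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED5 (score from column 5, or column 4 of a 4-column file)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"line {ln}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise FormatError(f"line {ln}: end <= start")
            score = np.nan
            if len(fields) >= 5:
                score = float(fields[4])
            elif len(fields) == 4:
                try:
                    score = float(fields[3])
                except ValueError:
                    score = np.nan
            rows.append((chrom, start, end, score))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]))


def write_bed(iset: IntervalSet, path: str | Path) -> Path:
    with open(path, "w") as fh:
        for i, rec in enumerate(iset.intervals.itertuples(index=False)):
            if np.isnan(rec.score):
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")
            else:
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\tpeak{i}\t{rec.score:g}\n")
    return Path(path)


def read_chrom_sizes(path: str | Path) -> Genome:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"line {ln}: expected 'chrom<TAB>length'")
            if fields[0] in sizes:
                raise FormatError(f"line {ln}: duplicate chromosome {fields[0]!r}")
            sizes[fields[0]] = int(fields[1])
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path: str | Path) -> Path:
    with open(path, "w") as fh:
        for chrom, length in genome.sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    return Path(path)


def write_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    """Write any tabular pipeline output as a header-rowed TSV."""
    pd.DataFrame(table).to_csv(path, sep="\t", index=False)
    return Path(path)
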