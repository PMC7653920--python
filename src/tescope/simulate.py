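"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate, at desk scale, the inputs of a staged germline
differentiation experiment:

* clustered negative-binomial UMI counts over genes and TE loci, with
  planted cluster markers (mean multiplied by 2^effect in one cluster) and
  stage-dependent TE programs (per-subfamily multiplicative factors);
* a toy genome with non-overlapping gene and TE loci, the TE loci grouped
  into RepeatMasker-style subfamily -> family -> class hierarchies;
* peak sets with planted fold-enrichment in chosen TE subfamilies;
* a second "platform" whose log-expression is a quadratic distortion of the
  first plus Gaussian noise.

Counts are overdispersed negative binomial (mean mu, size r; variance
mu + mu^2/r), the minimal model the downstream DEG filters assume, with
log-normal per-cell library-size variation so the per-cell normalizers are
exercised nontrivially. Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .enrichment import uniform_overlap_probability
from .errors import ConfigError
from .io import (GENE, TE_LOCUS, ANNOTATION_COLUMNS, CountMatrix,
                 FeatureAnnotation, Genome, IntervalSet, write_bed,
                 write_chrom_sizes, write_count_matrix, write_gtf, write_tsv)

#: canonical stage order of the differentiation time course
DEFAULT_STAGES = ("hiPSC", "iMeLC", "hPGCLC", "MLC", "TC", "T1LC")


@dataclass
class SimConfig:
    """Generating parameters for the synthetic count matrix.

    ``cluster_cells`` maps ordered stage names to cell numbers.
    ``marker_spec`` plants (feature_id, cluster, log2 effect) markers: the
    feature's NB mean is multiplied by 2^effect inside that cluster.
    ``te_layout`` maps subfamily -> (family, class, n_loci, locus_length);
    ``te_program`` maps cluster -> {subfamily: multiplicative factor}.
    """

    cluster_cells: dict
    n_genes: int
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    marker_spec: list = field(default_factory=list)
    te_layout: dict | None = None
    te_program: dict = field(default_factory=dict)
    library_size_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.library_size_sigma < 0:
            raise ConfigError("library_size_sigma must be >= 0")
        if len(set(self.cluster_cells)) != len(self.cluster_cells):
            raise ConfigError("duplicate cluster names")
        for _, _, eff in self.marker_spec:
            if not np.isfinite(eff):
                raise ConfigError("marker effects must be finite")
        for cluster, factors in self.te_program.items():
            for sub, f in factors.items():
                if f <= 0:
                    raise ConfigError(
                        f"te_program factor for {cluster}/{sub} must be > 0")

    @property
    def n_te_loci(self) -> int:
        if not self.te_layout:
            return 0
        return sum(n for _, _, n, _ in self.te_layout.values())


@dataclass
class SimTruth:
    """Planted ground truth accompanying a generated fixture."""

    markers: pd.DataFrame  # feature_id, cluster, effect
    te_program: dict = field(default_factory=dict)
    enriched_subfamilies: dict = field(default_factory=dict)
    poly_coeffs: tuple | None = None


def gene_ids(n: int) -> list:
    return [f"G{i + 1:05d}" for i in range(n)]


def te_locus_ids(te_layout: dict) -> tuple[list, list]:
    """Locus ids plus their subfamily, in layout order."""
    ids, subs = [], []
    for sub, (_fam, _cls, n_loci, _length) in te_layout.items():
        for i in range(n_loci):
            ids.append(f"{sub}_L{i + 1}")
            subs.append(sub)
    return ids, subs


def random_marker_spec(feature_ids, clusters, n_markers: int,
                       effect_lo: float, effect_hi: float,
                       rng: np.random.Generator) -> list:
    """Plant ``n_markers`` markers on distinct features, clusters cycled,
    log2 effects evenly spread over [effect_lo, effect_hi]."""
    chosen = rng.choice(np.asarray(feature_ids, dtype=object), size=n_markers,
                        replace=False)
    clusters = list(clusters)
    effects = np.linspace(effect_lo, effect_hi, n_markers)
    return [(f, clusters[i % len(clusters)], float(effects[i]))
            for i, f in enumerate(chosen)]


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw the clustered negative-binomial UMI matrix.

    Per-cluster feature means are baseline x 2^effect (planted markers) x
    te_program factor (TE loci), scaled by each cell's log-normal library
    size factor; counts ~ NB(mean, size=dispersion).
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config.n_genes)
    te_ids, te_subs = te_locus_ids(config.te_layout) if config.te_layout else ([], [])
    feature_ids = genes + te_ids
    kind = np.array([GENE] * len(genes) + [TE_LOCUS] * len(te_ids), dtype=object)
    fidx = {f: j for j, f in enumerate(feature_ids)}
    clusters = list(config.cluster_cells)
    for f, c, _ in config.marker_spec:
        if f not in fidx:
            raise ConfigError(f"marker feature {f!r} not in the matrix")
        if c not in clusters:
            raise ConfigError(f"marker cluster {c!r} unknown")

    base = np.full(len(feature_ids), config.baseline_mean)
    blocks, cell_ids_all, labels_all = [], [], []
    sigma = config.library_size_sigma
    for cluster in clusters:
        n_cells = int(config.cluster_cells[cluster])
        mean_f = base.copy()
        for f, c, eff in config.marker_spec:
            if c == cluster:
                mean_f[fidx[f]] *= 2.0 ** eff
        factors = config.te_program.get(cluster, {})
        for j, sub in enumerate(te_subs):
            mean_f[len(genes) + j] *= factors.get(sub, 1.0)
        if sigma > 0:
            lib = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=n_cells)
        else:
            lib = np.ones(n_cells)
        mu = lib[:, None] * mean_f[None, :]
        r = config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        blocks.append(sp.csr_matrix(counts))
        cell_ids_all += [f"{cluster}-{i + 1:04d}" for i in range(n_cells)]
        labels_all += [cluster] * n_cells

    matrix = CountMatrix(
        cell_ids=np.array(cell_ids_all, dtype=object),
        feature_ids=np.array(feature_ids, dtype=object),
        feature_kind=kind,
        counts=sp.vstack(blocks).tocsr(),
        cluster_labels=np.array(labels_all, dtype=object),
    )
    truth = SimTruth(
        markers=pd.DataFrame(config.marker_spec,
                             columns=["feature_id", "cluster", "effect"]),
        te_program=config.te_program,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Genome / annotation
# ---------------------------------------------------------------------------

def simulate_genome_annotation(n_chroms: int, chrom_length: int, n_genes: int,
                               te_layout: dict, seed: int = 0,
                               gene_length: int = 2000
                               ) -> tuple[FeatureAnnotation, Genome]:
    """Place genes and TE loci non-overlapping and uniformly on a toy genome.

    Features are spread over chromosomes in shuffled round-robin order; on
    each chromosome, starts are drawn by distributing the free space
    uniformly between the packed features. Infeasible packing (features
    outrunning a chromosome) raises.
    """
    if n_chroms < 1 or chrom_length < 1:
        raise ConfigError("need at least one chromosome of positive length")
    for sub, (_f, _c, n_loci, length) in te_layout.items():
        if length < 1 or n_loci < 0:
            raise ConfigError(f"bad layout for subfamily {sub!r}")
    rng = np.random.default_rng(seed)
    te_ids, te_subs = te_locus_ids(te_layout)
    items = [(g, GENE, gene_length, None) for g in gene_ids(n_genes)]
    items += [(t, TE_LOCUS, te_layout[s][3], s) for t, s in zip(te_ids, te_subs)]
    order = rng.permutation(len(items))
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    per_chrom: dict[str, list] = {c: [] for c in chrom_names}
    for pos, idx in enumerate(order):
        per_chrom[chrom_names[pos % n_chroms]].append(items[idx])

    rows = []
    for chrom in chrom_names:
        placed = per_chrom[chrom]
        total = sum(length for _, _, length, _ in placed)
        free = chrom_length - total
        if free < 0:
            raise ConfigError(
                f"cannot pack {total} bases of features into {chrom} "
                f"({chrom_length} bp)")
        offsets = np.sort(rng.integers(0, free + 1, size=len(placed)))
        cursor = 0
        for (fid, kind, length, sub), off in zip(placed, offsets):
            start = int(off) + cursor
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == TE_LOCUS:
                fam, cls, _, _ = te_layout[sub]
                rows.append((fid, chrom, start, start + length, strand,
                             TE_LOCUS, sub, fam, cls))
            else:
                rows.append((fid, chrom, start, start + length, strand,
                             GENE, None, None, None))
            cursor += length
    annotation = FeatureAnnotation(
        pd.DataFrame(rows, columns=ANNOTATION_COLUMNS))
    genome = Genome({c: chrom_length for c in chrom_names})
    return annotation, genome


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def simulate_peaks(genome: Genome, annotation: FeatureAnnotation,
                   n_peaks: int, peak_length: int, enrich: dict | None = None,
                   seed: int = 0) -> tuple[IntervalSet, SimTruth]:
    """Peak set with planted fold-enrichment in chosen TE subfamilies.

    For each (subfamily, target_fold) pair a calculated number of peaks is
    seeded inside that subfamily's loci so that the expected randomization
    fold-enrichment equals the target; the remaining peaks are placed
    uniformly (chromosome chosen proportional to its number of admissible
    starts). All peaks carry uniform random scores.
    """
    enrich = dict(enrich or {})
    if n_peaks < 0:
        raise ConfigError("n_peaks must be >= 0")
    empty = pd.DataFrame({"chrom": pd.Series(dtype=object),
                          "start": pd.Series(dtype=np.int64),
                          "end": pd.Series(dtype=np.int64),
                          "score": pd.Series(dtype=float)})
    truth = SimTruth(markers=pd.DataFrame(
        columns=["feature_id", "cluster", "effect"]),
        enriched_subfamilies=enrich)
    if n_peaks == 0:
        return IntervalSet(empty), truth
    if peak_length < 1 or peak_length > min(genome.sizes.values()):
        raise ConfigError("peak_length must fit on every chromosome")
    rng = np.random.default_rng(seed)
    te = annotation.te_loci()
    rows = []
    n_seeded_total = 0
    for sub, fold in enrich.items():
        if fold < 1:
            raise ConfigError("target_fold must be >= 1")
        loci = te[te["subfamily"] == sub]
        if loci.empty:
            raise ConfigError(f"no loci for enriched subfamily {sub!r}")
        p0 = uniform_overlap_probability(
            annotation.intervals(subfamily=sub), genome, peak_length)
        # seeded peaks overlap with probability 1, background with p0:
        # (n_s + (n - n_s) p0) / (n p0) = fold  =>  n_s = n p0 (fold-1)/(1-p0)
        n_seed = int(round(n_peaks * p0 * (fold - 1) / (1 - p0)))
        n_seeded_total += n_seed
        if n_seeded_total > n_peaks:
            raise ConfigError("planted enrichment requires more peaks than n_peaks")
        locs = loci.iloc[rng.integers(0, len(loci), size=n_seed)]
        for rec in locs.itertuples(index=False):
            g_len = genome.sizes[rec.chrom]
            lo = max(0, rec.start - peak_length + 1)
            hi = min(rec.end - 1, g_len - peak_length)
            start = int(rng.integers(lo, hi + 1))
            rows.append((rec.chrom, start, start + peak_length))

    chroms = list(genome.sizes)
    weights = np.array([genome.sizes[c] - peak_length + 1 for c in chroms],
                       dtype=float)
    weights /= weights.sum()
    n_bg = n_peaks - n_seeded_total
    bg_chroms = rng.choice(len(chroms), size=n_bg, p=weights)
    for ci in bg_chroms:
        chrom = chroms[ci]
        start = int(rng.integers(0, genome.sizes[chrom] - peak_length + 1))
        rows.append((chrom, start, start + peak_length))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["score"] = rng.uniform(100, 1000, size=len(df))
    return IntervalSet(df), truth


# ---------------------------------------------------------------------------
# Platform pair
# ---------------------------------------------------------------------------

def simulate_platform_pair(base_profile, coeffs, noise_sd: float = 0.0,
                           seed: int = 0):
    """Second-platform profile y = a*x^2 + b*x + c + N(0, noise_sd)."""
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    a, b, c = coeffs
    x = np.asarray(base_profile, dtype=float)
    rng = np.random.default_rng(seed)
    y = a * x ** 2 + b * x + c
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    if isinstance(base_profile, pd.Series):
        return base_profile.copy(), pd.Series(y, index=base_profile.index)
    return x, y


# ---------------------------------------------------------------------------
# Config file and fixture bundle
# ---------------------------------------------------------------------------

def read_sim_config(path) -> tuple[SimConfig, dict]:
    """Parse the key = value sectioned simulation config file.

    Sections: [clusters] name = n_cells; [sim] scalar knobs; [genome]
    n_chroms/chrom_length/gene_length; [te_layout] subfamily =
    family,class,n_loci,locus_length; [markers] feature = cluster,effect;
    [te_program.CLUSTER] subfamily = factor; [peaks] n_peaks/peak_length;
    [peak_enrich] subfamily = target_fold. Returns the SimConfig plus the
    genome/peak sections as a dict.
    """
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keys are feature/cluster names; keep their case
    with open(path) as fh:
        cp.read_file(fh)
    if "clusters" not in cp:
        raise ConfigError("config needs a [clusters] section")
    clusters = {k: int(v) for k, v in cp["clusters"].items()}
    sim = cp["sim"] if "sim" in cp else {}
    te_layout = None
    if "te_layout" in cp:
        te_layout = {}
        for sub, spec in cp["te_layout"].items():
            fam, cls, n_loci, length = [s.strip() for s in spec.split(",")]
            te_layout[sub] = (fam, cls, int(n_loci), int(length))
    markers = []
    if "markers" in cp:
        for feat, spec in cp["markers"].items():
            cluster, effect = [s.strip() for s in spec.split(",")]
            markers.append((feat, cluster, float(effect)))
    te_program: dict = {}
    for section in cp.sections():
        if section.startswith("te_program."):
            cluster = section.split(".", 1)[1]
            te_program[cluster] = {sub: float(f)
                                   for sub, f in cp[section].items()}
    config = SimConfig(
        cluster_cells=clusters,
        n_genes=int(sim.get("n_genes", 1000)),
        baseline_mean=float(sim.get("baseline_mean", 0.5)),
        dispersion=float(sim.get("dispersion", 2.0)),
        marker_spec=markers,
        te_layout=te_layout,
        te_program=te_program,
        library_size_sigma=float(sim.get("library_size_sigma", 0.35)),
        seed=int(sim.get("seed", 0)),
    )
    extra = {}
    for section in ("genome", "peaks"):
        if section in cp:
            extra[section] = {k: int(v) for k, v in cp[section].items()}
    if "peak_enrich" in cp:
        extra["peak_enrich"] = {s: float(f) for s, f in cp["peak_enrich"].items()}
    return config, extra


def write_fixture_bundle(config: SimConfig, out_dir, genome_params: dict,
                         peak_params: dict | None = None,
                         peak_enrich: dict | None = None) -> Path:
    """Emit the full synthetic fixture bundle into a directory.

    Writes the matrix triplet, combined GTF, chrom.sizes, per-cell label TSV
    and the planted-truth TSV; with ``peak_params`` also a scored peak BED.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation, genome = simulate_genome_annotation(
        n_chroms=genome_params.get("n_chroms", 2),
        chrom_length=genome_params["chrom_length"],
        n_genes=config.n_genes,
        te_layout=config.te_layout or {},
        seed=config.seed,
        gene_length=genome_params.get("gene_length", 2000),
    )
    matrix, truth = simulate_counts(config)
    write_count_matrix(matrix, out_dir)
    write_gtf(annotation, out_dir / "annotation.gtf")
    write_chrom_sizes(genome, out_dir / "chrom.sizes")
    write_tsv(pd.DataFrame({"barcode": matrix.cell_ids,
                            "cluster": matrix.cluster_labels}),
              out_dir / "clusters.tsv")
    write_tsv(truth.markers, out_dir / "truth_markers.tsv")
    if peak_params:
        peaks, _ = simulate_peaks(
            genome, annotation,
            n_peaks=peak_params["n_peaks"],
            peak_length=peak_params["peak_length"],
            enrich=peak_enrich, seed=config.seed + 1)
        write_bed(peaks, out_dir / "peaks.bed")
    return out_dir
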