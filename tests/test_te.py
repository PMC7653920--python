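import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import tescope as ts
from tescope.errors import ConfigError, IntegrityError, InputError
from tescope.te import te_matrix


def _locus_matrix(counts, locus_ids, cells=None, labels=None):
    counts = np.asarray(counts)
    cells = cells or [f"c{i}" for i in range(counts.shape[0])]
    return ts.TEMatrix(ts.CountMatrix(
        cells, locus_ids, ["te_locus"] * counts.shape[1],
        sp.csr_matrix(counts),
        cluster_labels=None if labels is None else np.asarray(labels, dtype=object)),
        level="locus")


class TestCombinedAnnotation:
    def test_union_counts(self, tiny_annotation):
        genes = ts.FeatureAnnotation(tiny_annotation.genes())
        tes = ts.FeatureAnnotation(tiny_annotation.te_loci())
        combined = ts.build_combined_annotation(genes, tes)
        assert len(combined) == 5

    def test_id_collision_rejected(self, tiny_annotation):
        with pytest.raises(IntegrityError, match="collision"):
            ts.build_combined_annotation(tiny_annotation, tiny_annotation)

    def test_gtf_round_trip_preserves_hierarchy(self, tiny_annotation, tmp_path):
        combined = ts.build_combined_annotation(
            ts.FeatureAnnotation(tiny_annotation.genes()),
            ts.FeatureAnnotation(tiny_annotation.te_loci()))
        back = ts.read_gtf(ts.write_gtf(combined, tmp_path / "c.gtf"))
        pd.testing.assert_frame_equal(
            back.records.sort_values("feature_id").reset_index(drop=True),
            combined.records.sort_values("feature_id").reset_index(drop=True))


class TestCountAssignments:
    # tiny_annotation features: g1 [100,300), te1 [500,600), te2 [700,760),
    # g2 [1000,1400), te3 [2000,2500)
    def _reads(self, rows):
        return pd.DataFrame(rows, columns=["barcode", "chrom", "start", "end"])

    def test_unique_overlap_assigned(self, tiny_annotation):
        reads = self._reads([("c1", "chr1", 150, 250)])
        m, stats = ts.count_assignments(reads, tiny_annotation, ["c1"])
        assert m.counts[0, 0] == 1
        assert stats == {"assigned": 1, "discarded": 0}

    def test_ambiguous_read_discarded(self, tiny_annotation):
        # spans the end of g1 through te1: two features -> discarded
        reads = self._reads([("c1", "chr1", 250, 550),
                             ("c1", "chr1", 510, 520)])
        m, stats = ts.count_assignments(reads, tiny_annotation, ["c1"])
        assert stats["assigned"] == 1 and stats["discarded"] == 1
        assert stats["assigned"] + stats["discarded"] == 2

    def test_half_open_boundary_no_overlap(self, tiny_annotation):
        # read [400,500) touches te1's start=500 only at the open boundary
        reads = self._reads([("c1", "chr1", 400, 500)])
        _, stats = ts.count_assignments(reads, tiny_annotation, ["c1"])
        assert stats == {"assigned": 0, "discarded": 1}

    def test_unknown_chromosome_discarded(self, tiny_annotation):
        reads = self._reads([("c1", "chrUn", 0, 100)])
        _, stats = ts.count_assignments(reads, tiny_annotation, ["c1"])
        assert stats == {"assigned": 0, "discarded": 1}

    def test_conservation_on_random_reads(self, tiny_annotation):
        rng = np.random.default_rng(20)
        starts = rng.integers(0, 2600, size=200)
        reads = self._reads([("c1", "chr1", int(s), int(s) + 80)
                             for s in starts])
        _, stats = ts.count_assignments(reads, tiny_annotation, ["c1"])
        assert stats["assigned"] + stats["discarded"] == 200


class TestDetectionFilter:
    def test_boundary_at_half_percent(self):
        counts = np.zeros((1000, 2), dtype=int)
        counts[:5, 0] = 1   # detected in exactly 0.5% -> kept
        counts[:4, 1] = 1   # detected in 0.4% -> removed
        tem = _locus_matrix(counts, ["L1", "L2"])
        kept = ts.filter_te_loci(tem)
        assert list(kept.matrix.feature_ids) == ["L1"]

    def test_zero_threshold_identity(self):
        tem = _locus_matrix(np.eye(4, dtype=int), [f"L{i}" for i in range(4)])
        assert ts.filter_te_loci(tem, 0.0).matrix.n_features == 4

    def test_filter_requires_locus_level(self, tiny_annotation):
        tem = _locus_matrix(np.ones((4, 3), dtype=int), ["te1", "te2", "te3"])
        agg = ts.aggregate_te(tem, tiny_annotation, "subfamily")
        with pytest.raises(InputError):
            ts.filter_te_loci(agg)


class TestAggregation:
    def test_subfamily_sum(self, tiny_annotation):
        tem = _locus_matrix([[3, 4, 7]], ["te1", "te2", "te3"])
        agg = ts.aggregate_te(tem, tiny_annotation, "subfamily")
        got = dict(zip(agg.matrix.feature_ids,
                       np.asarray(agg.matrix.counts.todense()).ravel()))
        assert got == {"AluYa5": 7, "LTR7": 7}

    def test_conservation_across_all_levels(self, tiny_annotation):
        rng = np.random.default_rng(21)
        tem = _locus_matrix(rng.poisson(2, size=(10, 3)),
                            ["te1", "te2", "te3"])
        locus_totals = np.asarray(tem.matrix.counts.sum(axis=1)).ravel()
        for level in ("subfamily", "family", "class", "total"):
            agg = ts.aggregate_te(tem, tiny_annotation, level)
            np.testing.assert_array_equal(
                np.asarray(agg.matrix.counts.sum(axis=1)).ravel(), locus_totals)

    def test_empty_group_absent_after_filtering(self, tiny_annotation):
        counts = np.zeros((10, 3), dtype=int)
        counts[:, 0] = 1  # only te1 (AluYa5) survives detection
        tem = ts.filter_te_loci(_locus_matrix(counts, ["te1", "te2", "te3"]),
                                min_cell_fraction=0.05)
        agg = ts.aggregate_te(tem, tiny_annotation, "subfamily")
        assert list(agg.matrix.feature_ids) == ["AluYa5"]

    def test_missing_hierarchy_rejected(self, tiny_annotation):
        tem = _locus_matrix([[1]], ["unknown_locus"])
        with pytest.raises(IntegrityError):
            ts.aggregate_te(tem, tiny_annotation, "family")


class TestNormalizationAndRanking:
    def test_te_normalize_uses_supplied_totals(self):
        tem = _locus_matrix([[20], [20]], ["L1"], cells=["c1", "c2"])
        norm = ts.te_normalize(tem, pd.Series({"c1": 2000, "c2": 20000}))
        assert norm.values[0, 0] == pytest.approx(np.log2(101))
        assert norm.values[1, 0] == pytest.approx(np.log2(11))

    def test_te_normalize_missing_total_rejected(self):
        tem = _locus_matrix([[1]], ["L1"], cells=["c1"])
        with pytest.raises(IntegrityError):
            ts.te_normalize(tem, pd.Series({"other": 100.0}))

    def test_variable_tes_full_ranking_and_constant_last(self):
        rng = np.random.default_rng(22)
        values = np.column_stack([
            rng.normal(5, 3, 50),            # high variance
            rng.normal(5, 1, 50),            # low variance
            np.full(50, 5.0),                # constant -> last
        ])
        values = np.abs(values)
        norm = ts.NormalizedMatrix(
            [f"c{i}" for i in range(50)], ["hi", "lo", "flat"],
            ["te_locus"] * 3, values, ts.CP10K_LOG2)
        assert ts.variable_tes(norm, 3) == ["hi", "lo", "flat"]
        with pytest.raises(ConfigError):
            ts.variable_tes(norm, 0)

    def test_variable_tes_stable_under_cell_duplication(self):
        rng = np.random.default_rng(23)
        values = np.abs(rng.normal(3, 1, size=(40, 8)))
        ids = [f"T{j}" for j in range(8)]
        norm = ts.NormalizedMatrix([f"c{i}" for i in range(40)], ids,
                                   ["te_locus"] * 8, values, ts.CP10K_LOG2)
        doubled = ts.NormalizedMatrix(
            [f"c{i}" for i in range(80)], ids, ["te_locus"] * 8,
            np.vstack([values, values]), ts.CP10K_LOG2)
        assert ts.variable_tes(norm, 8) == ts.variable_tes(doubled, 8)


class TestStageDynamics:
    def _total_norm(self, values, labels):
        return ts.NormalizedMatrix(
            [f"c{i}" for i in range(len(values))], ["TE_total"], ["te_locus"],
            np.asarray(values, dtype=float).reshape(-1, 1), ts.CP10K_LOG2,
            cluster_labels=np.asarray(labels, dtype=object))

    def test_identical_clusters_equal_means(self):
        norm = self._total_norm([2, 2, 2, 2], ["A", "A", "B", "B"])
        out = ts.te_stage_dynamics(norm)
        assert out["mean"].nunique() == 1

    def test_single_cell_cluster(self):
        norm = self._total_norm([1.5, 7.25], ["A", "B"])
        out = ts.te_stage_dynamics(norm, stage_order=["B", "A"])
        assert list(out["stage"]) == ["B", "A"]
        assert out.loc[0, "mean"] == 7.25 and out.loc[0, "sd"] == 0.0

    def test_planted_monotone_program_recovered(self, te_layout):
        factors = np.geomspace(1, 8, 6)
        program = {c: {"AluYa5": float(f), "LTR7": float(f)}
                   for c, f in zip(ts.DEFAULT_STAGES, factors)}
        cfg = ts.SimConfig(cluster_cells={c: 150 for c in ts.DEFAULT_STAGES},
                           n_genes=300, te_layout=te_layout,
                           te_program=program, seed=24)
        m, _ = ts.simulate_counts(cfg)
        tem = te_matrix(m)
        ann, _ = ts.simulate_genome_annotation(1, 1_000_000, 300, te_layout, seed=25)
        total = ts.aggregate_te(tem, ann, "total")
        norm = ts.te_normalize(total, m.cell_totals())
        out = ts.te_stage_dynamics(norm, stage_order=ts.DEFAULT_STAGES)
        assert (np.diff(out["mean"]) > 0).all()
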