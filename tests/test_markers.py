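import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import tescope as ts
from tescope.errors import InputError, UndefinedStatisticError
from .conftest import bh_direct


def _norm_from_values(values, labels=None):
    values = np.asarray(values, dtype=float)
    n_c, n_f = values.shape
    return ts.NormalizedMatrix(
        cell_ids=np.array([f"c{i}" for i in range(n_c)], dtype=object),
        feature_ids=np.array([f"g{j}" for j in range(n_f)], dtype=object),
        feature_kind=np.array(["gene"] * n_f, dtype=object),
        values=values, scheme=ts.TPM_LOG2,
        cluster_labels=None if labels is None else np.asarray(labels, dtype=object))


class TestWelch:
    def test_identical_samples(self):
        t, df, p = ts.welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_zero_variance_both(self):
        with pytest.raises(UndefinedStatisticError):
            ts.welch_t([0, 0, 0], [0, 0, 0])

    def test_against_closed_form(self):
        # independent hand computation of the Welch/Satterthwaite formulas
        x, y = np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5, 6])
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / 4 + vy / 4
        t_exp = (x.mean() - y.mean()) / np.sqrt(se2)
        df_exp = se2 ** 2 / ((vx / 4) ** 2 / 3 + (vy / 4) ** 2 / 3)
        p_exp = 2 * stats.t.sf(abs(t_exp), df_exp)
        t, df, p = ts.welch_t(x, y)
        assert t == pytest.approx(t_exp, abs=1e-12)
        assert df == pytest.approx(df_exp, abs=1e-9)
        assert p == pytest.approx(p_exp, abs=1e-12)

    def test_too_small_sample(self):
        with pytest.raises(InputError):
            ts.welch_t([1], [2, 3])


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(ts.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_value(self):
        assert ts.bh_adjust([1.0]) == pytest.approx([1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            ts.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60),
           st.randoms(use_true_random=False))
    def test_matches_direct_formula_and_permutation_invariance(self, ps, rnd):
        p = np.asarray(ps)
        q = ts.bh_adjust(p)
        np.testing.assert_allclose(q, bh_direct(p), atol=1e-12)
        perm = np.array(rnd.sample(range(len(p)), len(p)))
        np.testing.assert_allclose(ts.bh_adjust(p[perm]), q[perm], atol=1e-12)


class TestPairwiseDeg:
    def test_threshold_arithmetic(self):
        # feature 0: clear DEG for a; feature 1: abundance fails despite
        # a large fold-change; feature 2: fold fails
        rng = np.random.default_rng(0)
        a = np.column_stack([rng.normal(5, 0.1, 20),
                             rng.normal(1.9, 0.02, 20),
                             rng.normal(3.0, 0.1, 20)])
        b = np.column_stack([rng.normal(2, 0.1, 20),
                             rng.uniform(0.0, 0.02, 20),
                             rng.normal(2.5, 0.1, 20)])
        norm = _norm_from_values(np.vstack([a, b]), ["A"] * 20 + ["B"] * 20)
        deg = ts.pairwise_deg(norm, "A", "B")
        assert list(deg["deg_group"]) == ["a", "", ""]
        assert not deg.loc[1, "passes_abundance"]
        assert not deg.loc[2, "passes_fold"]

    def test_degenerate_thresholds_partition_by_sign(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 6, size=(30, 40))
        norm = _norm_from_values(values, ["A"] * 15 + ["B"] * 15)
        deg = ts.pairwise_deg(norm, "A", "B", min_mean=-np.inf, fold=1.0, fdr=1.0)
        expect = np.where(deg["delta_log2"] >= 0, "a", "b")
        assert (deg["deg_group"] == expect).all()

    def test_null_simulation_false_positive_bound(self):
        cfg = ts.SimConfig(cluster_cells={"A": 100, "B": 100}, n_genes=2000,
                           seed=21)
        m, _ = ts.simulate_counts(cfg)
        norm = ts.normalize(m, scheme=ts.TPM_LOG2)
        deg = ts.pairwise_deg(norm, "A", "B")
        bound = stats.binom.ppf(0.999, 2000, 0.01)
        assert (deg["deg_group"] != "").sum() <= bound

    def test_empty_group_rejected(self):
        norm = _norm_from_values(np.ones((4, 2)), ["A"] * 4)
        with pytest.raises(InputError):
            ts.pairwise_deg(norm, "A", "B")


class TestMultigroupMarkers:
    def test_planted_marker_recovered(self):
        genes = [f"G{i + 1:05d}" for i in range(300)]
        recovered = 0
        for rep in range(10):
            cfg = ts.SimConfig(
                cluster_cells={"A": 100, "B": 100, "C": 100}, n_genes=300,
                marker_spec=[("G00010", "C", 3.0)], seed=40 + rep)
            m, _ = ts.simulate_counts(cfg)
            mk = ts.multigroup_markers(ts.normalize(m, scheme=ts.TPM_LOG2))
            if (("G00010" == mk["feature_id"]) & (mk["cluster"] == "C")).any():
                recovered += 1
        assert recovered >= 9

    def test_null_marker_rate_bounded(self):
        cfg = ts.SimConfig(cluster_cells={"A": 80, "B": 80, "C": 80},
                           n_genes=1000, seed=50)
        m, _ = ts.simulate_counts(cfg)
        mk = ts.multigroup_markers(ts.normalize(m, scheme=ts.TPM_LOG2))
        assert len(mk) <= 10  # fold + FDR gates leave at most a handful

    def test_single_cluster_rejected(self):
        norm = _norm_from_values(np.ones((4, 3)), ["A"] * 4)
        with pytest.raises(InputError):
            ts.multigroup_markers(norm)


class TestProfiles:
    def test_r2_identity_and_affine_invariance(self):
        a = np.arange(10, dtype=float)
        assert ts.profile_r2(a, a) == pytest.approx(1.0)
        assert ts.profile_r2(a, 2 * a + 1) == pytest.approx(1.0)

    def test_r2_independent_profiles_near_zero(self):
        rng = np.random.default_rng(3)
        assert ts.profile_r2(rng.normal(size=10_000),
                             rng.normal(size=10_000)) < 0.01

    def test_r2_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ts.profile_r2(np.ones(5), np.arange(5.0))

    def test_cluster_profile_means(self):
        values = np.array([[1.0, 2], [3, 4], [10, 20], [30, 40]])
        norm = _norm_from_values(values, ["A", "A", "B", "B"])
        prof = ts.cluster_profile(norm)
        assert prof.means.loc["g0", "A"] == 2.0
        assert prof.means.loc["g1", "B"] == 30.0
        assert prof.n_cells["A"] == 2


class TestSelections:
    def _profile(self, table):
        means = pd.DataFrame(table).T
        return ts.ClusterProfile(means, pd.Series(10, index=means.columns))

    def test_expressed_panel_strict_boundary(self):
        prof = self._profile({
            "g_keep": {"A": 0.2, "B": 1.2, "C": 0.5},
            "g_drop": {"A": 1.0, "B": 1.0, "C": 0.3},
        })
        assert ts.select_expressed_panel(prof, ["g_keep", "g_drop"]) == ["g_keep"]

    def test_expressed_panel_empty_intersection(self):
        prof = self._profile({"g1": {"A": 5.0}})
        assert ts.select_expressed_panel(prof, ["absent"]) == []

    def test_shared_upregulated_thresholds(self):
        prof = self._profile({
            "m1": {"target": 4.0, "o1": 2.9, "o2": 1.0},   # delta 1.1 > 1
            "m2": {"target": 4.0, "o1": 3.5, "o2": 1.0},   # delta 0.5, dropped
        })
        kept = ts.shared_upregulated(["m1", "m2", "m_absent"], prof, "target")
        assert kept == ["m1"]

    def test_shared_upregulated_fold_one_keeps_strict_maxima(self):
        prof = self._profile({"m1": {"target": 2.0, "o1": 1.9}})
        assert ts.shared_upregulated(["m1"], prof, "target", fold=1.0) == ["m1"]

    def test_shared_upregulated_missing_cluster(self):
        prof = self._profile({"m1": {"A": 1.0}})
        with pytest.raises(InputError):
            ts.shared_upregulated(["m1"], prof, "missing")

    def test_t1lc_specific_boundaries(self):
        male = pd.Series({"g1": 4.5, "g2": 4.5, "g3": 4.0})
        female = pd.Series({"g1": 1.5, "g2": 2.5, "g3": 0.0})
        kept = ts.t1lc_specific(["g1", "g2", "g3"], male, female)
        assert kept == ["g1"]  # g2 fails lo, g3 fails strict "> 4"

    def test_selections_are_subsets_and_disjoint_on_forced_fixture(self):
        markers = ["g_shared", "g_specific", "g_neither"]
        female_prof = self._profile({
            "g_shared": {"target": 6.0, "o1": 3.0},
            "g_specific": {"target": 1.0, "o1": 0.5},
            "g_neither": {"target": 2.0, "o1": 2.0},
        })
        shared = ts.shared_upregulated(markers, female_prof, "target")
        male = pd.Series({g: 5.0 for g in markers})
        specific = ts.t1lc_specific(markers, male,
                                    female_prof.means["target"])
        assert set(shared) <= set(markers) and set(specific) <= set(markers)
        # the shared set's female floor (> 2-fold over others) forces
        # target means above lo=2 here, so the two sets cannot intersect
        assert not set(shared) & set(specific)
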