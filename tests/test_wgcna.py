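"""Adjacency, TOM, clustering, tree cut, eigengenes, merging, kME."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.cluster.hierarchy import fcluster

import mycorrnet as mn
from mycorrnet import wgcna


def naive_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap, the independent oracle."""
    n = a.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (L + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return out


def random_adjacency(rng, n):
    m = rng.uniform(0, 1, (n, n))
    a = (m + m.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def naive_average_linkage(d: np.ndarray) -> list:
    """Naive agglomeration; returns sorted merge heights."""
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                dist = np.mean([d[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters[a] = clusters[a] + clusters.pop(b)
    return heights


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.linspace(0, 1, 10)
        expr = pd.DataFrame([x, 2 * x + 1], index=["a", "b"])
        adj = mn.adjacency(expr, power=12)
        assert adj.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_soft_power_on_negative_half_correlation(self):
        # genes correlated exactly -0.5: unsigned adjacency 0.5^12
        base = np.asarray([1.0, -1.0, 0.0, 1.0, -1.0, 0.0])
        other = np.asarray([1.0, 0.0, -1.0, 1.0, 0.0, -1.0])
        r = np.corrcoef(base, -other)[0, 1]
        assert r == pytest.approx(-0.5)
        expr = pd.DataFrame([base, -other], index=["a", "b"])
        adj = mn.adjacency(expr, power=12, mode="unsigned")
        assert adj.loc["a", "b"] == pytest.approx(0.5**12, abs=1e-15)
        assert adj.loc["a", "b"] == pytest.approx(2.44140625e-4)

    def test_signed_mode(self):
        x = np.linspace(0, 1, 8)
        expr = pd.DataFrame([x, -x], index=["a", "b"])
        adj = mn.adjacency(expr, power=2, mode="signed")
        assert adj.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_gene_dropped_with_warning(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.0, 1.0, 1.0, 1.0], [4.0, 3.0, 2.0, 1.0]],
            index=["a", "flat", "b"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            adj = mn.adjacency(expr)
        assert list(adj.index) == ["a", "b"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3 samples"):
            mn.adjacency(pd.DataFrame([[1.0, 2.0], [2.0, 1.0]]))


class TestTopologicalOverlap:
    def test_complete_graph(self):
        a = np.ones((3, 3))
        tom = mn.topological_overlap(pd.DataFrame(a))
        # (L + a) / (min k + 1 - a) = (1 + 1) / (2 + 1 - 1) = 1
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_empty_graph(self):
        a = np.eye(4)
        tom = mn.topological_overlap(pd.DataFrame(a)).to_numpy()
        off = tom[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)
        assert np.allclose(np.diag(tom), 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = random_adjacency(rng, 20)
            got = mn.topological_overlap(pd.DataFrame(a)).to_numpy()
            assert np.abs(got - naive_tom(a)).max() < 1e-10

    @given(seed=st.integers(0, 100))
    def test_bounds_symmetry_diagonal(self, seed):
        a = random_adjacency(np.random.default_rng(seed), 12)
        tom = mn.topological_overlap(pd.DataFrame(a)).to_numpy()
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)

    def test_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            mn.topological_overlap(pd.DataFrame(a))


class TestClustering:
    def test_two_blocks_split_at_height_one(self):
        d = np.ones((8, 8))
        d[:4, :4] = 0.0
        d[4:, 4:] = 0.0
        np.fill_diagonal(d, 0.0)
        Z = mn.cluster_genes(d)
        assert Z[-1, 2] == pytest.approx(1.0)
        lab = fcluster(Z, t=0.5, criterion="distance")
        assert len(set(lab[:4])) == 1 and len(set(lab[4:])) == 1
        assert lab[0] != lab[4]

    def test_three_point_average_linkage_arithmetic(self):
        d = np.asarray([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        Z = mn.cluster_genes(d)
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.9)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_merge_heights_match_naive_agglomeration(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0.01, 1, (30, 30))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        Z = mn.cluster_genes(d)
        expected = naive_average_linkage(d)
        assert np.abs(np.sort(Z[:, 2]) - np.sort(expected)).max() < 1e-10

    def test_asymmetric_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = 0.2
        with pytest.raises(ValueError, match="symmetric"):
            mn.cluster_genes(d)


class TestDynamicCut:
    def test_two_clean_blocks_recovered(self):
        d = np.ones((120, 120))
        d[:60, :60] = 0.0
        d[60:, 60:] = 0.0
        np.fill_diagonal(d, 0.0)
        lab = mn.dynamic_cut(mn.cluster_genes(d), min_size=50)
        assert set(lab) == {1, 2}
        assert len(set(lab[:60])) == 1 and len(set(lab[60:])) == 1

    def test_small_block_unassigned(self):
        d = np.ones((70, 70))
        d[:40, :40] = 0.0  # block below min_size
        np.fill_diagonal(d, 0.0)
        lab = mn.dynamic_cut(mn.cluster_genes(d), min_size=50)
        assert (lab[:40] == 0).all()

    def test_iid_noise_mostly_unassigned(self):
        fracs = []
        for seed in range(5):
            X = np.random.default_rng(seed).normal(size=(300, 45))
            adj = wgcna._adjacency(X, 12, "unsigned")
            Z = wgcna._linkage(1.0 - wgcna._tom(adj))
            lab = mn.dynamic_cut(Z, min_size=50)
            fracs.append((lab == 0).mean())
        assert np.median(fracs) >= 0.8

    def test_min_size_exceeding_n_warns(self):
        d = np.ones((10, 10))
        np.fill_diagonal(d, 0.0)
        with pytest.warns(UserWarning, match="min_size"):
            lab = mn.dynamic_cut(mn.cluster_genes(d), min_size=50)
        assert (lab == 0).all()


class TestEigengenes:
    def test_identical_profiles(self):
        x = np.asarray([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = pd.DataFrame([x, 2 * x, 3 * x + 1], index=["a", "b", "c"])
        me, ve = mn.module_eigengenes(expr, np.asarray([1, 1, 1]))
        z = (x - x.mean()) / x.std()
        assert np.abs(me["M1"].to_numpy() - z).max() < 1e-10
        assert ve["M1"] == pytest.approx(1.0)

    @pytest.mark.parametrize("r_target", [0.9, 0.5, 0.0, -0.7])
    def test_two_gene_variance_explained(self, r_target):
        rng = np.random.default_rng(abs(int(r_target * 10)))
        x = rng.normal(size=200)
        y = r_target * x + np.sqrt(max(1 - r_target**2, 0)) * rng.normal(size=200)
        expr = pd.DataFrame([x, y], index=["a", "b"])
        r = np.corrcoef(x, y)[0, 1]
        _, ve = mn.module_eigengenes(expr, np.asarray([1, 1]))
        assert ve["M1"] == pytest.approx((1 + abs(r)) / 2, abs=1e-8)

    def test_matches_independent_svd(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(50, 30)) + rng.normal(size=30)
        expr = pd.DataFrame(vals)
        me, _ = mn.module_eigengenes(expr, np.ones(50, dtype=int))
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(
            axis=1, keepdims=True
        )
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        ref = vt[0] / vt[0].std()
        if np.corrcoef(ref, me["M1"])[0, 1] < 0:
            ref = -ref
        assert np.abs(me["M1"].to_numpy() - ref).max() < 1e-8

    def test_sign_anchored_to_members(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(40, 25)) + 2 * rng.normal(size=25)
        me, _ = mn.module_eigengenes(pd.DataFrame(vals), np.ones(40, dtype=int))
        kme = mn.module_membership(pd.DataFrame(vals), me)
        assert kme["M1"].mean() > 0

    def test_single_gene_module(self):
        x = np.asarray([0.0, 1.0, 4.0, 2.0])
        me, ve = mn.module_eigengenes(pd.DataFrame([x]), np.asarray([1]))
        assert np.abs(me["M1"] - (x - x.mean()) / x.std()).max() < 1e-12
        assert ve["M1"] == 1.0

    def test_unit_variance(self, small_expr):
        part = mn.detect_modules(small_expr["host"], min_module_size=40)
        assert np.allclose(part.eigengenes.to_numpy().std(axis=0), 1.0)


class TestMergeModules:
    def _two_correlated_modules(self, r):
        rng = np.random.default_rng(0)
        f = rng.normal(size=200)
        g = r * f + np.sqrt(1 - r**2) * rng.normal(size=200)
        rows, labels = [], []
        for _ in range(30):
            rows.append(f + 0.01 * rng.normal(size=200))
            labels.append(1)
        for _ in range(30):
            rows.append(g + 0.01 * rng.normal(size=200))
            labels.append(2)
        return pd.DataFrame(rows), np.asarray(labels)

    def test_highly_correlated_modules_merge(self):
        expr, labels = self._two_correlated_modules(0.97)
        part = mn.merge_modules(expr, labels, merge_cut=0.1)
        assert part.n_modules == 1

    def test_distinct_modules_not_merged(self):
        expr, labels = self._two_correlated_modules(0.8)
        part = mn.merge_modules(expr, labels, merge_cut=0.1)
        assert part.n_modules == 2

    def test_duplicated_module_collapses(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=100)
        expr = pd.DataFrame([f + 0.01 * rng.normal(size=100) for _ in range(40)])
        labels = np.asarray([1] * 20 + [2] * 20)  # same signal, split labels
        part = mn.merge_modules(expr, labels, merge_cut=0.1)
        assert part.n_modules == 1
        assert (part.labels > 0).all()

    def test_merge_idempotent_and_never_grows(self):
        expr, labels = self._two_correlated_modules(0.5)
        part1 = mn.merge_modules(expr, labels, merge_cut=0.1)
        part2 = mn.merge_modules(expr, part1.labels, merge_cut=0.1)
        assert part2.n_modules <= part1.n_modules <= len(set(labels))
        pd.testing.assert_series_equal(part1.labels, part2.labels)

    def test_unassigned_never_merge(self):
        expr, labels = self._two_correlated_modules(0.97)
        labels = labels.copy()
        labels[:5] = 0
        part = mn.merge_modules(expr, labels, merge_cut=0.1)
        assert (part.labels.iloc[:5] == 0).all()


class TestModuleMembership:
    def test_gene_equal_to_eigengene(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(20, 30)) + 3 * rng.normal(size=30)
        me, _ = mn.module_eigengenes(pd.DataFrame(vals), np.ones(20, dtype=int))
        probe = pd.DataFrame(
            [me["M1"].to_numpy(), -me["M1"].to_numpy()], index=["same", "neg"]
        )
        kme = mn.module_membership(probe, me)
        assert kme.loc["same", "M1"] == pytest.approx(1.0, abs=1e-10)
        assert kme.loc["neg", "M1"] == pytest.approx(-1.0, abs=1e-10)

    def test_matches_independent_correlation(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(30, 25))
        me = pd.DataFrame(rng.normal(size=(25, 3)), columns=["M1", "M2", "M3"])
        kme = mn.module_membership(pd.DataFrame(vals), me)
        for i in range(30):
            for m in me.columns:
                expected = np.corrcoef(vals[i], me[m])[0, 1]
                assert kme.iloc[i][m] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_nan(self):
        vals = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        me = pd.DataFrame({"M1": [0.1, 0.4, 0.2, 0.9]})
        kme = mn.module_membership(vals, me)
        assert np.isnan(kme.iloc[0, 0])
        assert np.isfinite(kme.iloc[1, 0])


class TestEstimator:
    def test_sklearn_contract(self):
        est = mn.CoexpressionModules(power=6, min_module_size=20)
        params = est.get_params()
        assert params["power"] == 6
        est.set_params(merge_cut=0.2)
        assert est.merge_cut == 0.2

    def test_fit_transform_equals_eigengenes(self, small_expr):
        X = small_expr["host"].values.to_numpy().T
        est = mn.CoexpressionModules(min_module_size=40).fit(X)
        assert est.n_modules_ >= 1
        scores = est.transform(X)
        assert np.abs(scores - est.eigengenes_) .max() < 1e-8

    def test_gene_permutation_equivalent_partition(self, small_expr):
        X = small_expr["host"].values.to_numpy().T
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.shape[1])
        a = mn.CoexpressionModules(min_module_size=40).fit(X).labels_
        b = mn.CoexpressionModules(min_module_size=40).fit(X[:, perm]).labels_
        from sklearn.metrics import adjusted_rand_score

        restored = b[np.argsort(perm)]
        mask = (a > 0) | (restored > 0)
        assert adjusted_rand_score(a[mask], restored[mask]) == pytest.approx(1.0)

    def test_sample_permutation_identical_partition(self, small_expr):
        X = small_expr["host"].values.to_numpy().T
        rng = np.random.default_rng(1)
        perm = rng.permutation(X.shape[0])
        a = mn.CoexpressionModules(min_module_size=40).fit(X).labels_
        b = mn.CoexpressionModules(min_module_size=40).fit(X[perm]).labels_
        assert (a == b).all()
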