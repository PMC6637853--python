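import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import make_expression, vectors_with_correlation
from mirnetfa import (
    CoexpressionNetwork,
    DataError,
    NetworkParams,
    SyntheticConfig,
    detect_modules,
    merge_modules,
    module_eigengene,
    module_membership,
    signed_adjacency,
    simulate,
    size_factors,
    normalize,
    log_transform,
    tom_similarity,
    top_hubs,
)
from mirnetfa.wgcna import ModulePartition


class TestSignedAdjacency:
    def test_perfectly_correlated_pair_is_one(self, rng):
        x = rng.normal(size=6)
        m = make_expression([x, 2 * x + 1], layer="log2")
        a = signed_adjacency(m, beta=6)
        assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pair_is_zero(self, rng):
        x = rng.normal(size=6)
        m = make_expression([x, -x], layer="log2")
        a = signed_adjacency(m, beta=6)
        assert a.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_uncorrelated_pair_closed_form(self, rng):
        x, y = vectors_with_correlation(0.0, 10, rng)
        a = signed_adjacency(make_expression([x, y], layer="log2"), beta=6)
        assert a.iloc[0, 1] == pytest.approx(0.5**6)

    def test_symmetric_bounded_monotone(self, rng):
        m = make_expression(rng.normal(size=(20, 10)), layer="log2")
        a = signed_adjacency(m, beta=6)
        arr = a.to_numpy()
        np.testing.assert_allclose(arr, arr.T, atol=1e-12)
        assert arr.min() >= 0 and arr.max() <= 1
        r = np.corrcoef(m.values.to_numpy())
        iu = np.triu_indices(20, 1)
        order = np.argsort(r[iu])
        assert (np.diff(arr[iu][order]) >= -1e-12).all()

    def test_zero_variance_feature_listed(self, rng):
        vals = rng.normal(size=(3, 5))
        vals[1] = 7.0
        with pytest.raises(DataError, match="f1"):
            signed_adjacency(make_expression(vals, layer="log2"), beta=6)


def tom_oracle(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.eye(n)
    k = [sum(a[i, u] for u in range(n) if u != i) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestTom:
    @pytest.mark.parametrize("a", [0.2, 0.5, 0.9])
    def test_complete_graph_identity(self, a):
        n = 6
        adj = np.full((n, n), a)
        np.fill_diagonal(adj, 1.0)
        tom = tom_similarity(pd.DataFrame(adj))
        off = tom.to_numpy()[np.triu_indices(n, 1)]
        np.testing.assert_allclose(off, a, rtol=1e-12)

    def test_empty_graph_zero_overlap(self):
        adj = np.eye(5)
        tom = tom_similarity(pd.DataFrame(adj))
        assert tom.to_numpy()[np.triu_indices(5, 1)].max() == 0.0

    def test_matches_triple_loop_oracle(self, rng):
        a = rng.uniform(0, 1, size=(15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        np.testing.assert_allclose(tom, tom_oracle(a), rtol=1e-10)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12

    def test_asymmetric_rejected(self):
        a = np.eye(4)
        a[0, 1] = 0.5
        with pytest.raises(DataError, match="symmetric"):
            tom_similarity(pd.DataFrame(a))


def block_dissimilarity(sizes):
    """Perfect blocks: dissimilarity 0 within, 1 between."""
    n = sum(sizes)
    d = np.ones((n, n))
    start = 0
    for s in sizes:
        d[start : start + s, start : start + s] = 0.0
        start += s
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=[f"f{i}" for i in range(n)],
                        columns=[f"f{i}" for i in range(n)])


class TestDetectModules:
    def test_two_perfect_blocks(self):
        d = block_dissimilarity([8, 6])
        labels = detect_modules(d, NetworkParams(min_module_size=5, cut_height=0.75))
        assert set(labels) == {"module0", "module1"}
        assert (labels.iloc[:8] == "module0").all()  # larger block named first

    def test_undersized_block_goes_grey(self):
        d = block_dissimilarity([8, 4])
        labels = detect_modules(d, NetworkParams(min_module_size=5, cut_height=0.75))
        assert (labels.iloc[8:] == "grey").all()

    def test_all_grey_warns(self):
        d = block_dissimilarity([2, 2, 2])
        with pytest.warns(UserWarning, match="grey"):
            labels = detect_modules(
                d, NetworkParams(min_module_size=5, cut_height=0.75)
            )
        assert (labels == "grey").all()

    def test_partition_invariant_to_feature_order(self, rng):
        cfg = SyntheticConfig(seed=2, n_mrna=90, n_mirna=8, n_modules=3)
        mrna, _, design, _ = simulate(cfg)
        log2 = log_transform(normalize(mrna, size_factors(mrna)))
        high = log2.subset_samples(design.samples("High"))
        res1 = CoexpressionNetwork(high).fit()
        perm = rng.permutation(high.n_features)
        shuffled = high.subset_features([high.feature_ids[i] for i in perm])
        res2 = CoexpressionNetwork(shuffled).fit()
        l1 = res1.partition.module_of_feature.sort_index()
        l2 = res2.partition.module_of_feature.sort_index()
        assert adjusted_rand_score(list(l1), list(l2)) == pytest.approx(1.0)


class TestEigengene:
    def test_identical_profiles_reproduced(self, rng):
        x = rng.normal(size=8)
        m = make_expression(np.tile(x, (4, 1)), layer="log2")
        me = module_eigengene(m, m.feature_ids)
        r = np.corrcoef(me, x)[0, 1]
        assert r == pytest.approx(1.0)
        assert me.std(ddof=1) == pytest.approx(1.0)
        mm = module_membership(m, pd.DataFrame([me.to_numpy()], index=["m0"],
                                               columns=m.sample_ids))
        np.testing.assert_allclose(mm.to_numpy(), 1.0, rtol=1e-10)

    def test_sign_orientation_stable_under_global_flip(self, rng):
        vals = rng.normal(size=(5, 9))
        vals += rng.normal(size=9)  # shared component
        m = make_expression(vals, layer="log2")
        me = module_eigengene(m, m.feature_ids)
        flipped = make_expression(-vals, layer="log2")
        me_f = module_eigengene(flipped, flipped.feature_ids)
        # orientation rule: members correlate positively on average both times
        x = m.values.to_numpy()
        mean_r = np.mean([np.corrcoef(row, me)[0, 1] for row in x])
        mean_rf = np.mean([np.corrcoef(row, me_f)[0, 1] for row in -x])
        assert mean_r >= 0 and mean_rf >= 0

    def test_variance_explained_matches_eigendecomposition(self, rng):
        vals = rng.normal(size=(7, 10))
        m = make_expression(vals, layer="log2")
        me = module_eigengene(m, m.feature_ids).to_numpy()
        x = (vals - vals.mean(1, keepdims=True)) / vals.std(1, ddof=1, keepdims=True)
        # share of standardized variance captured by projecting on the ME
        r2 = np.mean(
            [np.corrcoef(row, me)[0, 1] ** 2 for row in x]
        )
        eigvals = np.linalg.eigvalsh(np.corrcoef(x))
        assert r2 == pytest.approx(eigvals[-1] / x.shape[0], rel=1e-10)
        # the ME explains at least as much as any single member profile
        for row in x:
            r2_member = np.mean([np.corrcoef(other, row)[0, 1] ** 2 for other in x])
            assert r2 >= r2_member - 1e-12

    def test_single_sample_rejected(self):
        m = make_expression([[1.0], [2.0]], layer="log2")
        with pytest.raises(DataError):
            module_eigengene(m, m.feature_ids)


class TestMergeModules:
    def _labels(self, mapping):
        return pd.Series(mapping, dtype=object)

    def test_identical_eigengenes_merge(self, rng):
        x = rng.normal(size=10)
        vals = np.vstack([np.tile(x, (4, 1)) + rng.normal(0, 1e-6, size=(4, 10)),
                          np.tile(x, (4, 1)) + rng.normal(0, 1e-6, size=(4, 10))])
        m = make_expression(vals, layer="log2")
        labels = pd.Series(["module0"] * 4 + ["module1"] * 4, index=m.feature_ids)
        merged = merge_modules(labels, m, 0.25)
        assert set(merged) == {"module0"}

    def test_orthogonal_eigengenes_never_merge(self, rng):
        x, y = vectors_with_correlation(0.0, 12, rng)
        vals = np.vstack([np.tile(x, (4, 1)), np.tile(y, (4, 1))])
        vals += rng.normal(0, 1e-6, size=vals.shape)
        m = make_expression(vals, layer="log2")
        labels = pd.Series(["module0"] * 4 + ["module1"] * 4, index=m.feature_ids)
        merged = merge_modules(labels, m, 0.25)
        assert len(set(merged)) == 2

    def test_greedy_closure_chains_three_modules(self, rng):
        """Three modules whose eigengenes are mutually highly correlated
        collapse to one module after iterative merging."""
        base = rng.normal(size=14)
        vals = []
        for k in range(3):
            profile = base + rng.normal(0, 0.25, size=14)
            vals.append(np.tile(profile, (4, 1)) + rng.normal(0, 1e-3, size=(4, 14)))
        m = make_expression(np.vstack(vals), layer="log2")
        labels = pd.Series(
            ["module0"] * 4 + ["module1"] * 4 + ["module2"] * 4, index=m.feature_ids
        )
        merged = merge_modules(labels, m, 0.25)
        assert set(merged) == {"module0"}


class TestTopHubs:
    def _partition(self, mm_values, module="module0"):
        features = [f"f{i}" for i in range(len(mm_values))]
        labels = pd.Series([module] * len(features), index=features)
        mm = pd.DataFrame({module: mm_values}, index=features)
        me = pd.DataFrame([np.zeros(4)], index=[module], columns=list("abcd"))
        return ModulePartition(labels, me, mm, NetworkParams(min_module_size=1))

    def test_takes_largest_signed_mm(self):
        part = self._partition([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        assert top_hubs(part, "module0", 5) == ["f0", "f1", "f2", "f3", "f4"]

    def test_tie_broken_lexicographically(self):
        part = self._partition([0.9, 0.5, 0.5, 0.5, 0.5, 0.5])
        hubs = top_hubs(part, "module0", 5)
        assert hubs == ["f0", "f1", "f2", "f3", "f4"]

    def test_k_larger_than_module_returns_all(self):
        part = self._partition([0.3, 0.2])
        assert top_hubs(part, "module0", 5) == ["f0", "f1"]

    def test_matches_sort_oracle(self, rng):
        mm = rng.uniform(-1, 1, size=12)
        part = self._partition(list(mm))
        oracle = [f"f{i}" for i in np.argsort(-mm, kind="stable")][:5]
        assert top_hubs(part, "module0", 5) == oracle


def test_module_recovery_on_planted_partition():
    """End-to-end module detection recovers the planted partition."""
    cfg = SyntheticConfig(seed=4, n_mrna=300, n_mirna=30, n_modules=5, noise_sd=0.3)
    mrna, _, design, truth = simulate(cfg)
    log2 = log_transform(normalize(mrna, size_factors(mrna)))
    res = CoexpressionNetwork(log2.subset_samples(design.samples("High"))).fit()
    labels = res.partition.module_of_feature
    ari = adjusted_rand_score(
        [truth.module_of_feature[f] for f in labels.index], list(labels)
    )
    assert ari >= 0.8
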