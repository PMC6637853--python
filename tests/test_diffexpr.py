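import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_expression
from mirnetfa import (
    DataError,
    GroupDesign,
    GroupDifferentialExpression,
    SyntheticConfig,
    bh_adjust,
    differential_expression,
    log_transform,
    normalize,
    simulate,
    size_factors,
)


def median_of_ratios_oracle(counts: np.ndarray) -> np.ndarray:
    """Independent, loop-based median-of-ratios reimplementation."""
    rows = [i for i in range(counts.shape[0]) if all(c > 0 for c in counts[i])]
    factors = []
    for j in range(counts.shape[1]):
        ratios = []
        for i in rows:
            geo = np.exp(np.mean([np.log(c) for c in counts[i]]))
            ratios.append(counts[i, j] / geo)
        factors.append(np.median(ratios))
    return np.array(factors)


class TestSizeFactors:
    def test_doubled_sample_closed_form(self):
        m = make_expression([[2, 4], [10, 20], [6, 12]], layer="counts")
        sf = size_factors(m)
        np.testing.assert_allclose(
            sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_identical_samples_give_unit_factors(self):
        m = make_expression([[5, 5, 5], [7, 7, 7]], layer="counts")
        np.testing.assert_allclose(size_factors(m).to_numpy(), 1.0)

    def test_matches_brute_force_oracle(self, rng):
        counts = rng.integers(0, 500, size=(50, 6)).astype(float)
        counts[:10] += 1  # guarantee some all-positive reference rows
        m = make_expression(counts, layer="counts")
        np.testing.assert_allclose(
            size_factors(m).to_numpy(), median_of_ratios_oracle(counts), rtol=1e-12
        )

    def test_matches_independent_deseq_implementation(self, rng):
        # odd number of all-positive reference rows: the independent
        # implementation interpolates the even-n median in log space, so the
        # two conventions coincide only at odd n
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        counts = rng.integers(1, 800, size=(41, 8)).astype(float)
        m = make_expression(counts, layer="counts")
        _, ref = pydeseq2.deseq2_norm(pd.DataFrame(counts.T))
        np.testing.assert_allclose(size_factors(m).to_numpy(), ref, rtol=1e-10)

    def test_no_reference_feature_is_an_error(self):
        m = make_expression([[0, 5], [5, 0]], layer="counts")
        with pytest.raises(DataError, match="all-positive"):
            size_factors(m)

    def test_wrong_layer_rejected(self):
        m = make_expression([[1.0, 2.0]], layer="log2")
        with pytest.raises(DataError, match="counts layer"):
            size_factors(m)


class TestNormalizeLog:
    def test_normalize_divides_by_factor(self):
        m = make_expression([[2, 4]], layer="counts")
        sf = pd.Series([1.0, 2.0], index=m.sample_ids)
        out = normalize(m, sf)
        np.testing.assert_allclose(out.values.to_numpy(), [[2.0, 2.0]])
        assert out.layer == "normalized"

    def test_nonpositive_factor_rejected(self):
        m = make_expression([[2, 4]], layer="counts")
        sf = pd.Series([1.0, 0.0], index=m.sample_ids)
        with pytest.raises(DataError, match="> 0"):
            normalize(m, sf)

    def test_log_of_zero_with_unit_pseudocount(self):
        m = make_expression([[0.0, 3.0]], layer="normalized")
        out = log_transform(m, 1.0)
        assert out.values.iloc[0, 0] == 0.0
        assert out.values.iloc[0, 1] == pytest.approx(2.0)
        assert out.layer == "log2"

    def test_log_transform_monotone(self, rng):
        vals = rng.uniform(0, 100, size=(5, 4))
        m = make_expression(vals, layer="normalized")
        out = log_transform(m).values.to_numpy()
        order_in = np.argsort(vals, axis=None)
        order_out = np.argsort(out, axis=None)
        np.testing.assert_array_equal(order_in, order_out)


def bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{j >= i} p_(j) * n / j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q[order[rank - 1]] = min(running, 1.0)
    return q


class TestBenjaminiHochberg:
    def test_hand_checked_example(self):
        padj = bh_adjust(np.array([0.005, 0.011, 0.02, 0.04]))
        np.testing.assert_allclose(padj, [0.02, 0.022, 0.02 * 4 / 3, 0.04], rtol=1e-12)

    def test_exhaustive_over_permutations(self):
        base = [0.001, 0.02, 0.3, 0.7, 0.049, 0.1]
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(
                bh_adjust(np.array(perm)), bh_oracle(perm), rtol=1e-12
            )

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_oracle_and_monotone_in_sorted_p(self, p):
        padj = bh_adjust(np.array(p))
        np.testing.assert_allclose(padj, bh_oracle(p), rtol=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(padj[order]) >= -1e-15).all()


class TestDifferentialExpression:
    def test_identical_means_not_significant(self, small_design):
        vals = np.tile([[1.0, 2, 3, 4, 1, 2, 3, 4]], (3, 1))
        m = make_expression(vals, layer="log2", samples=small_design.sample_ids)
        table = differential_expression(m, small_design)
        assert (table["log2fc"] == 0).all()
        assert (table["direction"] == "ns").all()

    def test_label_swap_negates_fc_keeps_p(self, rng, small_design):
        vals = rng.normal(size=(10, 8))
        m = make_expression(vals, layer="log2", samples=small_design.sample_ids)
        swapped = GroupDesign(
            small_design.table.assign(
                group=small_design.table["group"].map({"High": "Low", "Low": "High"})
            )
        )
        a = differential_expression(m, small_design)
        b = differential_expression(m, swapped)
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], rtol=1e-12)
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-12)

    def test_zero_variance_conventions(self, small_design):
        vals = np.array(
            [[1.0, 1, 1, 1, 1, 1, 1, 1],  # equal, constant -> p = 1
             [2.0, 2, 2, 2, 1, 1, 1, 1]]  # different, constant -> p = 0
        )
        m = make_expression(vals, layer="log2", samples=small_design.sample_ids)
        table = differential_expression(m, small_design)
        assert table["p"].iloc[0] == 1.0
        assert table["p"].iloc[1] == 0.0

    def test_planted_fourfold_shift_power(self):
        """A 4-fold planted shift at n = 13/15 with small noise is recovered
        at padj < 0.1 in at least 95% of seeds."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = SyntheticConfig(
                seed=seed, n_mrna=120, n_mirna=8, n_modules=4,
                module_signal_sd=0.3, noise_sd=0.1, shift_log2=2.0,
                grey_frac=0.2, regulator_ids=(),
            )
            mrna, _, design, truth = simulate(cfg)
            res = GroupDifferentialExpression(mrna, design).fit()
            sig = set(res.significant["feature_id"])
            hits += truth.shifted_features <= sig
        assert hits >= 0.95 * n_seeds

    def test_model_summary_counts(self, default_sim):
        mrna, _, design, truth = default_sim
        res = GroupDifferentialExpression(mrna, design).fit()
        s = res.summary()
        assert s["n_significant"].iloc[0] == len(res.significant)
        up = set(res.significant["feature_id"])
        assert truth.shifted_features <= up
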