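import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from peachferm import (
    cooccurrence_network,
    correlation_matrix,
    taxa_volatile_correlations,
    to_relative,
)


def _direct_pearson(x, y):
    """Independent oracle: the covariance formula written out."""
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=6)
        R, _ = correlation_matrix(np.column_stack([x, x + 0.0]))
        assert R.iat[0, 1] == pytest.approx(1.0)

    def test_negated_variable_gives_minus_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=6)
        R, _ = correlation_matrix(np.column_stack([x, -x]))
        assert R.iat[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # x=(1,2,3,4), y=(1,3,2,4): cov terms sum 4, each SS 5 -> r = 4/5
        R, P = correlation_matrix(np.array([[1, 1], [2, 3], [3, 2], [4, 4]], dtype=float))
        assert R.iat[0, 1] == pytest.approx(0.8)
        r_sp, p_sp = stats.pearsonr([1, 2, 3, 4], [1, 3, 2, 4])
        assert P.iat[0, 1] == pytest.approx(p_sp, rel=1e-10)

    def test_matches_direct_formula_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(4, 12)
            m = rng.integers(2, 6)
            X = rng.normal(size=(n, m))
            R, _ = correlation_matrix(X)
            for i in range(m):
                for j in range(i + 1, m):
                    assert R.iat[i, j] == pytest.approx(
                        _direct_pearson(X[:, i], X[:, j]), abs=1e-12)

    def test_pvalues_symmetric_and_monotone_in_r(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 5))
        R, P = correlation_matrix(X)
        np.testing.assert_allclose(P.to_numpy(), P.to_numpy().T, equal_nan=True)
        flat = [(abs(R.iat[i, j]), P.iat[i, j]) for i in range(5) for j in range(i + 1, 5)]
        flat.sort()
        ps = [p for _, p in flat]
        assert all(ps[k] >= ps[k + 1] - 1e-12 for k in range(len(ps) - 1))

    def test_zero_variance_column_flagged_not_crashed(self):
        X = np.column_stack([np.arange(6.0), np.full(6, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            R, _ = correlation_matrix(X)
        assert np.isnan(R.iat[0, 1])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            correlation_matrix(np.random.default_rng(0).normal(size=(3, 2)))

    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0.1, max_value=10), st.floats(min_value=-5, max_value=5))
    def test_pearson_invariant_under_positive_affine(self, salt, a, b):
        rng = np.random.default_rng(salt)
        X = rng.normal(size=(8, 2))
        X2 = X.copy()
        X2[:, 0] = a * X2[:, 0] + b
        R1, _ = correlation_matrix(X)
        R2, _ = correlation_matrix(X2)
        assert R1.iat[0, 1] == pytest.approx(R2.iat[0, 1], abs=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_spearman_invariant_under_monotone_transform(self, salt):
        rng = np.random.default_rng(salt)
        X = rng.normal(size=(8, 2))
        X2 = X.copy()
        X2[:, 0] = np.exp(X2[:, 0])  # strictly monotone
        R1, _ = correlation_matrix(X, method="spearman")
        R2, _ = correlation_matrix(X2, method="spearman")
        assert R1.iat[0, 1] == pytest.approx(R2.iat[0, 1], abs=1e-12)


class TestNetwork:
    def _rp(self, r):
        R = pd.DataFrame([[1.0, r], [r, 1.0]], index=list("ab"), columns=list("ab"))
        n = 18
        from peachferm.association import correlation_pvalues
        P = pd.DataFrame(correlation_pvalues(R.to_numpy(), n),
                         index=R.index, columns=R.columns)
        return R, P

    def test_below_threshold_gives_empty_network(self):
        R, P = self._rp(0.5)
        assert cooccurrence_network(R, P, 0.7, 0.01) == []

    def test_strong_edge_retained_with_sign(self):
        R, P = self._rp(0.95)
        edges = cooccurrence_network(R, P, 0.9, 0.01)
        assert len(edges) == 1 and edges[0].sign == "+"

    def test_exact_threshold_excluded(self):
        R, P = self._rp(0.9)
        assert cooccurrence_network(R, P, 0.9, 0.5) == []

    def test_invalid_threshold_rejected(self):
        R, P = self._rp(0.5)
        with pytest.raises(ValueError):
            cooccurrence_network(R, P, 1.5, 0.01)

    def test_edge_set_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 8))
        X[:, 1] = X[:, 0] + 0.1 * rng.normal(size=10)
        X[:, 2] = -X[:, 0] + 0.2 * rng.normal(size=10)
        R, P = correlation_matrix(X)

        def key(e):
            return (e.node_a, e.node_b)

        for r_lo, r_hi in [(0.3, 0.5), (0.5, 0.7), (0.7, 0.9)]:
            lo = {key(e) for e in cooccurrence_network(R, P, r_lo, 0.05)}
            hi = {key(e) for e in cooccurrence_network(R, P, r_hi, 0.05)}
            assert hi <= lo
        for p_lo, p_hi in [(1e-4, 1e-2), (1e-2, 0.1)]:
            tight = {key(e) for e in cooccurrence_network(R, P, 0.3, p_lo)}
            loose = {key(e) for e in cooccurrence_network(R, P, 0.3, p_hi)}
            assert tight <= loose


class TestTaxaVolatileBlock:
    def test_planted_association_recovered(self, screening_dataset):
        abund, volatiles, truth = screening_dataset
        R, P = taxa_volatile_correlations(abund, volatiles)
        assert R.shape == (40, 12)
        for taxon in sorted(truth.core_taxa):
            driven = truth.B.loc[taxon][truth.B.loc[taxon] != 0].index
            for compound in driven:
                assert abs(R.at[taxon, compound]) > 0.9

    def test_identical_series_correlate_perfectly(self, screening_dataset):
        abund, volatiles, _ = screening_dataset
        rel = to_relative(abund)
        from peachferm import VolatileTable
        fake = VolatileTable(
            rel.data[["taxon_00"]].rename(columns={"taxon_00": "c"}),
            pd.Series({"c": "ester"}), stage=rel.stage, replicate=rel.replicate)
        R, _ = taxa_volatile_correlations(rel, fake)
        assert R.at["taxon_00", "c"] == pytest.approx(1.0)

    def test_constant_taxon_excluded_with_warning(self):
        from peachferm import AbundanceTable, VolatileTable

        data = pd.DataFrame(
            {"const": [0.25] * 4, "up": [0.15, 0.25, 0.45, 0.55],
             "down": [0.60, 0.50, 0.30, 0.20]},
            index=["A1", "A2", "B1", "B2"])
        rel = AbundanceTable(data, pd.Series(["A", "A", "B", "B"], index=data.index),
                             pd.Series([1, 2, 1, 2], index=data.index), mode="relative")
        vol = VolatileTable(
            pd.DataFrame({"c": [1.0, 2.0, 3.0, 4.0]}, index=data.index),
            pd.Series({"c": "ester"}), stage=rel.stage, replicate=rel.replicate)
        with pytest.warns(UserWarning, match="zero-variance"):
            R, _ = taxa_volatile_correlations(rel, vol)
        assert R.loc["const"].isna().all()

    def test_mismatched_designs_rejected(self, screening_dataset, small_counts_table):
        _, volatiles, _ = screening_dataset
        with pytest.raises(ValueError):
            taxa_volatile_correlations(small_counts_table, volatiles)
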