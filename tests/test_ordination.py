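"""Scaled PCA, the outlier loop, and PC group tests.

The PCA route is cross-checked against an independent brute-force
eigen-decomposition of the scaled covariance matrix.
"""

import numpy as np
import pandas as pd
import pytest

from ampdisc import (
    OtuTable,
    SampleMetadata,
    ValidationError,
    pc_group_tests,
    pca,
    pca_counts,
    remove_outliers_and_recompute,
    scale_counts,
)

from conftest import make_table


def eigen_oracle(scaled: np.ndarray):
    """Independent PCA via eigen-decomposition of the covariance matrix."""
    cov = np.cov(scaled, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    centered = scaled - scaled.mean(axis=0)
    return eigvals, centered @ eigvecs


class TestScaleCounts:
    def test_unit_sd_column_passthrough(self):
        table = make_table([[1, 2, 3]]).select_samples(["S1", "S2", "S3"])
        scaled = scale_counts(table)
        assert np.allclose(scaled.to_numpy().ravel(), [-1, 0, 1])

    def test_constant_column_dropped_with_warning(self, caplog):
        table = make_table([[5, 5, 5], [1, 2, 3]])
        with caplog.at_level("WARNING"):
            scaled = scale_counts(table)
        assert list(scaled.columns) == ["otu2"]
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_columns_standardised(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.integers(0, 100, size=(6, 10)))
        scaled = scale_counts(table)
        assert np.allclose(scaled.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(scaled.var(axis=0, ddof=1), 1, atol=1e-12)

    def test_requires_two_samples(self):
        with pytest.raises(ValidationError):
            scale_counts(make_table([[1]]))


class TestPca:
    @pytest.mark.parametrize("shape", [(5, 3), (8, 8), (10, 10), (4, 10)])
    def test_agrees_with_eigen_oracle(self, shape):
        rng = np.random.default_rng(42)
        X = rng.normal(size=shape)
        frame = pd.DataFrame(
            X, index=[f"s{i}" for i in range(shape[0])],
            columns=[f"v{j}" for j in range(shape[1])],
        )
        result = pca(frame)
        eigvals, oracle_scores = eigen_oracle(X)
        n_comp = result.scores.shape[1]
        total = eigvals.sum()
        assert np.allclose(
            result.variance_explained, eigvals[:n_comp] / total, atol=1e-8
        )
        for j in range(n_comp):
            a = result.scores.iloc[:, j].to_numpy()
            b = oracle_scores[:, j]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_total_variance_conserved(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.integers(0, 60, size=(12, 9)))
        scaled = scale_counts(table)
        result = pca(scaled)
        cov = np.cov(scaled.to_numpy(), rowvar=False, ddof=1)
        eigvals = np.linalg.eigvalsh(cov)
        lam = result.variance_explained * eigvals.sum()
        assert np.isclose(lam.sum(), np.trace(cov), atol=1e-8)

    def test_diagonal_line_axis(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=200)
        X = np.column_stack([t, t]) + rng.normal(scale=0.01, size=(200, 2))
        result = pca(pd.DataFrame(X))
        axis = result.loadings.iloc[:, 0].to_numpy()
        target = np.array([1, 1]) / np.sqrt(2)
        assert min(np.abs(axis - target).max(), np.abs(axis + target).max()) < 0.01

    def test_scores_covariance_is_diagonal(self):
        rng = np.random.default_rng(3)
        result = pca(pd.DataFrame(rng.normal(size=(30, 5))))
        cov = np.cov(result.scores.to_numpy(), rowvar=False, ddof=1)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-10

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        result = pca(pd.DataFrame(rng.normal(size=(20, 6))))
        loadings = result.loadings.to_numpy()
        for j in range(loadings.shape[1]):
            assert loadings[np.argmax(np.abs(loadings[:, j])), j] > 0

    def test_variance_explained_monotone(self):
        rng = np.random.default_rng(5)
        result = pca(pd.DataFrame(rng.normal(size=(15, 8))))
        ve = result.variance_explained
        assert (np.diff(ve) <= 1e-12).all() and ve.sum() <= 1 + 1e-9


class TestOutlierLoop:
    def _table_with_outlier(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(20, 40, size=(12, 31))
        counts[:, 30] += 500  # one sample displaced far along the main axis
        return make_table(counts)

    def test_displaced_sample_flagged(self):
        table = self._table_with_outlier()
        result = remove_outliers_and_recompute(table, sd_multiplier=4.0)
        assert result.removed_outliers == ["S31"]
        assert result.scores.shape[0] == 30

    def test_no_outliers_equals_plain_pca(self):
        rng = np.random.default_rng(8)
        table = make_table(rng.integers(0, 50, size=(10, 20)))
        looped = remove_outliers_and_recompute(table, sd_multiplier=6.0)
        plain = pca_counts(table)
        assert looped.removed_outliers == []
        assert np.allclose(looped.scores.to_numpy(), plain.scores.to_numpy())

    def test_overzealous_threshold_stops_early(self, caplog):
        rng = np.random.default_rng(9)
        table = make_table(rng.integers(0, 50, size=(8, 6)))
        with caplog.at_level("WARNING"):
            result = remove_outliers_and_recompute(table, sd_multiplier=0.1)
        assert result.scores.shape[0] >= 3
        assert any("keeping current result" in r.message for r in caplog.records)


class TestPcGroupTests:
    def _metadata(self, sizes):
        pairs, i = [], 0
        groups = ["upper_before", "upper_after", "middle_before", "lower_after"]
        for g, n in zip(groups, sizes):
            for _ in range(n):
                i += 1
                pairs.append((f"S{i}", g))
        return SampleMetadata(pairs)

    def test_family_is_components_times_pairs(self):
        rng = np.random.default_rng(10)
        table = make_table(rng.integers(0, 80, size=(25, 20)),
                           sample_ids=[f"S{i+1}" for i in range(20)])
        meta = self._metadata([5, 5, 5, 5])
        result = pca_counts(table)
        tests = pc_group_tests(result, meta, n_components=3)
        assert len(tests) == 18  # 3 PCs x C(4,2) pairs
        finite = tests.dropna()
        assert np.allclose(
            finite["p_adjusted"], np.minimum(1.0, finite["p_raw"] * 18)
        )

    def test_identical_groups_give_t0_p1(self):
        scores = pd.DataFrame(
            {"PC1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
            index=[f"S{i+1}" for i in range(6)],
        )
        from ampdisc.ordination import OrdinationResult

        result = OrdinationResult(
            scores=scores,
            loadings=pd.DataFrame({"PC1": [1.0]}, index=["otu1"]),
            variance_explained=np.array([1.0]),
        )
        meta = self._metadata([3, 3])
        tests = pc_group_tests(result, meta, n_components=1)
        assert np.isclose(tests["t_statistic"].iloc[0], 0.0)
        assert np.isclose(tests["p_raw"].iloc[0], 1.0)

    def test_null_type_one_error_controlled(self):
        # same-distribution groups: Bonferroni-adjusted rejections stay rare
        rng = np.random.default_rng(11)
        meta = self._metadata([6, 6, 6, 6])
        n_sig, n_rep = 0, 60
        for _ in range(n_rep):
            table = make_table(rng.integers(0, 60, size=(15, 24)),
                               sample_ids=[f"S{i+1}" for i in range(24)])
            tests = pc_group_tests(pca_counts(table), meta, n_components=3)
            n_sig += int(tests["significant"].any())
        assert n_sig / n_rep <= 0.10
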