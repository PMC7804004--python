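import numpy as np
import pytest
from hypothesis import given, strategies as st

import ctnets
from ctnets import CovariateModel, ThicknessDataset, make_atlas
from ctnets.preprocess import (
    DEFAULT_GRID,
    bootstrap_indices,
    bootstrap_sample,
    correlation_matrix,
    design_matrix,
    edge_capacity,
    n_edges_at_sparsity,
    rank_edges,
    residualize,
    sparsity_grid,
    threshold_to_binary,
)


def toy_dataset(thickness, age=None, sex=None, atlas=None):
    m, n = thickness.shape
    if atlas is None:
        atlas = make_atlas(n, [n])
    rng = np.random.default_rng(0)
    return ThicknessDataset(
        thickness=thickness,
        age=age if age is not None else rng.uniform(60, 80, m),
        sex=sex if sex is not None else (np.arange(m) % 2),
        group=np.full(m, "g", dtype=object),
        atlas=atlas,
    )


class TestResidualize:
    def test_perfect_linear_fit_leaves_zero_residuals(self):
        """Thickness exactly in the design span: residuals vanish.

        Each region is a + b*age + c*sex + w*g with a shared subject
        factor g; g is recoverable from the mean-CT column, so the fit is
        exact.
        """
        rng = np.random.default_rng(1)
        m, n = 10, 4
        age = rng.uniform(55, 90, m)
        sex = np.array([0, 1] * 5)
        g = rng.standard_normal(m)
        a = rng.uniform(2.0, 2.4, n)
        b = rng.uniform(-0.01, 0.01, n)
        c = rng.uniform(-0.05, 0.05, n)
        w = rng.uniform(0.5, 1.5, n)
        thickness = a + np.outer(age, b) + np.outer(sex, c) + np.outer(g, w)
        res = residualize(toy_dataset(thickness, age=age, sex=sex))
        assert np.abs(res.values).max() < 1e-10

    def test_normal_equations_oracle(self):
        """Residuals match an explicit normal-equations solve."""
        rng = np.random.default_rng(2)
        m, n = 8, 6
        thickness = 2.2 + 0.1 * rng.standard_normal((m, n))
        d = toy_dataset(thickness)
        res = residualize(d)
        x = design_matrix(d.age, d.sex, d.thickness)
        beta = np.linalg.solve(x.T @ x, x.T @ d.thickness)
        assert np.allclose(res.values, d.thickness - x @ beta, atol=1e-9)

    def test_residuals_orthogonal_to_design(self, small_dataset):
        res = residualize(small_dataset)
        m = small_dataset.n_subjects
        gram = np.abs(res.design.T @ res.values)
        assert gram.max() < 1e-8 * m
        assert np.abs(res.values.mean(axis=0)).max() < 1e-10

    def test_single_sex_sample_names_collinear_columns(self):
        rng = np.random.default_rng(3)
        thickness = 2.2 + 0.1 * rng.standard_normal((12, 6))
        d = toy_dataset(thickness, sex=np.ones(12, dtype=int))
        with pytest.raises(ValueError) as err:
            residualize(d)
        assert "age_x_sex" in str(err.value) or "sex" in str(err.value)

    def test_requires_more_subjects_than_design_columns(self):
        rng = np.random.default_rng(4)
        thickness = 2.2 + 0.1 * rng.standard_normal((5, 4))
        with pytest.raises(ValueError, match="more than 5 subjects"):
            residualize(toy_dataset(thickness))


class TestCorrelationMatrix:
    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(5)
        col = rng.standard_normal(20)
        res = ctnets.ResidualMatrix(
            values=np.column_stack([col, col, rng.standard_normal(20)]),
            design=np.ones((20, 1)),
        )
        c = correlation_matrix(res, positive_only=False)
        assert c.r[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(c.r) == 0.0)

    def test_negation_clipped_when_positive_only(self):
        rng = np.random.default_rng(6)
        col = rng.standard_normal(20)
        res = ctnets.ResidualMatrix(
            values=np.column_stack([col, -col, rng.standard_normal(20)]),
            design=np.ones((20, 1)),
        )
        assert correlation_matrix(res, positive_only=True).r[0, 1] == 0.0
        assert correlation_matrix(res, positive_only=False).r[
            0, 1
        ] == pytest.approx(-1.0)

    def test_textbook_pearson_oracle(self):
        """Hand-coded sum formula on a 5x3 toy."""
        v = np.array(
            [[1.0, 2.0, 0.5], [2.0, 1.5, 1.0], [3.0, 3.5, -1.0],
             [4.0, 3.0, 2.0], [5.0, 5.5, 0.0]]
        )
        res = ctnets.ResidualMatrix(values=v, design=np.ones((5, 1)))
        c = correlation_matrix(res, positive_only=False).r
        m = v.shape[0]
        for i in range(3):
            for j in range(i + 1, 3):
                x, y = v[:, i], v[:, j]
                num = m * (x * y).sum() - x.sum() * y.sum()
                den = np.sqrt(m * (x**2).sum() - x.sum() ** 2) * np.sqrt(
                    m * (y**2).sum() - y.sum() ** 2
                )
                assert c[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_region_is_named(self):
        v = np.column_stack(
            [np.ones(10), np.random.default_rng(0).standard_normal(10)]
        )
        res = ctnets.ResidualMatrix(
            values=v, design=np.ones((10, 1)),
            region_names=np.array(["flat_region", "ok_region"]),
        )
        with pytest.raises(ValueError, match="flat_region"):
            correlation_matrix(res)

    def test_invariance_to_affine_rescaling(self, small_dataset):
        res = residualize(small_dataset)
        c1 = correlation_matrix(res, positive_only=False).r
        scaled = ctnets.ResidualMatrix(
            values=res.values * np.linspace(0.5, 3.0, res.values.shape[1]),
            design=res.design,
        )
        c2 = correlation_matrix(scaled, positive_only=False).r
        assert np.allclose(c1, c2, atol=1e-12)


class TestBootstrap:
    def test_deterministic_given_seed(self, small_dataset):
        b1 = bootstrap_sample(small_dataset, seed=42)
        b2 = bootstrap_sample(small_dataset, seed=42)
        assert np.array_equal(b1.thickness, b2.thickness)
        assert b1.n_subjects == small_dataset.n_subjects

    def test_unique_fraction_matches_bootstrap_theory(self):
        """At m=1000, the expected unique fraction is 1 - 1/e."""
        m = 1000
        rng = np.random.default_rng(9)
        fracs = [
            len(np.unique(bootstrap_indices(m, rng))) / m for _ in range(40)
        ]
        expected = 1 - np.exp(-1)
        se = np.sqrt(expected * (1 - expected) / m)
        assert abs(np.mean(fracs) - expected) < 3 * se

    def test_degenerate_resample_exhausts_redraws(self):
        rng = np.random.default_rng(0)
        with pytest.raises(RuntimeError, match="redraws"):
            bootstrap_indices(1, rng, min_distinct=3, max_redraws=5)


class TestThreshold:
    def test_default_grid_has_21_points(self):
        grid = sparsity_grid()
        assert len(grid) == 21
        assert grid[0] == 0.5 and grid[-1] == 0.9
        assert np.allclose(np.diff(grid), 0.02)
        assert np.array_equal(grid, DEFAULT_GRID)

    def test_exact_edge_count_across_grid(self, rng):
        n = 30
        r = np.triu(rng.uniform(0.01, 1.0, (n, n)), 1)
        r = r + r.T
        for s in sparsity_grid():
            a = threshold_to_binary(r, s)
            k = n_edges_at_sparsity(n, s)
            assert a.sum() // 2 == k
            assert np.array_equal(a, a.T)
            assert np.all(np.diag(a) == 0)

    def test_nested_edge_sets(self, rng):
        n = 25
        r = np.triu(rng.uniform(0.01, 1.0, (n, n)), 1)
        r = r + r.T
        prev = None
        for s in sparsity_grid()[::-1]:  # sparsest first
            a = threshold_to_binary(r, s)
            if prev is not None:
                assert np.all(a >= prev)  # superset as density grows
            prev = a

    def test_top_k_matches_exhaustive_sort(self):
        """6-node toy at sparsity 0.8: top-3 edges by exhaustive sorting."""
        rng = np.random.default_rng(10)
        n = 6
        r = np.triu(rng.uniform(0.01, 1.0, (n, n)), 1)
        r = r + r.T
        a = threshold_to_binary(r, 0.8)
        k = n_edges_at_sparsity(n, 0.8)
        assert k == 3
        iu, ju = np.triu_indices(n, 1)
        order = np.argsort(-r[iu, ju])[:k]
        expected = {(iu[o], ju[o]) for o in order}
        got = {tuple(e) for e in np.argwhere(np.triu(a, 1) == 1)}
        assert got == expected

    def test_noop_threshold_when_k_equals_positive_count(self):
        rng = np.random.default_rng(11)
        n = 10
        r = np.triu(rng.uniform(-1, 1, (n, n)), 1)
        r = r + r.T
        rp = np.where(r > 0, r, 0.0)
        n_pos = int((np.triu(rp, 1) > 0).sum())
        s = 1 - n_pos / edge_capacity(n)
        a = threshold_to_binary(rp, s)
        assert np.array_equal(a, (rp > 0).astype(np.uint8))

    def test_insufficient_positive_entries(self):
        r = np.zeros((10, 10))
        r[0, 1] = r[1, 0] = 0.5
        with pytest.raises(ValueError, match="achievable maximum density"):
            threshold_to_binary(r, 0.5)
        capped = threshold_to_binary(r, 0.5, on_insufficient="cap")
        assert capped.sum() // 2 == 1

    def test_tie_break_is_lexicographic(self):
        n = 5
        r = np.full((n, n), 0.5)
        np.fill_diagonal(r, 0.0)
        a = threshold_to_binary(r, 0.8)  # K = 2 of 10 tied edges
        assert [tuple(e) for e in np.argwhere(np.triu(a, 1))] == [
            (0, 1),
            (0, 2),
        ]

    @given(st.integers(min_value=0, max_value=10**6))
    def test_rank_edges_orders_descending(self, seed):
        rng = np.random.default_rng(seed)
        r = np.triu(rng.uniform(-1, 1, (8, 8)), 1)
        r = r + r.T
        i, j, w = rank_edges(r)
        assert np.all(np.diff(w) <= 1e-15)
        assert len(w) == edge_capacity(8)
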