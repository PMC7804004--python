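import networkx as nx
import numpy as np
import pytest

import ctnets
from ctnets import (
    BinaryGraph,
    CovarianceSpec,
    CovariateModel,
    compare_groups,
    connected_sparsity_bound,
    group_modularity_report,
    make_atlas,
    property_curves,
    simulate_group,
)
from ctnets.metrics import (
    characteristic_path_length,
    clustering_index,
    global_efficiency,
    local_efficiency,
)
from ctnets.preprocess import (
    correlation_matrix,
    residualize,
    sparsity_grid,
    threshold_to_binary,
)
from ctnets.stats import (
    AUCSummary,
    _bc_percentile_ci,
    auc,
    auc_summaries,
    nodal_comparison,
)


def random_positive_matrix(n, seed):
    rng = np.random.default_rng(seed)
    r = np.triu(rng.uniform(0.01, 1.0, (n, n)), 1)
    return r + r.T


class TestAUC:
    def test_constant_curve_closed_form(self):
        assert auc(np.full(21, 3.0)) == pytest.approx(60.0)

    def test_linear_curve_arithmetic_series(self):
        assert auc(np.arange(21.0)) == pytest.approx(200.0)

    def test_matches_manual_trapezoid(self, rng):
        v = rng.standard_normal(15)
        manual = sum((v[i] + v[i + 1]) / 2 for i in range(14))
        assert auc(v) == pytest.approx(manual, abs=1e-12)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError, match="2 grid points"):
            auc(np.array([1.0]))
        with pytest.raises(ValueError, match="non-finite"):
            auc(np.array([1.0, np.nan, 2.0]))


class TestCompareGroups:
    def test_degenerate_distribution(self):
        b = 500
        a = AUCSummary(values=np.full(b, 5.0), estimate=5.0)
        c = AUCSummary(values=np.full(b, 2.0), estimate=2.0)
        cmp = compare_groups(a, c)
        assert cmp.estimate == 3.0
        assert (cmp.ci_low, cmp.ci_high) == (3.0, 3.0)
        assert cmp.significant
        assert cmp.p_value == pytest.approx(2 / (b + 1))

    def test_symmetric_null_not_significant(self, rng):
        d = rng.standard_normal(1000)
        a = AUCSummary(values=d, estimate=0.0)
        c = AUCSummary(values=np.zeros(1000), estimate=0.0)
        cmp = compare_groups(a, c)
        assert not cmp.significant
        assert cmp.ci_low < 0 < cmp.ci_high
        assert cmp.p_value > 0.5

    def test_normal_interval_matches_analytic(self, rng):
        d_b = 1.0 + rng.standard_normal(2000)
        a = AUCSummary(values=d_b, estimate=1.0)
        c = AUCSummary(values=np.zeros(2000), estimate=0.0)
        cmp = compare_groups(a, c)
        sd = d_b.std()
        assert cmp.ci_low == pytest.approx(1.0 - 1.96 * sd, abs=0.01)
        assert cmp.ci_high == pytest.approx(1.0 + 1.96 * sd, abs=0.01)

    def test_true_null_rejection_rate_near_alpha(self):
        """Monte-Carlo coverage oracle: ~5% rejections under the null."""
        rng = np.random.default_rng(2024)
        b, reps = 300, 1000
        rejections = 0
        for _ in range(reps):
            d_hat = rng.normal(0.0, 1.0)
            d_b = d_hat + rng.standard_normal(b)
            cmp = compare_groups(
                d_b, np.zeros(b), estimate_a=d_hat, estimate_b=0.0
            )
            rejections += cmp.significant
        assert 0.03 <= rejections / reps <= 0.07

    def test_bc_percentile_reduces_to_percentile_when_unbiased(self, rng):
        d = np.sort(rng.standard_normal(4001))
        d_hat = float(np.median(d))
        lo, hi = _bc_percentile_ci(d, d_hat, 0.05)
        plo, phi = np.quantile(d, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=0.02)
        assert hi == pytest.approx(phi, abs=0.02)

    def test_unequal_bootstrap_counts_rejected(self):
        with pytest.raises(ValueError, match="equal bootstrap"):
            compare_groups(np.zeros(10), np.zeros(11))

    def test_small_b_warns(self):
        with pytest.warns(UserWarning, match="CI unstable"):
            compare_groups(np.zeros(50), np.zeros(50))


class TestPropertyCurves:
    def test_values_match_single_call_recomputation(self, rng):
        """Every stored value equals a direct metric call on the same
        thresholded graph (dual-route check)."""
        n = 10
        r = random_positive_matrix(n, 0)
        grid = sparsity_grid(0.5, 0.9, 0.1)
        atlas = make_atlas(n, [n])
        pc = property_curves([r], grid, atlas=atlas, attack_strategy="initial")
        for gi, s in enumerate(grid):
            a = threshold_to_binary(r, s)
            g = BinaryGraph(a)
            assert pc.curves["clustering"][0, gi] == pytest.approx(
                clustering_index(g), abs=1e-12
            )
            assert pc.curves["global_efficiency"][0, gi] == pytest.approx(
                global_efficiency(g), abs=1e-12
            )
            assert pc.curves["local_efficiency"][0, gi] == pytest.approx(
                local_efficiency(g), abs=1e-12
            )
            if a.sum() > 0:
                assert pc.curves["path_length"][0, gi] == pytest.approx(
                    characteristic_path_length(g), abs=1e-12
                )
            nxg = nx.from_numpy_array(a)
            assert pc.connected[0, gi] == nx.is_connected(nxg)

    def test_expected_shapes(self):
        n, b = 12, 4
        mats = [random_positive_matrix(n, s) for s in range(b)]
        grid = sparsity_grid(0.5, 0.9, 0.02)
        pc = property_curves(mats, grid, atlas=make_atlas(n, [n]))
        assert pc.curves["clustering"].shape == (b, 21)
        assert pc.nbc.shape == (b, 21, n)
        assert pc.weighted["global_connectivity"].shape == (b,)

    def test_dense_matrix_keeps_clustering_at_one(self):
        """A complete-graph-inducing matrix stays fully clustered until
        the threshold binds."""
        n = 8
        r = np.full((n, n), 0.9)
        np.fill_diagonal(r, 0.0)
        r += np.triu(np.arange(n * n).reshape(n, n) * 1e-6, 1)
        r = np.triu(r, 1) + np.triu(r, 1).T
        pc = property_curves([r], np.array([0.5]), atlas=make_atlas(n, [n]))
        a = threshold_to_binary(r, 0.5)
        assert pc.curves["clustering"][0, 0] == pytest.approx(
            clustering_index(BinaryGraph(a))
        )


class TestConnectedBound:
    def _curves_from_flags(self, flags, grid):
        from ctnets.stats import PropertyCurves

        return PropertyCurves(
            grid=grid,
            curves={},
            weighted={},
            nbc=None,
            connected=np.asarray(flags, dtype=bool),
        )

    def test_fully_connected_returns_grid_max(self):
        grid = sparsity_grid()
        pc = self._curves_from_flags(np.ones((5, 21)), grid)
        assert connected_sparsity_bound([pc]) == pytest.approx(0.9)

    def test_min_rule(self):
        grid = sparsity_grid()
        flags = np.ones((3, 21), dtype=bool)
        flags[1, grid > 0.74] = False  # one sample disconnects above 0.74
        pc = self._curves_from_flags(flags, grid)
        assert connected_sparsity_bound([pc]) == pytest.approx(0.74)

    def test_sample_disconnected_everywhere_is_an_error(self):
        grid = sparsity_grid()
        flags = np.ones((2, 21), dtype=bool)
        flags[0] = False
        with pytest.raises(ValueError, match="disconnected at the grid minimum"):
            connected_sparsity_bound([self._curves_from_flags(flags, grid)])

    def test_matches_bfs_connectivity_oracle(self):
        """Bound equals an exhaustive per-sample networkx check."""
        n = 16
        grid = sparsity_grid(0.5, 0.9, 0.05)
        mats = [random_positive_matrix(n, s) for s in range(12)]
        pc = property_curves(mats, grid, atlas=make_atlas(n, [n]))
        bound = connected_sparsity_bound([pc])
        per_sample = []
        for r in mats:
            ok = [
                s
                for s in grid
                if nx.is_connected(nx.from_numpy_array(threshold_to_binary(r, s)))
            ]
            per_sample.append(max(ok))
        assert bound == pytest.approx(min(per_sample))


class TestNodalComparison:
    def _curves(self, nbc, grid):
        from ctnets.stats import PropertyCurves

        nbc = np.asarray(nbc, dtype=float)
        b, g, _ = nbc.shape
        return PropertyCurves(
            grid=grid,
            curves={},
            weighted={},
            nbc=nbc,
            connected=np.ones((b, g), dtype=bool),
        )

    def test_identical_groups_find_nothing(self, rng):
        grid = sparsity_grid(0.5, 0.7, 0.05)
        nbc = rng.random((40, len(grid), 6)) + 0.5
        a = self._curves(nbc, grid)
        b = self._curves(nbc.copy(), grid)
        full = self._curves(nbc[:1], grid)
        res = nodal_comparison(a, b, full, full)
        assert np.all(res.p_value == 1.0)
        assert res.significant.sum() == 0
        assert res.sparsity_upper == pytest.approx(0.7)

    def test_bh_qvalues_match_step_up_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(37)
        _, q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        n = len(p)
        order = np.argsort(p)
        brute = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * n / (rank + 1))
            brute[i] = running
        assert np.allclose(q, brute, atol=1e-12)

    def test_bound_below_minimum_rejected(self, rng):
        grid = sparsity_grid(0.5, 0.7, 0.05)
        nbc = rng.random((10, len(grid), 4)) + 0.5
        a = self._curves(nbc, grid)
        with pytest.raises(ValueError, match="below the grid minimum"):
            nodal_comparison(a, a, self._curves(nbc[:1], grid),
                             self._curves(nbc[:1], grid), sparsity_upper=0.4)


class TestAUCSummaries:
    def test_weighted_properties_pass_through_as_scalars(self):
        n = 12
        atlas = make_atlas(n, [n])
        mats = [random_positive_matrix(n, s) for s in range(3)]
        grid = sparsity_grid(0.6, 0.9, 0.1)
        boot = property_curves(mats, grid, atlas=atlas)
        full = property_curves(mats[:1], grid, atlas=atlas)
        summ = auc_summaries(boot, full)
        iu, ju = np.triu_indices(n, 1)
        assert summ["global_connectivity"].values[1] == pytest.approx(
            mats[1][iu, ju].mean()
        )
        # binary-graph property AUC integrates over the grid index
        assert summ["clustering"].values[0] == pytest.approx(
            auc(boot.curves["clustering"][0])
        )


class TestGroupModularityReport:
    def test_two_clique_toy(self):
        n = 8
        r = np.zeros((n, n))
        for i in range(4):
            for j in range(i + 1, 4):
                r[i, j] = r[i + 4, j + 4] = 0.9
        r[3, 4] = 0.5
        r = np.triu(r, 1) + np.triu(r, 1).T
        atlas = make_atlas(n, [n])
        # keep the 13 positive edges: sparsity = 1 - 13/28
        rep = group_modularity_report(r, atlas, sparsity=1 - 13 / 28)
        assert rep.partition.n_modules == 2
        assert rep.n_components == 1

    def test_three_block_spec_recovers_three_modules(self):
        atlas = make_atlas(30, [10, 10, 10])
        spec = CovarianceSpec(
            n_regions=30,
            module_sizes=(10, 10, 10),
            rho_within=0.6,
            rho_between=0.05,
            rho_homolog=0.0,
            rho_diffuse=0.0,
        )
        cm = CovariateModel(noise_sd=0.01)
        d = simulate_group(spec, cm, 500, seed=21, atlas=atlas)
        corr = correlation_matrix(residualize(d))
        rep = group_modularity_report(corr, atlas, sparsity=0.8)
        assert rep.partition.n_modules == 3
        assert rep.lobe_composition.to_numpy().sum() == 30
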