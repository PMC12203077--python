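"""F statistics, permutation plans, p-values and pooled FDR."""

import numpy as np
import pytest
from scipy.stats import chisquare

from discde import (
    DesignSpec,
    ValidationError,
    f_statistic,
    generate_dataset,
    hat_matrix,
    make_permutation_plan,
    omnibus_f,
    permutation_fdr,
    permutation_pvalues,
    permuted_response,
    run_disc,
)


def nested_ols_f(u, Y, Z):
    """Independent oracle: F from two least-squares fits (RSS reduction)."""
    n = len(u)
    reduced = np.column_stack([np.ones(n)] + ([Z] if Z.size else []))
    full = np.column_stack([reduced, Y])
    rss = []
    for design in (reduced, full):
        beta, *_ = np.linalg.lstsq(design, u, rcond=None)
        resid = u - design @ beta
        rss.append(resid @ resid)
    p = np.atleast_2d(Y.T).shape[0] if Y.ndim > 1 else 1
    df_res = n - np.linalg.matrix_rank(full)
    return ((rss[0] - rss[1]) / p) / (rss[1] / df_res)


class TestHatMatrix:
    def test_intercept_projection(self):
        h = hat_matrix(np.ones((3, 1)))
        assert np.allclose(h, np.full((3, 3), 1 / 3))

    def test_identity_design(self):
        h = hat_matrix(np.eye(4))
        assert np.allclose(h, np.eye(4))

    def test_duplicated_columns_same_projection(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=(6, 1))
        assert np.allclose(hat_matrix(col), hat_matrix(np.hstack([col, col])))

    def test_symmetric_idempotent(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=(8, 3))
        h = hat_matrix(d)
        assert np.allclose(h, h.T, atol=1e-10)
        assert np.allclose(h @ h, h, atol=1e-8)

    def test_empty_design_zero(self):
        assert np.allclose(hat_matrix(np.empty((5, 0))), 0)


class TestFStatistic:
    def test_worked_example_f_equals_8(self):
        # nested-OLS arithmetic: RSS_reduced=5, RSS_full=1 → ((5−1)/1)/(1/2)=8
        f = f_statistic([1, 2, 3, 4], np.array([0, 0, 1, 1.0]), None)
        assert f == pytest.approx(8.0, abs=1e-10)

    def test_scale_and_shift_invariance(self):
        u = np.array([1, 2, 3, 4.0])
        y = np.array([0, 0, 1, 1.0])
        assert f_statistic(10 * u, y) == pytest.approx(8.0, abs=1e-9)
        assert f_statistic(10 * u - 3.3, y) == pytest.approx(8.0, abs=1e-9)

    def test_constant_u_gives_zero(self):
        assert f_statistic([2.0, 2, 2, 2], np.array([0, 0, 1, 1.0])) == 0.0

    def test_perfect_fit_gives_inf(self):
        # u is exactly the group indicator → zero residual, signal present
        f = f_statistic([0, 0, 1, 1.0], np.array([0, 0, 1, 1.0]))
        assert np.isinf(f)

    def test_collinear_y_identified(self):
        z = np.arange(6.0)
        with pytest.raises(ValidationError, match="collinear"):
            f_statistic(np.random.default_rng(0).normal(size=6), 2 * z, z)

    def test_oracle_equivalence_random_designs(self):
        """Hat-matrix F matches the nested-OLS RSS F on random problems."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(6, 41)
            p = rng.integers(1, 3)
            q = rng.integers(0, 3)
            Y = rng.normal(size=(n, p))
            Z = rng.normal(size=(n, q))
            u = rng.normal(size=n)
            assert f_statistic(u, Y, Z) == pytest.approx(
                nested_ols_f(u, Y, Z), rel=1e-8, abs=1e-8
            )


class TestOmnibus:
    def test_maximum(self):
        assert omnibus_f([8, 2, 0.5]) == 8

    def test_all_zero(self):
        assert omnibus_f([0.0, 0, 0]) == 0

    def test_inf_propagates(self):
        assert np.isinf(omnibus_f([3, np.inf, 1]))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            omnibus_f([])


class TestPermutationPlan:
    def test_deterministic(self):
        a = make_permutation_plan(10, 50, "plain", seed=5)
        b = make_permutation_plan(10, 50, "plain", seed=5)
        assert np.array_equal(a.perm_indices, b.perm_indices)

    def test_rows_are_permutations(self):
        plan = make_permutation_plan(7, 20, "plain", seed=1)
        for row in plan.perm_indices:
            assert sorted(row) == list(range(7))

    def test_uniform_over_group_n3(self):
        """With N=3 each of the 6 permutations appears ~1/6 of the time."""
        plan = make_permutation_plan(3, 1000, "plain", seed=11)
        codes = plan.perm_indices @ np.array([9, 3, 1])
        _, counts = np.unique(codes, return_counts=True)
        assert len(counts) == 6
        assert chisquare(counts).pvalue > 1e-4

    def test_single_row(self):
        assert make_permutation_plan(4, 1, "plain", seed=0).B == 1


class TestPermutedResponse:
    def test_plain_identity(self):
        y = np.arange(5.0)[:, None]
        out = permuted_response(y, None, np.arange(5), "plain")
        assert np.array_equal(out, y)

    def test_smith_empty_z_centers(self):
        y = np.array([1.0, 2, 3, 7])[:, None]
        out = permuted_response(y, None, np.array([2, 0, 3, 1]), "smith")
        assert out.mean() == pytest.approx(0, abs=1e-12)

    def test_smith_orthogonal_z_matches_centered_permutation(self):
        # Z orthogonal to centered Y → residualizing on Z changes nothing
        y = np.array([1.0, -1, 2, -2, 3, -3])[:, None]
        z = np.ones((6, 1)) * np.array([[1], [1], [1], [1], [1], [1.0]])
        z = np.array([1, 1, 1, 1, 1, 1.0])[:, None]  # in span of intercept
        perm = np.array([5, 3, 1, 0, 2, 4])
        out = permuted_response(y, z, perm, "smith")
        yc = y - y.mean()
        assert np.allclose(out, yc[perm])


class TestPermutationPvalues:
    def test_printed_formula(self):
        f_obs = np.array([5.0])
        f_perm = np.concatenate([np.full(4, 6.0), np.zeros(95)])[None, :]
        assert permutation_pvalues(f_obs, f_perm)[0] == pytest.approx(0.04)

    def test_extremes(self):
        obs = np.array([1.0])
        all_above = np.full((1, 99), 2.0)
        none_above = np.zeros((1, 99))
        assert permutation_pvalues(obs, all_above)[0] == pytest.approx(99 / 100)
        assert permutation_pvalues(obs, none_above)[0] == 0.0

    def test_add_one_convention(self):
        obs = np.array([1.0])
        none_above = np.zeros((1, 99))
        assert permutation_pvalues(obs, none_above, add_one=True)[0] == pytest.approx(
            1 / 100
        )


class TestPermutationFdr:
    def test_hand_enumerated_example(self):
        obs = np.array([10.0, 5.0, 1.0])
        perm = np.array([[0.5, 2.0], [6.0, 1.0], [0.2, 3.0]])
        q = permutation_fdr(obs, perm)
        assert q == pytest.approx([0.25, 0.25, 2 / 3], abs=1e-12)

    def test_input_order_restored(self):
        obs = np.array([1.0, 10.0, 5.0])
        perm = np.array([[0.2, 3.0], [0.5, 2.0], [6.0, 1.0]])
        q = permutation_fdr(obs, perm)
        assert q == pytest.approx([2 / 3, 0.25, 0.25], abs=1e-12)

    def test_pseudocount_path(self):
        # every observed statistic beats every permuted one: the pooled count
        # is 0 at each threshold, so q̃_(i) = 0.5/(i·B); the monotonicity step
        # q_(i) = min_{j≥i} q̃_(j) then propagates the smallest value upward
        obs = np.array([10.0, 9.0, 8.0])
        perm = np.full((3, 5), 1.0)
        q = permutation_fdr(obs, perm)
        b = 5
        assert q == pytest.approx([0.5 / (3 * b)] * 3)

    def test_ties_counted_with_geq(self):
        obs = np.array([2.0])
        perm = np.array([[2.0, 1.0]])  # tie at the observed value
        q = permutation_fdr(obs, perm)
        assert q[0] == pytest.approx(1 / 2)  # count 1, not pseudo-count

    def test_monotone_along_decreasing_f(self):
        rng = np.random.default_rng(9)
        obs = rng.exponential(size=50)
        perm = rng.exponential(size=(50, 20))
        q = permutation_fdr(obs, perm)
        order = np.argsort(-obs, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_capped_at_one(self):
        obs = np.zeros(4)
        perm = np.ones((4, 10))
        assert permutation_fdr(obs, perm).max() <= 1.0


@pytest.fixture(scope="module")
def small_dataset():
    ds = generate_dataset(
        n_genes=120, n_individuals=12, n_cell=40, fold=1.0, seed=77
    )
    return ds


class TestRunDisc:
    def test_deterministic_and_thread_invariant(self, small_dataset):
        ds = small_dataset
        r1 = run_disc(ds.counts, ds.design, B=29, seed=3, n_threads=1)
        r2 = run_disc(ds.counts, ds.design, B=29, seed=3, n_threads=3)
        assert np.array_equal(r1.F_omnibus, r2.F_omnibus)
        assert np.array_equal(r1.p, r2.p)
        assert np.array_equal(r1.q, r2.q)

    def test_q_ranking_depends_only_on_omnibus_f(self, small_dataset):
        """More permutations change q magnitudes, never the gene ranking."""
        ds = small_dataset
        r1 = run_disc(ds.counts, ds.design, B=19, seed=3)
        r2 = run_disc(ds.counts, ds.design, B=59, seed=4)
        by_f = np.argsort(-r1.F_omnibus, kind="stable")
        assert np.all(np.diff(r1.q[by_f]) >= -1e-15)
        assert np.all(np.diff(r2.q[by_f]) >= -1e-15)

    def test_smith_equals_plain_without_covariates(self, small_dataset):
        ds = small_dataset
        design = DesignSpec(
            Y=ds.design.Y, Z=[], individual_ids=ds.design.individual_ids
        )
        rp = run_disc(ds.counts, design, B=29, seed=5, scheme="plain")
        rs = run_disc(ds.counts, design, B=29, seed=5, scheme="smith")
        assert np.allclose(rp.F_omnibus, rs.F_omnibus)
        assert np.allclose(rp.p, rs.p)
        assert np.allclose(rp.q, rs.q)

    def test_duplicated_y_in_z_rejected(self, small_dataset):
        ds = small_dataset
        with pytest.raises(ValidationError, match="collinear"):
            DesignSpec(
                Y=ds.design.Y,
                Z=ds.design.Y.copy(),
                individual_ids=ds.design.individual_ids,
            )

    def test_null_pvalues_close_to_uniform_at_5pct(self):
        """Under an exchangeable null, P(p < 0.05) stays near 5%."""
        ds = generate_dataset(n_genes=400, n_individuals=16, n_cell=60, fold=1.0, seed=5)
        res = run_disc(ds.counts, ds.design, B=99, seed=6)
        frac = float(np.mean(res.p < 0.05))
        se = np.sqrt(0.05 * 0.95 / res.p.size)
        # features within a gene are correlated; allow a wide MC band
        assert abs(frac - 0.05) < 5 * se + 0.01

    def test_result_tsv_round_trip(self, small_dataset, tmp_path):
        ds = small_dataset
        res = run_disc(ds.counts, ds.design, B=19, seed=1)
        res.write_tsv(tmp_path / "out.tsv")
        text = (tmp_path / "out.tsv").read_text()
        assert text.startswith("# B=19")
        import pandas as pd

        df = pd.read_csv(tmp_path / "out.tsv", sep="\t", comment="#")
        assert list(df.columns[:2]) == ["gene_id", "F_zero_prop"]
        assert len(df) == ds.counts.n_genes
        assert df.p_value.between(0, 1).all() and df.q_value.between(0, 1).all()
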