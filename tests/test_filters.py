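import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spacomod import (
    SpatialWeightMatrix,
    StructuralError,
    axis_correlation,
    build_weights,
    differential_score,
    filter_genes,
    morans_i,
    select_explicit,
)
from spacomod.filters import _moran_stats

from conftest import make_spatial


def moran_naive(x, w):
    """Literal O(N^2) double-sum evaluation of the Moran's I definition."""
    x = np.asarray(x, dtype=float)
    N = x.size
    xbar = x.mean()
    W = w.sum()
    num = 0.0
    for i in range(N):
        for j in range(N):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
    return (N / W) * num / ((x - xbar) ** 2).sum()


class TestDifferentialScore:
    def test_means_by_hand(self):
        ds = make_spatial(
            [[5.0], [5.0], [0.0], [0.0]], [[i, 0] for i in range(4)]
        )
        sel = select_explicit(ds, [0, 1])
        assert differential_score(ds, sel, "g0") == pytest.approx(5.0 - 2.5)

    def test_constant_gene_scores_zero(self, srt):
        ds = make_spatial(np.full((4, 1), 3.0), [[i, 0] for i in range(4)])
        sel = select_explicit(ds, [0, 2])
        assert differential_score(ds, sel, "g0") == 0.0

    def test_selection_of_all_cells_scores_zero(self, srt, all_cells):
        for g in srt.gene_symbols[:5]:
            assert differential_score(srt, all_cells, g) == pytest.approx(0.0, abs=1e-12)


class TestBuildWeights:
    def test_colinear_knn1_by_hand(self):
        coords = [[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]]
        w = build_weights(np.array(coords), "knn", k=1)
        W = w.dense()
        # endpoints weight their inner neighbour; interior cells their left
        # neighbour by the lower-index tie-break
        assert W[0, 1] == 1 and W[3, 2] == 1
        assert w.total == 4.0
        assert np.all(np.diag(W) == 0)

    def test_knn_weights_can_be_asymmetric(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [1.5, 0.0]])
        W = build_weights(coords, "knn", k=1).dense()
        assert W[0, 1] == 1 and W[1, 2] == 1 and W[2, 1] == 1
        assert not np.array_equal(W, W.T)

    def test_inverse_distance_values(self):
        coords = np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 0.0]])
        w = build_weights(coords, "invdist", cutoff=5.0)
        W = w.dense()
        assert W[0, 1] == pytest.approx(0.5)
        assert W[0, 2] == 0.0

    def test_cutoff_below_all_distances_errors(self):
        coords = np.array([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0]])
        with pytest.raises(StructuralError, match="W = 0"):
            build_weights(coords, "invdist", cutoff=0.1)

    def test_coincident_points_under_invdist_advise_knn(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(StructuralError, match="knn"):
            build_weights(coords, "invdist", cutoff=5.0)

    def test_too_few_cells_errors(self):
        with pytest.raises(StructuralError):
            build_weights(np.zeros((2, 2)), "knn", k=1)


class TestMoransI:
    def chain_weights(self, n):
        W = np.zeros((n, n))
        for i in range(n - 1):
            W[i, i + 1] = W[i + 1, i] = 1.0
        return SpatialWeightMatrix(weights=W, scheme="chain")

    def test_alternating_chain_is_minus_one(self):
        # values (+1,-1,+1,-1) on a 4-chain: numerator -6, denominator 4,
        # N/W = 4/6 -> I = -1
        w = self.chain_weights(4)
        r = _moran_stats(np.array([1.0, -1.0, 1.0, -1.0]), w)
        assert r.I == pytest.approx(-1.0, abs=1e-12)

    def test_null_expectation_formula(self):
        w = self.chain_weights(5)
        r = _moran_stats(np.array([1.0, 2.0, 1.0, 3.0, 2.0]), w)
        assert r.expected == pytest.approx(-0.25)

    def test_constant_values_give_nan_sentinel(self):
        w = self.chain_weights(4)
        r = _moran_stats(np.full(4, 2.0), w)
        assert np.isnan(r.I) and np.isnan(r.z)

    def test_dataset_level_wrapper(self, srt):
        sel = select_explicit(srt, list(range(100)))
        w = build_weights(srt.coordinates[sel.indices], "knn", k=8)
        r = morans_i(srt, sel, "grad_x_pos_0_00", w)
        x = srt.gene_values("grad_x_pos_0_00")[sel.indices]
        assert r.I == pytest.approx(moran_naive(x, w.dense()), abs=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 40))
    def test_matches_naive_double_sum_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        W = rng.uniform(0, 1, size=(n, n)) * rng.integers(0, 2, size=(n, n))
        np.fill_diagonal(W, 0)
        W[0, 1] = 1.0  # ensure W > 0
        x = rng.normal(size=n)
        w = SpatialWeightMatrix(weights=W, scheme="random")
        assert _moran_stats(x, w).I == pytest.approx(moran_naive(x, W), abs=1e-10)

    def test_permutation_null_mean_is_exact_by_enumeration(self):
        """The mean of I over ALL value permutations equals -1/(N-1) exactly."""
        import itertools

        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 10, size=(6, 2))
        w = build_weights(coords, "knn", k=2)
        x = rng.normal(size=6)
        vals = [
            _moran_stats(np.asarray(p), w).I for p in itertools.permutations(x)
        ]
        assert np.mean(vals) == pytest.approx(-1 / 5, abs=1e-12)

    def test_invariance_to_shift_and_positive_scale(self):
        rng = np.random.default_rng(3)
        w = self.chain_weights(20)
        x = rng.normal(size=20)
        base = _moran_stats(x, w).I
        assert _moran_stats(x + 100.0, w).I == pytest.approx(base, abs=1e-10)
        assert _moran_stats(3.5 * x, w).I == pytest.approx(base, abs=1e-10)


class TestAxisCorrelation:
    def test_expression_equal_to_coordinate(self):
        coords = [[i, 0.0] for i in range(5)]
        ds = make_spatial([[float(i)] for i in range(5)], coords)
        sel = select_explicit(ds, list(range(5)))
        assert axis_correlation(ds, sel, "g0", "x") == pytest.approx(1.0)
        assert axis_correlation(ds, sel, "g0", "y") != axis_correlation(ds, sel, "g0", "x")

    def test_anticorrelated_expression(self):
        coords = [[i, 0.0] for i in range(5)]
        ds = make_spatial([[-float(i)] for i in range(5)], coords)
        sel = select_explicit(ds, list(range(5)))
        assert axis_correlation(ds, sel, "g0", "x") == pytest.approx(-1.0)

    def test_symmetric_quadratic_is_uncorrelated(self):
        xs = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        ds = make_spatial((xs**2)[:, None], np.column_stack([xs, np.zeros(5)]))
        sel = select_explicit(ds, list(range(5)))
        assert axis_correlation(ds, sel, "g0", "x") == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_is_nan(self):
        ds = make_spatial(np.full((4, 1), 2.0), [[i, 0.0] for i in range(4)])
        sel = select_explicit(ds, list(range(4)))
        assert np.isnan(axis_correlation(ds, sel, "g0", "x"))

    def test_sign_flips_when_axis_is_reflected(self, srt, all_cells):
        r = axis_correlation(srt, all_cells, "grad_x_pos_0_00", "x")
        flipped = make_spatial(
            srt.dense(), srt.coordinates * np.array([-1.0, 1.0, 1.0]),
            genes=list(srt.gene_symbols),
        )
        rf = axis_correlation(flipped, all_cells, "grad_x_pos_0_00", "x")
        assert rf == pytest.approx(-r, abs=1e-12)

    def test_missing_axis_in_2d_coords(self):
        ds = make_spatial(np.eye(3), [[i, 0.0] for i in range(3)])
        sel = select_explicit(ds, list(range(3)))
        with pytest.raises(StructuralError):
            axis_correlation(ds, sel, "g0", "z")


class TestFilterGenes:
    def test_planted_gradient_genes_are_recovered(self, srt, truth, all_cells):
        n_grad = int((truth["class"] == "gradient").sum())
        table = filter_genes(srt, all_cells, "spatial-axis", n_keep=n_grad, axis="x")
        kept = set(table.retained_genes())
        planted = set(truth.loc[truth["class"] == "gradient", "gene"])
        assert kept == planted
        # brute-force check: retained |r| exceed every noise gene's |r|
        df = table.to_dataframe()
        worst_kept = df.loc[df["retained"], "ranking_key"].min()
        best_dropped = df.loc[~df["retained"], "ranking_key"].max()
        assert worst_kept > best_dropped

    def test_differential_ranking_is_signed(self, srt):
        sel = select_explicit(
            srt, np.flatnonzero(srt.annotations["region"] == "region_0").tolist()
        )
        table = filter_genes(srt, sel, "differential", n_keep=5)
        df = table.to_dataframe()
        assert (df["score"] == df["ranking_key"]).all()
        assert df["ranking_key"].is_monotonic_decreasing

    def test_moran_ranking_uses_absolute_z(self, srt):
        sel = select_explicit(srt, list(range(150)))
        table = filter_genes(srt, sel, "moran", n_keep=10, weights_k=8)
        np.testing.assert_allclose(table.ranking_key, np.abs(table.score))

    def test_identical_scores_tie_break_by_symbol(self):
        # two duplicated genes: identical scores, symbol order decides
        xs = np.arange(6.0)
        expr = np.column_stack([xs, xs, -xs])
        ds = make_spatial(
            expr, np.column_stack([xs, np.zeros(6)]), genes=["b", "a", "c"]
        )
        sel = select_explicit(ds, list(range(6)))
        table = filter_genes(ds, sel, "spatial-axis", n_keep=2, axis="x")
        df = table.to_dataframe()
        assert list(df["gene"]) == ["a", "b", "c"]
        assert table.retained_genes() == ["a", "b"]

    def test_n_keep_above_finite_count_warns_and_keeps_all(self):
        expr = np.column_stack([np.arange(4.0), np.full(4, 2.0)])
        ds = make_spatial(expr, [[i, 0.0] for i in range(4)])
        sel = select_explicit(ds, list(range(4)))
        with pytest.warns(UserWarning, match="finite"):
            table = filter_genes(ds, sel, "spatial-axis", n_keep=5, axis="x")
        assert table.retained_genes() == ["g0"]  # constant gene excluded

    def test_zero_variance_gene_never_retained(self):
        expr = np.column_stack([np.full(4, 7.0), np.arange(4.0)])
        ds = make_spatial(expr, [[i, 0.0] for i in range(4)])
        sel = select_explicit(ds, list(range(4)))
        table = filter_genes(ds, sel, "spatial-axis", n_keep=1, axis="x")
        assert table.retained_genes() == ["g1"]

    def test_reranking_is_byte_identical(self, srt, all_cells, tmp_path):
        from spacomod.io import write_table

        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        for p in (p1, p2):
            t = filter_genes(srt, all_cells, "spatial-axis", n_keep=10, axis="x")
            write_table(t.to_dataframe(), p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_significance_guideline_on_random_data(self):
        """~5% of spatially random genes exceed |Z| > 1.96."""
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, size=(100, 2))
        w = build_weights(coords, "knn", k=15)
        zs = np.array(
            [_moran_stats(rng.normal(size=100), w).z for _ in range(500)]
        )
        frac = float((np.abs(zs) > 1.96).mean())
        assert abs(frac - 0.05) <= 0.02
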