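import numpy as np
import pandas as pd
import pytest

import revokit as rk
from revokit.predictors import all_eigenvalues


def correlated_pair(r: float, n: int = 40, seed: int = 0) -> pd.DataFrame:
    """A, B standardized with Pearson correlation exactly r; C independent."""
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n, 3))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    z1, z2, z3 = q[:, 0], q[:, 1], q[:, 2]  # exactly orthonormal, mean ~0
    a = z1
    b = r * z1 + np.sqrt(1 - r**2) * z2
    return pd.DataFrame({"A": a, "B": b, "C": z3})


class TestCorrelationGroups:
    def test_perfectly_correlated_pair_always_groups(self):
        env = correlated_pair(1.0)[["A", "B"]]
        (part,) = rk.correlation_groups(env, [0.0])
        assert part == [["A", "B"]]

    def test_uncorrelated_pair_splits_at_half(self):
        env = correlated_pair(0.0)[["A", "B"]]
        (part,) = rk.correlation_groups(env, [0.5])
        assert part == [["A"], ["B"]]

    def test_duplicate_plus_independent_partition(self):
        env = correlated_pair(1.0)
        (part,) = rk.correlation_groups(env, [0.2])
        assert part == [["A", "B"], ["C"]]

    def test_zero_variance_predictor_rejected(self):
        env = pd.DataFrame({"A": [1.0, 2, 3], "B": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="B"):
            rk.correlation_groups(env, [0.5])


class TestCollinearityIndex:
    def test_perfect_pair_scores_two(self):
        env = correlated_pair(1.0)
        res = rk.collinearity_index(env, [["A", "B"], ["C"]])
        assert res.index_value == pytest.approx(2.0, abs=1e-10)

    def test_independent_pair_scores_half(self):
        env = correlated_pair(0.0)
        res = rk.collinearity_index(env, [["A", "B"], ["C"]])
        assert res.index_value == pytest.approx(0.5, abs=1e-10)

    def test_all_singletons_score_zero(self):
        env = correlated_pair(0.3)
        res = rk.collinearity_index(env, [["A"], ["B"], ["C"]])
        assert res.index_value == 0.0
        assert res.ss_pc1_per_group == {}

    @pytest.mark.parametrize("r", [0.0, 0.5, 1.0])
    def test_two_member_group_follows_closed_form(self, r):
        env = correlated_pair(r)
        res = rk.collinearity_index(env, [["A", "B"], ["C"]])
        assert res.index_value == pytest.approx((1 + r) / (2 - r), abs=1e-10)

    def test_non_partition_rejected(self):
        env = correlated_pair(0.5)
        with pytest.raises(ValueError, match="partition"):
            rk.collinearity_index(env, [["A", "B"]])


class TestSyntheticPredictors:
    def test_duplicated_member_gives_pc1_proportional_to_it(self):
        env = correlated_pair(1.0)
        table = rk.synthetic_predictors(env, [["A", "B"], ["C"]])
        za = (env["A"] - env["A"].mean()) / env["A"].std()
        corr = np.corrcoef(table.scores["A+B"], za)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)
        assert table.explained_variance["A+B"] == pytest.approx(1.0)

    def test_singleton_passes_through_standardized(self):
        env = correlated_pair(0.4)
        table = rk.synthetic_predictors(env, [["A", "B"], ["C"]])
        zc = (env["C"] - env["C"].mean()) / env["C"].std()
        assert np.allclose(table.scores["C"], zc)

    def test_sign_convention_and_flip_symmetry(self):
        env = correlated_pair(0.8)
        table = rk.synthetic_predictors(env, [["A", "B"], ["C"]])
        assert table.loadings["A+B"]["A"] >= 0
        flipped = rk.synthetic_predictors(-env, [["A", "B"], ["C"]])
        assert np.allclose(flipped.scores["A+B"], -table.scores["A+B"])
        assert flipped.explained_variance["A+B"] == pytest.approx(
            table.explained_variance["A+B"])


class TestVifPrune:
    def test_orthogonal_predictors_all_retained_with_unit_vif(self):
        env = correlated_pair(0.0)
        retained, table = rk.vif_prune(env)
        assert retained == ["A", "B", "C"]
        assert np.allclose(table.iloc[0].to_numpy(), 1.0)

    def test_exact_duplicate_removed_by_alphabetical_tie_break(self):
        env = correlated_pair(1.0)
        retained, table = rk.vif_prune(env)
        assert retained == ["A", "C"]
        assert np.isinf(table.iloc[0]["A"]) and np.isinf(table.iloc[0]["B"])

    def test_retained_vifs_verified_by_independent_regression(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        base = rng.standard_normal((60, 3))
        env = pd.DataFrame({
            "A": base[:, 0],
            "B": base[:, 0] * 0.97 + 0.1 * base[:, 1],
            "C": base[:, 1],
            "D": base[:, 2],
            "E": base[:, 0] + base[:, 1] + 0.2 * base[:, 2],
        })
        retained, _ = rk.vif_prune(env, threshold=5.0)
        assert len(retained) >= 2
        for name in retained:
            others = [c for c in retained if c != name]
            fit = sm.OLS(env[name],
                         sm.add_constant(env[others])).fit()
            assert 1.0 / (1.0 - fit.rsquared) <= 5.0

    def test_column_order_invariance(self):
        env = correlated_pair(0.9, seed=5)
        a, _ = rk.vif_prune(env, threshold=1.5)
        b, _ = rk.vif_prune(env[["C", "B", "A"]], threshold=1.5)
        assert sorted(a) == sorted(b)


class TestPearsonPrune:
    def test_identity_when_below_threshold(self):
        env = correlated_pair(0.5)
        assert rk.pearson_prune(env, r_max=0.8) == ["A", "B", "C"]

    def test_duplicate_resolved_and_no_high_pairs_remain(self):
        env = correlated_pair(1.0)
        retained = rk.pearson_prune(env, r_max=0.8)
        assert "C" in retained and len(retained) == 2
        r = np.corrcoef(env[retained].to_numpy(), rowvar=False)
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                assert abs(r[i, j]) <= 0.8

    def test_rmax_one_is_identity(self):
        env = correlated_pair(0.99)
        assert rk.pearson_prune(env, r_max=1.0) == ["A", "B", "C"]


class TestPcnm:
    @pytest.fixture
    def unit_square(self):
        return pd.DataFrame({"x": [0, 1, 0, 1], "y": [0, 0, 1, 1]},
                            index=list("abcd"))

    def test_unit_square_spectrum(self, unit_square):
        eigs = all_eigenvalues(unit_square)
        assert np.allclose(eigs, [8.0, 8.0, 0.0, -7.0], atol=1e-9)

    def test_unit_square_positive_axes_and_half_selection(self, unit_square):
        basis = rk.pcnm_vectors(unit_square)
        assert basis.n_positive == 2
        assert basis.select_half().shape == (4, 1)
        assert basis.truncation_threshold == pytest.approx(1.0)

    def test_eigenvectors_orthonormal(self):
        rng = np.random.default_rng(8)
        coords = pd.DataFrame(rng.uniform(0, 10, size=(15, 2)),
                              columns=["x", "y"])
        basis = rk.pcnm_vectors(coords)
        v = basis.eigenvectors.to_numpy()
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)

    def test_equally_spaced_line_needs_no_replacement(self):
        # spacing == MST max edge == t, so no distance exceeds t... except
        # the long chords; verify against the direct 4t-substituted oracle
        coords = pd.DataFrame({"x": np.arange(6, dtype=float),
                               "y": np.zeros(6)})
        basis = rk.pcnm_vectors(coords)
        assert basis.truncation_threshold == pytest.approx(1.0)
        from scipy.spatial.distance import pdist, squareform
        dm = squareform(pdist(coords.to_numpy()))
        dmod = np.where(dm > 1.0, 4.0, dm)
        n = len(dm)
        h = np.eye(n) - np.full((n, n), 1 / n)
        b = h @ (-0.5 * dmod**2) @ h
        expected = np.sort(np.linalg.eigvalsh(b))[::-1]
        got = all_eigenvalues(coords)
        assert np.allclose(got, expected, atol=1e-9)

    def test_eigenvalue_sum_matches_trace(self):
        rng = np.random.default_rng(9)
        coords = pd.DataFrame(rng.uniform(0, 5, size=(12, 2)),
                              columns=["x", "y"])
        eigs = all_eigenvalues(coords)
        from scipy.sparse.csgraph import minimum_spanning_tree
        from scipy.spatial.distance import pdist, squareform
        dm = squareform(pdist(coords.to_numpy()))
        t = minimum_spanning_tree(dm).toarray().max()
        dmod = np.where(dm > t, 4 * t, dm)
        n = len(dm)
        h = np.eye(n) - np.full((n, n), 1 / n)
        b = h @ (-0.5 * dmod**2) @ h
        assert eigs.sum() == pytest.approx(np.trace(b), abs=1e-8)

    def test_duplicate_coordinates_rejected(self):
        coords = pd.DataFrame({"x": [0, 0, 1], "y": [0, 0, 1]})
        with pytest.raises(ValueError, match="duplicate"):
            rk.pcnm_vectors(coords)
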