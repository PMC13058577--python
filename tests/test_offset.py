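import numpy as np
import pandas as pd
import pytest
from scipy import stats

import revokit as rk
from revokit.turnover import CumulativeCurve, TurnoverResults


def permutation_friedman_p(data: np.ndarray, n_perm: int, seed: int) -> float:
    """Brute-force permutation null for the tie-corrected Friedman statistic."""
    def statistic(d):
        r = np.apply_along_axis(stats.rankdata, 1, d)
        n, k = d.shape
        rj = r.sum(axis=0)
        a1 = (r**2).sum()
        c1 = n * k * (k + 1) ** 2 / 4
        if a1 <= c1:
            return 0.0
        return (k - 1) * ((rj - n * (k + 1) / 2) ** 2).sum() / (a1 - c1)

    rng = np.random.default_rng(seed)
    obs = statistic(data)
    hits = 0
    for _ in range(n_perm):
        perm = np.array([rng.permutation(row) for row in data])
        if statistic(perm) >= obs - 1e-12:
            hits += 1
    return hits / n_perm


class TestGeneticOffset:
    def test_identical_climates_give_zero_offset(self):
        results = rk.identity_results(["a", "b"])
        env = pd.DataFrame({"a": [0.1, 0.5], "b": [0.3, 0.9]})
        surf = rk.genetic_offset(results, env, env.copy())
        assert np.allclose(surf.offsets.to_numpy(), 0.0)

    def test_identity_model_recovers_euclidean_distance(self):
        results = rk.identity_results(["a", "b"])
        now = pd.DataFrame({"a": [0.2], "b": [0.1]})
        fut = pd.DataFrame({"a": [0.5], "b": [0.5]})  # deltas 0.3, 0.4
        surf = rk.genetic_offset(results, now, fut)
        assert surf.offsets.iloc[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_single_predictor_identity(self):
        results = rk.identity_results(["a"])
        now = pd.DataFrame({"a": [0.2]})
        fut = pd.DataFrame({"a": [0.5]})
        surf = rk.genetic_offset(results, now, fut)
        assert surf.offsets.iloc[0, 0] == pytest.approx(0.3, abs=1e-12)

    def test_misaligned_units_rejected(self):
        results = rk.identity_results(["a"])
        now = pd.DataFrame({"a": [0.2, 0.3]}, index=["u1", "u2"])
        fut = pd.DataFrame({"a": [0.2, 0.3]}, index=["u2", "u1"])
        with pytest.raises(ValueError, match="unit ids"):
            rk.genetic_offset(results, now, fut)

    def test_spatial_predictors_contribute_zero(self, fitted_cline_model):
        results, _, env, _ = fitted_cline_model
        spatial_results = TurnoverResults(
            curves=results.curves, importance=results.importance,
            r2=results.r2, n_contributing=results.n_contributing,
            spatial=["Z"], config=results.config)
        fut = env.drop(columns=["Z"]) + 0.05
        surf = rk.genetic_offset(spatial_results, env, fut)
        manual, _ = results.transform(env, predictors=["X", "Y"])
        manual_fut, _ = results.transform(fut, predictors=["X", "Y"])
        expected = np.sqrt(
            ((manual_fut.to_numpy() - manual.to_numpy()) ** 2).sum(axis=1))
        assert np.allclose(surf.offsets.iloc[:, 0].to_numpy(), expected)

    def test_offset_is_a_metric_on_random_triples(self):
        results = rk.identity_results(["a", "b", "c"])
        rng = np.random.default_rng(4)
        for _ in range(25):
            x, y, z = (pd.DataFrame(rng.uniform(size=(1, 3)),
                                    columns=["a", "b", "c"])
                       for _ in range(3))
            d = lambda u, v: rk.genetic_offset(results, u, v).offsets.iloc[0, 0]
            assert d(x, y) == pytest.approx(d(y, x), abs=1e-12)
            assert d(x, z) <= d(x, y) + d(y, z) + 1e-12

    def test_affine_reparameterization_leaves_offsets_unchanged(self):
        # rescaling predictor units with correspondingly remapped knots
        x = np.linspace(0, 1, 11)
        y = np.linspace(0, 0.3, 11)
        base = TurnoverResults(
            curves={"a": CumulativeCurve(x=x, y=y, x_min=0, x_max=1,
                                         kind="step")},
            importance=pd.Series({"a": 0.3}), r2=pd.Series(dtype=float),
            n_contributing=0)
        scale, shift = 7.0, -3.0
        remapped = TurnoverResults(
            curves={"a": CumulativeCurve(x=scale * x + shift, y=y,
                                         x_min=shift, x_max=scale + shift,
                                         kind="step")},
            importance=pd.Series({"a": 0.3}), r2=pd.Series(dtype=float),
            n_contributing=0)
        now = pd.DataFrame({"a": [0.15, 0.62]})
        fut = pd.DataFrame({"a": [0.48, 0.91]})
        o1 = rk.genetic_offset(base, now, fut).offsets
        o2 = rk.genetic_offset(remapped, scale * now + shift,
                               scale * fut + shift).offsets
        assert np.allclose(o1.to_numpy(), o2.to_numpy())


class TestOffsetSeries:
    def test_first_slice_equal_to_baseline_is_zero(self):
        results = rk.identity_results(["a"])
        env = pd.DataFrame({"a": [0.2, 0.6]})
        surf = rk.offset_series(results, env,
                                {"p1": env.copy(),
                                 "p2": env + 0.1})
        assert np.allclose(surf.offsets["p1"], 0.0)
        assert np.allclose(surf.offsets["p2"], 0.1)

    def test_monotone_trend_gives_nondecreasing_offsets(self,
                                                        fitted_cline_model):
        results, _, env, _ = fitted_cline_model
        slices = {f"p{k}": env + 0.06 * k for k in range(1, 5)}
        surf = rk.offset_series(results, env, slices)
        vals = surf.offsets.to_numpy()
        assert np.all(np.diff(vals, axis=1) >= -1e-12)

    def test_reordering_slices_reorders_columns_only(self):
        results = rk.identity_results(["a"])
        env = pd.DataFrame({"a": [0.2, 0.6]})
        s1 = rk.offset_series(results, env, {"p1": env + 0.1,
                                             "p2": env + 0.2})
        s2 = rk.offset_series(results, env, {"p2": env + 0.2,
                                             "p1": env + 0.1})
        pd.testing.assert_frame_equal(
            s1.offsets, s2.offsets[["p1", "p2"]])

    def test_slice_missing_predictor_is_named(self):
        results = rk.identity_results(["a", "b"])
        env = pd.DataFrame({"a": [0.2], "b": [0.3]})
        with pytest.raises(ValueError, match=r"p2.*\['b'\]"):
            rk.offset_series(results, env,
                             {"p1": env.copy(),
                              "p2": env[["a"]]})


class TestFriedmanConover:
    def test_identical_columns_give_zero_statistic(self):
        offsets = pd.DataFrame({"s1": [1.0, 2, 3], "s2": [1.0, 2, 3]})
        res = rk.friedman_conover(offsets)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0
        assert res.conover is None and "tied" in res.note

    def test_perfect_concordance_matches_closed_form_and_permutation(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 2, 10)
        offsets = pd.DataFrame({"A": base, "B": base + 1, "C": base + 2})
        res = rk.friedman_conover(offsets)
        # tie-free perfectly concordant rankings: statistic = n(k-1) = 20
        assert res.statistic == pytest.approx(20.0)
        p_perm = permutation_friedman_p(offsets.to_numpy(), 2000, seed=1)
        assert p_perm <= 0.01 and res.pvalue < 0.01

    def test_statistic_matches_scipy_on_untied_data(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.normal(size=(12, 4)),
                            columns=list("ABCD"))
        res = rk.friedman_conover(data)
        ref = stats.friedmanchisquare(*[data[c] for c in data.columns])
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_identical_pair_not_significant_in_posthoc(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=8)
        offsets = pd.DataFrame({"A": a, "B": a, "C": a + 2.0})
        res = rk.friedman_conover(offsets)
        assert res.conover.loc["A", "B"] >= 0.05

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rk.friedman_conover(pd.DataFrame({"A": [1.0, 2.0]}))
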