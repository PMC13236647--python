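import numpy as np
import pandas as pd
import pytest

from greenmood.explain import (
    DominantFactorMap,
    ShapleyAttribution,
    exact_shapley,
    global_importance,
    local_dominant_factors,
    local_effect_surface,
    partial_dependence,
    sampled_shapley,
    shapley_matrix,
    threshold_estimate,
)
from greenmood.models import ForestParams, GWRFModel, ModelFrame, fit_gwrf


def _linear_model(beta, intercept=0.0):
    beta = np.asarray(beta, dtype=float)
    return lambda X: intercept + np.asarray(X, dtype=float) @ beta


def test_exact_shapley_linear_analytic():
    rng = np.random.default_rng(0)
    beta = np.array([2.0, -1.0, 0.5, 0.0, 3.0])
    bg = rng.normal(size=(20, 5))
    x = rng.normal(size=5)
    phi = exact_shapley(_linear_model(beta, 1.0), x, bg)
    assert np.allclose(phi, beta * (x - bg.mean(axis=0)), atol=1e-10)


def test_exact_shapley_null_player_and_efficiency():
    rng = np.random.default_rng(1)
    bg = rng.normal(size=(10, 4))
    x = rng.normal(size=4)

    def model(X):
        X = np.asarray(X)
        return X[:, 0] ** 2 + np.sin(X[:, 1]) + X[:, 0] * X[:, 2]

    phi = exact_shapley(model, x, bg)
    assert phi[3] == pytest.approx(0.0, abs=1e-12)  # unused factor
    baseline = float(model(bg).mean())
    assert phi.sum() == pytest.approx(float(model(x[None, :])[0]) - baseline,
                                      abs=1e-10)


def test_exact_shapley_symmetry():
    rng = np.random.default_rng(2)
    bg = rng.normal(size=(8, 3))
    bg[:, 1] = bg[:, 0]  # interchangeable background columns

    def model(X):
        X = np.asarray(X)
        return X[:, 0] + X[:, 1] + X[:, 0] * X[:, 1]

    x = np.array([0.7, 0.7, -0.2])
    phi = exact_shapley(model, x, bg)
    assert phi[0] == pytest.approx(phi[1], abs=1e-12)


def test_exact_shapley_factor_limit():
    with pytest.raises(ValueError):
        exact_shapley(lambda X: np.zeros(len(X)), np.zeros(17), np.zeros((2, 17)))
    with pytest.raises(ValueError):
        exact_shapley(lambda X: np.zeros(len(X)), np.zeros(3), np.empty((0, 3)))


def test_sampled_within_three_se_of_exact():
    rng = np.random.default_rng(3)
    bg = rng.normal(size=(12, 5))
    x = rng.normal(size=5)

    def model(X):
        X = np.asarray(X)
        return X[:, 0] * X[:, 1] + np.abs(X[:, 2]) - 0.5 * X[:, 3] + 0.1 * X[:, 4] ** 3

    exact = exact_shapley(model, x, bg)
    phi, se = sampled_shapley(model, x, bg, n_samples=400, seed=4)
    assert np.all(np.abs(phi - exact) <= 3.0 * se + 1e-12)
    with pytest.raises(ValueError):
        sampled_shapley(model, x, bg, n_samples=50)


def test_sampled_efficiency_is_exact():
    rng = np.random.default_rng(5)
    bg = rng.normal(size=(6, 4))
    x = rng.normal(size=4)

    def model(X):
        X = np.asarray(X)
        return np.exp(0.3 * X[:, 0]) + X[:, 1] * X[:, 2] - X[:, 3]

    phi, _ = sampled_shapley(model, x, bg, n_samples=100, seed=6)
    baseline = float(model(bg).mean())
    assert phi.sum() == pytest.approx(float(model(x[None, :])[0]) - baseline,
                                      abs=1e-10)


def test_shapley_matrix_linear_exactness_and_determinism():
    rng = np.random.default_rng(7)
    beta = np.array([1.0, -2.0, 0.3])
    bg = rng.normal(size=(9, 3))
    X = rng.normal(size=(5, 3))
    model = _linear_model(beta)
    phi = shapley_matrix(model, X, bg, n_samples=16, seed=8)
    assert np.allclose(phi, beta[None, :] * (X - bg.mean(axis=0)), atol=1e-10)
    again = shapley_matrix(model, X, bg, n_samples=16, seed=8)
    assert np.array_equal(phi, again)


def _attr(phi_values, factors):
    phi = pd.DataFrame(phi_values, columns=factors)
    return ShapleyAttribution(
        phi=phi, baseline=0.0, background=np.zeros((1, len(factors))),
        method="exact",
    )


def test_global_importance_ranks_and_tie_break():
    attr = _attr([[1.0, -1.0, 0.2], [-1.0, 1.0, 0.1]], ["a", "b", "c"])
    ranking = global_importance(attr, factor_order=["b", "a", "c"])
    # a and b tie on mean |phi|; configured order puts b first
    assert ranking.ranked_factors == ["b", "a", "c"]
    assert sorted(ranking.table["rank"].tolist()) == [1, 2, 3]
    with pytest.raises(ValueError):
        global_importance(_attr(np.empty((0, 2)), ["a", "b"]))


def test_global_importance_row_order_invariance():
    phi = [[1.0, 0.5, 0.2], [0.3, 0.9, 0.1], [0.2, 0.1, 0.8]]
    r1 = global_importance(_attr(phi, ["a", "b", "c"]))
    r2 = global_importance(_attr(phi[::-1], ["a", "b", "c"]))
    assert r1.ranked_factors == r2.ranked_factors


def test_partial_dependence_flat_and_identity():
    rng = np.random.default_rng(9)
    X = pd.DataFrame({"a": rng.uniform(0, 1, 30), "b": rng.uniform(0, 1, 30)})
    flat = partial_dependence(lambda M: np.asarray(M)[:, 0] * 0.0 + 2.0, X, "b")
    assert np.allclose(flat.mean, 2.0)
    assert np.allclose(flat.band, 0.0)
    ident = partial_dependence(lambda M: np.asarray(M)[:, 1], X, "b")
    assert np.allclose(ident.mean, ident.grid)


def test_partial_dependence_constant_factor_warns():
    X = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
    with pytest.warns(UserWarning, match="constant"):
        curve = partial_dependence(lambda M: np.asarray(M)[:, 0], X, "a")
    assert len(curve.grid) == 1
    with pytest.raises(ValueError):
        partial_dependence(lambda M: np.zeros(len(M)), X, "zzz")


def test_threshold_estimate_valley_and_peak():
    from greenmood.explain import PdpCurve

    grid = np.linspace(0.0, 1.0, 11)
    valley = PdpCurve("f", grid, (grid - 0.4) ** 2, np.zeros(11))
    peak = PdpCurve("f", grid, -((grid - 0.7) ** 2), np.zeros(11))
    assert threshold_estimate(valley, "valley") == pytest.approx(0.4)
    assert threshold_estimate(peak, "peak") == pytest.approx(0.7)
    with pytest.raises(ValueError):
        threshold_estimate(valley, "plateau")


def test_local_effect_surface_linear_positive(toy_gwrf, toy_linear_frame):
    eff = local_effect_surface(toy_gwrf, toy_linear_frame, "a")
    assert (eff["flag"] == "ok").all()
    assert (eff["slope"] > 0).all()
    with pytest.raises(ValueError):
        local_effect_surface(toy_gwrf, toy_linear_frame, "zzz")


def test_local_effect_surface_attenuates_with_noise():
    rng = np.random.default_rng(0)
    n = 60
    coords = rng.uniform(0, 1000, size=(n, 2))
    X = pd.DataFrame(
        {
            "a": rng.uniform(0, 1, n),
            "b": rng.uniform(0, 1, n),
            "c": rng.uniform(0, 1, n),
        }
    )
    signal = 0.3 * X["a"].to_numpy()
    slopes = {}
    for sd in (0.0, 1.0):
        y = 1.0 + signal + rng.normal(0, sd, n)
        fr = ModelFrame(X=X, y=y, coords=coords)
        g = fit_gwrf(fr, 40, params=ForestParams(n_trees=30), seed=1,
                     collect_oob=False)
        slopes[sd] = float(local_effect_surface(g, fr, "a")["slope"].mean())
    assert 0.0 < slopes[1.0] < slopes[0.0]


def test_local_effect_surface_flags_constant_factor(toy_linear_frame):
    X = toy_linear_frame.X.copy()
    X["c"] = 0.5
    fr = ModelFrame(X=X, y=toy_linear_frame.y, coords=toy_linear_frame.coords)
    g = fit_gwrf(fr, 40, params=ForestParams(n_trees=10), seed=1, collect_oob=False)
    eff = local_effect_surface(g, fr, "c")
    assert (eff["flag"] == "constant").all()
    assert eff["slope"].isna().all()


def test_local_dominant_factors_toy(toy_gwrf, toy_linear_frame):
    dom = local_dominant_factors(
        toy_gwrf, toy_linear_frame, background_size=8, obs_per_community=4,
        n_samples=32, seed=2,
    )
    assert isinstance(dom, DominantFactorMap)
    assert dom.shares.sum() == pytest.approx(100.0)
    assert (dom.dominant == "a").mean() >= 0.9  # the only generating factor
    again = local_dominant_factors(
        toy_gwrf, toy_linear_frame, background_size=8, obs_per_community=4,
        n_samples=32, seed=2,
    )
    assert dom.dominant.equals(again.dominant)


def test_local_dominant_factors_rejects_unfitted():
    empty = GWRFModel(
        forests=[], neighbors=[], kernel_weights=[], bandwidth=0,
        bandwidth_dist=np.empty(0), kernel="uniform", coords=np.empty((0, 2)),
        factor_names=[], params=ForestParams(), seed=0,
    )
    frame = None
    with pytest.raises(ValueError):
        local_dominant_factors(empty, frame)
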