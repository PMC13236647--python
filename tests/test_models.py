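import numpy as np
import pandas as pd
import pytest

from greenmood.models import (
    ForestParams,
    ModelFrame,
    compare_models,
    evaluate,
    fit_global_rf,
    fit_gwr,
    fit_gwrf,
    select_bandwidth,
    spatial_folds,
)


def test_evaluate_hand_example():
    m = evaluate(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
    assert m.r2 == pytest.approx(0.5)
    assert m.mae == pytest.approx(1.0 / 3.0)
    assert m.rmse == pytest.approx(np.sqrt(1.0 / 3.0))


def test_evaluate_error_contracts():
    with pytest.raises(ValueError):
        evaluate(np.ones(3), np.ones(3))  # zero variance
    with pytest.raises(ValueError):
        evaluate(np.arange(3.0), np.arange(4.0))
    with pytest.raises(ValueError):
        evaluate(np.array([1.0]), np.array([1.0]))


def _frame(n=40, p=3, seed=0, noise=0.0, beta=None, intercept=1.5):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 100, size=(n, 2))
    X = pd.DataFrame(
        rng.uniform(0, 1, size=(n, p)), columns=[f"f{j}" for j in range(p)]
    )
    beta = np.asarray(beta if beta is not None else [2.0, -1.0, 0.5][:p])
    y = intercept + X.to_numpy() @ beta + rng.normal(0, noise, n)
    return ModelFrame(X=X, y=y, coords=coords), beta, intercept


def test_model_frame_names_missing_communities():
    frame, _, _ = _frame()
    X = frame.X.copy()
    X.index = [f"c{i}" for i in range(len(X))]
    X.loc["c3", "f1"] = np.nan
    with pytest.raises(ValueError, match="c3"):
        ModelFrame(X=X, y=frame.y, coords=frame.coords)


def test_model_frame_minimum_size_and_roundtrip():
    frame, _, _ = _frame(n=40)
    with pytest.raises(ValueError):
        _frame(n=7)
    tbl = frame.X.copy()
    tbl["y"] = frame.y
    tbl["coord_x"] = frame.coords[:, 0]
    tbl["coord_y"] = frame.coords[:, 1]
    back = ModelFrame.from_table(tbl, season="spring")
    assert back.factor_names == frame.factor_names
    assert np.allclose(back.y, frame.y)
    assert back.season == "spring"


def test_gwr_recovers_exact_linear_model():
    frame, beta, intercept = _frame(n=50, noise=0.0)
    model = fit_gwr(frame, bandwidth=30)
    expected = np.concatenate([[intercept], beta])
    assert np.allclose(model.coefs, expected[None, :], atol=1e-8)
    pred = model.predict(frame.X.to_numpy(), frame.coords)
    assert np.allclose(pred, frame.y, atol=1e-8)


def test_gwr_bandwidth_validation():
    frame, _, _ = _frame(n=40, p=3)
    with pytest.raises(ValueError):
        fit_gwr(frame, bandwidth=3)


def test_gwrf_validation():
    frame, _, _ = _frame(n=40)
    with pytest.raises(ValueError):
        fit_gwrf(frame, 10)  # below default minimum local sample
    with pytest.raises(ValueError):
        fit_gwrf(frame, 41)  # exceeds n


def test_gwrf_global_limit_small():
    frame, _, _ = _frame(n=40, noise=0.1)
    params = ForestParams(n_trees=30)
    gwrf = fit_gwrf(frame, 40, kernel="uniform", params=params, seed=3,
                    collect_oob=False)
    rf = fit_global_rf(frame, params, seed=3)
    Xmat = frame.X.to_numpy()
    assert np.array_equal(gwrf.fitted(Xmat), rf.predict(Xmat))


def test_gwrf_fitted_matches_local_predict(toy_gwrf, toy_linear_frame):
    Xmat = toy_linear_frame.X.to_numpy()
    fitted = toy_gwrf.fitted(Xmat)
    assert fitted[0] == pytest.approx(toy_gwrf.local_predict(0, Xmat[:1])[0])
    # prediction at the training coordinates routes through each location
    pred = toy_gwrf.predict(Xmat, toy_linear_frame.coords)
    assert np.allclose(pred, fitted)


@pytest.mark.filterwarnings("ignore:Some inputs do not have OOB scores")
def test_gwrf_oob_collected():
    frame, _, _ = _frame(n=40, noise=0.1)
    gwrf = fit_gwrf(frame, 40, params=ForestParams(n_trees=50), seed=1)
    assert np.isfinite(gwrf.oob_prediction).mean() > 0.9


def test_spatial_folds_deterministic():
    rng = np.random.default_rng(4)
    coords = rng.uniform(0, 100, size=(60, 2))
    f1 = spatial_folds(coords, n_folds=5, seed=2)
    f2 = spatial_folds(coords, n_folds=5, seed=2)
    assert np.array_equal(f1, f2)
    assert set(np.unique(f1)) == set(range(5))


@pytest.mark.filterwarnings("ignore:Some inputs do not have OOB scores")
def test_select_bandwidth_returns_candidate(toy_linear_frame):
    best, table = select_bandwidth(
        toy_linear_frame, [40, 60], params=ForestParams(n_trees=20), seed=1
    )
    assert best in (40, 60)
    assert list(table.columns) == ["bandwidth", "oob_rmse"]
    assert len(table) == 2
    assert table["oob_rmse"].min() == table.loc[
        table["bandwidth"] == best, "oob_rmse"
    ].iloc[0]


def test_compare_models_in_sample_shape(toy_linear_frame):
    out = compare_models(
        {"annual": toy_linear_frame}, bandwidth=40,
        params=ForestParams(n_trees=20), seed=1, eval_mode="in_sample",
    )
    assert set(out["model"]) == {"RF", "GWR", "GWRF"}
    assert (out["evaluation_mode"] == "in_sample").all()
    assert out["r2"].notna().all()
    with pytest.raises(ValueError):
        compare_models({"annual": toy_linear_frame}, eval_mode="loocv")
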