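"""Global RF, GWR and geographically weighted random forest (GWRF).

The GWRF fits one random-forest submodel per community, trained on that
community's adaptive neighborhood (its ``bandwidth`` nearest communities)
with kernel weights derived from distance relative to the neighborhood's
maximum distance. This lets the fitted covariate-response relationship vary
across space while retaining the forest's ability to capture nonlinear and
threshold effects. A global random forest and a geographically weighted
regression (kernel-weighted least squares per location) serve as
benchmarks; all three are scored with R^2, MAE and RMSE, in-sample,
out-of-bag, or under spatial cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ModelFrame",
    "ForestParams",
    "GWRFModel",
    "GWRModel",
    "FitMetrics",
    "fit_global_rf",
    "fit_gwr",
    "fit_gwrf",
    "select_bandwidth",
    "evaluate",
    "spatial_folds",
    "compare_models",
]

MIN_LOCAL_SAMPLE = 30


@dataclass
class ModelFrame:
    """Covariates, response and coordinates for one season's model."""

    X: pd.DataFrame  # n x p, the 14 covariates
    y: np.ndarray
    coords: np.ndarray  # n x 2 planar meters
    season: str = "annual"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n, p = self.X.shape
        if self.X.isna().any().any():
            bad = self.X.index[self.X.isna().any(axis=1)].tolist()
            raise ValueError(f"missing covariates for communities: {bad}")
        if len(self.y) != n or len(self.coords) != n:
            raise ValueError("X, y and coords must have equal length")
        if n < p + 5:
            raise ValueError(f"need at least p+5={p+5} communities, got {n}")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def factor_names(self) -> list[str]:
        return list(self.X.columns)

    @classmethod
    def from_table(cls, table: pd.DataFrame, season: str = "annual") -> "ModelFrame":
        """Build from a table holding factor columns plus y/coord_x/coord_y."""
        meta = {"y", "coord_x", "coord_y", "region"}
        factors = [c for c in table.columns if c not in meta]
        return cls(
            X=table[factors].copy(),
            y=table["y"].to_numpy(),
            coords=table[["coord_x", "coord_y"]].to_numpy(),
            season=season,
        )

    def subset(self, idx: np.ndarray) -> "ModelFrame":
        fr = ModelFrame.__new__(ModelFrame)
        fr.X = self.X.iloc[idx].copy()
        fr.y = self.y[idx]
        fr.coords = self.coords[idx]
        fr.season = self.season
        return fr


@dataclass(frozen=True)
class ForestParams:
    n_trees: int = 500
    max_depth: int | None = None
    min_leaf: int = 3

    def make(self, seed: int, oob: bool = False) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_leaf,
            random_state=seed,
            oob_score=oob,
            n_jobs=1,
        )


@dataclass
class FitMetrics:
    r2: float
    mae: float
    rmse: float
    evaluation_mode: str = "in_sample"


def evaluate(y: np.ndarray, y_hat: np.ndarray, mode: str = "in_sample") -> FitMetrics:
    """R^2 = 1 - SSE/SST, MAE, RMSE."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) != len(y_hat):
        raise ValueError("length mismatch")
    if len(y) < 2:
        raise ValueError("need at least two observations")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("zero total sum of squares: R^2 undefined")
    sse = float(((y - y_hat) ** 2).sum())
    return FitMetrics(
        r2=1.0 - sse / sst,
        mae=float(np.abs(y - y_hat).mean()),
        rmse=float(np.sqrt(((y - y_hat) ** 2).mean())),
        evaluation_mode=mode,
    )


def _kernel_weights(d: np.ndarray, d_max: float, kernel: str) -> np.ndarray:
    if kernel == "uniform":
        return np.ones_like(d)
    if d_max <= 0:
        return np.ones_like(d)
    u = d / d_max
    if kernel == "bisquare":
        return np.clip(1.0 - u**2, 0.0, None) ** 2
    if kernel == "gaussian":
        return np.exp(-0.5 * u**2)
    raise ValueError(f"unknown kernel {kernel!r}")


def _adaptive_neighbors(coords: np.ndarray, b: int) -> tuple[list[np.ndarray], np.ndarray]:
    """For each location: indices of its b nearest locations (including
    itself), sorted ascending by index, plus the neighborhood's max distance
    (the adaptive bandwidth distance)."""
    n = len(coords)
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=b)
    if b == 1:
        dist, idx = dist[:, None], idx[:, None]
    neighbors, d_max = [], np.empty(n)
    for i in range(n):
        order = np.argsort(idx[i], kind="stable")
        neighbors.append(idx[i][order].astype(np.int64))
        d_max[i] = float(dist[i].max())
    return neighbors, d_max


def fit_global_rf(
    frame: ModelFrame, params: ForestParams | None = None, seed: int = 0
) -> RandomForestRegressor:
    """One forest on all communities (the benchmark global model)."""
    params = params or ForestParams()
    if np.allclose(frame.y, frame.y[0]):
        import warnings

        warnings.warn("response has zero variance; fitting anyway")
    model = params.make(seed)
    # unit observation weights, so the fit is the exact global limit of the
    # kernel-weighted local fits (weights enter the bootstrap draw)
    model.fit(frame.X.to_numpy(), frame.y, sample_weight=np.ones(frame.n))
    return model


@dataclass
class GWRModel:
    """Per-location kernel-weighted least-squares coefficients."""

    coefs: np.ndarray  # n x (p+1), intercept first
    coords: np.ndarray
    bandwidth: int
    kernel: str
    factor_names: list[str]
    ridge: float = 0.0

    def predict(self, X_new: np.ndarray, coords_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        coords_new = np.asarray(coords_new, dtype=float)
        tree = cKDTree(self.coords)
        _, nearest = tree.query(coords_new, k=1)
        design = np.column_stack([np.ones(len(X_new)), X_new])
        return np.einsum("ij,ij->i", design, self.coefs[nearest])

    def fitted(self, X: np.ndarray) -> np.ndarray:
        design = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
        return np.einsum("ij,ij->i", design, self.coefs)


def fit_gwr(
    frame: ModelFrame,
    bandwidth: int | None = None,
    kernel: str = "bisquare",
    ridge_fallback: float = 1e-6,
) -> GWRModel:
    """Geographically weighted regression with adaptive bandwidth.

    Each location's coefficients come from weighted least squares over its
    ``bandwidth`` nearest communities; a rank-deficient local design falls
    back to a small ridge penalty (warned).
    """
    import warnings

    n, p = frame.X.shape
    b = bandwidth if bandwidth is not None else min(n, max(p + 10, n // 3))
    if b < p + 1:
        raise ValueError(f"bandwidth {b} below p+1={p+1} local observations")
    b = min(b, n)
    neighbors, d_max = _adaptive_neighbors(frame.coords, b)
    Xmat = frame.X.to_numpy()
    coefs = np.empty((n, p + 1))
    used_ridge = 0.0
    for i in range(n):
        idx = neighbors[i]
        d = np.linalg.norm(frame.coords[idx] - frame.coords[i], axis=1)
        w = _kernel_weights(d, d_max[i], kernel)
        if w.sum() <= 0 or (w > 0).sum() < p + 1:
            w = np.ones_like(w)  # degenerate kernel support: fall back to uniform
        design = np.column_stack([np.ones(len(idx)), Xmat[idx]])
        sw = np.sqrt(w)
        A = design * sw[:, None]
        z = frame.y[idx] * sw
        AtA = A.T @ A
        if np.linalg.matrix_rank(AtA) < p + 1:
            AtA = AtA + ridge_fallback * np.eye(p + 1)
            used_ridge = ridge_fallback
            warnings.warn(f"rank-deficient local design at location {i}; ridge fallback")
        coefs[i] = np.linalg.solve(AtA, A.T @ z)
    return GWRModel(
        coefs=coefs,
        coords=frame.coords.copy(),
        bandwidth=b,
        kernel=kernel,
        factor_names=frame.factor_names,
        ridge=used_ridge,
    )


@dataclass
class GWRFModel:
    """The set of local forests of a geographically weighted random forest."""

    forests: list[RandomForestRegressor]
    neighbors: list[np.ndarray]
    kernel_weights: list[np.ndarray]
    bandwidth: int  # adaptive: number of neighbors
    bandwidth_dist: np.ndarray  # per location, max distance in neighborhood
    kernel: str
    coords: np.ndarray
    factor_names: list[str]
    params: ForestParams
    seed: int
    oob_prediction: np.ndarray = field(default=None)  # at each fitted location

    @property
    def n(self) -> int:
        return len(self.forests)

    def local_predict(self, i: int, X: np.ndarray) -> np.ndarray:
        """Predict with location i's local forest."""
        return self.forests[i].predict(np.asarray(X, dtype=float))

    def predict(self, X_new: np.ndarray, coords_new: np.ndarray) -> np.ndarray:
        """Prediction at new points uses the nearest fitted location's local
        forest (no blending, for auditability)."""
        if not self.forests:
            raise ValueError("empty model")
        X_new = np.asarray(X_new, dtype=float)
        tree = cKDTree(self.coords)
        _, nearest = tree.query(np.asarray(coords_new, dtype=float), k=1)
        nearest = np.atleast_1d(nearest)
        out = np.empty(len(X_new))
        for loc in np.unique(nearest):
            sel = nearest == loc
            out[sel] = self.forests[loc].predict(X_new[sel])
        return out

    def fitted(self, X: np.ndarray) -> np.ndarray:
        """In-sample prediction: each location through its own local forest."""
        X = np.asarray(X, dtype=float)
        return np.array([self.forests[i].predict(X[i : i + 1])[0] for i in range(len(X))])


def fit_gwrf(
    frame: ModelFrame,
    bandwidth: int,
    kernel: str = "bisquare",
    params: ForestParams | None = None,
    seed: int = 0,
    min_local_sample: int = MIN_LOCAL_SAMPLE,
    collect_oob: bool = True,
) -> GWRFModel:
    """Fit one local forest per community over its adaptive neighborhood.

    ``bandwidth`` is the neighbor count b (the b-th nearest distance is the
    local bandwidth distance); kernel weights on distance/max-distance enter
    the forest as observation weights. With ``bandwidth == n`` and the
    uniform kernel every local forest sees all data equally, reproducing the
    global random forest exactly under a shared seed.
    """
    params = params or ForestParams()
    n = frame.n
    if bandwidth < min_local_sample:
        raise ValueError(
            f"bandwidth {bandwidth} below the minimum local sample "
            f"({min_local_sample}); raise bandwidth or lower min_local_sample"
        )
    if bandwidth > n:
        raise ValueError(f"bandwidth {bandwidth} exceeds n={n}")

    neighbors, d_max = _adaptive_neighbors(frame.coords, bandwidth)
    Xmat = frame.X.to_numpy()
    forests, kweights = [], []
    oob = np.full(n, np.nan)
    want_oob = collect_oob and params.n_trees >= 10
    for i in range(n):
        idx = neighbors[i]
        d = np.linalg.norm(frame.coords[idx] - frame.coords[i], axis=1)
        w = _kernel_weights(d, d_max[i], kernel)
        if w.sum() <= 0:
            w = np.ones_like(w)
        forest = params.make(seed, oob=want_oob)
        forest.fit(Xmat[idx], frame.y[idx], sample_weight=w)
        forests.append(forest)
        kweights.append(w)
        if want_oob:
            center_pos = int(np.searchsorted(idx, i))
            if center_pos < len(idx) and idx[center_pos] == i:
                pred = forest.oob_prediction_[center_pos]
                if np.isfinite(pred):
                    oob[i] = pred
    return GWRFModel(
        forests=forests,
        neighbors=neighbors,
        kernel_weights=kweights,
        bandwidth=bandwidth,
        bandwidth_dist=d_max,
        kernel=kernel,
        coords=frame.coords.copy(),
        factor_names=frame.factor_names,
        params=params,
        seed=seed,
        oob_prediction=oob,
    )


def select_bandwidth(
    frame: ModelFrame,
    candidates: list[int],
    kernel: str = "bisquare",
    params: ForestParams | None = None,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Grid search over neighbor counts minimizing out-of-bag RMSE at the
    fitted locations. Returns (best bandwidth, search table)."""
    rows = []
    for b in candidates:
        model = fit_gwrf(frame, b, kernel=kernel, params=params, seed=seed)
        ok = np.isfinite(model.oob_prediction)
        rmse = float(np.sqrt(np.mean((frame.y[ok] - model.oob_prediction[ok]) ** 2)))
        rows.append({"bandwidth": b, "oob_rmse": rmse})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["oob_rmse"].idxmin(), "bandwidth"])
    return best, table


def spatial_folds(coords: np.ndarray, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Spatially blocked folds: KMeans clusters of the coordinates."""
    km = KMeans(n_clusters=n_folds, random_state=seed, n_init=10)
    return km.fit_predict(np.asarray(coords, dtype=float))


def _cv_predictions(
    frame: ModelFrame,
    folds: np.ndarray,
    fitter,
) -> np.ndarray:
    y_hat = np.empty(frame.n)
    for f in np.unique(folds):
        test = np.where(folds == f)[0]
        train = np.where(folds != f)[0]
        model = fitter(frame.subset(train))
        y_hat[test] = model(frame.X.to_numpy()[test], frame.coords[test])
    return y_hat


def compare_models(
    frames: dict[str, ModelFrame],
    bandwidth: int = 80,
    kernel: str = "bisquare",
    params: ForestParams | None = None,
    seed: int = 0,
    eval_mode: str = "spatial_cv",
    n_folds: int = 5,
    min_local_sample: int = MIN_LOCAL_SAMPLE,
) -> pd.DataFrame:
    """Fit RF, GWR and GWRF per scenario (season or annual) and score them.

    Returns a long table with one row per scenario x model: columns
    scenario, model, r2, mae, rmse, evaluation_mode.
    """
    params = params or ForestParams()
    rows = []
    for scenario, frame in frames.items():
        n = frame.n
        b = min(bandwidth, n)
        if eval_mode == "spatial_cv":
            folds = spatial_folds(frame.coords, n_folds=n_folds, seed=seed)

            def rf_fitter(tr):
                m = fit_global_rf(tr, params, seed)
                return lambda X, c: m.predict(X)

            def gwr_fitter(tr):
                m = fit_gwr(tr, bandwidth=min(b, tr.n), kernel=kernel)
                return m.predict

            def gwrf_fitter(tr):
                m = fit_gwrf(
                    tr, min(b, tr.n), kernel=kernel, params=params, seed=seed,
                    min_local_sample=min(min_local_sample, tr.n), collect_oob=False,
                )
                return m.predict

            fitters = {"RF": rf_fitter, "GWR": gwr_fitter, "GWRF": gwrf_fitter}
            for name, fitter in fitters.items():
                y_hat = _cv_predictions(frame, folds, fitter)
                m = evaluate(frame.y, y_hat, mode="spatial_cv")
                rows.append(
                    {"scenario": scenario, "model": name, "r2": m.r2,
                     "mae": m.mae, "rmse": m.rmse, "evaluation_mode": m.evaluation_mode}
                )
        elif eval_mode in {"in_sample", "out_of_bag"}:
            rf = fit_global_rf(frame, params, seed)
            gwr = fit_gwr(frame, bandwidth=b, kernel=kernel)
            gwrf = fit_gwrf(
                frame, b, kernel=kernel, params=params, seed=seed,
                min_local_sample=min(min_local_sample, n),
                collect_oob=(eval_mode == "out_of_bag"),
            )
            Xmat = frame.X.to_numpy()
            if eval_mode == "in_sample":
                preds = {
                    "RF": rf.predict(Xmat),
                    "GWR": gwr.fitted(Xmat),
                    "GWRF": gwrf.fitted(Xmat),
                }
            else:
                rf_oob = params.make(seed, oob=True)
                rf_oob.fit(Xmat, frame.y)
                ok = np.isfinite(gwrf.oob_prediction)
                preds = {
                    "RF": rf_oob.oob_prediction_,
                    "GWR": gwr.fitted(Xmat),  # GWR has no OOB analogue; in-sample
                    "GWRF": np.where(ok, gwrf.oob_prediction, np.nanmean(gwrf.oob_prediction)),
                }
            for name, y_hat in preds.items():
                m = evaluate(frame.y, y_hat, mode=eval_mode)
                rows.append(
                    {"scenario": scenario, "model": name, "r2": m.r2,
                     "mae": m.mae, "rmse": m.rmse, "evaluation_mode": m.evaluation_mode}
                )
        else:
            raise ValueError(f"unknown eval_mode {eval_mode!r}")
    return pd.DataFrame(rows)
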