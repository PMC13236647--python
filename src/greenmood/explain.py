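"""Shapley-value attribution, importance rankings, partial dependence and
local effect surfaces.

The value function is interventional: v(S) is the model prediction with
features in S taken from the explained observation and the remaining
features replaced by background observations, averaged over the background
set. ``exact_shapley`` enumerates all 2^p coalitions with the factorial
weights; ``sampled_shapley`` is the unbiased permutation-sampling estimator
of the same quantity. For local models the background defaults to the
location's own neighbor set, so attributions are relative to the local
context rather than the whole city.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

__all__ = [
    "ShapleyAttribution",
    "ImportanceRanking",
    "DominantFactorMap",
    "PdpCurve",
    "exact_shapley",
    "sampled_shapley",
    "shapley_matrix",
    "global_importance",
    "local_dominant_factors",
    "partial_dependence",
    "threshold_estimate",
    "local_effect_surface",
]

EXACT_LIMIT = 16


@dataclass
class ShapleyAttribution:
    """phi matrix (observations x factors) plus the defining background."""

    phi: pd.DataFrame
    baseline: float
    background: np.ndarray
    method: str  # exact | sampled
    n_samples: int | None = None
    seed: int | None = None


@dataclass
class ImportanceRanking:
    """Mean |phi| and rank per factor (rank 1 = most important)."""

    table: pd.DataFrame  # index factor, columns mean_abs_phi, rank
    season: str = "annual"

    @property
    def ranked_factors(self) -> list[str]:
        return self.table.sort_values("rank").index.tolist()


@dataclass
class DominantFactorMap:
    """Per-community dominant factor and per-factor community shares (%)."""

    dominant: pd.Series  # index community_id -> factor name
    shares: pd.Series  # index factor -> percent of communities
    season: str = "annual"


@dataclass
class PdpCurve:
    factor: str
    grid: np.ndarray
    mean: np.ndarray
    band: np.ndarray  # across-observation SD at each grid point
    season: str = "annual"


def _as_2d(background: np.ndarray) -> np.ndarray:
    background = np.asarray(background, dtype=float)
    if background.ndim == 1:
        background = background[None, :]
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    return background


def exact_shapley(
    model_fn, x: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """Exact Shapley values by full coalition enumeration.

    phi_i = sum over S not containing i of |S|!(p-|S|-1)!/p! *
    [v(S + i) - v(S)], with interventional masking against the background.
    Limited to p <= 16 factors; use :func:`sampled_shapley` beyond that.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = _as_2d(background)
    p = len(x)
    if p > EXACT_LIMIT:
        raise ValueError(
            f"{p} factors exceeds the exact enumeration limit ({EXACT_LIMIT}); "
            "use sampled_shapley"
        )
    n_bg = len(background)
    n_sets = 1 << p
    # masks[s, j] = True if factor j in coalition s
    masks = (np.arange(n_sets)[:, None] >> np.arange(p)) & 1
    masks = masks.astype(bool)
    designs = np.where(
        masks[:, None, :], x[None, None, :], background[None, :, :]
    ).reshape(n_sets * n_bg, p)
    v = np.asarray(model_fn(designs), dtype=float).reshape(n_sets, n_bg).mean(axis=1)

    sizes = masks.sum(axis=1)
    weights = np.array(
        [factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)]
    )
    phi = np.zeros(p)
    for j in range(p):
        without = ~masks[:, j]
        s_idx = np.arange(n_sets)[without]
        phi[j] = float(
            (weights[sizes[s_idx]] * (v[s_idx | (1 << j)] - v[s_idx])).sum()
        )
    return phi


def _prefix_masks(perms: np.ndarray) -> np.ndarray:
    """(n_perm, p+1, p) boolean prefix-coalition masks for each permutation."""
    n_perm, p = perms.shape
    masks = np.zeros((n_perm, p + 1, p), dtype=bool)
    for k in range(p):
        masks[:, k + 1] = masks[:, k]
        masks[np.arange(n_perm), k + 1, perms[:, k]] = True
    return masks


def sampled_shapley(
    model_fn,
    x: np.ndarray,
    background: np.ndarray,
    n_samples: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-sampling Shapley estimate.

    Draws ``n_samples`` random factor orderings; each factor's marginal
    contribution is averaged over orderings. Returns (phi, standard_error)
    with the Monte-Carlo standard error per factor.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    x = np.asarray(x, dtype=float).ravel()
    background = _as_2d(background)
    p = len(x)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(p) for _ in range(n_samples)])
    masks = _prefix_masks(perms)  # (n_perm, p+1, p)
    n_bg = len(background)
    designs = np.where(
        masks[:, :, None, :], x[None, None, None, :], background[None, None, :, :]
    ).reshape(n_samples * (p + 1) * n_bg, p)
    v = np.asarray(model_fn(designs), dtype=float).reshape(n_samples, p + 1, n_bg).mean(axis=2)
    deltas = np.diff(v, axis=1)  # (n_perm, p): contribution at each position
    contrib = np.zeros((n_samples, p))
    rows = np.repeat(np.arange(n_samples), p)
    contrib[rows, perms.ravel()] = deltas.ravel()
    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / np.sqrt(n_samples)
    return phi, se


def shapley_matrix(
    model_fn,
    X: np.ndarray,
    background: np.ndarray,
    n_samples: int = 64,
    seed: int = 0,
) -> np.ndarray:
    """Permutation-sampling phi for many observations at once.

    Shares one set of permutations across observations and batches all
    model evaluations into a single call, which is what makes per-community
    local attributions affordable.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = _as_2d(background)
    n_obs, p = X.shape
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(p) for _ in range(n_samples)])
    masks = _prefix_masks(perms)  # (n_perm, p+1, p)
    n_bg = len(background)
    designs = np.where(
        masks[None, :, :, None, :],
        X[:, None, None, None, :],
        background[None, None, None, :, :],
    ).reshape(-1, p)
    v = (
        np.asarray(model_fn(designs), dtype=float)
        .reshape(n_obs, n_samples, p + 1, n_bg)
        .mean(axis=3)
    )
    deltas = np.diff(v, axis=2)  # (n_obs, n_perm, p)
    phi = np.zeros((n_obs, p))
    for j in range(n_samples):
        order = perms[j]
        contrib = np.zeros((n_obs, p))
        contrib[:, order] = deltas[:, j, :]
        phi += contrib
    return phi / n_samples


def global_importance(
    attr: ShapleyAttribution, factor_order: list[str] | None = None
) -> ImportanceRanking:
    """Mean |phi| per factor with descending ranks; ties broken by the
    configured factor order (first listed wins)."""
    phi = attr.phi
    if phi.empty:
        raise ValueError("empty attribution")
    order = factor_order or list(phi.columns)
    mean_abs = phi.abs().mean(axis=0)
    tie = pd.Series({f: i for i, f in enumerate(order)})
    tbl = pd.DataFrame({"mean_abs_phi": mean_abs, "tie": tie.reindex(mean_abs.index)})
    tbl = tbl.sort_values(["mean_abs_phi", "tie"], ascending=[False, True], kind="stable")
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    return ImportanceRanking(table=tbl[["mean_abs_phi", "rank"]])


def local_dominant_factors(
    gwrf,
    frame,
    background_size: int = 16,
    obs_per_community: int = 8,
    n_samples: int = 48,
    seed: int = 0,
    season: str = "annual",
) -> DominantFactorMap:
    """Dominant factor per community from its own local forest.

    For each community, phi is computed under the local forest with the
    neighbor set as background; the dominant factor maximizes mean |phi|
    over (a subsample of) the neighborhood observations, ties broken by
    factor order. Subsampling of both observations and background follows
    the local kernel weights, and the |phi| average is kernel-weighted, so
    the attribution reflects the same spatial weighting as the local fit.
    """
    if not getattr(gwrf, "forests", None):
        raise ValueError("unfitted model")
    Xmat = frame.X.to_numpy()
    factors = frame.factor_names
    ids = list(frame.X.index)
    rng = np.random.default_rng(seed)
    dominant = {}
    for i in range(gwrf.n):
        idx = gwrf.neighbors[i]
        kw = np.asarray(gwrf.kernel_weights[i], dtype=float)
        prob = kw / kw.sum() if kw.sum() > 0 else np.full(len(idx), 1.0 / len(idx))
        if len(idx) <= background_size:
            bg_idx = idx
        else:
            pos = rng.choice(len(idx), background_size, replace=False, p=prob)
            bg_idx = idx[pos]
        center_pos = int(np.searchsorted(idx, i))
        has_center = center_pos < len(idx) and idx[center_pos] == i
        if len(idx) <= obs_per_community or not has_center:
            obs_pos = np.arange(len(idx))[: max(obs_per_community, 1)]
        else:
            others = np.delete(np.arange(len(idx)), center_pos)
            p_o = prob[others] / prob[others].sum()
            obs_pos = np.concatenate(
                [[center_pos],
                 rng.choice(others, obs_per_community - 1, replace=False, p=p_o)]
            )
        obs_idx = idx[obs_pos]
        phi = shapley_matrix(
            gwrf.forests[i].predict,
            Xmat[obs_idx],
            Xmat[bg_idx],
            n_samples=n_samples,
            seed=int(rng.integers(2**31)),
        )
        w_obs = kw[obs_pos]
        if w_obs.sum() <= 0:
            w_obs = np.ones(len(obs_pos))
        mean_abs = (np.abs(phi) * w_obs[:, None]).sum(axis=0) / w_obs.sum()
        dominant[ids[i]] = factors[int(np.argmax(mean_abs))]  # argmax: first max wins
    dom = pd.Series(dominant, name="dominant_factor")
    counts = dom.value_counts()
    shares = (counts / counts.sum() * 100.0).reindex(factors).dropna()
    return DominantFactorMap(dominant=dom, shares=shares, season=season)


def partial_dependence(
    model_fn,
    X: pd.DataFrame,
    factor: str,
    grid_size: int = 20,
    season: str = "annual",
) -> PdpCurve:
    """Partial dependence: mean model response as one factor sweeps a
    quantile grid of its observed values; the band is the across-observation
    standard deviation of the response at each grid point (a dispersion
    band, not a confidence interval)."""
    import warnings

    if factor not in X.columns:
        raise ValueError(f"factor {factor!r} not in frame")
    vals = X[factor].to_numpy(dtype=float)
    grid = np.unique(np.quantile(vals, np.linspace(0, 1, grid_size)))
    if len(grid) == 1:
        warnings.warn(f"factor {factor!r} is constant; single-point curve")
    Xmat = X.to_numpy(dtype=float)
    j = X.columns.get_loc(factor)
    n, p = Xmat.shape
    designs = np.repeat(Xmat[None, :, :], len(grid), axis=0)
    designs[:, :, j] = grid[:, None]
    preds = np.asarray(model_fn(designs.reshape(-1, p)), dtype=float).reshape(len(grid), n)
    return PdpCurve(
        factor=factor,
        grid=grid,
        mean=preds.mean(axis=1),
        band=preds.std(axis=1),
        season=season,
    )


def threshold_estimate(curve: PdpCurve, shape: str = "valley") -> float:
    """Location where the PDP's slope changes sign.

    ``shape="valley"`` (effect turning from negative to positive) returns
    the grid point minimizing the curve; ``shape="peak"`` the maximizer.
    """
    if shape == "valley":
        return float(curve.grid[int(np.argmin(curve.mean))])
    if shape == "peak":
        return float(curve.grid[int(np.argmax(curve.mean))])
    raise ValueError("shape must be 'valley' or 'peak'")


def local_effect_surface(
    gwrf,
    frame,
    factor: str,
    grid_size: int = 7,
) -> pd.DataFrame:
    """Signed local association of one factor per community.

    For each community, a PDP of its local forest over its neighborhood
    observations across the local factor range; the reported value is the
    least-squares slope of that curve. Communities where the factor is
    locally constant get NaN (flagged in the 'flag' column).
    """
    if factor not in frame.X.columns:
        raise ValueError(f"factor {factor!r} not in frame")
    Xdf = frame.X
    rows = []
    for i in range(gwrf.n):
        idx = gwrf.neighbors[i]
        local = Xdf.iloc[idx]
        vals = local[factor].to_numpy(dtype=float)
        if np.ptp(vals) <= 0:
            rows.append({"community_id": Xdf.index[i], "slope": np.nan, "flag": "constant"})
            continue
        curve = partial_dependence(
            gwrf.forests[i].predict, local, factor, grid_size=grid_size
        )
        g = curve.grid - curve.grid.mean()
        slope = float((g @ (curve.mean - curve.mean.mean())) / (g @ g))
        rows.append({"community_id": Xdf.index[i], "slope": slope, "flag": "ok"})
    return pd.DataFrame(rows).set_index("community_id")
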