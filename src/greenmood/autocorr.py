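"""Global and local Moran's I with permutation inference.

Global Moran's I measures whether a community attribute (here the negative
emotion index) is spatially clustered; Local Moran's I (LISA) classifies
each community into high-high (HH), low-low (LL), high-low (HL) or low-high
(LH) cluster/outlier types, gated by a conditional-permutation p-value.

Weights are k-nearest-neighbor by Euclidean distance on planar coordinates
(default), or rook contiguity on a regular grid for raster fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "LisaResult",
    "build_weights",
    "rook_weights",
    "global_morans_i",
    "local_morans_i",
]


@dataclass
class SpatialWeights:
    """Sparse row-oriented spatial weights.

    ``neighbors[i]`` and ``weights[i]`` give unit i's neighbor indices and
    the corresponding non-negative weights; the diagonal is always zero.
    """

    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    scheme: str
    row_standardized: bool

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def total_weight(self) -> float:
        return float(sum(w.sum() for w in self.weights))

    def lag(self, values: np.ndarray) -> np.ndarray:
        """Spatial lag: weighted sum of neighbor values per unit."""
        values = np.asarray(values, dtype=float)
        return np.array(
            [w @ values[idx] if len(idx) else 0.0
             for idx, w in zip(self.neighbors, self.weights)]
        )

    def dense(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i, (idx, w) in enumerate(zip(self.neighbors, self.weights)):
            W[i, idx] = w
        return W


@dataclass
class MoranResult:
    I: float
    expected: float
    p_perm: float
    n_perm: int
    seed: int
    perm_mean: float = field(default=np.nan)


@dataclass
class LisaResult:
    local_i: np.ndarray
    p_perm: np.ndarray
    classes: np.ndarray  # array of {"HH","LL","HL","LH","ns"}
    alpha: float
    n_perm: int
    seed: int

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.classes, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def build_weights(
    coords: np.ndarray,
    scheme: str = "knn",
    k: int = 8,
    row_standardize: bool = True,
) -> SpatialWeights:
    """k-nearest-neighbor weights on planar coordinates.

    Distance ties (including exact duplicate coordinates) are broken by unit
    index: among equidistant candidates the lower index wins, so the weights
    are reproducible regardless of input order.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if scheme != "knn":
        raise ValueError(f"unknown scheme {scheme!r}; use build_weights/rook_weights")
    if n < 3:
        raise ValueError("need at least 3 units")
    if k >= n:
        raise ValueError("k must be smaller than the number of units")

    # Stable tie-break: sort candidates by (distance rounded to 1e-9, index).
    if len(np.unique(coords, axis=0)) < n:
        warnings.warn("duplicate coordinates; ties broken by unit index")
    tree = cKDTree(coords)
    # query k+1 then drop self; over-query to resolve ties deterministically
    kq = min(n, k + 8)
    dist, idx = tree.query(coords, k=kq)
    neighbors, wts = [], []
    for i in range(n):
        order = sorted(
            (round(float(d), 9), int(j))
            for d, j in zip(dist[i], idx[i])
            if j != i
        )
        chosen = np.array([j for _, j in order[:k]], dtype=np.int64)
        w = np.ones(k, dtype=float)
        if row_standardize:
            w = w / w.sum()
        neighbors.append(chosen)
        wts.append(w)
    return SpatialWeights(neighbors, wts, scheme="knn", row_standardized=row_standardize)


def rook_weights(n_rows: int, n_cols: int, row_standardize: bool = True) -> SpatialWeights:
    """Rook (edge-sharing) contiguity on a regular grid, row-major unit ids."""
    neighbors, wts = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            idx = []
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    idx.append(rr * n_cols + cc)
            idx = np.array(sorted(idx), dtype=np.int64)
            w = np.ones(len(idx), dtype=float)
            if row_standardize and len(w):
                w = w / w.sum()
            neighbors.append(idx)
            wts.append(w)
    return SpatialWeights(neighbors, wts, scheme="rook", row_standardized=row_standardize)


def _moran_stat(z: np.ndarray, W: SpatialWeights) -> float:
    n = len(z)
    num = float(z @ W.lag(z))
    return n / W.total_weight * num / float(z @ z)


def global_morans_i(
    values: np.ndarray,
    W: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with a two-sided permutation test.

    The permutation p-value counts permuted statistics at least as far from
    the null expectation E[I] = -1/(n-1) as the observed one:
    p = (#extreme + 1) / (n_perm + 1).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n != W.n:
        raise ValueError("values length does not match weights")
    z = values - values.mean()
    if np.allclose(z, 0):
        raise ValueError("zero variance: Moran's I undefined")

    I_obs = _moran_stat(z, W)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perm_I = np.empty(n_perm)
    for b in range(n_perm):
        perm_I[b] = _moran_stat(rng.permutation(z), W)
    extreme = np.abs(perm_I - expected) >= abs(I_obs - expected) - 1e-12
    p = (int(extreme.sum()) + 1) / (n_perm + 1)
    return MoranResult(
        I=I_obs, expected=expected, p_perm=p, n_perm=n_perm, seed=seed,
        perm_mean=float(perm_I.mean()),
    )


def local_morans_i(
    values: np.ndarray,
    W: SpatialWeights,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> LisaResult:
    """Local Moran's I with conditional permutation and HH/LL/HL/LH classes.

    For unit i, I_i = z_i * lag_i / m2 with m2 = sum(z^2)/n. The conditional
    permutation holds z_i fixed and draws its neighbors from the remaining
    n-1 values; the two-sided p-value compares |I_i| against the permuted
    distribution. Classes come from the signs of z_i and its spatial lag,
    reported only where p <= alpha, else "ns".
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n != W.n:
        raise ValueError("values length does not match weights")
    z = values - values.mean()
    if np.allclose(z, 0):
        raise ValueError("zero variance: local Moran's I undefined")
    m2 = float(z @ z) / n
    lag = W.lag(z)
    local_i = z * lag / m2

    rng = np.random.default_rng(seed)
    p = np.empty(n)
    for i in range(n):
        others = np.delete(z, i)
        k = len(W.neighbors[i])
        if k == 0:
            p[i] = 1.0
            continue
        w = W.weights[i]
        draws = rng.integers(0, n - 1, size=(n_perm, k))
        perm_lag = (others[draws] * w).sum(axis=1)
        perm_i = z[i] * perm_lag / m2
        extreme = np.abs(perm_i) >= abs(local_i[i]) - 1e-12
        p[i] = (int(extreme.sum()) + 1) / (n_perm + 1)

    classes = np.full(n, "ns", dtype=object)
    sig = p <= alpha
    hi = z > 0
    lag_hi = lag > 0
    classes[sig & hi & lag_hi] = "HH"
    classes[sig & ~hi & ~lag_hi] = "LL"
    classes[sig & hi & ~lag_hi] = "HL"
    classes[sig & ~hi & lag_hi] = "LH"
    return LisaResult(
        local_i=local_i, p_perm=p, classes=classes.astype(str),
        alpha=alpha, n_perm=n_perm, seed=seed,
    )
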