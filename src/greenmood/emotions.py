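"""Community-level negative-emotion indicator from geotagged posts.

Pipeline: filter posts to negative sentiment within a meteorological season,
turn the point events into a continuous intensity surface by kernel density
estimation, average the surface over each community footprint, and
standardize by permanent resident population (per 10,000 residents).

The KDE follows the planar form

    f_hat(s) = sum_i 1/(n h^2) K((s - s_i)/h)

with the quartic kernel K(u) = (3/pi)(1 - ||u||^2)^2 for ||u|| <= 1 as the
default (the kernel of ArcGIS-style point density tools); Gaussian and
uniform kernels are selectable. With this normalization an interior surface
integrates to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd
import shapely
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .grids import GridSpec, Raster

__all__ = [
    "SEASONS",
    "SENTIMENTS",
    "GeoPost",
    "DensitySurface",
    "EmotionIndicator",
    "ClassificationReport",
    "assign_season",
    "negative_events",
    "kde_surface",
    "community_emotion_index",
    "classification_metrics",
]

SEASONS = ("spring", "summer", "autumn", "winter")
SENTIMENTS = ("positive", "neutral", "negative")

_SEASON_OF_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}


@dataclass(frozen=True)
class GeoPost:
    """One geotagged post: the KDE input event."""

    id: str
    x: float
    y: float
    timestamp: datetime
    sentiment: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("post coordinates must be finite")
        if self.sentiment not in SENTIMENTS:
            raise ValueError(f"unknown sentiment {self.sentiment!r}")


@dataclass
class DensitySurface:
    """KDE surface on a regular grid (row 0 = north)."""

    raster: Raster
    bandwidth: float
    kernel: str
    n_events: int

    @property
    def values(self) -> np.ndarray:
        return self.raster.values

    @property
    def spec(self) -> GridSpec:
        return self.raster.spec

    def total_mass(self) -> float:
        """Integral of the surface over the grid (== 1 for interior events)."""
        return float(self.values.sum()) * self.spec.cell_size**2


@dataclass(frozen=True)
class EmotionIndicator:
    community_id: str
    season: str
    raw_density: float
    population: float
    index: float  # raw_density / (population / 10,000)


@dataclass
class ClassificationReport:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray  # rows = true, cols = predicted, class order SENTIMENTS


def assign_season(timestamp: datetime | str) -> str:
    """Meteorological season: Mar-May spring, Jun-Aug summer, Sep-Nov autumn,
    Dec-Feb winter. Boundary days belong to the starting month's season."""
    if isinstance(timestamp, str):
        ts = pd.to_datetime(timestamp)
        if pd.isna(ts):
            raise ValueError(f"unparsable timestamp {timestamp!r}")
        timestamp = ts
    return _SEASON_OF_MONTH[timestamp.month]


def negative_events(posts: list[GeoPost], season: str) -> np.ndarray:
    """(x, y) array of negative-sentiment posts falling in *season*."""
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    xy = [
        (p.x, p.y)
        for p in posts
        if p.sentiment == "negative" and assign_season(p.timestamp) == season
    ]
    return np.array(xy, dtype=float).reshape(-1, 2)


def _quartic(u2: np.ndarray) -> np.ndarray:
    return np.where(u2 <= 1.0, (3.0 / np.pi) * (1.0 - u2) ** 2, 0.0)


def _gaussian(u2: np.ndarray) -> np.ndarray:
    return np.exp(-u2 / 2.0) / (2.0 * np.pi)


def _uniform(u2: np.ndarray) -> np.ndarray:
    return np.where(u2 <= 1.0, 1.0 / np.pi, 0.0)


_KERNELS = {"quartic": (_quartic, 1.0), "gaussian": (_gaussian, 6.0), "uniform": (_uniform, 1.0)}


def kde_surface(
    events: np.ndarray,
    grid: GridSpec,
    bandwidth: float = 1000.0,
    kernel: str = "quartic",
) -> DensitySurface:
    """Kernel density surface of point events.

    Parameters
    ----------
    events
        (n, 2) array of planar event coordinates in meters.
    grid
        Output grid; densities are evaluated at cell centers.
    bandwidth
        Kernel bandwidth h in meters (the quartic/uniform kernels have
        support ``||s - s_i|| <= h``).
    kernel
        "quartic" (default), "gaussian" or "uniform".
    """
    events = np.asarray(events, dtype=float).reshape(-1, 2)
    if len(events) == 0:
        raise ValueError("empty event list")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if kernel not in _KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}")
    kfun, support = _KERNELS[kernel]

    n = len(events)
    h = float(bandwidth)
    values = np.zeros((grid.n_rows, grid.n_cols))
    xs = grid.x0 + (np.arange(grid.n_cols) + 0.5) * grid.cell_size
    ys = grid.y0 + (grid.n_rows - np.arange(grid.n_rows) - 0.5) * grid.cell_size
    radius = support * h
    scale = 1.0 / (n * h * h)
    for ex, ey in events:
        c0 = max(0, int(np.searchsorted(xs, ex - radius)))
        c1 = min(grid.n_cols, int(np.searchsorted(xs, ex + radius, side="right")))
        # ys is descending (row 0 = north)
        r0 = max(0, int(np.searchsorted(-ys, -(ey + radius))))
        r1 = min(grid.n_rows, int(np.searchsorted(-ys, -(ey - radius), side="right")))
        if c0 >= c1 or r0 >= r1:
            continue
        dx = (xs[c0:c1] - ex) / h
        dy = (ys[r0:r1] - ey) / h
        u2 = dy[:, None] ** 2 + dx[None, :] ** 2
        values[r0:r1, c0:c1] += scale * kfun(u2)
    return DensitySurface(
        raster=Raster(values=values, spec=grid),
        bandwidth=h,
        kernel=kernel,
        n_events=n,
    )


def community_emotion_index(
    surface: DensitySurface,
    communities: dict[str, shapely.Geometry],
    populations: dict[str, float],
    season: str,
    centroid_fallback: bool = False,
) -> list[EmotionIndicator]:
    """Average the density surface over each community footprint and
    standardize per 10,000 residents.

    raw_density is the mean of surface cells whose centers fall inside the
    community polygon; index = raw_density / (population / 10,000). A
    polygon smaller than one grid cell covers no cell center: by default
    that is an error; with ``centroid_fallback`` the nearest cell to the
    polygon centroid is used instead.
    """
    X, Y = surface.spec.cell_centers()
    x_flat, y_flat = X.ravel(), Y.ravel()
    v_flat = surface.values.ravel()
    out: list[EmotionIndicator] = []
    for cid, poly in communities.items():
        pop = populations[cid]
        if pop <= 0:
            raise ValueError(f"community {cid}: non-positive population")
        shapely.prepare(poly)
        minx, miny, maxx, maxy = poly.bounds
        near = (x_flat >= minx) & (x_flat <= maxx) & (y_flat >= miny) & (y_flat <= maxy)
        inside = np.zeros(len(x_flat), dtype=bool)
        inside[near] = shapely.contains_xy(poly, x_flat[near], y_flat[near])
        if not inside.any():
            if not centroid_fallback:
                raise ValueError(f"community {cid}: no surface cells cover its footprint")
            c = poly.centroid
            nearest = np.argmin((x_flat - c.x) ** 2 + (y_flat - c.y) ** 2)
            inside[nearest] = True
        raw = float(v_flat[inside].mean())
        out.append(
            EmotionIndicator(
                community_id=cid,
                season=season,
                raw_density=raw,
                population=float(pop),
                index=raw / (pop / 10_000.0),
            )
        )
    return out


def classification_metrics(
    true_labels: list[str], predicted_labels: list[str]
) -> ClassificationReport:
    """Accuracy, per-class precision/recall/F1 and macro averages for the
    3-class sentiment task. A class never predicted gets precision 0."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists differ in length")
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in SENTIMENTS:
            raise ValueError(f"unknown label {lab!r}")
    labels = list(SENTIMENTS)
    cm = confusion_matrix(true_labels, predicted_labels, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        true_labels, predicted_labels, labels=labels, zero_division=0
    )
    return ClassificationReport(
        accuracy=float(np.trace(cm)) / len(true_labels),
        precision=dict(zip(labels, prec.tolist())),
        recall=dict(zip(labels, rec.tolist())),
        f1=dict(zip(labels, f1.tolist())),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        confusion=cm,
    )
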