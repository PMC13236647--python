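"""Urban-green-space covariates: NDVI, street-view aggregation, catchment
accessibility counts, and lockdown intensity.

These are the "quantity" and "quality" covariates of the modelling frame;
landscape-pattern covariates live in :mod:`greenmood.landscape`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .grids import Raster

__all__ = [
    "StreetPointScore",
    "CatchmentDistances",
    "LockdownCalendar",
    "ndvi",
    "community_ndvi",
    "aggregate_streetview",
    "catchment_count",
    "lockdown_intensity",
]


@dataclass(frozen=True)
class StreetPointScore:
    """Per-sampling-point street-view scores, one value per viewing direction."""

    point_id: str
    community_id: str
    direction_scores: tuple[float, ...]
    score_kind: str  # gvi | openness | walkability

    def __post_init__(self) -> None:
        if not (1 <= len(self.direction_scores) <= 4):
            raise ValueError("1-4 direction scores required")

    @property
    def point_value(self) -> float:
        return float(np.mean(self.direction_scores))


@dataclass(frozen=True)
class CatchmentDistances:
    community_id: str
    destination_kind: str  # green_space | outdoor_public_space
    distances: tuple[float, ...]  # network meters

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.distances):
            raise ValueError("negative distance")


@dataclass(frozen=True)
class LockdownCalendar:
    community_id: str
    locked_days: int
    window_days: int

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")
        if not 0 <= self.locked_days <= self.window_days:
            raise ValueError("locked_days must lie in [0, window_days]")


def ndvi(nir: Raster, red: Raster) -> Raster:
    """Normalized difference vegetation index, (NIR - Red)/(NIR + Red).

    Cells where NIR + Red == 0 are set to NaN (missing) and excluded from
    community means.
    """
    if not nir.aligned_with(red):
        raise ValueError("NIR and Red rasters are not aligned")
    n = np.asarray(nir.values, dtype=float)
    r = np.asarray(red.values, dtype=float)
    denom = n + r
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (n - r) / denom, np.nan)
    return Raster(values=out, spec=nir.spec)


def community_ndvi(
    ndvi_raster: Raster, communities: dict[str, shapely.Geometry]
) -> dict[str, float]:
    """Mean NDVI over each community footprint, NaN cells excluded."""
    X, Y = ndvi_raster.spec.cell_centers()
    x_flat, y_flat = X.ravel(), Y.ravel()
    v = np.asarray(ndvi_raster.values, dtype=float).ravel()
    out: dict[str, float] = {}
    for cid, poly in communities.items():
        shapely.prepare(poly)
        inside = shapely.contains_xy(poly, x_flat, y_flat)
        vals = v[inside]
        vals = vals[np.isfinite(vals)]
        out[cid] = float(vals.mean()) if len(vals) else float("nan")
    return out


def aggregate_streetview(
    scores: list[StreetPointScore], score_kind: str
) -> dict[str, float]:
    """Two-level mean: per point over directions, then per community over
    points. Distinct from the pooled mean when direction counts differ."""
    by_community: dict[str, list[float]] = {}
    for s in scores:
        if s.score_kind != score_kind:
            raise ValueError(
                f"score kind mismatch: expected {score_kind!r}, got {s.score_kind!r}"
            )
        by_community.setdefault(s.community_id, []).append(s.point_value)
    return {cid: float(np.mean(vals)) for cid, vals in by_community.items()}


def catchment_count(d: CatchmentDistances, threshold: float = 1000.0) -> int:
    """Number of destinations within the walking catchment (closed boundary:
    a destination exactly at the threshold counts)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return int(sum(1 for x in d.distances if x <= threshold))


def lockdown_intensity(cal: LockdownCalendar) -> float:
    """Fraction of the study window spent under lockdown."""
    return cal.locked_days / cal.window_days
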