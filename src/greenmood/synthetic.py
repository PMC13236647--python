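"""Synthetic city generator with known ground truth.

Generates every input the analysis pipeline consumes — communities with
polygons and populations, 14 per-community covariates per season, geotagged
posts whose negative share follows a known function of a latent emotion
level, land-use class rasters, and two-band reflectance rasters — so that
indicator construction, spatial autocorrelation, geographically weighted
models and Shapley attribution can all be validated against stored truth.

The latent negative-emotion level of community i in season s is

    latent_i(s) = base + sum_f  m_region(f, r_i) * m_season(f, s) * g_f(x_fi)
                  + noise_i(s)

where g_f is a linear or piecewise-linear (threshold) effect on factor f's
standardized scale. Defaults encode the structure the pipeline is meant to
recover: a greenness (NDVI) effect that reverses sign at NDVI = 0.5, a
green-space-accessibility effect whose sign differs between the two
regions, seasonal magnitude modulation (strongest in spring, weakest in
winter), and a lockdown-intensity nuisance covariate.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .emotions import SEASONS, GeoPost
from .grids import GridSpec, Raster

__all__ = [
    "FACTORS",
    "SEASONAL_FACTORS",
    "FactorEffect",
    "FactorSpec",
    "CityConfig",
    "CityTruth",
    "SyntheticCity",
    "ReflectanceScene",
    "generate_city",
    "generate_posts",
    "generate_landuse",
    "generate_reflectance",
    "default_factor_specs",
]

# The 14 modelling covariates: green-space quantity, quality, landscape
# pattern, and controls.
FACTORS = (
    "ndvi",
    "gvi",
    "outdoor_access",
    "green_access",
    "openness",
    "walkability",
    "lpi",
    "pd",
    "ed",
    "shdi",
    "residential_density",
    "female_share",
    "night_light",
    "lockdown_intensity",
)

# Factors whose community values change with season (vegetation phenology
# and the time-varying mobility restrictions); the rest are static.
SEASONAL_FACTORS = ("ndvi", "gvi", "lockdown_intensity")

_SEASON_MONTHS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (1, 2, 12),  # single-year window: Jan, Feb and Dec of the study year
}
STUDY_YEAR = 2022


@dataclass(frozen=True)
class FactorEffect:
    """Effect of one factor on the latent emotion.

    ``slope`` acts on the factor's standardized (unit-range) scale. With a
    ``threshold`` (on the raw factor scale) the effect is piecewise linear:
    slope below the threshold, ``post_slope`` above it, continuous at the
    threshold. ``region_mult`` gives per-region magnitude/sign multipliers
    (cycled if there are more regions than entries); ``season_mult`` gives
    per-season magnitude multipliers.
    """

    slope: float = 0.0
    threshold: float | None = None
    post_slope: float | None = None
    region_mult: tuple[float, ...] = (1.0,)
    season_mult: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in SEASONS}
    )


@dataclass(frozen=True)
class FactorSpec:
    """Range, seasonality and generating effect for one covariate."""

    name: str
    low: float
    high: float
    effect: FactorEffect
    seasonal_shift: dict[str, float] | None = None  # additive shift of the field mean

    def contribution(self, x: np.ndarray, region: np.ndarray, season: str) -> np.ndarray:
        """Noise-free latent contribution of this factor (vectorized)."""
        x = np.asarray(x, dtype=float)
        eff = self.effect
        span = self.high - self.low
        if eff.threshold is None:
            g = eff.slope * ((x - self.low) / span - 0.5)
        else:
            post = eff.post_slope if eff.post_slope is not None else eff.slope
            g = np.where(
                x < eff.threshold,
                eff.slope * (x - eff.threshold) / span,
                post * (x - eff.threshold) / span,
            )
        mults = np.asarray(
            [eff.region_mult[r % len(eff.region_mult)] for r in np.asarray(region)]
        )
        return g * mults * eff.season_mult[season]


def default_factor_specs() -> dict[str, FactorSpec]:
    """The default generating design (two regions).

    Region 0 is driven chiefly by NDVI (threshold reversal at 0.5, negative
    below / positive above); region 1 chiefly by green-space accessibility,
    whose effect sign is positive in region 0 and negative in region 1.
    Seasonal multipliers make effects strongest in spring and mildest in
    winter. All other factors carry smaller effects, including the lockdown
    nuisance.
    """
    s = {}
    s["ndvi"] = FactorSpec(
        "ndvi", -0.1, 0.9,
        FactorEffect(
            slope=-0.9, threshold=0.5, post_slope=1.1,
            region_mult=(1.0, 0.35),
            season_mult={"spring": 1.3, "summer": 1.0, "autumn": 1.0, "winter": 0.7},
        ),
        seasonal_shift={"spring": 0.0, "summer": 0.08, "autumn": -0.03, "winter": -0.12},
    )
    s["gvi"] = FactorSpec(
        "gvi", 0.0, 0.6,
        FactorEffect(
            slope=-0.10, threshold=0.2, post_slope=-0.02,
            region_mult=(1.0, 1.0),
            season_mult={"spring": 1.2, "summer": 1.0, "autumn": 1.0, "winter": 0.8},
        ),
        seasonal_shift={"spring": 0.0, "summer": 0.05, "autumn": -0.02, "winter": -0.08},
    )
    s["outdoor_access"] = FactorSpec(
        "outdoor_access", 0.0, 25.0,
        FactorEffect(slope=-0.12, threshold=10.0, post_slope=0.08,
                     region_mult=(1.0, 1.0),
                     season_mult={"spring": 1.2, "summer": 1.0, "autumn": 1.0, "winter": 0.9}),
    )
    s["green_access"] = FactorSpec(
        "green_access", 0.0, 30.0,
        FactorEffect(
            slope=0.18, region_mult=(1.0, -3.0),
            season_mult={"spring": 1.3, "summer": 1.1, "autumn": 1.0, "winter": 0.8},
        ),
    )
    s["openness"] = FactorSpec(
        "openness", 0.0, 1.0,
        FactorEffect(slope=0.15, threshold=0.6, post_slope=-0.15,
                     region_mult=(1.0, 1.0),
                     season_mult={"spring": 1.3, "summer": 1.2, "autumn": 1.0, "winter": 0.8}),
    )
    s["walkability"] = FactorSpec(
        "walkability", 0.0, 6.0,
        FactorEffect(slope=-0.06, threshold=4.0, post_slope=0.05),
    )
    s["lpi"] = FactorSpec(
        "lpi", 5.0, 80.0,
        FactorEffect(slope=0.10, threshold=40.0, post_slope=-0.12,
                     region_mult=(1.0, 1.0),
                     season_mult={"spring": 0.8, "summer": 1.2, "autumn": 1.0, "winter": 1.0}),
    )
    s["pd"] = FactorSpec("pd", 0.0, 8.0, FactorEffect(slope=-0.05, threshold=4.0, post_slope=0.04))
    s["ed"] = FactorSpec("ed", 0.0, 10.0, FactorEffect(slope=-0.06, threshold=5.0, post_slope=0.05))
    s["shdi"] = FactorSpec("shdi", 0.0, 1.4, FactorEffect(slope=-0.05, threshold=0.2, post_slope=0.05))
    s["residential_density"] = FactorSpec(
        "residential_density", 0.0, 1.0, FactorEffect(slope=0.05)
    )
    s["female_share"] = FactorSpec("female_share", 0.4, 0.6, FactorEffect(slope=0.02))
    s["night_light"] = FactorSpec("night_light", 0.0, 63.0, FactorEffect(slope=0.04))
    s["lockdown_intensity"] = FactorSpec(
        "lockdown_intensity", 0.0, 1.0, FactorEffect(slope=0.12),
        seasonal_shift={"spring": 0.1, "summer": -0.05, "autumn": 0.0, "winter": 0.05},
    )
    return s


@dataclass(frozen=True)
class CityConfig:
    """Configuration of the synthetic city.

    Defaults are the reference study conditions: 300 communities in a
    30 x 30 km extent, two effect-sign regions, ~50 posts per community per
    season, latent noise SD 0.02.
    """

    n_communities: int = 300
    extent: tuple[float, float] = (30_000.0, 30_000.0)
    n_regions: int = 2
    cluster_strength: float = 0.6  # 0 = uniform communities, 1 = fully clustered
    post_rate: float = 50.0
    noise_sd: float = 0.02
    base_emotion: float = 0.14
    factor_specs: dict[str, FactorSpec] = field(default_factory=default_factor_specs)
    # negative_share_link: p_neg = link_max / (1 + exp(-(latent - link_mid)/link_scale))
    link_max: float = 0.6
    link_mid: float = 0.14
    link_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_communities < 10:
            raise ValueError("n_communities must be >= 10")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("extent must be positive")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.post_rate < 0:
            raise ValueError("post_rate must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for spec in self.factor_specs.values():
            for m in spec.effect.season_mult.values():
                if m <= 0:
                    raise ValueError("season multipliers must be positive")
        if set(self.factor_specs) != set(FACTORS):
            raise ValueError("factor_specs must cover exactly the 14 factors")

    def negative_share(self, latent: np.ndarray) -> np.ndarray:
        """Monotone map from latent emotion to P(post is negative)."""
        latent = np.asarray(latent, dtype=float)
        return self.link_max / (1.0 + np.exp(-(latent - self.link_mid) / self.link_scale))


@dataclass
class CityTruth:
    """The generating functions, retained for recovery tests."""

    factor_specs: dict[str, FactorSpec]
    base_emotion: float
    region_driver: tuple[str, ...]  # designated dominant factor per region
    sign_flip_factor: str  # factor whose effect sign differs by region
    threshold_factor: str  # factor with an effect-sign reversal at a threshold
    noise: dict[str, np.ndarray]  # realized noise per season

    def latent(
        self, covariates: pd.DataFrame, region: np.ndarray, season: str
    ) -> np.ndarray:
        """Noise-free latent emotion for arbitrary covariates."""
        total = np.full(len(covariates), self.base_emotion)
        for name, spec in self.factor_specs.items():
            total = total + spec.contribution(
                covariates[name].to_numpy(), region, season
            )
        return total

    def effect_sign(self, factor: str, region: int, season: str = "spring") -> float:
        """Sign of d latent / d factor for the (linear) factor in a region."""
        eff = self.factor_specs[factor].effect
        m = eff.region_mult[region % len(eff.region_mult)]
        return float(np.sign(eff.slope * m))


@dataclass
class SyntheticCity:
    config: CityConfig
    ids: list[str]
    centroids: np.ndarray  # (n, 2)
    polygons: list[shapely.Geometry]
    population: np.ndarray
    region_label: np.ndarray  # (n,) ints in [0, n_regions)
    covariates: dict[str, pd.DataFrame]  # season -> (n x 14) frame
    latent_emotion: dict[str, np.ndarray]  # season -> (n,)
    truth: CityTruth

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def extent(self) -> tuple[float, float]:
        return self.config.extent

    def community_polygons(self) -> dict[str, shapely.Geometry]:
        return dict(zip(self.ids, self.polygons))

    def populations(self) -> dict[str, float]:
        return dict(zip(self.ids, self.population.tolist()))

    def model_table(self, season: str) -> pd.DataFrame:
        """Covariates + latent emotion + coordinates for one season, or the
        across-season mean for season == "annual"."""
        if season == "annual":
            X = sum(self.covariates[s] for s in SEASONS) / len(SEASONS)
            y = np.mean([self.latent_emotion[s] for s in SEASONS], axis=0)
        else:
            X = self.covariates[season].copy()
            y = self.latent_emotion[season]
        out = X.copy()
        out["y"] = y
        out["coord_x"] = self.centroids[:, 0]
        out["coord_y"] = self.centroids[:, 1]
        out["region"] = self.region_label
        out.index = pd.Index(self.ids, name="community_id")
        return out


def _smooth_field(
    rng: np.random.Generator,
    xy: np.ndarray,
    extent: tuple[float, float],
    n_waves: int = 6,
) -> np.ndarray:
    """Smooth spatial surface: sum of random low-frequency cosines,
    standardized to mean 0 / SD 1 over the evaluation points."""
    scale = max(extent)
    out = np.zeros(len(xy))
    for _ in range(n_waves):
        wavelength = scale / rng.uniform(0.5, 3.0)
        theta = rng.uniform(0, 2 * np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        k = 2 * np.pi / wavelength * np.array([np.cos(theta), np.sin(theta)])
        out += rng.normal(0, 1) * np.cos(xy @ k + phase)
    sd = out.std()
    if sd > 0:
        out = (out - out.mean()) / sd
    return out


def _place_communities(
    rng: np.random.Generator, config: CityConfig
) -> np.ndarray:
    """Clustered (Thomas-like) point process: parents + Gaussian offspring,
    mixed with a uniform component."""
    w, h = config.extent
    n = config.n_communities
    n_parents = max(3, n // 40)
    parents = rng.uniform([0, 0], [w, h], size=(n_parents, 2))
    sigma = max(w, h) / 12
    pts = np.empty((n, 2))
    for i in range(n):
        if rng.uniform() < config.cluster_strength:
            p = parents[rng.integers(n_parents)]
            pts[i] = p + rng.normal(0, sigma, 2)
        else:
            pts[i] = rng.uniform([0, 0], [w, h])
    margin = min(w, h) * 0.01
    pts[:, 0] = np.clip(pts[:, 0], margin, w - margin)
    pts[:, 1] = np.clip(pts[:, 1], margin, h - margin)
    # nudge exact duplicates apart so Voronoi cells are well defined
    for i in range(1, n):
        while np.any(np.all(np.isclose(pts[:i], pts[i], atol=1e-6), axis=1)):
            pts[i] += rng.normal(0, margin, 2)
            pts[i] = np.clip(pts[i], margin, [w - margin, h - margin])
    return pts


def _voronoi_polygons(
    pts: np.ndarray, extent: tuple[float, float]
) -> list[shapely.Geometry]:
    env = box(0, 0, extent[0], extent[1])
    cells = voronoi_diagram(MultiPoint(pts.tolist()), envelope=env)
    clipped = [geom.intersection(env) for geom in cells.geoms]
    # voronoi_diagram returns cells in arbitrary order: match by containment
    out: list[shapely.Geometry] = [None] * len(pts)
    for geom in clipped:
        shapely.prepare(geom)
    for i, (x, y) in enumerate(pts):
        p = Point(x, y)
        for geom in clipped:
            if geom.covers(p):
                out[i] = geom
                break
        if out[i] is None:  # pragma: no cover - numeric edge case
            out[i] = p.buffer(1.0)
    return out


def generate_city(config: CityConfig) -> SyntheticCity:
    """Generate a city: a pure function of the config (and its seed)."""
    root = np.random.SeedSequence(config.seed)
    rng_place, rng_pop, rng_field, rng_noise = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    pts = _place_communities(rng_place, config)
    polygons = _voronoi_polygons(pts, config.extent)
    population = np.maximum(
        500.0, rng_pop.lognormal(mean=np.log(6000.0), sigma=0.6, size=config.n_communities)
    )

    # contiguous regions: nearest of n_regions centers spread along x
    w, h = config.extent
    centers = np.column_stack(
        [(np.arange(config.n_regions) + 0.5) / config.n_regions * w,
         np.full(config.n_regions, h / 2)]
    )
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    region_label = d2.argmin(axis=1)

    # covariate fields: one smooth regional surface per factor (+ seasonal
    # mean shifts for phenology-driven factors) + independent noise
    n = config.n_communities
    covariates: dict[str, pd.DataFrame] = {s: pd.DataFrame(index=range(n)) for s in SEASONS}
    for name in FACTORS:
        spec = config.factor_specs[name]
        base = _smooth_field(rng_field, pts, config.extent)
        span = spec.high - spec.low
        if name not in SEASONAL_FACTORS:
            frac = np.clip(0.5 + 0.22 * base + rng_noise.normal(0, 0.08, n), 0.0, 1.0)
            vals = spec.low + span * frac
            for season in SEASONS:
                covariates[season][name] = vals
        else:
            for season in SEASONS:
                shift = (spec.seasonal_shift or {}).get(season, 0.0)
                frac = np.clip(0.5 + 0.22 * base + rng_noise.normal(0, 0.08, n), 0.0, 1.0)
                vals = np.clip(spec.low + span * frac + shift, spec.low, spec.high)
                covariates[season][name] = vals

    truth = CityTruth(
        factor_specs=config.factor_specs,
        base_emotion=config.base_emotion,
        region_driver=("ndvi", "green_access"),
        sign_flip_factor="green_access",
        threshold_factor="ndvi",
        noise={},
    )
    latent: dict[str, np.ndarray] = {}
    for season in SEASONS:
        eps = rng_noise.normal(0, config.noise_sd, config.n_communities) \
            if config.noise_sd > 0 else np.zeros(config.n_communities)
        truth.noise[season] = eps
        latent[season] = truth.latent(covariates[season], region_label, season) + eps

    ids = [f"c{i:04d}" for i in range(config.n_communities)]
    for season in SEASONS:
        covariates[season].index = pd.Index(ids, name="community_id")
    return SyntheticCity(
        config=config,
        ids=ids,
        centroids=pts,
        polygons=polygons,
        population=population,
        region_label=region_label,
        covariates=covariates,
        latent_emotion=latent,
        truth=truth,
    )


def _sample_in_polygon(
    rng: np.random.Generator, poly: shapely.Geometry, n: int
) -> np.ndarray:
    """Uniform points inside a polygon via bounding-box rejection."""
    minx, miny, maxx, maxy = poly.bounds
    shapely.prepare(poly)
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(16, 2 * (n - got))
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(m, 2))
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        take = cand[inside][: n - got]
        out[got : got + len(take)] = take
        got += len(take)
    return out


def _random_season_timestamp(rng: np.random.Generator, season: str) -> datetime:
    month = int(rng.choice(_SEASON_MONTHS[season]))
    n_days = calendar.monthrange(STUDY_YEAR, month)[1]
    day = int(rng.integers(1, n_days + 1))
    return datetime(STUDY_YEAR, month, day) + timedelta(
        seconds=int(rng.integers(0, 86_400))
    )


def generate_posts(city: SyntheticCity, season: str, seed: int = 0) -> list[GeoPost]:
    """Geotagged posts for one season.

    Per community the post count is Poisson(post_rate * pop / mean_pop);
    locations are uniform within the community polygon; the sentiment is
    negative with probability ``negative_share(latent)``, otherwise an even
    split of positive/neutral.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    rng = np.random.default_rng(np.random.SeedSequence([city.config.seed, seed, SEASONS.index(season)]))
    cfg = city.config
    mean_pop = float(city.population.mean())
    p_neg = cfg.negative_share(city.latent_emotion[season])
    posts: list[GeoPost] = []
    for i, cid in enumerate(city.ids):
        lam = cfg.post_rate * city.population[i] / mean_pop
        count = int(rng.poisson(lam)) if lam > 0 else 0
        if count == 0:
            continue
        xy = _sample_in_polygon(rng, city.polygons[i], count)
        is_neg = rng.uniform(size=count) < p_neg[i]
        pos_or_neu = rng.uniform(size=count) < 0.5
        for k in range(count):
            sentiment = "negative" if is_neg[k] else ("positive" if pos_or_neu[k] else "neutral")
            posts.append(
                GeoPost(
                    id=f"{season}-{cid}-{k:04d}",
                    x=float(xy[k, 0]),
                    y=float(xy[k, 1]),
                    timestamp=_random_season_timestamp(rng, season),
                    sentiment=sentiment,
                )
            )
    return posts


def generate_landuse(
    city: SyntheticCity,
    n_classes: int,
    cell_size: float,
    seed: int = 0,
    proportions: tuple[float, ...] | None = None,
) -> Raster:
    """Integer land-use class raster covering the extent.

    Classes are quantile bands of a smooth random surface, so each class is
    spatially coherent (at least one contiguous patch) and realized class
    proportions match the requested ones closely on fine grids.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    w, h = city.extent
    if cell_size > w or cell_size > h:
        raise ValueError("cell size larger than extent")
    if proportions is None:
        proportions = tuple(1.0 / n_classes for _ in range(n_classes))
    if len(proportions) != n_classes or not np.isclose(sum(proportions), 1.0):
        raise ValueError("proportions must have n_classes entries summing to 1")

    rng = np.random.default_rng(np.random.SeedSequence([city.config.seed, seed, 11]))
    spec = GridSpec.from_extent(0.0, 0.0, w, h, cell_size)
    X, Y = spec.cell_centers()
    xy = np.column_stack([X.ravel(), Y.ravel()])
    fld = _smooth_field(rng, xy, city.extent, n_waves=8)
    ranks = fld.argsort().argsort() / max(len(fld) - 1, 1)  # uniform [0,1]
    edges = np.cumsum(proportions)[:-1]
    classes = np.searchsorted(edges, ranks, side="right").astype(np.int32)
    return Raster(values=classes.reshape(spec.n_rows, spec.n_cols), spec=spec)


@dataclass
class ReflectanceScene:
    nir: Raster
    red: Raster
    vegetated_mask: np.ndarray  # boolean, same grid


def generate_reflectance(
    city: SyntheticCity, cell_size: float, seed: int = 0
) -> ReflectanceScene:
    """Two-band (NIR, Red) reflectance rasters in [0, 1].

    Inside the vegetated zones (smooth-surface threshold) NIR is elevated
    over Red so the derived vegetation index is positive there.
    """
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    w, h = city.extent
    rng = np.random.default_rng(np.random.SeedSequence([city.config.seed, seed, 12]))
    spec = GridSpec.from_extent(0.0, 0.0, w, h, cell_size)
    X, Y = spec.cell_centers()
    xy = np.column_stack([X.ravel(), Y.ravel()])
    fld = _smooth_field(rng, xy, city.extent, n_waves=8).reshape(spec.n_rows, spec.n_cols)
    veg = fld > 0.0

    noise = rng.normal(0, 0.02, size=(2, spec.n_rows, spec.n_cols))
    nir = np.where(veg, 0.55 + 0.1 * fld, 0.30) + noise[0]
    red = np.where(veg, 0.12, 0.28) + noise[1]
    return ReflectanceScene(
        nir=Raster(values=np.clip(nir, 0.0, 1.0), spec=spec),
        red=Raster(values=np.clip(red, 0.0, 1.0), spec=spec),
        vegetated_mask=veg,
    )
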