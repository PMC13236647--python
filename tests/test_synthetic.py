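import numpy as np
import pytest
import shapely

from greenmood.emotions import SEASONS, assign_season
from greenmood.indicators import ndvi
from greenmood.synthetic import (
    FACTORS,
    CityConfig,
    FactorEffect,
    FactorSpec,
    default_factor_specs,
    generate_city,
    generate_landuse,
    generate_posts,
    generate_reflectance,
)


@pytest.fixture(scope="module")
def small_city():
    return generate_city(
        CityConfig(n_communities=40, extent=(8_000.0, 8_000.0), post_rate=30.0, seed=5)
    )


def test_city_is_deterministic():
    a = generate_city(CityConfig(n_communities=30, seed=2))
    b = generate_city(CityConfig(n_communities=30, seed=2))
    c = generate_city(CityConfig(n_communities=30, seed=3))
    for s in SEASONS:
        assert a.covariates[s].equals(b.covariates[s])
        assert np.array_equal(a.latent_emotion[s], b.latent_emotion[s])
    assert not np.array_equal(a.latent_emotion["spring"], c.latent_emotion["spring"])


def test_polygons_partition_extent(small_city):
    total = sum(p.area for p in small_city.polygons)
    assert total == pytest.approx(8_000.0 * 8_000.0, rel=1e-6)
    for pt, poly in zip(small_city.centroids, small_city.polygons):
        assert poly.covers(shapely.Point(pt))


def test_two_contiguous_regions(small_city):
    region = small_city.region_label
    x = small_city.centroids[:, 0]
    assert set(region.tolist()) == {0, 1}
    assert (x[region == 0] <= 4_000.0 + 1e-9).all()
    assert (x[region == 1] >= 4_000.0 - 1e-9).all()


def test_covariates_within_declared_ranges(small_city):
    specs = small_city.config.factor_specs
    for s in SEASONS:
        cov = small_city.covariates[s]
        assert list(cov.columns) == list(FACTORS)
        for name in FACTORS:
            assert cov[name].between(specs[name].low, specs[name].high).all()


def test_latent_equals_truth_plus_noise(small_city):
    for s in SEASONS:
        clean = small_city.truth.latent(
            small_city.covariates[s], small_city.region_label, s
        )
        assert np.allclose(
            small_city.latent_emotion[s], clean + small_city.truth.noise[s]
        )


def test_model_table_annual_is_season_mean(small_city):
    tbl = small_city.model_table("annual")
    manual = sum(small_city.covariates[s]["ndvi"] for s in SEASONS) / 4
    assert np.allclose(tbl["ndvi"].to_numpy(), manual.to_numpy())
    y_manual = np.mean([small_city.latent_emotion[s] for s in SEASONS], axis=0)
    assert np.allclose(tbl["y"].to_numpy(), y_manual)
    assert {"coord_x", "coord_y", "region"} <= set(tbl.columns)


def test_region_sign_flip_by_finite_difference(small_city):
    """Raising green-space accessibility lowers latent negative emotion in
    one region and raises it in the other."""
    truth = small_city.truth
    region = small_city.region_label
    cov = small_city.covariates["spring"]
    bumped = cov.copy()
    bumped["green_access"] = bumped["green_access"] + 1.0
    delta = truth.latent(bumped, region, "spring") - truth.latent(cov, region, "spring")
    assert (delta[region == 0] > 0).all()
    assert (delta[region == 1] < 0).all()
    assert truth.effect_sign("green_access", 0) == 1.0
    assert truth.effect_sign("green_access", 1) == -1.0


def test_threshold_effect_is_continuous_and_reverses():
    spec = default_factor_specs()["ndvi"]
    region = np.zeros(1, dtype=int)
    below = spec.contribution(np.array([0.5 - 1e-9]), region, "spring")
    above = spec.contribution(np.array([0.5 + 1e-9]), region, "spring")
    assert below[0] == pytest.approx(above[0], abs=1e-8)
    low = spec.contribution(np.array([0.3]), region, "spring")
    high = spec.contribution(np.array([0.7]), region, "spring")
    at = spec.contribution(np.array([0.5]), region, "spring")
    assert low[0] > at[0] < high[0]  # valley at the threshold


def test_posts_deterministic_and_in_season(small_city):
    p1 = generate_posts(small_city, "summer", seed=9)
    p2 = generate_posts(small_city, "summer", seed=9)
    assert [p.id for p in p1] == [p.id for p in p2]
    assert np.allclose([p.x for p in p1], [p.x for p in p2])
    assert all(assign_season(p.timestamp) == "summer" for p in p1)
    assert all(p.timestamp.year == 2022 for p in p1)


def test_posts_inside_their_community(small_city):
    posts = generate_posts(small_city, "spring", seed=2)
    polys = small_city.community_polygons()
    for p in posts[:200]:
        cid = p.id.split("-")[1]
        assert polys[cid].buffer(1e-6).covers(shapely.Point(p.x, p.y))


def test_negative_share_matches_binomial_expectation(small_city):
    posts = generate_posts(small_city, "spring", seed=2)
    counts: dict[str, int] = {}
    negs: dict[str, int] = {}
    for p in posts:
        cid = p.id.split("-")[1]
        counts[cid] = counts.get(cid, 0) + 1
        if p.sentiment == "negative":
            negs[cid] = negs.get(cid, 0) + 1
    p_neg = small_city.config.negative_share(small_city.latent_emotion["spring"])
    total = sum(negs.get(i, 0) for i in small_city.ids)
    expected = sum(
        counts.get(i, 0) * p_neg[k] for k, i in enumerate(small_city.ids)
    )
    var = sum(
        counts.get(i, 0) * p_neg[k] * (1 - p_neg[k])
        for k, i in enumerate(small_city.ids)
    )
    assert abs(total - expected) <= 3.0 * np.sqrt(var)


def test_landuse_classes_and_proportions(small_city):
    raster = generate_landuse(small_city, 4, 80.0, seed=1)
    vals = raster.values
    assert set(np.unique(vals).tolist()) == {0, 1, 2, 3}
    props = np.bincount(vals.ravel(), minlength=4) / vals.size
    assert np.allclose(props, 0.25, atol=0.01)
    again = generate_landuse(small_city, 4, 80.0, seed=1)
    assert np.array_equal(vals, again.values)
    with pytest.raises(ValueError):
        generate_landuse(small_city, 0, 80.0)
    with pytest.raises(ValueError):
        generate_landuse(small_city, 2, 80.0, proportions=(0.9, 0.2))


def test_reflectance_supports_vegetation_index(small_city):
    scene = generate_reflectance(small_city, 80.0, seed=1)
    for band in (scene.nir, scene.red):
        assert band.values.min() >= 0.0 and band.values.max() <= 1.0
    vi = ndvi(scene.nir, scene.red).values
    assert vi[scene.vegetated_mask].mean() > 0.3
    assert vi[scene.vegetated_mask].mean() > vi[~scene.vegetated_mask].mean()


def test_config_validation():
    with pytest.raises(ValueError):
        CityConfig(n_communities=5)
    with pytest.raises(ValueError):
        CityConfig(extent=(-1.0, 100.0))
    with pytest.raises(ValueError):
        CityConfig(post_rate=-1.0)
    with pytest.raises(ValueError):
        CityConfig(noise_sd=-0.1)
    with pytest.raises(ValueError):
        CityConfig(factor_specs={"ndvi": default_factor_specs()["ndvi"]})
    bad = default_factor_specs()
    bad["gvi"] = FactorSpec(
        "gvi", 0.0, 1.0,
        FactorEffect(slope=1.0, season_mult={s: 0.0 for s in SEASONS}),
    )
    with pytest.raises(ValueError):
        CityConfig(factor_specs=bad)


def test_negative_share_is_monotone_and_bounded():
    cfg = CityConfig()
    latent = np.linspace(-1.0, 1.0, 50)
    p = cfg.negative_share(latent)
    assert (np.diff(p) > 0).all()
    assert (p > 0).all() and (p < cfg.link_max).all()
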