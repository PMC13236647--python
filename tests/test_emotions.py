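from datetime import datetime

import numpy as np
import pytest
from shapely.geometry import box

from greenmood.emotions import (
    GeoPost,
    assign_season,
    classification_metrics,
    community_emotion_index,
    kde_surface,
    negative_events,
)
from greenmood.grids import GridSpec, Raster


def _post(pid, x, y, ts, sentiment):
    return GeoPost(id=pid, x=x, y=y, timestamp=ts, sentiment=sentiment)


def test_assign_season_goldens():
    assert assign_season(datetime(2022, 3, 1)) == "spring"
    assert assign_season(datetime(2022, 5, 31)) == "spring"
    assert assign_season(datetime(2022, 6, 1)) == "summer"
    assert assign_season(datetime(2022, 11, 30)) == "autumn"
    assert assign_season(datetime(2022, 12, 1)) == "winter"
    assert assign_season("2022-02-28") == "winter"
    with pytest.raises(ValueError):
        assign_season("not-a-date")


def test_negative_events_filters_sentiment_and_season():
    posts = [
        _post("a", 0.0, 0.0, datetime(2022, 4, 1), "negative"),
        _post("b", 1.0, 1.0, datetime(2022, 4, 2), "positive"),
        _post("c", 2.0, 2.0, datetime(2022, 7, 1), "negative"),
    ]
    ev = negative_events(posts, "spring")
    assert ev.shape == (1, 2)
    assert np.allclose(ev[0], [0.0, 0.0])
    assert negative_events(posts, "winter").shape == (0, 2)
    with pytest.raises(ValueError):
        negative_events(posts, "monsoon")


def test_kde_center_value_is_three_over_pi():
    spec = GridSpec(x0=0.0, y0=0.0, cell_size=1.0, n_cols=21, n_rows=21)
    surf = kde_surface(np.array([[10.5, 10.5]]), spec, bandwidth=1.0)
    assert surf.values[10, 10] == pytest.approx(3.0 / np.pi, abs=1e-12)


def test_kde_mass_and_symmetry():
    spec = GridSpec.from_extent(0.0, 0.0, 4000.0, 4000.0, 25.0)
    surf = kde_surface(np.array([[2000.0, 2000.0]]), spec, bandwidth=500.0)
    assert surf.total_mass() == pytest.approx(1.0, abs=0.01)
    v = surf.values
    assert np.allclose(v, v[::-1, :])  # north-south symmetric
    assert np.allclose(v, v[:, ::-1])  # west-east symmetric


def test_kde_kernels_normalize():
    spec = GridSpec.from_extent(0.0, 0.0, 4000.0, 4000.0, 25.0)
    events = np.array([[1700.0, 2100.0], [2300.0, 1800.0]])
    for kernel, bw in [("quartic", 500.0), ("gaussian", 300.0), ("uniform", 500.0)]:
        surf = kde_surface(events, spec, bandwidth=bw, kernel=kernel)
        assert surf.total_mass() == pytest.approx(1.0, abs=0.01), kernel


def test_kde_error_contracts():
    spec = GridSpec.from_extent(0.0, 0.0, 100.0, 100.0, 10.0)
    with pytest.raises(ValueError):
        kde_surface(np.empty((0, 2)), spec)
    with pytest.raises(ValueError):
        kde_surface(np.array([[1.0, 1.0]]), spec, bandwidth=0.0)
    with pytest.raises(ValueError):
        kde_surface(np.array([[1.0, 1.0]]), spec, kernel="cubic")


def _constant_surface(value=2.0):
    spec = GridSpec(0.0, 0.0, 10.0, 10, 10)
    from greenmood.emotions import DensitySurface

    return DensitySurface(
        raster=Raster(values=np.full((10, 10), value), spec=spec),
        bandwidth=1.0,
        kernel="quartic",
        n_events=1,
    )


def test_community_index_population_standardization():
    surf = _constant_surface(2.0)
    out = community_emotion_index(
        surf, {"c1": box(20, 20, 60, 60)}, {"c1": 5000.0}, "spring"
    )
    assert len(out) == 1
    assert out[0].raw_density == pytest.approx(2.0)
    # 2.0 density / (5000 residents / 10,000) = 4.0
    assert out[0].index == pytest.approx(4.0)


def test_community_index_tiny_polygon_fallback():
    surf = _constant_surface(3.0)
    tiny = box(10.5, 10.5, 12.0, 12.0)  # between cell centers: covers none
    with pytest.raises(ValueError, match="tiny"):
        community_emotion_index(surf, {"tiny": tiny}, {"tiny": 1000.0}, "spring")
    out = community_emotion_index(
        surf, {"tiny": tiny}, {"tiny": 1000.0}, "spring", centroid_fallback=True
    )
    assert out[0].raw_density == pytest.approx(3.0)


def test_community_index_rejects_bad_population():
    surf = _constant_surface()
    with pytest.raises(ValueError):
        community_emotion_index(surf, {"c": box(0, 0, 50, 50)}, {"c": 0.0}, "spring")


def test_classification_metrics_hand_example():
    true = ["negative", "negative", "positive", "positive"]
    pred = ["negative", "positive", "positive", "positive"]
    rep = classification_metrics(true, pred)
    assert rep.accuracy == pytest.approx(0.75)
    assert rep.precision["negative"] == pytest.approx(1.0)
    assert rep.recall["negative"] == pytest.approx(0.5)
    assert rep.f1["negative"] == pytest.approx(2.0 / 3.0)
    assert rep.confusion.shape == (3, 3)
    with pytest.raises(ValueError):
        classification_metrics(["negative"], ["negative", "positive"])
    with pytest.raises(ValueError):
        classification_metrics(["negative"], ["angry"])


def test_indicator_recovers_generating_intensity():
    """On a low-clustering city, the KDE indicator ranks communities like
    the generator's expected value (negative share over footprint area)."""
    from scipy.stats import spearmanr

    from greenmood.synthetic import CityConfig, generate_city, generate_posts

    cfg = CityConfig(
        n_communities=80, extent=(12_000.0, 12_000.0), cluster_strength=0.0,
        post_rate=80.0, noise_sd=0.02, seed=3,
    )
    city = generate_city(cfg)
    posts = generate_posts(city, "spring", seed=1)
    events = negative_events(posts, "spring")
    grid = GridSpec.from_extent(0.0, 0.0, 12_000.0, 12_000.0, 100.0)
    surf = kde_surface(events, grid, bandwidth=400.0)
    out = community_emotion_index(
        surf, city.community_polygons(), city.populations(), "spring",
        centroid_fallback=True,
    )
    index = np.array([e.index for e in out])
    p_neg = cfg.negative_share(city.latent_emotion["spring"])
    areas = np.array([p.area for p in city.polygons])
    rho, _ = spearmanr(index, p_neg / areas)
    assert rho >= 0.9
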