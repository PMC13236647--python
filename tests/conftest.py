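"""Shared fixtures: the reference synthetic city, a fitted GWRF, toy
spatial frames, and a reduced end-to-end pipeline run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from greenmood.models import ForestParams, ModelFrame, fit_gwrf
from greenmood.synthetic import CityConfig, generate_city


@pytest.fixture(scope="session")
def city11():
    """The reference two-region city: default conditions, seed 11."""
    return generate_city(CityConfig(seed=11))


@pytest.fixture(scope="session")
def annual_frame(city11):
    return ModelFrame.from_table(city11.model_table("annual"))


@pytest.fixture(scope="session")
def gwrf_annual(annual_frame):
    """GWRF on the reference city: adaptive bandwidth 80, 100 trees."""
    return fit_gwrf(
        annual_frame, 80, params=ForestParams(n_trees=100), seed=5,
        collect_oob=False,
    )


@pytest.fixture(scope="session")
def off_boundary(city11, gwrf_annual):
    """Communities whose neighborhoods are >= 90% within their own region;
    recovery claims apply away from the region boundary."""
    region = city11.region_label
    return np.array(
        [
            float((region[idx] == region[i]).mean()) >= 0.9
            for i, idx in enumerate(gwrf_annual.neighbors)
        ]
    )


@pytest.fixture(scope="session")
def toy_linear_frame():
    """60 communities, y = 1 + 2a + tiny noise: a spatially homogeneous
    linear ground truth for effect-surface and dominance checks."""
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
    y = 1.0 + 2.0 * X["a"].to_numpy() + rng.normal(0, 0.01, n)
    return ModelFrame(X=X, y=y, coords=coords)


@pytest.fixture(scope="session")
def toy_gwrf(toy_linear_frame):
    return fit_gwrf(
        toy_linear_frame, 40, params=ForestParams(n_trees=30), seed=1,
        collect_oob=False,
    )


def reduced_config(out_dir) -> dict:
    """A small but complete pipeline configuration (fast problem size)."""
    return {
        "mode": "synthetic",
        "seed": 7,
        "output_dir": str(out_dir),
        "city": {
            "n_communities": 60,
            "extent_width": 12_000.0,
            "extent_height": 12_000.0,
            "post_rate": 30.0,
        },
        "kde": {"bandwidth": 800.0, "cell_size": 150.0},
        "autocorr": {"n_perm": 99},
        "model": {"bandwidth": 40, "n_trees": 25, "eval_mode": "in_sample"},
        "explain": {
            "n_samples": 16,
            "background_size": 8,
            "obs_per_community": 4,
            "pdp_grid_size": 8,
        },
    }


@pytest.fixture(scope="session")
def pipeline_rerun(tmp_path_factory):
    """Run the reduced pipeline twice with the identical config (same
    output directory), snapshotting all first-run outputs in between.

    Returns (out_dir, first_manifest, second_manifest, first_bytes) where
    first_bytes maps output file name -> bytes after the first run.
    """
    from greenmood.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    cfg = reduced_config(out)
    m1 = run_pipeline(cfg)
    snapshot = {
        name: (out / name).read_bytes()
        for name in m1.outputs
        if name != "manifest.json"
    }
    m2 = run_pipeline(cfg)
    return out, m1, m2, snapshot
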