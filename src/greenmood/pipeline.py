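"""Config-driven orchestration of the full study design.

Stage order mirrors the analysis framework: data generation/ingestion →
emotion indicator construction → spatial autocorrelation → model fitting
and comparison → Shapley/PDP interpretation. Every stage seed derives from
the master seed, all outputs are flat files, and a machine-readable
manifest records config hash, seeds, input fingerprints, outputs and
per-stage wall time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import explain as ex
from . import io as gio
from .autocorr import build_weights, global_morans_i, local_morans_i
from .config import RunConfig, validate_config
from .emotions import SEASONS, community_emotion_index, kde_surface, negative_events
from .grids import GridSpec
from .models import ForestParams, ModelFrame, compare_models, fit_global_rf, fit_gwrf
from .synthetic import CityConfig, SyntheticCity, generate_city, generate_posts

__all__ = ["StageError", "RunManifest", "run_pipeline", "run_pipeline_from_yaml"]

logger = logging.getLogger("greenmood")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunManifest:
    config_hash: str
    schema_version: int
    package_version: str
    seeds: dict[str, int]
    input_fingerprints: dict[str, str]
    outputs: list[str] = field(default_factory=list)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    def comparable(self) -> dict:
        """Manifest content excluding wall times."""
        d = dict(self.__dict__)
        d.pop("stage_seconds")
        return d


def _config_hash(resolved: dict) -> str:
    return hashlib.sha256(
        json.dumps(resolved, sort_keys=True).encode()
    ).hexdigest()


def _fingerprint_file(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _city_from_config(cfg: RunConfig) -> SyntheticCity:
    c = cfg["city"]
    return generate_city(
        CityConfig(
            n_communities=c["n_communities"],
            extent=(c["extent_width"], c["extent_height"]),
            n_regions=c["n_regions"],
            cluster_strength=c["cluster_strength"],
            post_rate=c["post_rate"],
            noise_sd=c["noise_sd"],
            seed=cfg.stage_seeds["city"],
        )
    )


def run_pipeline(config: RunConfig | dict) -> RunManifest:
    """Execute the full pipeline; returns the manifest (also written to the
    output directory). Any stage failure raises :class:`StageError` naming
    the stage."""
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seasons = list(config["seasons"])
    scenarios = seasons + ["annual"]

    manifest = RunManifest(
        config_hash=_config_hash(config.resolved),
        schema_version=config.schema_version,
        package_version=_package_version(),
        seeds=dict(config.stage_seeds),
        input_fingerprints={},
    )
    (out_dir / "resolved_config.json").write_text(
        json.dumps(config.resolved, indent=2, sort_keys=True)
    )
    manifest.outputs.append("resolved_config.json")

    def _record(name: str) -> Path:
        manifest.outputs.append(name)
        return out_dir / name

    # ------------------------------------------------------------------ data
    t0 = time.perf_counter()
    try:
        if config["mode"] == "synthetic":
            city = _city_from_config(config)
            manifest.input_fingerprints["synthetic_city"] = _config_hash(
                {"city": config["city"], "seed": config.stage_seeds["city"]}
            )
            communities = city.community_polygons()
            populations = city.populations()
            posts_by_season = {
                s: generate_posts(city, s, seed=config.stage_seeds["posts"])
                for s in seasons
            }
            covariates = {s: city.covariates[s] for s in seasons}
            gio.write_communities_geojson(
                city.ids,
                city.polygons,
                {"population": city.population.tolist(),
                 "region": city.region_label.tolist()},
                _record("communities.geojson"),
            )
            for s in seasons:
                covariates[s].to_csv(_record(f"covariates_{s}.csv"))
                gio.write_posts_csv(posts_by_season[s], _record(f"posts_{s}.csv"))
            extent = city.extent
        else:
            files = config["files"]
            for key, path in files.items():
                manifest.input_fingerprints[key] = _fingerprint_file(path)
            ids, polys, props = gio.read_communities_geojson(files["communities"])
            communities = dict(zip(ids, polys))
            populations = {i: float(p) for i, p in props["population"].items()}
            all_posts = gio.read_posts_csv(files["posts"])
            from .emotions import assign_season

            posts_by_season = {
                s: [p for p in all_posts if assign_season(p.timestamp) == s]
                for s in seasons
            }
            cov_long = pd.read_csv(files["covariates"])
            covariates = {
                s: cov_long[cov_long["season"] == s]
                .drop(columns="season")
                .set_index("community_id")
                for s in seasons
            }
            extent = (
                max(p.bounds[2] for p in polys),
                max(p.bounds[3] for p in polys),
            )
    except Exception as err:  # noqa: BLE001
        raise StageError("data", err) from err
    manifest.stage_seconds["data"] = time.perf_counter() - t0
    logger.info("data stage done (%.1fs)", manifest.stage_seconds["data"])

    # ------------------------------------------------------- emotion indicator
    t0 = time.perf_counter()
    try:
        kde_cfg = config["kde"]
        grid = GridSpec.from_extent(0.0, 0.0, extent[0], extent[1], kde_cfg["cell_size"])
        index_by_scenario: dict[str, pd.Series] = {}
        all_rows = []
        for scen in scenarios:
            if scen == "annual":
                events = np.vstack(
                    [negative_events(posts_by_season[s], s) for s in seasons]
                )
            else:
                events = negative_events(posts_by_season[scen], scen)
            if len(events) == 0:
                raise ValueError(f"no negative posts in scenario {scen!r}")
            surface = kde_surface(
                events, grid, bandwidth=kde_cfg["bandwidth"], kernel=kde_cfg["kernel"]
            )
            indicators = community_emotion_index(
                surface, communities, populations, scen, centroid_fallback=True
            )
            index_by_scenario[scen] = pd.Series(
                {e.community_id: e.index for e in indicators}, name="index"
            )
            all_rows.extend(indicators)
        gio.write_indicators_csv(all_rows, _record("emotion_indicators.csv"))
    except Exception as err:  # noqa: BLE001
        raise StageError("emotion_indicator", err) from err
    manifest.stage_seconds["emotion_indicator"] = time.perf_counter() - t0

    # --------------------------------------------------- spatial autocorrelation
    t0 = time.perf_counter()
    try:
        ids = list(communities.keys())
        cents = np.array(
            [[communities[i].centroid.x, communities[i].centroid.y] for i in ids]
        )
        W = build_weights(
            cents, k=config["weights"]["k"],
            row_standardize=config["weights"]["row_standardize"],
        )
        ac = config["autocorr"]
        rows = []
        lisa_annual = None
        for scen in scenarios:
            vals = index_by_scenario[scen].reindex(ids).to_numpy()
            mi = global_morans_i(vals, W, n_perm=ac["n_perm"], seed=config.stage_seeds["autocorr"])
            li = local_morans_i(
                vals, W, alpha=ac["alpha"], n_perm=ac["n_perm"],
                seed=config.stage_seeds["autocorr"],
            )
            rows.append({"scenario": scen, "morans_i": mi.I, "expected": mi.expected,
                         "p_perm": mi.p_perm})
            if scen == "annual":
                lisa_annual = li
        pd.DataFrame(rows).to_csv(_record("morans_i.csv"), index=False)
        pd.DataFrame(
            {"community_id": ids, "local_i": lisa_annual.local_i,
             "p_perm": lisa_annual.p_perm, "lisa_class": lisa_annual.classes}
        ).to_csv(_record("lisa_annual.csv"), index=False)
    except Exception as err:  # noqa: BLE001
        raise StageError("spatial_autocorr", err) from err
    manifest.stage_seconds["spatial_autocorr"] = time.perf_counter() - t0

    # ------------------------------------------------------------------ models
    t0 = time.perf_counter()
    try:
        m = config["model"]
        params = ForestParams(
            n_trees=m["n_trees"], max_depth=m["max_depth"], min_leaf=m["min_leaf"]
        )
        frames: dict[str, ModelFrame] = {}
        for scen in scenarios:
            X = (
                sum(covariates[s] for s in seasons) / len(seasons)
                if scen == "annual"
                else covariates[scen]
            )
            X = X.reindex(ids)
            missing = X.index[X.isna().any(axis=1)].tolist()
            if missing:
                raise ValueError(f"missing covariates for communities: {missing}")
            y = index_by_scenario[scen].reindex(ids).to_numpy()
            frames[scen] = ModelFrame(X=X, y=y, coords=cents, season=scen)
            tbl = X.copy()
            tbl["y"] = y
            tbl["coord_x"] = cents[:, 0]
            tbl["coord_y"] = cents[:, 1]
            tbl.to_csv(_record(f"model_frame_{scen}.csv"))
        seed_m = config.stage_seeds["models"]
        bw = min(m["bandwidth"], frames["annual"].n)
        comparison = compare_models(
            frames, bandwidth=bw, kernel=m["kernel"], params=params,
            seed=seed_m, eval_mode=m["eval_mode"], n_folds=m["n_folds"],
            min_local_sample=min(m["min_local_sample"], frames["annual"].n),
        )
        comparison.to_csv(_record("model_comparison.csv"), index=False)
        gwrf_annual = fit_gwrf(
            frames["annual"], bw, kernel=m["kernel"], params=params,
            seed=seed_m, min_local_sample=min(m["min_local_sample"], frames["annual"].n),
            collect_oob=False,
        )
        meta = pd.DataFrame(
            {"community_id": ids, "bandwidth_neighbors": bw,
             "bandwidth_distance": gwrf_annual.bandwidth_dist}
        )
        meta.to_csv(_record("gwrf_metadata.csv"), index=False)
    except Exception as err:  # noqa: BLE001
        raise StageError("models", err) from err
    manifest.stage_seconds["models"] = time.perf_counter() - t0

    # ----------------------------------------------------------------- explain
    t0 = time.perf_counter()
    try:
        ecfg = config["explain"]
        seed_e = config.stage_seeds["explain"]
        rng = np.random.default_rng(seed_e)
        pdp_rows = []
        for scen in scenarios:
            frame = frames[scen]
            rf = fit_global_rf(frame, params, seed_m)
            Xmat = frame.X.to_numpy()
            bg_n = min(len(Xmat), max(ecfg["background_size"], 16))
            bg = Xmat[rng.choice(len(Xmat), bg_n, replace=False)]
            phi = ex.shapley_matrix(
                rf.predict, Xmat, bg, n_samples=ecfg["n_samples"],
                seed=int(rng.integers(2**31)),
            )
            attr = ex.ShapleyAttribution(
                phi=pd.DataFrame(phi, index=frame.X.index, columns=frame.factor_names),
                baseline=float(rf.predict(bg).mean()),
                background=bg,
                method="sampled",
                n_samples=ecfg["n_samples"],
                seed=seed_e,
            )
            ranking = ex.global_importance(attr, factor_order=frame.factor_names)
            ranking.table.to_csv(_record(f"importance_{scen}.csv"))
            for factor in ecfg["pdp_factors"]:
                curve = ex.partial_dependence(
                    rf.predict, frame.X, factor,
                    grid_size=ecfg["pdp_grid_size"], season=scen,
                )
                for g, mu, sd in zip(curve.grid, curve.mean, curve.band):
                    pdp_rows.append(
                        {"factor": factor, "scenario": scen, "grid": g,
                         "value": mu, "band": sd}
                    )
        pd.DataFrame(pdp_rows).to_csv(_record("pdp_curves.csv"), index=False)

        dom = ex.local_dominant_factors(
            gwrf_annual, frames["annual"],
            background_size=ecfg["background_size"],
            obs_per_community=ecfg["obs_per_community"],
            n_samples=ecfg["n_samples"], seed=seed_e,
        )
        dom.shares.rename("share_pct").to_csv(_record("dominant_factor_shares.csv"))
        gio.write_communities_geojson(
            ids, [communities[i] for i in ids],
            {"dominant_factor": [dom.dominant[i] for i in ids]},
            _record("dominant_factors.geojson"),
        )
        eff = ex.local_effect_surface(gwrf_annual, frames["annual"], ecfg["effect_factor"])
        eff.to_csv(_record(f"local_effect_{ecfg['effect_factor']}.csv"))
    except Exception as err:  # noqa: BLE001
        raise StageError("explain", err) from err
    manifest.stage_seconds["explain"] = time.perf_counter() - t0

    manifest.to_json(out_dir / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("greenmood")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_pipeline_from_yaml(path: str | Path) -> RunManifest:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    return run_pipeline(raw)
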