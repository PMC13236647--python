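"""Run configuration: schema, validation, defaults and seed derivation.

``validate_config`` checks a raw mapping (e.g. parsed YAML) against the
published schema, rejects unknown keys with a did-you-mean suggestion,
collects *all* violations rather than stopping at the first, and
materializes every default into the resolved config so a run manifest is
self-describing.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["SCHEMA_VERSION", "RunConfig", "ConfigError", "validate_config"]

SCHEMA_VERSION = 1

# schema entry: (type, default, allowed) — default REQUIRED marks a
# mandatory field; allowed is an optional set of permitted values.
REQUIRED = object()

_SCHEMA: dict[str, Any] = {
    "mode": (str, REQUIRED, {"synthetic", "files"}),
    "seed": (int, REQUIRED, None),
    "output_dir": (str, REQUIRED, None),
    "seasons": (list, ["spring", "summer", "autumn", "winter"], None),
    "city": {
        "n_communities": (int, 300, None),
        "extent_width": (float, 30_000.0, None),
        "extent_height": (float, 30_000.0, None),
        "n_regions": (int, 2, None),
        "cluster_strength": (float, 0.6, None),
        "post_rate": (float, 50.0, None),
        "noise_sd": (float, 0.02, None),
    },
    "kde": {
        "bandwidth": (float, 1000.0, None),
        "cell_size": (float, 150.0, None),
        "kernel": (str, "quartic", {"quartic", "gaussian", "uniform"}),
    },
    "weights": {
        "k": (int, 8, None),
        "row_standardize": (bool, True, None),
    },
    "autocorr": {
        "n_perm": (int, 999, None),
        "alpha": (float, 0.05, None),
    },
    "model": {
        "bandwidth": (int, 80, None),
        "kernel": (str, "bisquare", {"bisquare", "gaussian", "uniform"}),
        "n_trees": (int, 100, None),
        "max_depth": (int, None, None),
        "min_leaf": (int, 3, None),
        "min_local_sample": (int, 30, None),
        "eval_mode": (str, "spatial_cv", {"spatial_cv", "in_sample", "out_of_bag"}),
        "n_folds": (int, 5, None),
    },
    "explain": {
        "n_samples": (int, 48, None),
        "background_size": (int, 16, None),
        "obs_per_community": (int, 8, None),
        "pdp_grid_size": (int, 20, None),
        "pdp_factors": (list, ["ndvi", "green_access", "openness"], None),
        "effect_factor": (str, "green_access", None),
    },
    "files": {
        "posts": (str, None, None),
        "communities": (str, None, None),
        "covariates": (str, None, None),
    },
}

_STAGES = ("city", "posts", "kde", "autocorr", "models", "explain")


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(errors))


@dataclass
class RunConfig:
    """Resolved configuration with all defaults materialized."""

    resolved: dict[str, Any]
    schema_version: int = SCHEMA_VERSION
    stage_seeds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stage_seeds:
            root = np.random.SeedSequence(self.resolved["seed"])
            children = root.spawn(len(_STAGES))
            self.stage_seeds = {
                stage: int(c.generate_state(1)[0] % (2**31))
                for stage, c in zip(_STAGES, children)
            }

    def __getitem__(self, key: str) -> Any:
        return self.resolved[key]


def _suggest(key: str, known: list[str]) -> str:
    close = difflib.get_close_matches(key, known, n=1)
    return f"; did you mean {close[0]!r}?" if close else ""


def _validate_section(
    raw: dict[str, Any], schema: dict[str, Any], prefix: str, errors: list[str]
) -> dict[str, Any]:
    out: dict[str, Any] = {}
    known = list(schema.keys())
    for key in raw:
        if key not in schema:
            errors.append(f"unknown key {prefix}{key!r}{_suggest(key, known)}")
    for key, entry in schema.items():
        if isinstance(entry, dict):
            sub_raw = raw.get(key, {})
            if not isinstance(sub_raw, dict):
                errors.append(f"{prefix}{key} must be a mapping")
                sub_raw = {}
            out[key] = _validate_section(sub_raw, entry, f"{prefix}{key}.", errors)
            continue
        typ, default, allowed = entry
        if key in raw and raw[key] is not None:
            val = raw[key]
            if typ is float and isinstance(val, int) and not isinstance(val, bool):
                val = float(val)
            if typ is int and isinstance(val, bool):
                errors.append(f"{prefix}{key} must be {typ.__name__}, got bool")
                continue
            if not isinstance(val, typ):
                errors.append(
                    f"{prefix}{key} must be {typ.__name__}, got {type(val).__name__}"
                )
                continue
            if allowed is not None and val not in allowed:
                errors.append(
                    f"{prefix}{key} must be one of {sorted(allowed)}, got {val!r}"
                )
                continue
            out[key] = val
        elif default is REQUIRED:
            errors.append(f"missing required field {prefix}{key}")
        else:
            out[key] = default
    return out


def validate_config(raw: dict[str, Any] | None) -> RunConfig:
    """Validate a raw config mapping; raises :class:`ConfigError` listing
    every violation, or returns the resolved :class:`RunConfig`."""
    raw = raw or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    resolved = _validate_section(raw, _SCHEMA, "", errors)
    if not errors and resolved["mode"] == "files":
        for k in ("posts", "communities", "covariates"):
            if not resolved["files"].get(k):
                errors.append(f"files.{k} is required in files mode")
    if not errors:
        seasons = resolved["seasons"]
        bad = [s for s in seasons if s not in ("spring", "summer", "autumn", "winter")]
        if bad:
            errors.append(f"unknown seasons: {bad}")
    if errors:
        raise ConfigError(errors)
    resolved["schema_version"] = SCHEMA_VERSION
    return RunConfig(resolved=resolved)
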