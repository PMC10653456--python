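"""Flat run configuration: load, validate, round-trip, result manifests.

A config is a single flat mapping (YAML or JSON by extension).  Model
parameter keys are exactly ``b, d, r, K, alpha, c, epsilon, sigma``;
unknown keys are rejected so scenario files stay diffable and citable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError
from .integrate import IntegratorSettings
from .params import DEFAULTS, ModelParams

__all__ = ["RunConfig", "load_config", "save_config", "write_results"]

_PARAM_KEYS = tuple(DEFAULTS) + ("sigma",)
_INTEGRATOR_KEYS = ("dt", "t_end", "burn_in", "stride")
_NETWORK_KEYS = ("topology", "n_nodes", "avg_degree", "interaction", "delta", "edge_list")
_MISC_KEYS = ("seed", "out_dir", "tol_ratio", "tol_extrema")
_ALL_KEYS = _PARAM_KEYS + _INTEGRATOR_KEYS + _NETWORK_KEYS + _MISC_KEYS


@dataclass(frozen=True)
class RunConfig:
    """Validated flat configuration with defaults filled in.

    ``provenance`` records, per key, whether the value came from the file
    or from package defaults."""

    params: ModelParams
    sigma: float = 0.1
    settings: IntegratorSettings = IntegratorSettings()
    topology: Optional[str] = None
    n_nodes: Optional[int] = None
    avg_degree: Optional[float] = None
    interaction: str = "identity"
    delta: float = 0.0
    edge_list: Optional[str] = None
    seed: int = 0
    out_dir: str = "."
    tol_ratio: float = 1e-3
    tol_extrema: float = 1e-3
    provenance: dict = field(default_factory=dict)

    def to_flat_dict(self) -> dict:
        d = dict(self.params.to_dict())
        d["sigma"] = self.sigma
        for k in _INTEGRATOR_KEYS:
            d[k] = getattr(self.settings, k)
        for k in _NETWORK_KEYS + _MISC_KEYS:
            v = getattr(self, k if k != "n_nodes" else "n_nodes")
            if v is not None:
                d[k] = v
        return d


def _parse(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise ConfigError(f"unrecognized config extension {path.suffix!r} (use .yaml/.json)")
    if not isinstance(data, dict):
        raise ConfigError(f"config must be a flat mapping, got {type(data).__name__}")
    return data


def load_config(path) -> RunConfig:
    """Load and validate a flat YAML/JSON config; fill defaults.

    Raises :class:`ConfigError` naming the offending key on unknown keys
    or invalid values.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = _parse(path)
    unknown = set(data) - set(_ALL_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    provenance = {k: ("file" if k in data else "default") for k in _ALL_KEYS}
    try:
        params = ModelParams(**{k: data[k] for k in DEFAULTS if k in data})
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    sigma = float(data.get("sigma", 0.1))
    if sigma < 0:
        raise ConfigError(f"sigma must be >= 0, got {sigma}")
    try:
        settings = IntegratorSettings(
            **{k: data[k] for k in _INTEGRATOR_KEYS if k in data}
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(
        params=params,
        sigma=sigma,
        settings=settings,
        topology=data.get("topology"),
        n_nodes=data.get("n_nodes"),
        avg_degree=data.get("avg_degree"),
        interaction=data.get("interaction", "identity"),
        delta=float(data.get("delta", 0.0)),
        edge_list=data.get("edge_list"),
        seed=int(data.get("seed", 0)),
        out_dir=str(data.get("out_dir", ".")),
        tol_ratio=float(data.get("tol_ratio", 1e-3)),
        tol_extrema=float(data.get("tol_extrema", 1e-3)),
        provenance=provenance,
    )


def save_config(config: RunConfig, path) -> None:
    """Write a config back out (flat mapping, format by extension)."""
    path = Path(path)
    data = config.to_flat_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        raise ConfigError(f"unrecognized config extension {path.suffix!r}")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(bundle: dict, out_dir, seed: Optional[int] = None, config: Optional[RunConfig] = None) -> dict:
    """Write a runner's outputs plus a manifest; returns the manifest.

    ``bundle`` maps artifact names to objects: anything with ``to_csv``
    is written as CSV, anything with ``to_dict`` (or a plain dict/array)
    as JSON.  The manifest records the config hash, seed, package version
    and the written files, and suffices to re-run identically.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, obj in bundle.items():
        if hasattr(obj, "to_csv"):
            fname = f"{name}.csv"
            obj.to_csv(out / fname)
        else:
            fname = f"{name}.json"
            payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
            (out / fname).write_text(json.dumps(_jsonable(payload), indent=2))
        files.append(fname)
    config_flat = config.to_flat_dict() if config is not None else None
    config_hash = (
        hashlib.sha256(json.dumps(config_flat, sort_keys=True).encode()).hexdigest()
        if config_flat is not None
        else None
    )
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config_flat,
        "config_sha256": config_hash,
        "files": files,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest
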