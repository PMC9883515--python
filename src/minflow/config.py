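"""Run configuration: schema validation, seed fan-out, result bundling.

A run is described by a flat, fully serializable mapping (YAML on disk).
Top-level sections: ``params`` (named set + overrides), ``grid``,
``schedule``, ``protocol`` (stage-specific settings), ``output``.  Every
run writes the resolved configuration next to its results so any output
can be regenerated from its bundle alone.  All randomness derives from a
single ``seed`` fanned out per stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from minflow.parameters import KineticParameters, get_parameter_set
from minflow.simulator import Schedule
from minflow.state import Grid

_TOP_KEYS = {"params", "grid", "schedule", "protocol", "output", "seed",
             "command"}
_PARAM_KEYS = {"set", "overrides"}
_GRID_KEYS = {"length", "n", "length_y", "n_y"}
_SCHEDULE_KEYS = {"dt", "t_end", "save_every", "drift_check_every"}


class ConfigError(ValueError):
    """Schema violation; message names every offending key."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    params: KineticParameters
    grid: Grid | None
    schedule: Schedule | None
    protocol: dict
    output_dir: Path
    seed: int
    command: str | None
    raw: dict

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _check_keys(section: str, d: dict, allowed: set[str]) -> list[str]:
    return [f"{section}.{k}" for k in d if k not in allowed]


def validate_config(doc: dict) -> RunConfig:
    """Validate a configuration mapping field by field."""
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    errors = _check_keys("<top>", doc, _TOP_KEYS)

    pdoc = doc.get("params", {}) or {}
    errors += _check_keys("params", pdoc, _PARAM_KEYS)
    params = None
    if not errors:
        try:
            params = get_parameter_set(pdoc.get("set", "denk2d"),
                                       **(pdoc.get("overrides") or {}))
        except (KeyError, ValueError, TypeError) as e:
            errors.append(f"params: {e}")

    gdoc = doc.get("grid")
    grid = None
    if gdoc is not None:
        errors += _check_keys("grid", gdoc, _GRID_KEYS)
        if not errors:
            try:
                if "length_y" in gdoc:
                    grid = Grid.plane((gdoc["length"], gdoc["length_y"]),
                                      (gdoc["n"], gdoc["n_y"]))
                else:
                    grid = Grid.line(gdoc["length"], gdoc["n"])
            except (KeyError, ValueError, TypeError) as e:
                errors.append(f"grid: {e}")

    sdoc = doc.get("schedule")
    schedule = None
    if sdoc is not None:
        errors += _check_keys("schedule", sdoc, _SCHEDULE_KEYS)
        if not errors:
            try:
                schedule = Schedule(rng_seed=int(doc.get("seed", 0)), **sdoc)
            except (TypeError, ValueError) as e:
                errors.append(f"schedule: {e}")

    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))

    return RunConfig(params=params, grid=grid, schedule=schedule,
                     protocol=doc.get("protocol") or {},
                     output_dir=Path(doc.get("output", "minflow_run")),
                     seed=int(doc.get("seed", 0)),
                     command=doc.get("command"), raw=doc)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def write_bundle(cfg: RunConfig, results: dict, name: str = "summary") -> Path:
    """Write resolved config + JSON results + manifest into the run dir."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(cfg.raw, fh, sort_keys=False)
    res_path = out / f"{name}.json"
    with open(res_path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=1)
    manifest = {"config_digest": cfg.digest(),
                "files": sorted(p.name for p in out.iterdir())}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return res_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable({k: getattr(obj, k) for k in obj.__dataclass_fields__})
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
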