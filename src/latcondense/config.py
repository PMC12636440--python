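"""YAML run configuration: validated parameter loading for the CLI.

A config file names a model and supplies the parameter blocks that mirror
the corresponding dataclasses field-for-field.  Unknown keys are errors
(no silently ignored typos), and every numeric value is validated by the
target dataclass before any computation starts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .aggregation import KernelParams
from .field_dynamics import FieldParams, Grid, SolverConfig
from .homogeneous_bonds import BindingParams

log = logging.getLogger("latcondense")

MODELS = ("aggregate", "homogeneous", "field", "phasediagram", "classify", "fixtures")


class ConfigError(ValueError):
    """Raised for malformed or invalid run configurations."""


@dataclass
class RunConfig:
    model: str
    params: dict
    out: str | None = None
    seed: int | None = None
    log_level: str = "INFO"


def _build(cls, block: dict, where: str):
    """Instantiate a params dataclass from a dict, rejecting unknown keys."""
    if block is None:
        block = {}
    if not isinstance(block, dict):
        raise ConfigError(f"section '{where}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section '{where}'")
    try:
        return cls(**block)
    except (ValueError, TypeError) as e:
        raise ConfigError(f"invalid value in section '{where}': {e}") from e


def _build_grid(block: dict) -> Grid:
    block = block or {}
    unknown = set(block) - {"n", "box"}
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section 'grid'")
    try:
        return Grid(**block)
    except ValueError as e:
        raise ConfigError(f"invalid value in section 'grid': {e}") from e


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    Defaults are filled in from the parameter dataclasses and the resolved
    configuration is echoed to the log.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    model = raw.pop("model", None)
    if model not in MODELS:
        raise ConfigError(f"'model' must be one of {MODELS}, got {model!r}")
    out = raw.pop("out", None)
    seed = raw.pop("seed", None)
    log_level = raw.pop("log_level", "INFO")

    params: dict = {}
    if model == "aggregate":
        params["kernel"] = _build(KernelParams, raw.pop("params", raw.pop("kernel", None)), "params")
    elif model == "homogeneous":
        params["binding"] = _build(BindingParams, raw.pop("params", raw.pop("binding", None)), "params")
    elif model in ("field", "phasediagram"):
        params["field"] = _build(FieldParams, raw.pop("field", None), "field")
        params["grid"] = _build_grid(raw.pop("grid", None))
        solver_block = dict(raw.pop("solver", None) or {})
        if seed is not None and "seed" not in solver_block:
            solver_block["seed"] = seed
        params["solver"] = _build(SolverConfig, solver_block, "solver")
        if params["solver"].seed is None and params["solver"].noise_amp > 0:
            raise ConfigError(f"model={model} requires a seed (top-level or solver.seed)")
        if model == "phasediagram":
            scan = raw.pop("scan", None)
            if scan is not None and not isinstance(scan, list):
                raise ConfigError("'scan' must be a list of [beta3_hat, beta4_hat] pairs")
            params["scan"] = scan
    # classify / fixtures take their arguments from the CLI directly

    unknown = set(raw)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    cfg = RunConfig(model=model, params=params, out=out, seed=seed, log_level=log_level)
    log.info("loaded config %s: model=%s seed=%s", path, model, seed)
    for name, value in params.items():
        log.info("  %s: %s", name, value)
    return cfg
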