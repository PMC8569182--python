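"""Run configuration: YAML schema, validation and provenance records.

Validation is strict and total: unknown keys are errors (no silent typos),
out-of-range values are errors naming the admissible bound, and every problem
found is reported at once rather than first-failure.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field
from pathlib import Path

from .io import read_yaml, write_yaml

__all__ = ["RunConfig", "Provenance", "validate_config", "default_config"]

_DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "out",
    "branch": "simulated",
    "connectome": {
        "path": None,
        "n_regions": 30,
        "n_modules": 3,
        "density": 0.3,
        "weight_scale": 0.25,
    },
    "series_path": None,
    "series_dt": 0.72,
    "model": {},
    "hemo": {},
    "simulation": {
        "G": 1.5,
        "duration": 120.0,
        "dt": 1e-4,
        "record_dt": 1e-3,
        "transient": 10.0,
        "out_dt": 0.72,
    },
    "fit": {
        "enabled": False,
        "targets_path": None,
        "g_min": 0.0,
        "g_max": 2.5,
        "g_step": 0.025,
        "n_repeats": 2,
    },
    "extraction": {
        "threshold_sd": 1.0,
        "temporal_bins_ms": [150.0, 720.0],
        "source": "rates",
    },
    "export": {"rates_tsv": False, "series_hdf5": True},
}

_MODEL_KEYS = {
    "g_E", "g_I", "d_E", "d_I", "I_thr_E", "I_thr_I", "w_E", "w_I",
    "w_plus", "w_NMDA", "I_0", "tau_NMDA", "tau_GABA", "gamma_syn",
    "sigma_noise",
}
_HEMO_KEYS = {"kappa", "gamma_h", "tau", "alpha_exp", "rho", "V0", "k1", "k2", "k3"}


@dataclass
class RunConfig:
    """Fully-resolved pipeline configuration (defaults applied, validated)."""

    seed: int
    output_dir: str
    branch: str
    connectome: dict
    series_path: str | None
    series_dt: float
    model: dict
    hemo: dict
    simulation: dict
    fit: dict
    extraction: dict
    export: dict

    def g_grid(self):
        import numpy as np

        f = self.fit
        return np.arange(f["g_min"], f["g_max"] + 1e-9, f["g_step"])


@dataclass
class Provenance:
    """Everything needed to reproduce an artifact: config, version, seeds, timings."""

    config: dict
    package_version: str
    seeds: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        write_yaml(path, self.__dict__)


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(defaults: dict, given: dict, prefix: str, errors: list[str]) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in (given or {}).items():
        if key not in defaults:
            errors.append(f"unknown key {prefix}{key!r}")
            continue
        if isinstance(defaults[key], dict) and not isinstance(value, dict) and value is not None:
            errors.append(f"{prefix}{key!r} must be a mapping")
            continue
        if isinstance(defaults[key], dict):
            out[key] = _merge(defaults[key], value, f"{prefix}{key}.", errors)
        else:
            out[key] = value
    return out


def _check_range(errors, cond: bool, message: str) -> None:
    if not cond:
        errors.append(message)


def validate_config(source) -> RunConfig:
    """Resolve and validate a config mapping or YAML path.

    All defaults are applied; every unknown key and every out-of-range value
    is collected and reported together in a single ``ValueError``.
    """
    if isinstance(source, (str, Path)):
        raw = read_yaml(source) or {}
    else:
        raw = dict(source or {})

    errors: list[str] = []
    cfg = _merge(_DEFAULTS, raw, "", errors)

    for key in cfg["model"]:
        if key not in _MODEL_KEYS:
            errors.append(f"unknown key model.{key!r}")
    for key in cfg["hemo"]:
        if key not in _HEMO_KEYS:
            errors.append(f"unknown key hemo.{key!r}")

    _check_range(errors, cfg["branch"] in ("simulated", "empirical"),
                 "branch must be 'simulated' or 'empirical'")
    con = cfg["connectome"]
    if con["path"] is None:
        _check_range(errors, isinstance(con["n_regions"], int) and con["n_regions"] >= 2,
                     "connectome.n_regions must be an integer >= 2")
        _check_range(errors, isinstance(con["n_modules"], int)
                     and 1 <= con["n_modules"] <= (con["n_regions"] or 1),
                     "connectome.n_modules must satisfy 1 <= n_modules <= n_regions")
        _check_range(errors, 0 < con["density"] <= 1,
                     f"connectome.density = {con['density']} outside (0, 1]")
        _check_range(errors, con["weight_scale"] > 0,
                     "connectome.weight_scale must be > 0")
    elif not Path(con["path"]).exists():
        errors.append(f"connectome.path does not exist: {con['path']}")

    if cfg["branch"] == "empirical":
        if cfg["series_path"] is None:
            errors.append("branch 'empirical' requires series_path")
        elif not Path(cfg["series_path"]).exists():
            errors.append(f"series_path does not exist: {cfg['series_path']}")
        _check_range(errors, cfg["series_dt"] > 0, "series_dt must be > 0")

    sim = cfg["simulation"]
    _check_range(errors, sim["G"] >= 0, "simulation.G must be >= 0")
    _check_range(errors, 0 < sim["dt"] <= 1e-3,
                 "simulation.dt must lie in (0, 0.001] seconds")
    _check_range(errors, sim["duration"] > sim["transient"] >= 0,
                 "simulation.duration must exceed the (nonnegative) transient")
    _check_range(errors, sim["record_dt"] >= sim["dt"],
                 "simulation.record_dt must be >= dt")
    _check_range(errors, sim["out_dt"] >= sim["record_dt"],
                 "simulation.out_dt must be >= record_dt")

    fit = cfg["fit"]
    _check_range(errors, 0 <= fit["g_min"] <= fit["g_max"],
                 "fit grid must satisfy 0 <= g_min <= g_max")
    _check_range(errors, fit["g_step"] > 0, "fit.g_step must be > 0")
    _check_range(errors, fit["n_repeats"] >= 1, "fit.n_repeats must be >= 1")
    if fit["enabled"] and fit["targets_path"] is not None and not Path(fit["targets_path"]).exists():
        errors.append(f"fit.targets_path does not exist: {fit['targets_path']}")

    ext = cfg["extraction"]
    _check_range(errors, ext["threshold_sd"] > 0, "extraction.threshold_sd must be > 0")
    _check_range(errors, ext["source"] in ("rates", "gating"),
                 "extraction.source must be 'rates' or 'gating'")
    bins = ext["temporal_bins_ms"]
    if not isinstance(bins, (list, tuple)) or not bins:
        errors.append("extraction.temporal_bins_ms must be a nonempty list")
    else:
        for b in bins:
            _check_range(errors, b is None or b >= sim["record_dt"] * 1000,
                         f"temporal bin {b} ms is finer than the recorded step "
                         f"({sim['record_dt'] * 1000:g} ms)")

    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return RunConfig(**cfg)
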