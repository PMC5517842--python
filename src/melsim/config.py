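"""Run configuration, deterministic serialization, and provenance echoing.

A run is described by a flat key-value document (YAML).  Unknown keys are
rejected up front, parameter overrides are validated against the parameter
set, and the full effective configuration is echoed next to the outputs so
every result file is reproducible from its own directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as _dcfield, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .parameters import ParameterSet, baseline_parameters
from .solver import SolverOptions, SimulationResult
from .experiments import EfficacyMap
from .sensitivity import SensitivityResult

__all__ = ["RunConfig", "load_config", "write_results", "config_hash"]

_SOLVER_KEYS = ("n_nodes", "tau", "picard_tol", "picard_max", "remesh_ratio",
                "output_interval", "rescale_initial_c", "printed_initial_p")


@dataclass
class RunConfig:
    """Effective configuration of one experiment run."""

    experiment: str = "control"
    overrides: dict = _dcfield(default_factory=dict)   # parameter name -> value
    gamma_A: float = 0.0           # anti-PD-1 source level (g/cm^3/day)
    gamma_B: float = 0.0           # BRAF/MEKi source level (g/cm^3/day)
    gamma_I12: float = 0.0         # direct IL-12 injection (g/cm^3/day)
    t_end: float = 60.0
    map_nb: int = 6                # efficacy-map resolution in gamma_B
    map_na: int = 5                # efficacy-map resolution in gamma_A
    gamma_B_max: float = 5e-9
    gamma_A_max: float = 1.4e-9
    profile_fixed_drug: str = "A"
    profile_fixed_level: float = 1.26e-9
    profile_points: int = 5
    n_samples: int = 100           # sensitivity sample count
    seed: int = 0
    solver: dict = _dcfield(default_factory=dict)  # SolverOptions overrides
    out_dir: str = "results"

    _EXPERIMENTS = ("control", "therapy", "map", "profile", "il12",
                    "sensitivity", "derive-params")

    def __post_init__(self) -> None:
        if self.experiment not in self._EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"choose one of {self._EXPERIMENTS}")
        bad = sorted(set(self.solver) - set(_SOLVER_KEYS))
        if bad:
            raise KeyError(f"unknown solver option(s): {', '.join(bad)}")
        # validate override names and positivity through the parameter set
        self.parameters()

    def parameters(self) -> ParameterSet:
        return baseline_parameters().with_overrides(**self.overrides)

    def solver_options(self) -> SolverOptions:
        return SolverOptions(**self.solver)

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Parse a YAML key-value file, merged over defaults.

    ``None`` or an empty file yields pure defaults.  Unknown top-level keys
    fail fast, listing the offenders.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration must be a key-value mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(data) - known)
    if unknown:
        raise KeyError(f"unknown configuration key(s): {', '.join(unknown)}")
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.as_dict(), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    # full precision so identical runs produce byte-identical files
    frame.to_csv(path, index=False, float_format="%.17g")


def write_results(result, out_dir: str | Path, config: RunConfig | None = None) -> dict:
    """Serialize a result object to CSV + JSON metadata; returns the manifest.

    Supported: :class:`SimulationResult`, :class:`EfficacyMap`,
    :class:`SensitivityResult`, and the ``{name: (derived, stored)}`` mapping
    of the parameter regeneration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {"format_version": 1}
    if config is not None:
        meta["config"] = config.as_dict()
        meta["config_hash"] = config_hash(config)
        meta["seed"] = config.seed
        # full effective parameter set, with override provenance per entry
        meta["parameters"] = {
            name: {"value": value,
                   "source": "override" if name in config.overrides else "default"}
            for name, value in config.parameters().as_dict().items()}

    files: dict[str, str] = {}
    if isinstance(result, SimulationResult):
        _write_csv(result.to_frame(), out / "timeseries.csv")
        files["timeseries"] = "timeseries.csv"
        meta["summary"] = {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                           for k, v in result.metadata.items()}
    elif isinstance(result, EfficacyMap):
        e_frame, r_frame = result.to_frames()
        e_frame.reset_index().to_csv(out / "efficacy.csv", index=False, float_format="%.17g")
        r_frame.reset_index().to_csv(out / "r60.csv", index=False, float_format="%.17g")
        files["efficacy"] = "efficacy.csv"
        files["r60"] = "r60.csv"
        meta["summary"] = {"max_efficacy": result.max_efficacy,
                           "failures": result.failures}
    elif isinstance(result, SensitivityResult):
        _write_csv(result.to_frame(), out / "sensitivity.csv")
        samples = pd.DataFrame(result.samples, columns=list(result.names))
        samples["R60"] = result.response
        _write_csv(samples, out / "samples.csv")
        files["sensitivity"] = "sensitivity.csv"
        files["samples"] = "samples.csv"
        meta["summary"] = {"n": result.n, "n_failed": result.n_failed,
                           "seed": result.seed}
    elif isinstance(result, dict):  # parameter regeneration table
        rows = [{"name": k, "derived": d, "stored": s,
                 "rel_error": abs(d - s) / abs(s)}
                for k, (d, s) in result.items()]
        _write_csv(pd.DataFrame(rows), out / "derived_parameters.csv")
        files["derived_parameters"] = "derived_parameters.csv"
        meta["summary"] = {"n_entries": len(rows),
                           "max_rel_error": max(r["rel_error"] for r in rows)}
    else:
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")

    meta["files"] = files
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True,
                                              default=float) + "\n")
    return meta
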