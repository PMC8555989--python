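"""Run configuration, provenance, and the pipeline driver.

A :class:`RunConfig` names a stage, a seed, input/output paths, and a flat
``params`` mapping of stage parameters.  Unknown keys — at the top level or
inside ``params`` — are rejected, with the offending key named.  Parameter
defaults live in one place only (the library function signatures); the
provenance record written next to every output echoes the fully resolved
values, harvested via :func:`inspect.signature`.
"""

from __future__ import annotations

import hashlib
import inspect
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ValidationError

_CONFIG_KEYS = {"stage", "seed", "inputs", "out_dir", "params", "units"}

#: stage name -> the functions whose signature defaults are its parameters
_STAGE_FUNCTIONS: dict[str, list] = {}


#: data-carrying argument names never exposed as config parameters
_DATA_ARGS = {"accept", "shifts", "pulses", "phases", "lines", "seed"}


def _stage_extras(stage: str) -> dict:
    """Required-but-configurable keys that have no library default."""
    from . import vessel

    return {
        "ecg": {"mode": "ventricular"},
        "vessel": {
            "line_p0": None,
            "line_p1": None,
            "band_width": vessel.DEFAULT_BAND_WIDTH_UM,
            "exclusion": None,
            "laser_on": None,
            "laser_off": None,
        },
    }.get(stage, {})


def _stage_functions(stage: str) -> list:
    # resolved lazily to avoid import cycles
    from . import ecg, gating, pipeline, vessel

    table = {
        "synth_ecg": [pipeline.synth_ecg_stage],
        "synth_vessel": [pipeline.synth_vessel_stage],
        "synth_linescan": [pipeline.synth_linescan_stage],
        "synth_fluor": [pipeline.synth_fluor_stage],
        "ecg": [ecg.analyze_ecg],
        "vessel": [
            vessel.stabilize_stack,
            vessel.diameter_series,
            vessel.smooth_running_average,
            vessel.response_metrics,
        ],
        "gate": [gating.respiratory_gate, gating.reconstruct_phase_bins],
        "fluor": [gating.detect_transient_onsets, gating.pacing_coupling],
    }
    if stage not in table:
        raise ValidationError(f"unknown stage {stage!r}; choose from {sorted(table)}")
    return table[stage]


def stage_defaults(stage: str) -> dict:
    """All keyword defaults of the stage's functions (single source of truth:
    the library signatures, harvested, not duplicated)."""
    out: dict = {}
    for fn in _stage_functions(stage):
        for name, p in inspect.signature(fn).parameters.items():
            if name in _DATA_ARGS:
                continue
            if p.default is not inspect.Parameter.empty:
                out[name] = p.default
    out.update(_stage_extras(stage))
    return out


@dataclass
class RunConfig:
    """One pipeline invocation: stage, seed, paths, and parameter overrides."""

    stage: str
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    out_dir: str = "."
    params: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        defaults = stage_defaults(self.stage)
        unknown = [k for k in self.params if k not in defaults]
        if unknown:
            raise ValidationError(
                f"unknown parameter key(s) {unknown} for stage {self.stage!r}; "
                f"known: {sorted(defaults)}"
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = [k for k in mapping if k not in _CONFIG_KEYS]
        if unknown:
            raise ValidationError(f"unknown config key(s): {unknown}")
        if "stage" not in mapping:
            raise ValidationError("config must name a 'stage'")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)

    def to_mapping(self) -> dict:
        return {
            "stage": self.stage,
            "seed": self.seed,
            "inputs": dict(self.inputs),
            "out_dir": str(self.out_dir),
            "params": dict(self.params),
            "units": dict(self.units),
        }

    def resolved_params(self) -> dict:
        """Stage defaults overlaid with this run's overrides."""
        out = stage_defaults(self.stage)
        out.update(self.params)
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_mapping(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_provenance(out_dir: str | Path, config: RunConfig, outputs: list[str]) -> Path:
    """JSON provenance record next to the outputs: config, hash, seed,
    resolved parameter values, package version."""
    from . import __version__

    record = {
        "package": "optopace",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_mapping(),
        "config_hash": config.config_hash(),
        "resolved_params": {k: repr(v) for k, v in config.resolved_params().items()},
        "outputs": outputs,
    }
    path = Path(out_dir) / "provenance.json"
    path.write_text(json.dumps(record, indent=1, sort_keys=True))
    return path
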