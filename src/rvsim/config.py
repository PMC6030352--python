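"""Structured run configuration.

The study's experiments are pure parameter edits, so the configuration
file *is* the experiment: a YAML mapping whose key hierarchy mirrors the
model parameter structure (``sarcomere.*`` shared by the three walls,
``walls.<lv|septum|rv>.{Vw,Am_ref}``, ``circulation.*``,
``atria.<la|ra>.*``, ``protocol.*``).  Defaults, file values and
command-line overrides merge in that precedence order; unknown keys are
rejected by name, and the fully resolved configuration is echoed next to
every run's outputs for provenance.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .circulation import (AtrialParams, CirculationParams, ModelParams,
                          default_model)
from .errors import ConfigError
from .sarcomere import SarcomereParams
from .triseg import WallSegment

__all__ = ["RunConfig", "parse_config", "default_config_dict"]

PROTOCOL_DEFAULTS = {
    "max_beats": 500,
    "sv_tol": 0.01,
    "edv_tol": 1e-3,
    "rtol": 1e-7,
    "n_samples": 512,
    "preload_fractions": [1.0, 0.95, 0.9, 0.85, 0.8],
    "homeostasis_mode": "per-scenario",
    "aop_lo": 110.0,
    "aop_hi": 125.0,
    "rv_mass_mult": 1.0,
    "fmax_ratio_a6": 0.78,
}


def default_config_dict() -> dict[str, Any]:
    model = default_model()
    return {
        "sarcomere": asdict(model.walls[0].sarcomere),
        "walls": {
            "lv": {"Vw": model.walls[0].Vw, "Am_ref": model.walls[0].Am_ref},
            "septum": {"Vw": model.walls[1].Vw, "Am_ref": model.walls[1].Am_ref},
            "rv": {"Vw": model.walls[2].Vw, "Am_ref": model.walls[2].Am_ref},
        },
        "circulation": asdict(model.circulation),
        "atria": {"la": asdict(model.la), "ra": asdict(model.ra)},
        "protocol": copy.deepcopy(PROTOCOL_DEFAULTS),
    }


def _merge(base: dict, extra: Mapping, path: str = "") -> None:
    for key, value in extra.items():
        full = f"{path}{key}" if not path else f"{path}.{key}"
        if key not in base:
            raise ConfigError(f"unknown configuration key {full!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{full!r} expects a mapping")
            _merge(base[key], value, full)
        else:
            if isinstance(value, Mapping):
                raise ConfigError(f"{full!r} does not accept a mapping")
            base[key] = _coerce(full, base[key], value)


def _coerce(key: str, default: Any, value: Any) -> Any:
    if isinstance(default, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"{key!r} expects a boolean")
        return value
    if isinstance(default, (int, float)) and isinstance(value, (int, float)):
        return type(default)(value) if isinstance(default, float) else value
    if isinstance(default, str):
        return str(value)
    if isinstance(default, list):
        if not isinstance(value, Sequence) or isinstance(value, str):
            raise ConfigError(f"{key!r} expects a list")
        return [float(v) for v in value]
    raise ConfigError(f"{key!r}: cannot coerce {value!r}")


def _set_dotted(cfg: dict, dotted: str, value: Any) -> None:
    parts = dotted.split(".")
    node = cfg
    for part in parts[:-1]:
        if part not in node or not isinstance(node[part], dict):
            raise ConfigError(f"unknown configuration key {dotted!r}")
        node = node[part]
    leaf = parts[-1]
    if leaf not in node:
        raise ConfigError(f"unknown configuration key {dotted!r}")
    if isinstance(node[leaf], dict):
        raise ConfigError(f"{dotted!r} is not a leaf key")
    node[leaf] = _coerce(dotted, node[leaf], value)


@dataclass
class RunConfig:
    """Fully resolved configuration for one invocation."""

    values: dict[str, Any]
    scenarios: list[str] = field(default_factory=lambda: ["baseline"])
    output_dir: Path = Path("rvsim_output")
    log_level: str = "INFO"
    seed: int = 0  # used only by the random-scenario generator

    def build_model(self) -> ModelParams:
        v = self.values
        sarc = SarcomereParams(**v["sarcomere"])
        walls = tuple(
            WallSegment(name, Vw=v["walls"][short]["Vw"],
                        Am_ref=v["walls"][short]["Am_ref"], sarcomere=sarc)
            for name, short in (("lv_free_wall", "lv"), ("septum", "septum"),
                                ("rv_free_wall", "rv")))
        return ModelParams(
            walls=walls,
            circulation=CirculationParams(**v["circulation"]),
            la=AtrialParams(**v["atria"]["la"]),
            ra=AtrialParams(**v["atria"]["ra"]))

    @property
    def protocol(self) -> dict[str, Any]:
        return self.values["protocol"]

    def run_kwargs(self) -> dict[str, Any]:
        p = self.protocol
        return {"max_beats": int(p["max_beats"]), "sv_tol": p["sv_tol"],
                "edv_tol": p["edv_tol"], "rtol": p["rtol"],
                "n_samples": int(p["n_samples"])}

    def echo(self, directory: Path | None = None) -> Path:
        """Write the resolved configuration next to the outputs."""
        from . import __version__
        directory = Path(directory) if directory else self.output_dir
        directory.mkdir(parents=True, exist_ok=True)
        doc = {"package_version": __version__,
               "scenarios": self.scenarios,
               "seed": self.seed,
               "config": self.values}
        path = directory / "resolved_config.yaml"
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path


def parse_config(path: str | Path | None = None,
                 overrides: Sequence[tuple[str, Any]] | Mapping[str, Any] | None = None,
                 **kwargs) -> RunConfig:
    """Merge defaults, an optional YAML file, and dotted-path overrides.

    Precedence: defaults < file < overrides.  Unknown keys raise
    :class:`ConfigError` naming the offending key.
    """
    cfg = default_config_dict()
    if path is not None:
        path = Path(path)
        if not path.is_file():
            raise ConfigError(f"configuration file not found: {path}")
        try:
            loaded = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"unreadable configuration file: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigError("configuration file must contain a mapping")
        _merge(cfg, loaded)
    if overrides:
        items = overrides.items() if isinstance(overrides, Mapping) \
            else overrides
        for dotted, value in items:
            _set_dotted(cfg, dotted, value)
    return RunConfig(values=cfg, **kwargs)


def dumps_json(obj: Any) -> str:
    """JSON with stable key order for metric documents."""
    return json.dumps(obj, indent=2, sort_keys=True)
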