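"""YAML run configuration: validated parameter overrides, protocol, sweep.

Every default is either a value of the pea parameterization or a documented
package choice (see docs/methods.md).  Unknown keys are rejected by name so
that typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .dynamics import Protocol, Segment, standard_protocol
from .errors import ConfigError, ParameterError
from .params import KineticParameters, TemperatureResponse

__all__ = ["RunConfig", "load_config", "save_config"]

_PROTOCOL_PRESET_KEYS = {
    "preset", "par", "stress_temperature", "stress_act_j", "stress_act_c",
    "base_temperature", "co2", "gs_scale", "dt", "record_every",
}
_SEGMENT_KEYS = {"duration", "par", "temperature", "act_j", "act_c", "co2", "gs_scale"}
_SWEEP_KEYS = {
    "kind", "par", "pars", "temps", "grid_steps", "grid_j", "grid_c",
    "gs_scale", "base_temperature",
}
_OUTPUT_KEYS = {"dir", "prefix"}
_TOP_KEYS = {"parameters", "temperature_responses", "protocol", "sweep", "output", "seed"}


@dataclass
class RunConfig:
    """Fully validated run configuration with defaults filled in."""

    params: KineticParameters = field(default_factory=KineticParameters)
    tr_c: TemperatureResponse = field(default_factory=TemperatureResponse.rubisco_default)
    tr_j: TemperatureResponse = field(default_factory=TemperatureResponse.etc_default)
    protocol: Optional[Protocol] = None
    sweep: Optional[dict] = None
    output: dict = field(default_factory=lambda: {"dir": ".", "prefix": "photofvcb"})
    seed: int = 0

    def resolved_protocol(self) -> Protocol:
        """The configured protocol, or the standard one at 239 µmol·m⁻²·s⁻¹."""
        return self.protocol if self.protocol is not None else standard_protocol(239.0)


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def _build_params(section: dict) -> KineticParameters:
    allowed = {f.name for f in fields(KineticParameters)}
    _check_keys(section, allowed, "parameters")
    try:
        return KineticParameters(**{k: float(v) for k, v in section.items()})
    except ParameterError as exc:
        raise ConfigError(f"invalid parameters: {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"non-numeric value in parameters: {exc}") from exc


def _build_tr(section: dict, default: TemperatureResponse, where: str) -> TemperatureResponse:
    _check_keys(section, {"t_opt", "sigma_lo", "sigma_hi"}, where)
    values = {f.name: getattr(default, f.name) for f in fields(TemperatureResponse)}
    values.update({k: float(v) for k, v in section.items()})
    try:
        return TemperatureResponse(**values)
    except ParameterError as exc:
        raise ConfigError(f"invalid {where}: {exc}") from exc


def _build_protocol(section: dict) -> Protocol:
    if "segments" in section:
        extra = set(section) - {"segments", "dt", "record_every"}
        if extra:
            raise ConfigError(f"unknown key(s) in protocol: {', '.join(sorted(extra))}")
        segs = []
        for i, raw in enumerate(section["segments"]):
            _check_keys(raw, _SEGMENT_KEYS, f"protocol.segments[{i}]")
            try:
                segs.append(Segment(**raw))
            except ParameterError as exc:
                raise ConfigError(f"invalid protocol.segments[{i}]: {exc}") from exc
        try:
            return Protocol(segments=tuple(segs),
                            dt=float(section.get("dt", 0.1)),
                            record_every=float(section.get("record_every", 10.0)))
        except ParameterError as exc:
            raise ConfigError(f"invalid protocol: {exc}") from exc
    _check_keys(section, _PROTOCOL_PRESET_KEYS, "protocol")
    preset = section.get("preset", "standard_20_20_20")
    if preset != "standard_20_20_20":
        raise ConfigError(f"unknown protocol preset: {preset}")
    kwargs = {k: v for k, v in section.items() if k != "preset"}
    try:
        return standard_protocol(par=float(kwargs.pop("par", 239.0)), **kwargs)
    except ParameterError as exc:
        raise ConfigError(f"invalid protocol: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file = all defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "configuration")
    cfg = RunConfig()
    if "parameters" in raw:
        cfg.params = _build_params(raw["parameters"] or {})
    if "temperature_responses" in raw:
        tr = raw["temperature_responses"] or {}
        _check_keys(tr, {"rubisco", "etc"}, "temperature_responses")
        if "rubisco" in tr:
            cfg.tr_c = _build_tr(tr["rubisco"] or {}, cfg.tr_c,
                                 "temperature_responses.rubisco")
        if "etc" in tr:
            cfg.tr_j = _build_tr(tr["etc"] or {}, cfg.tr_j,
                                 "temperature_responses.etc")
    if "protocol" in raw:
        cfg.protocol = _build_protocol(raw["protocol"] or {})
    if "sweep" in raw:
        sweep = raw["sweep"] or {}
        _check_keys(sweep, _SWEEP_KEYS, "sweep")
        cfg.sweep = sweep
    if "output" in raw:
        out = raw["output"] or {}
        _check_keys(out, _OUTPUT_KEYS, "output")
        cfg.output.update(out)
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    """Serialize a RunConfig back to YAML (round-trips through load_config)."""
    doc: dict = {
        "parameters": dataclasses.asdict(cfg.params),
        "temperature_responses": {
            "rubisco": dataclasses.asdict(cfg.tr_c),
            "etc": dataclasses.asdict(cfg.tr_j),
        },
        "output": dict(cfg.output),
        "seed": cfg.seed,
    }
    if cfg.protocol is not None:
        doc["protocol"] = {
            "segments": [dataclasses.asdict(s) for s in cfg.protocol.segments],
            "dt": cfg.protocol.dt,
            "record_every": cfg.protocol.record_every,
        }
    if cfg.sweep is not None:
        doc["sweep"] = dict(cfg.sweep)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
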