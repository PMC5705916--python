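"""Run configuration: file loading, validation, and default resolution.

Configs are flat YAML (or JSON, a YAML subset) documents.  Parameter
overrides use the ParameterSet field names verbatim, either at top level
(``R_A: 0.5``) or under a ``params`` mapping.  Unknown keys are rejected
fail-fast, naming the offending key.  Every run writes the fully resolved
configuration (defaults + overrides + provenance flags) alongside results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Union

import yaml

from .model import STATE_FIELDS, CultureState, ModelVariant
from .params import ParameterSet, ParameterError, default_parameters
from .simulate import FeedSchedule, TransferProtocol, default_initial_state

__all__ = ["ConfigError", "RunConfig", "load_config", "parse_set_overrides"]

SCENARIOS = ("batch", "transfer", "fedbatch", "scan:affinity",
             "scan:excretion", "scan:inoculum", "critical-ratio")

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ParameterSet)}

_SCALAR_KEYS = {
    "scenario", "variant", "duration", "affinity_ratio",
    "growth_margin", "decline_tol", "out", "grid_dt",
}
_MAPPING_KEYS = {"params", "init", "transfer", "feed", "scan", "critical"}

_TRANSFER_KEYS = {"batch_duration", "dilution_fraction", "n_transfers",
                  "fresh_medium", "carry_spent_medium"}
_FEED_KEYS = {"pulse_times", "pulse_interval", "increment", "species",
              "duration"}
_SCAN_KEYS = {"kind", "values", "start", "stop", "num", "affinity_ratio",
              "reference_density"}
_CRITICAL_KEYS = {"criterion", "bounds", "tol"}


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending key."""


@dataclass
class RunConfig:
    """Validated, fully resolvable description of one simulation run."""

    scenario: str = "batch"
    variant: str = "default"
    duration: float = 300.0
    affinity_ratio: Optional[float] = None
    param_overrides: Dict[str, float] = field(default_factory=dict)
    init: Dict[str, float] = field(default_factory=dict)
    transfer: Dict[str, Any] = field(default_factory=dict)
    feed: Dict[str, Any] = field(default_factory=dict)
    scan: Dict[str, Any] = field(default_factory=dict)
    critical: Dict[str, Any] = field(default_factory=dict)
    growth_margin: float = 2.0
    decline_tol: float = 0.01
    grid_dt: float = 1.0
    out: str = "."

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"scenario: unknown value {self.scenario!r}; "
                f"expected one of {SCENARIOS}")
        try:
            ModelVariant.coerce(self.variant)
        except ValueError as err:
            raise ConfigError(f"variant: {err}") from None
        if self.duration <= 0:
            raise ConfigError("duration: must be > 0")
        if self.affinity_ratio is not None and self.affinity_ratio <= 0:
            raise ConfigError("affinity_ratio: must be > 0")
        self.parameters()  # validate overrides eagerly
        bad = set(self.init) - set(STATE_FIELDS)
        if bad:
            raise ConfigError(f"init: unknown state variable(s) {sorted(bad)}")
        for mapping, allowed, label in (
                (self.transfer, _TRANSFER_KEYS, "transfer"),
                (self.feed, _FEED_KEYS, "feed"),
                (self.scan, _SCAN_KEYS, "scan"),
                (self.critical, _CRITICAL_KEYS, "critical")):
            bad = set(mapping) - allowed
            if bad:
                raise ConfigError(f"{label}: unknown key(s) {sorted(bad)}")

    # -- resolution --------------------------------------------------------

    def parameters(self) -> ParameterSet:
        try:
            p = default_parameters(**self.param_overrides)
            if self.affinity_ratio is not None:
                p = p.with_affinity_ratio(self.affinity_ratio)
                # explicit K overrides win over the ratio convenience key
                keys = {k: v for k, v in self.param_overrides.items()
                        if k in ("K_A", "K_AR")}
                if keys:
                    p = p.with_overrides(**keys)
            return p
        except ParameterError as err:
            raise ConfigError(str(err)) from None

    def initial_state(self) -> CultureState:
        base = default_initial_state()
        vals = {name: getattr(base, name) for name in STATE_FIELDS}
        vals.update(self.init)
        return CultureState(**vals)

    def model_variant(self) -> ModelVariant:
        return ModelVariant.coerce(self.variant)

    def transfer_protocol(self) -> TransferProtocol:
        kwargs = dict(self.transfer)
        try:
            return TransferProtocol(**kwargs)
        except (TypeError, ValueError) as err:
            raise ConfigError(f"transfer: {err}") from None

    def feed_schedule(self) -> FeedSchedule:
        kwargs = dict(self.feed)
        interval = kwargs.pop("pulse_interval", None)
        if interval is not None and "pulse_times" not in kwargs:
            duration = float(kwargs.get("duration", 96.0))
            n = int(duration / interval)
            kwargs["pulse_times"] = tuple(interval * k for k in range(1, n + 1))
        try:
            return FeedSchedule(**kwargs)
        except (TypeError, ValueError) as err:
            raise ConfigError(f"feed: {err}") from None

    def as_config_dict(self) -> Dict[str, Any]:
        """A mapping that, loaded as a config, reproduces this run exactly."""
        doc: Dict[str, Any] = {
            "scenario": self.scenario,
            "variant": self.variant,
            "duration": self.duration,
            "params": self.parameters().to_dict(),
            "growth_margin": self.growth_margin,
            "decline_tol": self.decline_tol,
            "grid_dt": self.grid_dt,
            "out": self.out,
        }
        for key in ("init", "transfer", "feed", "scan", "critical"):
            val = getattr(self, key)
            if val:
                doc[key] = dict(val)
        return doc

    def resolved(self) -> Dict[str, Any]:
        """Defaults + overrides + provenance, suitable for the sidecar."""
        return {
            "scenario": self.scenario,
            "variant": self.variant,
            "duration": self.duration,
            "affinity_ratio": self.affinity_ratio,
            "parameters": self.parameters().describe(),
            "initial_state": {n: getattr(self.initial_state(), n)
                              for n in STATE_FIELDS},
            "transfer": self.transfer,
            "feed": self.feed,
            "scan": self.scan,
            "critical": self.critical,
            "growth_margin": self.growth_margin,
            "decline_tol": self.decline_tol,
            "grid_dt": self.grid_dt,
            "out": self.out,
        }


def _from_mapping(doc: Dict[str, Any]) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    doc = dict(doc)
    params = dict(doc.pop("params", {}) or {})
    # parameter names may also appear at top level
    for key in list(doc):
        if key in _PARAM_FIELDS:
            params[key] = doc.pop(key)
    unknown = set(doc) - _SCALAR_KEYS - _MAPPING_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    bad_params = set(params) - _PARAM_FIELDS
    if bad_params:
        raise ConfigError(f"params: unknown parameter(s) {sorted(bad_params)}")
    kwargs: Dict[str, Any] = {"param_overrides": params}
    for key in _SCALAR_KEYS & set(doc):
        kwargs[key] = doc[key]
    for key in _MAPPING_KEYS & set(doc):
        val = doc[key] or {}
        if not isinstance(val, dict):
            raise ConfigError(f"{key}: must be a mapping")
        kwargs[key] = val
    kwargs.pop("params", None)
    return RunConfig(**kwargs)


def load_config(path: Union[str, Path, None] = None,
                overrides: Optional[Dict[str, Any]] = None) -> RunConfig:
    """Load and validate a config file; ``None`` means all defaults.

    ``overrides`` (e.g. from repeated ``--set key=value`` flags) are applied
    on top of the file contents before validation.
    """
    doc: Dict[str, Any] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        text = p.read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config document must be a key-value mapping")
        doc = loaded
    for key, value in (overrides or {}).items():
        _assign_dotted(doc, key, value)
    return _from_mapping(doc)


def _assign_dotted(doc: Dict[str, Any], dotted: str, value: Any) -> None:
    parts = dotted.split(".")
    node = doc
    for part in parts[:-1]:
        nxt = node.get(part)
        if nxt is None:
            nxt = node[part] = {}
        if not isinstance(nxt, dict):
            raise ConfigError(f"cannot set {dotted!r}: {part!r} is not a mapping")
        node = nxt
    node[parts[-1]] = value


def parse_set_overrides(pairs: List[str]) -> Dict[str, Any]:
    """Parse repeated ``--set key=value`` strings (values as YAML scalars)."""
    out: Dict[str, Any] = {}
    for pair in pairs:
        if "=" not in pair:
            raise ConfigError(f"--set expects key=value, got {pair!r}")
        key, _, raw = pair.partition("=")
        key = key.strip()
        if not key:
            raise ConfigError(f"--set expects key=value, got {pair!r}")
        value = yaml.safe_load(raw)
        if isinstance(value, str):
            # YAML needs '2.7e+6' for scientific notation; accept '2.7e6' too
            try:
                value = float(value)
            except ValueError:
                pass
        out[key] = value
    return out
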