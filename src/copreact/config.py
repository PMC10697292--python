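"""Pipeline configuration: defaults, YAML loading, unknown-key rejection.

Config keys use dotted names grouped by stage (``filter.*``,
``epoch.*``, ``baseline.*``, ``trigger.*``, ``features.*``,
``stats.*``).  The only key without a default is
``trigger.mechanical_delay_s`` - the actuator travel time between the
electrical valve command and pelvis contact is rig-specific and must be
declared explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields

import yaml

from .errors import ConfigError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # filtering
    filter_cutoff_hz: float = 10.0
    filter_order: int = 4
    # epoch window (s relative to perturbation contact)
    epoch_t_pre: float = -0.4
    epoch_t_post: float = 2.0
    # baseline window (s)
    baseline_window: tuple[float, float] = (-0.35, -0.2)
    # trigger handling
    trigger_threshold: float = 2.5
    trigger_mechanical_delay_s: float | None = None  # required, rig-specific
    trigger_refractory_s: float = 0.5
    expected_events_per_recording: int = 3
    default_direction: int = 1
    # feature extraction
    features_window: tuple[float, float] = (0.0, 0.4)
    features_velocity_mode: str = "directional"
    # statistics
    stats_alpha: float = 0.05
    stats_rho: float = 0.5

    _ALIASES = {
        "filter.cutoff_hz": "filter_cutoff_hz",
        "filter.order": "filter_order",
        "epoch.t_pre": "epoch_t_pre",
        "epoch.t_post": "epoch_t_post",
        "baseline.window": "baseline_window",
        "trigger.threshold": "trigger_threshold",
        "trigger.mechanical_delay_s": "trigger_mechanical_delay_s",
        "trigger.refractory_s": "trigger_refractory_s",
        "expected_events_per_recording": "expected_events_per_recording",
        "default_direction": "default_direction",
        "features.window": "features_window",
        "features.velocity_mode": "features_velocity_mode",
        "stats.alpha": "stats_alpha",
        "stats.rho": "stats_rho",
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for key, val in d.items():
            attr = cls._ALIASES.get(key, key)
            if attr not in {f.name for f in dc_fields(cls)}:
                raise ConfigError(f"unknown config key {key!r}")
            if attr in ("baseline_window", "features_window"):
                val = tuple(float(v) for v in val)
            kwargs[attr] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(d)

    def require_delay(self) -> float:
        if self.trigger_mechanical_delay_s is None:
            raise ConfigError(
                "trigger.mechanical_delay_s is required (actuator travel time); "
                "set it in the config"
            )
        return float(self.trigger_mechanical_delay_s)

    def echo(self) -> None:
        """Log every materialized value for run provenance."""
        for f in dc_fields(self):
            log.info("config %s = %r", f.name, getattr(self, f.name))

    def to_dict(self) -> dict:
        inv = {v: k for k, v in self._ALIASES.items()}
        return {
            inv[f.name]: getattr(self, f.name)
            for f in dc_fields(self)
            if f.name in inv
        }
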