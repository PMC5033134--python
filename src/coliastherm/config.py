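"""Structured YAML run configuration with schema validation.

A config file has up to three sections; every key must belong to the schema,
and offending keys are named in the error:

.. code-block:: yaml

    experiments:
      n_per_cell: 24
      n_days: 3
      t_end: 800
    physical_params:
      proj_frac: 0.3
    sensitivity:
      meadii:   {mu: 24.7, sd: 1.5, p_mot: 0.8}
      eriphyle: {mu: 25.5, sd: 1.5, p_mot: 0.8}

Values override the package defaults; anything omitted keeps its default.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .biophys import PhysicalParams
from .flight import ThermalSensitivity

__all__ = ["ConfigError", "RunConfig", "load_run_config"]

_EXPERIMENT_KEYS = {"n_per_cell", "n_days", "t_end", "check_interval"}
_SENS_KEYS = {"mu", "sd", "p_mot"}


class ConfigError(ValueError):
    """A config file contains an unknown or invalid key."""


@dataclass
class RunConfig:
    """Validated overrides applied on top of the package defaults."""

    experiments: dict = field(default_factory=dict)
    physical_params: PhysicalParams = field(default_factory=PhysicalParams)
    sensitivities: dict = field(default_factory=dict)


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping of sections")

    known_sections = {"experiments", "physical_params", "sensitivity"}
    for sec in raw:
        if sec not in known_sections:
            raise ConfigError(f"unknown config section {sec!r}")

    exp = dict(raw.get("experiments") or {})
    for key in exp:
        if key not in _EXPERIMENT_KEYS:
            raise ConfigError(f"unknown key {key!r} in section 'experiments'")

    pp_fields = {f.name for f in dataclasses.fields(PhysicalParams)}
    pp_raw = dict(raw.get("physical_params") or {})
    for key in pp_raw:
        if key not in pp_fields:
            raise ConfigError(f"unknown key {key!r} in section 'physical_params'")
    try:
        params = PhysicalParams(**pp_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid physical_params: {exc}") from exc

    sens = {}
    for sp, entry in (raw.get("sensitivity") or {}).items():
        if not isinstance(entry, dict):
            raise ConfigError(f"sensitivity for {sp!r} must be a mapping")
        for key in entry:
            if key not in _SENS_KEYS:
                raise ConfigError(
                    f"unknown key {key!r} in section 'sensitivity.{sp}'"
                )
        missing = _SENS_KEYS - set(entry)
        if missing:
            raise ConfigError(
                f"sensitivity.{sp} missing key(s) {sorted(missing)}"
            )
        try:
            sens[sp] = ThermalSensitivity(**entry)
        except ValueError as exc:
            raise ConfigError(f"invalid sensitivity.{sp}: {exc}") from exc

    return RunConfig(experiments=exp, physical_params=params,
                     sensitivities=sens)
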