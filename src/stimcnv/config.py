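"""YAML configuration: schema, defaults, validation, round-trip dump.

The configuration mirrors the model parameter blocks one-to-one:

.. code-block:: yaml

    seed: 0
    activity:   { copper_K: 0.3, ... }      # environment -> locus activity map
    rate:       { b: 0.0015, r_max: 0.05, ... }
    switch:     { p_forward: 0.5, n_switches: 2, ... }
    fitness:    { mu_max: 0.5, K0: 0.385, ... }
    simulation: { p_esc: 0.0, population_cap: 100000, ... }

Every key is optional (defaults fill in); unknown keys are rejected with the
offending dotted key name. Dataclass invariants (e.g. b + r_max <= 1) are
enforced on load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .core_model import ActivityParams, RateParams, SwitchScheme
from .errors import ConfigurationError
from .population import FitnessParams, ModelParams, SimParams

__all__ = ["RunConfig", "load_config", "dump_config", "default_config"]

_SECTIONS = {
    "activity": ActivityParams,
    "rate": RateParams,
    "switch": SwitchScheme,
    "fitness": FitnessParams,
    "simulation": SimParams,
}


@dataclass(frozen=True)
class RunConfig:
    """Fully-validated run configuration with all defaults filled."""

    seed: int = 0
    activity: ActivityParams = field(default_factory=ActivityParams)
    rate: RateParams = field(default_factory=RateParams)
    switch: SwitchScheme = field(default_factory=SwitchScheme)
    fitness: FitnessParams = field(default_factory=FitnessParams)
    simulation: SimParams = field(default_factory=SimParams)

    def model_params(self) -> ModelParams:
        return ModelParams(
            activity=self.activity,
            rate=self.rate,
            switch=self.switch,
            fitness=self.fitness,
            sim=self.simulation,
        )


def default_config() -> RunConfig:
    return RunConfig()


def _build_section(name: str, cls, payload) -> object:
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ConfigurationError(f"section {name!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    for key in payload:
        if key not in known:
            raise ConfigurationError(f"unknown configuration key '{name}.{key}'")
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid section {name!r}: {exc}") from exc


def load_config(path: Union[str, Path, None]) -> RunConfig:
    """Load and validate a YAML config; ``None`` or an empty file gives defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw, source=str(path))


def config_from_dict(raw, source: str = "<config>") -> RunConfig:
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{source}: top level must be a mapping")
    known = set(_SECTIONS) | {"seed"}
    for key in raw:
        if key not in known:
            raise ConfigurationError(f"unknown configuration key '{key}'")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigurationError("'seed' must be an integer")
    sections = {
        name: _build_section(name, cls, raw.get(name)) for name, cls in _SECTIONS.items()
    }
    return RunConfig(
        seed=seed,
        activity=sections["activity"],
        rate=sections["rate"],
        switch=sections["switch"],
        fitness=sections["fitness"],
        simulation=sections["simulation"],
    )


def dump_config(config: RunConfig) -> str:
    """Serialise a config to YAML; ``load`` of the dump is an identity."""
    payload = {"seed": config.seed}
    for name in _SECTIONS:
        payload[name] = dataclasses.asdict(getattr(config, name))
    return yaml.safe_dump(payload, sort_keys=False)
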