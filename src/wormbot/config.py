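"""Global run configuration.

A single nested dataclass tree holds every tunable the simulator exposes:
integrator step, the nA->uA/cm^2 stimulus scale, synapse defaults, spike
detection, and robot physical parameters.  Configs load from JSON or YAML,
reject unknown keys, and serialize losslessly into run metadata so any run
can be replayed bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "IntegratorConfig",
    "SynapseConfig",
    "SpikeConfig",
    "RobotConfig",
    "RunConfig",
    "load_config",
]


class ConfigError(ValueError):
    """Raised for unknown keys or malformed config files."""


@dataclass
class IntegratorConfig:
    #: fixed time step, ms; gates use an exponential update, V explicit Euler
    dt: float = 0.01
    #: stimulus unit scale: protocol amplitudes are "nA" in the interface,
    #: current densities internally; 1 nA == `na_scale` uA/cm^2
    na_scale: float = 1.0


@dataclass
class SynapseConfig:
    #: presynaptic membrane-voltage threshold for chemical transmission, mV
    threshold: float = -30.0
    #: reversal potential of excitatory synapses, mV
    e_excitatory: float = 0.0
    #: reversal potential of inhibitory synapses, mV
    e_inhibitory: float = -80.0
    #: default conductance decay constant when a file omits it, ms
    tau: float = 10.0
    #: global multiplier bridging unitless weights and current densities
    gain: float = 1.0


@dataclass
class SpikeConfig:
    #: upward-crossing detection level, mV
    crossing: float = 0.0
    #: minimum separation between detected spikes, ms
    refractory: float = 2.0


@dataclass
class RobotConfig:
    mass: float = 10.0  # kg
    #: body-frame principal moments of inertia, kg m^2 (uniform sphere default)
    inertia: tuple[float, float, float] = (0.36, 0.36, 0.36)
    gravity: float = 9.81  # m/s^2
    contact_stiffness: float = 2.0e4  # N/m, leg-tip normal spring
    contact_damping: float = 500.0  # N s/m
    friction: float = 0.8  # Coulomb coefficient at the leg tips
    #: viscous slope used below the Coulomb cap (regularized stiction), N s/m
    tangential_damping: float = 500.0
    leg_min: float = 0.24  # m, fully retracted tip radius
    leg_max: float = 0.50  # m, fully extended (expansion ratio ~2.08)
    leg_rate: float = 0.25  # m/s slew limit
    #: radius of the central shell, used as a fallback ground contact, m
    shell_radius: float = 0.20


@dataclass
class RunConfig:
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    synapse: SynapseConfig = field(default_factory=SynapseConfig)
    spike: SpikeConfig = field(default_factory=SpikeConfig)
    robot: RobotConfig = field(default_factory=RobotConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        return _build(cls, data, path="")


def _build(cls: type, data: dict[str, Any], path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping at {path or 'top level'}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}"
        )
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = _NESTED.get((cls.__name__, name))
        if target is not None:
            kwargs[name] = _build(target, value, path=f"{path}{name}.")
        elif name == "inertia":
            kwargs[name] = tuple(float(v) for v in value)
        else:
            kwargs[name] = value
    del ftype
    return cls(**kwargs)


_NESTED = {
    ("RunConfig", "integrator"): IntegratorConfig,
    ("RunConfig", "synapse"): SynapseConfig,
    ("RunConfig", "spike"): SpikeConfig,
    ("RunConfig", "robot"): RobotConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    return RunConfig.from_dict(data)
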