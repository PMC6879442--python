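"""Declarative run configuration.

A single YAML file (or nested dict) describes a complete experiment:
network topology, per-class neuron parameters, per-projection synapse
parameters, plasticity constants, the stimulation protocol, and engine
settings.  Every omitted field falls back to the shipped defaults, so an
empty file is the complete default experiment.  Unknown keys and invariant
violations raise :class:`ConfigurationError` naming the field path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import params as P
from .engine import EngineConfig
from .errors import ConfigurationError
from .network import Network, NetworkSpec, build
from .neurons import NeuronParams
from .plasticity import BcpnnParams
from .stimulation import NoiseSpec, Protocol, default_protocol

__all__ = ["ProtocolConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class ProtocolConfig:
    """Amplitudes of the two-stimulus default protocol."""

    stim_rate: float = P.STIM_RATE
    stim_weight_pyr: float = P.STIM_WEIGHT_PYR
    stim_weight_dbc: float = P.STIM_WEIGHT_DBC
    noise_rate: float = P.ZMN_RATE
    noise_g_exc: float = P.ZMN_G_EXC
    noise_g_inh: float | None = None
    noise_v_ref: float = P.ZMN_V_REF
    noise_class_scale: tuple[tuple[str, float], ...] = P.ZMN_CLASS_SCALE


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved experiment description."""

    network: NetworkSpec = field(default_factory=NetworkSpec)
    neurons: dict = field(default_factory=lambda: dict(P.NEURON_DEFAULTS))
    synapses: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in P.PROJECTION_DEFAULTS.items()})
    plasticity: BcpnnParams = field(default_factory=lambda: P.BCPNN_DEFAULTS)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)

    def __post_init__(self) -> None:
        for t in self.engine.snapshot_times:
            if t > self.engine.t_end + 1e-9:
                raise ConfigurationError(
                    f"engine.snapshot_times: {t} exceeds t_end")

    # ---- realization ----------------------------------------------------
    def build_network(self, rng_seed: int | None = None) -> Network:
        spec = self.network
        if rng_seed is not None:
            spec = replace(spec, rng_seed=rng_seed)
        return build(spec, neuron_params=self.neurons,
                     projection_params=self.synapses)

    def build_protocol(self) -> Protocol:
        pc = self.protocol
        noise = NoiseSpec(rate=pc.noise_rate, g_exc=pc.noise_g_exc,
                          g_inh=pc.noise_g_inh, v_ref=pc.noise_v_ref,
                          class_scale=pc.noise_class_scale)
        return default_protocol(self.network, rate=pc.stim_rate,
                                weight_pyr=pc.stim_weight_pyr,
                                weight_dbc=pc.stim_weight_dbc, noise=noise)

    # ---- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "network": dataclasses.asdict(self.network),
            "neurons": {k: dataclasses.asdict(v) for k, v in self.neurons.items()},
            "synapses": {k: dict(v) for k, v in self.synapses.items()},
            "plasticity": dataclasses.asdict(self.plasticity),
            "protocol": dataclasses.asdict(self.protocol),
            "engine": dataclasses.asdict(self.engine),
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _coerce_dataclass(cls, defaults, updates: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(updates) - known
    if unknown:
        raise ConfigurationError(
            f"{path}.{sorted(unknown)[0]}: unknown configuration key")
    merged = {**dataclasses.asdict(defaults), **updates}
    # dataclass validators raise ValueError/ConfigurationError; re-tag with path
    try:
        return cls(**_tupled(cls, merged))
    except ConfigurationError:
        raise
    except ValueError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def _tupled(cls, d: dict) -> dict:
    # YAML produces lists where the dataclasses expect tuples
    out = {}
    for f in dataclasses.fields(cls):
        v = d[f.name]
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        out[f.name] = v
    return out


def from_dict(data: dict | None) -> RunConfig:
    """Resolve a (possibly partial) configuration dict against defaults."""
    data = data or {}
    known_sections = {"network", "neurons", "synapses", "plasticity",
                      "protocol", "engine"}
    unknown = set(data) - known_sections
    if unknown:
        raise ConfigurationError(
            f"{sorted(unknown)[0]}: unknown configuration section")

    network = _coerce_dataclass(NetworkSpec, NetworkSpec(),
                                data.get("network", {}), "network")

    neurons = dict(P.NEURON_DEFAULTS)
    for cls_name, upd in (data.get("neurons") or {}).items():
        if cls_name not in neurons:
            raise ConfigurationError(f"neurons.{cls_name}: unknown cell class")
        neurons[cls_name] = _coerce_dataclass(
            NeuronParams, neurons[cls_name], upd, f"neurons.{cls_name}")

    synapses = {k: dict(v) for k, v in P.PROJECTION_DEFAULTS.items()}
    for kind, upd in (data.get("synapses") or {}).items():
        if kind not in synapses:
            raise ConfigurationError(f"synapses.{kind}: unknown projection kind")
        bad = set(upd) - set(synapses[kind])
        if bad:
            raise ConfigurationError(
                f"synapses.{kind}.{sorted(bad)[0]}: unknown key")
        synapses[kind].update(upd)

    plasticity = _coerce_dataclass(BcpnnParams, P.BCPNN_DEFAULTS,
                                   data.get("plasticity", {}), "plasticity")
    protocol = _coerce_dataclass(ProtocolConfig, ProtocolConfig(),
                                 data.get("protocol", {}), "protocol")
    engine = _coerce_dataclass(EngineConfig, EngineConfig(),
                               data.get("engine", {}), "engine")
    return RunConfig(network=network, neurons=neurons, synapses=synapses,
                     plasticity=plasticity, protocol=protocol, engine=engine)


def load_config(path=None) -> RunConfig:
    """Load a YAML run configuration; ``None`` or an empty file yields the
    complete default experiment."""
    if path is None:
        return from_dict({})
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    return from_dict(data)
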