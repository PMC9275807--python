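"""Configuration loading, validation and serialisation.

One structured YAML file holds everything a run needs: integration step,
nucleus parameters, synapse table (with shared constants), baseline
currents, stimulation protocols, synthetic-target generator anchors and
GA settings.  Loading is strict: unknown keys and missing sections are
errors, and every value passes the domain types' own invariants.  The
package ships a reference file whose synapse rows are the published
fitted values and whose nucleus/input values are this package's
re-derived defaults.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError
from .ga import GAConfig, default_bounds, genome_from_synapses
from .network import NetworkConfig, StepInput, StimulationProtocol
from .nucleus import NUCLEUS_LABELS, NucleusParams
from .patterns import PATTERNS, GeneratorSettings
from .synapse import PROJECTIONS, SYNAPSE_NAMES, SynapseParams

_NUCLEUS_KEYS = {"a", "b", "c", "d", "regime"}
_SYNAPSE_KEYS = {"alpha", "beta", "g_syn", "t_max"}
_SHARED_KEYS = {"threshold", "E_syn", "T"}
_TOP_KEYS = {"integration", "nuclei", "synapses", "baseline", "protocols",
             "generator", "ga"}
_PROTOCOL_KEYS = {"total_duration", "init_duration", "onset", "duration",
                  "amplitudes"}
_GA_KEYS = {"population_size", "elite_fraction", "crossover_prob",
            "mutation_prob", "mutation_scale", "max_generations",
            "stop_fitness_ratio"}
_GENERATOR_KEYS = {"resting_ipi", "acceleration_plateau", "scallop_floor",
                   "cessation_pause", "jitter", "onset", "step_duration",
                   "total_duration", "recovery"}


@dataclass(frozen=True)
class ProtocolSettings:
    """Timing shared by the four stimulation cases plus per-pattern step
    amplitudes (nucleus -> current)."""

    total_duration: float
    init_duration: tuple[float, float]
    onset: float
    duration: float
    amplitudes: dict[str, dict[str, float]]

    def build(self, pattern: str) -> StimulationProtocol:
        """The StimulationProtocol of one pattern (or 'baseline')."""
        if pattern == "baseline":
            steps: tuple[StepInput, ...] = ()
        else:
            if pattern not in self.amplitudes:
                raise ConfigError(f"no step amplitudes for pattern {pattern!r}")
            steps = tuple(
                StepInput(nucleus=n, onset=self.onset, duration=self.duration,
                          amplitude=a)
                for n, a in sorted(self.amplitudes[pattern].items())
            )
        return StimulationProtocol(
            pattern_label=pattern,
            steps=steps,
            total_duration=self.total_duration,
            init_duration=self.init_duration,
        )

    def build_all(self) -> dict[str, StimulationProtocol]:
        return {p: self.build(p) for p in PATTERNS}


@dataclass(frozen=True)
class FullConfig:
    """Validated bundle of everything in one configuration file."""

    network: NetworkConfig
    protocols: ProtocolSettings
    generator: GeneratorSettings
    ga: GAConfig


def _require_keys(section: dict, allowed: set[str], where: str,
                  required: set[str] | None = None) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    missing = (required if required is not None else allowed) - set(section)
    if missing:
        raise ConfigError(f"missing keys in {where}: {sorted(missing)}")


def parse_config(raw: dict) -> FullConfig:
    """Validate a parsed YAML mapping into a FullConfig."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _require_keys(raw, _TOP_KEYS, "configuration root")

    integ = raw["integration"]
    _require_keys(integ, {"dt"}, "integration")
    dt = float(integ["dt"])

    nuclei = {}
    _require_keys(raw["nuclei"], set(NUCLEUS_LABELS), "nuclei")
    for label in NUCLEUS_LABELS:
        sec = raw["nuclei"][label]
        _require_keys(sec, _NUCLEUS_KEYS, f"nuclei.{label}",
                      required=_NUCLEUS_KEYS - {"regime"})
        try:
            nuclei[label] = NucleusParams(
                a=float(sec["a"]), b=float(sec["b"]), c=float(sec["c"]),
                d=float(sec["d"]), label=label,
                regime=str(sec.get("regime", "")),
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    syn_raw = dict(raw["synapses"])
    shared = syn_raw.pop("shared", {})
    _require_keys(shared, _SHARED_KEYS, "synapses.shared", required=set())
    _require_keys(syn_raw, set(SYNAPSE_NAMES), "synapses")
    synapses = {}
    for name in SYNAPSE_NAMES:
        sec = syn_raw[name]
        _require_keys(sec, _SYNAPSE_KEYS, f"synapses.{name}")
        pre, post = PROJECTIONS[name]
        try:
            synapses[name] = SynapseParams(
                alpha=float(sec["alpha"]), beta=float(sec["beta"]),
                g_syn=float(sec["g_syn"]), t_max=float(sec["t_max"]),
                threshold=float(shared.get("threshold", 0.0)),
                E_syn=float(shared.get("E_syn", -80.0)),
                T=float(shared.get("T", 1.0)),
                pre_label=pre, post_label=post,
            )
        except ValueError as exc:
            raise ConfigError(f"synapse {name}: {exc}") from exc

    _require_keys(raw["baseline"], set(NUCLEUS_LABELS), "baseline")
    baseline = {k: float(v) for k, v in raw["baseline"].items()}

    try:
        network = NetworkConfig(nuclei=nuclei, synapses=synapses,
                                baseline_inputs=baseline, dt=dt)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    psec = raw["protocols"]
    _require_keys(psec, _PROTOCOL_KEYS, "protocols")
    amps = psec["amplitudes"]
    _require_keys(amps, set(PATTERNS), "protocols.amplitudes")
    try:
        protocols = ProtocolSettings(
            total_duration=float(psec["total_duration"]),
            init_duration=tuple(float(x) for x in psec["init_duration"]),
            onset=float(psec["onset"]),
            duration=float(psec["duration"]),
            amplitudes={p: {n: float(a) for n, a in amps[p].items()}
                        for p in PATTERNS},
        )
        protocols.build_all()  # validates step/nucleus assignments
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"protocols: {exc}") from exc

    gsec = raw["generator"]
    _require_keys(gsec, _GENERATOR_KEYS, "generator")
    generator = GeneratorSettings(**{k: float(gsec[k]) for k in _GENERATOR_KEYS})

    gasec = raw["ga"]
    _require_keys(gasec, _GA_KEYS, "ga")
    try:
        ga = GAConfig(
            bounds=default_bounds(genome_from_synapses(synapses)),
            population_size=int(gasec["population_size"]),
            elite_fraction=float(gasec["elite_fraction"]),
            crossover_prob=float(gasec["crossover_prob"]),
            mutation_prob=float(gasec["mutation_prob"]),
            mutation_scale=float(gasec["mutation_scale"]),
            max_generations=int(gasec["max_generations"]),
            stop_fitness_ratio=float(gasec["stop_fitness_ratio"]),
        )
    except ValueError as exc:
        raise ConfigError(f"ga: {exc}") from exc

    return FullConfig(network=network, protocols=protocols,
                      generator=generator, ga=ga)


def load_config(path: str | Path) -> FullConfig:
    """Load and validate one YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw)


def dump_config(cfg: FullConfig) -> dict:
    """FullConfig back to the plain mapping the YAML schema defines."""
    n = cfg.network
    first = next(iter(n.synapses.values()))
    return {
        "integration": {"dt": n.dt},
        "nuclei": {
            label: {"a": p.a, "b": p.b, "c": p.c, "d": p.d, "regime": p.regime}
            for label, p in n.nuclei.items()
        },
        "synapses": {
            "shared": {"threshold": first.threshold, "E_syn": first.E_syn,
                       "T": first.T},
            **{
                name: {"alpha": s.alpha, "beta": s.beta, "g_syn": s.g_syn,
                       "t_max": s.t_max}
                for name, s in n.synapses.items()
            },
        },
        "baseline": dict(n.baseline_inputs),
        "protocols": {
            "total_duration": cfg.protocols.total_duration,
            "init_duration": list(cfg.protocols.init_duration),
            "onset": cfg.protocols.onset,
            "duration": cfg.protocols.duration,
            "amplitudes": {p: dict(v) for p, v in cfg.protocols.amplitudes.items()},
        },
        "generator": {
            "resting_ipi": cfg.generator.resting_ipi,
            "acceleration_plateau": cfg.generator.acceleration_plateau,
            "scallop_floor": cfg.generator.scallop_floor,
            "cessation_pause": cfg.generator.cessation_pause,
            "jitter": cfg.generator.jitter,
            "onset": cfg.generator.onset,
            "step_duration": cfg.generator.step_duration,
            "total_duration": cfg.generator.total_duration,
            "recovery": cfg.generator.recovery,
        },
        "ga": {
            "population_size": cfg.ga.population_size,
            "elite_fraction": cfg.ga.elite_fraction,
            "crossover_prob": cfg.ga.crossover_prob,
            "mutation_prob": cfg.ga.mutation_prob,
            "mutation_scale": cfg.ga.mutation_scale,
            "max_generations": cfg.ga.max_generations,
            "stop_fitness_ratio": cfg.ga.stop_fitness_ratio,
        },
    }


def save_config(cfg: FullConfig, path: str | Path) -> None:
    """Write a FullConfig as YAML (round-trips through load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(dump_config(cfg), fh, sort_keys=False)


def reference_path() -> Path:
    """Path of the shipped reference configuration file."""
    return Path(
        importlib.resources.files("electromotor").joinpath("data/reference_rga.yaml")
    )


def load_reference_config() -> FullConfig:
    """The shipped reference configuration (published synapse table plus
    this package's re-derived nucleus and input settings)."""
    return load_config(reference_path())


def synapse_table(synapses: dict[str, SynapseParams]) -> pd.DataFrame:
    """Synapse parameters as a table mirroring the published layout
    (columns synapse, alpha, beta, g_syn, t_max)."""
    rows = [
        {"synapse": name, "alpha": s.alpha, "beta": s.beta,
         "g_syn": s.g_syn, "t_max": s.t_max}
        for name, s in synapses.items()
    ]
    return pd.DataFrame(rows)


def synapses_from_table(
    table: pd.DataFrame, template: dict[str, SynapseParams]
) -> dict[str, SynapseParams]:
    """Rebuild SynapseParams from a synapse table, taking shared constants
    and wiring from ``template``."""
    out = {}
    for _, row in table.iterrows():
        name = row["synapse"]
        if name not in template:
            raise ConfigError(f"unknown synapse {name!r} in table")
        out[name] = replace(
            template[name],
            alpha=float(row["alpha"]), beta=float(row["beta"]),
            g_syn=float(row["g_syn"]), t_max=float(row["t_max"]),
        )
    missing = set(template) - set(out)
    if missing:
        raise ConfigError(f"table missing synapses: {sorted(missing)}")
    return out
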