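"""Experiment configuration: TOML parsing, defaults, serialization.

An experiment ties simulation → group ICA runs → RA evaluation into one
reproducible unit. Defaults are a desk-scale study (10 datasets, 32
channels, 256 samples, 100 trials) that finishes in minutes on one CPU;
the full-scale study configuration (20 datasets, 63 channels, 500
trials) is provided alongside as ``configs/full_scale.toml``.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .ica import available_algorithms

__all__ = ["SimulationConfig", "AnalysisConfig", "EvaluationConfig",
           "ExperimentConfig", "load_config", "dump_config"]


@dataclass
class SimulationConfig:
    n_datasets: int = 10
    n_channels: int = 32
    samples_per_epoch: int = 256
    n_trials: int = 100
    jitter: list[float] = field(default_factory=lambda: [20.0, 40.0, 60.0])
    mean_latencies: list[float] = field(default_factory=lambda: [64.0, 128.0, 192.0])
    fwhm: float = 20.0
    between_jitter: float = 20.0
    location_stride: int = 2
    seed: int = 1000


@dataclass
class AnalysisConfig:
    L: int = 20
    n_components: list = field(default_factory=lambda: [20])  # ints or "mdl"
    algorithms: list[str] = field(default_factory=lambda: ["infomax"])
    seed: int = 2000
    include_single_subject: bool = False


@dataclass
class EvaluationConfig:
    peak_window: int = 20
    report: str = "ra_report.tsv"
    results_dir: str = "results"


@dataclass
class ExperimentConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def validate(self) -> None:
        sim, ana = self.simulation, self.analysis
        if len(sim.jitter) != 3 or len(sim.mean_latencies) != 3:
            raise ValueError("jitter and mean_latencies must list three sources")
        if sim.n_datasets < 1 or sim.n_trials < 1:
            raise ValueError("n_datasets and n_trials must be positive")
        if ana.L > sim.n_channels:
            raise ValueError(f"L={ana.L} exceeds channel count {sim.n_channels}")
        known = set(available_algorithms())
        unknown = [a for a in ana.algorithms if a not in known]
        if unknown:
            raise ValueError(
                f"unknown algorithm(s) {unknown}; available: {sorted(known)}"
            )
        for n in ana.n_components:
            if n == "mdl":
                continue
            if not isinstance(n, int) or n < 1 or n > ana.L * sim.n_datasets:
                raise ValueError(f"invalid component count {n!r}")


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse a TOML experiment configuration; absent keys keep defaults."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = ExperimentConfig()
    for section, target in (("simulation", cfg.simulation),
                            ("analysis", cfg.analysis),
                            ("evaluation", cfg.evaluation)):
        for key, value in raw.get(section, {}).items():
            if not hasattr(target, key):
                raise ValueError(f"unknown config key [{section}] {key}")
            setattr(target, key, value)
    cfg.validate()
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, list):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_config(cfg: ExperimentConfig, path: str | Path) -> None:
    """Serialize a configuration to TOML; round-trips through load_config."""
    lines = []
    for section in ("simulation", "analysis", "evaluation"):
        lines.append(f"[{section}]")
        for key, value in asdict(getattr(cfg, section)).items():
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
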