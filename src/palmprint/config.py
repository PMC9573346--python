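"""Run configuration: the heuristic score ledger plus clustering and rank
band constants, round-trippable through a flat TOML file.

Defaults are the shipped constants: motif-score floor 2 bits, V1 short
bound 35 aa with a 5-bit penalty, high-confidence threshold 20 bits,
species clustering threshold 90% identity, rank band bounds 90/70/45.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .scanner import HeuristicConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    heuristics: HeuristicConfig = field(default_factory=HeuristicConfig)
    cluster_threshold: float = 90.0
    band_species: float = 90.0
    band_genus: float = 70.0
    band_family: float = 45.0
    seed: int = 1
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not (self.band_family < self.band_genus < self.band_species):
            raise ValueError("rank band bounds must be strictly increasing")


def load_config(path: str | Path) -> RunConfig:
    """Load a flat TOML config; unknown keys are an error."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    heur_data = data.pop("heuristics", {})
    heur_fields = {f.name for f in fields(HeuristicConfig)}
    run_fields = {f.name for f in fields(RunConfig)} - {"heuristics"}
    bad = (set(heur_data) - heur_fields) | (set(data) - run_fields)
    if bad:
        raise ValueError(f"unknown config key(s): {sorted(bad)}")
    return RunConfig(heuristics=HeuristicConfig(**heur_data), **data)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, int):
        return str(v)
    return f'"{v}"'


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config as flat TOML; load_config round-trips it losslessly."""
    with open(path, "w") as fh:
        for f in fields(RunConfig):
            if f.name == "heuristics":
                continue
            fh.write(f"{f.name} = {_toml_value(getattr(cfg, f.name))}\n")
        fh.write("\n[heuristics]\n")
        for k, v in asdict(cfg.heuristics).items():
            fh.write(f"{k} = {_toml_value(v)}\n")
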