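"""Flat YAML pipeline configuration.

One file with per-stage sections; unknown keys and bad values are rejected
with the offending field named.  CLI flags override config values; all
randomness flows from a single root seed split per stage.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .classification import ClassificationParams
from .decomposition import ALSParams
from .errors import ConfigError
from .synthetic import PRESETS, GeneratorConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclasses.dataclass
class PipelineConfig:
    simulate: GeneratorConfig
    preset: str | None
    concentrations: tuple[float, ...]
    n_fields: int
    als: ALSParams | None  # None -> derived from frame rate
    classification: ClassificationParams
    imaging: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "simulate": dataclasses.asdict(self.simulate),
            "preset": self.preset,
            "concentrations": list(self.concentrations),
            "n_fields": self.n_fields,
            "als": dataclasses.asdict(self.als) if self.als else None,
            "classification": dataclasses.asdict(self.classification),
            "imaging": self.imaging,
            "seed": self.seed,
        }


def _build_section(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in section:
        if key not in valid:
            raise ConfigError(f"{name}.{key}", "unknown parameter")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(name, str(exc)) from exc


def load_config(path: str | Path, seed: int | None = None) -> PipelineConfig:
    """Load and validate a pipeline YAML file.

    ``seed`` (e.g. from a CLI flag) overrides the file's seed.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("<root>", "config must be a mapping")
    known = {
        "simulate", "preset", "concentrations", "n_fields",
        "als", "classification", "imaging", "seed",
    }
    for key in raw:
        if key not in known:
            raise ConfigError(key, "unknown section")

    preset = raw.get("preset")
    if preset is not None and preset not in PRESETS:
        raise ConfigError("preset", f"must be one of {sorted(PRESETS)}")

    sim = _build_section(GeneratorConfig, raw.get("simulate", {}), "simulate")
    als = None
    if raw.get("als"):
        als = _build_section(ALSParams, raw["als"], "als")
    cls_params = _build_section(
        ClassificationParams, raw.get("classification", {}), "classification"
    )

    concs = raw.get("concentrations", [sim.concentration_nmol])
    if not isinstance(concs, (list, tuple)) or not concs:
        raise ConfigError("concentrations", "must be a non-empty list")
    n_fields = int(raw.get("n_fields", 1))
    if n_fields < 1:
        raise ConfigError("n_fields", "must be >= 1")

    cfg_seed = int(raw.get("seed", sim.seed))
    if seed is not None:
        cfg_seed = int(seed)

    return PipelineConfig(
        simulate=sim,
        preset=preset,
        concentrations=tuple(float(c) for c in concs),
        n_fields=n_fields,
        als=als,
        classification=cls_params,
        imaging=dict(raw.get("imaging", {})),
        seed=cfg_seed,
    )
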