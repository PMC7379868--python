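"""Run configuration: a schema-versioned, strictly-validated YAML block.

A single master ``seed`` is fanned out to per-stage seeds through a
documented counter scheme (``SeedSequence([master, STAGE_INDEX])`` reduced
below 2**31), so any stage can be replayed in isolation.  Unknown keys are
rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "stage_seed", "STAGES"]

SCHEMA_VERSION = 1

#: Stage names and their fan-out indices for seed derivation.
STAGES = {"synthdata": 1, "ensemble": 2, "cv": 3}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive the deterministic sub-seed of a named stage (< 2**31)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; known: {sorted(STAGES)}")
    seq = np.random.SeedSequence([int(master_seed), STAGES[stage]])
    return int(seq.generate_state(1)[0] % (2**31))


def _check_keys(section: str, raw: dict, allowed: set[str]) -> None:
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {section!r}: {sorted(unknown)}")


@dataclass
class SynthSection:
    n_channels: int = 16
    n_trials_per_class: int = 30
    hrf_amplitude_hbo: float = 0.05
    hrf_amplitude_hbr: float = -0.02
    responsive_channel_fraction: float = 0.5


@dataclass
class FilterSection:
    low: float = 0.01
    high: float = 0.09
    order: int = 6


@dataclass
class EpochSection:
    window: tuple[float, float] = (-1.0, 15.0)
    baseline: tuple[float, float] = (-1.0, 0.0)


@dataclass
class FeatureSection:
    features: tuple[str, ...] = ("AVG",)
    window_type: int = 4
    slope_method: str = "ols"


@dataclass
class EnsembleSection:
    M: int | str = "auto"  # "auto" -> ladder search
    N: int = 100
    strong_kind: str = "linear_svm"


@dataclass
class EvaluateSection:
    R: int = 10
    K: int = 10
    df: int = 10
    test: str = "corrected"
    n_grid: tuple[int, ...] = (1, 2, 5, 10, 20, 50, 100)


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    seed: int = 0
    schema_version: int = SCHEMA_VERSION
    synthdata: SynthSection = field(default_factory=SynthSection)
    filter: FilterSection = field(default_factory=FilterSection)
    epoch: EpochSection = field(default_factory=EpochSection)
    features: FeatureSection = field(default_factory=FeatureSection)
    ensemble: EnsembleSection = field(default_factory=EnsembleSection)
    evaluate: EvaluateSection = field(default_factory=EvaluateSection)

    _SECTIONS = {
        "synthdata": SynthSection,
        "filter": FilterSection,
        "epoch": EpochSection,
        "features": FeatureSection,
        "ensemble": EnsembleSection,
        "evaluate": EvaluateSection,
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        _check_keys("config", raw, {"seed", "schema_version", *cls._SECTIONS})
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {version}")
        kwargs: dict = {"seed": int(raw.pop("seed", 0)), "schema_version": version}
        for name, section_cls in cls._SECTIONS.items():
            block = dict(raw.pop(name, {}))
            allowed = {f.name for f in fields(section_cls)}
            _check_keys(name, block, allowed)
            for key, val in block.items():
                if isinstance(val, list):
                    block[key] = tuple(val)
            kwargs[name] = section_cls(**block)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)
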