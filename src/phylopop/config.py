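"""Pipeline configuration: one nested dataclass per stage, strict YAML loading.

Defaults are the study settings: cd-hit-style redundancy at 0.99 identity,
MCL inflation 1.4, clusters kept at >= 4 taxa, long-branch trimming at
0.02 subs/site relative (10x sister) / 0.03 absolute over two rounds, deep
splits at > 0.2 subs/site with >= 4 taxa per side, orthologs at >= 10 taxa,
10% column occupancy, and the 2 / 20 / 10 / 0.25-0.75 / 0.05 / 0.05
genotype filter with the 15-of-19 locus-presence rule.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields, is_dataclass

import numpy as np
import yaml

from .genofilter import FilterThresholds
from .orthology import MIParams
from .simdata import FamilySimConfig, GenoSimConfig
from .treeclean import CleanParams

__all__ = ["PipelineConfig", "ConfigError", "stage_seed"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key; the message carries the key path."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from the single global seed."""
    return zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    seed: int = 0
    #: similarity-graph edge cutoff (stand-in for a blast e-value rule)
    min_identity: float = 0.7
    kmer: int = 12
    redundancy_identity: float = 0.99
    inflation: float = 1.4
    min_cluster_taxa: int = 4
    occupancy: float = 0.10
    #: JC distance assigned to saturated pairs when building guide trees
    saturation_cap: float = 3.0
    clean: CleanParams = field(default_factory=CleanParams)
    mi: MIParams = field(default_factory=MIParams)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    family_sim: FamilySimConfig = field(default_factory=FamilySimConfig)
    geno_sim: GenoSimConfig = field(default_factory=GenoSimConfig)

    _NESTED = {
        "clean": CleanParams,
        "mi": MIParams,
        "thresholds": FilterThresholds,
        "family_sim": FamilySimConfig,
        "geno_sim": GenoSimConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if data is None:
            return cls()
        valid = {f.name for f in fields(cls)}
        kwargs = {}
        for key, val in data.items():
            if key not in valid or key.startswith("_"):
                raise ConfigError(f"unknown config key: {key}")
            if key in cls._NESTED:
                sub = cls._NESTED[key]
                sub_valid = {f.name for f in fields(sub)}
                if not isinstance(val, dict):
                    raise ConfigError(f"config block {key} must be a mapping")
                for sk in val:
                    if sk not in sub_valid:
                        raise ConfigError(f"unknown config key: {key}.{sk}")
                try:
                    kwargs[key] = sub(**val)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"invalid config block {key}: {exc}") from exc
            else:
                kwargs[key] = val
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def reseed(self, seed: int) -> "PipelineConfig":
        """Return a copy with the global seed and derived stage seeds set."""
        cfg = PipelineConfig.from_dict(self.to_dict())
        cfg.seed = seed
        cfg.family_sim.seed = stage_seed(seed, "family_sim")
        cfg.geno_sim.seed = stage_seed(seed, "geno_sim")
        return cfg

    def to_dict(self) -> dict:
        def clean(obj):
            if is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return clean(self)
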