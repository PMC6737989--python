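"""Pipeline configuration.

Every numeric cutoff used by the atlas pipeline lives in one frozen
dataclass so a run can be reproduced from its JSON summary alone.
Defaults are the published analysis cutoffs; a config file (JSON or
YAML) and CLI flags may override them (CLI > file > default).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration value violates its domain."""


@dataclass(frozen=True)
class PipelineConfig:
    """Cutoffs and options for the multi-tissue mRNA/miRNA atlas pipeline.

    Attributes
    ----------
    expressed_threshold
        Abundance (RPKM or TPM) above which a feature counts as expressed
        in a sample (strict ``>``).
    universal_mrna_min
        RPKM floor a gene must exceed in *every* tissue to be called
        universally expressed.
    universal_mirna_min, universal_mirna_cv_max
        TPM floor (every tissue) and across-tissue coefficient-of-variation
        ceiling for universally expressed miRNAs.
    associated_z_min, associated_expr_min
        Across-tissue z-score cutoff and abundance floor for
        tissue-associated features.
    specific_fold, specific_expr_min
        Fold over the leave-one-out mean of the other tissues, and the
        abundance floor, for tissue-specific features.
    network_r_min
        Pearson threshold for co-expression edges.
    mcl_inflation
        Markov-clustering inflation exponent.
    host_min_tissues, host_p_max, host_r_min
        Expression-breadth and correlation criteria for intragenic
        miRNA / host-gene pairs.
    interact_r_max
        Correlation ceiling (strict ``<``) for the miRNA-target screen.
    de_lfc_min, de_fdr_max
        Differential-expression call thresholds.
    mfe_max
        Duplex minimum-free-energy ceiling (kcal/mol) when energy
        filtering of target sites is enabled.
    mfe_filter
        Whether duplex energy participates in the site filter
        (off by default; a seed match alone qualifies).
    rng_seed
        Seed for every stochastic step of a run.
    """

    expressed_threshold: float = 0.1
    universal_mrna_min: float = 10.0
    universal_mirna_min: float = 1.0
    universal_mirna_cv_max: float = 0.5
    associated_z_min: float = 1.5
    associated_expr_min: float = 1.0
    specific_fold: float = 10.0
    specific_expr_min: float = 10.0
    network_r_min: float = 0.90
    mcl_inflation: float = 2.2
    host_min_tissues: int = 5
    host_p_max: float = 0.05
    host_r_min: float = 0.6
    interact_r_max: float = -0.5
    de_lfc_min: float = 1.0
    de_fdr_max: float = 0.05
    mfe_max: float = -15.0
    mfe_filter: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("host_p_max", "de_fdr_max", "universal_mirna_cv_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1], got {v!r}")
        for name in ("network_r_min", "host_r_min", "interact_r_max"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [-1, 1], got {v!r}")
        for name in (
            "expressed_threshold",
            "universal_mrna_min",
            "universal_mirna_min",
            "associated_z_min",
            "associated_expr_min",
            "specific_fold",
            "specific_expr_min",
            "de_lfc_min",
            "mcl_inflation",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(f"{name} must be > 0, got {v!r}")
        if self.host_min_tissues < 1:
            raise ConfigError(
                f"host_min_tissues must be >= 1, got {self.host_min_tissues!r}"
            )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, values: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(values))

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        """Load a JSON or YAML config file; ``overrides`` win over the file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    def replace(self, **changes: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)
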