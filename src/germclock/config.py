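"""Pipeline configuration.

All analysis thresholds live here so that a run is fully described by
(matrix, sample sheet, mapping, PipelineConfig, seed).  Defaults follow the
conventions of the germination time-course analysis this package implements:
fold change >= 2 with nonparametric probability >= 0.8 for differential
expression, and the +/-1.96 significance rule on enrichment Z-values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis.

    Parameters
    ----------
    pseudocount:
        Constant added to every FPKM value before means and log-ratios, so
        zero-expression genes keep finite statistics.
    fc_threshold:
        Minimum fold change (linear scale) for a differential-expression
        call; inclusive.
    prob_threshold:
        Minimum nonparametric probability for a call; inclusive.
    universe:
        ``"annotated"`` restricts enrichment universes to genes present in
        the category map; ``"all_measured"`` uses every matrix gene.
    min_bin_size:
        Bins with fewer member genes in the universe are not tested.
    twosided:
        Two-sided p-value dialect: ``"minlike"`` (minimum-likelihood
        summation, Fisher-style) or ``"double"`` (doubled smaller tail).
    z_cap:
        Absolute cap on enrichment Z-values (guards against p underflow).
    significance_z:
        |Z| (and |sigma Z|) at or above this value is significant.
    expression_threshold, min_replicates:
        A gene counts as expressed at a stage when at least
        ``min_replicates`` replicates reach ``expression_threshold`` FPKM.
    specific_mode:
        Stage-specific gene definition: ``"expression"`` (presence call) or
        ``"de"`` (differential vs. the baseline stage).
    offset_rule:
        Timetable offset definition: ``"nonpositive"`` (sigma Z <= 0, loss
        of activity) or ``"nonsignificant"`` (sigma Z < significance_z).
    case_insensitive_ids:
        Case-fold gene identifiers when joining matrix and mapping.
    """

    pseudocount: float = 0.5
    fc_threshold: float = 2.0
    prob_threshold: float = 0.8
    universe: str = "annotated"
    min_bin_size: int = 5
    twosided: str = "minlike"
    z_cap: float = 8.0
    significance_z: float = 1.96
    expression_threshold: float = 1.0
    min_replicates: int = 2
    specific_mode: str = "expression"
    offset_rule: str = "nonpositive"
    case_insensitive_ids: bool = True
    rollup: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")
        if self.fc_threshold <= 0 or self.prob_threshold <= 0:
            raise ConfigError("thresholds must be positive")
        if self.universe not in ("annotated", "all_measured"):
            raise ConfigError(f"unknown universe mode {self.universe!r}")
        if self.twosided not in ("minlike", "double"):
            raise ConfigError(f"unknown two-sided dialect {self.twosided!r}")
        if self.specific_mode not in ("expression", "de"):
            raise ConfigError(f"unknown specific mode {self.specific_mode!r}")
        if self.offset_rule not in ("nonpositive", "nonsignificant"):
            raise ConfigError(f"unknown offset rule {self.offset_rule!r}")
        if self.expression_threshold < 0:
            raise ConfigError("expression_threshold must be >= 0")
        if self.min_replicates < 1:
            raise ConfigError("min_replicates must be >= 1")
        if self.min_bin_size < 1:
            raise ConfigError("min_bin_size must be >= 1")
        if self.z_cap <= 0 or self.significance_z <= 0:
            raise ConfigError("z_cap and significance_z must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)
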