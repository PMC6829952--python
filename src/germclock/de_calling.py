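"""Nonparametric differential-expression calling for staged FPKM data.

For a contrast (test stage vs. reference stage) every gene gets a signal
pair: the log2 ratio of stage-mean expression (M) and the absolute
difference of stage means (D).  A noise distribution of (|M*|, D*) pairs is
built from all within-stage replicate comparisons of the two stages pooled,
and the probability of differential expression is the fraction of noise
points strictly dominated by the gene's signal — the construction used by
NOISeq-style callers.  A gene is called up (down) when its fold change is at
least ``fc_threshold`` and its probability at least ``prob_threshold``, both
inclusive.

This is deliberately a NOISeq-*like* caller, not a clone: no length-bias
correction, no counts handling, no kernel smoothing of the noise cloud.
Externally produced calls can be substituted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ConfigError, FormatError, InputError
from .io_formats import ExpressionMatrix


@dataclass(frozen=True)
class ContrastSpec:
    """One test-vs-reference comparison within a declared contrast system."""

    test_stage: str
    reference_stage: str
    system: str = "fixed"  # "fixed" (vs baseline) or "continuous" (vs previous)

    def __post_init__(self) -> None:
        if self.test_stage == self.reference_stage:
            raise ConfigError("test and reference stage must differ")
        if self.system not in ("fixed", "continuous"):
            raise ConfigError(f"unknown contrast system {self.system!r}")

    @property
    def name(self) -> str:
        return f"{self.test_stage}h_vs_{self.reference_stage}h"


def stage_means(matrix: ExpressionMatrix, stage: str, pseudocount: float = 0.5) -> pd.Series:
    """Arithmetic mean of replicate FPKM per gene, pseudo-counted."""
    vals = matrix.stage_values(stage)
    return vals.add(pseudocount).mean(axis=1)


def signal_statistics(
    matrix: ExpressionMatrix, contrast: ContrastSpec, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-gene (M, D): log2 mean ratio and absolute mean difference."""
    mean_test = stage_means(matrix, contrast.test_stage, pseudocount)
    mean_ref = stage_means(matrix, contrast.reference_stage, pseudocount)
    m = np.log2(mean_test / mean_ref)
    d = (mean_test - mean_ref).abs()
    return pd.DataFrame({"M": m, "D": d})


def noise_distribution(
    matrix: ExpressionMatrix, contrast: ContrastSpec, pseudocount: float = 0.5
) -> np.ndarray:
    """Pooled within-stage replicate noise points, shape (P, 2) of (|M*|, D*).

    Every unordered replicate pair within each stage of the contrast
    contributes one point per gene; with r and s replicates this yields
    (C(r,2) + C(s,2)) * n_genes points.
    """
    points: list[np.ndarray] = []
    for stage in (contrast.test_stage, contrast.reference_stage):
        cols = matrix.samples_for_stage(stage)
        if len(cols) < 2:
            raise InputError(
                f"stage {stage!r} has a single replicate; the noise distribution "
                "needs >= 2 replicates per stage — simulate technical replicates "
                "or fall back to fold-change-only calling"
            )
        vals = matrix.values[cols].to_numpy(dtype=float) + pseudocount
        for i, j in combinations(range(len(cols)), 2):
            a, b = vals[:, i], vals[:, j]
            m_star = np.abs(np.log2(a / b))
            d_star = np.abs(a - b)
            points.append(np.column_stack([m_star, d_star]))
    return np.concatenate(points, axis=0)


def de_probability(signal: pd.DataFrame, noise_points: np.ndarray) -> pd.Series:
    """Fraction of noise points strictly dominated by each gene's (|M|, D).

    Strict dominance (m* < |M| and d* < D) counts ties against the gene, so
    a flat gene with (M, D) = (0, 0) has probability exactly 0.
    """
    if noise_points.size == 0:
        raise InputError("empty noise distribution")
    abs_m = signal["M"].abs().to_numpy()
    d = signal["D"].to_numpy()
    nm = noise_points[:, 0]
    nd = noise_points[:, 1]
    total = len(nm)
    probs = np.empty(len(abs_m), dtype=float)
    chunk = max(1, int(4_000_000 // max(total, 1)))
    for start in range(0, len(abs_m), chunk):
        stop = start + chunk
        dominated = (nm[None, :] < abs_m[start:stop, None]) & (nd[None, :] < d[start:stop, None])
        probs[start:stop] = dominated.sum(axis=1) / total
    return pd.Series(probs, index=signal.index, name="probability")


def call_de(
    de_result: pd.DataFrame, fc_threshold: float = 2.0, prob_threshold: float = 0.8
) -> pd.Series:
    """Three-way call per gene: up / down / ns, thresholds inclusive."""
    if fc_threshold <= 0 or prob_threshold <= 0:
        raise ConfigError("thresholds must be positive")
    m = de_result["M"].to_numpy()
    prob = de_result["probability"].to_numpy()
    log2_fc = np.log2(fc_threshold)
    confident = prob >= prob_threshold
    call = np.where(
        confident & (m >= log2_fc), "up", np.where(confident & (m <= -log2_fc), "down", "ns")
    )
    return pd.Series(call, index=de_result.index, name="call")


def de_table(
    matrix: ExpressionMatrix, contrast: ContrastSpec, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Full per-gene DE result for one contrast: M, D, probability, call."""
    cfg = config or PipelineConfig()
    signal = signal_statistics(matrix, contrast, cfg.pseudocount)
    noise = noise_distribution(matrix, contrast, cfg.pseudocount)
    result = signal.copy()
    result["probability"] = de_probability(signal, noise)
    result["call"] = call_de(result, cfg.fc_threshold, cfg.prob_threshold)
    result.index.name = "gene_id"
    return result


def run_contrasts(
    matrix: ExpressionMatrix,
    contrasts: list[ContrastSpec],
    config: PipelineConfig | None = None,
) -> dict[ContrastSpec, pd.DataFrame]:
    """DE tables for a list of contrasts, keyed by their specs."""
    return {c: de_table(matrix, c, config) for c in contrasts}


def read_de_calls(path, contrasts: list[ContrastSpec], gene_ids: list[str]) -> dict:
    """Load externally produced DE calls, bypassing the built-in caller.

    The TSV must have columns gene_id, contrast, call with call in
    {up, down, ns} and contrast names matching ``ContrastSpec.name``
    (e.g. "24h_vs_0h").  Genes absent from the file are treated as ns; M,
    D and probability are filled with neutral placeholders since only the
    call feeds downstream enrichment.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "contrast", "call"}
    if not required.issubset(table.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}, found {list(table.columns)}")
    bad = set(table["call"]) - {"up", "down", "ns"}
    if bad:
        raise FormatError(f"{path}: unknown call values {sorted(bad)}")
    by_name = {c.name: c for c in contrasts}
    unknown = set(table["contrast"]) - set(by_name)
    if unknown:
        raise FormatError(f"{path}: unknown contrasts {sorted(unknown)}")
    index = pd.Index(gene_ids, name="gene_id")
    out: dict[ContrastSpec, pd.DataFrame] = {}
    for contrast in contrasts:
        sub = table[table["contrast"] == contrast.name].set_index("gene_id")["call"]
        calls = pd.Series("ns", index=index)
        known = sub.index.intersection(index)
        calls.loc[known] = sub.loc[known]
        out[contrast] = pd.DataFrame(
            {"M": np.nan, "D": np.nan, "probability": np.nan, "call": calls}
        )
    return out
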