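"""Stage-specific gene identification (the Venn partition over stages).

A gene is *expressed* at a stage when at least ``min_replicates`` of its
replicate FPKM values reach ``expression_threshold``; a gene is
*stage-specific* when expressed at exactly one stage.  An alternative mode
derives the per-stage presence from differential-expression status against
the baseline stage instead of an expression call.
"""

from __future__ import annotations

import pandas as pd

from .config import PipelineConfig
from .errors import ConfigError
from .io_formats import CategoryMap, ExpressionMatrix


def expressed_mask(matrix: ExpressionMatrix, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Gene x stage boolean table of the expression call."""
    cfg = config or PipelineConfig()
    out = {}
    for stage in matrix.stage_order:
        vals = matrix.stage_values(stage)
        if cfg.min_replicates > vals.shape[1]:
            raise ConfigError(
                f"min_replicates={cfg.min_replicates} exceeds the "
                f"{vals.shape[1]} replicates of stage {stage!r}"
            )
        out[stage] = (vals >= cfg.expression_threshold).sum(axis=1) >= cfg.min_replicates
    return pd.DataFrame(out, index=matrix.values.index)


def de_mask(de_tables: dict, stage_order: list[str]) -> pd.DataFrame:
    """Gene x stage membership from fixed-system DE status (call != ns).

    The baseline stage has no self-contrast, so its column is all-False in
    this mode; only non-baseline stages can own specific genes.
    """
    cols = {}
    index = None
    for contrast, table in de_tables.items():
        if contrast.system != "fixed":
            continue
        cols[contrast.test_stage] = table["call"] != "ns"
        index = table.index
    if index is None:
        raise ConfigError("de_mask needs at least one fixed-system DE table")
    mask = pd.DataFrame(index=index)
    for stage in stage_order:
        mask[stage] = cols.get(stage, pd.Series(False, index=index))
    return mask


def venn_partition(mask: pd.DataFrame) -> dict[str, set[str]]:
    """Per-stage sets of genes present at exactly one stage.

    Returns one set per stage plus a ``"_other"`` set holding genes present
    at zero or >= 2 stages.  Stage-specific sets are pairwise disjoint by
    construction.
    """
    counts = mask.sum(axis=1)
    specific = counts == 1
    out: dict[str, set[str]] = {}
    for stage in mask.columns:
        out[str(stage)] = set(mask.index[specific & mask[stage]])
    out["_other"] = set(mask.index[~specific])
    return out


def annotate_specific(
    specific_sets: dict[str, set[str]],
    category_map: CategoryMap,
    rollup: bool = True,
) -> pd.DataFrame:
    """Join each stage-specific gene to its (rolled-up) bins.

    Unannotated genes are retained with an empty bincode list.  Output is
    sorted by stage order of the input dict, then gene id.
    """
    membership = category_map.membership(rollup=rollup)
    gene_bins: dict[str, list[str]] = {}
    for code, members in membership.items():
        for gene in members:
            gene_bins.setdefault(gene, []).append(code)
    rows = []
    for stage, genes in specific_sets.items():
        if stage == "_other":
            continue
        for gene in sorted(genes):
            codes = sorted(
                gene_bins.get(gene, []), key=lambda c: tuple(int(x) for x in c.split("."))
            )
            rows.append({"stage": stage, "gene_id": gene, "bincodes": ";".join(codes)})
    return pd.DataFrame(rows, columns=["stage", "gene_id", "bincodes"])


def specific_summary(specific_sets: dict[str, set[str]], stage_order: list[str]) -> pd.DataFrame:
    """Count of stage-specific genes per stage, in stage order."""
    rows = [
        {"stage": s, "n_specific": len(specific_sets.get(s, set()))} for s in stage_order
    ]
    return pd.DataFrame(rows)
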