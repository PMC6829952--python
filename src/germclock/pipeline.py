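"""End-to-end orchestration: matrix + category map + config -> result tables."""

from __future__ import annotations

import pandas as pd

from . import activity_profiling as ap
from . import de_calling, enrichment, stage_specific
from .config import PipelineConfig
from .io_formats import CategoryMap, ExpressionMatrix


def run_pipeline(
    matrix: ExpressionMatrix,
    category_map: CategoryMap,
    config: PipelineConfig | None = None,
    de_calls: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """Run differential expression, enrichment, activity, concordance,
    timetable and stage-specific analyses.

    ``de_calls`` optionally supplies externally produced DE tables (dict of
    ContrastSpec -> frame with M, probability, call), bypassing the built-in
    caller.  Returns a dict of result tables keyed by analysis name.
    """
    cfg = config or PipelineConfig()
    fixed, continuous = ap.build_contrast_systems(matrix.stage_order)
    contrasts = fixed + continuous

    if de_calls is None:
        de_tables = de_calling.run_contrasts(matrix, contrasts, cfg)
    else:
        de_tables = de_calls

    de_long = pd.concat(
        [
            t.reset_index().assign(contrast=c.name, system=c.system)
            for c, t in de_tables.items()
        ],
        ignore_index=True,
    )

    universe = enrichment.build_universe(matrix, category_map, cfg.universe)
    enr = enrichment.enrich_all(de_tables, category_map, universe, cfg)
    activity = ap.activity_table(enr, cfg)
    conc = ap.concordance(activity, matrix.stage_order, cfg.significance_z)
    timetable = ap.activation_timetable(activity, matrix.stage_order, cfg)

    if cfg.specific_mode == "expression":
        mask = stage_specific.expressed_mask(matrix, cfg)
    else:
        mask = stage_specific.de_mask(de_tables, matrix.stage_order)
    sets = stage_specific.venn_partition(mask)
    specific = stage_specific.annotate_specific(sets, category_map, cfg.rollup)
    summary = stage_specific.specific_summary(sets, matrix.stage_order)

    return {
        "de": de_long,
        "enrichment": enr,
        "activity": activity,
        "concordance": conc,
        "timetable": timetable,
        "stage_specific": specific,
        "stage_specific_summary": summary,
    }
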