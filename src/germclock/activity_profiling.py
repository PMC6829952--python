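"""Pathway activity (sigma Z), contrast-system concordance, and the
activation timetable.

The activity of a pathway at a contrast is sigma Z = Z_up - Z_down, the
enrichment Z of up-regulated genes minus that of down-regulated genes:
positive when up-regulation dominates.  sigma Z > 0 marks a pathway active,
>= 1.96 significantly active; negative values mark it inactive, <= -1.96
significantly inactive.

Two contrast systems are profiled: the *fixed* system compares every stage
to the baseline (first) stage, the *continuous* system compares every stage
to its immediate predecessor.  Plotting each pathway's sigma Z from the two
systems as an (x, y) point at each stage gives the concordance view: points
in quadrants I/III (same sign) mean the systems agree.

The timetable ranks pathways by when they first become significantly active
on the fixed system (onset), breaking ties by peak (argmax sigma Z) and
then bincode; pathways never significantly active sort last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .de_calling import ContrastSpec
from .errors import ConfigError, InputError

STATUSES = ("significantly_active", "active", "inactive", "significantly_inactive")

log = logging.getLogger(__name__)


def sigma_z(z_up: float, z_down: float) -> float:
    """Relative Z-value of a pathway: enrichment Z of up- minus down-regulated genes."""
    if not (np.isfinite(z_up) and np.isfinite(z_down)):
        raise InputError("sigma_z requires finite Z inputs")
    return float(z_up) - float(z_down)


def classify_activity(sigma_z_value: float, threshold: float = 1.96) -> str:
    """Four-way activity status; the significance boundary is inclusive."""
    if threshold <= 0:
        raise ConfigError("significance threshold must be positive")
    if sigma_z_value >= threshold:
        return "significantly_active"
    if sigma_z_value > 0:
        return "active"
    if sigma_z_value <= -threshold:
        return "significantly_inactive"
    return "inactive"


def build_contrast_systems(stage_order: list[str]) -> tuple[list[ContrastSpec], list[ContrastSpec]]:
    """Fixed (every stage vs. baseline) and continuous (vs. previous stage) systems.

    For S stages each system has S - 1 contrasts and the first contrast of
    the two systems coincides (stage 1 vs. stage 0).
    """
    if len(stage_order) < 2:
        raise ConfigError("need at least 2 stages to build contrasts")
    baseline = stage_order[0]
    fixed = [ContrastSpec(s, baseline, "fixed") for s in stage_order[1:]]
    continuous = [
        ContrastSpec(stage_order[i], stage_order[i - 1], "continuous")
        for i in range(1, len(stage_order))
    ]
    return fixed, continuous


def activity_table(enrichment: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per (bin, contrast, system) activity records from an enrichment table.

    A direction missing from the enrichment table contributes Z = 0 — the
    continuous limit of n = 0 => p = 1 => Z = 0.
    """
    cfg = config or PipelineConfig()
    if not len(enrichment):
        return pd.DataFrame(
            columns=[
                "bincode", "bin_name", "contrast", "system", "test_stage",
                "reference_stage", "Z_up", "Z_down", "sigma_Z", "status",
            ]
        )
    wide = enrichment.pivot_table(
        index=["bincode", "bin_name", "contrast", "system", "test_stage", "reference_stage"],
        columns="direction",
        values="Z",
        aggfunc="first",
    )
    for direction in ("up", "down"):
        if direction not in wide.columns:
            wide[direction] = 0.0
    wide = wide.fillna(0.0).reset_index()
    wide["Z_up"] = wide["up"]
    wide["Z_down"] = wide["down"]
    wide["sigma_Z"] = wide["Z_up"] - wide["Z_down"]
    wide["status"] = [classify_activity(v, cfg.significance_z) for v in wide["sigma_Z"]]
    out = wide[
        [
            "bincode", "bin_name", "contrast", "system", "test_stage",
            "reference_stage", "Z_up", "Z_down", "sigma_Z", "status",
        ]
    ].copy()
    out.columns.name = None
    key = out["bincode"].map(lambda c: tuple(int(x) for x in c.split(".")))
    out = (
        out.assign(_key=key)
        .sort_values(["_key", "system", "contrast"], kind="mergesort")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    return out


def _quadrant(x: float, y: float) -> str:
    if x == 0 or y == 0:
        return "axis"
    if x > 0 and y > 0:
        return "I"
    if x < 0 and y > 0:
        return "II"
    if x < 0 and y < 0:
        return "III"
    return "IV"


def concordance(
    activity: pd.DataFrame,
    stage_order: list[str],
    threshold: float = 1.96,
) -> pd.DataFrame:
    """Concordance points between the fixed and continuous contrast systems.

    For every non-baseline stage and every bin present in both systems, the
    point (x, y) pairs the fixed-system sigma Z against the continuous-system
    sigma Z at that stage.  Color classes follow the significance rule with
    |value| = threshold counting as significant: green = neither axis
    significant; blue = significant and strictly in quadrant I or III (the
    systems agree); red = significant but discordant or on an axis.
    """
    fixed = activity[activity["system"] == "fixed"].set_index(["bincode", "test_stage"])
    cont = activity[activity["system"] == "continuous"].set_index(["bincode", "test_stage"])
    rows = []
    for stage in stage_order[1:]:
        bins_fixed = {b for b, s in fixed.index if s == stage}
        bins_cont = {b for b, s in cont.index if s == stage}
        only_one = bins_fixed ^ bins_cont
        if only_one:
            log.warning(
                "stage %s: %d bin(s) present in only one contrast system, excluded",
                stage, len(only_one),
            )
        for code in bins_fixed & bins_cont:
            x = float(fixed.loc[(code, stage), "sigma_Z"])
            y = float(cont.loc[(code, stage), "sigma_Z"])
            significant = abs(x) >= threshold or abs(y) >= threshold
            if not significant:
                color = "green"
            elif (x > 0 and y > 0) or (x < 0 and y < 0):
                color = "blue"
            else:
                color = "red"
            rows.append(
                {
                    "bincode": code,
                    "stage": stage,
                    "x": x,
                    "y": y,
                    "quadrant": _quadrant(x, y),
                    "color_class": color,
                }
            )
    table = pd.DataFrame(rows, columns=["bincode", "stage", "x", "y", "quadrant", "color_class"])
    if len(table):
        key = table["bincode"].map(lambda c: tuple(int(x) for x in c.split(".")))
        stage_idx = table["stage"].map(stage_order.index)
        table = (
            table.assign(_key=key, _s=stage_idx)
            .sort_values(["_key", "_s"], kind="mergesort")
            .drop(columns=["_key", "_s"])
            .reset_index(drop=True)
        )
    return table


@dataclass
class TimetableEntry:
    bincode: str
    onset_stage: str | None
    peak_stage: str
    offset_stage: str | None
    rank: int


def activation_timetable(
    activity: pd.DataFrame,
    stage_order: list[str],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Onset / peak / offset of every bin's fixed-system sigma Z trajectory.

    onset: first stage whose contrast is significantly active; peak: global
    argmax of sigma Z (first stage on ties); offset: first stage after onset
    with sigma Z <= 0 (or < significance threshold under the
    ``nonsignificant`` offset rule).  Ranking sorts by onset stage index,
    then peak stage index, then bincode; bins with no onset rank last.
    """
    cfg = config or PipelineConfig()
    fixed = activity[activity["system"] == "fixed"]
    if not len(fixed):
        return pd.DataFrame(columns=["bincode", "onset_stage", "peak_stage", "offset_stage", "rank"])
    stages = stage_order[1:]
    entries = []
    for code, group in fixed.groupby("bincode", sort=False):
        traj = group.set_index("test_stage")["sigma_Z"]
        missing = [s for s in stages if s not in traj.index]
        if missing:
            raise InputError(
                f"bin {code!r} lacks fixed-system records for stages {missing}"
            )
        values = np.array([traj[s] for s in stages], dtype=float)
        sig = values >= cfg.significance_z
        onset_idx = int(np.argmax(sig)) if sig.any() else None
        peak_idx = int(np.argmax(values))
        offset_idx = None
        if onset_idx is not None:
            if cfg.offset_rule == "nonpositive":
                off = values <= 0
            else:
                off = values < cfg.significance_z
            later = np.nonzero(off[onset_idx + 1:])[0]
            if len(later):
                offset_idx = onset_idx + 1 + int(later[0])
        entries.append(
            {
                "bincode": code,
                "onset_stage": stages[onset_idx] if onset_idx is not None else None,
                "peak_stage": stages[peak_idx],
                "offset_stage": stages[offset_idx] if offset_idx is not None else None,
                "_onset_idx": onset_idx if onset_idx is not None else len(stages),
                "_peak_idx": peak_idx,
                "_code_key": tuple(int(x) for x in code.split(".")),
            }
        )
    table = pd.DataFrame(entries).sort_values(
        ["_onset_idx", "_peak_idx", "_code_key"], kind="mergesort"
    )
    table["rank"] = range(1, len(table) + 1)
    return table.drop(columns=["_onset_idx", "_peak_idx", "_code_key"]).reset_index(drop=True)
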