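"""Synthetic germination time courses with a planted activation schedule.

The generator emulates the study design the pipeline targets: six stages
(0, 0.75, 6, 24, 48, 144 h) with three replicates each, FPKM-scale values,
and functional categories organised as Mapman-style bins (each top-level
bin carries two sub-bins, so category roll-up is exercised).  Baseline gene
means are log-normal; a planted schedule marks some categories as up- or
down-regulated over a subset of stages, scaling responder means by
2^(direction * effect_size * stage_weight); replicate noise is
multiplicative log-normal on the log2 scale.  The planted truth is returned
so downstream calls can be scored.

``canonical_schedule`` plants the canonical ordering — carbohydrate (CHO)
metabolism activates first, then lipid metabolism, then protein metabolism —
against null filler categories; ``monotone_schedule`` plants trajectories
whose expression changes in one direction at every active stage, the regime
in which the fixed and continuous contrast systems must agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import CategoryMap, ExpressionMatrix

DEFAULT_STAGES = ("0", "0.75", "6", "24", "48", "144")

#: Mapman-like top-level roster used for synthetic category maps.  The three
#: scheduled primary-metabolism categories come first so they exist at any
#: n_categories >= 3; the rest are filler in field-typical bins.
CATEGORY_ROSTER = (
    ("2", "major CHO metabolism"),
    ("11", "lipid metabolism"),
    ("29", "protein"),
    ("27", "RNA"),
    ("13", "amino acid metabolism"),
    ("9", "mitochondrial electron transport / ATP synthesis"),
    ("28", "DNA"),
    ("1", "photosynthesis"),
    ("3", "minor CHO metabolism"),
    ("4", "glycolysis"),
    ("5", "fermentation"),
    ("6", "gluconeogenesis"),
    ("7", "oxidative pentose phosphate"),
    ("8", "TCA / organic acid transformation"),
    ("10", "cell wall"),
    ("16", "secondary metabolism"),
    ("17", "hormone metabolism"),
    ("20", "stress"),
    ("26", "misc"),
    ("30", "signalling"),
)

CHO_BIN = "2"
LIPID_BIN = "11"
PROTEIN_BIN = "29"


@dataclass(frozen=True)
class CategoryActivation:
    """Planted regulation of one category.

    ``stage_weights`` optionally scales the effect per active stage
    (default 1.0 everywhere), letting a category ramp up or decay.
    """

    direction: int  # +1 up, -1 down
    active_stages: tuple[str, ...]
    effect_size: float  # log2 fold-change magnitude at weight 1
    responder_fraction: float
    stage_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ConfigError("direction must be +1 or -1")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ConfigError("responder_fraction must lie in [0, 1]")
        if not np.isfinite(self.effect_size) or self.effect_size < 0:
            raise ConfigError("effect_size must be finite and >= 0")

    def weight(self, stage: str) -> float:
        return self.stage_weights.get(stage, 1.0)

    @property
    def onset(self) -> str | None:
        return self.active_stages[0] if self.active_stages else None


@dataclass(frozen=True)
class ActivationSchedule:
    """Per-category planted activations, keyed by top-level bincode."""

    categories: dict[str, CategoryActivation]

    def validate(self, config: "SimulationConfig") -> None:
        known = {code for code, _n in config.category_roster()}
        stages = set(config.stage_labels)
        baseline = config.stage_labels[0]
        for code, act in self.categories.items():
            if code not in known:
                raise ConfigError(f"schedule references unknown category {code!r}")
            bad = set(act.active_stages) - stages
            if bad:
                raise ConfigError(f"category {code!r}: unknown active stages {sorted(bad)}")
            if baseline in act.active_stages:
                raise ConfigError(f"category {code!r}: the baseline stage cannot be active")


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and noise of a simulated time course.

    Defaults mirror the targeted study design: 6 stages x 3 replicates,
    log-normal baseline FPKM (median ~7, long right tail), and replicate
    noise of 0.25 on the log2 scale.
    """

    n_genes: int = 2000
    n_categories: int = 20
    genes_per_category: int = 60
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    replicates: int = 3
    baseline_log_mean: float = 2.0  # natural-log mean of baseline FPKM
    baseline_log_sigma: float = 1.5
    noise_sigma: float = 0.25  # log2-scale replicate noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_categories, self.genes_per_category, self.replicates) < 1:
            raise ConfigError("all counts must be positive")
        if len(self.stage_labels) < 2:
            raise ConfigError("need at least 2 stages")
        if len(set(self.stage_labels)) != len(self.stage_labels):
            raise ConfigError("stage labels must be unique")
        if self.noise_sigma < 0 or self.baseline_log_sigma < 0:
            raise ConfigError("noise parameters must be >= 0")
        if self.n_categories * self.genes_per_category > self.n_genes:
            raise ConfigError("categories require more genes than n_genes provides")

    def category_roster(self) -> list[tuple[str, str]]:
        roster = list(CATEGORY_ROSTER[: self.n_categories])
        next_code = 31
        while len(roster) < self.n_categories:
            roster.append((str(next_code), f"synthetic category {next_code}"))
            next_code += 1
        return roster


def null_schedule() -> ActivationSchedule:
    """No planted regulation anywhere."""
    return ActivationSchedule(categories={})


def canonical_schedule(
    effect_size: float = 2.0, responder_fraction: float = 0.6
) -> ActivationSchedule:
    """Canonical test schedule: CHO activates first, then lipid, then protein.

    CHO metabolism is up-regulated from 0.75 h with its effect decaying
    after 24 h; lipid metabolism is up-regulated over 6-48 h; protein
    metabolism is up-regulated over the same stages but ramps up late (its
    6 h effect sits below the fold-change detection threshold), so its
    detected activation trails lipid's.  All other categories are null.
    Schedule onsets satisfy onset(CHO) < onset(lipid) <= onset(protein).
    """
    return ActivationSchedule(
        categories={
            CHO_BIN: CategoryActivation(
                direction=1,
                active_stages=("0.75", "6", "24", "48"),
                effect_size=effect_size,
                responder_fraction=responder_fraction,
                stage_weights={"24": 0.8, "48": 0.5},
            ),
            LIPID_BIN: CategoryActivation(
                direction=1,
                active_stages=("6", "24", "48"),
                effect_size=effect_size,
                responder_fraction=responder_fraction,
                stage_weights={"48": 0.8},
            ),
            PROTEIN_BIN: CategoryActivation(
                direction=1,
                active_stages=("6", "24", "48"),
                effect_size=effect_size,
                responder_fraction=responder_fraction,
                stage_weights={"6": 0.3},
            ),
        }
    )


def monotone_schedule(
    effect_size: float = 2.0,
    responder_fraction: float = 0.6,
    step: float = 0.75,
) -> ActivationSchedule:
    """Trajectories monotone in expression across stages.

    Each regulated category's effect weight grows by ``step`` per active
    stage, so both the fixed-reference and the stage-over-stage contrast see
    a change of the same sign at every active stage.  Includes one
    down-regulated category to populate quadrant III.
    """
    stages = DEFAULT_STAGES

    def ramp(onset_idx: int, direction: int, code_frac: float = responder_fraction) -> CategoryActivation:
        active = stages[onset_idx:]
        weights = {s: step * (i + 1) for i, s in enumerate(active)}
        return CategoryActivation(
            direction=direction,
            active_stages=active,
            effect_size=effect_size,
            responder_fraction=code_frac,
            stage_weights=weights,
        )

    return ActivationSchedule(
        categories={
            CHO_BIN: ramp(1, +1),
            LIPID_BIN: ramp(2, +1),
            PROTEIN_BIN: ramp(3, +1),
            "27": ramp(2, -1),  # RNA: planted monotone down-regulation
        }
    )


def _build_category_map(config: SimulationConfig, gene_ids: list[str]) -> tuple[CategoryMap, dict[str, list[str]]]:
    bins: dict[str, str] = {}
    assignments: set[tuple[str, str]] = set()
    category_genes: dict[str, list[str]] = {}
    cursor = 0
    for code, name in config.category_roster():
        members = gene_ids[cursor: cursor + config.genes_per_category]
        cursor += config.genes_per_category
        category_genes[code] = members
        bins[code] = name
        bins[f"{code}.1"] = f"{name}.synthesis"
        bins[f"{code}.2"] = f"{name}.degradation"
        for i, gene in enumerate(members):
            sub = f"{code}.{1 + (i % 2)}"
            assignments.add((sub, gene))
    return CategoryMap(bins=bins, assignments=assignments), category_genes


def simulate(
    config: SimulationConfig, schedule: ActivationSchedule
) -> tuple[ExpressionMatrix, CategoryMap, pd.DataFrame]:
    """Generate (matrix, category map, truth table) from a planted schedule.

    Fully reproducible from ``config.seed``: the seed is split into
    deterministic substreams for the baseline draw, responder selection and
    per-stage replicate noise.  The truth table records one row per
    (responder gene, active stage) with the planted direction and effective
    log2 fold change.
    """
    schedule.validate(config)
    n_digits = max(4, len(str(config.n_genes - 1)))
    gene_ids = [f"g{i:0{n_digits}d}" for i in range(config.n_genes)]
    cmap, category_genes = _build_category_map(config, gene_ids)

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 + len(config.stage_labels))
    rng_base = np.random.default_rng(children[0])
    rng_resp = np.random.default_rng(children[1])
    stage_rngs = {s: np.random.default_rng(c) for s, c in zip(config.stage_labels, children[2:])}

    baseline = rng_base.lognormal(config.baseline_log_mean, config.baseline_log_sigma, config.n_genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # planted per-gene, per-stage log2 shifts
    shift = np.zeros((config.n_genes, len(config.stage_labels)))
    truth_rows = []
    for code in sorted(schedule.categories, key=lambda c: tuple(int(x) for x in c.split("."))):
        act = schedule.categories[code]
        members = category_genes[code]
        n_resp = int(round(act.responder_fraction * len(members)))
        responders = sorted(rng_resp.choice(members, size=n_resp, replace=False))
        for stage in act.active_stages:
            s_idx = config.stage_labels.index(stage)
            log2fc = act.direction * act.effect_size * act.weight(stage)
            for gene in responders:
                shift[gene_pos[gene], s_idx] += log2fc
                truth_rows.append(
                    {
                        "gene_id": gene,
                        "bincode": code,
                        "stage": stage,
                        "direction": act.direction,
                        "log2fc": log2fc,
                    }
                )

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for s_idx, stage in enumerate(config.stage_labels):
        stage_mean = baseline * np.exp2(shift[:, s_idx])
        rng = stage_rngs[stage]
        for rep in range(1, config.replicates + 1):
            noise = rng.normal(0.0, config.noise_sigma, config.n_genes) if config.noise_sigma > 0 else 0.0
            sample_id = f"s{stage}h_r{rep}"
            columns[sample_id] = stage_mean * np.exp2(noise)
            meta_rows.append({"sample_id": sample_id, "stage": stage, "replicate": rep})

    values = pd.DataFrame(columns, index=gene_ids)
    values.index.name = "gene_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta["stage"] = pd.Categorical(meta["stage"], categories=list(config.stage_labels), ordered=True)
    matrix = ExpressionMatrix(values=values, sample_meta=meta, stage_order=list(config.stage_labels))
    matrix.validate()

    truth = pd.DataFrame(truth_rows, columns=["gene_id", "bincode", "stage", "direction", "log2fc"])
    return matrix, cmap, truth
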