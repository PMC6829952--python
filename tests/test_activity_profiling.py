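import numpy as np
import pandas as pd
import pytest

from germclock.activity_profiling import (
    activation_timetable,
    activity_table,
    build_contrast_systems,
    classify_activity,
    concordance,
    sigma_z,
)
from germclock.config import PipelineConfig
from germclock.errors import ConfigError

STAGES = ["0", "0.75", "6", "24", "48", "144"]


def make_activity(records):
    """records: (bincode, test_stage, system, sigma_Z) -> activity frame."""
    rows = []
    for code, stage, system, sz in records:
        ref = "0" if system == "fixed" else STAGES[STAGES.index(stage) - 1]
        rows.append(
            {
                "bincode": code,
                "bin_name": code,
                "contrast": f"{stage}h_vs_{ref}h",
                "system": system,
                "test_stage": stage,
                "reference_stage": ref,
                "Z_up": sz,
                "Z_down": 0.0,
                "sigma_Z": sz,
                "status": classify_activity(sz),
            }
        )
    return pd.DataFrame(rows)


class TestSigmaZ:
    def test_equal_inputs_cancel(self):
        assert sigma_z(1.3, 1.3) == 0.0

    def test_difference_and_classification(self):
        value = sigma_z(2.0, -0.5)
        assert value == 2.5
        assert classify_activity(value) == "significantly_active"

    def test_swapping_directions_negates(self):
        assert sigma_z(2.0, -0.5) == -sigma_z(-0.5, 2.0)


class TestClassifyActivity:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (1.96, "significantly_active"),   # boundary inclusive
            (2.5, "significantly_active"),
            (0.5, "active"),
            (0.0, "inactive"),                # "greater than 0" excludes 0
            (-0.5, "inactive"),
            (-1.96, "significantly_inactive"),
        ],
    )
    def test_rule(self, value, expected):
        assert classify_activity(value) == expected

    def test_threshold_must_be_positive(self):
        with pytest.raises(ConfigError):
            classify_activity(1.0, threshold=0)


class TestContrastSystems:
    def test_six_stages_give_five_contrasts_each(self):
        fixed, continuous = build_contrast_systems(STAGES)
        assert len(fixed) == 5 and len(continuous) == 5
        assert ("144", "0") in [(c.test_stage, c.reference_stage) for c in fixed]
        assert ("144", "48") in [(c.test_stage, c.reference_stage) for c in continuous]

    def test_first_contrasts_coincide(self):
        fixed, continuous = build_contrast_systems(STAGES)
        assert (fixed[0].test_stage, fixed[0].reference_stage) == (
            continuous[0].test_stage, continuous[0].reference_stage)

    def test_two_stages_degenerate(self):
        fixed, continuous = build_contrast_systems(["0", "24"])
        assert len(fixed) == len(continuous) == 1
        assert fixed[0].name == continuous[0].name

    def test_single_stage_rejected(self):
        with pytest.raises(ConfigError):
            build_contrast_systems(["0"])


class TestActivityTable:
    def test_missing_direction_counts_as_zero(self):
        enr = pd.DataFrame(
            [
                {
                    "bincode": "2", "bin_name": "CHO", "contrast": "24h_vs_0h",
                    "system": "fixed", "test_stage": "24", "reference_stage": "0",
                    "direction": "up", "N": 10, "K": 5, "n": 3, "k": 3,
                    "expected": 1.5, "p": 0.04, "Z": 2.05,
                }
            ]
        )
        out = activity_table(enr)
        assert out.loc[0, "Z_down"] == 0.0
        assert out.loc[0, "sigma_Z"] == pytest.approx(2.05)
        assert out.loc[0, "status"] == "significantly_active"


class TestConcordance:
    @pytest.mark.parametrize(
        "x,y,quadrant,color",
        [
            (2.5, 2.7, "I", "blue"),
            (0.5, -0.3, "IV", "green"),
            (2.5, -2.2, "IV", "red"),
            (-2.5, -2.2, "III", "blue"),
            (-0.5, 2.2, "II", "red"),
            (1.96, 0.5, "I", "blue"),   # boundary counts as significant
            (2.5, 0.0, "axis", "red"),
        ],
    )
    def test_point_classification(self, x, y, quadrant, color):
        activity = make_activity(
            [("2", "24", "fixed", x), ("2", "24", "continuous", y)]
        )
        points = concordance(activity, STAGES)
        assert len(points) == 1
        pt = points.iloc[0]
        assert pt["quadrant"] == quadrant and pt["color_class"] == color

    def test_bin_missing_from_one_system_excluded(self):
        activity = make_activity(
            [("2", "24", "fixed", 2.0), ("11", "24", "continuous", 2.0)]
        )
        assert len(concordance(activity, STAGES)) == 0


class TestActivationTimetable:
    def test_onset_peak_offset_from_trajectory(self):
        traj = [2.1, 2.5, 1.0, -0.2, -1.0]
        activity = make_activity(
            [("2", s, "fixed", v) for s, v in zip(STAGES[1:], traj)]
        )
        out = activation_timetable(activity, STAGES)
        row = out.iloc[0]
        # onset = contrast 1 (0.75 h), peak = contrast 2 (6 h),
        # offset = contrast 4 (48 h), the first nonpositive after onset
        assert row["onset_stage"] == "0.75"
        assert row["peak_stage"] == "6"
        assert row["offset_stage"] == "48"

    def test_never_active_bin_has_no_onset_and_sorts_last(self):
        records = [("2", s, "fixed", v) for s, v in zip(STAGES[1:], [2.1, 2.5, 1.0, -0.2, -1.0])]
        records += [("11", s, "fixed", 0.0) for s in STAGES[1:]]
        out = activation_timetable(make_activity(records), STAGES)
        last = out.iloc[-1]
        assert last["bincode"] == "11"
        assert last["onset_stage"] is None
        assert last["rank"] == 2

    def test_offset_rule_nonsignificant(self):
        traj = [2.1, 2.5, 1.0, -0.2, -1.0]
        activity = make_activity([("2", s, "fixed", v) for s, v in zip(STAGES[1:], traj)])
        cfg = PipelineConfig(offset_rule="nonsignificant")
        out = activation_timetable(activity, STAGES, cfg)
        assert out.iloc[0]["offset_stage"] == "24"  # first stage after onset below 1.96

    def test_invariant_to_bin_input_order(self):
        records = []
        rng = np.random.default_rng(4)
        for code in ("2", "11", "29"):
            for s in STAGES[1:]:
                records.append((code, s, "fixed", float(rng.normal())))
        a = activation_timetable(make_activity(records), STAGES)
        b = activation_timetable(make_activity(records[::-1]), STAGES)
        pd.testing.assert_frame_equal(a, b)


class TestAntisymmetry:
    def test_up_down_relabel_negates_sigma_z(self):
        """Flipping every DE call's direction mirrors the activity statistic."""
        from germclock.de_calling import ContrastSpec
        from germclock.enrichment import enrich_all
        from germclock.io_formats import CategoryMap

        rng = np.random.default_rng(9)
        genes = [f"g{i:03d}" for i in range(60)]
        cmap = CategoryMap(
            bins={"2": "a", "11": "b"},
            assignments={("2", g) for g in genes[:25]} | {("11", g) for g in genes[25:55]},
        )
        call = pd.Series(rng.choice(["up", "down", "ns"], size=60, p=[0.2, 0.2, 0.6]),
                         index=pd.Index(genes, name="gene_id"))
        contrast = ContrastSpec("24", "0", "fixed")

        def activity_of(calls):
            table = pd.DataFrame({"M": 0.0, "D": 0.0, "probability": 0.0, "call": calls})
            enr = enrich_all({contrast: table}, cmap, set(genes))
            return activity_table(enr)

        fwd = activity_of(call)
        flipped = activity_of(call.map({"up": "down", "down": "up", "ns": "ns"}))
        merged = fwd.merge(flipped, on=["bincode", "contrast"], suffixes=("_f", "_r"))
        assert np.allclose(merged["sigma_Z_f"], -merged["sigma_Z_r"])
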