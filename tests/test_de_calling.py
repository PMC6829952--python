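import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germclock.config import PipelineConfig
from germclock.de_calling import (
    ContrastSpec,
    call_de,
    de_probability,
    de_table,
    noise_distribution,
    signal_statistics,
    stage_means,
)
from germclock.errors import ConfigError, InputError

from conftest import build_matrix

CONTRAST = ContrastSpec("24", "0", "fixed")


class TestStageMeans:
    def test_arithmetic_mean(self, two_stage_matrix):
        means = stage_means(two_stage_matrix, "0", pseudocount=0.0)
        assert means["g000"] == pytest.approx(20.0)  # (10+20+30)/3

    def test_single_replicate_is_identity(self):
        m = build_matrix({"a1": [7.0], "b1": [3.0], "b2": [5.0]},
                         {"a1": "0", "b1": "24", "b2": "24"}, ["0", "24"])
        assert stage_means(m, "0", pseudocount=0.0)["g000"] == 7.0

    def test_all_zero_gene_gets_pseudocount(self, two_stage_matrix):
        means = stage_means(two_stage_matrix, "24", pseudocount=0.5)
        assert means["g002"] == pytest.approx(0.5)

    def test_unknown_stage_rejected(self, two_stage_matrix):
        with pytest.raises(ConfigError):
            stage_means(two_stage_matrix, "99")


class TestSignalStatistics:
    @pytest.mark.parametrize(
        "mean_test,mean_ref,expected_m,expected_d",
        [(40.0, 10.0, 2.0, 30.0), (10.0, 10.0, 0.0, 0.0), (5.0, 20.0, -2.0, 15.0)],
    )
    def test_closed_form(self, mean_test, mean_ref, expected_m, expected_d):
        m = build_matrix(
            {"a1": [mean_ref], "a2": [mean_ref], "b1": [mean_test], "b2": [mean_test]},
            {"a1": "0", "a2": "0", "b1": "24", "b2": "24"}, ["0", "24"],
        )
        stats = signal_statistics(m, CONTRAST, pseudocount=0.0)
        assert stats["M"].iloc[0] == pytest.approx(expected_m)
        assert stats["D"].iloc[0] == pytest.approx(expected_d)

    def test_pseudocount_keeps_statistics_finite(self, two_stage_matrix):
        stats = signal_statistics(two_stage_matrix, CONTRAST, pseudocount=0.5)
        assert np.isfinite(stats.to_numpy()).all()


class TestNoiseDistribution:
    def test_point_count_is_combinatorial(self, two_stage_matrix):
        pts = noise_distribution(two_stage_matrix, CONTRAST)
        # 2 stages x C(3,2) pairs x 3 genes
        assert pts.shape == (2 * 3 * 3, 2)

    def test_identical_replicates_give_zero_noise(self):
        m = build_matrix(
            {"a1": [5.0], "a2": [5.0], "b1": [9.0], "b2": [9.0]},
            {"a1": "0", "a2": "0", "b1": "24", "b2": "24"}, ["0", "24"],
        )
        pts = noise_distribution(m, CONTRAST)
        assert np.allclose(pts, 0.0)

    def test_invariant_to_replicate_order(self, two_stage_matrix):
        pts = noise_distribution(two_stage_matrix, CONTRAST)
        shuffled = build_matrix(
            {c: two_stage_matrix.values[c].tolist()
             for c in ["a3", "a1", "a2", "b2", "b3", "b1"]},
            {s: ("0" if s.startswith("a") else "24") for s in two_stage_matrix.sample_ids},
            ["0", "24"],
        )
        pts2 = noise_distribution(shuffled, CONTRAST)
        assert np.allclose(
            np.array(sorted(map(tuple, pts))), np.array(sorted(map(tuple, pts2)))
        )

    def test_single_replicate_stage_rejected(self):
        m = build_matrix({"a1": [5.0], "b1": [9.0], "b2": [9.0]},
                         {"a1": "0", "b1": "24", "b2": "24"}, ["0", "24"])
        with pytest.raises(InputError, match="replicate"):
            noise_distribution(m, CONTRAST)


class TestDeProbability:
    NOISE = np.array([[0.1 * i, 1.0 * i] for i in range(1, 11)])

    def _prob(self, m, d):
        signal = pd.DataFrame({"M": [m], "D": [d]})
        return de_probability(signal, self.NOISE).iloc[0]

    def test_full_dominance_gives_one(self):
        assert self._prob(5.0, 100.0) == 1.0

    def test_flat_gene_gives_zero(self):
        assert self._prob(0.0, 0.0) == 0.0

    def test_partial_dominance_fraction(self):
        # strictly dominates exactly the 8 noise points below (0.85, 8.5)
        assert self._prob(0.85, 8.5) == pytest.approx(0.8)

    def test_ties_count_against_the_gene(self):
        assert self._prob(0.1, 1.0) == 0.0  # equal to the smallest noise point

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        m1=st.floats(0, 5), m2=st.floats(0, 5),
        d1=st.floats(0, 50), d2=st.floats(0, 50),
    )
    def test_monotone_in_signal(self, m1, m2, d1, d2):
        lo = self._prob(min(m1, m2), min(d1, d2))
        hi = self._prob(max(m1, m2), max(d1, d2))
        assert hi >= lo


class TestCallDe:
    def _frame(self, m, prob):
        return pd.DataFrame({"M": [m], "D": [1.0], "probability": [prob]})

    @pytest.mark.parametrize(
        "m,prob,expected",
        [
            (1.0, 0.8, "up"),      # fold change exactly 2, probability exactly 0.8: inclusive
            (2.0, 0.79, "ns"),
            (-3.0, 0.95, "down"),
            (0.9, 0.99, "ns"),
        ],
    )
    def test_threshold_contract(self, m, prob, expected):
        assert call_de(self._frame(m, prob)).iloc[0] == expected

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ConfigError):
            call_de(self._frame(1.0, 1.0), fc_threshold=0)


class TestContrastSymmetry:
    def test_swapping_stages_negates_m_and_swaps_calls(self, two_stage_matrix):
        cfg = PipelineConfig(prob_threshold=0.1)
        fwd = de_table(two_stage_matrix, ContrastSpec("24", "0", "fixed"), cfg)
        rev = de_table(two_stage_matrix, ContrastSpec("0", "24", "fixed"), cfg)
        assert np.allclose(fwd["M"], -rev["M"])
        assert np.allclose(fwd["D"], rev["D"])
        assert np.allclose(fwd["probability"], rev["probability"])
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert (fwd["call"].map(swap) == rev["call"]).all()


class TestReadDeCalls:
    def test_external_calls_loaded_and_padded_with_ns(self, tmp_path):
        from germclock.de_calling import read_de_calls

        path = tmp_path / "calls.tsv"
        path.write_text(
            "gene_id\tcontrast\tcall\n"
            "g000\t24h_vs_0h\tup\n"
            "g001\t24h_vs_0h\tdown\n"
        )
        contrasts = [ContrastSpec("24", "0", "fixed")]
        tables = read_de_calls(path, contrasts, ["g000", "g001", "g002"])
        calls = tables[contrasts[0]]["call"]
        assert calls.tolist() == ["up", "down", "ns"]

    def test_unknown_contrast_rejected(self, tmp_path):
        from germclock.de_calling import read_de_calls
        from germclock.errors import FormatError

        path = tmp_path / "calls.tsv"
        path.write_text("gene_id\tcontrast\tcall\ng000\t99h_vs_0h\tup\n")
        with pytest.raises(FormatError, match="99h_vs_0h"):
            read_de_calls(path, [ContrastSpec("24", "0", "fixed")], ["g000"])

    def test_bad_call_value_rejected(self, tmp_path):
        from germclock.de_calling import read_de_calls
        from germclock.errors import FormatError

        path = tmp_path / "calls.tsv"
        path.write_text("gene_id\tcontrast\tcall\ng000\t24h_vs_0h\tmaybe\n")
        with pytest.raises(FormatError, match="maybe"):
            read_de_calls(path, [ContrastSpec("24", "0", "fixed")], ["g000"])


class TestContrastSpec:
    def test_self_contrast_rejected(self):
        with pytest.raises(ConfigError):
            ContrastSpec("0", "0", "fixed")

    def test_name(self):
        assert ContrastSpec("144", "48", "continuous").name == "144h_vs_48h"
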