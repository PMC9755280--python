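"""Evaluation surfaces: tallies, calibration curves, panel coverage, AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conformalqc import (BINARY, GRADING, PanelVotes, PredictionRegion,
                         calibration_curve, human_in_loop_auc, panel_coverage,
                         point_prediction_tally, region_size_stats,
                         tally_regions)
from conftest import make_table, oracle_auc


def region(included, eid="e"):
    return PredictionRegion(example_id=eid, p_values={},
                            included=frozenset(included))


class TestTallyRegions:
    def test_toy_categorization(self):
        """Hand-checked five-example tally over {benign, cancer}."""
        regions = [region({"benign"}), region(set()), region({"benign"}),
                   region({"benign", "cancer"}), region({"cancer"})]
        truths = ["benign", "benign", "cancer", "cancer", "benign"]
        rep = tally_regions(regions, truths, BINARY)
        row = rep.counts.loc["all"]
        assert (row["correct_single"], row["empty"], row["error"],
                row["correct_multiple"]) == (1, 1, 2, 1)
        assert rep.efficiency == pytest.approx(0.2)

    def test_full_regions_are_all_multiple(self):
        regions = [region(set(BINARY.labels)) for _ in range(10)]
        rep = tally_regions(regions, ["cancer"] * 10, BINARY)
        assert rep.counts.loc["all", "correct_multiple"] == 10
        assert rep.efficiency == 0.0

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 1)),
                    min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_categories_partition_every_class(self, rows):
        """error + empty + single + multiple = n per class, any input."""
        subsets = [set(), {"benign"}, {"cancer"}, {"benign", "cancer"}]
        regions = [region(subsets[r]) for r, _ in rows]
        truths = [BINARY.labels[t] for _, t in rows]
        rep = tally_regions(regions, truths, BINARY)
        for cls in list(BINARY.labels) + ["all"]:
            row = rep.counts.loc[cls]
            assert row[["error", "empty", "correct_single",
                        "correct_multiple"]].sum() == row["n"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tally_regions([region({"benign"})], ["benign", "cancer"], BINARY)

    def test_percentages_recompute_from_counts(self):
        regions = [region({"benign"})] * 3 + [region(set())]
        rep = tally_regions(regions, ["benign"] * 4, BINARY)
        assert rep.percentages().loc["all", "correct_single"] == 75


class TestPointPredictions:
    def test_perfect_scores_have_zero_errors(self):
        t = make_table(BINARY, [[0.9, 0.1], [0.1, 0.9]], truths=["benign", "cancer"])
        out = point_prediction_tally(t)
        assert out.loc["all", "error"] == 0

    def test_single_misranked_row(self):
        probs = [[0.9, 0.1], [0.8, 0.2], [0.3, 0.7], [0.6, 0.4]]
        truths = ["benign", "benign", "cancer", "cancer"]  # last row misranked
        out = point_prediction_tally(make_table(BINARY, probs, truths=truths))
        assert out.loc["all", "error"] == 1
        assert out.loc["all", "correct"] == 3
        assert out.loc["cancer", "error"] == 1


class TestCalibrationCurve:
    def test_counting_example(self):
        p = np.arange(0.1, 1.05, 0.1)
        cc = calibration_curve(p, grid_size=21)
        # eps = 0.35 -> 3 of 10 p-values at or below
        i = np.argmin(np.abs(cc.epsilon - 0.35))
        assert cc.observed_error[i] == pytest.approx(0.3)
        assert cc.observed_error[0] == 0.0

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        cc = calibration_curve(rng.random(500) * 0.999 + 0.001)
        assert (np.diff(cc.observed_error) >= 0).all()
        assert cc.observed_error.min() >= 0 and cc.observed_error.max() <= 1

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            calibration_curve(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            calibration_curve(np.array([]))


class TestPanelCoverage:
    def test_full_regions_cover_everything(self):
        regions = [region(set(GRADING.labels))] * 2
        votes = PanelVotes([("ISUP1", "ISUP2"), ("benign",)])
        assert panel_coverage(regions, votes) == 1.0

    def test_vote_counting(self):
        regions = [region({"ISUP1", "ISUP2"}), region({"ISUP2"})]
        votes = PanelVotes([("ISUP1", "ISUP1", "ISUP3"), ("ISUP2",) * 3])
        assert panel_coverage(regions, votes) == pytest.approx(5 / 6)

    def test_no_votes_covered(self):
        regions = [region(set())]
        votes = PanelVotes([("ISUP1", "ISUP2")])
        assert panel_coverage(regions, votes) == 0.0

    def test_monotone_under_region_enlargement(self):
        votes = PanelVotes([("ISUP1", "ISUP4"), ("ISUP2", "benign")])
        small = [region({"ISUP1"}), region({"ISUP2"})]
        big = [region({"ISUP1", "ISUP4"}), region({"ISUP2", "benign"})]
        assert panel_coverage(big, votes) >= panel_coverage(small, votes)

    def test_misalignment_rejected(self):
        with pytest.raises(ValueError):
            panel_coverage([region({"ISUP1"})], PanelVotes([("ISUP1",), ("ISUP2",)]))


class TestRegionSizeStats:
    def test_singletons(self):
        stats = region_size_stats([region({"benign"})] * 5)
        assert stats["median"] == 1 and stats["distribution"] == {1: 5}

    def test_multiples_only_median(self):
        regions = [region({"ISUP1"}), region({"ISUP1", "ISUP2"}),
                   region({"ISUP2", "ISUP3"}), region(set(GRADING.labels) - {"benign", "ISUP1", "ISUP2"})]
        stats = region_size_stats(regions, multiples_only=True)
        assert stats["median"] == 2 and stats["n"] == 3


class TestHumanInLoopAUC:
    def _table(self, probs, truths):
        return make_table(BINARY, probs, truths=truths)

    def test_no_flagged_examples_leaves_auc_unchanged(self):
        t = self._table([[0.9, 0.1], [0.2, 0.8], [0.6, 0.4]],
                        ["benign", "cancer", "benign"])
        regions = [region({"benign"}), region({"cancer"}), region({"benign"})]
        standalone, combined = human_in_loop_auc(t, regions, expert_accuracy=1.0)
        assert combined == standalone

    def test_oracle_expert_on_all_flagged_gives_perfect_auc(self):
        t = self._table([[0.4, 0.6], [0.6, 0.4], [0.5, 0.5], [0.45, 0.55]],
                        ["benign", "cancer", "benign", "cancer"])
        regions = [region({"benign", "cancer"})] * 4
        _, combined = human_in_loop_auc(t, regions, expert_accuracy=1.0, seed=0)
        assert combined == 1.0

    def test_matches_brute_force_rank_statistic(self):
        probs = [[0.9, 0.1], [0.3, 0.7], [0.45, 0.55], [0.55, 0.45],
                 [0.2, 0.8], [0.7, 0.3]]
        truths = ["benign", "cancer", "cancer", "benign", "cancer", "benign"]
        t = self._table(probs, truths)
        # flag rows 2 and 3; oracle expert pins them to their truth extremes
        regions = [region({"benign"}), region({"cancer"}),
                   region({"benign", "cancer"}), region(set()),
                   region({"cancer"}), region({"benign"})]
        standalone, combined = human_in_loop_auc(t, regions, expert_accuracy=1.0, seed=0)
        y = np.array([0, 1, 1, 0, 1, 0])
        scores = np.array([0.1, 0.7, 0.55, 0.45, 0.8, 0.3])
        assert standalone == pytest.approx(oracle_auc(y, scores))
        expert_scores = scores.copy()
        expert_scores[2], expert_scores[3] = 1.0, 0.0
        assert combined == pytest.approx(oracle_auc(y, expert_scores))

    def test_non_binary_rejected(self, grading_table):
        with pytest.raises(ValueError):
            human_in_loop_auc(grading_table, [region({"ISUP1"})] * len(grading_table))
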