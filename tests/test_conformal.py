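"""Conformal core: splits, nonconformity, p-values (vs. brute force), regions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conformalqc import (BINARY, GRADING, ConfidenceSpec, MondrianCalibrator,
                         SplitSpec, calibrate, nonconformity, p_value,
                         p_values, predict_region, predict_regions,
                         split_train_calibration, true_label_p_values)
from conftest import make_table, oracle_p_value


class TestSplit:
    def test_group_split_keeps_subjects_whole(self):
        probs = np.full((100, 2), 0.5)
        subjects = [f"s{i // 10}" for i in range(100)]
        table = make_table(BINARY, probs, truths=["benign"] * 100, subjects=subjects)
        train, cal = split_train_calibration(table, SplitSpec(0.10, "subject_id", seed=3))
        assert len(cal) == 10 and len(train) == 90
        assert set(cal.df["subject_id"]).isdisjoint(train.df["subject_id"])
        assert len(set(cal.df["subject_id"])) == 1

    def test_default_fraction_is_ten_percent(self):
        assert SplitSpec().calibration_fraction == 0.10

    def test_split_is_deterministic_and_exhaustive(self, binary_calibrated):
        spec = SplitSpec(seed=8)
        t1, c1 = split_train_calibration(binary_calibrated, spec)
        t2, c2 = split_train_calibration(binary_calibrated, spec)
        assert (c1.df["example_id"] == c2.df["example_id"]).all()
        ids = set(t1.df["example_id"]) | set(c1.df["example_id"])
        assert len(ids) == len(binary_calibrated)
        assert len(t1) + len(c1) == len(binary_calibrated)

    def test_missing_truth_rejected(self):
        table = make_table(BINARY, [[0.5, 0.5]], truths=None)
        with pytest.raises(ValueError):
            split_train_calibration(table, SplitSpec())


class TestNonconformity:
    @pytest.mark.parametrize("p,label,expected", [
        ([0.0, 1.0], "cancer", 0.0),
        ([1.0, 0.0], "cancer", 1.0),
        ([0.7, 0.3], "benign", 0.3),
    ])
    def test_one_minus_probability(self, p, label, expected):
        assert nonconformity(np.array(p), label, BINARY) == pytest.approx(expected)

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            nonconformity(np.array([0.5, 0.5]), "ISUP9", BINARY)


class TestCalibrate:
    def test_hand_computed_strata(self):
        table = make_table(BINARY, [[0.9, 0.1], [0.8, 0.2], [0.6, 0.4]],
                           truths=["benign"] * 3)
        cal = calibrate(table, min_per_class=0)
        np.testing.assert_allclose(cal.scores["benign"], [0.1, 0.2, 0.4])
        assert cal.scores["cancer"].size == 0

    def test_class_counts_partition_table(self, binary_calibrated):
        cal = calibrate(binary_calibrated.subset(range(500)))
        assert sum(cal.class_counts.values()) == 500

    def test_order_invariance(self, binary_calibrated):
        sub = binary_calibrated.subset(range(400))
        perm = sub.subset(np.random.default_rng(0).permutation(400))
        a, b = calibrate(sub), calibrate(perm)
        for lab in BINARY:
            np.testing.assert_array_equal(a.scores[lab], b.scores[lab])

    def test_small_stratum_warns(self):
        table = make_table(BINARY, [[0.9, 0.1]] * 3, truths=["benign"] * 3)
        with pytest.warns(UserWarning, match="cancer"):
            calibrate(table, min_per_class=25)

    def test_empty_table_rejected(self, binary_calibrated):
        with pytest.raises(ValueError):
            calibrate(binary_calibrated.subset([]))

    def test_json_roundtrip(self, tmp_path, binary_calibrator):
        path = tmp_path / "cal.json"
        binary_calibrator.to_json(path)
        back = MondrianCalibrator.from_json(path)
        assert back.label_set == binary_calibrator.label_set
        for lab in BINARY:
            np.testing.assert_array_equal(back.scores[lab],
                                          binary_calibrator.scores[lab])


class TestPValue:
    def _cal(self, scores):
        return MondrianCalibrator(BINARY, {"benign": np.asarray(scores),
                                           "cancer": np.asarray([])})

    @pytest.mark.parametrize("alpha,expected", [
        (0.25, 0.5),    # 1 of 3 scores >= 0.25 -> (1+1)/4
        (0.05, 1.0),    # all >= -> (3+1)/4
        (0.95, 0.25),   # none >= -> 1/4
        (0.2, 0.75),    # tie counts as >= -> (2+1)/4
    ])
    def test_counting_examples(self, alpha, expected):
        cal = self._cal([0.1, 0.2, 0.3])
        assert p_value(cal, "benign", alpha) == pytest.approx(expected)

    def test_empty_stratum_forces_one(self):
        cal = self._cal([0.1])
        assert p_value(cal, "cancer", 0.9) == 1.0

    def test_smoothed_tie_formula(self):
        cal = self._cal([0.1, 0.2, 0.2, 0.3])
        # 1 score > 0.2, 2 equal: (1 + tau*3)/5
        assert p_value(cal, "benign", 0.2, smoothed=True, tie_draw=0.5) == \
            pytest.approx((1 + 0.5 * 3) / 5)

    def test_oracle_equivalence_on_random_instances(self):
        """Vectorized p-values match brute-force counting, ties included."""
        rng = np.random.default_rng(12)
        for _ in range(300):
            n = rng.integers(0, 51)
            # a coarse value grid makes exact ties common
            scores = rng.integers(0, 11, size=n) / 10.0
            cal = self._cal(np.sort(scores))
            a = rng.integers(0, 11, size=5) / 10.0
            tau = rng.random(5)
            got = p_values(cal, "benign", a)
            got_s = p_values(cal, "benign", a, smoothed=True, tie_draws=tau)
            for i in range(5):
                assert got[i] == oracle_p_value(scores, a[i])
                assert got_s[i] == pytest.approx(
                    oracle_p_value(scores, a[i], smoothed=True, tau=tau[i]),
                    abs=1e-12)

    @given(st.lists(st.integers(0, 20), min_size=0, max_size=30),
           st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_alpha(self, scores, a1, a2):
        """p-value never increases as the score grows more extreme."""
        cal = self._cal(np.sort(np.asarray(scores) / 20.0))
        lo, hi = sorted((a1 / 20.0, a2 / 20.0))
        assert p_value(cal, "benign", hi) <= p_value(cal, "benign", lo)

    def test_bounds(self):
        cal = self._cal([0.3, 0.5])
        for a in (0.0, 0.3, 0.7, 1.0):
            assert 0.0 < p_value(cal, "benign", a) <= 1.0


class TestPredictRegion:
    def _cal_with_pvals(self, p_benign, p_cancer, n=99):
        """Calibrator tuned so a prob vector of (0.5, 0.5) gets roughly
        the wanted p-values; for exactness we instead build regions from
        scores that realize the target counts."""
        # choose calibration scores so that alpha_new=0.5 has the desired rank
        k_b = round(p_benign * (n + 1)) - 1   # scores >= alpha_new
        k_c = round(p_cancer * (n + 1)) - 1
        mk = lambda k: np.sort(np.concatenate([
            np.full(k, 0.9), np.full(n - k, 0.1)]))
        return MondrianCalibrator(BINARY, {"benign": mk(k_b), "cancer": mk(k_c)})

    def test_multiple_prediction_at_high_confidence(self):
        cal = self._cal_with_pvals(0.6, 0.02)
        conf = ConfidenceSpec.global_level(0.999, BINARY)
        region = predict_region(cal, np.array([0.5, 0.5]), conf)
        assert region.included == {"benign", "cancer"}

    def test_single_prediction_at_low_confidence(self):
        cal = self._cal_with_pvals(0.6, 0.02)
        conf = ConfidenceSpec.global_level(0.50, BINARY)
        region = predict_region(cal, np.array([0.5, 0.5]), conf)
        assert region.included == {"benign"}

    def test_classwise_confidence_inclusion_rule(self):
        """p=0.20 beats eps=0.15 at 85%; p=0.30 fails eps=0.33 at 67%."""
        n = 99
        mk = lambda k: np.sort(np.concatenate([np.full(k, 0.9), np.full(n - k, 0.1)]))
        two = MondrianCalibrator(
            BINARY, {"benign": mk(round(0.20 * 100) - 1),
                     "cancer": mk(round(0.30 * 100) - 1)})
        conf = ConfidenceSpec({"benign": 0.85, "cancer": 0.67})
        region = predict_region(two, np.array([0.5, 0.5]), conf)
        assert region.p_values["benign"] == pytest.approx(0.20)
        assert region.p_values["cancer"] == pytest.approx(0.30)
        assert region.included == {"benign"}

    def test_nested_regions_under_increasing_confidence(self, binary_calibrator,
                                                        binary_calibrated):
        test = binary_calibrated.subset(range(1000, 1300))
        levels = [0.5, 0.67, 0.8, 0.95, 0.999]
        all_regions = [predict_regions(binary_calibrator, test,
                                       ConfidenceSpec.global_level(c, BINARY))
                       for c in levels]
        for low, high in zip(all_regions, all_regions[1:]):
            for r_low, r_high in zip(low, high):
                assert r_low.included <= r_high.included

    def test_incomplete_confidence_spec_rejected(self, binary_calibrator):
        with pytest.raises((ValueError, KeyError)):
            predict_region(binary_calibrator, np.array([0.5, 0.5]),
                           ConfidenceSpec({"benign": 0.9}))

    def test_unreachable_epsilon_warns(self):
        cal = MondrianCalibrator(BINARY, {"benign": np.array([0.5] * 5),
                                          "cancer": np.array([0.5] * 5)})
        with pytest.warns(UserWarning, match="cannot yield"):
            predict_region(cal, np.array([0.5, 0.5]),
                           ConfidenceSpec.global_level(0.999, BINARY))


class TestTrueLabelPValues:
    def test_matches_per_row_p_value(self, binary_calibrator, binary_calibrated):
        test = binary_calibrated.subset(range(1000, 1050))
        pv = true_label_p_values(binary_calibrator, test)
        for i in range(len(test)):
            lab = test.true_labels[i]
            a = 1.0 - test.probs[i, BINARY.index(lab)]
            assert pv[i] == p_value(binary_calibrator, lab, a)
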