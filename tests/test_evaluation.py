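"""Onset-annotation matching, metric arithmetic (including the published
worked examples), grouped fold assignment, and cross-validation averaging."""

import numpy as np
import pytest

from coughwatch import (
    AnnotatedInterval,
    ConfusionCounts,
    OnsetEvent,
    confusion_metrics,
    detection_rate,
    make_grouped_folds,
    match_onsets,
)
from coughwatch.evaluation import average_results, round_half_up_1


def _iv(a, b, label="cough", rid="r"):
    return AnnotatedInterval(recording_id=rid, start_s=a, end_s=b, label=label)


class TestMatchOnsets:
    def test_single_onset_inside_single_interval(self):
        assert match_onsets([OnsetEvent(1.0, 2.0)], [_iv(0.9, 1.35)]) == (1, 0, 0)

    def test_no_onsets_means_all_missed(self):
        truth = [_iv(0, 1), _iv(2, 3), _iv(4, 5)]
        assert match_onsets([], truth) == (0, 3, 0)

    def test_multiple_hits_count_interval_once(self):
        truth = [_iv(0, 1), _iv(2, 3)]
        onsets = [OnsetEvent(t, 1.0) for t in (0.2, 0.5, 0.8, 5.0, 6.0)]
        assert match_onsets(onsets, truth) == (1, 1, 2)

    def test_interval_end_is_exclusive(self):
        detected, missed, outside = match_onsets([OnsetEvent(1.0, 1.0)], [_iv(0.5, 1.0)])
        assert (detected, missed, outside) == (0, 1, 1)

    def test_mixed_recordings_rejected(self):
        with pytest.raises(ValueError):
            match_onsets([], [_iv(0, 1, rid="a"), _iv(2, 3, rid="b")])

    def test_overlapping_same_label_intervals_merge(self):
        truth = [_iv(0.0, 1.0), _iv(0.5, 1.5)]
        assert match_onsets([OnsetEvent(0.7, 1.0)], truth) == (1, 0, 0)

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_brute_force_containment(self, seed):
        rng = np.random.default_rng(seed)
        n_iv = int(rng.integers(0, 6))
        starts = np.sort(rng.uniform(0, 20, n_iv))
        truth = [_iv(s, s + float(rng.uniform(0.2, 1.0))) for s in starts]
        onsets = [OnsetEvent(float(t), 1.0) for t in rng.uniform(0, 22, int(rng.integers(0, 10)))]
        # oracle: O(n*m) scan over the merged interval list
        merged = []
        for iv in sorted(truth, key=lambda v: v.start_s):
            if merged and iv.start_s < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], iv.end_s)
            else:
                merged.append([iv.start_s, iv.end_s])
        hit = [any(a <= o.time_s < b for o in onsets) for a, b in merged]
        outside = sum(1 for o in onsets if not any(a <= o.time_s < b for a, b in merged))
        assert match_onsets(onsets, truth) == (sum(hit), len(merged) - sum(hit), outside)


class TestMetricArithmetic:
    def test_detection_rate_reproduces_published_value(self):
        # 275 of 284 annotated cough onsets received a detected onset
        assert detection_rate(275, 284) == 96.8

    @pytest.mark.parametrize("hit,total,expect", [(0, 7, 0.0), (7, 7, 100.0)])
    def test_detection_rate_extremes(self, hit, total, expect):
        assert detection_rate(hit, total) == expect

    def test_detection_rate_zero_total_rejected(self):
        with pytest.raises(ValueError):
            detection_rate(0, 0)

    def test_sensitivity_reproduces_published_value(self):
        # 26 of 27 cough events spotted by the classifier
        result = confusion_metrics(ConfusionCounts(tp=26, fn=1, fp=0, tn=1))
        assert result.sensitivity_pct == 96.3

    def test_specificity_reproduces_published_value(self):
        # 4537 gated onsets, 27 cough, 13 false alarms -> tn = 4537 - 27 - 13
        result = confusion_metrics(ConfusionCounts(tp=26, fn=1, fp=13, tn=4497))
        assert result.specificity_pct == 99.7

    def test_balanced_counts_give_fifty_fifty(self):
        result = confusion_metrics(ConfusionCounts(tp=5, fn=5, fp=3, tn=3))
        assert result.sensitivity_pct == 50.0
        assert result.specificity_pct == 50.0

    def test_zero_denominator_reports_missing_not_zero(self):
        result = confusion_metrics(ConfusionCounts(tp=0, fn=0, fp=2, tn=8))
        assert result.sensitivity_pct is None
        assert result.specificity_pct == 80.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fn=0, fp=0, tn=0)

    def test_rounding_is_half_up(self):
        assert round_half_up_1(96.75) == 96.8
        assert round_half_up_1(96.849) == 96.8
        assert round_half_up_1(0.05) == 0.1


class TestGroupedFolds:
    def test_eight_recordings_four_folds_of_two(self):
        folds = make_grouped_folds([f"r{i}" for i in range(8)], k=4, seed=0)
        sizes = [len(folds.fold_ids(f)) for f in range(4)]
        assert sizes == [2, 2, 2, 2]

    def test_k_equals_one_puts_everything_in_fold_zero(self):
        folds = make_grouped_folds(["a", "b", "c"], k=1, seed=0)
        assert folds.fold_ids(0) == {"a", "b", "c"}

    def test_no_recording_straddles_train_and_validation(self):
        ids = [f"r{i}" for i in range(11)]
        folds = make_grouped_folds(ids, k=4, seed=3)
        for f in range(4):
            assert not (folds.fold_ids(f) & folds.train_ids(f))
            assert folds.fold_ids(f) | folds.train_ids(f) == set(ids)

    def test_fold_sizes_differ_by_at_most_one(self):
        folds = make_grouped_folds([f"r{i}" for i in range(10)], k=4, seed=1)
        sizes = [len(folds.fold_ids(f)) for f in range(4)]
        assert max(sizes) - min(sizes) <= 1

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_grouped_folds(["a", "b"], k=3, seed=0)

    def test_deterministic_in_seed(self):
        ids = [f"r{i}" for i in range(9)]
        assert make_grouped_folds(ids, 3, seed=5).mapping == make_grouped_folds(ids, 3, seed=5).mapping


class TestAveraging:
    def test_identical_folds_average_to_themselves(self):
        r = confusion_metrics(ConfusionCounts(tp=9, fn=1, fp=1, tn=9))
        avg = average_results([r, r, r, r])
        assert avg.sensitivity_pct == r.sensitivity_pct
        assert avg.specificity_pct == r.specificity_pct

    def test_average_equals_independently_recomputed_mean(self):
        folds = [
            confusion_metrics(ConfusionCounts(tp=8, fn=2, fp=1, tn=9)),
            confusion_metrics(ConfusionCounts(tp=7, fn=3, fp=0, tn=12)),
            confusion_metrics(ConfusionCounts(tp=10, fn=0, fp=2, tn=6)),
        ]
        avg = average_results(folds)
        sens_hand = round_half_up_1(sum(f.sensitivity_pct for f in folds) / 3)
        spec_hand = round_half_up_1(sum(f.specificity_pct for f in folds) / 3)
        assert avg.sensitivity_pct == sens_hand
        assert avg.specificity_pct == spec_hand

    def test_missing_metrics_excluded_from_mean(self):
        folds = [
            confusion_metrics(ConfusionCounts(tp=0, fn=0, fp=1, tn=9)),  # sens missing
            confusion_metrics(ConfusionCounts(tp=9, fn=1, fp=0, tn=10)),
        ]
        avg = average_results(folds)
        assert avg.sensitivity_pct == 90.0
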