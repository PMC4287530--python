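import math

import numpy as np
import pytest

from urimod.evaluation import (
    THRESHOLD_GRID,
    confusion_at,
    cross_validate,
    kingdomwise_evaluate,
    metrics,
    roc_auc,
    threshold_table,
)
from urimod.svm import SVMParams, train
from urimod.encoders import encode_windows
from urimod.windows import POSITIVE


def brute_force_auc(scores, labels):
    """Pairwise Mann–Whitney oracle: wins + half-ties over all pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_basic_counts(self):
        conf = confusion_at([1.2, -0.3], [1, 0], 0.0)
        assert (conf.TP, conf.FP, conf.TN, conf.FN) == (1, 0, 1, 0)

    def test_threshold_below_min_predicts_all_positive(self):
        conf = confusion_at([0.5, 0.2, -0.1], [1, 0, 0], -1.0)
        assert conf.FN == 0 and conf.TN == 0
        assert conf.TP == 1 and conf.FP == 2

    def test_tie_counts_as_positive(self):
        conf = confusion_at([0.0], [1], 0.0)
        assert conf.TP == 1

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            confusion_at([0.1], [1, 0], 0.0)

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        conf = confusion_at(scores, labels, 0.3)
        assert conf.N == 50


class TestMetrics:
    def test_perfect_prediction(self):
        from urimod.evaluation import Confusion

        row = metrics(Confusion(TP=1, FP=0, TN=1, FN=0))
        assert row.sensitivity == row.specificity == row.accuracy == 100.0
        assert row.mcc == 1.0

    def test_mcc_closed_form(self):
        from urimod.evaluation import Confusion

        row = metrics(Confusion(TP=8, FP=1, TN=9, FN=2))
        assert row.mcc == pytest.approx(70 / math.sqrt(9900), abs=1e-12)
        assert row.sensitivity == pytest.approx(80.0)
        assert row.specificity == pytest.approx(90.0)
        assert row.accuracy == pytest.approx(85.0)

    def test_all_wrong_gives_minus_one(self):
        from urimod.evaluation import Confusion

        assert metrics(Confusion(TP=0, FP=3, TN=0, FN=3)).mcc == -1.0

    def test_degenerate_denominator_convention(self):
        from urimod.evaluation import Confusion

        assert metrics(Confusion(TP=5, FP=0, TN=0, FN=0)).mcc == 0.0

    def test_mcc_matches_sklearn_on_random_confusions(self):
        from sklearn.metrics import matthews_corrcoef
        from urimod.evaluation import Confusion

        rng = np.random.default_rng(3)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 30, size=4)
            row = metrics(Confusion(TP=tp, FP=fp, TN=tn, FN=fn))
            y_true = [1] * (tp + fn) + [0] * (tn + fp)
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            assert row.mcc == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )


class TestRocAuc:
    def test_separated_classes_give_one(self):
        assert roc_auc([0.9, 0.6, 0.4, 0.1], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_pairs(self):
        assert roc_auc([0.8, 0.3, 0.6, 0.1], [1, 1, 0, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 10, [1] * 5 + [0] * 5) == 0.5

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        scores = np.round(rng.normal(size=200), 1)  # rounding forces ties
        labels = rng.integers(0, 2, size=200)
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_label_flip_complements_auc(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        a = roc_auc(scores, labels)
        b = roc_auc(scores, 1 - labels)
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestThresholdTable:
    def test_grid_has_21_rows(self):
        scores = [-0.9, -0.5, 0.5, 0.9]
        report = threshold_table(scores, [0, 0, 1, 1])
        assert len(report.rows) == 21
        assert [r.threshold for r in report.rows] == list(THRESHOLD_GRID)

    def test_separable_scores_peak_at_zero_threshold(self):
        scores = [-0.8, -0.4, 0.4, 0.8]
        report = threshold_table(scores, [0, 0, 1, 1])
        assert report.best_mcc_threshold == pytest.approx(0.0)
        at_zero = [r for r in report.rows if r.threshold == 0.0][0]
        assert at_zero.mcc == 1.0

    def test_label_reversal_swaps_sn_and_sp_profiles(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        fwd = threshold_table(scores, labels)
        rev = threshold_table(-scores, 1 - labels)
        # predicting the complement problem with negated scores swaps the
        # roles of the two classes; sweeps mirror around the grid centre
        for row_f, row_r in zip(fwd.rows, reversed(rev.rows)):
            # grid edges differ by the tie rule; interior rows with no tied
            # score mirror exactly
            if not np.any(np.isclose(scores, row_f.threshold)) and not np.any(
                np.isclose(-scores, row_r.threshold)
            ):
                assert row_f.sensitivity == pytest.approx(row_r.specificity)
                assert row_f.specificity == pytest.approx(row_r.sensitivity)

    def test_hand_computed_grid_row(self):
        # brute-force confusion at t=0.2: pos {0.25, 0.15}, neg {0.3, -0.4}
        scores = [0.25, 0.15, 0.3, -0.4]
        labels = [1, 1, 0, 0]
        report = threshold_table(scores, labels)
        row = [r for r in report.rows if r.threshold == 0.2][0]
        assert row.sensitivity == pytest.approx(50.0)
        assert row.specificity == pytest.approx(50.0)

    def test_monotone_sensitivity_specificity(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, size=300)
        report = threshold_table(scores, labels)
        sns = [r.sensitivity for r in report.rows]
        sps = [r.specificity for r in report.rows]
        assert all(b <= a + 1e-12 for a, b in zip(sns, sns[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(sps, sps[1:]))

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            threshold_table([0.1, 0.2], [1, 1])


class TestCrossValidation:
    def test_window_mode_stratifies_both_classes(self, um_windows):
        report = cross_validate(um_windows, "bpp", seed=0)
        labels = np.array([1 if w.label == POSITIVE else 0 for w in um_windows])
        for fold in range(5):
            in_fold = report.folds == fold
            n_pos = int(labels[in_fold].sum())
            assert abs(n_pos - labels.sum() / 5) <= 1

    def test_every_window_scored_exactly_once(self, um_windows):
        report = cross_validate(um_windows, "bpp", seed=0)
        assert report.scores.shape[0] == len(um_windows)
        assert np.isfinite(report.scores).all()

    def test_sequence_mode_keeps_record_windows_together(self, um_windows):
        report = cross_validate(um_windows, "bpp", mode="sequence", seed=0)
        fold_of_record = {}
        for w, fold in zip(um_windows, report.folds):
            fold_of_record.setdefault(w.record_id, set()).add(int(fold))
        assert all(len(folds) == 1 for folds in fold_of_record.values())

    def test_same_seed_reproduces_scores_byte_identically(self, um_windows):
        a = cross_validate(um_windows, "bpp", seed=42)
        b = cross_validate(um_windows, "bpp", seed=42)
        assert a.scores.tobytes() == b.scores.tobytes()
        assert a.folds.tobytes() == b.folds.tobytes()

    def test_different_seed_changes_fold_assignment(self, um_windows):
        a = cross_validate(um_windows, "bpp", seed=0)
        b = cross_validate(um_windows, "bpp", seed=1)
        assert not np.array_equal(a.folds, b.folds)

    def test_too_few_windows_errors(self, um_windows):
        few = [w for w in um_windows if w.label == POSITIVE][:3] + [
            w for w in um_windows if w.label != POSITIVE
        ][:3]
        with pytest.raises(ValueError, match="at least 5"):
            cross_validate(few, "bpp", seed=0)


class TestKingdomwise:
    def test_reports_per_group_plus_pooled_all(self, strong_corpus, table):
        from urimod.datasets import split_by_taxon
        from urimod.windows import WindowConfig, windows_for_task

        config = WindowConfig(L=17, task="UM")
        all_windows = windows_for_task(strong_corpus, table, config)
        X = encode_windows(all_windows, "bpp")
        y = np.array([1 if w.label == POSITIVE else 0 for w in all_windows])
        model = train(X, y, SVMParams(), scheme="bpp")

        splits = split_by_taxon(strong_corpus)
        group_windows = {
            name: windows_for_task(split.records, table, config)
            for name, split in splits.items()
            if name not in ("all", "unassigned") and split.records
        }
        reports = kingdomwise_evaluate(model, group_windows)
        assert "all" in reports
        pooled = reports["all"]
        assert pooled.n_pos + pooled.n_neg == sum(
            len(v) for v in group_windows.values()
        )

    def test_single_class_group_is_not_evaluable(self, um_windows):
        X = encode_windows(um_windows, "bpp")
        y = np.array([1 if w.label == POSITIVE else 0 for w in um_windows])
        model = train(X, y, SVMParams(), scheme="bpp")
        negs = [w for w in um_windows if w.label != POSITIVE][:10]
        reports = kingdomwise_evaluate(model, {"only_negatives": negs})
        assert reports["only_negatives"] is None
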