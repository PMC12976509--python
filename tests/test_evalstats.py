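"""Grouped folds, metrics, ROC/AUC oracle checks and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitoscore import evalstats, refdata
from mitoscore.evalstats import (
    aggregate_fold_scores,
    classification_metrics,
    f1_from_precision_recall,
    group_compare,
    holm_adjust,
    make_grouped_folds,
    patient_prediction,
    roc_auc,
)


def _manifest(n_per_exp, labels=("CCCP", "FL3", "NC")):
    rows = []
    i = 0
    for exp, n in n_per_exp.items():
        for _ in range(n):
            rows.append({"field_id": f"f{i}", "label": labels[i % len(labels)], "experiment_id": exp})
            i += 1
    return pd.DataFrame(rows)


class TestGroupedFolds:
    def test_five_groups_five_folds_is_bijection(self):
        m = _manifest({f"E{i}": 6 for i in range(5)})
        folds = make_grouped_folds(m, n_folds=5, seed=0)
        assert sorted(folds.experiment_to_fold.values()) == [0, 1, 2, 3, 4]

    def test_partition_no_field_in_train_and_test(self):
        m = _manifest({f"E{i}": 4 + i for i in range(8)})
        folds = make_grouped_folds(m, n_folds=5, seed=1)
        for f in range(5):
            train = set(folds.train_experiments(f))
            test = set(folds.test_experiments(f))
            assert not train & test
            assert train | test == set(m["experiment_id"])

    def test_train_plus_test_equals_class_total(self):
        m = _manifest({f"E{i}": 5 + 2 * i for i in range(7)})
        folds = make_grouped_folds(m, n_folds=5, seed=2)
        table = folds.counts_table(m)
        for lbl, total in m["label"].value_counts().items():
            assert ((table[f"train_{lbl}"] + table[f"test_{lbl}"]) == total).all()

    def test_fewer_groups_than_folds_rejected(self):
        m = _manifest({"E0": 5, "E1": 5})
        with pytest.raises(ValueError):
            make_grouped_folds(m, n_folds=5)

    def test_balancing_spreads_large_groups(self):
        m = _manifest({"E0": 50, "E1": 50, "E2": 50, "E3": 50, "E4": 50, "E5": 2, "E6": 2})
        folds = make_grouped_folds(m, n_folds=5, seed=3)
        sizes = pd.Series(folds.experiment_to_fold).groupby(lambda e: folds.experiment_to_fold[e]).count()
        loads = m.groupby(m["experiment_id"].map(folds.experiment_to_fold)).size()
        assert loads.max() - loads.min() <= 50


class TestClassificationMetrics:
    def test_hand_computed_confusion(self):
        # TP=2, FP=1, FN=2, TN=6 (n=11)
        y_true = ["P", "P", "P", "P", "N", "N", "N", "N", "N", "N", "N"]
        y_pred = ["P", "P", "N", "N", "P", "N", "N", "N", "N", "N", "N"]
        m = classification_metrics(y_true, y_pred, positive_label="P")
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(1 / 2)
        assert m["f1"] == pytest.approx(4 / 7)
        assert m["accuracy"] == pytest.approx(8 / 11)

    def test_perfect_predictions(self):
        y = ["A", "B", "A", "B"]
        m = classification_metrics(y, y, positive_label="A")
        assert all(v == 1.0 for v in m.values())

    def test_no_positive_predictions_warns_zero_precision(self):
        with pytest.warns(UserWarning):
            m = classification_metrics(["P", "N"], ["N", "N"], positive_label="P")
        assert m["precision"] == 0.0

    def test_published_binary_f1_reproduced(self):
        assert round(
            f1_from_precision_recall(refdata.CCCP_NC_PRECISION, refdata.CCCP_NC_RECALL), 4
        ) == 0.9970


class TestROC:
    def test_textbook_example(self):
        roc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_curve_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(4)
        roc = roc_auc(rng.random(50), rng.integers(0, 2, 50))
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_mann_whitney_pair_counting(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            u = stats.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
            expected = u / ((y == 1).sum() * (y == 0).sum())
            assert roc_auc(scores, y).auc == pytest.approx(expected, abs=1e-12)


class TestAggregateFoldScores:
    def test_reproduces_published_averages(self):
        cccp = aggregate_fold_scores(refdata.cccp_nc_fold_scores())
        assert cccp.loc["Average", "CCCP_group_CCCP_score"] == 0.9745
        assert cccp.loc["Average", "NC_group_NC_score"] == 0.9995
        fl3 = aggregate_fold_scores(refdata.fl3_nc_fold_scores())
        assert fl3.loc["Average", "FL3_group_FL3_score"] == 0.8624
        assert fl3.loc["Average", "NC_group_NC_score"] == 0.9780

    def test_identical_rows_average_to_that_row(self):
        table = pd.DataFrame({"a": [0.3] * 5, "b": [0.7] * 5})
        out = aggregate_fold_scores(table)
        assert out.loc["Average", "a"] == 0.3
        assert out.loc["Average", "b"] == 0.7

    def test_missing_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate_fold_scores(pd.DataFrame({"a": [0.1] * 4}))


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        res = group_compare([1, 2, 3], [1, 2, 3])
        assert res["p"] > 0.95

    def test_disjoint_small_groups_exact_enumeration(self):
        # U = 0; one-sided exact p = 1 / C(6,3) = 0.05
        res = group_compare([1, 2, 3], [4, 5, 6], alternative="less")
        assert res["U"] == 0
        assert res["p"] == pytest.approx(1 / 20)

    def test_swapping_groups_flips_u_keeps_p(self):
        x, y = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0]
        a = group_compare(x, y)
        b = group_compare(y, x)
        assert a["U"] + b["U"] == len(x) * len(y)
        assert a["p"] == pytest.approx(b["p"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1, 2, 3])


def test_holm_adjustment_step_down():
    assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])


class TestPatientPrediction:
    def _table(self, pos, ref):
        rows = [{"participant_id": f"a{i}", "group": "AD", "score_FL3": v, "score_CCCP": 0.1}
                for i, v in enumerate(pos)]
        rows += [{"participant_id": f"c{i}", "group": "CN", "score_FL3": v, "score_CCCP": 0.1}
                 for i, v in enumerate(ref)]
        return pd.DataFrame(rows)

    def test_separated_scores_give_high_auc(self):
        t = self._table([0.8, 0.9, 0.7, 0.85], [0.2, 0.3, 0.1, 0.25])
        assert patient_prediction(t, "AD").auc == 1.0

    def test_constant_predictor_is_half_with_warning(self):
        t = self._table([0.5] * 4, [0.5] * 4)
        with pytest.warns(UserWarning):
            assert patient_prediction(t, "AD").auc == 0.5

    def test_relabelling_maps_auc_to_complement(self):
        t = self._table([0.8, 0.6, 0.9, 0.3], [0.4, 0.5, 0.2, 0.7])
        a = patient_prediction(t, "AD", reference_group="CN").auc
        b = patient_prediction(t, "CN", reference_group="AD").auc
        assert a + b == pytest.approx(1.0)

    def test_combined_predictor_runs(self):
        t = self._table([0.8, 0.9, 0.7, 0.85], [0.2, 0.3, 0.1, 0.25])
        assert patient_prediction(t, "AD", predictor="combined").auc >= 0.9

    def test_too_few_participants_rejected(self):
        t = self._table([0.8, 0.9], [0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            patient_prediction(t, "AD")


def test_reference_fold_counts_consistent_with_totals():
    table = refdata.fold_counts()
    for lbl, total in refdata.FIELD_COUNTS.items():
        assert ((table[f"train_{lbl}"] + table[f"test_{lbl}"]) == total).all()
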