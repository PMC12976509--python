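"""Grouped cross-validation, classification metrics, ROC/AUC and group tests.

Fields acquired in the same session ("experiment") are strongly correlated,
so cross-validation folds are partitions of experiments, never of fields —
a field's batch must not straddle train and test.  Metrics follow the usual
conventions: binary tasks report precision/recall/F1 on the treatment class
as positive; the three-class task macro-averages.  ROC curves come from a
threshold sweep; the area equals the Mann-Whitney pair-counting statistic
with ties counted 1/2, which the test-suite verifies against direct
enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics
from sklearn.linear_model import LogisticRegression


@dataclass
class FoldAssignment:
    """Partition of acquisition batches ("experiments") into CV folds."""

    n_folds: int
    experiment_to_fold: dict[str, int]

    def fold_of(self, experiment_id: str) -> int:
        return self.experiment_to_fold[experiment_id]

    def test_experiments(self, fold: int) -> list[str]:
        return sorted(e for e, f in self.experiment_to_fold.items() if f == fold)

    def train_experiments(self, fold: int) -> list[str]:
        return sorted(e for e, f in self.experiment_to_fold.items() if f != fold)

    def counts_table(self, manifest: pd.DataFrame) -> pd.DataFrame:
        """Per-fold train/test field counts by class (the bookkeeping table
        reported alongside cross-validation results)."""
        rows = []
        labels = sorted(manifest["label"].unique())
        folds = manifest["experiment_id"].map(self.experiment_to_fold)
        for f in range(self.n_folds):
            row: dict[str, object] = {"fold": f}
            for lbl in labels:
                in_class = manifest["label"] == lbl
                row[f"train_{lbl}"] = int((in_class & (folds != f)).sum())
                row[f"test_{lbl}"] = int((in_class & (folds == f)).sum())
            rows.append(row)
        return pd.DataFrame(rows)


def make_grouped_folds(
    manifest: pd.DataFrame,
    n_folds: int = 5,
    group_key: str = "experiment_id",
    seed: int = 0,
) -> FoldAssignment:
    """Assign experiments to folds, greedily balancing total field counts.

    Groups are shuffled (seeded), sorted by size descending, and each is
    placed in the currently lightest fold; every experiment lands in exactly
    one fold.
    """
    sizes = manifest.groupby(group_key).size()
    if len(sizes) < n_folds:
        raise ValueError(f"need at least {n_folds} distinct {group_key} groups, have {len(sizes)}")
    rng = np.random.default_rng(seed)
    groups = list(sizes.index)
    rng.shuffle(groups)
    groups.sort(key=lambda g: -sizes[g])  # stable: ties keep shuffled order
    fold_load = np.zeros(n_folds, dtype=int)
    assignment: dict[str, int] = {}
    for g in groups:
        f = int(fold_load.argmin())
        assignment[str(g)] = f
        fold_load[f] += sizes[g]
    return FoldAssignment(n_folds=n_folds, experiment_to_fold=assignment)


def classification_metrics(
    y_true,
    y_pred,
    positive_label: str | None = None,
    average: str = "macro",
) -> dict[str, float]:
    """Accuracy, precision, recall and F1.

    Binary tasks pass ``positive_label`` (the treatment class); multi-class
    tasks use the requested ``average`` (macro by default).  Precision is 0
    (with a warning) when there are no positive predictions.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    acc = float(skmetrics.accuracy_score(y_true, y_pred))
    if positive_label is not None:
        if positive_label not in y_pred:
            warnings.warn("no positive predictions; precision defined as 0", stacklevel=2)
        prec, rec, f1, _ = skmetrics.precision_recall_fscore_support(
            y_true, y_pred, pos_label=positive_label, average="binary", zero_division=0
        )
    else:
        prec, rec, f1, _ = skmetrics.precision_recall_fscore_support(
            y_true, y_pred, average=average, zero_division=0
        )
    return {"accuracy": acc, "precision": float(prec), "recall": float(rec), "f1": float(f1)}


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean; 0 when precision + recall == 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels, positive_label=1) -> ROCCurve:
    """Threshold-sweep ROC with trapezoidal AUC.

    Ties in scores advance TPR and FPR simultaneously, so the trapezoidal
    area equals the Mann-Whitney pair statistic (concordant pairs + half the
    ties, over all positive-negative pairs).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == positive_label else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, thr = skmetrics.roc_curve(y, scores, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))


def aggregate_fold_scores(fold_table: pd.DataFrame, n_folds: int = 5, decimals: int = 4) -> pd.DataFrame:
    """Append the unweighted Average row to a per-fold mean-score table.

    ``fold_table`` has one row per fold (indexed or ordered fold 0..n-1) and
    one column per (true group, score) combination.  The report is rounded to
    ``decimals`` (4, matching standard reporting); full precision is kept in
    the returned frame's ``attrs['average_full']``.
    """
    if len(fold_table) != n_folds:
        raise ValueError(f"expected {n_folds} fold rows, got {len(fold_table)}")
    num = fold_table.select_dtypes("number")
    avg_full = num.mean()
    out = fold_table.copy()
    out.index = [f"Fold {i}" for i in range(n_folds)]
    avg = avg_full.round(decimals)
    out.loc["Average"] = avg
    out.attrs["average_full"] = avg_full
    return out.round(decimals)


def group_compare(x, y, alternative: str = "two-sided") -> dict[str, float]:
    """Mann-Whitney U between two score groups.

    Exact enumeration when both groups have n <= 8 (and there are no ties),
    normal approximation otherwise; reports U, p, and the rank-biserial
    effect size r = 1 - 2U/(n1*n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("group_compare requires non-empty groups")
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    except ValueError:  # ties with exact method
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    u = float(res.statistic)
    n1n2 = len(x) * len(y)
    return {"U": u, "p": float(res.pvalue), "rank_biserial": 1.0 - 2.0 * u / n1n2}


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjustment for a family of pairwise comparisons."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


def patient_prediction(
    participant_scores: pd.DataFrame,
    positive_group: str,
    reference_group: str = "CN",
    predictor: str = "score_FL3",
    group_col: str = "group",
) -> ROCCurve:
    """ROC of a participant-level score for positive vs reference group.

    ``predictor`` is a score column name, or ``"combined"`` for an in-sample
    logistic combination of the FL3- and CCCP-scores (flagged as in-sample:
    it is fitted on the same participants it ranks).  Degenerate (constant)
    predictors yield AUC 0.5 with a warning.
    """
    sub = participant_scores[participant_scores[group_col].isin([positive_group, reference_group])]
    n_pos = int((sub[group_col] == positive_group).sum())
    n_ref = int((sub[group_col] == reference_group).sum())
    if n_pos < 3 or n_ref < 3:
        raise ValueError(f"need >= 3 participants per group, have {n_pos} vs {n_ref}")
    y = (sub[group_col] == positive_group).astype(int).to_numpy()
    if predictor == "combined":
        feats = sub[["score_FL3", "score_CCCP"]].to_numpy()
        model = LogisticRegression().fit(feats, y)
        scores = model.predict_proba(feats)[:, 1]
    else:
        scores = sub[predictor].to_numpy(dtype=float)
    if np.ptp(scores) == 0:
        warnings.warn("constant predictor; AUC defined as 0.5", stacklevel=2)
        return ROCCurve(
            thresholds=np.array([np.inf, scores[0]]),
            fpr=np.array([0.0, 1.0]),
            tpr=np.array([0.0, 1.0]),
            auc=0.5,
        )
    return roc_auc(scores, y, positive_label=1)
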