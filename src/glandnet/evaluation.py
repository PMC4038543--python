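"""Classifier and survival evaluation harness.

Feature tables are evaluated the same way throughout: a random-forest
classifier, repeated randomized 3-fold cross-validation (held-out thirds
pooled per repeat into one accuracy and one AUC), receiver operating
characteristic analysis, and Kaplan-Meier / logrank comparison of the
predicted groups' recurrence-free survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold


@dataclass
class LabeledDataset:
    """Per-case feature matrix with binary labels (1 = positive class)."""

    ids: List[str]
    X: np.ndarray                 # (n, d)
    y: np.ndarray                 # (n,) in {0, 1}
    feature_names: List[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("feature matrix and labels are inconsistent")
        if np.isnan(self.X).any():
            raise ValueError("missing feature values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, labels: Sequence[int]):
        return cls(ids=[str(i) for i in df.index], X=df.to_numpy(dtype=float),
                   y=np.asarray(labels, dtype=int),
                   feature_names=list(df.columns))


@dataclass
class CVResult:
    accuracies: List[float]       # one per repeat (pooled held-out thirds)
    aucs: List[float]
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0


@dataclass
class SurvivalRecord:
    case_id: str
    time_months: float
    event: bool                   # True when recurrence was observed
    predicted_group: str          # e.g. "BCR" or "NR"

    def __post_init__(self):
        if self.time_months < 0:
            raise ValueError("survival time must be non-negative")


def train_classifier(train: LabeledDataset, n_trees: int = 100,
                     seed: int = 0) -> RandomForestClassifier:
    """Fit a random forest (bootstrap aggregation of decision trees)."""
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(train.X, train.y)
    return clf


def decision_scores(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fuzzy decision value in [-1, 1]: 2 v - 1 with v the positive-class
    vote fraction, so 0 is the natural decision threshold."""
    proba = clf.predict_proba(np.asarray(X, dtype=float))
    pos_col = int(np.nonzero(clf.classes_ == 1)[0][0])
    return 2.0 * proba[:, pos_col] - 1.0


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    total = tp + tn + fp + fn
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if total == 0:
        raise ValueError("at least one count must be positive")
    return (tp + tn) / total


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (sensitivity against 1 - specificity swept
    over all decision thresholds).

    Computed by the rank (Mann-Whitney) formulation, which equals the
    trapezoidal area with tie plateaus handled midway: an AUC of 1 is
    perfect separation, 0.5 is chance.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def repeated_cv(data: LabeledDataset, folds: int = 3, repeats: int = 100,
                seed: int = 0, n_trees: int = 100) -> CVResult:
    """Repeated randomized stratified k-fold cross-validation.

    Each repeat draws a fresh stratified 3-way split; every held-out third
    is scored by a forest trained on the other two, and the pooled held-out
    predictions of the repeat give one accuracy and one AUC.  Stratification
    guarantees both classes in every training fold at cohort sizes of a few
    dozen cases.
    """
    if len(data.y) < folds:
        raise ValueError("fewer cases than folds")
    if len(np.unique(data.y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    accs, aucs = [], []
    for _ in range(repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=rep_seed)
        scores = np.empty(len(data.y))
        pred = np.empty(len(data.y), dtype=int)
        for train_idx, test_idx in skf.split(data.X, data.y):
            sub = LabeledDataset(ids=[data.ids[i] for i in train_idx],
                                 X=data.X[train_idx], y=data.y[train_idx],
                                 feature_names=data.feature_names)
            clf = train_classifier(sub, n_trees=n_trees, seed=rep_seed)
            s = decision_scores(clf, data.X[test_idx])
            scores[test_idx] = s
            pred[test_idx] = (s > 0).astype(int)
        tp = int(((pred == 1) & (data.y == 1)).sum())
        tn = int(((pred == 0) & (data.y == 0)).sum())
        fp = int(((pred == 1) & (data.y == 0)).sum())
        fn = int(((pred == 0) & (data.y == 1)).sum())
        accs.append(accuracy(tp, tn, fp, fn))
        aucs.append(roc_auc(scores, data.y))
    return CVResult(accuracies=accs, aucs=aucs, seed=seed)


def kaplan_meier(records: Sequence[SurvivalRecord], group: str
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Product-limit recurrence-free survival curve of one predicted group.

    Returns (times, survival) of the step function; the curve starts at 1
    and is non-increasing, with censored cases (event=False) contributing
    at-risk time only.
    """
    sel = [r for r in records if r.predicted_group == group]
    if not sel:
        raise ValueError(f"no records in group {group!r}")
    km = KaplanMeierFitter()
    km.fit([r.time_months for r in sel], [r.event for r in sel])
    times = km.survival_function_.index.to_numpy(dtype=float)
    surv = km.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    return times, surv


def logrank(records: Sequence[SurvivalRecord]) -> Tuple[float, float]:
    """Two-group logrank test between the two predicted groups.

    Returns (chi-square statistic, p-value); a low p indicates the
    recurrence-free survival of the groups differs.
    """
    groups = sorted({r.predicted_group for r in records})
    if len(groups) != 2:
        raise ValueError("exactly two nonempty predicted groups required")
    a = [r for r in records if r.predicted_group == groups[0]]
    b = [r for r in records if r.predicted_group == groups[1]]
    if not any(r.event for r in records):
        raise ValueError("no events in either group")
    res = logrank_test([r.time_months for r in a], [r.time_months for r in b],
                       event_observed_A=[r.event for r in a],
                       event_observed_B=[r.event for r in b])
    return float(res.test_statistic), float(res.p_value)


def read_survival_records(path) -> List[SurvivalRecord]:
    """Load survival records from CSV with columns case_id, time_months,
    event (0/1), predicted_group."""
    df = pd.read_csv(path)
    return [SurvivalRecord(case_id=str(r.case_id),
                           time_months=float(r.time_months),
                           event=bool(int(r.event)),
                           predicted_group=str(r.predicted_group))
            for r in df.itertuples()]
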