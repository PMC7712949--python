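"""Feature selection, subject-blocked cross-validation and classification.

The evaluation protocol is five-fold cross-validation with *subject
blocking*: all epochs of one subject stay together in either the
training or the test side of every fold, so a classifier can never
exploit subject identity.  Within each training fold the top-k features
are chosen by greedy forward selection on a partial F-statistic, then
one of eight standard classifier families is trained on the selected
columns and scored on the held-out epochs.

The selection criterion: at each step every remaining candidate column
is residualized on the intercept and the already-selected columns, and
the candidate with the largest two-class one-way-ANOVA F on those
residuals enters.  This rewards features carrying class information not
already captured by the selected set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import METADATA_COLUMNS, FeatureConfig, build_feature_table
from .metrics import ConfusionCounts, auc_rank, classification_metrics
from .preprocess import Epoch

__all__ = [
    "CVSplit",
    "SelectionResult",
    "EvaluationReport",
    "FrameworkConfig",
    "CLASSIFIER_NAMES",
    "make_grouped_folds",
    "stepwise_select",
    "evaluate_classifier",
    "run_framework",
]


@dataclass
class CVSplit:
    """Subject-to-fold assignment for grouped cross-validation."""

    fold_of_subject: dict[str, int]
    k: int

    def masks(self, subject_ids) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-fold ``(train_mask, test_mask)`` over epoch rows."""
        sids = np.asarray(subject_ids)
        folds = np.array([self.fold_of_subject[s] for s in sids])
        out = []
        for f in range(1, self.k + 1):
            test = folds == f
            train = ~test
            train_subj = set(sids[train])
            test_subj = set(sids[test])
            if train_subj & test_subj:  # pragma: no cover - structural guard
                raise AssertionError(f"subject leakage in fold {f}: {train_subj & test_subj}")
            out.append((train, test))
        return out


def make_grouped_folds(subject_ids, labels, k: int = 5, seed: int = 0) -> CVSplit:
    """Assign subjects to k folds, stratified by class.

    Subjects of each class are shuffled with the seed and dealt
    round-robin, so per-class fold sizes differ by at most one.  The
    returned split is reused for every classifier so all models see
    identical folds.
    """
    sids = np.asarray(subject_ids)
    labs = np.asarray(labels)
    subj_label: dict[str, str] = {}
    for s, l in zip(sids, labs):
        if s in subj_label and subj_label[s] != l:
            raise ValueError(f"subject {s} appears with conflicting labels")
        subj_label[s] = l
    classes = sorted(set(subj_label.values()))
    for cls in classes:
        n_cls = sum(1 for v in subj_label.values() if v == cls)
        if n_cls < k:
            raise ValueError(f"class {cls!r} has {n_cls} subjects, fewer than k={k}")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for cls in classes:
        members = sorted(s for s, v in subj_label.items() if v == cls)
        rng.shuffle(members)
        for i, s in enumerate(members):
            fold_of[s] = i % k + 1
    return CVSplit(fold_of_subject=fold_of, k=k)


@dataclass
class SelectionResult:
    """Ordered selected feature names plus the criterion trace."""

    features: list[str]
    trace: list[tuple[str, float]] = field(default_factory=list)


def stepwise_select(
    table: pd.DataFrame,
    k: int = 20,
    feature_columns: list[str] | None = None,
    label_column: str = "label",
) -> SelectionResult:
    """Greedy forward selection of up to ``k`` features.

    At each step every remaining column is residualized on the selected
    set (plus intercept) by projection onto an orthonormal basis, and
    the column with the largest two-class ANOVA F-statistic of the
    residuals enters.  Columns whose residual variance is negligible
    (collinear with the selected set) are skipped, so a duplicate of a
    selected column can never enter twice.
    """
    cols = feature_columns or [c for c in table.columns if c not in METADATA_COLUMNS]
    if not cols:
        raise ValueError("no candidate feature columns")
    y = np.asarray(table[label_column])
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"stepwise selection requires exactly 2 classes, got {len(classes)}")
    X = table[cols].to_numpy(dtype=float)
    n = X.shape[0]
    if k >= len(cols):
        return SelectionResult(features=list(cols))

    g1 = y == classes[1]
    n0, n1 = int((~g1).sum()), int(g1.sum())
    col_var = X.var(axis=0)
    Q = np.full((n, 1), 1.0 / np.sqrt(n))  # intercept
    remaining = np.ones(len(cols), dtype=bool)
    selected: list[str] = []
    trace: list[tuple[str, float]] = []
    for _ in range(k):
        R = X - Q @ (Q.T @ X)  # residualize every candidate at once
        ss_tot = (R**2).sum(axis=0)
        m0 = R[~g1].mean(axis=0)
        m1 = R[g1].mean(axis=0)
        m_all = R.mean(axis=0)
        ssb = n0 * (m0 - m_all) ** 2 + n1 * (m1 - m_all) ** 2
        ssw = np.maximum(ss_tot - n * m_all**2 - ssb, 0.0)
        # skip columns collinear with the selected set; a perfect
        # separator (ssw = 0, ssb > 0) gets an effectively infinite F
        valid = remaining & (ss_tot > 1e-12 * np.maximum(col_var * n, 1e-30))
        if not valid.any():
            break
        F = np.where(valid, ssb / np.maximum(ssw, 1e-300) * (n - 2), -np.inf)
        best = int(np.argmax(F))
        remaining[best] = False
        selected.append(cols[best])
        trace.append((cols[best], float(F[best])))
        r = R[:, best] - Q @ (Q.T @ R[:, best])
        norm = np.linalg.norm(r)
        if norm > 0:
            Q = np.hstack([Q, (r / norm)[:, None]])
    return SelectionResult(features=selected, trace=trace)


def _make_classifier(name: str, seed: int):
    """Estimator plus a small hyperparameter grid for inner-CV tuning."""
    name = name.lower()
    if name == "lda":
        return LinearDiscriminantAnalysis(), {}
    if name == "logreg":
        return LogisticRegression(max_iter=5000), {"clf__C": [0.1, 1.0, 10.0]}
    if name == "knn":
        return KNeighborsClassifier(), {"clf__n_neighbors": [3, 5, 11]}
    if name == "svm":
        return SVC(kernel="rbf", gamma="scale"), {"clf__C": [1.0, 10.0]}
    if name == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed), {}
    if name == "nbayes":
        return GaussianNB(), {}
    if name == "adaboost":
        return AdaBoostClassifier(n_estimators=100, random_state=seed), {}
    if name == "nnet":
        return MLPClassifier(hidden_layer_sizes=(32,), max_iter=1000, random_state=seed), {}
    raise ValueError(f"unknown classifier {name!r}; choose from {', '.join(CLASSIFIER_NAMES)}")


CLASSIFIER_NAMES = ("lda", "logreg", "knn", "svm", "rf", "nbayes", "adaboost", "nnet")


@dataclass(frozen=True)
class FrameworkConfig:
    """End-to-end evaluation options.

    ``selection_scope='fold'`` fits the stepwise selection inside each
    training fold (no leakage); ``'global'`` fits it once on the whole
    table before splitting, mimicking protocols that select features
    outside cross-validation (optimistic, provided for comparison).
    ``aggregate='subject'`` majority-votes epoch predictions (and
    averages scores) per subject before computing metrics.
    """

    filters: tuple[str, ...] = ("la8",)
    classifiers: tuple[str, ...] = ("lda",)
    k_folds: int = 5
    n_select: int = 20
    seed: int = 0
    positive_label: str = "AD"
    selection_scope: str = "fold"
    tune: bool = True
    aggregate: str = "epoch"
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self):
        if self.selection_scope not in ("fold", "global"):
            raise ValueError("selection_scope must be 'fold' or 'global'")
        if self.aggregate not in ("epoch", "subject"):
            raise ValueError("aggregate must be 'epoch' or 'subject'")


@dataclass
class EvaluationReport:
    """Cross-validated performance of one classifier on one table.

    ``per_fold`` holds one row per fold with confusion counts and all
    six metrics; ``summary()`` returns mean and standard deviation over
    folds.
    """

    classifier: str
    per_fold: pd.DataFrame
    selected: list[list[str]]

    def summary(self) -> dict[str, tuple[float, float]]:
        out = {}
        for m in ("accuracy", "auc", "f_measure", "specificity", "recall", "precision"):
            vals = self.per_fold[m].to_numpy(dtype=float)
            out[m] = (float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1)))
        return out


def evaluate_classifier(
    table: pd.DataFrame,
    split: CVSplit,
    classifier_name: str,
    config: FrameworkConfig | None = None,
) -> EvaluationReport:
    """Run one classifier through the grouped five-fold protocol.

    Per fold: stepwise selection on the training epochs (unless
    ``selection_scope='global'``), a standardize-then-classify pipeline
    fitted on the selected columns (with inner grouped 3-fold grid
    search when the family has a grid and tuning is enabled), then
    held-out scoring.  Metrics treat ``config.positive_label`` as the
    positive class.
    """
    cfg = config or FrameworkConfig(classifiers=(classifier_name,))
    sids = table["subject_id"].to_numpy()
    y = table["label"].to_numpy()
    pos = cfg.positive_label
    if pos not in set(y):
        raise ValueError(f"positive label {pos!r} absent from table")
    feature_cols = [c for c in table.columns if c not in METADATA_COLUMNS]

    global_sel = None
    if cfg.selection_scope == "global":
        global_sel = stepwise_select(table, k=cfg.n_select, feature_columns=feature_cols)

    rows = []
    selected_per_fold: list[list[str]] = []
    for fold_idx, (train, test) in enumerate(split.masks(sids), start=1):
        train_tab = table.loc[train]
        if len(np.unique(train_tab["label"])) < 2:
            raise ValueError(f"fold {fold_idx}: training data contains a single class")
        sel = global_sel or stepwise_select(train_tab, k=cfg.n_select, feature_columns=feature_cols)
        selected_per_fold.append(list(sel.features))

        est, grid = _make_classifier(classifier_name, cfg.seed + fold_idx)
        pipe = Pipeline([("scale", StandardScaler()), ("clf", clone(est))])
        Xtr = train_tab[sel.features].to_numpy(dtype=float)
        ytr = train_tab["label"].to_numpy()
        if cfg.tune and grid:
            inner = GroupKFold(n_splits=3)
            groups = train_tab["subject_id"].to_numpy()
            search = GridSearchCV(pipe, grid, cv=inner.split(Xtr, ytr, groups), n_jobs=1)
            search.fit(Xtr, ytr)
            model = search.best_estimator_
        else:
            model = pipe.fit(Xtr, ytr)

        Xte = table.loc[test, sel.features].to_numpy(dtype=float)
        yte = table.loc[test, "label"].to_numpy()
        y_pred = model.predict(Xte)
        if hasattr(model, "predict_proba"):
            classes = list(model.classes_)
            scores = model.predict_proba(Xte)[:, classes.index(pos)]
        else:
            dfun = model.decision_function(Xte)
            scores = dfun if model.classes_[1] == pos else -dfun

        if cfg.aggregate == "subject":
            te_sids = table.loc[test, "subject_id"].to_numpy()
            agg_true, agg_pred, agg_scores = [], [], []
            for s in pd.unique(te_sids):
                m = te_sids == s
                agg_true.append(yte[m][0])
                votes = pd.Series(y_pred[m]).value_counts()
                agg_pred.append(votes.idxmax())
                agg_scores.append(float(np.mean(scores[m])))
            yte, y_pred, scores = np.array(agg_true), np.array(agg_pred), np.array(agg_scores)

        counts = ConfusionCounts.from_labels(yte, y_pred, positive=pos)
        met = classification_metrics(counts)
        met["auc"] = auc_rank(scores, yte, positive=pos)
        rows.append(
            {"fold": fold_idx, "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn, **met}
        )
    return EvaluationReport(
        classifier=classifier_name,
        per_fold=pd.DataFrame(rows),
        selected=selected_per_fold,
    )


def run_framework(
    epochs: list[Epoch],
    config: FrameworkConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], EvaluationReport]]:
    """Evaluate every configured (wavelet filter, classifier) pair.

    Builds one feature table per filter from the given preprocessed
    epochs, fixes a single subject-blocked fold assignment, and returns
    a tidy summary table (one row per pair, ``metric_mean`` /
    ``metric_sd`` columns) plus the full per-fold reports.
    """
    cfg = config or FrameworkConfig()
    sids = [e.subject_id for e in epochs]
    labels = [e.label for e in epochs]
    split = make_grouped_folds(sids, labels, k=cfg.k_folds, seed=cfg.seed)

    summary_rows = []
    reports: dict[tuple[str, str], EvaluationReport] = {}
    for filt in cfg.filters:
        table = build_feature_table(epochs, filt, config=cfg.feature_config)
        for clf in cfg.classifiers:
            rep = evaluate_classifier(table, split, clf, cfg)
            reports[(filt, clf)] = rep
            row: dict[str, object] = {"filter": filt, "classifier": clf}
            for m, (mean, sd) in rep.summary().items():
                row[f"{m}_mean"] = mean
                row[f"{m}_sd"] = sd
            summary_rows.append(row)
    return pd.DataFrame(summary_rows), reports
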