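"""Multi-class SVM drug-response classifier under repeated holdout.

The evaluation engine used by every selection stage: a linear-kernel
multi-class SVM (one-vs-one decomposition, C = 1.0) with per-feature
standardization fitted on the training split only, evaluated under repeated
stratified 80/20 holdout (default 50 replicates).  Accuracy distributions,
a replicate-summed confusion matrix, per-class precision/sensitivity and
pooled one-vs-rest ROC AUCs are reported.

A :class:`HoldoutPlan` pins the split seeds, so two evaluations under the
same plan see identical train/test partitions — accuracy differences between
feature sets then reflect the features, not split noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_io import CLASSES, ExpressionMatrix, ResponseLabels


@dataclass(frozen=True)
class HoldoutPlan:
    """A repeated train/test holdout protocol with pinned split seeds."""

    split_seeds: tuple[int, ...]
    test_fraction: float = 0.2
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if len(set(self.split_seeds)) != len(self.split_seeds):
            raise ValueError("split seeds must be distinct")
        if not self.split_seeds:
            raise ValueError("need at least one split seed")

    @property
    def n_replicates(self) -> int:
        return len(self.split_seeds)

    @classmethod
    def from_seed(
        cls,
        seed: int,
        n_replicates: int = 50,
        test_fraction: float = 0.2,
        stratified: bool = True,
    ) -> "HoldoutPlan":
        """Derive ``n_replicates`` distinct split seeds from one base seed."""
        rng = np.random.default_rng(seed)
        seeds: list[int] = []
        seen: set[int] = set()
        while len(seeds) < n_replicates:
            s = int(rng.integers(0, 2**31))
            if s not in seen:
                seen.add(s)
                seeds.append(s)
        return cls(tuple(seeds), test_fraction=test_fraction, stratified=stratified)


@dataclass
class EvalReport:
    """Metrics accumulated over the holdout replicates.

    ``confusion`` rows are true classes, columns predicted, both in
    (RD, NR, PR) order, summed over all replicates.  Precision and
    sensitivity are derived from that summed matrix; AUCs are one-vs-rest on
    decision scores pooled over replicates.
    """

    per_replicate_accuracy: np.ndarray
    confusion: np.ndarray
    per_class_auc: dict[str, float]
    classes: tuple[str, ...] = CLASSES
    mean_accuracy: float = field(init=False)
    per_class_precision: dict[str, float] = field(init=False)
    per_class_sensitivity: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.per_replicate_accuracy = np.asarray(self.per_replicate_accuracy, float)
        self.confusion = np.asarray(self.confusion, dtype=int)
        self.mean_accuracy = float(self.per_replicate_accuracy.mean())
        diag = np.diag(self.confusion).astype(float)
        col = self.confusion.sum(axis=0).astype(float)
        row = self.confusion.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(col > 0, diag / col, np.nan)
            sens = np.where(row > 0, diag / row, np.nan)
        self.per_class_precision = {c: float(p) for c, p in zip(self.classes, prec)}
        self.per_class_sensitivity = {c: float(s) for c, s in zip(self.classes, sens)}


def evaluate_features(
    m: ExpressionMatrix,
    labels: ResponseLabels,
    features: list[str],
    plan: HoldoutPlan,
    C: float = 1.0,
) -> EvalReport:
    """Evaluate an mSVM restricted to ``features`` under ``plan``.

    Per replicate: split (stratified by class unless the plan says
    otherwise), standardize each feature with training-set statistics, fit a
    linear-kernel one-vs-one SVM, predict the held-out samples.  Deterministic
    given the plan.
    """
    if not features:
        raise ValueError("feature list is empty")
    sub = m.subset(features)  # raises KeyError naming unknown features
    if sub.missing_mask.any():
        raise ValueError("matrix contains missing values; impute first")
    aligned = labels.aligned_to(m.sample_ids)
    y = aligned.class_array()
    for c, cnt in aligned.counts().items():
        if 0 < cnt < 2:
            raise ValueError(f"class {c} has a single sample; need at least 2")
    X = sub.values.T  # samples x features

    accs = np.empty(plan.n_replicates)
    conf = np.zeros((3, 3), dtype=int)
    pooled_true: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    for r, seed in enumerate(plan.split_seeds):
        idx_train, idx_test = train_test_split(
            np.arange(X.shape[0]),
            test_size=plan.test_fraction,
            random_state=seed % (2**32),
            stratify=y if plan.stratified else None,
        )
        if set(y[idx_train]) != set(y):
            raise ValueError(
                f"replicate {r}: class absent from training split; "
                "use a stratified plan"
            )
        scaler = StandardScaler().fit(X[idx_train])
        clf = SVC(kernel="linear", C=C, decision_function_shape="ovr")
        clf.fit(scaler.transform(X[idx_train]), y[idx_train])
        Xt = scaler.transform(X[idx_test])
        pred = clf.predict(Xt)
        accs[r] = float(np.mean(pred == y[idx_test]))
        conf += confusion_matrix(y[idx_test], pred, labels=list(CLASSES))
        scores = clf.decision_function(Xt)
        if scores.ndim == 1:  # two-class edge: expand to per-class columns
            scores = np.column_stack([-scores, scores])
        # reorder score columns from the classifier's class order to CLASSES
        order = [list(clf.classes_).index(c) for c in CLASSES if c in clf.classes_]
        full = np.full((scores.shape[0], 3), np.nan)
        for j, c in enumerate(CLASSES):
            if c in clf.classes_:
                full[:, j] = scores[:, list(clf.classes_).index(c)]
        pooled_true.append(y[idx_test])
        pooled_scores.append(full)

    ytrue = np.concatenate(pooled_true)
    sc = np.vstack(pooled_scores)
    aucs: dict[str, float] = {}
    for j, c in enumerate(CLASSES):
        pos = ytrue == c
        if pos.any() and (~pos).any() and np.all(np.isfinite(sc[:, j])):
            aucs[c] = float(roc_auc_score(pos, sc[:, j]))
        else:
            aucs[c] = float("nan")
    return EvalReport(per_replicate_accuracy=accs, confusion=conf, per_class_auc=aucs)


def accuracy_summary(report: EvalReport) -> float:
    """Mean accuracy over the holdout replicates."""
    return float(np.mean(report.per_replicate_accuracy))
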