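"""Pattern recognition on the functionome.

Informativeness of the GSR indices is evaluated two ways: supervised, by
linear-kernel SVM under stratified 5-fold cross-validation repeated 10 times
(binary case/control and multiclass across diseases + control), with
sensitivity, specificity and accuracy read off the cumulative confusion
matrix and AUC from pooled held-out decision values; and unsupervised, by
hierarchical clustering of per-group mean GSR profiles (Euclidean distance,
complete linkage — the defaults of the usual R heatmap/hclust stack).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.svm import SVC

from .gsr_core import FunctionomeMatrix

N_FOLDS = 5
N_REPEATS = 10
SVM_COST = 1.0  # cost parameter C of the linear-kernel SVM


@dataclass
class ClassificationReport:
    task: str  # "binary" | "multiclass"
    classes: list[str]
    sensitivity: float | None
    specificity: float | None
    accuracy: float
    sd_sensitivity: float | None
    sd_specificity: float | None
    sd_accuracy: float
    auc: float | None
    confusion: np.ndarray  # cumulative over folds and repeats, rows = truth
    n_folds: int = N_FOLDS
    n_repeats: int = N_REPEATS
    seed: int = 0
    params: dict = field(default_factory=dict)
    # held-out decision values pooled over folds/repeats (binary task only;
    # kept for auditing the AUC against the rank concordance statistic)
    pooled_scores: np.ndarray | None = None
    pooled_truth: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "classes": self.classes,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "sd_sensitivity": self.sd_sensitivity,
            "sd_specificity": self.sd_specificity,
            "sd_accuracy": self.sd_accuracy,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "params": self.params,
        }


def _check_classes(y: np.ndarray, minimum: int, n_min_per_class: int = 5) -> list:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < minimum:
        raise ValueError(f"need >= {minimum} classes, got {len(classes)}")
    small = [str(c) for c, n in zip(classes, counts) if n < n_min_per_class]
    if small:
        raise ValueError(f"classes with < {n_min_per_class} samples: {small}")
    return list(classes)


def _cv_splits(y: np.ndarray, seed: int, stratify: bool):
    """Yield (repeat, train_idx, test_idx); folds reshuffled every repeat."""
    for r in range(N_REPEATS):
        cls = (StratifiedKFold if stratify else KFold)(
            n_splits=N_FOLDS, shuffle=True, random_state=seed * N_REPEATS + r
        )
        for tr, te in cls.split(np.zeros(len(y)), y):
            yield r, tr, te


def crossval_binary(
    X: np.ndarray,
    y,
    seed: int = 0,
    positive_label: str = "case",
    stratify: bool = True,
) -> ClassificationReport:
    """Stratified 5-fold CV x 10 repeats of a linear SVM, case vs control.

    Sensitivity/specificity/accuracy come from the cumulative confusion
    matrix; their SDs are across the 10 repeats; AUC is computed on the
    held-out decision values pooled over all folds and repeats.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in y])
    classes = _check_classes(y, minimum=2)
    if len(classes) != 2:
        raise ValueError(f"binary task needs exactly 2 classes, got {classes}")
    if positive_label not in classes:
        positive_label = classes[-1]
    negative_label = next(c for c in classes if c != positive_label)

    confusion = np.zeros((2, 2), dtype=int)  # rows truth [neg, pos]
    per_repeat = np.zeros((N_REPEATS, 2, 2), dtype=int)
    pooled_scores, pooled_truth = [], []
    for r, tr, te in _cv_splits(y, seed, stratify):
        clf = SVC(kernel="linear", C=SVM_COST)
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        scores = clf.decision_function(X[te])
        if clf.classes_[1] != positive_label:
            scores = -scores
        pooled_scores.append(scores)
        pooled_truth.append(y[te] == positive_label)
        for t, p in zip(y[te], pred):
            i = int(t == positive_label)
            j = int(p == positive_label)
            confusion[i, j] += 1
            per_repeat[r, i, j] += 1

    def _rates(cm):
        tn, fp, fn, tp = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        acc = (tp + tn) / cm.sum()
        return sens, spec, acc

    sens, spec, acc = _rates(confusion)
    rep_rates = np.array([_rates(per_repeat[r]) for r in range(N_REPEATS)])
    auc = float(
        roc_auc_score(np.concatenate(pooled_truth), np.concatenate(pooled_scores))
    )
    return ClassificationReport(
        task="binary",
        classes=[negative_label, positive_label],
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=float(acc),
        sd_sensitivity=float(rep_rates[:, 0].std(ddof=1)),
        sd_specificity=float(rep_rates[:, 1].std(ddof=1)),
        sd_accuracy=float(rep_rates[:, 2].std(ddof=1)),
        auc=auc,
        confusion=confusion,
        seed=seed,
        params={"C": SVM_COST, "kernel": "linear", "stratify": stratify},
        pooled_scores=np.concatenate(pooled_scores),
        pooled_truth=np.concatenate(pooled_truth),
    )


def crossval_multiclass(X: np.ndarray, y, seed: int = 0, stratify: bool = True) -> ClassificationReport:
    """Same CV protocol with one-vs-one linear SVMs; accuracy = correct/total
    over the cumulative predictions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in y])
    classes = _check_classes(y, minimum=3)
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)
    per_repeat_acc = np.zeros(N_REPEATS)
    per_repeat_n = np.zeros(N_REPEATS)
    for r, tr, te in _cv_splits(y, seed, stratify):
        clf = SVC(kernel="linear", C=SVM_COST, decision_function_shape="ovo")
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        for t, p in zip(y[te], pred):
            confusion[index[t], index[p]] += 1
        per_repeat_acc[r] += (pred == y[te]).sum()
        per_repeat_n[r] += len(te)
    acc = confusion.trace() / confusion.sum()
    rep_acc = per_repeat_acc / per_repeat_n
    return ClassificationReport(
        task="multiclass",
        classes=classes,
        sensitivity=None,
        specificity=None,
        accuracy=float(acc),
        sd_sensitivity=None,
        sd_specificity=None,
        sd_accuracy=float(rep_acc.std(ddof=1)),
        auc=None,
        confusion=confusion,
        seed=seed,
        params={"C": SVM_COST, "kernel": "linear", "stratify": stratify},
    )


def disease_control_labels(functionome: FunctionomeMatrix) -> np.ndarray:
    """Multiclass labels: the disease name for cases, 'control' otherwise."""
    labels = []
    for s in functionome.sample_ids:
        lab = functionome.sample_labels[s]
        labels.append(lab["disease"] if lab["group"] == "case" else "control")
    return np.asarray(labels)


def cluster_group_profiles(
    functionome: FunctionomeMatrix,
    by: str = "case_disease",
    method: str = "complete",
    metric: str = "euclidean",
):
    """Hierarchical clustering of per-group mean GSR profiles.

    Groups are the case cohorts of each disease (``by="case_disease"``) or
    every (disease, group) combination (``by="disease_group"``).  Returns
    ``(group_names, linkage_matrix, ordered_profile_frame)`` with profile rows
    reordered by dendrogram leaf order.
    """
    groups: dict[str, np.ndarray] = {}
    for s_i, s in enumerate(functionome.sample_ids):
        lab = functionome.sample_labels[s]
        if by == "case_disease":
            if lab["group"] != "case":
                continue
            key = lab["disease"]
        else:
            key = f"{lab['disease']}_{lab['group']}"
        groups.setdefault(key, []).append(s_i)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to cluster")
    names = sorted(groups)
    profiles = np.vstack([functionome.gsr[groups[n], :].mean(axis=0) for n in names])
    Z = linkage(profiles, method=method, metric=metric)
    order = leaves_list(Z)
    frame = pd.DataFrame(
        profiles[order], index=[names[i] for i in order], columns=functionome.set_names
    )
    return names, Z, frame


def first_merge_pair(names: list[str], Z: np.ndarray) -> tuple[str, str]:
    """The two (singleton-expanded) leaves joined by the lowest merge."""
    a, b = int(Z[0, 0]), int(Z[0, 1])
    leaves = {i: names[i] for i in range(len(names))}
    return tuple(sorted((leaves.get(a, str(a)), leaves.get(b, str(b)))))
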