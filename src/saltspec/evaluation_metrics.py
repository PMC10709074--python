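"""Pot-level splitting, confusion-matrix metrics, classical baselines.

The experimental unit is the pot: all four top-view images of a pot (and all
its periods) must land on the same side of the train/validation split, else
near-duplicate views leak across the boundary.  The study design has 203
pots (102 control, 101 salt-stressed), 152 of them for training and 51 for
validation, i.e. 51 x 4 = 204 validation images per period and 612 across
the three periods.

Metrics treat the salt-stressed class as positive:

    accuracy  = (TP + TN) / total
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

and :func:`confusion_from_class_accuracies` reconstructs a confusion matrix
from published per-class accuracies and class sizes, so printed accuracy /
precision / F1 rows can be re-derived exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import SaltSpecError, SplitError
from .imaging_io import FeatureTable


@dataclass
class ConfusionMatrix:
    """Binary confusion counts; positive class = salt-stressed."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise SaltSpecError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class SplitPlan:
    """Pot-disjoint train/validation partition."""

    train_pots: list
    val_pots: list
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_pots) & set(self.val_pots)
        if overlap:
            raise SplitError(f"pots in both splits: {sorted(overlap)[:5]}")


def pot_level_split(pot_labels: dict, n_train: int, seed: int = 0) -> SplitPlan:
    """Seeded, class-stratified random split at pot granularity.

    ``pot_labels`` maps pot ID -> class label.  Stratification apportions the
    ``n_train`` training pots to the classes by largest remainder, so a
    152-of-203 split of 102 control + 101 salt pots holds out 26 control and
    25 salt pots.
    """
    pots = list(pot_labels)
    if n_train >= len(pots):
        raise SplitError(f"n_train={n_train} must be < pot count {len(pots)}")
    if n_train < 1:
        raise SplitError("n_train must be >= 1")
    rng = np.random.default_rng(seed)
    classes = sorted({pot_labels[p] for p in pots})
    exact = {c: n_train * sum(pot_labels[p] == c for p in pots) / len(pots) for c in classes}
    counts = {c: int(np.floor(exact[c])) for c in classes}
    shortfall = n_train - sum(counts.values())
    for c in sorted(classes, key=lambda c: (-(exact[c] - np.floor(exact[c])), c))[:shortfall]:
        counts[c] += 1
    train, val = [], []
    for c in classes:
        members = sorted(p for p in pots if pot_labels[p] == c)
        perm = rng.permutation(len(members))
        chosen = {members[i] for i in perm[: counts[c]]}
        train += [p for p in members if p in chosen]
        val += [p for p in members if p not in chosen]
    return SplitPlan(train_pots=sorted(train), val_pots=sorted(val), seed=seed)


def confusion_from_class_accuracies(acc_control: float, acc_salt: float,
                                    n_control: int, n_salt: int,
                                    tol: float = 0.5) -> ConfusionMatrix:
    """Confusion matrix implied by per-class accuracies (%) and class sizes."""
    for acc in (acc_control, acc_salt):
        if not 0 <= acc <= 100:
            raise SaltSpecError("class accuracies must be in [0, 100]")
    if min(n_control, n_salt) <= 0:
        raise SaltSpecError("class sizes must be positive")
    exact_tn = acc_control * n_control / 100.0
    exact_tp = acc_salt * n_salt / 100.0
    tn, tp = round(exact_tn), round(exact_tp)
    if abs(exact_tn - tn) > tol or abs(exact_tp - tp) > tol:
        raise SaltSpecError("implied counts are not integral within tolerance")
    return ConfusionMatrix(tp=tp, fp=n_control - tn, fn=n_salt - tp, tn=tn)


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, precision, recall and F1; undefined metrics come back None."""
    if cm.total == 0:
        raise SaltSpecError("empty confusion matrix")
    out: dict[str, float | None] = {"accuracy": (cm.tp + cm.tn) / cm.total}
    out["precision"] = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else None
    out["recall"] = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None
    p, r = out["precision"], out["recall"]
    out["f1"] = f1_score(p, r) if p is not None and r is not None else None
    return out


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


_BASELINES = {
    "knn": lambda hp, seed: KNeighborsClassifier(**{"n_neighbors": 5, **hp}),
    "svm": lambda hp, seed: SVC(**{"kernel": "rbf", "random_state": seed, **hp}),
    "rf": lambda hp, seed: RandomForestClassifier(**{"n_estimators": 200,
                                                     "random_state": seed, **hp}),
}


def baseline_classifiers(train_table: FeatureTable, val_table: FeatureTable,
                         which: str, hyperparameters: dict | None = None,
                         columns=None, seed: int = 0) -> dict:
    """Fit KNN / SVM / RF on scalar features and report the metric set."""
    if which not in _BASELINES:
        raise SaltSpecError(f"unknown model {which!r}; choose from {sorted(_BASELINES)}")
    train_pots = set(train_table.df["pot_id"])
    val_pots = set(val_table.df["pot_id"])
    if train_pots & val_pots:
        raise SplitError("pot leakage between train and validation tables")
    if train_table.df["class_label"].nunique() < 2:
        raise SaltSpecError("training data contains a single class")
    names = list(columns) if columns is not None else train_table.feature_names
    Xtr = train_table.df[names].to_numpy(dtype=float)
    Xva = val_table.df[names].to_numpy(dtype=float)
    ytr = (train_table.class_labels == "salt").astype(int)
    yva = (val_table.class_labels == "salt").astype(int)
    # z-score with training statistics
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    clf = _BASELINES[which](hyperparameters or {}, seed)
    clf.fit((Xtr - mu) / sd, ytr)
    pred = clf.predict((Xva - mu) / sd)
    cm = ConfusionMatrix(
        tp=int(((pred == 1) & (yva == 1)).sum()),
        fp=int(((pred == 1) & (yva == 0)).sum()),
        fn=int(((pred == 0) & (yva == 1)).sum()),
        tn=int(((pred == 0) & (yva == 0)).sum()),
    )
    report = metrics(cm)
    report["model"] = which
    report["confusion"] = cm
    return report


def format_metrics(m: dict) -> dict:
    """Round to the reporting precision: percentages at 2 d.p., F1 at 3 d.p."""
    out = {}
    for key in ("accuracy", "precision", "recall"):
        if m.get(key) is not None:
            out[f"{key}_pct"] = round(100 * m[key], 2)
    if m.get("f1") is not None:
        out["f1"] = round(m["f1"], 3)
    return out
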