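"""Quadratic-kernel SVM sub-technique classification from retained PC scores.

A small manually labelled subset of cycles trains a degree-2 polynomial-kernel
SVM (inputs standardized per score column, C = 1 by default); the fitted model
then labels every cycle in the database. Evaluation reports accuracy, a
macro-averaged one-vs-rest ROC AUC (trapezoidal), and the confusion table.
The catch-all "unknown" class trains like any other but is excluded from the
macro AUC by default.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .body import SKILL_LEVELS

log = logging.getLogger(__name__)

CLASSES = ("double_pole", "kick_double_pole", "diagonal_stride",
           "standing_glide", "free_glide", "skating", "unknown")

MIN_PER_CLASS = 3


@dataclass
class TechniqueModel:
    """Fitted quadratic SVM over retained PC scores."""

    pipeline: Pipeline
    classes: tuple[str, ...]
    n_features: int
    c: float = 1.0

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(np.asarray(scores, dtype=float))

    def decision_scores(self, scores: np.ndarray) -> np.ndarray:
        """(n, n_classes) one-vs-rest decision values (2-class models are
        expanded to two antisymmetric columns)."""
        d = self.pipeline.decision_function(np.asarray(scores, dtype=float))
        if d.ndim == 1:
            d = np.column_stack([-d, d])
        return d


def train(scores: np.ndarray, labels, c: float = 1.0) -> TechniqueModel:
    """Fit the degree-2 polynomial-kernel SVM on the labelled subset.

    Requires at least two classes and at least 3 labelled examples per class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must align")
    counts = Counter(labels)
    unknown = set(counts) - set(CLASSES)
    if unknown:
        raise ValueError(f"labels outside the taxonomy: {sorted(unknown)}")
    if len(counts) < 2:
        raise ValueError("training needs at least 2 classes")
    starved = [cls for cls, n in counts.items() if n < MIN_PER_CLASS]
    if starved:
        raise ValueError(f"class(es) with fewer than {MIN_PER_CLASS} labelled "
                         f"examples: {sorted(starved)}")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        # coef0=1 gives the inhomogeneous (true quadratic) kernel (g x.y + 1)^2;
        # the homogeneous default cannot separate sign-symmetric clusters
        ("svm", SVC(kernel="poly", degree=2, coef0=1.0, C=c, gamma="scale",
                    decision_function_shape="ovr")),
    ])
    pipe.fit(scores, labels)
    return TechniqueModel(pipeline=pipe, classes=tuple(pipe.classes_),
                          n_features=scores.shape[1], c=c)


@dataclass
class EvalReport:
    accuracy: float
    auc: float  # macro one-vs-rest; NaN when undefined
    confusion: pd.DataFrame  # rows true, columns predicted
    per_class_counts: dict[str, int] = field(default_factory=dict)
    excluded_classes: tuple[str, ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy out of [0, 1]")
        if np.isfinite(self.auc) and not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc out of [0, 1]")


def evaluate(model: TechniqueModel, scores: np.ndarray, labels,
             exclude_unknown: bool = True) -> EvalReport:
    """Accuracy, macro one-vs-rest ROC AUC and confusion table on held-out
    cycles. Classes absent from the held-out set (and, by default, the
    "unknown" catch-all) are excluded from the macro AUC with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pred = model.predict(scores)
    accuracy = float(np.mean(pred == labels))
    dvals = model.decision_scores(scores)
    aucs = []
    excluded = []
    for j, cls in enumerate(model.classes):
        if exclude_unknown and cls == "unknown":
            excluded.append(cls)
            continue
        mask = labels == cls
        if mask.sum() == 0 or mask.sum() == len(labels):
            log.warning("class %r absent from held-out set; excluded from macro AUC", cls)
            excluded.append(cls)
            continue
        aucs.append(roc_auc_score(mask.astype(int), dvals[:, j]))
    auc = float(np.mean(aucs)) if aucs else float("nan")
    all_classes = sorted(set(model.classes) | set(labels))
    cm = confusion_matrix(labels, pred, labels=all_classes)
    confusion = pd.DataFrame(cm, index=all_classes, columns=all_classes)
    return EvalReport(accuracy=accuracy, auc=auc, confusion=confusion,
                      per_class_counts=dict(Counter(labels)),
                      excluded_classes=tuple(excluded))


def stratified_split(scores: np.ndarray, labels, test_size: float = 0.5,
                     seed: int = 0):
    """Seeded, class-stratified train/held-out split with disjoint rows."""
    idx = np.arange(len(labels))
    tr, te = train_test_split(idx, test_size=test_size, random_state=seed,
                              stratify=np.asarray(labels, dtype=object))
    assert not set(tr) & set(te)
    return tr, te


def cross_validate(scores: np.ndarray, labels, folds: int = 5, seed: int = 0,
                   c: float = 1.0) -> dict:
    """Stratified k-fold CV on the labelled subset: mean/SD accuracy and
    macro AUC across folds, plus resubstitution figures reported separately.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, aucs = [], []
    for tr, te in skf.split(scores, labels):
        try:
            model = train(scores[tr], labels[tr], c=c)
        except ValueError as exc:
            # a rare class can drop below the training minimum inside a fold
            log.warning("fold skipped: %s", exc)
            continue
        rep = evaluate(model, scores[te], labels[te])
        accs.append(rep.accuracy)
        if np.isfinite(rep.auc):
            aucs.append(rep.auc)
    if not accs:
        log.warning("no feasible CV folds; reporting NaN cross-validation figures")
    full = train(scores, labels, c=c)
    resub = evaluate(full, scores, labels)
    return {
        "cv_accuracy_mean": float(np.mean(accs)) if accs else float("nan"),
        "cv_accuracy_sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else float("nan"),
        "cv_auc_mean": float(np.mean(aucs)) if aucs else float("nan"),
        "resub_accuracy": resub.accuracy,
        "resub_auc": resub.auc,
        "folds": folds,
        "c": c,
        "model": full,
    }


def classify_all(model: TechniqueModel, scores: np.ndarray) -> np.ndarray:
    """Deterministically label every cycle (one label per row)."""
    return model.predict(scores)


def technique_by_skill(labels, skills) -> pd.DataFrame:
    """Per-skill technique usage proportions (rows sum to 1)."""
    df = pd.DataFrame({"label": np.asarray(labels, dtype=object),
                       "skill": np.asarray(skills, dtype=object)})
    table = pd.crosstab(df["skill"], df["label"], normalize="index")
    order = [s for s in SKILL_LEVELS if s in table.index]
    return table.loc[order]
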