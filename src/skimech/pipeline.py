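"""End-to-end experiment drivers built from the package's stages.

Two canonical synthetic experiments:

* ``run_classification_experiment`` — a cohort with the default skill-dependent
  technique mix; a small stratified subset of cycles is "manually" labelled,
  a quadratic SVM is trained on their retained PC scores, evaluated on the
  held-out cycles, and all cycles are then auto-labelled to tabulate technique
  usage by skill.

* ``run_skill_contrast`` — a controlled skill-graded cohort (single technique,
  fixed effort) isolating the embedded within-technique skill effects; per-PC
  ANOVAs select the significant-and-stepwise PCs, MCR builds the
  beginner/elite avatar pair, and the drag/ski-angle/power metrics are
  computed on both. Holding technique and effort constant removes composition
  confounds (skill levels favouring different techniques) that would otherwise
  dominate the contrast — see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify as _classify
from . import metrics as _metrics
from . import pca as _pca
from . import stats as _stats
from .body import SKILL_LEVELS, default_point_model
from .preprocess import Cycle, preprocess_trial
from .simulate import SkillEffectProfile, generate_cohort


def cycles_from_cohort(cohort, threshold_mm: float = 10.0) -> list[Cycle]:
    """Preprocess every trial of a simulated cohort, attaching ground-truth
    technique labels to the extracted cycles."""
    cycles: list[Cycle] = []
    for trial, truth in cohort:
        cycles += preprocess_trial(trial, threshold_mm=threshold_mm,
                                   truth_labels=list(truth.technique_labels))
    return cycles


def label_subset(labels, fraction: float = 0.04, min_per_class: int = 3,
                 seed: int = 0) -> np.ndarray:
    """Indices of a stratified "manually labelled" subset.

    Roughly ``fraction`` of all cycles, allocated proportionally per class but
    never fewer than ``min_per_class`` from any class present.
    """
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    n = len(labels)
    target = max(int(round(fraction * n)), 1)
    picked = []
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        k = max(min_per_class, int(round(target * len(idx) / n)))
        picked.append(rng.choice(idx, size=min(k, len(idx)), replace=False))
    return np.sort(np.concatenate(picked))


@dataclass
class ClassificationResult:
    model: _classify.TechniqueModel
    report: _classify.EvalReport  # held-out evaluation
    cv: dict  # stratified k-fold summary on the labelled subset
    labelled_idx: np.ndarray
    predicted: np.ndarray  # labels for every cycle
    truth_agreement: float  # vs simulator ground truth, all cycles
    usage_by_skill: pd.DataFrame
    pc_model: _pca.PCModel
    meta: pd.DataFrame


def run_classification_experiment(n_per_skill: int = 12, n_cycles: int = 20,
                                  seed: int = 0, label_fraction: float = 0.04,
                                  effects: SkillEffectProfile | None = None
                                  ) -> ClassificationResult:
    """Simulate, preprocess, fit the PCA, train/evaluate the sub-technique
    classifier on a small labelled subset, and auto-label all cycles."""
    effects = effects or SkillEffectProfile()
    cohort = generate_cohort(n_per_skill, effects=effects, seed=seed, n_cycles=n_cycles)
    cycles = cycles_from_cohort(cohort)
    db = _pca.amplitude_normalize(_pca.build_database(cycles))
    model = _pca.fit_pca(db)
    scores = model.scores[:, :model.retained_k]
    truth = db.meta["technique"].to_numpy()
    lab_idx = label_subset(truth, fraction=label_fraction, seed=seed)
    held = np.setdiff1d(np.arange(len(scores)), lab_idx)
    svm = _classify.train(scores[lab_idx], truth[lab_idx])
    report = _classify.evaluate(svm, scores[held], truth[held])
    cv = _classify.cross_validate(scores[lab_idx], truth[lab_idx],
                                  folds=min(5, np.bincount(
                                      pd.factorize(truth[lab_idx])[0]).min()),
                                  seed=seed)
    predicted = _classify.classify_all(svm, scores)
    usage = _classify.technique_by_skill(predicted, db.meta["skill"].to_numpy())
    return ClassificationResult(
        model=svm, report=report, cv=cv, labelled_idx=lab_idx, predicted=predicted,
        truth_agreement=float(np.mean(predicted == truth)),
        usage_by_skill=usage, pc_model=model, meta=db.meta)


@dataclass
class SkillContrastResult:
    pc_model: _pca.PCModel
    anova: list[_stats.PCAnovaResult]
    selected_pcs: tuple[int, ...]
    directions: tuple[int, ...]
    reconstruction: _pca.Reconstruction
    beginner: _metrics.CycleMetrics
    elite: _metrics.CycleMetrics
    meta: pd.DataFrame


def run_skill_contrast(n_per_skill: int = 8, n_cycles: int = 15, seed: int = 0,
                       technique: str = "skating", effort: str = "medium",
                       effects: SkillEffectProfile | None = None,
                       alpha: float = 0.05) -> SkillContrastResult:
    """Controlled skill-contrast experiment ending in the avatar pair.

    One technique, one effort: the only systematic gradient in the cohort is
    skill, so the selected PCs isolate the embedded skill effects.
    """
    if effects is None:
        effects = SkillEffectProfile(
            technique_mix={s: {technique: 1.0} for s in SKILL_LEVELS})
    cohort = generate_cohort(n_per_skill, effects=effects, seed=seed,
                             n_cycles=n_cycles, efforts=(effort,))
    cycles = cycles_from_cohort(cohort)
    db = _pca.amplitude_normalize(_pca.build_database(cycles))
    model = _pca.fit_pca(db)
    results = _stats.anova_per_pc(model.scores[:, :model.retained_k],
                                  db.meta["skill"].to_numpy(), alpha=alpha)
    pcs, dirs = _stats.select_pcs_for_mcr(results)
    rec = _pca.mcr_reconstruct(model, pcs, dirs)
    beginner, elite = _metrics.metrics_for_reconstruction(rec, default_point_model())
    return SkillContrastResult(pc_model=model, anova=results, selected_pcs=pcs,
                               directions=dirs, reconstruction=rec,
                               beginner=beginner, elite=elite, meta=db.meta)
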