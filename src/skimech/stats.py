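"""Skill-level statistics on PC scores: per-PC one-way ANOVA, the stepwise
(strict monotonicity) criterion, violin-plot data, and selection of PCs for
multi-component reconstruction.

Each retained PC's scores are tested with a fixed-effects one-way ANOVA with
skill level (beginner → elite) as the factor. A PC is *selected* for
reconstruction when the effect is significant (raw p < alpha, matching the
reported-table convention; a Holm-adjusted column is reported alongside but
does not drive selection) and the four group means are strictly monotone in
skill — the "systematic, stepwise" criterion. Cycles are treated as
independent observations; with few athletes per group this pseudo-replicates,
which the report flags rather than silently corrects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import f_oneway, gaussian_kde
from statsmodels.stats.multitest import multipletests

from .body import SKILL_LEVELS

log = logging.getLogger(__name__)

CLUSTER_CAVEAT = ("cycles are treated as independent observations; with few "
                  "athletes per skill group this pseudo-replicates and p-values "
                  "are anti-conservative")


@dataclass
class PCAnovaResult:
    pc_index: int  # 0-based
    f_statistic: float
    p_value: float
    p_holm: float
    group_means: dict[str, float]  # ordered beginner -> elite
    significant: bool
    stepwise: bool
    direction: int  # +1 / -1 / 0 (not stepwise)
    selected: bool


def stepwise_flag(group_means) -> tuple[bool, int]:
    """Strict monotonicity of ordered group means; ties break monotonicity.

    Returns (is_stepwise, direction) with direction +1 (increasing with
    skill), -1 (decreasing) or 0 when not monotone.
    """
    means = np.asarray(list(group_means), dtype=float)
    if len(means) < 3:
        raise ValueError("stepwise criterion needs at least 3 group means")
    diffs = np.diff(means)
    if np.any(diffs == 0):
        log.info("tied group means: not stepwise")
        return False, 0
    if np.all(diffs > 0):
        return True, +1
    if np.all(diffs < 0):
        return True, -1
    return False, 0


def anova_per_pc(scores: np.ndarray, skills, alpha: float = 0.05,
                 k: int | None = None) -> list[PCAnovaResult]:
    """One-way ANOVA of each PC's scores on skill level.

    Groups with fewer than 2 cycles are dropped with a warning. F and p follow
    the standard F distribution; the stepwise flag is evaluated only when at
    least 3 groups remain.
    """
    scores = np.asarray(scores, dtype=float)
    skills = np.asarray(skills, dtype=object)
    if scores.ndim != 2 or len(scores) != len(skills):
        raise ValueError("scores must be (n, K) aligned with skills")
    k = scores.shape[1] if k is None else min(k, scores.shape[1])
    groups_idx = {}
    for s in SKILL_LEVELS:
        idx = np.where(skills == s)[0]
        if 0 < len(idx) < 2:
            log.warning("skill group %r has <2 cycles; dropped from ANOVA", s)
            continue
        if len(idx) >= 2:
            groups_idx[s] = idx
    if len(groups_idx) < 2:
        raise ValueError("ANOVA needs at least 2 skill groups with >= 2 cycles")
    log.info("%s", CLUSTER_CAVEAT)
    results = []
    pvals = []
    for j in range(k):
        samples = [scores[idx, j] for idx in groups_idx.values()]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = f_oneway(*samples)
            f_stat, p = float(f_stat), float(p)
        means = {s: float(scores[idx, j].mean()) for s, idx in groups_idx.items()}
        if len(means) >= 3:
            step, direction = stepwise_flag(means.values())
        else:
            step, direction = False, 0
        significant = p < alpha
        results.append(PCAnovaResult(
            pc_index=j, f_statistic=f_stat, p_value=p, p_holm=np.nan,
            group_means=means, significant=significant, stepwise=step,
            direction=direction, selected=significant and step))
        pvals.append(p)
    # Holm column is informational only; selection uses raw p (table convention)
    _, p_holm, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    for res, ph in zip(results, p_holm):
        res.p_holm = float(ph)
    return results


def select_pcs_for_mcr(results: list[PCAnovaResult]) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Indices and trend directions of the significant-and-stepwise PCs,
    ready to hand to mcr_reconstruct. An empty selection is allowed."""
    sel = [(r.pc_index, r.direction) for r in results if r.selected]
    if not sel:
        log.warning("no PC is both significant and stepwise; empty selection")
        return (), ()
    pcs, dirs = zip(*sel)
    return tuple(pcs), tuple(dirs)


def violin_data(scores_1d, skills, n_grid: int = 128,
                bandwidth_floor: float = 1e-3) -> dict[str, dict]:
    """Per-skill raw samples and Gaussian-KDE summaries for violin plots.

    Densities integrate to ~1 on their grid. Degenerate groups (a single
    point, or zero variance) get a documented bandwidth floor relative to the
    pooled scale.
    """
    scores_1d = np.asarray(scores_1d, dtype=float)
    skills = np.asarray(skills, dtype=object)
    pooled_scale = float(np.std(scores_1d)) or 1.0
    out = {}
    for s in SKILL_LEVELS:
        sample = scores_1d[skills == s]
        if sample.size == 0:
            continue
        if sample.size < 2 or np.ptp(sample) == 0:
            bw = max(bandwidth_floor * pooled_scale, bandwidth_floor)
            grid = np.linspace(sample.mean() - 4 * bw, sample.mean() + 4 * bw, n_grid)
            dens = np.exp(-0.5 * ((grid - sample.mean()) / bw) ** 2) \
                / (bw * np.sqrt(2 * np.pi))
        else:
            kde = gaussian_kde(sample)
            lo, hi = sample.min(), sample.max()
            pad = 3 * sample.std(ddof=1)
            grid = np.linspace(lo - pad, hi + pad, n_grid)
            dens = kde(grid)
        out[s] = {"sample": sample, "grid": grid, "density": dens,
                  "median": float(np.median(sample))}
    return out
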