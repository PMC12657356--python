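"""Preprocess a raw trial into time-normalized propulsion cycles.

Runs the fixed chain — pelvis alignment (heading removal), T12 referencing
(translation/drift removal), left-toe displacement segmentation at the 1 cm
peak threshold, PCHIP resampling to 101 points — and compares recovered cycle
boundaries with the simulator's ground truth. Ends with a cadence comparison
across skill levels.
"""

import numpy as np

import skimech as sk
from skimech.preprocess import cadence_summary

config = sk.SimConfig(technique="double_pole", skill="intermediate",
                      n_cycles=12, seed=7)
trial, truth = sk.generate_trial(config)

aligned = sk.reference_to_t12(sk.align_to_pelvis(trial))
intervals = sk.segment_cycles(aligned)
peaks = np.array([a for a, _ in intervals] + [intervals[-1][1]])
err = np.abs(peaks - truth.cycle_boundaries).max()
print(f"segmentation: {len(peaks)} toe-displacement peaks "
      f"(truth {len(truth.cycle_boundaries)}), max boundary error {err} frames")

cycles = sk.extract_cycles(aligned, truth_labels=list(truth.technique_labels))
durs = [c.duration_s for c in cycles]
print(f"{len(cycles)} cycles time-normalized to 101 samples; durations "
      f"{min(durs):.2f}-{max(durs):.2f} s (configured mean 1.0 s, CV 8%)")

# cadence across skills: equal configured periods -> no significant difference
rng = np.random.default_rng(0)
durations = {}
for skill in sk.SKILL_LEVELS:
    cfg = sk.SimConfig(technique="diagonal_stride", skill=skill, n_cycles=15,
                       seed=int(rng.integers(2**31)))
    t, tr = sk.generate_trial(cfg)
    cyc = sk.preprocess_trial(t)
    durations[skill] = np.array([c.duration_s for c in cyc])
summary = cadence_summary(durations)
print("mean cycle time by skill:",
      {s: round(m, 3) for s, m in summary.means.items()})
print(f"one-way ANOVA on cycle time: F={summary.f_statistic:.2f}, "
      f"p={summary.p_value:.3f} (no cadence-skill effect embedded, so p should "
      f"usually exceed 0.05)")
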