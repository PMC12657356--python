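"""Alignment, T12 referencing, segmentation, time normalization, cadence."""

import numpy as np
import pytest

import skimech as sk
from skimech import body
from skimech.preprocess import (align_to_pelvis, cadence_summary, extract_cycles,
                                reference_to_t12, segment_cycles, time_normalize)
from conftest import make_static_trial


def _rotz(deg):
    h = np.radians(deg)
    return np.array([[np.cos(h), -np.sin(h), 0], [np.sin(h), np.cos(h), 0], [0, 0, 1.0]])


class TestAlignToPelvis:
    def test_identity_when_pelvis_matches_global(self, static_trial):
        aligned = align_to_pelvis(static_trial)
        np.testing.assert_allclose(aligned.frames, static_trial.frames, atol=1e-9)
        np.testing.assert_allclose(aligned.rotations[0], np.eye(3), atol=1e-12)

    def test_half_turn(self, model, meta):
        """Pelvis rotated 180 deg about vertical: global (1000,0,0) relative to
        the pelvis origin lands at local (-1000,0,0)."""
        trial = make_static_trial(1, model, meta)
        frames = trial.frames @ _rotz(180.0).T  # whole body (incl. pelvis) turned
        probe = model.index("HEAD_TOP")
        frames[0, probe] = [1000.0, 0.0, 0.0]
        trial = trial.copy_with(frames=frames)
        aligned = align_to_pelvis(trial)
        np.testing.assert_allclose(aligned.frames[0, probe], [-1000.0, 0.0, 0.0],
                                   atol=1e-9)

    def test_equivariance_under_global_heading(self, clean_trial):
        trial, _ = clean_trial
        rotated = trial.copy_with(frames=trial.frames @ _rotz(90.0).T)
        a0 = align_to_pelvis(trial)
        a1 = align_to_pelvis(rotated)
        np.testing.assert_allclose(a1.frames, a0.frames, atol=1e-9)

    def test_rotations_proper(self, clean_trial):
        trial, _ = clean_trial
        rot = align_to_pelvis(trial).rotations
        dets = np.linalg.det(rot)
        np.testing.assert_allclose(dets, 1.0, atol=1e-9)

    def test_pelvis_axes_coincide_with_output_frame(self, clean_trial):
        from skimech.preprocess import pelvis_basis
        trial, _ = clean_trial
        aligned = align_to_pelvis(trial)
        basis_after = pelvis_basis(aligned.frames, trial.model)
        np.testing.assert_allclose(basis_after,
                                   np.broadcast_to(np.eye(3), basis_after.shape),
                                   atol=1e-9)

    def test_degenerate_pelvis_raises_with_frame(self, static_trial, model):
        frames = static_trial.frames.copy()
        for lbl in ("PELVIS_ORIGIN", "PELVIS_LASIS", "PELVIS_RASIS"):
            frames[3, model.index(lbl)] = [0.0, 0.0, 0.0]
        with pytest.raises(ValueError, match="frame 3"):
            align_to_pelvis(static_trial.copy_with(frames=frames))


class TestReferenceToT12:
    def test_t12_exactly_zero(self, clean_trial):
        trial, _ = clean_trial
        ref = reference_to_t12(align_to_pelvis(trial))
        np.testing.assert_array_equal(ref.point(body.T12), 0.0)

    def test_translation_invariance(self, clean_trial):
        trial, _ = clean_trial
        shifted = trial.copy_with(frames=trial.frames + 5000.0)
        r0 = reference_to_t12(align_to_pelvis(trial))
        r1 = reference_to_t12(align_to_pelvis(shifted))
        np.testing.assert_allclose(r1.frames, r0.frames, atol=1e-9)

    def test_rigid_shift_preserves_relative_vectors(self, clean_trial):
        trial, _ = clean_trial
        aligned = align_to_pelvis(trial)
        ref = reference_to_t12(aligned)
        before = aligned.point(body.TOE_L) - aligned.point(body.T12)
        after = ref.point(body.TOE_L) - ref.point(body.T12)
        np.testing.assert_array_equal(before, after)

    def test_commutes_with_alignment(self, clean_trial):
        trial, _ = clean_trial
        ab = reference_to_t12(align_to_pelvis(trial))
        ba = align_to_pelvis(reference_to_t12(trial))
        np.testing.assert_allclose(ab.frames, ba.frames, atol=1e-9)


class TestSegmentCycles:
    def _loop_trial(self, model, meta, r0_mm, a_mm, period_s, total_s, rate=240.0):
        """Left toe rides a planar limacon: displacement norm about the
        centroid is (to first order) a sinusoid with one peak per period."""
        trial = make_static_trial(int(total_s * rate), model, meta, rate_hz=rate)
        t = trial.time_s
        theta = 2 * np.pi * t / period_s - np.pi  # start at a displacement minimum
        rho = r0_mm + a_mm * np.cos(theta)
        frames = trial.frames.copy()
        j = model.index(body.TOE_L)
        frames[:, j, 0] += rho * np.cos(theta)
        frames[:, j, 2] += rho * np.sin(theta)
        return trial.copy_with(frames=frames)

    def test_analytic_peak_count(self, model, meta):
        """10 s.. 12 s of a 1.2 s period: 10 peaks hence 9 intervals."""
        trial = self._loop_trial(model, meta, r0_mm=150, a_mm=100,
                                 period_s=1.2, total_s=12.0)
        intervals = segment_cycles(trial)
        assert len(intervals) == 9
        starts = [a for a, _ in intervals]
        assert np.all(np.diff(starts) > 0)

    def test_sub_threshold_amplitude_empty(self, model, meta):
        trial = self._loop_trial(model, meta, r0_mm=5, a_mm=2,
                                 period_s=1.2, total_s=6.0)
        assert segment_cycles(trial) == []

    def test_recovers_simulator_boundaries_noise_free(self, clean_trial):
        trial, truth = clean_trial
        aligned = reference_to_t12(align_to_pelvis(trial))
        intervals = segment_cycles(aligned)
        peaks = np.array([a for a, _ in intervals] + [intervals[-1][1]])
        assert len(peaks) == len(truth.cycle_boundaries)
        assert np.abs(peaks - truth.cycle_boundaries).max() <= 2

    def test_offset_and_heading_invariance(self, clean_trial):
        """Segmentation result unchanged by a constant offset or a heading
        rotation of the raw trial (both removed upstream)."""
        trial, _ = clean_trial
        base = segment_cycles(reference_to_t12(align_to_pelvis(trial)))
        h = np.radians(40.0)
        rot = np.array([[np.cos(h), -np.sin(h), 0], [np.sin(h), np.cos(h), 0], [0, 0, 1.0]])
        moved = trial.copy_with(frames=trial.frames @ rot.T + 1234.5)
        assert segment_cycles(reference_to_t12(align_to_pelvis(moved))) == base

    def test_intervals_bounded_by_peaks(self, noisy_trial):
        trial, truth = noisy_trial
        aligned = reference_to_t12(align_to_pelvis(trial))
        intervals = segment_cycles(aligned)
        assert len(intervals) <= len(truth.cycle_boundaries) - 1 + 1


class TestTimeNormalize:
    def test_linear_ramp_exact(self, meta):
        n = 37
        t = np.linspace(0.0, 1.7, n)
        coords = np.tile((3.0 * t - 1.0)[:, None, None], (1, 76, 3))
        power = np.tile((2.0 * t)[:, None], (1, 5))
        cyc = time_normalize(t, coords, power, meta)
        expect = 3.0 * (cyc.time_norm * cyc.duration_s) - 1.0
        np.testing.assert_allclose(cyc.coords[:, 0, 0], expect, atol=1e-9)
        assert cyc.coords[0, 0, 0] == coords[0, 0, 0]
        assert cyc.coords[-1, 0, 0] == coords[-1, 0, 0]

    def test_constant_channel(self, meta):
        t = np.linspace(0, 1, 10)
        coords = np.full((10, 76, 3), 42.0)
        power = np.full((10, 5), 7.0)
        cyc = time_normalize(t, coords, power, meta)
        np.testing.assert_array_equal(cyc.coords, 42.0)
        np.testing.assert_array_equal(cyc.power, 7.0)

    def test_sinusoid_interpolation_error(self, meta):
        rate, period = 240.0, 1.0
        t = np.arange(0, period, 1 / rate)
        amp = 100.0
        sig = amp * np.sin(2 * np.pi * t / period)
        coords = np.tile(sig[:, None, None], (1, 76, 3))
        power = np.zeros((len(t), 5))
        cyc = time_normalize(t, coords, power, meta)
        t_new = cyc.time_norm * cyc.duration_s
        err = np.abs(cyc.coords[:, 0, 0] - amp * np.sin(2 * np.pi * t_new / period))
        assert err.max() < 1e-3 * amp

    def test_short_segment_rejected(self, meta):
        t = np.array([0.0, 0.1, 0.2])
        with pytest.raises(ValueError, match="PCHIP"):
            time_normalize(t, np.zeros((3, 76, 3)), np.zeros((3, 5)), meta)

    def test_extract_cycles_counts(self, clean_trial):
        trial, truth = clean_trial
        aligned = reference_to_t12(align_to_pelvis(trial))
        cycles = extract_cycles(aligned, truth_labels=list(truth.technique_labels))
        assert len(cycles) == len(truth.cycle_boundaries) - 1
        assert all(c.coords.shape == (101, 76, 3) for c in cycles)
        assert all(c.technique == "diagonal_stride" for c in cycles)


class TestCadence:
    def test_degenerate_equal_durations(self):
        groups = {s: np.ones(5) for s in sk.SKILL_LEVELS}
        summary = cadence_summary(groups)
        assert summary.p_value == 1.0
        assert len(set(summary.means.values())) == 1

    def test_type_one_error_calibration(self):
        """Null ANOVA rejects at ~alpha over repeated simulated cohorts."""
        rng = np.random.default_rng(2024)
        n_sims, rejections = 400, 0
        for _ in range(n_sims):
            groups = {s: rng.normal(1.0, 0.1, 30) for s in sk.SKILL_LEVELS}
            if cadence_summary(groups).p_value < 0.05:
                rejections += 1
        rate = rejections / n_sims
        assert 0.02 <= rate <= 0.08

    def test_small_group_excluded(self):
        groups = {"beginner": np.array([1.0]), "intermediate": np.ones(5) * 1.1,
                  "elite": np.ones(5) * 0.9}
        summary = cadence_summary(groups)
        assert "beginner" not in summary.groups
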