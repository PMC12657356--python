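"""Synthetic skier generator: determinism, ground-truth contracts, skill-effect
embedding, cohort structure and the GNSS track generator."""

import numpy as np
import pytest
from scipy import stats as sps

import skimech as sk
from skimech.simulate import TECH_TEMPLATES


class TestGenerateTrial:
    def test_deterministic_given_seed(self):
        cfg = sk.SimConfig(technique="skating", skill="elite", n_cycles=5, seed=99)
        t1, g1 = sk.generate_trial(cfg)
        t2, g2 = sk.generate_trial(cfg)
        assert np.array_equal(t1.frames, t2.frames)
        assert np.array_equal(t1.power, t2.power)
        assert np.array_equal(g1.cycle_boundaries, g2.cycle_boundaries)
        assert np.array_equal(g1.peak_upper_wkg, g2.peak_upper_wkg)

    def test_ground_truth_counts(self):
        cfg = sk.SimConfig(technique="double_pole", skill="beginner", n_cycles=20,
                           noise_sd_mm=0.0, drift_mm_per_s=0.0, seed=1)
        _, truth = sk.generate_trial(cfg)
        assert len(truth.cycle_boundaries) == 20
        assert truth.technique_labels == ["double_pole"] * 20
        assert np.all(np.diff(truth.cycle_boundaries) > 0)

    def test_skill_gradient_embedded(self):
        """Same seed and effects: elite must out-power and out-tuck a beginner."""
        kw = dict(technique="diagonal_stride", n_cycles=6, seed=4)
        _, beg = sk.generate_trial(sk.SimConfig(skill="beginner", **kw))
        _, eli = sk.generate_trial(sk.SimConfig(skill="elite", **kw))
        assert eli.peak_upper_wkg.mean() > beg.peak_upper_wkg.mean()
        assert eli.frontal_area_m2.mean() < beg.frontal_area_m2.mean()

    def test_unknown_technique_rejected(self):
        with pytest.raises(ValueError, match="technique"):
            sk.SimConfig(technique="telemark", skill="elite")

    def test_noise_burying_threshold_rejected(self):
        amp_mm = TECH_TEMPLATES["standing_glide"].toe_loop_amp * 1000
        with pytest.raises(ValueError, match="bury"):
            sk.generate_trial(sk.SimConfig(technique="standing_glide", skill="beginner",
                                           noise_sd_mm=10 * amp_mm))

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            sk.SimConfig(technique="skating", skill="elite",
                         cycle_period_s=1.0, sample_rate_hz=1.5)

    def test_power_nonnegative_and_phase_locked(self, noisy_trial):
        trial, truth = noisy_trial
        assert np.all(trial.power >= 0)
        # pulses: power at boundaries similar cycle to cycle (phase lock)
        upper = trial.power[:, 0] + trial.power[:, 1]
        vals = upper[truth.cycle_boundaries]
        assert vals.std() < 0.5 * upper.max()


class TestEffectEmbedding:
    def test_regression_recovers_multiplier_signs(self):
        """Realized embedded effects regress on skill rank with the configured
        sign at p < 0.01 (cohort of 25 trials per skill)."""
        eff = sk.SkillEffectProfile(
            technique_mix={s: {"skating": 1.0} for s in sk.SKILL_LEVELS})
        cohort = sk.generate_cohort(25, effects=eff, seed=5, n_cycles=3)
        rank, area, yaw, up, lo = [], [], [], [], []
        for trial, truth in cohort:
            rank.append(sk.skill_rank(trial.meta.skill))
            area.append(truth.frontal_area_m2.mean())
            yaw.append(truth.ski_angle_deg.mean())
            up.append(truth.peak_upper_wkg.mean())
            lo.append(truth.peak_lower_wkg.mean())
        for sample, sign in ((area, -1), (yaw, -1), (up, +1), (lo, +1)):
            res = sps.linregress(rank, sample)
            assert np.sign(res.slope) == sign
            assert res.pvalue < 0.01


class TestGenerateCohort:
    def test_counts(self):
        cohort = sk.generate_cohort(2, seed=0, n_cycles=2)
        assert len(cohort) == 8
        skills = [t.meta.skill for t, _ in cohort]
        assert sorted(set(skills)) == sorted(sk.SKILL_LEVELS)

    def test_degenerate_mix(self):
        mix = {s: {"diagonal_stride": 1.0} for s in sk.SKILL_LEVELS}
        cohort = sk.generate_cohort(3, effects=sk.SkillEffectProfile(technique_mix=mix),
                                    seed=0, n_cycles=2)
        assert all(t.meta.technique == "diagonal_stride" for t, _ in cohort)

    def test_mix_shares_binomial(self):
        """Empirical beginner diagonal-stride share ~ its configured probability."""
        n = 50  # 50 trials per skill
        cohort = sk.generate_cohort(n, seed=3, n_cycles=1)
        beg = [t.meta.technique for t, _ in cohort if t.meta.skill == "beginner"]
        p = sk.SkillEffectProfile().technique_mix["beginner"]["diagonal_stride"]
        share = np.mean([t == "diagonal_stride" for t in beg])
        se = np.sqrt(p * (1 - p) / n)
        assert abs(share - p) <= 3 * se

    def test_invalid_mix_rejected(self):
        bad = {s: {"skating": 0.7} for s in sk.SKILL_LEVELS}
        with pytest.raises(ValueError, match="sums to"):
            sk.SkillEffectProfile(technique_mix=bad)


class TestGnssTrack:
    def test_laps_identical_without_noise(self):
        series, bounds = sk.generate_gnss_track(3, lap_length_m=800,
                                                drift_m_per_s=0.0, noise_m=0.0, seed=0)
        per = bounds[1] - bounds[0]
        xyz = series.xyz()
        for k in (1, 2):
            np.testing.assert_allclose(xyz[k * per:(k + 1) * per, :],
                                       xyz[:per, :], atol=1e-9)

    def test_elevation_range(self):
        series, _ = sk.generate_gnss_track(2, elevation_change_m=20.0,
                                           noise_m=0.0, seed=0)
        assert np.ptp(series.elev_m) == pytest.approx(20.0, abs=1e-6)

    def test_samples_per_lap(self):
        series, bounds = sk.generate_gnss_track(2, rate_hz=4.0, lap_time_s=150.0,
                                                noise_m=0.0)
        assert bounds[1] - bounds[0] == 600
        assert len(series.time_s) == 1200

    def test_lap_length_close(self):
        series, bounds = sk.generate_gnss_track(1, lap_length_m=1000.0, noise_m=0.0)
        xy = series.xyz()[:, :2]
        closed = np.vstack([xy, xy[:1]])
        length = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        assert length == pytest.approx(1000.0, rel=0.01)
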