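"""Cycle database, amplitude normalization, PCA (vs eigendecomposition oracle),
variance-based retention, and multi-component reconstruction identities."""

import numpy as np
import pandas as pd
import pytest

from skimech import pca as P

# Per-PC explained variances as printed for the field dataset (percent).
TABLE_EXPLAINED = [23.4, 20.5, 10.7, 6.3, 4.8, 3.8, 3.4, 2.8, 2.7, 2.4,
                   2.2, 1.7, 1.5, 1.3, 1.1, 1.0, 0.9]


def _toy_db(n=12, seed=0):
    """Small CycleDatabase with distinguishable block scales."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, P.N_FEATURES))
    X[:, P.BLOCKS["time"]] = rng.uniform(0, 1.2, (n, 101))
    X[:, P.BLOCKS["coords"]] = rng.normal(0, 300.0, (n, 228 * 101))
    X[:, P.BLOCKS["power"]] = rng.uniform(0, 6.0, (n, 3 * 101))
    meta = pd.DataFrame({"skill": ["beginner"] * n})
    return P.CycleDatabase(X=X, meta=meta, block_scalars=None)


class TestAmplitudeNormalize:
    def test_ranges_equalized(self):
        db = P.amplitude_normalize(_toy_db())
        ranges = {name: np.ptp(db.X[:, sl]) for name, sl in P.BLOCKS.items()}
        target = ranges["coords"]
        for r in ranges.values():
            assert r == pytest.approx(target, rel=0.01)

    def test_equal_ranges_fixed_point(self):
        raw = _toy_db()
        X = raw.X.copy()
        # force all blocks to the same range [0, 100]
        for sl in P.BLOCKS.values():
            blk = X[:, sl]
            X[:, sl] = 100 * (blk - blk.min()) / np.ptp(blk)
        db = P.CycleDatabase(X=X, meta=raw.meta, block_scalars=None)
        normed = P.amplitude_normalize(db)
        for s in normed.block_scalars.values():
            assert s == pytest.approx(1.0, rel=1e-12)

    def test_round_trip(self):
        raw = _toy_db(seed=3)
        back = P.invert_normalization(P.amplitude_normalize(raw))
        np.testing.assert_allclose(back.X, raw.X, atol=1e-12)

    def test_zero_range_block_scalar_one(self):
        raw = _toy_db()
        X = raw.X.copy()
        X[:, P.BLOCKS["power"]] = 5.0
        db = P.amplitude_normalize(P.CycleDatabase(X=X, meta=raw.meta))
        assert db.block_scalars["power"] == 1.0


class TestFitPca:
    def test_known_eigenstructure(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10_000, 2)) @ np.diag([3.0, 1.0])  # cov eigvals 9, 1
        model = P.fit_pca(X)
        assert model.explained_var[0] == pytest.approx(90.0, abs=1.0)
        assert model.explained_var[1] == pytest.approx(10.0, abs=1.0)

    def test_degenerate_database(self):
        X = np.tile(np.arange(5.0), (6, 1))
        model = P.fit_pca(X)
        assert np.all(model.explained_var == 0)
        assert model.retained_k == 0

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="at least 2"):
            P.fit_pca(np.ones((1, 4)))

    def test_full_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 25))
        model = P.fit_pca(X)
        np.testing.assert_allclose(P.reconstruct_rows(model), X, atol=1e-8)

    def test_invariants(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 30)) * rng.uniform(0.5, 4.0, 30)
        model = P.fit_pca(X)
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)
        assert np.all(np.diff(model.explained_var) <= 1e-9)
        assert model.explained_var.sum() == pytest.approx(100.0, abs=1e-6)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0.0, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        """SVD route equals a brute-force covariance eigendecomposition."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 50))
        model = P.fit_pca(X)
        C = np.cov(X, rowvar=False)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        var_svd = model.explained_var / 100.0 * evals.sum()
        k = min(len(evals), len(var_svd))
        np.testing.assert_allclose(var_svd[:k], evals[:k], atol=1e-6)
        scores_oracle = (X - X.mean(axis=0)) @ evecs
        for j in range(k):
            dot = np.dot(model.scores[:, j], scores_oracle[:, j])
            np.testing.assert_allclose(model.scores[:, j],
                                       np.sign(dot) * scores_oracle[:, j], atol=1e-6)

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 12))
        m1, m2 = P.fit_pca(X), P.fit_pca(X.copy())
        np.testing.assert_array_equal(m1.loadings, m2.loadings)
        idx = np.argmax(np.abs(m1.loadings), axis=1)
        assert np.all(m1.loadings[np.arange(len(idx)), idx] > 0)

    def test_agrees_with_sklearn(self):
        """Independent cross-check against scikit-learn's PCA."""
        from sklearn.decomposition import PCA as SkPCA
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 15))
        model = P.fit_pca(X)
        ref = SkPCA().fit(X)
        np.testing.assert_allclose(model.explained_var / 100.0,
                                   ref.explained_variance_ratio_, atol=1e-9)


class TestRetention:
    def test_published_table_retains_17(self):
        assert P.retain_components(TABLE_EXPLAINED, threshold_pct=90.0) == 17

    @pytest.mark.parametrize("ev,expect", [((50, 30, 20), 3), ((95, 5), 1),
                                           ((45, 45), 2)])
    def test_simple_cases(self, ev, expect):
        assert P.retain_components(ev, threshold_pct=90.0) == expect

    def test_threshold_unreachable_keeps_all(self):
        assert P.retain_components([10.0, 5.0], threshold_pct=90.0) == 2

    def test_monotone_in_threshold(self):
        ks = [P.retain_components(TABLE_EXPLAINED, threshold_pct=t)
              for t in (30, 50, 70, 90)]
        assert ks == sorted(ks)
        assert ks[0] < ks[-1]


class TestMcr:
    def _model(self, n=100, p=20, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p)) * np.linspace(5, 0.5, p)
        return P.fit_pca(X)

    def test_zero_scores_give_mean(self):
        model = self._model()
        rec = P.mcr_reconstruct(model, (), ())
        np.testing.assert_array_equal(rec.x_elite, model.mean)
        np.testing.assert_array_equal(rec.x_beginner, model.mean)

    def test_single_pc_percentile_arithmetic(self):
        model = self._model()
        rec = P.mcr_reconstruct(model, (0,), (+1,))
        z95 = np.percentile(model.scores[:, 0], 95)
        z5 = np.percentile(model.scores[:, 0], 5)
        np.testing.assert_allclose(rec.x_elite - model.mean, z95 * model.loadings[0],
                                   atol=1e-12)
        np.testing.assert_allclose(rec.x_beginner - model.mean, z5 * model.loadings[0],
                                   atol=1e-12)

    def test_negative_direction_swaps_tails(self):
        model = self._model()
        pos = P.mcr_reconstruct(model, (1,), (+1,))
        neg = P.mcr_reconstruct(model, (1,), (-1,))
        np.testing.assert_array_equal(pos.x_elite, neg.x_beginner)
        np.testing.assert_array_equal(pos.x_beginner, neg.x_elite)

    def test_linearity_reflection(self):
        """Scores z and -z reconstruct to reflections about the mean."""
        model = self._model()
        u = model.loadings[:2]
        z = np.array([3.0, -1.5])
        plus = model.mean + z @ u
        minus = model.mean + (-z) @ u
        np.testing.assert_allclose(plus - model.mean, -(minus - model.mean),
                                   atol=1e-12)

    def test_selection_outside_retained_rejected(self):
        model = self._model()
        with pytest.raises(ValueError, match="retained"):
            P.mcr_reconstruct(model, (model.retained_k,), (+1,))


class TestRowLayoutAndExport:
    def test_row_roundtrip(self, meta):
        from skimech.preprocess import Cycle
        rng = np.random.default_rng(0)
        cyc = Cycle(time_norm=np.linspace(0, 1, 101), duration_s=1.3,
                    coords=rng.normal(size=(101, 76, 3)),
                    power=np.abs(rng.normal(size=(101, 5))), meta=meta)
        row = P.row_from_cycle(cyc)
        assert row.shape == (P.N_FEATURES,)
        back = P.unpack_row(row)
        np.testing.assert_allclose(back["coords"], cyc.coords, atol=1e-12)
        np.testing.assert_allclose(back["time"], cyc.time_norm * cyc.duration_s,
                                   atol=1e-12)
        p = cyc.power / meta.body_mass_kg
        np.testing.assert_allclose(back["power"][:, 0], p[:, 0] + p[:, 1], atol=1e-12)
        np.testing.assert_allclose(back["power"][:, 2], p[:, 4], atol=1e-12)

    def test_export_animation_roundtrip(self, model, meta, tmp_path):
        rng = np.random.default_rng(1)
        x = rng.normal(size=P.N_FEATURES)
        rec = P.Reconstruction(x_beginner=x, x_elite=x.copy(), pcs=(), directions=())
        path = tmp_path / "avatar.csv"
        P.export_animation(rec, model, path, which="elite")
        coords = P.read_animation(path, model)
        np.testing.assert_allclose(coords, rec.unscaled("elite")["coords"], atol=1e-9)
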