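"""BRISQUE stack: MSCN normalization, GGD/AGGD fits, features, scorer."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from histosr import brisque, synthetic
from histosr.brisque import (
    DegenerateImageError,
    brisque_features,
    brisque_score,
    fit_aggd,
    fit_ggd,
    mscn_coefficients,
    train_brisque_model,
)


@pytest.fixture(scope="module")
def scene():
    return synthetic.generate_scene(
        synthetic.SceneConfig(width=96, height=96, n_nuclei=12,
                              nucleus_axes_range=(3.0, 6.0), seed=21))


class TestMSCN:
    def test_constant_image_exactly_zero(self):
        assert np.all(mscn_coefficients(np.full((16, 16), 50.0)) == 0.0)

    def test_white_noise_coefficients_near_zero_mean(self):
        rng = np.random.default_rng(0)
        img = rng.normal(128, 1.0, (256, 256))
        assert abs(mscn_coefficients(img).mean()) < 0.02

    def test_matches_per_pixel_loop_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (16, 16))
        got = mscn_coefficients(img)
        # direct windowed evaluation with the same definition (global offset
        # removed, 7x7 Gaussian sigma 7/6, reflect border, C = 1)
        work = img - img.min()
        r = np.arange(7) - 3.0
        g = np.exp(-(r**2) / (2 * (7.0 / 6.0) ** 2))
        k = np.outer(g, g) / np.outer(g, g).sum()
        padded = np.pad(work, 3, mode="symmetric")  # edge-inclusive reflection
        for i in range(16):
            for j in range(16):
                win = padded[i : i + 7, j : j + 7]
                mu = (k * win).sum()
                var = (k * win * win).sum() - mu * mu
                sigma = np.sqrt(max(var, 0.0))
                assert got[i, j] == pytest.approx(
                    (work[i, j] - mu) / (sigma + 1.0), abs=1e-9)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            mscn_coefficients(np.zeros((5, 5)))


class TestDistributionFits:
    def test_ggd_shape_recovery(self):
        rng = np.random.default_rng(2)
        a1, _ = fit_ggd(rng.laplace(0, 1, 100_000))       # alpha = 1
        a2, _ = fit_ggd(rng.normal(0, 1, 100_000))        # alpha = 2
        assert 0.9 <= a1 <= 1.1
        assert 1.9 <= a2 <= 2.1

    def test_ggd_second_moment(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2.0, 100_000)
        _, s2 = fit_ggd(x)
        assert s2 == pytest.approx(np.mean(x**2), abs=1e-12)

    def test_aggd_symmetric_samples(self):
        rng = np.random.default_rng(4)
        nu, sl2, sr2, eta = fit_aggd(rng.normal(0, 1, 100_000))
        assert abs(np.sqrt(sl2) - np.sqrt(sr2)) / np.sqrt(sr2) < 0.05
        assert abs(eta) < 0.01

    def test_aggd_asymmetric_recovery(self):
        # sample a genuine AGGD(nu=2, sigma_l=1, sigma_r=2): side chosen with
        # probability proportional to its scale, magnitude from a one-sided
        # generalized Gaussian of that scale
        from scipy.special import gamma as G
        from scipy.stats import gennorm

        nu0, s_l, s_r = 2.0, 1.0, 2.0
        rng = np.random.default_rng(5)
        n = 100_000
        mag = np.abs(gennorm.rvs(nu0, size=n, random_state=rng))
        beta = np.sqrt(G(1 / nu0) / G(3 / nu0))
        right_side = rng.uniform(size=n) < s_r / (s_l + s_r)
        x = np.where(right_side, mag * s_r * beta, -mag * s_l * beta)
        nu, sl2, sr2, eta = fit_aggd(x)
        assert np.sqrt(sl2) == pytest.approx(s_l, rel=0.1)
        assert np.sqrt(sr2) == pytest.approx(s_r, rel=0.1)
        assert nu == pytest.approx(nu0, rel=0.1)
        assert eta > 0

    def test_degenerate_samples_rejected(self):
        with pytest.raises(DegenerateImageError):
            fit_ggd(np.full(500, 1.25))
        with pytest.raises(DegenerateImageError):
            fit_aggd(np.zeros(500))


class TestFeatures:
    def test_vector_length_36(self, scene):
        f = brisque_features(scene)
        assert f.values.shape == (36,) and not f.degenerate
        assert np.all(np.isfinite(f.values))

    def test_constant_image_flagged_fallback(self):
        f = brisque_features(np.full((64, 64, 3), 200, np.uint8))
        assert f.degenerate and f.values.shape == (36,)

    def test_distortion_shifts_mscn_shape_parameter(self, scene):
        noisy = synthetic.degrade(scene, synthetic.DistortionSpec(
            "additive_gaussian_noise", 5), seed=0)
        a_clean = brisque_features(scene).values[0]
        a_noisy = brisque_features(noisy).values[0]
        assert abs(a_noisy - a_clean) / a_clean > 0.10

    def test_invariant_to_constant_intensity_shift(self, scene):
        shifted = np.clip(scene.astype(int) + 20, 0, 255).astype(np.uint8)
        f0 = brisque_features(scene).values
        f1 = brisque_features(shifted).values
        # MSCN removes the local mean; saturation keeps this approximate
        assert np.allclose(f0, f1, rtol=0.15, atol=0.05)


class TestScorer:
    def test_training_deterministic(self, brisque_model):
        held = brisque_model["held_out"]
        feats = np.asarray([f for grp in held for f, _ in grp])
        sevs = np.asarray([s for grp in held for _, s in grp])
        m1 = train_brisque_model(feats, sevs, seed=3)
        m2 = train_brisque_model(feats, sevs, seed=3)
        assert np.array_equal(m1.dual_coef, m2.dual_coef)
        assert np.array_equal(m1.X, m2.X)

    def test_single_severity_level_rejected(self):
        feats = np.random.default_rng(6).normal(size=(10, 36))
        with pytest.raises(ValueError, match="severity"):
            train_brisque_model(feats, np.full(10, 3), seed=0)

    def test_held_out_severity_rank_correlation(self, brisque_model):
        model = brisque_model["model"]
        scores, sevs = [], []
        for group in brisque_model["held_out"]:
            for f, s in group:
                scores.append(model.predict(f))
                sevs.append(s)
        rho = spearmanr(scores, sevs).statistic
        assert rho >= 0.8

    def test_score_range_and_determinism(self, scene, brisque_model):
        model = brisque_model["model"]
        s1 = brisque_score(scene, model)
        s2 = brisque_score(scene, model)
        assert s1 == s2 and 0.0 <= s1 <= 100.0

    def test_pristine_beats_heavy_blur(self, scene, brisque_model):
        model = brisque_model["model"]
        blurred = synthetic.degrade(scene, synthetic.DistortionSpec("gaussian_blur", 5))
        assert brisque_score(scene, model) < brisque_score(blurred, model)

    def test_degenerate_image_warns(self, brisque_model):
        with pytest.warns(UserWarning, match="degenerate"):
            brisque_score(np.full((64, 64, 3), 99, np.uint8), brisque_model["model"])

    def test_model_json_round_trip(self, brisque_model, tmp_path):
        model = brisque_model["model"]
        path = tmp_path / "brisque.json"
        model.save(str(path))
        loaded = brisque.BrisqueModel.load(str(path))
        feats = brisque_model["held_out"][0][0][0]
        assert loaded.predict(feats) == pytest.approx(model.predict(feats), abs=1e-12)
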