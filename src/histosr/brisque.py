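"""BRISQUE: no-reference quality from natural-scene statistics.

The feature extractor follows the published recipe: mean-subtracted
contrast-normalized (MSCN) coefficients (I - mu)/(sigma + C) with a 7x7
Gaussian window (sigma = 7/6, C = 1), a generalized Gaussian fit to the MSCN
histogram and asymmetric generalized Gaussian fits to the four orientations
of pairwise MSCN products, at two scales (the second a factor-2 box
downsample) - 18 features per scale, 36 in total.

The mapping from features to a 0-100 score (lower = better) is a scene
statistic regressor that must be trained on distorted/pristine image pairs.
The scorer shipped here is an RBF kernel-ridge regressor calibrated on the
synthetic-fixture distortion set; absolute scores are therefore only
comparable within one trained model, and only score *orderings* are treated
as reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    "MscnResult",
    "BrisqueFeatures",
    "BrisqueModel",
    "mscn_coefficients",
    "fit_ggd",
    "fit_aggd",
    "brisque_features",
    "train_brisque_model",
    "brisque_score",
    "DegenerateImageError",
]

N_FEATURES = 36


class DegenerateImageError(ValueError):
    """Raised by the distribution fits on constant / all-equal samples."""


# ---------------------------------------------------------------------------
# MSCN coefficients
# ---------------------------------------------------------------------------

def _gaussian_kernel2d(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def mscn_coefficients(gray: np.ndarray, params=None) -> np.ndarray:
    """(I - mu) / (sigma + C) with Gaussian-weighted local moments.

    ``mu`` and ``sigma`` are the local Gaussian-weighted mean and standard
    deviation (7x7 window, sigma 7/6 by default); boundaries are handled by
    edge-inclusive (symmetric) reflection.  A constant image yields exactly zero everywhere (the
    numerator vanishes while the denominator is C).
    """
    from .metrics import MetricParams  # local import to avoid cycle

    p = params or MetricParams()
    img = np.asarray(gray, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("mscn_coefficients expects a single-channel image")
    if min(img.shape) < p.mscn_window:
        raise ValueError("image smaller than the MSCN window")
    # (I - mu)/(sigma + C) is invariant to a global intensity shift; removing
    # the image minimum first makes the coefficients of a constant image
    # exactly zero instead of rounding noise.
    img = img - img.min()
    kern = _gaussian_kernel2d(p.mscn_window, p.mscn_sigma)
    mu = ndimage.correlate(img, kern, mode="reflect")
    var = ndimage.correlate(img * img, kern, mode="reflect") - mu * mu
    sigma = np.sqrt(np.maximum(var, 0.0))
    return (img - mu) / (sigma + p.mscn_c)


@dataclass
class MscnResult:
    coefficients: np.ndarray
    degenerate: bool


# ---------------------------------------------------------------------------
# generalized Gaussian fits (moment matching)
# ---------------------------------------------------------------------------

def _log_gamma_ratio(alpha: float) -> float:
    """log of r(alpha) = Gamma(1/a) Gamma(3/a) / Gamma(2/a)^2 (decreasing)."""
    return gammaln(1.0 / alpha) + gammaln(3.0 / alpha) - 2.0 * gammaln(2.0 / alpha)


_ALPHA_LO, _ALPHA_HI = 0.05, 30.0


def _solve_shape(log_rho: float) -> float:
    """Invert r(alpha) = rho by bisection; clamps outside the bracket."""
    lo, hi = _ALPHA_LO, _ALPHA_HI
    f_lo = _log_gamma_ratio(lo) - log_rho
    f_hi = _log_gamma_ratio(hi) - log_rho
    if f_lo <= 0:   # rho larger than r(alpha_lo): extremely peaky
        return lo
    if f_hi >= 0:   # rho below r(alpha_hi): near-uniform
        return hi
    return float(brentq(lambda a: _log_gamma_ratio(a) - log_rho, lo, hi, xtol=1e-9))


def fit_ggd(samples: np.ndarray) -> tuple[float, float]:
    """Zero-mean generalized Gaussian moment fit -> (alpha, sigma2).

    ``alpha`` solves r(alpha) = E[x^2] / E[|x|]^2; ``sigma2`` is the sample
    second moment.  Raises :class:`DegenerateImageError` on all-equal input.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 2 or np.all(x == x[0]):
        raise DegenerateImageError("all-equal samples: GGD fit undefined")
    e_abs = float(np.mean(np.abs(x)))
    e_sq = float(np.mean(x * x))
    if e_abs == 0.0:
        raise DegenerateImageError("zero first absolute moment")
    alpha = _solve_shape(np.log(e_sq) - 2.0 * np.log(e_abs))
    return alpha, e_sq


def fit_aggd(samples: np.ndarray) -> tuple[float, float, float, float]:
    """Asymmetric generalized Gaussian fit -> (nu, sigma_l2, sigma_r2, eta).

    Left/right scales come from the one-sided second moments; the shape
    ``nu`` from the moment ratio of the pooled samples; ``eta`` is the mean
    offset implied by the fitted parameters.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 2 or np.all(x == x[0]):
        raise DegenerateImageError("all-equal samples: AGGD fit undefined")
    left = x[x < 0]
    right = x[x > 0]
    if left.size == 0 or right.size == 0:
        raise DegenerateImageError("one-sided samples: AGGD fit undefined")
    sigma_l = float(np.sqrt(np.mean(left**2)))
    sigma_r = float(np.sqrt(np.mean(right**2)))
    gamma_hat = sigma_l / sigma_r
    r_hat = float(np.mean(np.abs(x))) ** 2 / float(np.mean(x**2))
    R_hat = r_hat * (gamma_hat**3 + 1.0) * (gamma_hat + 1.0) / (gamma_hat**2 + 1.0) ** 2
    # R_hat estimates 1/r(nu); reuse the same inverse on -log
    nu = _solve_shape(-np.log(R_hat))
    ratio = np.exp(gammaln(2.0 / nu) - 0.5 * (gammaln(1.0 / nu) + gammaln(3.0 / nu)))
    eta = (sigma_r - sigma_l) * ratio
    return nu, sigma_l**2, sigma_r**2, eta


# ---------------------------------------------------------------------------
# 36-feature vector
# ---------------------------------------------------------------------------

@dataclass
class BrisqueFeatures:
    values: np.ndarray          # shape (36,)
    degenerate: bool = False    # constant-image fallback flag


def _scale_features(mscn: np.ndarray) -> list[float]:
    feats: list[float] = []
    alpha, sigma2 = fit_ggd(mscn)
    feats += [alpha, sigma2]
    pairs = (
        mscn[:, :-1] * mscn[:, 1:],      # horizontal
        mscn[:-1, :] * mscn[1:, :],      # vertical
        mscn[:-1, :-1] * mscn[1:, 1:],   # main diagonal
        mscn[1:, :-1] * mscn[:-1, 1:],   # secondary diagonal
    )
    for prod in pairs:
        nu, sl2, sr2, eta = fit_aggd(prod)
        feats += [nu, sl2, sr2, eta]
    return feats


def brisque_features(gray: np.ndarray, params=None) -> BrisqueFeatures:
    """18 features per scale x 2 scales; scale 2 is a factor-2 box downsample.

    A degenerate (constant) image cannot support the distribution fits; it
    returns an all-zero fallback vector with the ``degenerate`` flag set
    instead of propagating NaNs.
    """
    from .metrics import MetricParams, to_gray

    p = params or MetricParams()
    img = to_gray(np.asarray(gray))
    feats: list[float] = []
    try:
        for s in range(p.brisque_scales):
            if s > 0:
                h, w = img.shape
                img = img[: h - h % 2, : w - w % 2]
                img = img.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
            feats += _scale_features(mscn_coefficients(img, p))
    except DegenerateImageError:
        return BrisqueFeatures(values=np.zeros(N_FEATURES), degenerate=True)
    return BrisqueFeatures(values=np.asarray(feats, dtype=np.float64))


# ---------------------------------------------------------------------------
# scoring model (RBF kernel ridge, JSON-serializable)
# ---------------------------------------------------------------------------

@dataclass
class BrisqueModel:
    """Feature scaling + RBF kernel-ridge regressor -> [0, 100] score."""

    feature_min: np.ndarray     # (36,)
    feature_max: np.ndarray     # (36,)
    X: np.ndarray               # (n, 36) scaled training features
    dual_coef: np.ndarray       # (n,)
    gamma: float
    ridge: float
    score_clip: tuple[float, float] = (0.0, 100.0)
    seed: int = 0

    def scale(self, feats: np.ndarray) -> np.ndarray:
        span = self.feature_max - self.feature_min
        span = np.where(span > 0, span, 1.0)
        return 2.0 * (feats - self.feature_min) / span - 1.0

    def predict(self, feats: np.ndarray) -> float:
        z = self.scale(np.asarray(feats, dtype=np.float64))
        d2 = np.sum((self.X - z) ** 2, axis=1)
        score = float(np.exp(-self.gamma * d2) @ self.dual_coef)
        return float(np.clip(score, *self.score_clip))

    # -- plain-text serialization ------------------------------------------
    def save(self, path: str) -> None:
        blob = {
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "X": self.X.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "gamma": self.gamma,
            "ridge": self.ridge,
            "score_clip": list(self.score_clip),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path: str) -> "BrisqueModel":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(
            feature_min=np.asarray(blob["feature_min"]),
            feature_max=np.asarray(blob["feature_max"]),
            X=np.asarray(blob["X"]),
            dual_coef=np.asarray(blob["dual_coef"]),
            gamma=blob["gamma"],
            ridge=blob["ridge"],
            score_clip=tuple(blob["score_clip"]),
            seed=blob["seed"],
        )


def train_brisque_model(features: np.ndarray, severities: np.ndarray,
                        seed: int = 0, ridge: float = 1e-2) -> BrisqueModel:
    """Calibrate the scorer on (feature, severity) pairs.

    Severity 0 denotes pristine images; the maximum severity maps to score
    100.  Requires at least two distinct severity levels.  Fully
    deterministic for fixed inputs and seed.
    """
    F = np.asarray(features, dtype=np.float64)
    sev = np.asarray(severities, dtype=np.float64)
    if F.ndim != 2 or F.shape[1] != N_FEATURES:
        raise ValueError(f"features must be (n, {N_FEATURES})")
    if len(np.unique(sev)) < 2:
        raise ValueError("need at least two distinct severity levels")
    y = 100.0 * sev / sev.max()
    fmin, fmax = F.min(axis=0), F.max(axis=0)
    model = BrisqueModel(
        feature_min=fmin, feature_max=fmax, X=np.empty(0), dual_coef=np.empty(0),
        gamma=0.0, ridge=ridge, seed=seed,
    )
    Z = model.scale(F)
    gamma = 1.0 / (N_FEATURES * max(Z.var(), 1e-12))
    d2 = np.sum(Z**2, axis=1)[:, None] + np.sum(Z**2, axis=1)[None, :] - 2.0 * Z @ Z.T
    K = np.exp(-gamma * np.maximum(d2, 0.0))
    dual = np.linalg.solve(K + ridge * np.eye(len(Z)), y)
    model.X = Z
    model.dual_coef = dual
    model.gamma = gamma
    return model


def brisque_score(image: np.ndarray, model: BrisqueModel, params=None) -> float:
    """Score one image with a trained model; clipped to [0, 100], lower = better.

    A degenerate (constant) image propagates its fallback-feature flag as a
    ``UserWarning`` rather than failing.
    """
    feats = brisque_features(image, params)
    if feats.degenerate:
        import warnings

        warnings.warn("degenerate (constant) image: BRISQUE fallback features used",
                      UserWarning, stacklevel=2)
    return model.predict(feats.values)
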