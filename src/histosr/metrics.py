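"""Full-reference image quality metrics and the quality-report builder.

PSNR is computed on RGB jointly (MSE pooled over all channels); SSIM on a
Rec.601 luminance conversion with the standard 11x11 / sigma 1.5 Gaussian
window and k1=0.01, k2=0.03 constants.  Identical images return the infinite
sentinel (``math.inf``) for PSNR and exactly 1.0 for SSIM.  All constants
live in :class:`MetricParams` so deviations from the canonical definitions
are explicit and switchable.

The no-reference BRISQUE stack (MSCN coefficients, GGD/AGGD fits, the
36-feature vector and the retrainable scoring model) lives in
:mod:`histosr.brisque` and is re-exported here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .brisque import (  # noqa: F401  (module facade)
    BrisqueModel,
    brisque_features,
    brisque_score,
    fit_aggd,
    fit_ggd,
    mscn_coefficients,
    train_brisque_model,
)

__all__ = [
    "MetricParams",
    "psnr",
    "ssim",
    "to_gray",
    "ReportRow",
    "QualityReport",
    "build_report",
    "BrisqueModel",
    "mscn_coefficients",
    "fit_ggd",
    "fit_aggd",
    "brisque_features",
    "train_brisque_model",
    "brisque_score",
]

CATEGORIES = ("WSI", "nuclear_division", "nuclear_groove")
METHODS = ("GT_40x", "RHR_Bicubic_40x", "RHR_Ours_40x")


@dataclass(frozen=True)
class MetricParams:
    """All metric constants (canonical published defaults)."""

    psnr_max: float = 255.0                 # L, gray-levels
    ssim_window: int = 11
    ssim_sigma: float = 1.5
    ssim_k: tuple[float, float] = (0.01, 0.03)
    ssim_on_luminance: bool = True          # Rec.601 conversion before SSIM
    mscn_window: int = 7
    mscn_sigma: float = 7.0 / 6.0
    mscn_c: float = 1.0                     # stabilizer in (I - mu)/(sigma + C)
    brisque_scales: int = 2

    def __post_init__(self) -> None:
        if self.psnr_max <= 0:
            raise ValueError("psnr_max must be positive")
        if self.ssim_window % 2 == 0 or self.mscn_window % 2 == 0:
            raise ValueError("window sizes must be odd")
        if min(self.ssim_k) <= 0 or self.mscn_c <= 0:
            raise ValueError("stabilizing constants must be positive")

    @property
    def c1(self) -> float:
        return (self.ssim_k[0] * self.psnr_max) ** 2

    @property
    def c2(self) -> float:
        return (self.ssim_k[1] * self.psnr_max) ** 2


def to_gray(img: np.ndarray) -> np.ndarray:
    """Rec.601 luminance; pass-through for single-channel input."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"expected HxW or HxWx3 image, got shape {arr.shape}")


def psnr(ref: np.ndarray, test: np.ndarray, L: float = 255.0) -> float:
    """10 log10(L^2 / MSE) in dB; ``math.inf`` when the images are identical.

    MSE pools all channels jointly.  Symmetric and strictly decreasing in MSE.
    """
    a = np.asarray(ref, dtype=np.float64)
    b = np.asarray(test, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(L * L / mse)


def _gaussian_kernel2d(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(ref: np.ndarray, test: np.ndarray, params: MetricParams = MetricParams()) -> float:
    """Mean structural similarity over the valid Gaussian-windowed map.

    Uses population (Gaussian-weighted) variances; the local map is
    ((2 mu_x mu_y + C1)(2 sigma_xy + C2)) / ((mu_x^2 + mu_y^2 + C1)
    (sigma_x^2 + sigma_y^2 + C2)).  Exactly 1.0 for identical inputs,
    symmetric in its arguments.
    """
    a = np.asarray(ref, dtype=np.float64)
    b = np.asarray(test, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim == 3 and not params.ssim_on_luminance:
        # per-channel SSIM, averaged
        return float(np.mean([ssim(a[:, :, c], b[:, :, c], params) for c in range(a.shape[2])]))
    x, y = to_gray(a), to_gray(b)
    if min(x.shape) < params.ssim_window:
        raise ValueError("image smaller than the SSIM window")
    win = _gaussian_kernel2d(params.ssim_window, params.ssim_sigma)

    def f(img):
        return fftconvolve(img, win, mode="valid")

    mu_x, mu_y = f(x), f(y)
    sxx = f(x * x) - mu_x * mu_x
    syy = f(y * y) - mu_y * mu_y
    sxy = f(x * y) - mu_x * mu_y
    c1, c2 = params.c1, params.c2
    num = (2 * mu_x * mu_y + c1) * (2 * sxy + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (sxx + syy + c2)
    return float(np.mean(num / den))


# ---------------------------------------------------------------------------
# summary-table report (methods as columns, image categories as rows)
# ---------------------------------------------------------------------------

@dataclass
class ReportRow:
    image_id: str
    category: str      # WSI | nuclear_division | nuclear_groove
    method: str        # GT_40x | RHR_Bicubic_40x | RHR_Ours_40x
    psnr: float | None = None
    ssim: float | None = None
    brisque: float | None = None


@dataclass
class QualityReport:
    rows: list[ReportRow]
    aggregates: dict = field(default_factory=dict)  # (category, method) -> {metric: mean}

    def cell(self, category: str, method: str, metric: str):
        """Aggregate mean for one cell, or None when the cell is absent."""
        return self.aggregates.get((category, method), {}).get(metric)

    def render(self, metric: str = "brisque") -> str:
        """Tab-delimited table for one metric: methods as columns, categories
        as rows (the summary-table layout); absent cells render as '-'."""
        fmt = {"brisque": "{:.2f}", "psnr": "{:.2f}", "ssim": "{:.4f}"}[metric]
        lines = ["category\t" + "\t".join(METHODS)]
        label = {"WSI": "WSI", "nuclear_division": "Nuclear division",
                 "nuclear_groove": "Nuclear groove"}
        for cat in CATEGORIES:
            vals = []
            for meth in METHODS:
                v = self.cell(cat, meth, metric)
                vals.append("-" if v is None else fmt.format(v))
            lines.append(label[cat] + "\t" + "\t".join(vals))
        return "\n".join(lines) + "\n"


def build_report(rows) -> QualityReport:
    """Aggregate per-image rows into per-(category, method) mean cells.

    A cell with no finite values for a metric is absent, never zero;
    infinite PSNR values are excluded from the mean.
    """
    rows = list(rows)
    agg: dict = {}
    for row in rows:
        key = (row.category, row.method)
        bucket = agg.setdefault(key, {"psnr": [], "ssim": [], "brisque": []})
        for metric in ("psnr", "ssim", "brisque"):
            v = getattr(row, metric)
            if v is not None and math.isfinite(v):
                bucket[metric].append(float(v))
    aggregates = {
        key: {m: float(np.mean(vs)) for m, vs in bucket.items() if vs}
        for key, bucket in agg.items()
    }
    aggregates = {k: v for k, v in aggregates.items() if v}
    return QualityReport(rows=rows, aggregates=aggregates)
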