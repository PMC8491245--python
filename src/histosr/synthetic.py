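"""Deterministic H&E-like RGB fixture generator.

Renders the minimal motifs a pathologist looks for at high magnification on
hematoxylin/eosin stained tumor sections: a pale eosin background, dark
elliptical hematoxylin nuclei, "coffee-bean" nuclear grooves (a 1-2 px dark
line along the nuclear long axis, the hallmark of adult granulosa cell
tumors) and mitotic-figure-like multi-lobed bodies (the feature counted for
leiomyosarcoma grading), plus additive sensor noise.  Everything is a pure
function of (config, seed), so two magnifications related exactly by factor
2 can be produced by rendering one scene and box-downsampling it.

It makes no attempt at photorealistic stain physics or tissue architecture;
it exists so the super-resolution, metric and reader-study stages are
testable without slide data.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

__all__ = [
    "SceneConfig",
    "DistortionSpec",
    "DISTORTION_KINDS",
    "generate_scene",
    "degrade",
    "generate_texture_crops",
    "write_fixture_set",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic H&E scene.

    ``groove_fraction`` and ``mitotic_fraction`` are the shares of nuclei
    rendered with a nuclear groove / as a mitotic-figure-like body; the
    remainder are plain elliptical nuclei.
    """

    width: int = 256
    height: int = 256
    background_rgb: tuple[float, float, float] = (232, 220, 235)
    n_nuclei: int = 40
    nucleus_axes_range: tuple[float, float] = (4.0, 9.0)
    nucleus_rgb: tuple[float, float, float] = (88, 60, 130)
    groove_fraction: float = 0.0
    mitotic_fraction: float = 0.0
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        for frac in (self.groove_fraction, self.mitotic_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.groove_fraction + self.mitotic_fraction > 1.0 + 1e-12:
            raise ValueError("groove_fraction + mitotic_fraction must be <= 1")
        for col in (self.background_rgb, self.nucleus_rgb):
            if len(col) != 3 or not all(0 <= c <= 255 for c in col):
                raise ValueError("colors must be 3-vectors in [0, 255]")
        if self.nucleus_axes_range[0] <= 0 or (
            self.nucleus_axes_range[1] < self.nucleus_axes_range[0]
        ):
            raise ValueError("invalid nucleus_axes_range")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


DISTORTION_KINDS = ("gaussian_blur", "additive_gaussian_noise", "down_up_resample", "block_artifact")

# severity 1..5 -> parameter strength (strictly increasing within each kind)
_SEVERITY_PARAMS = {
    "gaussian_blur": {"sigma": (0.6, 1.2, 2.0, 3.2, 5.0)},
    "additive_gaussian_noise": {"sigma": (3.0, 6.0, 12.0, 22.0, 38.0)},
    "down_up_resample": {"factor": (1.25, 1.5, 2.0, 3.0, 4.0)},
    "block_artifact": {"strength": (0.2, 0.4, 0.6, 0.8, 1.0), "block": 8},
}


@dataclass(frozen=True)
class DistortionSpec:
    """A distortion kind at an ordinal severity 1..5.

    ``params`` overrides the default severity-indexed parameters; the default
    tables are strictly ordered so full-reference error is monotone in
    severity for a fixed image.
    """

    kind: str
    severity: int = 3
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in DISTORTION_KINDS:
            raise ValueError(f"unknown distortion kind {self.kind!r}")
        if not 1 <= self.severity <= 5:
            raise ValueError("severity must be an ordinal level in 1..5")

    def resolved_params(self) -> dict:
        base = {}
        for key, val in _SEVERITY_PARAMS[self.kind].items():
            base[key] = val[self.severity - 1] if isinstance(val, tuple) else val
        base.update(self.params)
        return base


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _draw_ellipse(img, cy, cx, a, b, theta, color):
    """Alpha-composite one anti-aliased filled ellipse in place."""
    h, w, _ = img.shape
    r_max = max(a, b) + 2.0
    y0, y1 = max(0, int(cy - r_max)), min(h, int(cy + r_max) + 1)
    x0, x1 = max(0, int(cx - r_max)), min(w, int(cx + r_max) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a   # along major axis
    v = (-dx * st + dy * ct) / b
    r = np.sqrt(u * u + v * v)
    # ~1 px anti-aliased edge: coverage ramps linearly through r = 1
    alpha = np.clip((1.0 - r) * min(a, b) + 0.5, 0.0, 1.0)
    patch = img[y0:y1, x0:x1, :]
    patch *= (1.0 - alpha)[:, :, None]
    patch += alpha[:, :, None] * np.asarray(color, dtype=np.float64)


def _draw_groove(img, cy, cx, a, b, theta, color):
    """Dark 1-2 px line along the major axis ('coffee-bean' groove)."""
    h, w, _ = img.shape
    r_max = a + 2.0
    y0, y1 = max(0, int(cy - r_max)), min(h, int(cy + r_max) + 1)
    x0, x1 = max(0, int(cx - r_max)), min(w, int(cx + r_max) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    half_w = 0.8  # => ~1.6 px wide line
    alpha = np.clip(half_w - np.abs(v) + 0.5, 0.0, 1.0)
    alpha *= np.clip(0.8 * a - np.abs(u) + 0.5, 0.0, 1.0)
    patch = img[y0:y1, x0:x1, :]
    patch *= (1.0 - alpha)[:, :, None]
    patch += alpha[:, :, None] * np.asarray(color, dtype=np.float64)


def _render(config: SceneConfig):
    """Render scene; returns (float image, list of (cy, cx, kind) records).

    All randomness is drawn from one seeded stream in a fixed order: for each
    nucleus center -> axes -> angle -> color jitter -> kind-specific shape
    draws; the additive noise field is drawn last.
    """
    rng = np.random.default_rng(config.seed)
    img = np.empty((config.height, config.width, 3), dtype=np.float64)
    img[:] = np.asarray(config.background_rgb, dtype=np.float64)

    n = config.n_nuclei
    n_groove = int(round(config.groove_fraction * n))
    n_mitotic = int(round(config.mitotic_fraction * n))
    n_mitotic = min(n_mitotic, n - n_groove)
    kinds = ["groove"] * n_groove + ["mitotic"] * n_mitotic
    kinds += ["plain"] * (n - len(kinds))
    kinds = [kinds[i] for i in rng.permutation(n)] if n else []

    a_lo, a_hi = config.nucleus_axes_range
    margin = a_hi * 2.0 + 2.0
    if n and (config.width <= 2 * margin or config.height <= 2 * margin):
        raise ValueError("scene too small for the requested nucleus size")
    records = []
    base_col = np.asarray(config.nucleus_rgb, dtype=np.float64)
    for kind in kinds:
        cy = rng.uniform(margin, config.height - margin)
        cx = rng.uniform(margin, config.width - margin)
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(a_lo, a_hi)
        a, b = max(a, b), min(a, b)  # a = major semi-axis
        theta = rng.uniform(0, np.pi)
        color = np.clip(base_col + rng.uniform(-10, 10, size=3), 0, 255)
        if kind == "mitotic":
            # 2-4 overlapping dark lobes around the center
            n_lobes = int(rng.integers(2, 5))
            lobe_col = np.clip(color * 0.55, 0, 255)
            for _ in range(n_lobes):
                oy, ox = rng.uniform(-0.5 * a, 0.5 * a, size=2)
                la = rng.uniform(0.35 * a, 0.7 * a)
                lb = rng.uniform(0.3 * a, 0.6 * a)
                lth = rng.uniform(0, np.pi)
                _draw_ellipse(img, cy + oy, cx + ox, max(la, 1.2), max(lb, 1.2), lth, lobe_col)
        else:
            _draw_ellipse(img, cy, cx, a, b, theta, color)
            if kind == "groove":
                _draw_groove(img, cy, cx, a, b, theta, np.clip(color * 0.45, 0, 255))
        records.append((cy, cx, kind))

    if config.noise_sigma > 0:
        img += rng.normal(0.0, config.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255), records


def generate_scene(config: SceneConfig) -> np.ndarray:
    """Render one scene as an 8-bit RGB array (height x width x 3)."""
    img, _ = _render(config)
    return np.rint(img).astype(np.uint8)


# ---------------------------------------------------------------------------
# degradations (BRISQUE calibration set)
# ---------------------------------------------------------------------------

def degrade(image: np.ndarray, spec: DistortionSpec, seed: int = 0) -> np.ndarray:
    """Apply one distortion; same shape, 8-bit RGB out, seeded where random."""
    img = np.asarray(image)
    if img.dtype != np.uint8 or img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an 8-bit HxWx3 RGB image")
    p = spec.resolved_params()
    x = img.astype(np.float64)
    if spec.kind == "gaussian_blur":
        out = ndimage.gaussian_filter(x, sigma=(p["sigma"], p["sigma"], 0), mode="reflect")
    elif spec.kind == "additive_gaussian_noise":
        rng = np.random.default_rng(seed)
        out = x + rng.normal(0.0, p["sigma"], size=x.shape)
    elif spec.kind == "down_up_resample":
        from skimage.transform import resize

        f = p["factor"]
        h, w = img.shape[:2]
        small = (max(1, int(round(h / f))), max(1, int(round(w / f))))
        down = resize(x, small + (3,), order=1, anti_aliasing=True, preserve_range=True)
        out = resize(down, (h, w, 3), order=1, anti_aliasing=False, preserve_range=True)
    elif spec.kind == "block_artifact":
        out = _blockiness(x, int(p["block"]), float(p["strength"]))
    else:  # pragma: no cover - DistortionSpec already validates
        raise ValueError(f"unknown distortion kind {spec.kind!r}")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _blockiness(x: np.ndarray, block: int, strength: float) -> np.ndarray:
    """Blend each b x b block toward its mean; strength in [0, 1]."""
    h, w, _ = x.shape
    hb, wb = -(-h // block) * block, -(-w // block) * block
    xp = np.pad(x, ((0, hb - h), (0, wb - w), (0, 0)), mode="edge")
    blocks = xp.reshape(hb // block, block, wb // block, block, 3)
    means = blocks.mean(axis=(1, 3), keepdims=True)
    blended = blocks * (1 - strength) + means * strength
    return blended.reshape(hb, wb, 3)[:h, :w, :]


# ---------------------------------------------------------------------------
# texture crops (nuclear division / nuclear groove test material)
# ---------------------------------------------------------------------------

def generate_texture_crops(config: SceneConfig, kind: str, n: int,
                           crop_size: int = 32, seed: int = 0) -> list[np.ndarray]:
    """``n`` crops of ``crop_size`` square, each centered on a structure.

    ``kind`` selects the motif: ``nuclear_division`` (mitotic-figure bodies)
    or ``nuclear_groove`` (grooved nuclei).  Scenes are re-rendered with
    derived seeds until enough structures have been collected.
    """
    if kind not in ("nuclear_division", "nuclear_groove"):
        raise ValueError(f"unknown texture kind {kind!r}")
    if n <= 0:
        raise ValueError("n must be positive")
    if crop_size > min(config.width, config.height):
        raise ValueError("crop_size exceeds scene dimensions")
    want = "mitotic" if kind == "nuclear_division" else "groove"
    fracs = {"groove_fraction": 0.0, "mitotic_fraction": 0.0}
    fracs["mitotic_fraction" if want == "mitotic" else "groove_fraction"] = 1.0
    crops: list[np.ndarray] = []
    ss = np.random.SeedSequence(seed)
    half = crop_size // 2
    while len(crops) < n:
        scene_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        cfg = SceneConfig(**{**asdict(config), **fracs, "seed": scene_seed})
        img, records = _render(cfg)
        img8 = np.rint(img).astype(np.uint8)
        for cy, cx, k in records:
            if k != want or len(crops) >= n:
                continue
            y0 = int(np.clip(round(cy) - half, 0, cfg.height - crop_size))
            x0 = int(np.clip(round(cx) - half, 0, cfg.width - crop_size))
            crops.append(img8[y0 : y0 + crop_size, x0 : x0 + crop_size].copy())
    return crops


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

def write_fixture_set(configs: list[SceneConfig], out_dir: str) -> str:
    """Write scenes as PNGs plus a tab-delimited manifest; returns manifest path."""
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("path\tkind\tseed\tconfig_hash\n")
        for i, cfg in enumerate(configs):
            name = f"scene_{i:04d}.png"
            iio.imwrite(os.path.join(out_dir, name), generate_scene(cfg))
            fh.write(f"{name}\tscene\t{cfg.seed}\t{cfg.digest()}\n")
    return manifest
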