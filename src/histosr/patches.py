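"""Tiled-slide I/O and LR/HR training-pair construction.

Slides are stored in an open tiled layout: a directory holding a small JSON
header (``slide.json``) plus lossless PNG tiles named ``r{row}_c{col}.png``.
All coordinates are 0-based (row, col) with a top-left origin and half-open
extents, recorded at the HR (x40) scale; LR origins are exactly HR/2.

Pairs come in two flavors mirroring the two evaluation regimes:
``bilinear_as_lr`` (the LR arm is the factor-2 bilinear downsample of the HR
patch; under the half-pixel-center convention this is exactly the 2x2 box
average) and ``self_as_lr`` (the LR arm is cut from a co-registered x20
slide).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio

__all__ = [
    "TiledSlide",
    "PatchPair",
    "DatasetSplit",
    "extract_hr_patches",
    "bilinear_downsample",
    "compute_mean_rgb",
    "make_pairs",
    "split_by_slide",
    "write_pair_manifest",
]


class TiledSlide:
    """A single-level tiled RGB slide backed by a directory of PNG tiles."""

    HEADER = "slide.json"

    def __init__(self, path: str):
        self.path = path
        with open(os.path.join(path, self.HEADER)) as fh:
            hdr = json.load(fh)
        self.slide_id: str = hdr["slide_id"]
        self.magnification: str = hdr["magnification"]
        self.tile_size: int = hdr["tile_size"]
        self.width: int = hdr["width"]
        self.height: int = hdr["height"]
        self.rows: int = -(-self.height // self.tile_size)
        self.cols: int = -(-self.width // self.tile_size)

    # -- creation -----------------------------------------------------------
    @classmethod
    def create(cls, path: str, image: np.ndarray, tile_size: int = 512,
               slide_id: str = "slide", magnification: str = "x40") -> "TiledSlide":
        """Tile a full image into the open layout (lossless round-trip)."""
        img = np.asarray(image)
        if img.dtype != np.uint8 or img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("expected an 8-bit HxWx3 RGB image")
        if magnification not in ("x20", "x40"):
            raise ValueError("magnification must be 'x20' or 'x40'")
        os.makedirs(path, exist_ok=True)
        h, w = img.shape[:2]
        hdr = {"slide_id": slide_id, "magnification": magnification,
               "tile_size": tile_size, "width": w, "height": h}
        with open(os.path.join(path, cls.HEADER), "w") as fh:
            json.dump(hdr, fh, indent=1)
        for r0 in range(0, h, tile_size):
            for c0 in range(0, w, tile_size):
                tile = img[r0 : r0 + tile_size, c0 : c0 + tile_size]
                iio.imwrite(
                    os.path.join(path, f"r{r0 // tile_size}_c{c0 // tile_size}.png"), tile
                )
        return cls(path)

    @classmethod
    def empty(cls, path: str, height: int, width: int, tile_size: int,
              slide_id: str, magnification: str) -> "TiledSlide":
        """Header-only slide; tiles are appended with :meth:`write_tile`."""
        os.makedirs(path, exist_ok=True)
        hdr = {"slide_id": slide_id, "magnification": magnification,
               "tile_size": tile_size, "width": width, "height": height}
        with open(os.path.join(path, cls.HEADER), "w") as fh:
            json.dump(hdr, fh, indent=1)
        return cls(path)

    # -- access -------------------------------------------------------------
    def tile(self, row: int, col: int) -> np.ndarray:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"tile ({row}, {col}) outside {self.rows}x{self.cols} grid")
        return iio.imread(os.path.join(self.path, f"r{row}_c{col}.png"))

    def write_tile(self, row: int, col: int, tile: np.ndarray) -> None:
        iio.imwrite(os.path.join(self.path, f"r{row}_c{col}.png"), tile)

    def region(self, y: int, x: int, h: int, w: int) -> np.ndarray:
        """Assemble an arbitrary rectangle from the tiles it straddles."""
        if y < 0 or x < 0 or y + h > self.height or x + w > self.width:
            raise ValueError("region outside slide bounds")
        out = np.empty((h, w, 3), dtype=np.uint8)
        t = self.tile_size
        for r in range(y // t, (y + h - 1) // t + 1):
            for c in range(x // t, (x + w - 1) // t + 1):
                tile = self.tile(r, c)
                ty0, tx0 = r * t, c * t
                sy0, sy1 = max(y, ty0), min(y + h, ty0 + tile.shape[0])
                sx0, sx1 = max(x, tx0), min(x + w, tx0 + tile.shape[1])
                out[sy0 - y : sy1 - y, sx0 - x : sx1 - x] = tile[
                    sy0 - ty0 : sy1 - ty0, sx0 - tx0 : sx1 - tx0
                ]
        return out

    def to_array(self) -> np.ndarray:
        return self.region(0, 0, self.height, self.width)


# ---------------------------------------------------------------------------
# pairs and splits
# ---------------------------------------------------------------------------

@dataclass
class PatchPair:
    """One LR/HR pair; ``hr_origin`` is the HR-scale (row, col) top-left."""

    lr: np.ndarray
    hr: np.ndarray
    slide_id: str = ""
    hr_origin: tuple[int, int] = (0, 0)
    mode: str = "bilinear_as_lr"

    def __post_init__(self) -> None:
        if self.mode not in ("bilinear_as_lr", "self_as_lr"):
            raise ValueError(f"unknown pairing mode {self.mode!r}")
        if (self.hr.shape[0], self.hr.shape[1]) != (2 * self.lr.shape[0], 2 * self.lr.shape[1]):
            raise ValueError(
                f"hr dims {self.hr.shape[:2]} must be exactly 2x lr dims {self.lr.shape[:2]}"
            )

    def check(self) -> None:
        """Assert the pairing invariant (bilinear arm reproducible from hr)."""
        if self.mode == "bilinear_as_lr":
            ref = bilinear_downsample(self.hr)
            if not np.allclose(np.asarray(self.lr, dtype=np.float64), ref, atol=1e-9):
                raise AssertionError("lr arm does not equal bilinear_downsample(hr)")


@dataclass
class DatasetSplit:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split partitions overlap (slide leakage)")


def _as_region_reader(slide):
    """Accept a TiledSlide or a plain HxWx3 array."""
    if isinstance(slide, TiledSlide):
        return slide.region, slide.height, slide.width, slide.slide_id
    arr = np.asarray(slide)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected a TiledSlide or an HxWx3 array")

    def region(y, x, h, w):
        return arr[y : y + h, x : x + w]

    return region, arr.shape[0], arr.shape[1], ""


def extract_hr_patches(slide, n: int, size: int = 512, seed: int = 0):
    """``n`` random ``size`` x ``size`` patches with origins uniform over the
    valid top-left positions (duplicates allowed); deterministic per seed.

    Returns a list of ``(patch, (row, col))`` tuples.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    region, h, w, _sid = _as_region_reader(slide)
    if h < size or w < size:
        raise ValueError(f"slide smaller than patch: slide {h}x{w}, patch {size}")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h - size + 1, size=n)
    cols = rng.integers(0, w - size + 1, size=n)
    return [(np.asarray(region(int(r), int(c), size, size)), (int(r), int(c)))
            for r, c in zip(rows, cols)]


def bilinear_downsample(hr: np.ndarray, factor: int = 2) -> np.ndarray:
    """Factor-``factor`` bilinear downsample with half-pixel centers.

    At integer factors with aligned half-pixel centers this is exactly the
    ``factor`` x ``factor`` block (box) average, which is the testable anchor
    for all pair construction.  Returns float64.
    """
    img = np.asarray(hr, dtype=np.float64)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[:, :, None]
    h, w, c = img.shape
    if h % factor or w % factor:
        raise ValueError(f"dims {h}x{w} not divisible by factor {factor}")
    out = img.reshape(h // factor, factor, w // factor, factor, c).mean(axis=(1, 3))
    return out[:, :, 0] if squeeze else out


def compute_mean_rgb(patches) -> np.ndarray:
    """Per-channel arithmetic mean over all pixels of all patches."""
    patches = list(patches)
    if not patches:
        raise ValueError("empty patch list")
    sums = np.zeros(3, dtype=np.float64)
    count = 0
    for p in patches:
        arr = np.asarray(p, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("patches must be HxWx3")
        sums += arr.sum(axis=(0, 1))
        count += arr.shape[0] * arr.shape[1]
    return sums / count


def make_pairs(hr_patches, mode: str = "bilinear_as_lr", lr_source=None,
               slide_id: str = "") -> list[PatchPair]:
    """Build :class:`PatchPair` objects from ``(patch, origin)`` tuples.

    ``self_as_lr`` requires ``lr_source``: ``(patch, origin)`` tuples at the
    LR scale whose origins are exactly HR origin / 2.
    """
    if mode == "bilinear_as_lr":
        return [
            PatchPair(lr=bilinear_downsample(hr), hr=np.asarray(hr),
                      slide_id=slide_id, hr_origin=tuple(origin), mode=mode)
            for hr, origin in hr_patches
        ]
    if mode == "self_as_lr":
        if lr_source is None:
            raise ValueError("self_as_lr mode requires lr_source patches")
        index = {tuple(origin): np.asarray(p) for p, origin in lr_source}
        pairs = []
        for hr, origin in hr_patches:
            key = (origin[0] // 2, origin[1] // 2)
            if origin[0] % 2 or origin[1] % 2:
                raise ValueError(f"self_as_lr HR origin {tuple(origin)} is not even")
            if key not in index:
                raise ValueError(f"missing co-located LR patch at LR origin {key}")
            pairs.append(PatchPair(lr=index[key], hr=np.asarray(hr),
                                   slide_id=slide_id, hr_origin=tuple(origin), mode=mode))
        return pairs
    raise ValueError(f"unknown pairing mode {mode!r}")


def split_by_slide(ids, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> DatasetSplit:
    """Slide-level train/val/test split; sizes are largest-remainder rounds."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate slide ids")
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ValueError("fractions must be 3 non-negative values summing to 1")
    n = len(ids)
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    # distribute the remainder by largest fractional part (ties: earlier bin)
    order = sorted(range(3), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in range(n - sum(sizes)):
        sizes[order[i % 3]] += 1
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    train = perm[: sizes[0]]
    val = perm[sizes[0] : sizes[0] + sizes[1]]
    test = perm[sizes[0] + sizes[1] :]
    return DatasetSplit(train_ids=train, val_ids=val, test_ids=test, seed=seed)


def write_pair_manifest(pairs: list[PatchPair], path: str) -> None:
    """Tab-delimited manifest: slide_id, hr_origin, mode (one row per pair)."""
    with open(path, "w") as fh:
        fh.write("slide_id\thr_row\thr_col\tmode\n")
        for p in pairs:
            fh.write(f"{p.slide_id}\t{p.hr_origin[0]}\t{p.hr_origin[1]}\t{p.mode}\n")
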