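"""Tile-by-tile super-resolution of a x20 slide into a seamless x40 slide.

The slide is covered by overlapping LR tiles (default 256 px with 32 px
overlap; edge tiles shift inward rather than pad, so the network always sees
valid tissue statistics).  Each tile is super-resolved independently and the
overlapping SR tiles are combined with triangular (linear feathering)
weights normalized to sum to one at every output pixel, which removes
blocked-boundary artifacts at tile seams.

Reconstruction streams: tiles are processed row-band by row-band and output
rows are flushed to the destination tile store as soon as no later tile can
contribute to them, so peak resident memory is a few tile-heights of output
rows, never the whole slide.  An optional accounting hook receives the
resident pixel count so the contract can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import edsr
from .patches import TiledSlide, bilinear_downsample, make_pairs, _as_region_reader

__all__ = ["TilePlan", "plan_tiles", "reconstruct", "reconstruct_array", "infer_pair_modes"]


@dataclass
class TilePlan:
    tile: int
    overlap: int
    positions: list[tuple[int, int]]   # (row, col) LR origins, row-major
    covered: tuple[int, int]           # (H, W)


def _starts(dim: int, tile: int, overlap: int) -> list[int]:
    if dim <= tile:
        return [0]
    step = tile - overlap
    s = list(range(0, dim - tile + 1, step))
    if s[-1] != dim - tile:
        s.append(dim - tile)   # shift the last tile inward, never pad
    return s


def plan_tiles(H: int, W: int, tile: int = 256, overlap: int = 32) -> TilePlan:
    """Full-coverage overlapping tile plan; all tiles full-size when dims >= tile."""
    if H < 1 or W < 1:
        raise ValueError("dimensions must be >= 1")
    if overlap >= tile:
        raise ValueError(f"overlap {overlap} must be smaller than tile {tile}")
    rows = _starts(H, tile, overlap)
    cols = _starts(W, tile, overlap)
    positions = [(r, c) for r in rows for c in cols]
    return TilePlan(tile=tile, overlap=overlap, positions=positions, covered=(H, W))


def _feather_1d(length: int, ramp: int, at_start: bool, at_end: bool) -> np.ndarray:
    """Triangular weight profile; ramps only on sides that have a neighbor."""
    w = np.ones(length, dtype=np.float64)
    if ramp > 0:
        up = (np.arange(ramp) + 1.0) / (ramp + 1.0)
        if at_start:
            w[:ramp] = up
        if at_end:
            w[-ramp:] = up[::-1]
    return w


def reconstruct(slide20x, model, out_path: str | None = None, tile: int = 256,
                overlap: int = 32, sr_fn=None, out_tile_size: int | None = None,
                memory_hook=None):
    """Super-resolve a x20 slide (TiledSlide or array) to a x40 slide.

    ``sr_fn`` overrides the model with an arbitrary LR-tile -> SR-tile
    operator (used by the stitching identity tests).  Returns the output
    :class:`TiledSlide` when ``out_path`` is given, else the full uint8 array.
    """
    if sr_fn is None:
        if model.config.scale != 2:
            raise ValueError(f"model scale {model.config.scale} != 2")
        sr_fn = lambda t: edsr.forward(model, t)  # noqa: E731
    region, H, W, sid = _as_region_reader(slide20x)
    plan = plan_tiles(H, W, tile=tile, overlap=overlap)
    H2, W2 = 2 * H, 2 * W
    out_tile = out_tile_size or 2 * tile

    writer = _StripWriter(out_path, H2, W2, out_tile, sid)
    row_starts = sorted({r for r, _ in plan.positions})
    col_starts = sorted({c for _, c in plan.positions})
    th = min(tile, H)
    tw = min(tile, W)
    ramp = 2 * overlap

    acc = None      # accumulator over output rows [band_lo, band_hi)
    wacc = None
    band_lo = 0
    peak = 0
    for ri, r in enumerate(row_starts):
        y0, y1 = 2 * r, 2 * r + 2 * th
        # flush rows that no later band can touch
        if acc is not None and y0 > band_lo:
            flush_to = min(y0, H2)
            writer.feed(acc[: flush_to - band_lo] / wacc[: flush_to - band_lo])
            acc = acc[flush_to - band_lo :]
            wacc = wacc[flush_to - band_lo :]
            band_lo = flush_to
        band_hi = y1
        need = band_hi - band_lo
        if acc is None:
            acc = np.zeros((need, W2, 3), dtype=np.float64)
            wacc = np.zeros((need, W2, 1), dtype=np.float64)
        elif acc.shape[0] < need:
            pad = need - acc.shape[0]
            acc = np.concatenate([acc, np.zeros((pad, W2, 3))], axis=0)
            wacc = np.concatenate([wacc, np.zeros((pad, W2, 1))], axis=0)

        wr = _feather_1d(2 * th, ramp, at_start=ri > 0, at_end=ri < len(row_starts) - 1)
        for ci, c in enumerate(col_starts):
            lr_tile = np.asarray(region(r, c, th, tw))
            sr = np.asarray(sr_fn(lr_tile), dtype=np.float64)
            if sr.shape[:2] != (2 * th, 2 * tw):
                raise ValueError("SR operator did not produce a 2x tile")
            wc = _feather_1d(2 * tw, ramp, at_start=ci > 0, at_end=ci < len(col_starts) - 1)
            wt = wr[:, None] * wc[None, :]
            x0 = 2 * c
            acc[y0 - band_lo : y1 - band_lo, x0 : x0 + 2 * tw] += sr * wt[:, :, None]
            wacc[y0 - band_lo : y1 - band_lo, x0 : x0 + 2 * tw, 0] += wt
        resident = acc.shape[0] * W2 + writer.resident_pixels()
        peak = max(peak, resident)
        if memory_hook is not None:
            memory_hook(resident)
    writer.feed(acc / wacc)
    if memory_hook is not None:
        memory_hook(peak)
    return writer.finish()


class _StripWriter:
    """Collect finished output rows; emit tiles (or an array) incrementally."""

    def __init__(self, out_path, H, W, tile_size, slide_id):
        self.H, self.W, self.t = H, W, tile_size
        self.out_path = out_path
        if out_path is None:
            self.full = np.empty((H, W, 3), dtype=np.uint8)
            self.slide = None
        else:
            self.full = None
            self.slide = TiledSlide.empty(out_path, H, W, tile_size,
                                          slide_id or "reconstructed", "x40")
        self.row = 0                 # next output row to receive data
        self.buf: list[np.ndarray] = []
        self.buf_rows = 0

    def resident_pixels(self) -> int:
        return self.buf_rows * self.W if self.slide is not None else 0

    def feed(self, rows: np.ndarray) -> None:
        data = np.clip(np.rint(rows), 0, 255).astype(np.uint8)
        if self.full is not None:
            self.full[self.row : self.row + len(data)] = data
            self.row += len(data)
            return
        self.buf.append(data)
        self.buf_rows += len(data)
        self._drain(final=False)

    def _drain(self, final: bool) -> None:
        while self.buf_rows and (self.buf_rows >= self.t or final):
            strip = np.concatenate(self.buf, axis=0)
            take = min(self.t, len(strip))
            band, rest = strip[:take], strip[take:]
            tr = self.row // self.t
            for c0 in range(0, self.W, self.t):
                self.slide.write_tile(tr, c0 // self.t, band[:, c0 : c0 + self.t])
            self.row += take
            self.buf = [rest] if len(rest) else []
            self.buf_rows = len(rest)

    def finish(self):
        if self.full is not None:
            return self.full
        self._drain(final=True)
        return self.slide


def reconstruct_array(image: np.ndarray, model=None, **kw) -> np.ndarray:
    """Convenience wrapper: array in, uint8 array out."""
    return reconstruct(image, model, out_path=None, **kw)


def infer_pair_modes(slide40x, mode: str, slide20x=None, n: int = 16,
                     size: int = 512, seed: int = 0):
    """Emit evaluation PatchPairs in the requested regime.

    ``bilinear_as_lr`` needs only the x40 slide; ``self_as_lr`` additionally
    needs a pixel-registered x20 slide (synthetic fixtures provide exact
    registration) and samples HR origins at even coordinates so LR origins
    are integral.
    """
    from .patches import extract_hr_patches

    region40, H, W, sid = _as_region_reader(slide40x)
    if mode == "bilinear_as_lr":
        patches = extract_hr_patches(slide40x, n=n, size=size, seed=seed)
        return make_pairs(patches, mode="bilinear_as_lr", slide_id=sid)
    if mode == "self_as_lr":
        if slide20x is None:
            raise ValueError("self_as_lr mode requires a co-registered x20 slide")
        region20, h20, w20, _ = _as_region_reader(slide20x)
        if (H, W) != (2 * h20, 2 * w20):
            raise ValueError("x40 slide dims must be exactly 2x the x20 slide dims")
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, (H - size) // 2 + 1, size=n) * 2
        cols = rng.integers(0, (W - size) // 2 + 1, size=n) * 2
        hr_patches = [(region40(int(r), int(c), size, size), (int(r), int(c)))
                      for r, c in zip(rows, cols)]
        lr_patches = [(region20(r // 2, c // 2, size // 2, size // 2), (r // 2, c // 2))
                      for _, (r, c) in hr_patches]
        return make_pairs(hr_patches, mode="self_as_lr", lr_source=lr_patches, slide_id=sid)
    raise ValueError(f"unknown mode {mode!r}")
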