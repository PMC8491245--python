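"""EDSR-baseline x2 generator implemented on NumPy.

The network follows the single-scale EDSR baseline: a 3->F head convolution,
B residual blocks (conv-ReLU-conv plus identity skip, no batch normalization,
no residual scaling), a global skip connection from the head output, a
sub-pixel upsampler (conv F -> F*r^2 followed by pixel shuffling) and a
F->3 tail convolution.  The dataset mean RGB is subtracted on the way in and
added back on the way out, so the convolutional trunk operates on zero-mean
intensities in the [0, 255] range.

Every layer carries an explicit backward pass so the trainer can run plain
reverse-mode differentiation without an autodiff framework.  The trunk uses
the NHWC layout internally (convolution reduces to one im2col copy plus one
matmul, and the backward scatter keeps the channel axis contiguous); weights
are stored in the conventional (C_out, C_in, kh, kw) order.  The public API
accepts and returns HxWx3 images, and the standalone ``pixel_shuffle`` /
``residual_block`` operations use the channel-first convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "EDSRConfig",
    "ModelState",
    "init_model",
    "forward",
    "forward_core",
    "backward_core",
    "residual_block",
    "pixel_shuffle",
    "pixel_unshuffle",
    "bicubic_upscale",
    "parameter_count",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# configuration / state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EDSRConfig:
    """Architecture hyper-parameters of the baseline generator.

    ``n_feats=64`` and ``scale=2`` are the published baseline settings for the
    x20 -> x40 task; smaller values are used for desk-scale experiments.
    Residual scaling is permanently disabled (baseline topology).
    """

    n_resblocks: int = 16
    n_feats: int = 64
    scale: int = 2
    kernel: int = 3
    mean_rgb: tuple[float, float, float] = (0.0, 0.0, 0.0)
    padding: str = "reflect"  # or "zero"

    def __post_init__(self) -> None:
        if self.n_resblocks < 1 or self.n_feats < 1:
            raise ValueError("n_resblocks and n_feats must be positive")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        if self.padding not in ("reflect", "zero"):
            raise ValueError(f"unknown padding mode {self.padding!r}")
        if len(self.mean_rgb) != 3:
            raise ValueError("mean_rgb must have 3 components")


@dataclass
class ModelState:
    """Configuration + named weights + training provenance."""

    config: EDSRConfig
    params: dict[str, np.ndarray]
    train_meta: dict = field(default_factory=dict)

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            train_meta=dict(self.train_meta),
        )


def init_model(config: EDSRConfig, seed: int = 0) -> ModelState:
    """Fan-in-scaled uniform initialization, fully determined by ``seed``."""
    rng = np.random.default_rng(seed)
    k, f, r = config.kernel, config.n_feats, config.scale
    params: dict[str, np.ndarray] = {}

    def conv_init(name: str, c_out: int, c_in: int) -> None:
        bound = float(np.sqrt(1.0 / (c_in * k * k)))
        params[f"{name}.w"] = rng.uniform(
            -bound, bound, size=(c_out, c_in, k, k)
        ).astype(np.float32)
        params[f"{name}.b"] = np.zeros(c_out, dtype=np.float32)

    conv_init("head", f, 3)
    for i in range(config.n_resblocks):
        conv_init(f"block{i}.conv1", f, f)
        conv_init(f"block{i}.conv2", f, f)
    conv_init("up.conv", f * r * r, f)
    conv_init("tail", 3, f)
    return ModelState(config=config, params=params, train_meta={"step": 0})


def parameter_count(config: EDSRConfig) -> int:
    """Closed-form parameter count for the baseline topology."""
    k2 = config.kernel ** 2
    f, r = config.n_feats, config.scale
    head = f * 3 * k2 + f
    blocks = config.n_resblocks * 2 * (f * f * k2 + f)
    up = (f * r * r) * f * k2 + f * r * r
    tail = 3 * f * k2 + 3
    return head + blocks + up + tail


# ---------------------------------------------------------------------------
# primitive layers on NHWC tensors (forward + backward)
# ---------------------------------------------------------------------------

def _pad(x: np.ndarray, p: int, mode: str) -> np.ndarray:
    if p == 0:
        return x
    np_mode = "reflect" if mode == "reflect" else "constant"
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode=np_mode)


def _unpad_grad(gxp: np.ndarray, p: int, mode: str) -> np.ndarray:
    """Fold the gradient of the padded tensor back onto the interior."""
    if p == 0:
        return gxp
    h = gxp.shape[1] - 2 * p
    w = gxp.shape[2] - 2 * p
    gx = gxp[:, p : p + h, p : p + w, :].copy()
    if mode == "zero":
        return gx
    # reflect (no edge repeat): padded row i < p mirrors interior row p - i,
    # padded row 2p + h - 1 - i mirrors interior row h - 1 - (p - i)
    for i in range(p):
        gx[:, p - i, :, :] += gxp[:, i, p : p + w, :]
        gx[:, h - 1 - (p - i), :, :] += gxp[:, 2 * p + h - 1 - i, p : p + w, :]
    for j in range(p):
        gx[:, :, p - j, :] += gxp[:, p : p + h, j, :]
        gx[:, :, w - 1 - (p - j), :] += gxp[:, p : p + h, 2 * p + w - 1 - j, :]
    for i in range(p):  # corner cells mirror in both axes
        for j in range(p):
            gx[:, p - i, p - j, :] += gxp[:, i, j, :]
            gx[:, p - i, w - 1 - (p - j), :] += gxp[:, i, 2 * p + w - 1 - j, :]
            gx[:, h - 1 - (p - i), p - j, :] += gxp[:, 2 * p + h - 1 - i, j, :]
            gx[:, h - 1 - (p - i), w - 1 - (p - j), :] += gxp[
                :, 2 * p + h - 1 - i, 2 * p + w - 1 - j, :
            ]
    return gx


def _w_matrix(w: np.ndarray) -> np.ndarray:
    """(C_out, C_in, kh, kw) -> (kh*kw*C_in, C_out) matmul operand."""
    c_out, c_in, kh, kw = w.shape
    return np.ascontiguousarray(
        w.transpose(2, 3, 1, 0).reshape(kh * kw * c_in, c_out)
    )


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, padding: str):
    """Same-size 2-D convolution (cross-correlation) on NHWC tensors."""
    c_out, c_in, kh, kw = w.shape
    if x.shape[3] != c_in:
        raise ValueError(f"channel mismatch: input {x.shape[3]}, kernel {c_in}")
    p = (kh - 1) // 2
    xp = _pad(x, p, padding)
    n, hp, wp, _ = xp.shape
    h, wdt = hp - kh + 1, wp - kw + 1
    # (n, h, w, kh, kw, c) view -> one contiguous copy -> single matmul
    cols = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # n,h,w,c,kh,kw
    cols_m = cols.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * wdt, kh * kw * c_in)
    out = cols_m @ _w_matrix(w)
    out += b
    out = out.reshape(n, h, wdt, c_out)
    cache = (cols_m, w, padding, (n, h, wdt))
    return out, cache


def conv2d_backward(gy: np.ndarray, cache):
    cols_m, w, padding, (n, h, wdt) = cache
    c_out, c_in, kh, kw = w.shape
    p = (kh - 1) // 2
    gy_m = gy.reshape(n * h * wdt, c_out)
    gw_m = cols_m.T @ gy_m  # (kh*kw*c_in, c_out)
    gw = gw_m.reshape(kh, kw, c_in, c_out).transpose(3, 2, 0, 1)
    gb = gy_m.sum(axis=0)
    gcols = gy_m @ _w_matrix(w).T  # (n*h*w, kh*kw*c_in)
    gcols = gcols.reshape(n, h, wdt, kh, kw, c_in)
    gxp = np.zeros((n, h + 2 * p, wdt + 2 * p, c_in), dtype=gy.dtype)
    for i in range(kh):
        for j in range(kw):
            gxp[:, i : i + h, j : j + wdt, :] += gcols[:, :, :, i, j, :]
    gx = _unpad_grad(gxp, p, padding)
    return gx, np.ascontiguousarray(gw), gb


def _shuffle_nhwc(x: np.ndarray, r: int) -> np.ndarray:
    n, h, w, c2 = x.shape
    c = c2 // (r * r)
    return np.ascontiguousarray(
        x.reshape(n, h, w, c, r, r)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, h * r, w * r, c)
    )


def _unshuffle_nhwc(y: np.ndarray, r: int) -> np.ndarray:
    n, hr, wr, c = y.shape
    h, w = hr // r, wr // r
    return np.ascontiguousarray(
        y.reshape(n, h, r, w, r, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h, w, c * r * r)
    )


def pixel_shuffle(x: np.ndarray, r: int) -> np.ndarray:
    """Rearrange channel-first (C*r^2, H, W) -> (C, rH, rW).

    Sub-pixel order is row-major:
    ``out[c, r*i+di, r*j+dj] = x[c*r^2 + di*r + dj, i, j]``.
    Batched (N, C*r^2, H, W) input is also accepted.
    """
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    n, c2, h, w = x.shape
    if c2 % (r * r) != 0:
        raise ValueError(f"channel count {c2} not divisible by r^2={r * r}")
    c = c2 // (r * r)
    out = (
        x.reshape(n, c, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, c, h * r, w * r)
    )
    out = np.ascontiguousarray(out)
    return out[0] if squeeze else out


def pixel_unshuffle(y: np.ndarray, r: int) -> np.ndarray:
    """Exact inverse of :func:`pixel_shuffle` (channel-first layout)."""
    squeeze = y.ndim == 3
    if squeeze:
        y = y[None]
    n, c, hr, wr = y.shape
    if hr % r or wr % r:
        raise ValueError("spatial dims not divisible by r")
    h, w = hr // r, wr // r
    out = (
        y.reshape(n, c, h, r, w, r)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, c * r * r, h, w)
    )
    out = np.ascontiguousarray(out)
    return out[0] if squeeze else out


def residual_block(x: np.ndarray, params: dict[str, np.ndarray], prefix: str = "block0",
                   padding: str = "reflect") -> np.ndarray:
    """conv -> ReLU -> conv -> add identity skip (channel-first C x H x W).

    ReLU appears only between the two inner convolutions; there is no batch
    normalization and no residual scaling.
    """
    squeeze = x.ndim == 3
    xb = (x[None] if squeeze else x).transpose(0, 2, 3, 1)
    out, _ = _resblock_forward(np.ascontiguousarray(xb), params, prefix, padding)
    out = out.transpose(0, 3, 1, 2)
    return out[0] if squeeze else out


def _resblock_forward(x, params, prefix, padding):
    h1, c1 = conv2d_forward(x, params[f"{prefix}.conv1.w"], params[f"{prefix}.conv1.b"], padding)
    mask = h1 > 0
    h1 *= mask
    h2, c2 = conv2d_forward(h1, params[f"{prefix}.conv2.w"], params[f"{prefix}.conv2.b"], padding)
    h2 += x
    return h2, (c1, mask, c2)


def _resblock_backward(gy, cache, grads, prefix):
    c1, mask, c2 = cache
    gx2, gw2, gb2 = conv2d_backward(gy, c2)
    gx2 *= mask
    gx1, gw1, gb1 = conv2d_backward(gx2, c1)
    grads[f"{prefix}.conv2.w"] = gw2
    grads[f"{prefix}.conv2.b"] = gb2
    grads[f"{prefix}.conv1.w"] = gw1
    grads[f"{prefix}.conv1.b"] = gb1
    return gy + gx1  # identity skip path


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

def forward_core(model: ModelState, x: np.ndarray, want_cache: bool = False):
    """Trunk on mean-subtracted NHWC float32 input; returns NHWC output.

    The mean shift is applied by the public :func:`forward` / the trainer,
    not here, so training losses can be computed in the zero-mean domain.
    """
    cfg, p = model.config, model.params
    pad = cfg.padding
    caches: list = []
    h0, c = conv2d_forward(x, p["head.w"], p["head.b"], pad)
    caches.append(c)
    h = h0
    for i in range(cfg.n_resblocks):
        h, c = _resblock_forward(h, p, f"block{i}", pad)
        caches.append(c)
    body = h + h0  # global skip
    u, c = conv2d_forward(body, p["up.conv.w"], p["up.conv.b"], pad)
    caches.append(c)
    s = _shuffle_nhwc(u, cfg.scale)
    y, c = conv2d_forward(s, p["tail.w"], p["tail.b"], pad)
    caches.append(c)
    if want_cache:
        return y, caches
    return y


def backward_core(model: ModelState, caches, gy: np.ndarray) -> dict[str, np.ndarray]:
    cfg = model.config
    grads: dict[str, np.ndarray] = {}
    gs, gw, gb = conv2d_backward(gy, caches[-1])
    grads["tail.w"], grads["tail.b"] = gw, gb
    gu = _unshuffle_nhwc(gs, cfg.scale)
    gbody, gw, gb = conv2d_backward(gu, caches[-2])
    grads["up.conv.w"], grads["up.conv.b"] = gw, gb
    g = gbody
    for i in range(cfg.n_resblocks - 1, -1, -1):
        g = _resblock_backward(g, caches[1 + i], grads, f"block{i}")
    g = g + gbody  # global skip feeds head output directly
    _, gw, gb = conv2d_backward(g, caches[0])
    grads["head.w"], grads["head.b"] = gw, gb
    return grads


def forward(model: ModelState, lr_image: np.ndarray) -> np.ndarray:
    """Super-resolve one HxWx3 image; returns float32 HxWx3 in [0, 255].

    Output dimensions are exactly ``scale`` times the input dimensions for
    any valid input size, which is what makes tiled slide inference possible.
    """
    img = np.asarray(lr_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {img.shape}")
    mean = np.asarray(model.config.mean_rgb, dtype=np.float32)
    x = (img.astype(np.float32) - mean)[None]
    y = forward_core(model, x)
    out = y[0] + mean
    return np.clip(out, 0.0, 255.0)


# ---------------------------------------------------------------------------
# bicubic baseline
# ---------------------------------------------------------------------------

def _keys_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    at = np.abs(t)
    return np.where(
        at <= 1,
        (a + 2) * at**3 - (a + 3) * at**2 + 1,
        np.where(at < 2, a * at**3 - 5 * a * at**2 + 8 * a * at - 4 * a, 0.0),
    )


def _bicubic_1d(length_in: int, r: int):
    """Tap indices (edge-clamped) and weights for one axis, half-pixel centers."""
    out = np.arange(length_in * r, dtype=np.float64)
    src = (out + 0.5) / r - 0.5
    i0 = np.floor(src).astype(np.int64)
    taps = np.stack([i0 - 1, i0, i0 + 1, i0 + 2], axis=1)
    wts = _keys_kernel(src[:, None] - taps)
    wts /= wts.sum(axis=1, keepdims=True)  # guard tiny numeric drift
    return np.clip(taps, 0, length_in - 1), wts


def bicubic_upscale(lr: np.ndarray, r: int = 2) -> np.ndarray:
    """Separable Keys cubic (a = -0.5) upscaling with half-pixel centers.

    Edge handling clamps taps to the image border.  Returns float64 clipped
    to [0, 255] (the caller rounds at file-write time).
    """
    if r < 1:
        raise ValueError("upscale factor must be >= 1")
    img = np.asarray(lr, dtype=np.float64)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[:, :, None]
    h, w, _ = img.shape
    ti, wi = _bicubic_1d(h, r)
    tmp = np.einsum("ok,okwc->owc", wi, img[ti, :, :])
    tj, wj = _bicubic_1d(w, r)
    out = np.einsum("ok,hokc->hoc", wj, tmp[:, tj, :])
    out = np.clip(out, 0.0, 255.0)
    return out[:, :, 0] if squeeze else out


# ---------------------------------------------------------------------------
# checkpoint container
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(model: ModelState, path) -> None:
    """Self-describing container; round-trips bit-exactly."""
    header = {
        "version": _CKPT_VERSION,
        "config": asdict(model.config),
        "train_meta": model.train_meta,
        "param_names": sorted(model.params),
    }
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    with open(path, "wb") as fh:
        np.savez(fh, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ModelState:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header["version"] != _CKPT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        cfg_d = header["config"]
        cfg_d["mean_rgb"] = tuple(cfg_d["mean_rgb"])
        config = EDSRConfig(**cfg_d)
        params = {k: data[f"param_{k}"] for k in header["param_names"]}
    return ModelState(config=config, params=params, train_meta=header["train_meta"])
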