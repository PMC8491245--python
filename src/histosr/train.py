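"""L1 training of the generator with validation-PSNR model selection.

The optimizer is Adam at learning rate 1e-4, halved at fixed step intervals
(standard practice for this architecture family; exposed in
:class:`TrainConfig`).  The loss is the mean absolute difference computed on
mean-subtracted intensities; validation PSNR is computed on the clamped
[0, 255] outputs, matching what a user of the saved model sees.  Everything
is seeded: weight initialization, batch order, and hence the full record
stream and the selected best checkpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import edsr
from .metrics import psnr
from .patches import PatchPair

__all__ = [
    "TrainConfig",
    "TrainRecord",
    "ValidationResult",
    "TrainingDivergedError",
    "l1_loss",
    "train",
    "validate",
    "write_record_log",
]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    total_steps: int = 1000
    learning_rate: float = 1e-4
    lr_decay: tuple[int, float] = (100_000, 0.5)   # (interval steps, factor)
    seed: int = 0
    val_interval: int = 100
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.total_steps < 1 or self.val_interval < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.lr_decay[1] <= 1:
            raise ValueError("lr decay factor must be in (0, 1]")


@dataclass
class TrainRecord:
    step: int
    train_l1: float
    val_psnr: float | None = None
    best: bool = False


@dataclass
class ValidationResult:
    mean_psnr: float        # mean over finite-PSNR pairs; nan if none
    n_finite: int
    n_infinite: int

    @property
    def all_infinite(self) -> bool:
        return self.n_finite == 0 and self.n_infinite > 0


def l1_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute difference over all elements."""
    a, b = np.asarray(pred), np.asarray(target)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a.astype(np.float64) - b.astype(np.float64))))


def validate(model: edsr.ModelState, val_pairs: list[PatchPair]) -> ValidationResult:
    """Mean PSNR of forward(lr) against hr over the validation pairs.

    Pairs with infinite PSNR (bit-identical prediction) are excluded from
    the mean and counted separately.
    """
    if not val_pairs:
        raise ValueError("empty validation set")
    finite, n_inf = [], 0
    for pair in val_pairs:
        sr = edsr.forward(model, pair.lr)
        v = psnr(np.asarray(pair.hr, dtype=np.float64), sr)
        if math.isinf(v):
            n_inf += 1
        else:
            finite.append(v)
    mean = float(np.mean(finite)) if finite else float("nan")
    return ValidationResult(mean_psnr=mean, n_finite=len(finite), n_infinite=n_inf)


class _Adam:
    def __init__(self, params, lr, betas, eps):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _stack_batch(pairs, idx, mean):
    lr = np.stack([np.asarray(pairs[i].lr, dtype=np.float32) for i in idx]) - mean
    hr = np.stack([np.asarray(pairs[i].hr, dtype=np.float32) for i in idx]) - mean
    return lr, hr


def train(model: edsr.ModelState, pairs: list[PatchPair], val_pairs: list[PatchPair],
          cfg: TrainConfig) -> tuple[edsr.ModelState, list[TrainRecord]]:
    """Train, validating every ``val_interval`` steps; returns the checkpoint
    with the highest validation PSNR (earliest on ties) and the record stream.

    ``model`` may be a fresh initialization or a loaded checkpoint (warm
    start from the best model achieved before).  A non-finite loss aborts
    with :class:`TrainingDivergedError`.
    """
    if not pairs or not val_pairs:
        raise ValueError("empty training or validation set")
    state = model.copy()
    mean = np.asarray(state.config.mean_rgb, dtype=np.float32)
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(state.params, cfg.learning_rate, cfg.adam_betas, cfg.adam_eps)

    records: list[TrainRecord] = []
    best_psnr, best_state, best_idx = -math.inf, None, -1

    def run_validation(step, train_l1):
        nonlocal best_psnr, best_state, best_idx
        res = validate(state, val_pairs)
        vp = math.inf if res.all_infinite else res.mean_psnr
        records.append(TrainRecord(step=step, train_l1=train_l1, val_psnr=vp))
        if vp > best_psnr:
            best_psnr = vp
            best_state = state.copy()
            best_idx = len(records) - 1

    run_validation(0, math.nan)  # step-0 baseline (warm-start contract)

    decay_every, decay_factor = cfg.lr_decay
    for step in range(1, cfg.total_steps + 1):
        idx = rng.integers(0, len(pairs), size=cfg.batch_size)
        x, y = _stack_batch(pairs, idx, mean)
        pred, caches = edsr.forward_core(state, x, want_cache=True)
        diff = pred - y
        loss = float(np.mean(np.abs(diff)))
        if not math.isfinite(loss):
            raise TrainingDivergedError(
                f"non-finite L1 loss {loss} at step {step}; aborting"
            )
        gy = np.sign(diff).astype(np.float32) / diff.size
        grads = edsr.backward_core(state, caches, gy)
        opt.lr = cfg.learning_rate * decay_factor ** (step // decay_every)
        opt.step(state.params, grads)
        if step % cfg.val_interval == 0 or step == cfg.total_steps:
            run_validation(step, loss)
        else:
            records.append(TrainRecord(step=step, train_l1=loss))

    records[best_idx].best = True
    best_state.train_meta = {
        "step": records[best_idx].step,
        "best_val_psnr": best_psnr,
        "parent": model.train_meta.get("checkpoint_id"),
    }
    return best_state, records


def write_record_log(records: list[TrainRecord], path: str) -> None:
    """Delimited log (step, train_l1, val_psnr) for loss/PSNR curve plots."""
    with open(path, "w") as fh:
        fh.write("step\ttrain_l1\tval_psnr\tbest\n")
        for r in records:
            vp = "" if r.val_psnr is None else f"{r.val_psnr:.6f}"
            tl = "" if math.isnan(r.train_l1) else f"{r.train_l1:.8f}"
            fh.write(f"{r.step}\t{tl}\t{vp}\t{int(r.best)}\n")
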