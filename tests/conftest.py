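"""Shared fixtures: the standard synthetic-fixture datasets and one trained
tiny generator reused by the end-to-end tests (training is the expensive
step, so it is session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

from histosr import edsr, patches, synthetic, train

# the standard fixture-study conditions: H&E-like scenes at the x40 scale
SCENE_KW = dict(
    width=320, height=320, n_nuclei=55,
    groove_fraction=0.3, mitotic_fraction=0.2,
    nucleus_axes_range=(4.0, 9.0), noise_sigma=2.0,
)

# smaller scenes for the BRISQUE calibration material
CALIB_KW = dict(
    width=96, height=96, n_nuclei=10,
    groove_fraction=0.3, mitotic_fraction=0.2,
    nucleus_axes_range=(3.0, 6.0), noise_sigma=2.0,
)

TRAIN_CFG = train.TrainConfig(
    batch_size=4, total_steps=800, learning_rate=1e-3,
    lr_decay=(400, 0.5), seed=1, val_interval=100,
)


def make_scene(seed: int, **overrides) -> np.ndarray:
    return synthetic.generate_scene(synthetic.SceneConfig(**{**SCENE_KW, **overrides, "seed": seed}))


def make_pair_set(scene_seeds, patches_per_scene, size=128, patch_seed=0):
    hr = []
    for i, s in enumerate(scene_seeds):
        img = make_scene(s)
        hr += patches.extract_hr_patches(img, n=patches_per_scene, size=size,
                                         seed=patch_seed + i)
    pairs = patches.make_pairs(hr, mode="bilinear_as_lr")
    for p in pairs:
        p.lr = p.lr.astype(np.float32)
    return pairs


@pytest.fixture(scope="session")
def fixture_pairs():
    """~2000 training pairs (64x64 -> 128x128) plus held-out val/test pairs."""
    train_pairs = make_pair_set(range(100, 110), 200, patch_seed=0)
    test_pairs = make_pair_set(range(900, 902), 25, patch_seed=50)
    return {"train": train_pairs, "val": test_pairs[:10], "test": test_pairs}


@pytest.fixture(scope="session")
def trained_model(fixture_pairs):
    """Tiny EDSR (2 blocks, 16 features, x2) trained on the standard run."""
    mean = tuple(patches.compute_mean_rgb([p.hr for p in fixture_pairs["train"][:200]]))
    cfg = edsr.EDSRConfig(n_resblocks=2, n_feats=16, scale=2, mean_rgb=mean)
    model = edsr.init_model(cfg, seed=1)
    best, records = train.train(model, fixture_pairs["train"], fixture_pairs["val"], TRAIN_CFG)
    return {"model": best, "records": records}


@pytest.fixture(scope="session")
def brisque_model():
    """Fixture-calibrated BRISQUE scorer + its held-out calibration images."""
    from histosr import brisque as bq

    feats, sevs = [], []
    train_seeds = range(200, 215)
    held_seeds = range(215, 220)

    def featurize(seeds):
        out = []
        for s in seeds:
            img = synthetic.generate_scene(synthetic.SceneConfig(**CALIB_KW, seed=s))
            rows = [(img, 0)]
            for kind in synthetic.DISTORTION_KINDS:
                for sev in range(1, 6):
                    rows.append((synthetic.degrade(img, synthetic.DistortionSpec(kind, sev),
                                                   seed=1000 * s + sev), sev))
            out.append([(bq.brisque_features(im).values, sv) for im, sv in rows])
        return out

    for group in featurize(train_seeds):
        for f, s in group:
            feats.append(f)
            sevs.append(s)
    model = bq.train_brisque_model(np.asarray(feats), np.asarray(sevs), seed=0)
    held = featurize(held_seeds)
    return {"model": model, "held_out": held}
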