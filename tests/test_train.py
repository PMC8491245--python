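"""Trainer: loss semantics, convergence, model selection, warm starts."""

import math

import numpy as np
import pytest

from histosr import edsr, train
from histosr.patches import PatchPair
from histosr.train import TrainConfig, l1_loss, validate


def constant_pairs(n, value=120.0, lr_size=16):
    """Trivial task: constant LR -> the same constant HR."""
    return [PatchPair(lr=np.full((lr_size, lr_size, 3), value, np.float32),
                      hr=np.full((2 * lr_size, 2 * lr_size, 3), value, np.float32),
                      mode="self_as_lr")
            for _ in range(n)]


def textured_pairs(n, lr_size=16, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        hr = rng.integers(0, 256, (2 * lr_size, 2 * lr_size, 3)).astype(np.uint8)
        lr = hr.reshape(lr_size, 2, lr_size, 2, 3).mean(axis=(1, 3)).astype(np.float32)
        pairs.append(PatchPair(lr=lr, hr=hr, mode="bilinear_as_lr"))
    return pairs


class TestL1Loss:
    def test_identical_and_extreme(self):
        x = np.random.default_rng(0).uniform(0, 255, (4, 8, 8, 3))
        assert l1_loss(x, x) == 0.0
        assert l1_loss(np.zeros((2, 4, 4)), np.full((2, 4, 4), 255.0)) == 255.0

    def test_matches_flat_mean_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 255, (3, 5, 5, 3)), rng.uniform(0, 255, (3, 5, 5, 3))
        assert abs(l1_loss(a, b) - np.abs(a - b).mean()) < 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestValidate:
    def test_matches_per_pair_psnr_oracle(self):
        from histosr.metrics import psnr

        pairs = textured_pairs(4, seed=2)
        m = edsr.init_model(edsr.EDSRConfig(n_resblocks=1, n_feats=4), seed=0)
        res = validate(m, pairs)
        oracle = np.mean([psnr(np.asarray(p.hr, float), edsr.forward(m, p.lr))
                          for p in pairs])
        assert abs(res.mean_psnr - oracle) < 1e-9
        assert res.n_finite == 4 and res.n_infinite == 0

    def test_all_identical_predictions_flagged(self):
        # zero network + constant pairs at the mean: predictions == targets
        m = edsr.init_model(edsr.EDSRConfig(n_resblocks=1, n_feats=4,
                                            mean_rgb=(120.0, 120.0, 120.0)), seed=0)
        for k in m.params:
            m.params[k][:] = 0
        res = validate(m, constant_pairs(3, value=120.0))
        assert res.all_infinite and res.n_infinite == 3

    def test_empty_set_rejected(self):
        m = edsr.init_model(edsr.EDSRConfig(n_resblocks=1, n_feats=4), seed=0)
        with pytest.raises(ValueError):
            validate(m, [])


class TestTrain:
    def toy_cfg(self, steps=200, seed=0, **kw):
        return TrainConfig(batch_size=4, total_steps=steps, learning_rate=2e-3,
                           lr_decay=(50, 0.5), seed=seed, val_interval=50, **kw)

    def test_converges_on_constant_task(self):
        pairs = constant_pairs(8, value=140.0, lr_size=8)
        cfg = edsr.EDSRConfig(n_resblocks=2, n_feats=8, mean_rgb=(100.0, 100.0, 100.0))
        model = edsr.init_model(cfg, seed=0)
        best, records = train.train(model, pairs, pairs[:2], self.toy_cfg(200))
        losses = [r.train_l1 for r in records if not math.isnan(r.train_l1)]
        assert losses[-1] < 0.01 * losses[0]

    def test_best_checkpoint_has_max_val_psnr(self):
        pairs = textured_pairs(12, seed=3)
        model = edsr.init_model(edsr.EDSRConfig(n_resblocks=1, n_feats=8), seed=1)
        best, records = train.train(model, pairs, pairs[:3], self.toy_cfg(100))
        vals = [r.val_psnr for r in records if r.val_psnr is not None]
        flagged = [r for r in records if r.best]
        assert len(flagged) == 1
        assert flagged[0].val_psnr == max(vals)
        assert best.train_meta["best_val_psnr"] == flagged[0].val_psnr

    def test_reproducible_record_stream(self):
        pairs = textured_pairs(10, seed=4)
        cfg = edsr.EDSRConfig(n_resblocks=1, n_feats=8)
        runs = []
        for _ in range(2):
            best, recs = train.train(edsr.init_model(cfg, seed=2), pairs, pairs[:2],
                                     self.toy_cfg(60, seed=7))
            runs.append((recs, best))
        assert [(r.step, r.train_l1, r.val_psnr) for r in runs[0][0]] == \
               [(r.step, r.train_l1, r.val_psnr) for r in runs[1][0]]
        for k in runs[0][1].params:
            assert np.array_equal(runs[0][1].params[k], runs[1][1].params[k])

    def test_warm_start_resumes_at_recorded_psnr(self, tmp_path):
        pairs = textured_pairs(10, seed=5)
        model = edsr.init_model(edsr.EDSRConfig(n_resblocks=1, n_feats=8), seed=3)
        best, _ = train.train(model, pairs, pairs[:3], self.toy_cfg(100))
        path = tmp_path / "best.ckpt"
        edsr.save_checkpoint(best, path)
        warm = edsr.load_checkpoint(path)
        _, records = train.train(warm, pairs, pairs[:3], self.toy_cfg(20))
        step0 = records[0]
        assert step0.step == 0
        assert step0.val_psnr == pytest.approx(warm.train_meta["best_val_psnr"], abs=1e-9)

    def test_warm_start_never_worse_than_fresh_init_at_step0(self):
        # over 3 seeds: the best-model warm start begins at least as high as
        # a fresh initialization on the same task
        pairs = textured_pairs(10, seed=6)
        for seed in (0, 1, 2):
            cfg = edsr.EDSRConfig(n_resblocks=1, n_feats=8)
            fresh = edsr.init_model(cfg, seed=seed)
            best, _ = train.train(fresh, pairs, pairs[:3], self.toy_cfg(60, seed=seed))
            warm_res = validate(best, pairs[:3])
            fresh_res = validate(fresh, pairs[:3])
            assert warm_res.mean_psnr >= fresh_res.mean_psnr

    def test_empty_dataset_rejected(self):
        model = edsr.init_model(edsr.EDSRConfig(n_resblocks=1, n_feats=4), seed=0)
        with pytest.raises(ValueError):
            train.train(model, [], constant_pairs(1), self.toy_cfg())

    def test_divergence_aborts_with_diagnostic(self):
        pairs = textured_pairs(6, seed=7)
        model = edsr.init_model(edsr.EDSRConfig(n_resblocks=1, n_feats=4), seed=0)
        model.params["head.w"][:] = np.inf
        with np.errstate(invalid="ignore"):
            with pytest.raises(train.TrainingDivergedError, match="non-finite"):
                train.train(model, pairs, pairs[:2], self.toy_cfg(10))

    def test_record_log_round_trip(self, tmp_path):
        pairs = textured_pairs(6, seed=8)
        model = edsr.init_model(edsr.EDSRConfig(n_resblocks=1, n_feats=4), seed=0)
        _, records = train.train(model, pairs, pairs[:2], self.toy_cfg(20))
        path = tmp_path / "log.tsv"
        train.write_record_log(records, str(path))
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "step\ttrain_l1\tval_psnr\tbest"
        assert len(lines) == len(records) + 1
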