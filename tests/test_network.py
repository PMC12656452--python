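"""Model assembly: forward contract, objective composition, training
determinism, gradient health, schedules and checkpointing."""

import numpy as np
import pytest

import pflnet as P
from pflnet import network
from pflnet.autodiff import Tensor
from pflnet.nn import cosine_lr

import _oracles as orc


def tiny_cfg(**over):
    base = dict(n_classes=3, input_size=16, backbone_widths=(4, 6, 8),
                common_channels=4, classifier_hidden=5, k=2, epochs=2,
                batch_size=4, seed=0)
    base.update(over)
    return P.desk_config(**base)


@pytest.fixture
def batch(rng):
    x = rng.standard_normal((4, 3, 16, 16)).astype(np.float32)
    y = np.array([0, 1, 2, 1])
    return x, y


# --------------------------------------------------------------------------
# manual numpy re-implementation of the forward pass (independent of the
# autodiff graph) used as the integration oracle
# --------------------------------------------------------------------------

def conv_oracle(x, w, b, stride, pad):
    cin, h, wid = x.shape
    cout, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (wid + 2 * pad - kw) // stride + 1
    out = np.zeros((cout, oh, ow))
    for co in range(cout):
        for i in range(oh):
            for j in range(ow):
                patch = xp[:, i * stride:i * stride + kh,
                           j * stride:j * stride + kw]
                out[co, i, j] = np.sum(patch * w[co]) + b[co]
    return out


def gn_oracle(x, norm):
    c = x.shape[0]
    g = norm.groups
    xg = x.reshape(g, -1)
    mu = xg.mean(axis=1, keepdims=True)
    var = ((xg - mu) ** 2).mean(axis=1, keepdims=True)
    xhat = ((xg - mu) / np.sqrt(var + norm.eps)).reshape(x.shape)
    return xhat * norm.gamma.data[0, :, :, :] + norm.beta.data[0, :, :, :]


def head_oracle(head, v):
    h = np.maximum(head.fc1.weight.data @ v + head.fc1.bias.data, 0.0)
    return head.fc2.weight.data @ h + head.fc2.bias.data


def manual_forward(model, img):
    bb = model.backbone
    h = np.maximum(gn_oracle(conv_oracle(img, bb.stem_a.weight.data,
                                         bb.stem_a.bias.data, 2, 1),
                             bb.norm_a), 0.0)
    feats = [np.maximum(gn_oracle(conv_oracle(h, bb.stem_b.weight.data,
                                              bb.stem_b.bias.data, 2, 1),
                                  bb.norm_b), 0.0)]
    for conv, norm in zip(bb.stage_convs, bb.stage_norms):
        feats.append(np.maximum(
            gn_oracle(conv_oracle(feats[-1], conv.weight.data,
                                  conv.bias.data, 2, 1), norm), 0.0))
    tapped = feats[-model.cfg.n_tapped_stages:]
    refined = [np.maximum(gn_oracle(conv_oracle(f, cv.weight.data,
                                                cv.bias.data, 1, 0), nm), 0.0)
               for f, cv, nm in zip(tapped, model.ssrm_convs,
                                    model.ssrm_norms)]
    projected = [np.maximum(conv_oracle(v, pj.weight.data, pj.bias.data,
                                        1, 0), 0.0)
                 for v, pj in zip(refined, model.projections)]
    scales = [p.reshape(p.shape[0], -1) for p in projected]
    fused = orc.mcpm_oracle(scales, model.cfg.gamma)
    pooled = [z.mean(axis=1) for z in fused]
    logits = [head_oracle(hd, p) for hd, p in zip(model.stage_heads, pooled)]
    y_cat = head_oracle(model.cat_head, np.concatenate(pooled))
    return logits, y_cat


class TestForward:
    def test_logit_shape_contract(self, rng):
        cfg = tiny_cfg(n_classes=5)
        model = P.PFLNet(cfg)
        logits, y_cat = model.forward(
            rng.standard_normal((1, 3, 16, 16)).astype(np.float32))
        assert len(logits) == 3
        for lg in logits:
            assert lg.shape == (1, 5)
        assert y_cat.shape == (1, 5)

    def test_identical_images_get_identical_logits(self, rng):
        model = P.PFLNet(tiny_cfg())
        one = rng.standard_normal((1, 3, 16, 16)).astype(np.float32)
        two = np.concatenate([one, one])
        logits, y_cat = model.forward(two)
        np.testing.assert_allclose(y_cat.data[0], y_cat.data[1], atol=1e-6)
        for lg in logits:
            np.testing.assert_allclose(lg.data[0], lg.data[1], atol=1e-6)

    def test_forward_matches_layer_by_layer_oracle(self, rng):
        """End-to-end forward equals an independent numpy re-computation
        (loop convolution, manual norms, loop-oracle fusion)."""
        model = P.PFLNet(tiny_cfg())
        img = rng.standard_normal((1, 3, 16, 16)).astype(np.float32)
        logits, y_cat = model.forward(img)
        logits_o, y_cat_o = manual_forward(model, img[0].astype(np.float64))
        for lg, lo in zip(logits, logits_o):
            np.testing.assert_allclose(lg.data[0], lo, rtol=1e-3, atol=1e-4)
        np.testing.assert_allclose(y_cat.data[0], y_cat_o, rtol=1e-3,
                                   atol=1e-4)


class TestObjective:
    def test_total_is_weighted_sum_of_terms(self, batch):
        x, y = batch
        model = P.PFLNet(tiny_cfg())
        bundle = model.training_step(x, y, rng=0)
        expected = (sum(float(t) for t in bundle.ce_per_head)
                    + model.cfg.mu * float(bundle.cd)
                    + model.cfg.lambda_ssrm / len(y)
                    * (float(bundle.ssrm_d) + float(bundle.ssrm_a)))
        assert float(bundle.total) == pytest.approx(expected, rel=1e-5)

    def test_disabled_modules_reduce_to_multihead_ce(self, batch):
        x, y = batch
        model = P.PFLNet(tiny_cfg(use_ssrm=False, use_mcpm=False,
                                  use_cd=False))
        bundle = model.training_step(x, y, rng=0)
        assert float(bundle.cd) == 0.0
        assert float(bundle.ssrm_d) == 0.0
        assert float(bundle.total) == pytest.approx(
            sum(float(t) for t in bundle.ce_per_head), rel=1e-6)

    def test_perfect_polar_prediction_zeroes_ssrm(self, rng):
        """Injecting the target grids into the loss functions yields zero."""
        from pflnet import ssrm
        r, th = ssrm.polar_targets((2, 2), 6)
        m = rng.random((6, 6)) + 0.1
        parts = ssrm.ssrm_image_loss(r, th, r, th, m)
        assert float(parts.L_ssrm) == pytest.approx(0.0, abs=1e-12)

    def test_gradient_health_all_terms_enabled(self, batch):
        """Every learnable parameter receives a finite gradient from the
        joint objective."""
        x, y = batch
        model = P.PFLNet(tiny_cfg())
        bundle = model.training_step(x, y, rng=0)
        model.zero_grad()
        bundle.total.backward()
        named = list(model.named_parameters())
        assert len(named) > 20
        for name, p in named:
            assert p.grad is not None, f"no gradient reached {name}"
            assert np.all(np.isfinite(p.grad)), f"non-finite grad in {name}"


class TestTrainingLoop:
    def test_repeat_runs_are_bit_identical(self, rng):
        imgs, labels, _ = P.generate_arrays(3, 8, 16, seed=4)
        x = P.normalize_images(imgs)
        cfg = tiny_cfg()
        _, h1 = P.train_model(cfg, x, labels)
        _, h2 = P.train_model(cfg, x, labels)
        for a, b in zip(h1, h2):
            assert a["total"] == b["total"]
            assert a["cd"] == b["cd"]

    def test_history_has_one_record_per_epoch(self, rng):
        imgs, labels, _ = P.generate_arrays(2, 4, 16, seed=4)
        x = P.normalize_images(imgs)
        model, hist = P.train_model(tiny_cfg(n_classes=2, epochs=3), x, labels)
        assert [h["epoch"] for h in hist] == [0, 1, 2]
        assert all(np.isfinite(h["total"]) for h in hist)


class TestScheduleAndOptimizer:
    def test_cosine_endpoints(self):
        sched = cosine_lr(1000)
        assert sched(0) == pytest.approx(1.0)
        assert sched(999) < 1e-2
        assert sched(1000) == pytest.approx(0.0, abs=1e-12)

    def test_final_epoch_rate_and_constant_aux(self):
        cfg = tiny_cfg(epochs=200)
        model = P.PFLNet(cfg)
        spe = 4
        opt = model.make_optimizer(cfg.epochs * spe)
        opt.step_count = (cfg.epochs - 1) * spe  # first step of last epoch
        lrs = opt.current_lrs()
        assert lrs[0] <= 1e-2 * cfg.lr_backbone
        assert lrs[1] <= 1e-2 * cfg.lr_new
        assert lrs[2] == pytest.approx(cfg.lr_aux)  # aux head: constant

    def test_gradient_clipping_bounds_global_norm(self, batch):
        x, y = batch
        model = P.PFLNet(tiny_cfg(max_grad_norm=0.5))
        opt = model.make_optimizer(10)
        opt.zero_grad()
        bundle = model.training_step(x, y, rng=0)
        bundle.total.backward()
        opt._clip_gradients()
        total = sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                    for p in model.parameters() if p.grad is not None)
        assert np.sqrt(total) <= 0.5 + 1e-6


class TestPredictEvaluate:
    def test_uniform_logits_tie_break_to_class_zero(self, batch):
        x, _ = batch
        model = P.PFLNet(tiny_cfg())
        for p in model.parameters():
            p.data = np.zeros_like(p.data)
        preds = network.predict(model, x)
        assert np.all(preds == 0)

    def test_predict_matches_softmax_average_oracle(self, batch):
        from scipy.special import softmax as sp_softmax
        x, _ = batch
        model = P.PFLNet(tiny_cfg())
        logits, y_cat = model.forward(x)
        probs = np.mean([sp_softmax(lg.data, axis=1)
                         for lg in logits + [y_cat]], axis=0)
        np.testing.assert_array_equal(network.predict(model, x),
                                      probs.argmax(axis=1))

    def test_cat_head_switch(self, batch):
        from scipy.special import softmax as sp_softmax
        x, _ = batch
        model = P.PFLNet(tiny_cfg(predict_head="cat"))
        _, y_cat = model.forward(x)
        np.testing.assert_array_equal(
            network.predict(model, x),
            sp_softmax(y_cat.data, axis=1).argmax(axis=1))

    def test_evaluate_is_a_counting_oracle(self, batch):
        x, y = batch
        model = P.PFLNet(tiny_cfg())
        preds = network.predict(model, x)
        expected = 100.0 * np.mean(preds == y)
        assert network.evaluate(model, x, y) == pytest.approx(expected)

    def test_empty_dataset_rejected(self):
        model = P.PFLNet(tiny_cfg())
        with pytest.raises(ValueError):
            network.evaluate(model, np.empty((0, 3, 16, 16)), np.empty(0))


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, batch):
        x, _ = batch
        model = P.PFLNet(tiny_cfg())
        path = tmp_path / "ckpt.npz"
        network.save_checkpoint(model, path)
        clone = network.load_checkpoint(path)
        np.testing.assert_array_equal(network.predict(model, x),
                                      network.predict(clone, x))
        _, y1 = model.forward(x)
        _, y2 = clone.forward(x)
        np.testing.assert_allclose(y1.data, y2.data, atol=0)

    def test_state_dict_mismatch_rejected(self):
        model = P.PFLNet(tiny_cfg())
        state = model.state_dict()
        state.pop(next(iter(state)))
        with pytest.raises(KeyError):
            model.load_state_dict(state)
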