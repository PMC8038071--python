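"""Architecture, gradients and training behavior of the multimodal CNN."""

import numpy as np
import pytest

import contrp
from contrp.errors import ConfigError, DataError
from conftest import TINY_ARCH, make_image_samples


def triple(side, seed=0, label=1, rec="r0"):
    rng = np.random.default_rng(seed)
    return contrp.SampleTriple(rng.random((side, side)), rng.random((side, side)),
                               rng.random((side, side)), label, rec)


class TestArchitecture:
    def test_branch_and_concat_dims_follow_config(self):
        model = contrp.build_model(TINY_ARCH, seed=0)
        reps = model.extract_representation([triple(36), triple(36, 1)])
        assert reps.shape == (2, 3 * TINY_ARCH.block_filters[-1])

    def test_feature_dim_independent_of_input_side(self):
        model = contrp.build_model(TINY_ARCH, seed=0)
        for side in (36, 52):
            assert model.extract_representation([triple(side)]).shape[1] == \
                3 * TINY_ARCH.block_filters[-1]

    def test_parameter_count_matches_layer_formula(self):
        """Total trainables = 3 branches of sum (k^2 c_in + 1) c_out, plus head."""
        arch = contrp.ArchConfig()
        model = contrp.build_model(arch, seed=0)
        expected = 0
        cin = 1
        for cout, reps in zip(arch.block_filters, arch.convs_per_block):
            for _ in range(reps):
                expected += (9 * cin + 1) * cout
                cin = cout
        expected = 3 * expected + (3 * arch.block_filters[-1] + 1)
        assert model.num_params() == expected

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ConfigError):
            contrp.ArchConfig(block_filters=(8, 16), convs_per_block=(2, 2, 3))

    def test_zero_input_outputs_strictly_inside_unit_interval(self):
        model = contrp.build_model(TINY_ARCH, seed=0)
        z = np.zeros((36, 36))
        p = model.predict_proba([contrp.SampleTriple(z, z, z, 0, "r")])
        assert 0.0 < p[0] < 1.0

    def test_complement_probability(self):
        """Single sigmoid unit: P(relaxed) is exactly 1 - P(stressed)."""
        model = contrp.build_model(TINY_ARCH, seed=3)
        p = model.predict_proba([triple(36, s) for s in range(3)])
        np.testing.assert_allclose((1 - p) + p, 1.0)


class TestRepresentation:
    def test_head_independence(self):
        model = contrp.build_model(TINY_ARCH, seed=1)
        s = [triple(36, 5)]
        before = model.extract_representation(s)
        model.head_w = np.random.default_rng(0).normal(
            size=model.head_w.shape).astype(model.head_w.dtype)
        after = model.extract_representation(s)
        np.testing.assert_array_equal(before, after)

    def test_permutation_equivariance(self):
        model = contrp.build_model(TINY_ARCH, seed=1)
        batch = [triple(36, s) for s in range(5)]
        reps = model.extract_representation(batch)
        perm = [3, 0, 4, 1, 2]
        reps_p = model.extract_representation([batch[i] for i in perm])
        np.testing.assert_allclose(reps_p, reps[perm], atol=1e-6)

    def test_branch_isolation(self):
        """Zeroing one modality input changes only that branch's feature block."""
        model = contrp.build_model(TINY_ARCH, seed=2)
        F = TINY_ARCH.block_filters[-1]
        s = triple(36, 7)
        base = model.extract_representation([s])[0]
        zero = np.zeros((36, 36))
        hollow = contrp.SampleTriple(zero, s.rp_hgsr, s.rp_hr, s.label, "r")
        rep = model.extract_representation([hollow])[0]
        assert not np.allclose(rep[:F], base[:F])
        np.testing.assert_array_equal(rep[F:], base[F:])

    def test_mismatched_sides_rejected(self):
        model = contrp.build_model(TINY_ARCH, seed=0)
        with pytest.raises(DataError):
            model.extract_representation([triple(36), triple(44)])


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences on a tiny net."""
        arch = contrp.ArchConfig(block_filters=(2, 3, 3, 4, 4))
        model = contrp.build_model(arch, seed=4, dtype=np.float64)
        rng = np.random.default_rng(0)
        side = 36
        batch = [contrp.SampleTriple(rng.random((side, side)), rng.random((side, side)),
                                     rng.random((side, side)), i % 2, "r")
                 for i in range(2)]
        y = np.array([s.label for s in batch], dtype=float)

        def loss():
            p, _, _ = model._forward(batch, train=False)
            return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())

        # analytic gradients for one pass
        p, reps, caches = model._forward(batch, train=True)
        dz = (p - y) / len(batch)
        grads = {}
        grads[("head_w",)] = reps.T @ dz
        dreps = np.outer(dz, model.head_w)
        F = arch.block_filters[-1]
        for mi, mod in enumerate(("rp_fgsr", "rp_hgsr", "rp_hr")):
            for layer, dW, db in model._backward_branch(
                    dreps[:, mi * F:(mi + 1) * F], caches[mod]):
                grads[(mod, id(layer), "W")] = dW
                grads[(mod, id(layer), "b")] = db

        eps = 1e-6
        # head weights: a few coordinates
        for idx in (0, F, 2 * F + 1):
            w0 = model.head_w[idx]
            model.head_w[idx] = w0 + eps; lp = loss()
            model.head_w[idx] = w0 - eps; lm = loss()
            model.head_w[idx] = w0
            num = (lp - lm) / (2 * eps)
            assert grads[("head_w",)][idx] == pytest.approx(num, abs=1e-7)
        # a sample of conv weights across depth, every branch
        rng2 = np.random.default_rng(1)
        # pre-train the head so conv gradients are nonzero
        model.head_w[:] = rng2.normal(0, 0.5, model.head_w.shape)
        p, reps, caches = model._forward(batch, train=True)
        dz = (p - y) / len(batch)
        dreps = np.outer(dz, model.head_w)
        for mi, mod in enumerate(("rp_fgsr", "rp_hgsr", "rp_hr")):
            layer_grads = model._backward_branch(
                dreps[:, mi * F:(mi + 1) * F], caches[mod])
            for layer, dW, db in layer_grads[::4]:
                W = layer["W"]
                flat = rng2.choice(W.size, size=2, replace=False)
                for fi in flat:
                    idx = np.unravel_index(fi, W.shape)
                    w0 = W[idx]
                    W[idx] = w0 + eps; lp = loss()
                    W[idx] = w0 - eps; lm = loss()
                    W[idx] = w0
                    num = (lp - lm) / (2 * eps)
                    assert dW[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestTraining:
    def test_zero_epochs_is_noop(self):
        model = contrp.build_model(TINY_ARCH, seed=0)
        w_before = [l["W"].copy() for b in model.branches["rp_fgsr"] for l in b]
        trace = model.train(make_image_samples(4), contrp.TrainConfig(epochs=0))
        assert trace == []
        w_after = [l["W"] for b in model.branches["rp_fgsr"] for l in b]
        for a, b in zip(w_before, w_after):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_identical_loss_trace(self):
        samples = make_image_samples(6)
        traces = []
        for _ in range(2):
            model = contrp.build_model(TINY_ARCH, seed=5)
            traces.append(model.train(samples,
                                      contrp.TrainConfig(0.01, 4, 2, seed=5)))
        assert traces[0] == traces[1]

    def test_single_class_rejected(self):
        samples = [s for s in make_image_samples(4) if s.label == 1]
        model = contrp.build_model(TINY_ARCH, seed=0)
        with pytest.raises(DataError):
            model.train(samples, contrp.TrainConfig())

    def test_easy_task_learned_and_loss_decreases(self):
        """On strongly separated image classes the net fits its training set
        and the mean loss falls from the first to the last epoch."""
        samples = make_image_samples(12, seed=3, contrast=10.0)
        model = contrp.build_model(TINY_ARCH, seed=6)
        trace = model.train(samples, contrp.TrainConfig(0.1, 4, 6, seed=6))
        assert trace[-1] < trace[0]
        _, pred = model.predict(samples)
        y = np.array([s.label for s in samples])
        assert (pred == y).mean() >= 0.95

    def test_bias_calibration_matches_base_rate_on_zero_head(self):
        """With a zero head all logits are the bias, so the BCE-optimal bias
        is the log-odds of the class base rate."""
        samples = make_image_samples(6)  # 6 stressed / 6 relaxed -> base rate 1/2
        samples = samples[:4] + [s for s in samples if s.label == 1][:4]
        y = np.array([s.label for s in samples], dtype=float)
        model = contrp.build_model(TINY_ARCH, seed=0)
        model.calibrate_head_bias(samples)
        expected = np.log(y.mean() / (1 - y.mean()))
        assert abs(float(model.head_b) - expected) < 1e-6

    def test_bias_calibration_only_shifts_logits_by_a_constant(self):
        samples = make_image_samples(8, seed=2, contrast=10.0)
        model = contrp.build_model(TINY_ARCH, seed=1)
        model.train(samples, contrp.TrainConfig(0.05, 4, 2, seed=1))

        def logits(m):
            return m.extract_representation(samples).astype(np.float64) \
                       @ m.head_w.astype(np.float64) + float(m.head_b)

        before = logits(model)
        model.calibrate_head_bias(samples)
        after = logits(model)
        shifts = after - before
        assert np.allclose(shifts, shifts[0], atol=1e-6)

    def test_calibrate_bias_flag_runs_in_train(self):
        samples = make_image_samples(6, seed=4, contrast=10.0)
        model = contrp.build_model(TINY_ARCH, seed=2)
        model.train(samples, contrp.TrainConfig(0.05, 4, 2, seed=2,
                                                calibrate_bias=True))
        p = model.predict_proba(samples)
        y = np.array([s.label for s in samples])
        # calibrated scores put the two classes on both sides of the base rate
        assert p[y == 1].mean() > p[y == 0].mean()


class TestPredict:
    def test_tie_breaks_to_stressed(self):
        # a freshly built model has a zero head: p is exactly 0.5
        model = contrp.build_model(TINY_ARCH, seed=0)
        p, labels = model.predict([triple(36)])
        assert p[0] == 0.5 and labels[0] == 1

    def test_prediction_reproducible(self):
        model = contrp.build_model(TINY_ARCH, seed=1)
        model.train(make_image_samples(4), contrp.TrainConfig(0.01, 4, 1, seed=1))
        s = [triple(36, 9)]
        p1, _ = model.predict(s)
        p2, _ = model.predict(s)
        np.testing.assert_allclose(p1, p2, atol=1e-6)


def test_checkpoint_roundtrip(tmp_path):
    model = contrp.build_model(TINY_ARCH, seed=8)
    model.train(make_image_samples(4), contrp.TrainConfig(0.02, 4, 1, seed=8))
    path = tmp_path / "model.npz"
    contrp.save_checkpoint(model, path)
    back = contrp.load_checkpoint(path)
    s = [triple(36, 11)]
    np.testing.assert_allclose(back.predict_proba(s), model.predict_proba(s),
                               atol=1e-7)
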