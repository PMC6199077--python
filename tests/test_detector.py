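"""MLP arithmetic, gradient correctness, augmentation, scanning, detection."""

import math

import numpy as np
import pytest

from nanopillar.containers import Micrograph
from nanopillar.detector import (
    AUGMENT_ANGLES,
    AUGMENT_SCALES,
    PATCH_SIZE,
    DivergenceError,
    NetworkWeights,
    ResponseMap,
    augment_patch,
    augment_training_set,
    detect_tips,
    forward,
    forward_batch,
    loss_and_gradient,
    normalize_image,
    patch_to_input,
    scan,
    train,
)


def toy_patches(rng, n_per_class=4, noise=0.02):
    """Linearly separable toy set: bright 'P' patches vs dark 'E' patches."""
    bright = 0.9 + noise * rng.standard_normal((n_per_class, PATCH_SIZE, PATCH_SIZE))
    dark = 0.1 + noise * rng.standard_normal((n_per_class, PATCH_SIZE, PATCH_SIZE))
    X = np.vstack(
        [
            np.array([patch_to_input(p) for p in bright]),
            np.array([patch_to_input(p) for p in dark]),
        ]
    )
    labels = np.array(["P"] * n_per_class + ["E"] * n_per_class)
    return X, labels


class TestForward:
    def test_zero_weights_give_half(self):
        net = NetworkWeights(np.zeros((432, 24)), np.zeros(24), np.zeros((24, 2)),
                             np.zeros(2))
        out = forward(net, np.zeros(432))
        assert out == (0.5, 0.5)

    def test_outputs_in_open_unit_interval(self, rng):
        net = NetworkWeights.initialize(seed=1)
        for _ in range(5):
            e, p = forward(net, rng.uniform(0, 1, 432))
            assert 0.0 < e < 1.0 and 0.0 < p < 1.0

    def test_hand_computed_2_2_2_network(self):
        # sigma(z) = 1/(1+exp(-z)); x = [1.0, 0.5]
        net = NetworkWeights(
            w1=[[0.1, -0.2], [0.3, 0.4]], b1=[0.05, -0.05],
            w2=[[0.2, -0.1], [0.5, 0.3]], b2=[0.1, 0.2],
        )
        s = lambda z: 1.0 / (1.0 + math.exp(-z))
        h1 = s(1.0 * 0.1 + 0.5 * 0.3 + 0.05)          # 0.3
        h2 = s(1.0 * -0.2 + 0.5 * 0.4 - 0.05)          # -0.05
        o1 = s(h1 * 0.2 + h2 * 0.5 + 0.1)
        o2 = s(h1 * -0.1 + h2 * 0.3 + 0.2)
        out = forward(net, np.array([1.0, 0.5]))
        assert out[0] == pytest.approx(o1, rel=1e-12)
        assert out[1] == pytest.approx(o2, rel=1e-12)

    def test_nonfinite_input_rejected(self):
        net = NetworkWeights.initialize(seed=0)
        with pytest.raises(ValueError):
            forward(net, np.full(432, np.nan))


class TestGradient:
    def test_backprop_matches_finite_differences(self, rng):
        net = NetworkWeights.initialize(seed=2, n_in=10, n_hidden=5, n_out=2)
        X = rng.uniform(0, 1, (6, 10))
        T = rng.uniform(0.1, 0.9, (6, 2))
        _, grads = loss_and_gradient(net, X, T)
        eps = 1e-6
        for arr, g in zip((net.w1, net.b1, net.w2, net.b2), grads):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = loss_and_gradient(net, X, T)
                arr[idx] = orig - eps
                lm, _ = loss_and_gradient(net, X, T)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestTrain:
    def test_separable_toy_reaches_full_accuracy(self, rng):
        X, labels = toy_patches(rng)
        net = NetworkWeights.initialize(seed=3)
        net = train(net, X, labels, passes_per_pattern=60, learning_rate=0.1, seed=3)
        out = forward_batch(net, X)
        pred = np.where(out[:, 1] > out[:, 0], "P", "E")
        assert (pred == labels).all()

    def test_loss_monotone_on_toy_set(self, rng):
        X, labels = toy_patches(rng)
        net = NetworkWeights.initialize(seed=4)
        net = train(net, X, labels, passes_per_pattern=40, learning_rate=0.05, seed=4)
        losses = np.array(net.meta["loss_curve"])
        assert losses[-1] < losses[0]
        assert np.all(np.diff(losses) <= 1e-6)

    def test_zero_passes_leaves_weights_unchanged(self, rng):
        X, labels = toy_patches(rng)
        net = NetworkWeights.initialize(seed=5)
        trained = train(net, X, labels, passes_per_pattern=0)
        np.testing.assert_array_equal(net.w1, trained.w1)
        np.testing.assert_array_equal(net.b2, trained.b2)

    def test_divergence_raises(self, rng):
        X, labels = toy_patches(rng)
        net = NetworkWeights.initialize(seed=6)
        with pytest.raises((DivergenceError, FloatingPointError, RuntimeWarning)):
            with np.errstate(over="raise"):
                train(net, X, labels, passes_per_pattern=30, learning_rate=1e6)

    def test_single_class_rejected(self, rng):
        X, labels = toy_patches(rng)
        with pytest.raises(ValueError, match="class"):
            train(NetworkWeights.initialize(seed=0), X, np.full(X.shape[0], "P"), 1)

    def test_held_out_accuracy_on_synthetic_renders(self):
        import nanopillar as npl
        from nanopillar.detector import sample_training_patches

        def render(seed):
            tips = npl.generate_pattern(
                npl.PatternSpec(density=10, field_width=3000, field_height=3000,
                                seed=seed)
            )
            return npl.render_micrograph(tips, npl.RenderSpec(seed=seed)), tips

        img_a, tips_a = render(20)
        base, labels = sample_training_patches(img_a, tips_a, n_per_class=7, seed=20)
        tset = augment_training_set(base, labels)
        net = NetworkWeights.initialize(seed=20)
        net = train(net, tset.X, tset.labels, passes_per_pattern=40,
                    learning_rate=0.1, seed=20)

        img_b, tips_b = render(21)
        held_p, held_l = sample_training_patches(img_b, tips_b, n_per_class=30, seed=21)
        X = np.array([patch_to_input(p) for p in held_p])
        out = forward_batch(net, X)
        pred = np.where(out[:, 1] > out[:, 0], "P", "E")
        assert (pred == held_l).mean() >= 0.95

    def test_reproducible(self, rng):
        X, labels = toy_patches(rng)
        a = train(NetworkWeights.initialize(seed=7), X, labels, 10, seed=7)
        b = train(NetworkWeights.initialize(seed=7), X, labels, 10, seed=7)
        np.testing.assert_array_equal(a.w1, b.w1)


class TestAugmentation:
    def test_counts_504_per_class(self, rng):
        patches = rng.uniform(0, 1, (14, PATCH_SIZE, PATCH_SIZE))
        labels = ["P"] * 7 + ["E"] * 7
        tset = augment_training_set(patches, labels)
        assert tset.per_class == {"E": 504, "P": 504}
        assert tset.X.shape == (1008, 432)

    def test_identity_variant_reproduces_base(self, rng):
        patch = rng.uniform(0, 1, (PATCH_SIZE, PATCH_SIZE))
        variants = augment_patch(patch)
        # scales loop outer (0.9, 1.0, 1.1), angles inner: identity at index 24
        identity_index = len(AUGMENT_ANGLES) * AUGMENT_SCALES.index(1.0)
        np.testing.assert_array_equal(variants[identity_index], patch)

    def test_rotationally_symmetric_patch_invariant(self):
        y, x = np.mgrid[0:PATCH_SIZE, 0:PATCH_SIZE]
        c = (PATCH_SIZE - 1) / 2
        patch = np.exp(-((x - c) ** 2 + (y - c) ** 2) / (2 * 3.0**2))
        variants = augment_patch(patch)
        scale1 = variants[24:48]  # the 24 rotations at scale 1.0
        spread = scale1.max(axis=0) - scale1.min(axis=0)
        # compare inside the inscribed disc; corner content necessarily comes
        # from the reflective padding and is not rotation-invariant
        disc = (x - c) ** 2 + (y - c) ** 2 <= 4.5**2
        assert spread[disc].max() < 0.05  # bilinear interpolation tolerance

    def test_weights_json_round_trip(self, tmp_path):
        net = NetworkWeights.initialize(seed=8)
        net.save(tmp_path / "w.json")
        back = NetworkWeights.load(tmp_path / "w.json")
        np.testing.assert_array_equal(net.w1, back.w1)
        np.testing.assert_array_equal(net.b1, back.b1)


class TestScanDetect:
    def test_constant_image_constant_response(self):
        net = NetworkWeights.initialize(seed=9)
        img = Micrograph(np.full((40, 40), 55.0), 10.0)
        resp = scan(net, img)
        assert np.allclose(resp.values, resp.values[0, 0])

    def test_stride_two_subsamples_stride_one(self, rng):
        net = NetworkWeights.initialize(seed=10)
        img = Micrograph(rng.uniform(0, 255, (50, 50)), 10.0)
        r1 = scan(net, img, stride=1)
        r2 = scan(net, img, stride=2)
        np.testing.assert_allclose(r2.values, r1.values[::2, ::2], rtol=1e-12)

    def test_scan_matches_single_patch_forward(self, rng):
        net = NetworkWeights.initialize(seed=11)
        img = Micrograph(rng.uniform(0, 255, (30, 30)), 10.0)
        resp = scan(net, img)
        norm = normalize_image(img.data)
        x = patch_to_input(norm[5 : 5 + PATCH_SIZE, 3 : 3 + PATCH_SIZE])
        assert resp.values[5, 3] == pytest.approx(forward(net, x)[1], rel=1e-12)

    def test_subthreshold_response_empty(self):
        resp = ResponseMap(np.full((20, 20), 0.2), 1, 10.0)
        tips = detect_tips(resp, threshold=0.5, min_separation_nm=100)
        assert tips.n == 0

    def test_close_maxima_suppressed_highest_wins(self):
        v = np.zeros((21, 21))
        v[10, 8] = 0.9
        v[10, 12] = 0.8   # 4 px = 40 nm away, below min separation
        resp = ResponseMap(v, 1, 10.0)
        tips = detect_tips(resp, threshold=0.5, min_separation_nm=100)
        assert tips.n == 1
        # winner is the higher response at column 8 -> x = (8 + 5.5) * 10 nm
        assert tips.xy[0, 0] == pytest.approx((8 + 5.5) * 10.0)

    def test_distant_maxima_kept(self):
        v = np.zeros((40, 40))
        v[10, 10] = 0.9
        v[30, 30] = 0.8
        resp = ResponseMap(v, 1, 10.0)
        tips = detect_tips(resp, threshold=0.5, min_separation_nm=100)
        assert tips.n == 2
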