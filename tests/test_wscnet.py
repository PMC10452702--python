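"""Counting network: loss identities, architecture contract, gradients,
training plumbing and inference mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropcell import wscnet
from dropcell.astm import CircleProposal
from dropcell.wscnet import (
    TrainConfig,
    build_model,
    counting_loss,
    density_peaks,
    infer,
    load_checkpoint,
    max_regularizer,
    reclassify,
    save_checkpoint,
    total_loss,
    truncated_count,
)

#: parameter count of a 34-layer residual classifier (the usual deep
#: baseline for this task); the counting network must stay far smaller
RESNET34_PARAMS = 21_797_672


class TestTruncatedCount:
    def test_below_truncation_passes_through(self):
        assert truncated_count(np.full((2, 2), 1.5 / 4), 0.001) == pytest.approx(1.5)

    def test_above_truncation_small_slope(self):
        assert truncated_count(np.full((2, 2), 3 / 4), 0.001) == pytest.approx(2.003)

    def test_zero(self):
        assert truncated_count(np.zeros((4, 4)), 0.001) == 0.0

    def test_boundary_uses_truncated_branch(self):
        assert truncated_count(np.full((1, 2), 1.0), 0.5) == pytest.approx(3.0)

    @given(st.floats(0, 10), st.floats(0, 10))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_nondecreasing_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        g = 0.01
        assert truncated_count(np.array([lo]), g) <= truncated_count(
            np.array([hi]), g
        ) + 1e-12
        assert truncated_count(np.array([hi]), g) <= 2 + g * hi + 1e-12

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            truncated_count(np.zeros((2, 2)), 0.0)


class TestMaxRegularizer:
    @pytest.mark.parametrize(
        "dmax,expect", [(1.3, 0.3), (0.8, 0.0), (1.0, 0.0), (2.5, 1.5)]
    )
    def test_values(self, dmax, expect):
        d = np.zeros((3, 3))
        d[1, 1] = dmax
        assert max_regularizer(d) == pytest.approx(expect)


class TestCountingLoss:
    def test_perfect_prediction(self):
        d = np.full((2, 2), 0.25)  # Dsum=1, Dmax=0.25
        assert counting_loss(d, 1, 0.001) == 0.0

    def test_truncated_squared_error(self):
        d = np.full((2, 2), 0.75)  # Dsum=3 -> f=2.003
        assert counting_loss(d, 2, 0.001) == pytest.approx(9e-6, rel=1e-6)

    def test_error_plus_regularizer(self):
        # y=0 with Dsum=0.5, Dmax=1.2: squared error 0.25 plus penalty 0.2
        d = np.array([[1.2, 0.0], [0.0, -0.7]])
        assert counting_loss(d, 0, 0.001) == pytest.approx(0.25 + 0.2)

    def test_zero_iff_exact_and_bounded_max(self, rng):
        # counting_loss == 0 exactly when f(D) = y and Dmax <= 1
        for _ in range(20):
            d = rng.uniform(0, 0.6, size=(4, 4))
            y = int(rng.integers(0, 3))
            loss = counting_loss(d, y, 0.001)
            exact = (
                truncated_count(d, 0.001) == y and max_regularizer(d) == 0.0
            )
            assert (loss == 0.0) == exact

    def test_invalid_label(self):
        with pytest.raises(ValueError):
            counting_loss(np.zeros((2, 2)), 3, 0.001)


class TestTotalLoss:
    def test_zero(self):
        assert total_loss(0.0, 0.0, 1.0) == 0.0

    def test_additive_combination(self):
        assert total_loss(0.7, 0.3, 1.0) == pytest.approx(1.0)
        assert total_loss(0.7, 0.3, 2.0) == pytest.approx(1.3)

    def test_classification_only_limit(self):
        assert total_loss(0.7, 123.0, 0.0) == pytest.approx(0.7)

    def test_invalid_omega(self):
        with pytest.raises(ValueError):
            total_loss(0.1, 0.1, -1.0)


class TestReclassify:
    @pytest.mark.parametrize(
        "dsum,expect",
        [(0.3, 0), (1.4, 1), (5.0, 2), (0.0, 0), (2.0, 2), (0.49, 0), (0.51, 1)],
    )
    def test_nearest_category(self, dsum, expect):
        assert reclassify(dsum) == expect

    def test_ties_break_toward_smaller_count(self):
        assert reclassify(0.5) == 0
        assert reclassify(1.5) == 1

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            reclassify(-0.1)


class TestArchitecture:
    def test_seven_convolutional_layers(self):
        model = build_model(0)
        assert len(model.trunk) + len(model.head) == 7

    def test_parameter_budget(self):
        # far below one eighth of the 34-layer residual baseline
        assert build_model(0).n_params * 8 < RESNET34_PARAMS

    def test_deterministic_initialization(self):
        assert build_model(7).checksum() == build_model(7).checksum()
        assert build_model(7).checksum() != build_model(8).checksum()

    def test_forward_contract(self):
        model = build_model(0)
        x = np.random.default_rng(0).random((3, 32, 32), dtype=np.float32)
        logits, density = model.forward(x, train=False)
        assert logits.shape == (3, 2)
        assert density.shape == (3, 32, 32)  # same resolution as the input
        assert float(density.min()) >= 0.0  # nonnegative activation

    def test_gradient_against_finite_differences(self):
        """Backprop matches central finite differences.

        Trunk and counting-head parameters are checked against the counting
        loss (the classification readout deliberately does not propagate
        into the trunk); the linear readout is checked against the
        cross-entropy.
        """
        rng = np.random.default_rng(1)
        model = build_model(3)
        # evaluate in float64 so central differences are noise-free
        for layer in model.layers:
            layer.W = layer.W.astype(np.float64)
            layer.b = layer.b.astype(np.float64)
        x = rng.random((2, 8, 8))
        cls = np.array([0, 1])
        y = np.array([1.0, 2.0])
        mask = np.array([True, True])
        gamma = 0.5  # large slope so the truncated branch is exercised

        import dropcell.wscnet as W

        def count_loss():
            _logits, density = model.forward(x, train=True)
            lk, dd = W._count_loss_batch(density, y, mask, gamma)
            return lk, dd

        def class_loss():
            logits, _density = model.forward(x, train=True)
            lc, dlogits = W._softmax_ce(logits, cls)
            return lc, dlogits

        _, dd = count_loss()
        model.backward(np.zeros((2, 2)), dd.astype(np.float64))
        grads = [g.copy() for g in model.grads()]
        params = model.params()

        eps = 1e-6
        # conv1 W, conv3 W, head conv7 W and bias
        for pi, idx in [(0, (0, 0, 0, 0)), (4, (1, 1, 0, 3)),
                        (12, (1, 1, 2, 0)), (13, (0,))]:
            p = params[pi]
            orig = float(p[idx])
            p[idx] = orig + eps
            lp, _ = count_loss()
            p[idx] = orig - eps
            lm, _ = count_loss()
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(float(grads[pi][idx]),
                                            rel=1e-4, abs=1e-9)

        _, dlogits = class_loss()
        model.backward(dlogits, np.zeros((2, 8, 8)))
        fc_grads = [g.copy() for g in model.fc.grads()]
        for arr, g, idx in [(model.fc.W, fc_grads[0], (3, 1)),
                            (model.fc.b, fc_grads[1], (0,))]:
            orig = float(arr[idx])
            arr[idx] = orig + eps
            lp, _ = class_loss()
            arr[idx] = orig - eps
            lm, _ = class_loss()
            arr[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(float(g[idx]), rel=1e-4, abs=1e-9)


class TestDensityPeaks:
    def test_known_peaks_recovered_in_order(self):
        d = np.zeros((20, 20))
        d[5, 5] = 1.0
        d[15, 12] = 0.8
        peaks = density_peaks(d, 2)
        assert peaks == [(5.0, 5.0), (12.0, 15.0)]  # (x, y)

    def test_minimum_separation_enforced(self):
        d = np.zeros((20, 20))
        d[5, 5] = 1.0
        d[5, 6] = 0.9  # within 3 px of the first peak
        d[5, 12] = 0.5
        peaks = density_peaks(d, 2, min_separation=3.0)
        assert peaks == [(5.0, 5.0), (12.0, 5.0)]


class TestInference:
    def test_detection_contract(self, small_scene):
        _, img, truth = small_scene
        cx, cy, r = truth.circles[0]
        model = build_model(0)
        det = infer(model, CircleProposal(cx, cy, r, 0.99), img)
        if det.is_droplet:
            assert det.predicted_count == int(np.floor(det.dsum + 0.5))
            assert len(det.cell_locations) == det.predicted_count
            assert det.category == reclassify(det.dsum)
        else:
            assert det.dsum is None and det.cell_locations == []

    def test_proposal_outside_frame_rejected(self, small_scene):
        _, img, _ = small_scene
        model = build_model(0)
        with pytest.raises(ValueError):
            infer(model, CircleProposal(-5.0, 10.0, 4.0, 0.9), img)

    def test_count_from_dsum_floor(self):
        # floor(Dsum + 0.5) maps 1.4 -> 1 and 2.6 -> 3
        assert int(np.floor(1.4 + 0.5)) == 1
        assert int(np.floor(2.6 + 0.5)) == 3
        d = np.zeros((10, 10))
        d[2, 2], d[7, 7], d[2, 7] = 0.9, 0.9, 0.8
        k = int(np.floor(d.sum() + 0.5))
        assert len(density_peaks(d, k)) == k == 3


class TestTrainingPlumbing:
    def test_missing_category_rejected(self, tiny_patches):
        ds = tiny_patches
        keep = ds.count_label != 2  # drop every multicell patch
        import dataclasses

        broken = dataclasses.replace(
            ds,
            images=ds.images[keep],
            is_droplet=ds.is_droplet[keep],
            count_label=ds.count_label[keep],
            true_counts=ds.true_counts[keep],
            cell_xy=[c for c, k in zip(ds.cell_xy, keep) if k],
            split=ds.split[keep],
        )
        with pytest.raises(ValueError, match="multiple"):
            wscnet.train(build_model(0), broken, TrainConfig(max_epochs=1))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainConfig(gamma=0.0)
        with pytest.raises(ValueError):
            TrainConfig(omega=-1.0)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        model = build_model(5)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path, TrainConfig())
        loaded, meta = load_checkpoint(path)
        assert loaded.checksum() == model.checksum()
        assert meta["gamma"] == 0.001 and meta["omega"] == 1.0

    def test_architecture_mismatch_detected(self, tmp_path):
        model = build_model(0)
        path = tmp_path / "model.npz"
        arrays = {f"p{i}": p[..., :1] for i, p in enumerate(model.params())}
        np.savez(path, **arrays)
        with pytest.raises(ValueError, match="architecture"):
            load_checkpoint(path)
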