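"""Training protocol: losses, normalization, augmentation, split, loop."""

import numpy as np
import pytest

from octfluid.errors import ConfigError
from octfluid.network import NetworkSpec, build_model
from octfluid.training import (TrainConfig, augment_pair, bce_loss,
                               combined_loss, dice_loss, normalize_inputs,
                               one_hot, split_dataset, train)

RNG = np.random.default_rng(99)


class TestLosses:
    def setup_method(self):
        self.target = np.zeros((1, 3, 4, 4), np.float32)
        self.target[0, :, :2, :] = 1.0  # half-ones per class
        self.half = np.full((1, 3, 4, 4), 0.5, np.float32)

    def test_dice_zero_for_perfect_and_one_for_disjoint(self):
        assert float(dice_loss(self.target, self.target).data) <= 1e-5
        assert float(dice_loss(1 - self.target, self.target).data) >= 1 - 1e-5

    def test_dice_half_overlap_closed_form(self):
        assert abs(float(dice_loss(self.half, self.target).data) - 0.5) < 1e-6

    def test_bce_at_half_is_ln2(self):
        assert abs(float(bce_loss(self.half, self.target).data)
                   - np.log(2)) < 1e-6

    def test_bce_matches_pixel_loop_oracle(self):
        p = RNG.random((1, 3, 8, 8)).astype(np.float64) * 0.98 + 0.01
        t = (RNG.random((1, 3, 8, 8)) > 0.5).astype(np.float64)
        total = 0.0
        for idx in np.ndindex(p.shape):
            total += -(t[idx] * np.log(p[idx])
                       + (1 - t[idx]) * np.log(1 - p[idx]))
        assert abs(float(bce_loss(p, t).data) - total / p.size) < 1e-9

    def test_combined_weights(self):
        b = float(bce_loss(self.half, self.target).data)
        d = float(dice_loss(self.half, self.target).data)
        assert float(combined_loss(self.half, self.target, (1, 0)).data) == \
            pytest.approx(b)
        assert float(combined_loss(self.half, self.target, (0, 1)).data) == \
            pytest.approx(d)
        assert float(combined_loss(self.half, self.target, (1, 1)).data) == \
            pytest.approx(b + d)

    def test_both_weights_zero_rejected(self):
        with pytest.raises(ConfigError):
            combined_loss(self.half, self.target, (0, 0))

    def test_combined_loss_nonnegative_and_zero_only_at_target(self):
        for _ in range(5):
            p = RNG.random((1, 3, 4, 4))
            t = (RNG.random((1, 3, 4, 4)) > 0.5).astype(float)
            assert float(combined_loss(p, t).data) > 0
        assert float(combined_loss(self.target, self.target).data) < 1e-4


class TestNormalize:
    def test_zero_mean_unit_variance(self):
        out = normalize_inputs(RNG.random((32, 32)))
        assert abs(out.mean()) <= 1e-6
        assert abs(out.var() - 1) <= 1e-5

    def test_affine_invariance(self):
        img = RNG.random((16, 16))
        assert np.allclose(normalize_inputs(3.0 * img + 0.2),
                           normalize_inputs(img), atol=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ConfigError):
            normalize_inputs(np.full((8, 8), 0.3))


class TestAugment:
    def test_mask_labels_never_invented(self):
        img = RNG.random((64, 64))
        mask = np.zeros((64, 64), np.uint8)
        mask[20:30, 10:40] = 2
        for seed in range(10):
            _, m2 = augment_pair(img, mask, np.random.default_rng(seed))
            assert set(np.unique(m2)) <= set(np.unique(mask))

    def test_flip_twice_restores(self):
        img = RNG.random((16, 16))
        flipped = img[:, ::-1]
        assert np.array_equal(flipped[:, ::-1], img)

    def test_geometric_transform_shared_by_image_and_mask(self):
        img = np.zeros((64, 64))
        img[30:40, 10:20] = 1.0
        mask = (img > 0).astype(np.uint8)
        i2, m2 = augment_pair(img, mask, np.random.default_rng(3))
        # wherever the bright patch went, the mask went with it
        assert ((i2 > 0.5) == (m2 > 0)).mean() > 0.99


class TestSplit:
    def test_80_20_counts(self):
        train_set, val = split_dataset(list(range(10)), 0.2, seed=0)
        assert len(train_set) == 8 and len(val) == 2

    def test_same_seed_same_split(self):
        a = split_dataset(list(range(20)), 0.2, seed=5)
        b = split_dataset(list(range(20)), 0.2, seed=5)
        assert a == b

    def test_disjoint_and_exhaustive(self):
        items = list(range(17))
        tr, va = split_dataset(items, 0.3, seed=1)
        assert set(tr) & set(va) == set()
        assert sorted(tr + va) == items

    def test_too_few_items_rejected(self):
        with pytest.raises(ConfigError):
            split_dataset([1], 0.2, seed=0)


def _tiny_net(size=32):
    return build_model(NetworkSpec(in_size=(size, size), base_channels=8,
                                   n_stages=2), seed=0)


class TestTrainLoop:
    def test_single_step_decreases_loss_on_most_seeds(self, small_samples):
        """Over 20 seeds, one Adam step on one sample lowers that
        sample's loss at least 18 times."""
        from octfluid._autodiff import Tensor
        from octfluid._nn import Adam
        from octfluid.training import _batch_arrays

        wins = 0
        for seed in range(20):
            net = build_model(NetworkSpec(in_size=(64, 64), base_channels=8,
                                          n_stages=2), seed=seed)
            x, e, t = _batch_arrays(small_samples[:1], 3, False, None)
            opt = Adam(net.parameters(), lr=1e-4)
            probs = net.forward_tensor(Tensor(x), Tensor(e))
            before = combined_loss(probs, t)
            before.backward()
            opt.step()
            after = net.forward_tensor(Tensor(x), Tensor(e))
            if float(combined_loss(after, t).data) < float(before.data):
                wins += 1
        assert wins >= 18

    def test_lr_trace_non_increasing_with_exact_drops(self, small_samples):
        cfg = TrainConfig(batch_size=2, max_epochs=6, lr=1e-12,
                          plateau_patience=1, early_stop_patience=5,
                          seed=0, val_fraction=0.25)
        net = _tiny_net(64)
        _, hist = train(net, small_samples, cfg)
        lrs = hist.lr
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        for a, b in zip(lrs, lrs[1:]):
            assert b == a or b == pytest.approx(a * 0.1)
        assert lrs[-1] < lrs[0]  # at least one drop happened

    def test_early_stopping_halts_frozen_model_after_two_epochs(
            self, small_samples):
        cfg = TrainConfig(batch_size=2, max_epochs=20, lr=0.0,
                          plateau_patience=10, early_stop_patience=1,
                          seed=0, val_fraction=0.25)
        net = _tiny_net(64)
        _, hist = train(net, small_samples, cfg)
        assert hist.n_epochs() == 2

    def test_max_steps_caps_optimizer_steps(self, small_samples):
        cfg = TrainConfig(batch_size=2, max_epochs=50, max_steps=3,
                          plateau_patience=50, early_stop_patience=50,
                          seed=0, val_fraction=0.25)
        net = _tiny_net(64)
        _, hist = train(net, small_samples, cfg)
        assert hist.n_epochs() <= 3

    def test_empty_dataset_rejected(self):
        with pytest.raises(ConfigError):
            train(_tiny_net(), [], TrainConfig())


def test_one_hot_roundtrip():
    mask = np.array([[0, 1], [2, 3]], np.uint8)
    oh = one_hot(mask, 3)
    assert oh.shape == (3, 2, 2)
    assert oh[0, 0, 1] == 1 and oh[1, 1, 0] == 1 and oh[2, 1, 1] == 1
    assert oh[:, 0, 0].sum() == 0  # background has no channel


def test_class_permutation_symmetry(small_samples):
    """Permuting two target channels (and the head's initial kernels the
    same way) permutes the output channels and their gradients: no class
    is hard-coded anywhere in the architecture or loss."""
    from octfluid._autodiff import Tensor
    from octfluid.training import _batch_arrays

    perm = [1, 0, 2]
    x, e, t = _batch_arrays(small_samples[:2], 3, False, None)

    def forward_backward(targets, permute_head):
        net = build_model(NetworkSpec(in_size=(64, 64), base_channels=8,
                                      n_stages=2), seed=4)
        if permute_head:
            net.head.weight.data = net.head.weight.data[perm]
            net.head.bias.data = net.head.bias.data[perm]
        probs = net.forward_tensor(Tensor(x), Tensor(e))
        combined_loss(probs, targets).backward()
        return net, probs.data

    net_a, out_a = forward_backward(t, permute_head=False)
    net_b, out_b = forward_backward(t[:, perm], permute_head=True)
    # outputs are exactly permuted at initialization
    assert np.allclose(out_b, out_a[:, perm], atol=1e-6)
    # head gradients are the permuted head gradients
    assert np.allclose(net_b.head.weight.grad,
                       net_a.head.weight.grad[perm], atol=1e-6)
    # gradients of a shared trunk parameter are unchanged
    ga = net_a.bottleneck1.conv.weight.grad
    gb = net_b.bottleneck1.conv.weight.grad
    assert np.allclose(ga, gb, atol=1e-5)
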