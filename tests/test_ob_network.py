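import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import saltspec as ss
from saltspec.errors import AllocationError, SaltSpecError, SplitError
from saltspec.ob_network import (
    ObClassifierNet,
    _xent_loss_grad,
    parameter_breakdown,
    round_filters,
)


class TestCompoundScaling:
    def test_phi_zero_gives_unit_multipliers(self):
        d, w, r, _ = ss.compound_multipliers(ss.ScalingSpec(phi=0))
        assert (d, w, r) == (1.0, 1.0, 1.0)

    def test_reference_constants_at_phi_one(self):
        d, w, r, c = ss.compound_multipliers(
            ss.ScalingSpec(alpha=1.2, beta=1.1, gamma=1.15, phi=1)
        )
        assert (d, w, r) == (1.2, 1.1, 1.15)
        assert c == pytest.approx(1.2 * 1.1 ** 2 * 1.15 ** 2)
        assert c == pytest.approx(1.9203, abs=1e-4)
        assert 1.8 <= c <= 2.2

    def test_invalid_constants_rejected(self):
        with pytest.raises(SaltSpecError):
            ss.ScalingSpec(alpha=0.9)
        with pytest.raises(SaltSpecError):
            ss.ScalingSpec(phi=-1)


class TestVariantScaling:
    def test_stem_widths_after_divisor8_rounding(self):
        assert round_filters(32, 1.0) == 32
        assert round_filters(32, 1.1) == 32   # B2
        assert round_filters(32, 1.4) == 48   # B4
        assert ss.make_network_spec("B2", 9, 2).stem_width == 32
        assert ss.make_network_spec("B4", 9, 2).stem_width == 48

    def test_variant_resolutions(self):
        assert ss.make_network_spec("B0", 3, 2).input_resolution == 224
        assert ss.make_network_spec("B2", 9, 2).input_resolution == 260
        assert ss.make_network_spec("B4", 9, 2).input_resolution == 388


class TestParameterAudit:
    def test_baseline_b0_strict_and_statistics_conventions(self):
        spec = ss.make_network_spec("B0", 3, 2)
        strict = ss.count_learnable_parameters(spec)
        breakdown = parameter_breakdown(spec)
        assert strict == breakdown["strict_total"]
        assert breakdown["bn_scale_offset"] == 2 * breakdown["bn_feature_count"]
        # adding one per-channel statistics vector per batch-norm layer
        assert (ss.count_learnable_parameters(spec, include_bn_stat_sets=1)
                == strict + breakdown["bn_feature_count"])

    def test_parameter_count_affine_in_input_channels(self):
        base = ss.count_learnable_parameters(ss.make_network_spec("B0", 3, 2))
        for n in range(4, 10):
            spec = ss.make_network_spec("B0", n, 2)
            delta = ss.count_learnable_parameters(spec) - base
            assert delta == (n - 3) * 3 * 3 * 32

    def test_ob_stem_weight_total_independent_of_channel_count(self):
        for n_ch in (3, 6, 9):
            alloc = ss.allocate_stem_kernels([1.0] * n_ch, total=32)
            spec = ss.make_network_spec("B0", n_ch, 2, ob=True, allocation=alloc)
            stem_w = sum(e.count for e in spec.manifest if e.name.startswith("stem.ob"))
            assert stem_w == 3 * 3 * spec.stem_width

    def test_ob_and_baseline_agree_downstream_of_stem(self):
        alloc = ss.allocate_stem_kernels([3, 2, 1, 1, 1, 1], total=32)
        ob = ss.make_network_spec("B0", 6, 2, ob=True, allocation=alloc)
        base = ss.make_network_spec("B0", 6, 2)
        strip = lambda spec: [(e.name, e.count) for e in spec.manifest
                              if not e.name.startswith("stem.") or e.name == "stem.bn"]
        assert strip(ob) == strip(base)

    def test_toy_model_count(self):
        class Toy:
            def parameters(self):
                return [np.zeros((1, 1, 3, 3)), np.zeros(1)]  # one 3x3x1 kernel + bias

        assert ss.count_learnable_parameters(Toy()) == 10


class TestStemAllocation:
    def test_reference_contribution_vector_reproduced(self):
        shares = [11, 6, 5, 3, 2, 2, 1, 1, 1]
        alloc = ss.allocate_stem_kernels(shares, 32)
        assert alloc.kernel_counts == shares
        assert sum(alloc.kernel_counts) == 32

    def test_equal_shares(self):
        assert ss.allocate_stem_kernels([1.0] * 9, 32).kernel_counts == \
            [4, 4, 4, 4, 4, 3, 3, 3, 3]

    def test_single_channel_takes_all(self):
        assert ss.allocate_stem_kernels([0.7], 32).kernel_counts == [32]

    def test_floor_of_one_preserved_for_tiny_shares(self):
        alloc = ss.allocate_stem_kernels([0.97, 0.01, 0.01, 0.01], 8)
        assert min(alloc.kernel_counts) >= 1
        assert sum(alloc.kernel_counts) == 8

    def test_infeasible_total_rejected(self):
        with pytest.raises(AllocationError):
            ss.allocate_stem_kernels([1.0] * 9, 8)
        with pytest.raises(AllocationError):
            ss.allocate_stem_kernels([1.0, -0.1], 8)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        shares=st.lists(st.floats(min_value=0.01, max_value=10), min_size=1, max_size=12),
        total=st.integers(min_value=12, max_value=64),
    )
    def test_allocation_invariants(self, shares, total):
        alloc = ss.allocate_stem_kernels(shares, total)
        counts = alloc.kernel_counts
        assert sum(counts) == total
        assert min(counts) >= 1
        for i in range(len(shares)):
            for j in range(len(shares)):
                if shares[i] > shares[j]:
                    assert counts[i] >= counts[j]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_allocation_permutation_equivariant(self, seed):
        rng = np.random.default_rng(seed)
        shares = rng.uniform(0.1, 5.0, size=6)
        # distinct shares so the allocation is permutation-unambiguous
        shares = np.sort(shares) + np.arange(6) * 1e-3
        perm = rng.permutation(6)
        a = ss.allocate_stem_kernels(shares, 24).kernel_counts
        b = ss.allocate_stem_kernels(shares[perm], 24).kernel_counts
        assert [a[p] for p in perm] == b


class TestRunnableNetwork:
    def _net(self, ob=True, n_ch=3, seed=0):
        alloc = ss.allocate_stem_kernels([5, 3, 1][:n_ch], total=8) if ob else None
        return ObClassifierNet(input_channels=n_ch, stem_width=8,
                               stage_widths=(6,), n_classes=2,
                               allocation=alloc, seed=seed)

    def test_ob_stem_depth_equals_stem_width(self):
        for n_ch in (1, 2, 3):
            alloc = ss.allocate_stem_kernels([1.0] * n_ch, total=8)
            net = ObClassifierNet(n_ch, stem_width=8, stage_widths=(), n_classes=2,
                                  allocation=alloc)
            logits = net.forward(np.random.default_rng(0).uniform(size=(2, n_ch, 12, 12)))
            assert net._feature_map.shape[1] == 8
            assert logits.shape == (2, 2)

    def test_gradients_match_numerical_differences(self):
        """Manual backprop agrees with central finite differences."""
        net = self._net()
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 3, 10, 10))
        y = np.array([0, 1])

        def loss_at():
            logits = net.forward(x, train=False)  # eval mode: deterministic stats
            return _xent_loss_grad(logits, y)[0]

        logits = net.forward(x, train=False)
        loss, dlogits = _xent_loss_grad(logits, y)
        net.backward(dlogits)
        params, grads = net.parameters(), net.gradients()
        rng_idx = np.random.default_rng(0)
        for p, g in zip(params, grads):
            flat = p.reshape(-1)
            for k in rng_idx.choice(flat.size, size=min(3, flat.size), replace=False):
                eps = 1e-5
                orig = flat[k]
                flat[k] = orig + eps
                up = loss_at()
                flat[k] = orig - eps
                down = loss_at()
                flat[k] = orig
                num = (up - down) / (2 * eps)
                assert num == pytest.approx(g.reshape(-1)[k], rel=1e-4, abs=1e-6)

    def test_allocation_mismatch_rejected(self):
        alloc = ss.allocate_stem_kernels([1, 1], total=8)
        with pytest.raises(AllocationError):
            ObClassifierNet(3, stem_width=8, allocation=alloc)
        with pytest.raises(AllocationError):
            ObClassifierNet(2, stem_width=16, allocation=alloc)


class TestAugmentation:
    def _cfg(self, **kw):
        base = dict(batch_size=8, max_epochs=1, scale_range=(1.0, 1.0),
                    flip_x=False, flip_y=False, shift_within_frame=False)
        base.update(kw)
        return ss.TrainConfig(**base)

    def _sample(self, seed=0):
        rng = np.random.default_rng(seed)
        img = np.zeros((3, 16, 16))
        img[:, 5:10, 6:12] = rng.uniform(1, 2, size=(3, 5, 6))
        return img

    def test_everything_off_is_identity(self):
        x = self._sample()
        np.testing.assert_array_equal(ss.augment(x, self._cfg(), seed=1), x)

    def test_same_seed_reproduces(self):
        cfg = self._cfg(flip_x=True, flip_y=True, scale_range=(0.75, 1.25),
                        shift_within_frame=True)
        x = self._sample()
        a = ss.augment(x, cfg, seed=42)
        b = ss.augment(x, cfg, seed=42)
        np.testing.assert_array_equal(a, b)
        c = ss.augment(x, cfg, seed=43)
        assert not np.array_equal(a, c)

    def test_flip_is_an_involution(self):
        cfg = self._cfg(flip_x=True)
        x = self._sample()
        # find a seed whose first draw flips
        for seed in range(20):
            out = ss.augment(x, cfg, seed=seed)
            if not np.array_equal(out, x):
                np.testing.assert_array_equal(out[:, :, ::-1], x)
                break
        else:
            pytest.fail("no flipping seed found")

    def test_fixed_scale_changes_mass_by_scale_squared(self):
        # pure isotropic rescale, no flip/shift: mass scales with area
        cfg = self._cfg(scale_range=(0.8, 0.8))
        x = self._sample()
        out = ss.augment(x, cfg, seed=5)
        assert out.sum() == pytest.approx(0.8 ** 2 * x.sum(), rel=0.1)

    def test_plant_stays_inside_frame(self):
        cfg = self._cfg(scale_range=(0.75, 1.25), shift_within_frame=True)
        x = self._sample()
        area = (x[0] != 0).sum()
        for seed in range(10):
            out = ss.augment(x, cfg, seed=seed)
            # count solid content (>0.5, i.e. above half the minimum plant
            # value) so the 1-px bilinear skirt does not inflate the area
            ratio = (np.abs(out).max(axis=0) > 0.5).sum() / area
            # solid area tracks scale^2 in [0.75^2, 1.25^2]; nothing clipped
            assert 0.45 <= ratio <= 1.75
            assert out.max() <= x.max() * 1.01

    def test_identical_transform_across_channels(self):
        cfg = self._cfg(flip_x=True, flip_y=True, scale_range=(0.75, 1.25),
                        shift_within_frame=True)
        x = np.repeat(self._sample()[:1], 4, axis=0)  # identical channels
        out = ss.augment(x, cfg, seed=9)
        for ch in range(1, 4):
            np.testing.assert_array_equal(out[ch], out[0])


def _separable_dataset(n=200, seed=7, n_ch=3, size=16):
    """Two-class stacks whose class shifts the mean level of channel 0."""
    rng = np.random.default_rng(seed)
    y = rng.permutation(np.repeat([0, 1], n // 2))
    X = rng.normal(0, 0.3, size=(n, n_ch, size, size))
    X[y == 1, 0] += 2.0
    pots = np.array([f"P{i}" for i in range(n)])
    return X, y, pots


class TestTraining:
    def test_learns_linearly_separable_stacks(self):
        X, y, pots = _separable_dataset(n=200, seed=7)
        net = ObClassifierNet(3, stem_width=8, stage_widths=(6,), seed=0)
        cfg = ss.TrainConfig(batch_size=32, max_epochs=30, seed=0, augment=False,
                             early_stop_acc=0.98)
        result = ss.train_classifier(
            (X[:150], y[:150], pots[:150]), (X[150:], y[150:], pots[150:]), net, cfg
        )
        assert result.best_val_accuracy >= 0.95

    def test_shuffled_labels_stay_at_chance(self):
        X, y, pots = _separable_dataset(n=120, seed=8)
        rng = np.random.default_rng(0)
        y_shuf = rng.permutation(y)
        net = ObClassifierNet(3, stem_width=8, stage_widths=(6,), seed=1)
        cfg = ss.TrainConfig(batch_size=32, max_epochs=5, seed=1, augment=False)
        result = ss.train_classifier(
            (X[:80], y_shuf[:80], pots[:80]), (X[80:], y_shuf[80:], pots[80:]), net, cfg
        )
        final = result.curves.val_accuracy.iloc[-1]
        assert 0.2 <= final <= 0.8  # permutation null: near 0.5

    def test_zero_epochs_returns_initialized_model(self):
        X, y, pots = _separable_dataset(n=40, seed=9)
        net = ObClassifierNet(3, stem_width=8, stage_widths=(6,), seed=2)
        before = [p.copy() for p in net.parameters()]
        cfg = ss.TrainConfig(batch_size=16, max_epochs=0, seed=2)
        result = ss.train_classifier(
            (X[:30], y[:30], pots[:30]), (X[30:], y[30:], pots[30:]), net, cfg
        )
        assert len(result.curves) == 0
        for p, b in zip(result.model.parameters(), before):
            np.testing.assert_array_equal(p, b)

    def test_pot_leakage_refused(self):
        X, y, pots = _separable_dataset(n=40, seed=10)
        net = ObClassifierNet(3, stem_width=8, stage_widths=(6,), seed=3)
        cfg = ss.TrainConfig(batch_size=16, max_epochs=1, seed=3)
        with pytest.raises(SplitError):
            ss.train_classifier((X[:30], y[:30], pots[:30]),
                                (X[25:], y[25:], pots[25:]), net, cfg)

    def test_training_is_seed_reproducible(self):
        X, y, pots = _separable_dataset(n=60, seed=11)
        outs = []
        for _ in range(2):
            net = ObClassifierNet(3, stem_width=8, stage_widths=(6,), seed=4)
            cfg = ss.TrainConfig(batch_size=16, max_epochs=2, seed=4)
            r = ss.train_classifier((X[:40], y[:40], pots[:40]),
                                    (X[40:], y[40:], pots[40:]), net, cfg)
            outs.append(r)
        assert outs[0].curves.equals(outs[1].curves)
        for a, b in zip(outs[0].model.parameters(), outs[1].model.parameters()):
            np.testing.assert_array_equal(a, b)


class TestGradCam:
    def test_map_shape_and_range(self):
        net = ObClassifierNet(3, stem_width=8, stage_widths=(6,), seed=5)
        x = np.random.default_rng(12).uniform(size=(3, 20, 20))
        cam = ss.grad_cam_map(net, x, target_class=1)
        assert cam.shape == (20, 20)
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_class_index_validated(self):
        net = ObClassifierNet(3, stem_width=8, stage_widths=(), seed=5)
        x = np.zeros((3, 12, 12))
        with pytest.raises(SaltSpecError):
            ss.grad_cam_map(net, x, target_class=5)

    def test_matches_hand_computed_chain_rule_on_toy_model(self):
        """Stem conv -> BN -> Swish -> GAP -> linear: the class-score gradient
        at the feature map is fc_w[class, ch] / (H*W), so the saliency map is
        relu(sum_ch fc_w[class, ch] * A_ch) up to max-normalization."""
        net = ObClassifierNet(2, stem_width=4, stage_widths=(), seed=6)
        x = np.random.default_rng(13).uniform(0.5, 1.5, size=(2, 14, 14))
        cam = ss.grad_cam_map(net, x, target_class=0)

        logits = net.forward(x[None], train=False)
        A = net._feature_map[0]                       # (4, 7, 7)
        hw = A.shape[1] * A.shape[2]
        weights = net.fc_w[0] / hw
        expected = np.maximum((weights[:, None, None] * A).sum(0), 0.0)
        from scipy import ndimage as ndi
        expected = ndi.zoom(expected, (2, 2), order=1)
        if expected.max() > 0:
            expected = expected / expected.max()
        np.testing.assert_allclose(cam, expected, atol=1e-10)


class TestBuildNetwork:
    def test_desk_profile_returns_runnable_model(self):
        alloc = ss.allocate_stem_kernels([0.5, 0.3, 0.2], total=32)
        spec, model = ss.build_network("B2", 3, 2, ob=True, allocation=alloc,
                                       profile="desk")
        assert spec.stem_width == 32 and spec.ob_allocation is alloc
        logits = model.forward(np.zeros((1, 3, 16, 16)))
        assert logits.shape == (1, 2)

    def test_full_profile_audit_only(self):
        spec, model = ss.build_network("B0", 3, 2)
        assert model is None
        assert ss.count_learnable_parameters(spec) > 4_000_000

    def test_ob_requires_allocation(self):
        with pytest.raises(AllocationError):
            ss.build_network("B2", 3, 2, ob=True)
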