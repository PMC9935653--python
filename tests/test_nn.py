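"""Network, loss and segmenter contracts at desk scale."""

import numpy as np
import pytest

from thalseg import ScannerProfile, ThalamusSegmenter, make_phantom, scaled_spec
from thalseg.nn import (
    NetConfig,
    UNet3D,
    composite_loss_and_grad,
    one_hot,
    softmax,
)
from thalseg.segmenter import hard_dice, volumes_from_labels
from thalseg.image_io import LabelMap, VolumeImage


def test_bottleneck_extent_after_four_reductions():
    """160^3 input with four halvings reaches a 10^3 bottleneck."""
    assert 160 // 2**4 == 10
    cfg = NetConfig(patch_size=160, depth=4)
    assert cfg.patch_size // 2**cfg.depth == 10


def test_patch_not_divisible_by_depth_is_rejected():
    with pytest.raises(ValueError, match="divisible"):
        NetConfig(patch_size=30, depth=2)


def test_output_shape_and_softmax_normalization(rng):
    net = UNet3D(NetConfig(patch_size=16, depth=2, base_channels=4), seed=0)
    x = rng.standard_normal((1, 16, 16, 16)).astype(np.float32)
    logits = net.forward(x)
    assert logits.shape == (5, 16, 16, 16)
    probs = softmax(logits)
    np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)
    assert (probs >= 0).all() and (probs <= 1).all()


def test_seeded_initialization_is_deterministic():
    cfg = NetConfig(patch_size=16, depth=2, base_channels=4)
    p1 = UNet3D(cfg, seed=3).params()
    p2 = UNet3D(cfg, seed=3).params()
    for a, b in zip(p1, p2):
        np.testing.assert_array_equal(a.value, b.value)


def test_gradients_match_finite_differences(rng):
    """Backprop through conv / instance norm / residual blocks / the
    composite loss agrees with central finite differences."""
    net = UNet3D(
        NetConfig(patch_size=8, depth=1, base_channels=2, n_classes=3),
        seed=1,
        dtype=np.float64,
    )
    x = rng.standard_normal((1, 8, 8, 8))
    labels = rng.integers(0, 3, (8, 8, 8))

    def loss():
        return composite_loss_and_grad(net.forward(x), labels)[0]

    _, dlogits, _ = composite_loss_and_grad(net.forward(x), labels)
    net.forward(x)
    net.backward(dlogits)
    params = net.params()
    for p in [params[0], params[2], params[5], params[-2], params[-1]]:
        idx = tuple(rng.integers(0, s) for s in p.value.shape)
        eps = 1e-6
        orig = p.value[idx]
        p.value[idx] = orig + eps
        lp = loss()
        p.value[idx] = orig - eps
        lm = loss()
        p.value[idx] = orig
        numeric = (lp - lm) / (2 * eps)
        assert abs(numeric - p.grad[idx]) <= 1e-5 * max(1.0, abs(numeric))


def test_perfect_prediction_minimizes_composite_loss(rng):
    """One-hot logits equal to the target give cross-entropy ~0 and a soft
    Dice term ~0 (the analytic minimum)."""
    labels = rng.integers(0, 5, (8, 8, 8))
    logits = one_hot(labels, 5).astype(np.float64) * 50.0  # ~hard softmax
    loss, _, parts = composite_loss_and_grad(logits, labels)
    assert parts["ce"] < 1e-6
    assert parts["dice_loss"] < 1e-6
    assert loss < 1e-5


def test_training_is_deterministic_given_seed(small_spec, identity_profile):
    pairs = [make_phantom(small_spec, identity_profile, s) for s in range(3)]
    X = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    runs = []
    for _ in range(2):
        est = ThalamusSegmenter(
            patch_size=16, depth=2, base_channels=4, epochs_stage1=1,
            epochs_stage2=0, augment=None, val_fraction=0.0, random_state=5,
        )
        est.fit(X, y)
        runs.append(est.history_[0]["loss"])
    assert runs[0] == runs[1]


def test_overfits_three_phantoms(small_spec):
    """Memorization sanity check: a correct implementation must fit three
    easy samples to high soft-Dice."""
    profile = ScannerProfile(noise_std=1.0, bias_amplitude=0.05)
    pairs = [make_phantom(small_spec, profile, s) for s in range(3)]
    X = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    est = ThalamusSegmenter(
        patch_size=16, depth=2, base_channels=8, epochs_stage1=60,
        epochs_stage2=20, augment=None, val_fraction=0.0,
        uniform_crop_fraction=0.15, random_state=0,
    )
    est.fit(X, y)
    dices = [
        hard_dice(est.predict(v).label_map.data, l.data, (1, 2))
        for v, l in zip(X, y)
    ]
    assert np.mean(dices) >= 0.80
    # loss keeps falling through training and ends well below its start
    assert est.history_[-1]["loss"] < 0.6
    assert est.history_[-1]["loss"] < 0.25 * est.history_[0]["loss"]


def test_label_outside_codebook_names_sample(small_spec, identity_profile):
    v, l, _ = make_phantom(small_spec, identity_profile, 0)
    est = ThalamusSegmenter(n_classes=3)
    with pytest.raises(ValueError, match="sample 0"):
        est.fit([v], [l])


def test_single_patch_volume_equals_one_forward_pass(rng):
    """A volume exactly one patch in size is segmented by a single pass."""
    est = ThalamusSegmenter(patch_size=16, depth=2, base_channels=4, random_state=1)
    est.config_ = est._make_config()
    est.net_ = est.build_network()
    data = rng.standard_normal((16, 16, 16)).astype(np.float32)
    v = VolumeImage(data)
    result = est.predict(v)
    assert result.log["n_patches"] == 1
    direct = np.argmax(est.net_.forward(est._norm(data)[None]), axis=0)
    np.testing.assert_array_equal(result.label_map.data, direct)


def test_tiling_agrees_with_dense_sliding_window(rng):
    """50%-overlap tiling vs an exhaustive stride-1 sliding window on a toy
    volume: identical labels wherever the dense window is locally unanimous."""
    est = ThalamusSegmenter(patch_size=16, depth=2, base_channels=4, random_state=2)
    est.config_ = est._make_config()
    est.net_ = est.build_network()
    data = rng.standard_normal((24, 24, 24)).astype(np.float32)
    v = VolumeImage(data)
    tiled = est.predict(v).label_map.data

    norm = est._norm(data)
    ps = 16
    votes = [[[set() for _ in range(24)] for _ in range(24)] for _ in range(24)]
    for z in range(0, 24 - ps + 1, 4):
        for yy in range(0, 24 - ps + 1, 4):
            for x in range(0, 24 - ps + 1, 4):
                pred = np.argmax(
                    est.net_.forward(norm[z : z + ps, yy : yy + ps, x : x + ps][None]),
                    axis=0,
                )
                for dz in range(ps):
                    for dy in range(ps):
                        for dx in range(ps):
                            votes[z + dz][yy + dy][x + dx].add(int(pred[dz, dy, dx]))
    checked = 0
    for z in range(24):
        for yy in range(24):
            for x in range(24):
                s = votes[z][yy][x]
                if len(s) == 1:
                    assert tiled[z, yy, x] == s.pop()
                    checked += 1
    assert checked > 100  # the oracle actually constrained something


def test_small_volume_is_padded_and_logged(rng):
    est = ThalamusSegmenter(patch_size=16, depth=2, base_channels=4, random_state=0)
    est.config_ = est._make_config()
    est.net_ = est.build_network()
    v = VolumeImage(rng.standard_normal((10, 16, 12)).astype(np.float32))
    result = est.predict(v)
    assert result.label_map.data.shape == (10, 16, 12)
    assert "padded" in result.log


def test_volumes_from_labels_unit_conversion():
    labels = np.zeros((20, 20, 20), dtype=np.int16)
    labels.ravel()[:1000] = 1
    lm = LabelMap(labels)
    out = volumes_from_labels(lm)
    assert out["left_thalamus"] == pytest.approx(1.0)
    assert out["THALV"] == pytest.approx(1.0)
    assert out["TIV"] == pytest.approx(1.0)


def test_volumes_from_empty_label_map():
    out = volumes_from_labels(LabelMap(np.zeros((8, 8, 8), dtype=np.int16)))
    assert all(v == 0.0 for v in out.values())


def test_scores_sum_to_one_and_argmax_matches_labels(small_spec, identity_profile):
    v, _, _ = make_phantom(small_spec, identity_profile, 2)
    est = ThalamusSegmenter(patch_size=16, depth=2, base_channels=4, random_state=0)
    est.config_ = est._make_config()
    est.net_ = est.build_network()
    result = est.predict(v)
    np.testing.assert_allclose(result.scores.sum(axis=0), 1.0, atol=1e-4)
    np.testing.assert_array_equal(
        np.argmax(result.scores, axis=0), result.label_map.data
    )


def test_checkpoint_round_trip(tmp_path, rng, small_spec, identity_profile):
    v, _, _ = make_phantom(small_spec, identity_profile, 4)
    est = ThalamusSegmenter(patch_size=16, depth=2, base_channels=4, random_state=3)
    est.config_ = est._make_config()
    est.net_ = est.build_network()
    before = est.predict(v).label_map.data
    path = tmp_path / "model.npz"
    est.save(path)
    est2 = ThalamusSegmenter.load(path)
    np.testing.assert_array_equal(est2.predict(v).label_map.data, before)
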