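import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from histostack.register2d import (
    RegistrationParams,
    Transform2D,
    WeightedTarget,
    apply_transform,
    compose,
    endpoint_error,
    invert,
    mutual_information,
    register_pair,
)


def brute_force_mi(a, b, bins):
    """Independent oracle: explicit joint histogram and plogp sums."""
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    ea = np.linspace(a.min(), a.max(), bins + 1)
    eb = np.linspace(b.min(), b.max(), bins + 1)
    ia = np.clip(np.searchsorted(ea, a, side="right") - 1, 0, bins - 1)
    ib = np.clip(np.searchsorted(eb, b, side="right") - 1, 0, bins - 1)
    joint = np.zeros((bins, bins))
    for x, y in zip(ia, ib):
        joint[x, y] += 1
    p = joint / joint.sum()
    mi = 0.0
    px, py = p.sum(1), p.sum(0)
    for i in range(bins):
        for j in range(bins):
            if p[i, j] > 0:
                mi += p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
    return mi


class TestMutualInformation:
    def test_two_level_rasters_match_hand_computation(self):
        # 4x4 two-level images with known joint counts:
        # (0,0): 6, (0,1): 2, (1,0): 1, (1,1): 7
        a = np.array([0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1]).reshape(4, 4)
        b = np.array([0, 0, 0, 0, 0, 0, 1, 1, 0, 1, 1, 1, 1, 1, 1, 1]).reshape(4, 4)
        p = np.array([[6, 2], [1, 7]]) / 16.0
        px, py = p.sum(1), p.sum(0)
        expected = sum(
            p[i, j] * np.log2(p[i, j] / (px[i] * py[j])) for i in range(2) for j in range(2)
        )
        assert mutual_information(a, b, bins=2) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        a = rng.random((8, 8))
        b = rng.random((8, 8))
        assert mutual_information(a, b, bins=4) == pytest.approx(brute_force_mi(a, b, 4), abs=1e-12)

    def test_self_mi_equals_entropy(self, rng):
        a = rng.random((32, 32))
        h, _ = np.histogram(a, bins=8)
        p = h / h.sum()
        entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert mutual_information(a, a, bins=8) == pytest.approx(entropy, abs=1e-12)

    def test_independent_noise_mi_near_zero(self):
        r = np.random.default_rng(0)
        a, b = r.random((100, 100)), r.random((100, 100))
        assert mutual_information(a, b, bins=8) < 0.05

    def test_constant_image_gives_zero(self):
        assert mutual_information(np.zeros((8, 8)), np.arange(64.0).reshape(8, 8)) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.random((16, 16)), r.random((16, 16))
        assert mutual_information(a, b, 8) == pytest.approx(mutual_information(b, a, 8), abs=1e-12)


class TestTransforms:
    def test_apply_identity(self, rng):
        img = rng.random((20, 20))
        np.testing.assert_allclose(apply_transform(img, Transform2D.identity(img.shape)), img)

    def test_integer_translation_exact(self):
        img = np.arange(100.0).reshape(10, 10)
        t = Transform2D(affine=np.array([[1.0, 0, 2], [0, 1.0, 3]]), shape=(10, 10))
        out = apply_transform(img, t)
        np.testing.assert_array_equal(out[:8, :7], img[2:, 3:])

    def test_apply_then_inverse_recovers(self, rng):
        img = ndi.gaussian_filter(rng.random((64, 64)), 2)
        field = np.stack([ndi.gaussian_filter(rng.standard_normal((64, 64)), 12) for _ in range(2)])
        field *= 4.0 / np.sqrt((field**2).sum(0)).mean()
        t = Transform2D(field=field)
        warped = apply_transform(img, t)
        back = apply_transform(warped, invert(t, 60, 1e-4))
        core = np.abs(back - img)[8:-8, 8:-8]
        assert core.mean() < 0.01 * np.ptp(img)

    def test_compose_identity_is_noop(self, rng):
        field = np.stack([ndi.gaussian_filter(rng.standard_normal((32, 32)), 8) for _ in range(2)])
        t = Transform2D(field=field)
        ident = Transform2D.identity((32, 32))
        np.testing.assert_allclose(
            compose(ident, t).displacement(), t.displacement(), atol=1e-9
        )

    def test_compose_translations_sum(self):
        t1 = Transform2D(affine=np.array([[1.0, 0, 1.5], [0, 1.0, -2.0]]), shape=(16, 16))
        t2 = Transform2D(affine=np.array([[1.0, 0, 0.5], [0, 1.0, 3.0]]), shape=(16, 16))
        d = compose(t1, t2).displacement()
        np.testing.assert_allclose(d[0], 2.0, atol=1e-9)
        np.testing.assert_allclose(d[1], 1.0, atol=1e-9)

    def test_compose_matches_sequential_apply(self, rng):
        img = ndi.gaussian_filter(rng.random((48, 48)), 2) * 100
        mk = lambda s: Transform2D(
            field=np.stack(
                [ndi.gaussian_filter(np.random.default_rng(s + d).standard_normal((48, 48)), 10) * 8 for d in range(2)]
            )
        )
        t1, t2 = mk(1), mk(5)
        seq = apply_transform(apply_transform(img, t1), t2)
        once = apply_transform(img, compose(t1, t2))
        core = np.abs(seq - once)[6:-6, 6:-6]
        assert core.mean() < 0.02 * np.ptp(img)


class TestRegisterPair:
    def test_identity_recovery(self, small_phantom):
        bf = small_phantom.blockface.voxels[9]
        t = register_pair(bf, [WeightedTarget(bf)], RegistrationParams(iterations_per_scale=15))
        assert np.abs(t.displacement()).mean() < 0.1

    def test_known_translation_recovery_cross_contrast(self, rng):
        base = ndi.gaussian_filter(rng.random((128, 128)), 3)
        base = (base - base.min()) / np.ptp(base)
        img = np.zeros((128, 128))
        img[20:100, 30:110] = base[20:100, 30:110] * 200 + 50
        target = 255 - 0.5 * img  # monotone lookup
        t_true = Transform2D(affine=np.array([[1.0, 0, 4.0], [0, 1.0, -7.0]]), shape=img.shape)
        moving = apply_transform(img, t_true)
        t = register_pair(moving, [WeightedTarget(target)])
        assert endpoint_error(t, t_true, img > 60) < 0.5

    def test_phantom_cross_contrast_warp_recovery(self, small_phantom):
        key = (9, "nissl")
        sec = small_phantom.section(*key)
        bf = small_phantom.blockface.voxels[9]
        mask = small_phantom.truth.label_volume.voxels[9] > 0
        t = register_pair(sec.pixels, [WeightedTarget(bf)])
        assert endpoint_error(t, small_phantom.truth.true_fields[key], mask) < 2.0

    def test_metric_trace_non_decreasing_across_levels(self, small_phantom):
        key = (9, "nissl")
        sec = small_phantom.section(*key)
        t = register_pair(sec.pixels, [WeightedTarget(small_phantom.blockface.voxels[9])])
        trace = t.meta["trace"]
        assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_requires_positive_weight(self, rng):
        img = rng.random((32, 32))
        with pytest.raises(ValueError):
            register_pair(img, [WeightedTarget(img, weight=0.0)])

    def test_contrast_invariance_monotone_lookup(self, small_phantom):
        # same section registered against two monotone re-mappings of the
        # blockface must give similar errors: the property MI provides
        key = (10, "bielschowsky")
        sec = small_phantom.section(*key)
        bf = small_phantom.blockface.voxels[9]
        mask = small_phantom.truth.label_volume.voxels[9] > 0
        tt = small_phantom.truth.true_fields[key]
        e1 = endpoint_error(register_pair(sec.pixels, [WeightedTarget(bf)]), tt, mask)
        e2 = endpoint_error(
            register_pair(sec.pixels, [WeightedTarget(300.0 - np.sqrt(bf) * 12)]), tt, mask
        )
        assert e2 < 2.0 and abs(e2 - e1) < 1.0
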