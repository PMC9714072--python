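"""Block-matching registration: rigid recovery, dense field, composition."""

import numpy as np
import pytest

from rhizotrack.core import RigidTransform
from rhizotrack.register import (RegistrationError, compose_daisychain,
                                 estimate_dense_field,
                                 estimate_rigid_blockmatching, resample)
from conftest import small_params
from rhizotrack.simulate import simulate_plate


@pytest.fixture(scope="module")
def textured():
    """A root-bearing frame to register against (rich local structure)."""
    plate = simulate_plate(small_params(n_timesteps=6, seed=5))
    return plate.stack.frames[-1]


def _center(img):
    return ((img.shape[1] - 1) / 2.0, (img.shape[0] - 1) / 2.0)


class TestRigid:
    def test_identical_images_give_identity(self, textured):
        t, rep = estimate_rigid_blockmatching(textured, textured)
        assert abs(t.dx) < 0.25 and abs(t.dy) < 0.25
        assert abs(np.degrees(t.theta)) < 0.05

    def test_known_translation_recovered(self, textured):
        gt = RigidTransform(0.0, 12.0, -5.0, _center(textured))
        moving = resample(textured, gt.inverse())
        t, _ = estimate_rigid_blockmatching(moving, textured)
        assert abs(t.dx - 12.0) < 0.5 and abs(t.dy + 5.0) < 0.5

    def test_known_rotation_recovered(self, textured):
        gt = RigidTransform(np.radians(1.5), 0.0, 0.0, _center(textured))
        moving = resample(textured, gt.inverse())
        t, _ = estimate_rigid_blockmatching(moving, textured)
        assert abs(np.degrees(t.theta) - 1.5) < 0.1

    def test_uniform_image_raises_not_identity(self):
        flat = np.full((300, 300), 180.0, dtype=np.float32)
        with pytest.raises(RegistrationError):
            estimate_rigid_blockmatching(flat, flat)


class TestDense:
    def test_identical_images_give_zero_field(self, textured):
        field = estimate_dense_field(textured, textured)
        assert field.max_magnitude() < 0.25

    def test_uniform_images_give_zero_field(self):
        flat = np.full((300, 300), 100.0, dtype=np.float32)
        field = estimate_dense_field(flat, flat + 0.0)
        assert field.max_magnitude() == 0.0

    def test_smooth_warp_recovered(self, textured):
        rows, cols = textured.shape
        yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
        cy, cx = rows / 2, cols / 2
        bump = 4.0 * np.exp(-(((yy - cy) / 90) ** 2 + ((xx - cx) / 90) ** 2))
        from scipy.ndimage import map_coordinates
        moving = map_coordinates(textured, [yy + bump, xx], order=1,
                                 mode="nearest").astype(np.float32)
        field = estimate_dense_field(moving, textured)
        est = field.sample(np.column_stack([xx.ravel(), yy.ravel()]))[:, 1]
        true = bump.ravel()
        # evaluate where the images carry structure: blocks on featureless
        # background are (correctly) discarded and the field is zero there
        from scipy.ndimage import binary_dilation
        support = binary_dilation(textured < 150, iterations=12).ravel()
        assert support.any()
        err = np.sum((est[support] - true[support]) ** 2)
        energy = np.sum(true[support] ** 2)
        assert 1.0 - err / energy >= 0.8


class TestCompose:
    def test_identities_compose_to_identity(self):
        ident = RigidTransform(0, 0, 0, (10, 10))
        composed = compose_daisychain([ident, ident, ident], n_t=4)
        assert len(composed) == 3
        for c in composed:
            net = c.net_rigid()
            assert net.is_identity(tol=1e-12)

    def test_translations_accumulate(self):
        step = RigidTransform(0.0, 1.0, 0.0, (50, 50))
        composed = compose_daisychain([step] * 3, n_t=4)
        net = composed[0].net_rigid()
        assert net.dx == pytest.approx(3.0) and net.dy == pytest.approx(0.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compose_daisychain([RigidTransform()], n_t=4)

    def test_single_resampling_matches_sequential(self, textured):
        steps = [RigidTransform(np.radians(0.4), 1.5, -0.8, _center(textured))
                 for _ in range(3)]
        composed = compose_daisychain(steps, n_t=4)[0]
        pts = np.array([[30.0, 40.0], [250.0, 260.0]])
        seq = pts.copy()
        for s in steps:
            seq = s.apply(seq)
        once = composed.map_points(pts)
        assert np.abs(once - seq).max() < 0.5


class TestResample:
    def test_identity_returns_copy(self, textured):
        out = resample(textured, RigidTransform(0, 0, 0, _center(textured)))
        np.testing.assert_array_equal(out, textured)

    def test_integer_translation_is_exact_shift(self, textured):
        t = RigidTransform(0.0, 3.0, 0.0, _center(textured))
        out = resample(textured, t, fill=0.0)
        np.testing.assert_allclose(out[:, 3:], textured[:, :-3], atol=1e-4)

    def test_half_pixel_shift_averages_step_edge(self):
        img = np.zeros((9, 10), dtype=np.float32)
        img[:, 5:] = 100.0
        t = RigidTransform(0.0, 0.5, 0.0, (4.5, 4.0))
        out = resample(img, t, fill=0.0)
        # output(x=5) samples input at x=4.5: bilinear average of 0 and 100
        assert out[4, 5] == pytest.approx(50.0, abs=1e-3)


def test_registration_recovers_simulated_jitter():
    from rhizotrack.validate import registration_recovery
    from rhizotrack.simulate import SimParams

    params = SimParams(n_plants=2, n_timesteps=4, image_shape=(320, 320),
                       px_size_um=130.0, jitter=(6.0, 0.6),
                       crossing_bias=0.0, artifact_rate=0.0, seed=21)
    res = registration_recovery(params=params)
    assert res["max_translation_err_px"] < 0.5
    assert res["max_rotation_err_deg"] < 0.1
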