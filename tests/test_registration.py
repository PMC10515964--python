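"""Registration engine: recovery harnesses, transform algebra, serialization."""

import numpy as np
import pytest
from scipy import ndimage

from devatlas.registration import (Grid, RegistrationSpec, Transform,
                                   apply_transform, average_transforms,
                                   compose_transforms, load_transform,
                                   metric_value, register, save_transform)
from devatlas.synthetic import smooth_field


@pytest.fixture(scope="module")
def image(phantom48):
    return phantom48.image.data


@pytest.fixture(scope="module")
def mask(phantom48):
    return phantom48.mask.data.astype(bool)


def _warp_pair(image, seed=3, magnitude=4.0):
    """Moving image such that registering it to `image` recovers field u."""
    shape = image.shape
    rng = np.random.default_rng(seed)
    u = smooth_field(shape, magnitude, 6.0, rng)
    mesh = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                indexing="ij"), axis=-1)
    x = mesh.copy()
    for _ in range(30):  # invert m(x) = x + u(x) by fixed point
        coords = np.moveaxis(x.reshape(-1, 3), -1, 0)
        ux = np.stack([ndimage.map_coordinates(u[..., d], coords, order=1,
                                               mode="nearest").reshape(shape)
                       for d in range(3)], axis=-1)
        x = mesh - ux
    coords = np.moveaxis(x.reshape(-1, 3), -1, 0)
    moving = ndimage.map_coordinates(image, coords, order=1,
                                     mode="nearest").reshape(shape)
    return moving, u


class TestLinear:
    def test_known_translation_recovered(self, image):
        from devatlas.volume import ImageVolume

        moving = ndimage.shift(image, (3, 2, 1), order=1)
        spec = RegistrationSpec(mode="linear", metric="mean_squared_error",
                                affine_dof=3)
        t = register(ImageVolume(image), ImageVolume(moving), spec)
        assert np.all(np.abs(t.affine[:3, 3] - (3, 2, 1)) < 0.25)

    def test_self_registration_is_identity(self, image):
        from devatlas.volume import ImageVolume

        spec = RegistrationSpec(mode="linear", metric="mean_squared_error")
        t = register(ImageVolume(image), ImageVolume(image), spec)
        assert np.abs(t.affine - np.eye(4)).max() < 1e-3


class TestNonlinear:
    def test_known_smooth_warp_recovered(self, image, mask):
        from devatlas.volume import ImageVolume

        moving, u = _warp_pair(image)
        spec = RegistrationSpec(mode="nonlinear", metric="mean_squared_error",
                                levels=(4, 2, 1), iterations=(100, 60, 30),
                                smoothing_sigmas=(2.0, 1.0, 0.0))
        t = register(ImageVolume(image), ImageVolume(moving), spec)
        err = np.linalg.norm(t.warp - u, axis=-1)
        assert err[mask].mean() < 1.0

    def test_self_registration_nonlinear(self, image):
        from devatlas.volume import ImageVolume

        spec = RegistrationSpec(mode="nonlinear", metric="mean_squared_error",
                                levels=(4, 2), iterations=(30, 15),
                                smoothing_sigmas=(1.0, 0.5))
        t = register(ImageVolume(image), ImageVolume(image), spec)
        assert np.abs(t.warp).max() < 0.5

    def test_inverse_consistency(self, image, mask):
        from devatlas.volume import ImageVolume

        moving, _ = _warp_pair(image)
        spec = RegistrationSpec(mode="nonlinear", metric="mean_squared_error",
                                levels=(4, 2, 1), iterations=(60, 40, 20),
                                smoothing_sigmas=(2.0, 1.0, 0.0))
        t = register(ImageVolume(image), ImageVolume(moving), spec)
        g = Grid(image.shape, (1.0,) * 3, (0.0,) * 3)
        pts = t.map_points(g.world_mesh())
        back = t.inverse().map_points(pts)
        err = np.linalg.norm(back - g.world_mesh(), axis=-1)
        assert err[mask].max() < 0.5

    def test_mi_invariant_to_contrast_flip(self, image, mask):
        from devatlas.volume import ImageVolume

        flipped = image.max() - image
        spec = RegistrationSpec(mode="linear_then_nonlinear",
                                metric="mutual_information",
                                levels=(4, 2), iterations=(40, 20),
                                smoothing_sigmas=(1.0, 0.5))
        t = register(ImageVolume(image), ImageVolume(flipped), spec)
        assert np.abs(t.affine - np.eye(4)).max() < 0.2
        warp_mag = np.linalg.norm(t.warp, axis=-1)
        assert warp_mag[mask].mean() < 1.0

    def test_metric_never_worse_than_identity(self, image, rng):
        from devatlas.volume import ImageVolume

        # pure noise pair: registration may do nothing, never harm
        noise = rng.random(image.shape)
        spec = RegistrationSpec(mode="nonlinear", metric="mean_squared_error",
                                levels=(4,), iterations=(20,),
                                smoothing_sigmas=(1.0,))
        t = register(ImageVolume(image), ImageVolume(noise), spec)
        warped = apply_transform(ImageVolume(noise), t, ImageVolume(image))
        before = metric_value(image, noise, "mean_squared_error")
        after = metric_value(image, warped.data, "mean_squared_error")
        assert after <= before + 1e-9


class TestErrors:
    def test_empty_channels(self):
        with pytest.raises(ValueError, match="empty"):
            register([], [], RegistrationSpec())

    def test_non_finite_voxels(self):
        from devatlas.volume import ImageVolume

        bad = np.zeros((8, 8, 8))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            register(ImageVolume(bad), ImageVolume(np.zeros((8, 8, 8))),
                     RegistrationSpec())

    def test_bad_weights(self):
        with pytest.raises(ValueError, match="weights"):
            RegistrationSpec(channel_weights=(0.0, 0.0))


class TestApply:
    def test_identity_transform_is_resample_only(self, image):
        from devatlas.volume import ImageVolume

        v = ImageVolume(image)
        out = apply_transform(v, Transform.identity(3), v)
        assert np.allclose(out.data, image)

    def test_apply_then_inverse_restores(self, image):
        from devatlas.volume import ImageVolume

        v = ImageVolume(image)
        t = Transform.from_translation((2.0, -1.0, 0.5))
        fwd = apply_transform(v, t, v)
        back = apply_transform(fwd, t.inverse(), v)
        core = (slice(4, -4),) * 3
        assert np.abs(back.data[core] - image[core]).mean() < 0.02

    def test_labels_through_nearest(self, rng):
        from devatlas.volume import ImageVolume

        labels = ImageVolume(rng.integers(0, 4, (12, 12, 12)).astype(np.int32))
        t = Transform.from_translation((1.3, 0.0, -0.7))
        out = apply_transform(labels, t, labels, interpolation="nearest")
        assert set(np.unique(out.data)) <= set(np.unique(labels.data))


class TestCompose:
    def test_compose_with_inverse_is_identity(self):
        t = Transform.from_translation((2.0, 1.0, -1.0))
        c = compose_transforms([t, t.inverse()])
        assert np.abs(c.affine - np.eye(4)).max() < 1e-9

    def test_translations_sum(self):
        a = Transform.from_translation((1.0, 0.0, 0.0))
        b = Transform.from_translation((0.0, 2.0, 0.0))
        c = compose_transforms([a, b])
        assert np.allclose(c.affine[:3, 3], (1.0, 2.0, 0.0))

    def test_matrix_convention_point_oracle(self, rng):
        """compose([A, B]) maps x -> B(A(x)), i.e. matrix B @ A."""
        A = np.eye(4)
        A[:3, :3] = ndimage.rotate(np.eye(3), 0, reshape=False)  # identity base
        A[:3, 3] = (1.0, 2.0, 3.0)
        A[0, 1] = 0.1
        B = np.eye(4)
        B[:3, 3] = (-2.0, 0.5, 1.0)
        B[1, 2] = -0.2
        c = compose_transforms([Transform(A), Transform(B)])
        assert np.allclose(c.affine, B @ A)
        pts = rng.random((10, 3)) * 10
        seq = Transform(B).map_points(Transform(A).map_points(pts))
        assert np.allclose(c.affine[:3, :3] @ pts.T + c.affine[:3, 3:4],
                           seq.T)

    def test_composite_equals_sequential_on_images(self, phantom_small):
        """Applying the composite equals applying the list in reverse order."""
        v = phantom_small.image
        t1 = Transform.from_translation((1.0, 0.0, 0.0))
        t2 = Transform.from_translation((0.0, 2.0, 0.0))
        seq = apply_transform(apply_transform(v, t2, v), t1, v)
        comp = apply_transform(v, compose_transforms([t1, t2]), v)
        core = (slice(3, -3),) * 3
        assert np.abs(seq.data[core] - comp.data[core]).max() < 0.25


class TestAverage:
    def test_opposite_displacements_cancel(self):
        g = Grid((8, 8, 8), (1.0,) * 3, (0.0,) * 3)
        d = np.ones(g.shape + (3,))
        a = Transform(np.eye(4), warp=d, grid=g)
        b = Transform(np.eye(4), warp=-d, grid=g)
        avg = average_transforms([a, b])
        assert np.abs(avg.warp).max() < 1e-12

    def test_average_of_identical_is_itself(self):
        t = Transform.from_translation((1.0, 2.0, 3.0))
        avg = average_transforms([t, t, t])
        assert np.allclose(avg.affine, t.affine)

    def test_translation_mean(self):
        a = Transform.from_translation((1.0, 0.0, 0.0))
        b = Transform.from_translation((3.0, 0.0, 0.0))
        avg = average_transforms([a, b])
        assert np.allclose(avg.affine[:3, 3], (2.0, 0.0, 0.0))

    def test_mixed_grids_rejected(self):
        g1 = Grid((4, 4, 4), (1.0,) * 3, (0.0,) * 3)
        g2 = Grid((5, 5, 5), (1.0,) * 3, (0.0,) * 3)
        a = Transform(np.eye(4), warp=np.zeros(g1.shape + (3,)), grid=g1)
        b = Transform(np.eye(4), warp=np.zeros(g2.shape + (3,)), grid=g2)
        with pytest.raises(ValueError, match="grids"):
            average_transforms([a, b])


def test_serialization_round_trip_bit_exact(tmp_path, rng):
    g = Grid((6, 6, 6), (1.0,) * 3, (0.0,) * 3)
    warp = rng.standard_normal(g.shape + (3,))
    t = Transform(np.diag([1.0, 2.0, 0.5, 1.0]), warp=warp,
                  inverse_warp=-warp, grid=g)
    save_transform(t, tmp_path / "t")
    t2 = load_transform(tmp_path / "t")
    assert np.array_equal(t.affine, t2.affine)
    assert np.array_equal(t.warp, t2.warp)
    assert np.array_equal(t.inverse_warp, t2.inverse_warp)
    assert t2.grid.compatible(t.grid)


class TestExternalBackend:
    """An independently implemented registration toolkit plugged behind the
    same contract must pass the same recovery thresholds as the built-in
    engine."""

    def test_translation_recovery_parity(self, image):
        pytest.importorskip("SimpleITK")
        from devatlas.sitk_backend import sitk_register
        from devatlas.volume import ImageVolume

        moving = ndimage.shift(image, (3, 2, 1), order=1)
        spec = RegistrationSpec(mode="linear", metric="mean_squared_error",
                                affine_dof=3)
        t = sitk_register(ImageVolume(image), ImageVolume(moving), spec)
        assert np.all(np.abs(t.affine[:3, 3] - (3, 2, 1)) < 0.25)

    def test_usable_as_template_engine(self, phantom_small):
        pytest.importorskip("SimpleITK")
        from devatlas.sitk_backend import sitk_register
        from devatlas.template import Cohort, SubjectRecord, build_template

        spec = RegistrationSpec(mode="linear", metric="mean_squared_error",
                                affine_dof=3)
        c = Cohort([SubjectRecord("a", phantom_small.image),
                    SubjectRecord("b", phantom_small.image)])
        res = build_template(c, engine=sitk_register, spec=spec, n_iter=1)
        for t in res.transforms.values():
            assert np.abs(t.affine[:3, 3]).max() < 0.5
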