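"""2-D section series -> 3-D template mapping."""

import numpy as np
import pytest

from devatlas.ish import (adjacent_slice_ncc, align_template_linear,
                          bspline_fill, map_to_template, preprocess_slices,
                          run_chain, slicewise_refine, split_genes)
from devatlas.registration import RegistrationSpec, Transform, Grid
from devatlas.synthetic import PhantomSpec, make_ish_series, make_phantom
from devatlas.volume import ImageVolume, SliceSeries


@pytest.fixture(scope="module")
def ish_phantom():
    return make_phantom(PhantomSpec(shape=(64, 64, 48), n_random=10, seed=4))


def _series(slices, zs=None, mask=None, genes=None):
    n = len(slices) if mask is None else len(mask)
    zs = np.arange(n, dtype=float) if zs is None else zs
    mask = np.ones(n, dtype=bool) if mask is None else np.asarray(mask)
    return SliceSeries(slices=slices, z_positions=zs, present_mask=mask,
                       channel_of_slice=genes)


class TestPreprocess:
    def test_zero_slice_becomes_one(self):
        s = _series([np.zeros((8, 8)), np.ones((8, 8))])
        out = preprocess_slices(s, size=8)
        assert np.allclose(out.slices[0], 1.0)
        assert np.allclose(out.slices[1], 0.0)

    def test_resampled_to_working_size(self, rng):
        s = _series([rng.random((128, 128)) for _ in range(2)])
        out = preprocess_slices(s, size=64)
        assert all(sl.shape == (64, 64) for sl in out.slices)

    def test_aspect_preserved_by_padding(self, rng):
        s = _series([rng.random((40, 20)) for _ in range(2)])
        out = preprocess_slices(s, size=40)
        assert out.slices[0].shape == (40, 40)
        # padding is background (0 after inversion: white field -> no signal)
        assert np.allclose(out.slices[0][:, :10], 0.0)
        assert np.allclose(out.slices[0][:, 30:], 0.0)

    def test_inversion_is_involution(self, rng):
        raw = rng.random((16, 16))
        s = _series([raw, raw])
        once = preprocess_slices(s, size=16)
        twice = preprocess_slices(_series(list(once.slices)), size=16)
        assert np.allclose(twice.slices[0], (raw - raw.min()) / np.ptp(raw),
                           atol=1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            preprocess_slices(_series([], zs=np.array([0.0]),
                                      mask=np.array([False])))


class TestBsplineFill:
    def test_no_missing_slices_stacks_exactly(self, rng):
        slices = [rng.random((8, 8)) for _ in range(5)]
        rec = bspline_fill(_series(slices))
        assert np.array_equal(rec.volume.data,
                              np.stack(slices, axis=-1))

    def test_linear_ramp_reproduced(self):
        nz = 16
        ramp = [np.full((6, 6), z / (nz - 1)) for z in range(nz)]
        mask = np.zeros(nz, dtype=bool)
        mask[::2] = True
        mask[-1] = True
        present = [ramp[i] for i in np.flatnonzero(mask)]
        rec = bspline_fill(_series(present, zs=np.arange(nz, dtype=float),
                                   mask=mask))
        target = np.stack(ramp, axis=-1)
        assert np.abs(rec.volume.data - target).max() < 0.01

    def test_blob_centroid_interpolated(self):
        from scipy import ndimage as ndi

        nz = 7
        slices = []
        for z in range(nz):
            s = np.zeros((32, 32))
            s[10 + z, 16] = 1.0
            slices.append(ndi.gaussian_filter(s, 2.0))
        mask = np.ones(nz, dtype=bool)
        mask[3] = False
        present = [slices[i] for i in np.flatnonzero(mask)]
        rec = bspline_fill(_series(present, zs=np.arange(nz, dtype=float),
                                   mask=mask))
        com = ndi.center_of_mass(rec.volume.data[..., 3])
        assert abs(com[0] - 13) < 1.0

    def test_present_slices_bit_identical(self, rng):
        nz = 9
        mask = np.ones(nz, dtype=bool)
        mask[[2, 5]] = False
        present = [rng.random((8, 8)) for _ in range(int(mask.sum()))]
        rec = bspline_fill(_series(present, zs=np.arange(nz, dtype=float),
                                   mask=mask))
        for i, p in enumerate(np.flatnonzero(mask)):
            assert np.array_equal(rec.volume.data[..., p], present[i])
        for p in np.flatnonzero(~mask):
            assert rec.provenance[p] == "interpolated"

    def test_single_present_slice_rejected(self, rng):
        mask = np.array([True, False, False])
        with pytest.raises(ValueError, match="2 present"):
            bspline_fill(_series([rng.random((4, 4))],
                                 zs=np.arange(3, dtype=float), mask=mask))


class TestSlicewiseRefine:
    def test_identity_when_reference_matches(self, ish_phantom):
        series, _ = make_ish_series(ish_phantom.expression, dz=2,
                                    drop_fraction=0.0, jitter_px=0, seed=1)
        pre = preprocess_slices(series, size=64)
        rec = bspline_fill(pre)
        out = slicewise_refine(rec, rec.volume)
        # registering each slice to itself must leave it nearly unchanged
        assert np.abs(out.volume.data - rec.volume.data).max() < 0.05

    def test_jittered_slice_corrected(self, ish_phantom):
        from scipy import ndimage as ndi

        series, _ = make_ish_series(ish_phantom.image, dz=2,
                                    drop_fraction=0.0, jitter_px=0, seed=1,
                                    invert=False)
        pre = preprocess_slices(series, size=64)
        rec = bspline_fill(pre)
        clean = rec.volume.data.copy()
        k = 10
        rec.volume.data[..., k] = ndi.shift(clean[..., k], (4.0, 0.0),
                                            order=1, mode="nearest")
        ref = rec.volume.copy(data=clean)
        out = slicewise_refine(rec, ref)
        err_before = np.abs(rec.volume.data[..., k] - clean[..., k]).mean()
        err_after = np.abs(out.volume.data[..., k] - clean[..., k]).mean()
        assert err_after < 0.35 * err_before

    def test_consistency_never_decreases(self, ish_phantom):
        series, _ = make_ish_series(ish_phantom.expression, dz=2,
                                    drop_fraction=0.1, jitter_px=3, seed=5)
        pre = preprocess_slices(series, size=64)
        rec = bspline_fill(pre)
        ref = align_template_linear(rec, ish_phantom.image)
        out = slicewise_refine(rec, ref)
        assert adjacent_slice_ncc(out.volume.data) >= \
            adjacent_slice_ncc(rec.volume.data) - 1e-9

    def test_grid_mismatch_rejected(self, ish_phantom, rng):
        series, _ = make_ish_series(ish_phantom.expression, dz=2,
                                    drop_fraction=0.0, jitter_px=0, seed=1)
        rec = bspline_fill(preprocess_slices(series, size=64))
        with pytest.raises(ValueError, match="grid"):
            slicewise_refine(rec, ImageVolume(rng.random((10, 10, 10))))


class TestMapToTemplate:
    def test_template_grid_contract(self, ish_phantom):
        series, _ = make_ish_series(ish_phantom.expression, dz=2,
                                    drop_fraction=0.0, jitter_px=0, seed=1)
        rec = bspline_fill(preprocess_slices(series, size=64))
        spec = RegistrationSpec(mode="linear", metric="mutual_information")
        t, mapped = map_to_template(rec, ish_phantom.image, spec=spec)
        assert mapped.shape == ish_phantom.image.shape
        assert mapped.spacing == ish_phantom.image.spacing

    def test_known_affine_recovered(self, ish_phantom):
        """Reconstruction equal to the template under a known translation:
        the inverse mapping must undo it."""
        from scipy import ndimage as ndi

        tpl = ish_phantom.image
        shifted = ImageVolume(ndi.shift(tpl.data, (3.0, 2.0, 0.0), order=1))
        rec_vol = shifted
        from devatlas.ish import SparseReconstruction

        rec = SparseReconstruction(volume=rec_vol,
                                   present_mask=np.ones(48, dtype=bool),
                                   provenance=["slice"] * 48)
        spec = RegistrationSpec(mode="linear", metric="mean_squared_error",
                                affine_dof=3)
        t, mapped = map_to_template(rec, tpl, spec=spec)
        core = (slice(6, -6),) * 3
        num = np.corrcoef(mapped.data[core].ravel(),
                          tpl.data[core].ravel())[0, 1]
        assert num > 0.99


class TestSplitGenes:
    def _two_gene_recon(self, ish_phantom):
        series, _ = make_ish_series(ish_phantom.expression, dz=2,
                                    drop_fraction=0.0, jitter_px=0,
                                    genes=("A", "B"), seed=1)
        pre = preprocess_slices(series, size=64)
        return bspline_fill(pre)

    def test_gene_bookkeeping(self, ish_phantom):
        rec = self._two_gene_recon(ish_phantom)
        g = Grid.of(ish_phantom.image)
        ident = Transform(np.eye(4), warp=np.zeros(g.shape + (3,)),
                          inverse_warp=np.zeros(g.shape + (3,)), grid=g)
        vols = split_genes(rec, ident, ish_phantom.image)
        assert set(vols) == {"A", "B"}

    def test_single_section_gene_skipped(self, ish_phantom, caplog):
        series, _ = make_ish_series(ish_phantom.expression, dz=8,
                                    drop_fraction=0.0, jitter_px=0,
                                    genes=("A", "A", "A", "A", "A", "B"),
                                    seed=1)
        rec = bspline_fill(preprocess_slices(series, size=64))
        g = Grid.of(ish_phantom.image)
        ident = Transform(np.eye(4), warp=np.zeros(g.shape + (3,)),
                          inverse_warp=np.zeros(g.shape + (3,)), grid=g)
        vols = split_genes(rec, ident, ish_phantom.image)
        assert "B" not in vols


def test_end_to_end_chain_fidelity(ish_phantom):
    """Slice, drop 20%, jitter, run all seven steps against the phantom:
    the mapped volume must correlate strongly with the expression channel."""
    series, _ = make_ish_series(ish_phantom.expression, dz=2,
                                drop_fraction=0.2, jitter_px=4,
                                genes=("A",), seed=7)
    out = run_chain(series, ish_phantom.image, size=64)
    c = np.corrcoef(out["mapped"].data.ravel(),
                    ish_phantom.expression.data.ravel())[0, 1]
    assert c >= 0.9
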