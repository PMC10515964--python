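"""Count downsampling, regional occupancy, cell-type proportions, MTR."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from devatlas.ontology import AnnotationVolume, Ontology, Region
from devatlas.quantify import (cell_type_distribution, compute_mtr,
                               downsample_count, regional_occupancy)
from devatlas.synthetic import make_ontology_and_annotation
from devatlas.volume import ImageVolume


class TestDownsampleCount:
    def test_all_ones_block(self):
        v = ImageVolume(np.ones((4, 4, 4), dtype=np.uint8))
        out = downsample_count(v, 2)
        assert np.all(out.data == 8)
        assert out.data.sum() == 64

    def test_single_positive_voxel(self):
        x = np.zeros((8, 8, 8), dtype=np.uint8)
        x[3, 5, 7] = 1
        out = downsample_count(ImageVolume(x), 4)
        assert out.data.sum() == 1
        assert (out.data == 1).sum() == 1

    def test_anisotropic_factor_block_sum_oracle(self, rng):
        x = (rng.random((32, 32, 32)) > 0.5).astype(np.uint8)
        out = downsample_count(ImageVolume(x), (2, 2, 4))
        expected = x.reshape(16, 2, 16, 2, 8, 4).sum(axis=(1, 3, 5))
        assert np.array_equal(out.data, expected)
        assert out.spacing == (2.0, 2.0, 4.0)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            downsample_count(ImageVolume(np.full((4, 4, 4), 2)), 2)


def _two_region_annot():
    labels = np.zeros((10, 10, 2), dtype=np.int32)
    labels[:5] = 1   # region A: 100 voxels
    labels[5:] = 2   # region B: 100 voxels
    onto = Ontology([Region(1, "A", "A", None), Region(2, "B", "B", None)])
    return AnnotationVolume(ImageVolume(labels), onto), onto


class TestOccupancy:
    def test_all_zero_counts(self):
        annot, onto = _two_region_annot()
        occ = regional_occupancy(ImageVolume(np.zeros((10, 10, 2))), annot,
                                 onto, downsample_factor=2)
        assert (occ.table["ratio"] == 0).all()

    def test_fully_positive_region_ratio_one(self):
        annot, onto = _two_region_annot()
        counts = np.zeros((10, 10, 2))
        counts[annot.data == 1] = 8  # factor 2 -> 8 fine voxels per bin
        occ = regional_occupancy(ImageVolume(counts), annot, onto,
                                 downsample_factor=2)
        assert occ.row(1)["ratio"] == 1.0
        assert occ.row(2)["ratio"] == 0.0

    def test_hand_counted_ratio(self):
        """12 positives in region A of 100 bins x 8 capacity -> 12/800."""
        annot, onto = _two_region_annot()
        counts = np.zeros((10, 10, 2))
        counts[0, 0, 0] = 5
        counts[1, 1, 0] = 7
        occ = regional_occupancy(ImageVolume(counts), annot, onto,
                                 downsample_factor=2)
        assert occ.row(1)["positive"] == 12
        assert occ.row(1)["total_capacity"] == 800
        assert occ.row(1)["ratio"] == 12 / 800

    def test_label_permutation_equivariance(self, rng):
        annot, onto = _two_region_annot()
        counts = ImageVolume(rng.integers(0, 9, (10, 10, 2)).astype(float))
        occ = regional_occupancy(counts, annot, onto, downsample_factor=2)
        swapped = np.where(annot.data == 1, 2, 1).astype(np.int32)
        annot2 = AnnotationVolume(ImageVolume(swapped), onto)
        occ2 = regional_occupancy(counts, annot2, onto, downsample_factor=2)
        assert occ.row(1)["ratio"] == occ2.row(2)["ratio"]
        assert occ.row(2)["ratio"] == occ2.row(1)["ratio"]

    def test_grid_mismatch(self):
        annot, onto = _two_region_annot()
        with pytest.raises(ValueError, match="grid"):
            regional_occupancy(ImageVolume(np.zeros((4, 4, 4))), annot, onto)

    def test_hierarchical_rollup(self):
        onto, annot, mask = make_ontology_and_annotation(
            depth=3, branching=2, shape=(16, 16, 16), seed=2)
        counts = ImageVolume(np.ones(annot.labels.shape))
        occ = regional_occupancy(counts, annot, onto)
        rolled = occ.rolled_up(onto).set_index("region_id")
        assert rolled.loc[1, "positive"] == occ.table["positive"].sum()


class TestCellTypes:
    def _cells(self, rows):
        return pd.DataFrame(rows, columns=["x_mm", "y_mm", "z_mm", "class",
                                           "subclass"])

    def test_single_region_subclass(self):
        annot, _ = _two_region_annot()
        cells = self._cells([(2.0, 2.0, 0.0, "c", "s")])
        m = cell_type_distribution(cells, annot)
        assert m.loc["1", "s"] == 1.0

    def test_three_one_split(self):
        annot, _ = _two_region_annot()
        cells = self._cells([(2.0, 2.0, 0.0, "c", "s")] * 3
                            + [(7.0, 2.0, 0.0, "c", "s")])
        m = cell_type_distribution(cells, annot)
        assert m.loc["1", "s"] == 0.75
        assert m.loc["2", "s"] == 0.25

    def test_outside_cells_unassigned(self):
        annot, _ = _two_region_annot()
        cells = self._cells([(50.0, 2.0, 0.0, "c", "s"),
                             (2.0, 2.0, 0.0, "c", "s")])
        m = cell_type_distribution(cells, annot)
        assert m.loc["unassigned", "s"] == 0.5

    def test_columns_sum_to_one_exactly(self, rng):
        onto, annot, _ = make_ontology_and_annotation(depth=2, branching=3,
                                                      shape=(16, 16, 16),
                                                      seed=3)
        n = 500
        cells = pd.DataFrame({
            "x_mm": rng.uniform(0, 16, n), "y_mm": rng.uniform(0, 16, n),
            "z_mm": rng.uniform(0, 16, n),
            "class": ["c"] * n,
            "subclass": rng.choice(["s1", "s2", "s3"], n),
        })
        m = cell_type_distribution(cells, annot, exact=True)
        for col in m.columns:
            assert sum(m[col]) == Fraction(1, 1)

    def test_brute_force_point_lookup(self, rng):
        onto, annot, _ = make_ontology_and_annotation(depth=2, branching=3,
                                                      shape=(16, 16, 16),
                                                      seed=3)
        n = 500
        cells = pd.DataFrame({
            "x_mm": rng.uniform(0, 16, n), "y_mm": rng.uniform(0, 16, n),
            "z_mm": rng.uniform(0, 16, n),
            "class": ["c"] * n,
            "subclass": rng.choice(["s1", "s2"], n),
        })
        m = cell_type_distribution(cells, annot)
        # brute force tally
        tally: dict = {}
        totals: dict = {}
        for _, row in cells.iterrows():
            idx = tuple(int(np.floor(v)) for v in
                        (row.x_mm, row.y_mm, row.z_mm))
            lab = annot.data[idx] if all(0 <= i < 16 for i in idx) else 0
            key = "unassigned" if lab == 0 else str(int(lab))
            tally[(key, row.subclass)] = tally.get((key, row.subclass), 0) + 1
            totals[row.subclass] = totals.get(row.subclass, 0) + 1
        for (reg, sub), count in tally.items():
            assert m.loc[reg, sub] == count / totals[sub]

    def test_empty_table_rejected(self):
        annot, _ = _two_region_annot()
        with pytest.raises(ValueError, match="empty"):
            cell_type_distribution(pd.DataFrame(columns=["x_mm", "y_mm",
                                                         "z_mm", "subclass"]),
                                   annot)


class TestMTR:
    def test_equal_images_give_zero(self, rng):
        m0 = ImageVolume(rng.random((6, 6, 6)) + 0.5)
        out = compute_mtr(m0, m0)
        assert np.allclose(out.data, 0.0)

    def test_zero_mt_gives_one(self, rng):
        m0 = ImageVolume(rng.random((6, 6, 6)) + 0.5)
        out = compute_mtr(ImageVolume(np.zeros((6, 6, 6))), m0)
        assert np.allclose(out.data, 1.0)

    def test_direct_substitution(self):
        out = compute_mtr(ImageVolume(np.full((2, 2, 2), 0.5)),
                          ImageVolume(np.ones((2, 2, 2))))
        assert np.allclose(out.data, 0.5)

    def test_nonpositive_m0_masked(self):
        m0 = np.ones((2, 2, 2))
        m0[0, 0, 0] = 0.0
        out = compute_mtr(ImageVolume(np.ones((2, 2, 2))), ImageVolume(m0))
        assert np.isnan(out.data[0, 0, 0])
        assert np.allclose(out.data[~np.isnan(out.data)], 0.0)


def test_count_conservation_through_chain(rng):
    """binary -> count volume -> occupancy table positives, all equal."""
    binary = (rng.random((32, 32, 32)) > 0.8).astype(np.uint8)
    counts = downsample_count(ImageVolume(binary), 2)
    onto, annot, _ = make_ontology_and_annotation(depth=2, branching=2,
                                                  shape=(16, 16, 16), seed=4)
    occ = regional_occupancy(counts, annot, onto, downsample_factor=2)
    inside = counts.data[annot.data != 0].sum()
    assert occ.table["positive"].sum() == inside
    assert counts.data.sum() == binary.sum()


class TestWarpCounts:
    def test_jacobian_mode_conserves_within_two_percent(self, rng):
        from devatlas.quantify import warp_counts
        from devatlas.registration import Grid, Transform
        from devatlas.synthetic import smooth_field

        c = np.zeros((32, 32, 32))
        c[8:24, 8:24, 8:24] = (rng.random((16, 16, 16)) > 0.7).astype(float)
        counts = ImageVolume(c)
        u = smooth_field((32, 32, 32), 2.0, 5.0, rng)
        w = np.ones(32)
        w[:6] = np.linspace(0, 1, 6)
        w[-6:] = np.linspace(1, 0, 6)
        u *= (w[:, None, None] * w[None, :, None] * w[None, None, :])[..., None]
        t = Transform(np.eye(4), warp=u, grid=Grid.of(counts))
        out = warp_counts(counts, t, counts, jacobian=True)
        assert abs(out.data.sum() - c.sum()) / c.sum() < 0.02

    def test_jacobian_beats_naive_under_scaling(self, rng):
        from devatlas.quantify import warp_counts
        from devatlas.registration import Transform

        c = np.zeros((32, 32, 32))
        c[8:24, 8:24, 8:24] = (rng.random((16, 16, 16)) > 0.7).astype(float)
        counts = ImageVolume(c)
        A = np.eye(4) * 1.1
        A[3, 3] = 1.0
        A[:3, 3] = -0.05 * 31  # scale about the volume center
        t = Transform(A)
        err_j = abs(warp_counts(counts, t, counts, True).data.sum() - c.sum())
        err_n = abs(warp_counts(counts, t, counts, False).data.sum() - c.sum())
        assert err_j < 0.1 * err_n
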