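"""Regional quantification: count downsampling, occupancy, cell-type maps, MTR.

Classified voxel data (e.g. a binary map of GABAergic-lineage-positive
voxels at full imaging resolution) is reduced to a coarse count volume in
which each voxel holds the number of positive fine voxels in its block —
total counts are conserved exactly.  After warping such a count volume onto
a template, relative occupancy per anatomical region is the ratio of the
summed positive counts to the region's voxel capacity at classification
resolution, so 1.0 means fully occupied.

Cell-type point tables (x, y, z, class, subclass) are assigned to regions by
flooring world coordinates to voxel indices; the proportion matrix gives,
for each subclass, the fraction of its cells in each region (columns sum to
one over regions plus an 'unassigned' row).

The magnetization transfer ratio map is the closed form MTR = 1 - MT/M0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .ontology import AnnotationVolume, Ontology
from .volume import ImageVolume, block_sum

__all__ = [
    "OccupancyTable",
    "downsample_count",
    "warp_counts",
    "regional_occupancy",
    "cell_type_distribution",
    "compute_mtr",
]

UNASSIGNED = "unassigned"


def downsample_count(binary: ImageVolume, factor) -> ImageVolume:
    """Sum a {0,1} volume over blocks; each coarse voxel counts its positives.

    The per-axis integer ``factor`` also scales the voxel spacing, and the
    total count is conserved exactly (trailing partial blocks are kept,
    zero-padded).
    """
    vals = np.unique(binary.data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("input must be binary (values in {0, 1})")
    f = np.atleast_1d(np.asarray(factor, dtype=int))
    if f.size == 1:
        f = np.repeat(f, 3)
    if np.any(f < 1):
        raise ValueError("factors must be >= 1")
    data = block_sum(binary.data.astype(np.int64), tuple(f))
    return ImageVolume(data, spacing=tuple(np.asarray(binary.spacing) * f),
                       origin=binary.origin, orientation=binary.orientation,
                       unit=binary.unit)


def warp_counts(counts: ImageVolume, t, reference: ImageVolume,
                jacobian: bool = True) -> ImageVolume:
    """Warp a count volume onto a template grid, conserving mass.

    Plain interpolation redistributes counts but ignores the local volume
    change of the deformation; scaling by the Jacobian determinant of the
    pull-back map restores conservation (to interpolation accuracy).
    ``jacobian=False`` gives the naive resampling.
    """
    from .registration import Grid, apply_transform

    out = apply_transform(counts, t, reference, interpolation="linear")
    if not jacobian:
        return out
    g = Grid.of(reference)
    pts = t.map_points(g.world_mesh())
    jac = np.zeros(g.shape)
    grads = [np.gradient(pts[..., d], *g.spacing) for d in range(3)]
    J = np.stack([np.stack(gr, axis=-1) for gr in grads], axis=-2)
    jac = np.abs(np.linalg.det(J))
    return out.copy(data=out.data * jac)


@dataclass
class OccupancyTable:
    """Per-region positive counts, voxel capacity and occupancy ratio."""

    table: pd.DataFrame  # region_id, acronym, positive, total_capacity, ratio
    voxels_per_bin: int
    downsample_factor: tuple[int, int, int]
    age_tag: str | None = None

    def row(self, region_id: int) -> pd.Series:
        return self.table.set_index("region_id").loc[int(region_id)]

    def rolled_up(self, ontology: Ontology) -> pd.DataFrame:
        """Aggregate positive counts and capacity over each region's subtree."""
        base = self.table.set_index("region_id")
        rows = []
        for rid in ontology.regions:
            ids = [rid] + ontology.descendants(rid)
            ids = [i for i in ids if i in base.index]
            if not ids:
                continue
            pos = int(base.loc[ids, "positive"].sum())
            cap = int(base.loc[ids, "total_capacity"].sum())
            rows.append({"region_id": rid,
                         "acronym": ontology[rid].acronym,
                         "positive": pos, "total_capacity": cap,
                         "ratio": pos / cap if cap else 0.0})
        return pd.DataFrame(rows)


def regional_occupancy(
    counts: ImageVolume,
    annot: AnnotationVolume,
    ontology: Ontology | None = None,
    voxels_per_bin: int | None = None,
    downsample_factor=(1, 1, 1),
    age_tag: str | None = None,
) -> OccupancyTable:
    """Relative occupancy per region: positives / (voxels x per-bin capacity).

    ``counts`` holds per-voxel positive-voxel sums at the annotation's
    resolution; ``voxels_per_bin`` is the number of classification-resolution
    voxels per annotation voxel (defaults to the product of
    ``downsample_factor``), so a ratio of 1.0 means fully occupied at
    classification resolution.
    """
    if counts.shape != annot.labels.shape:
        raise ValueError("count volume and annotation grids differ")
    ontology = ontology or annot.ontology
    factor = tuple(int(x) for x in np.atleast_1d(downsample_factor))
    if len(factor) == 1:
        factor = factor * 3
    if voxels_per_bin is None:
        voxels_per_bin = int(np.prod(factor))
    lab = annot.data.ravel()
    cnt = np.asarray(counts.data, dtype=float).ravel()
    ids = np.unique(lab[lab != 0])
    pos = np.array([cnt[lab == i].sum() for i in ids])
    nvox = np.array([(lab == i).sum() for i in ids])
    rows = pd.DataFrame({
        "region_id": ids.astype(int),
        "acronym": [ontology[i].acronym if int(i) in ontology else str(i)
                    for i in ids],
        "positive": pos,
        "total_capacity": nvox * voxels_per_bin,
    })
    rows["ratio"] = rows["positive"] / rows["total_capacity"]
    return OccupancyTable(table=rows, voxels_per_bin=voxels_per_bin,
                          downsample_factor=factor, age_tag=age_tag)


def cell_type_distribution(
    cells: pd.DataFrame,
    annot: AnnotationVolume,
    subclass_col: str = "subclass",
    exact: bool = False,
) -> pd.DataFrame:
    """Region-by-subclass proportion matrix.

    Each cell's world coordinate (columns ``x_mm, y_mm, z_mm``) is floored to
    a voxel index and assigned that voxel's region label (or 'unassigned'
    outside the volume or on background).  Entry (region, subclass) is
    n(region, subclass) / n(subclass); every subclass column sums to 1 over
    regions plus the unassigned row.  ``exact=True`` returns
    :class:`fractions.Fraction` entries so the column sums are exactly one.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    for c in ("x_mm", "y_mm", "z_mm", subclass_col):
        if c not in cells.columns:
            raise ValueError(f"cell table lacks column {c!r}")
    pts = cells[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("cell coordinates must be finite")
    vol = annot.labels
    idx = np.floor(vol.world_to_index(pts)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(vol.shape)), axis=1)
    labels = np.full(len(cells), 0, dtype=int)
    labels[inside] = vol.data[tuple(idx[inside].T)]
    region = np.where(labels == 0, UNASSIGNED, labels.astype(str))
    counts = pd.crosstab(pd.Series(region, name="region"),
                         cells[subclass_col])
    totals = counts.sum(axis=0)
    if exact:
        out = counts.apply(
            lambda col: [Fraction(int(v), int(totals[col.name])) for v in col])
        return out
    return counts / totals


def compute_mtr(mt: ImageVolume, m0: ImageVolume,
                sentinel: float = np.nan) -> ImageVolume:
    """Magnetization transfer ratio: voxel-wise 1 - MT/M0.

    Voxels where M0 <= 0 get the masked ``sentinel`` value (NaN by default).
    """
    if mt.shape != m0.shape:
        raise ValueError("MT and M0 grids differ")
    m0d = np.asarray(m0.data, dtype=float)
    mtd = np.asarray(mt.data, dtype=float)
    valid = m0d > 0
    out = np.full(mtd.shape, sentinel, dtype=float)
    out[valid] = 1.0 - mtd[valid] / m0d[valid]
    return mt.copy(data=out)
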