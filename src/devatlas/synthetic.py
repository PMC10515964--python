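"""Seeded synthetic fixtures: phantoms, cohorts, tile grids, ISH series,
ontologies and classified-voxel volumes.

Every generator is a pure function of its arguments plus an explicit integer
seed (no generator touches ambient randomness), so reruns are bit-identical
and every recovery test can score against the returned ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .ontology import AnnotationVolume, Ontology, Region
from .stitching import CountingReader, Tile, TileGrid
from .template import Cohort, SubjectRecord
from .volume import ImageVolume, SliceSeries

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "make_texture_phantom",
    "make_cohort",
    "make_tile_stack",
    "make_ish_series",
    "make_ontology_and_annotation",
    "smooth_field",
    "warp_by_field",
]


# ---------------------------------------------------------------------------
# phantom brains
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Recipe for a blob-and-ellipsoid phantom.

    ``structures`` is a list of dicts with keys ``center`` (voxels), ``radii``
    (voxels), ``intensity`` and optional ``kind`` ('gaussian' or 'ellipsoid')
    and ``expression`` (contribution to the expression channel).  When empty,
    ``n_random`` seeded gaussian blobs inside an ellipsoidal 'brain' are
    generated.  ``asymmetry`` shifts a fraction of random structures off the
    midline to break mirror symmetry.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    structures: list[dict] = field(default_factory=list)
    n_random: int = 8
    asymmetry: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0


@dataclass
class Phantom:
    image: ImageVolume
    mask: ImageVolume
    expression: ImageVolume | None = None


def _sq_dist(shape, center, radii) -> np.ndarray:
    """Normalized squared distance field via broadcasting (no index grid)."""
    axes = [(((np.arange(n, dtype=float) - c) / r) ** 2).reshape(
        [-1 if j == i else 1 for j in range(3)])
        for i, (n, c, r) in enumerate(zip(shape, center, radii))]
    return axes[0] + axes[1] + axes[2]


def _ellipsoid(shape, center, radii) -> np.ndarray:
    return _sq_dist(shape, center, radii) <= 1.0


def _gaussian(shape, center, radii) -> np.ndarray:
    return np.exp(-_sq_dist(shape, center, radii))


def _add_blob(img: np.ndarray, center, radii, amp: float,
              kind: str = "gaussian") -> None:
    """Accumulate one structure in place, evaluated only on its support box."""
    shape = img.shape
    center = np.asarray(center, dtype=float)
    radii = np.asarray(radii, dtype=float)
    reach = 4.0 if kind == "gaussian" else 1.0
    lo = np.maximum(0, np.floor(center - reach * radii).astype(int))
    hi = np.minimum(shape, np.ceil(center + reach * radii).astype(int) + 1)
    axes = [np.arange(lo[i], hi[i], dtype=float) for i in range(3)]
    d = sum((((ax - center[i]) / radii[i]) ** 2).reshape(
        [-1 if j == i else 1 for j in range(3)])
        for i, ax in enumerate(axes))
    box = tuple(slice(lo[i], hi[i]) for i in range(3))
    if kind == "gaussian":
        img[box] += amp * np.exp(-d)
    else:
        img[box] += amp * (d <= 1.0)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministic phantom: brain-shaped envelope + internal structures."""
    shape = tuple(spec.shape)
    rng = np.random.default_rng(spec.seed)
    img = np.zeros(shape)
    expr = np.zeros(shape)
    center = (np.asarray(shape) - 1) / 2.0
    brain_radii = np.asarray(shape) * 0.42
    mask = _ellipsoid(shape, center, brain_radii)
    img += 0.3 * _gaussian(shape, center, brain_radii)

    structures = list(spec.structures)
    if not structures:
        # brains are near-mirror-symmetric: random structures come in
        # left/right pairs, with `asymmetry` perturbing one member of each
        # pair slightly (position jitter in units of the grid size)
        n_pairs = max(1, spec.n_random // 2)
        for _ in range(n_pairs):
            margin = 0.28 * np.asarray(shape)
            c = rng.uniform(margin, np.asarray(shape) - margin)
            radii = rng.uniform(0.05, 0.12, 3) * np.asarray(shape)
            intensity = float(rng.uniform(0.4, 1.0))
            expression = float(rng.uniform(0.0, 1.0))
            mirror = c.copy()
            mirror[0] = shape[0] - 1 - c[0]
            if spec.asymmetry > 0:
                mirror += spec.asymmetry * np.asarray(shape) \
                    * rng.uniform(-1.0, 1.0, 3)
            for center in (c, np.clip(mirror, 2, np.asarray(shape) - 3)):
                structures.append({
                    "center": center,
                    "radii": radii,
                    "intensity": intensity,
                    "expression": expression,
                })
    for s in structures:
        c = np.asarray(s["center"], dtype=float)
        r = np.asarray(s["radii"], dtype=float)
        if np.any(c - r < -1) or np.any(c + r > np.asarray(shape)):
            raise ValueError(f"structure at {c} with radii {r} exceeds the grid")
        kind = s.get("kind", "gaussian")
        _add_blob(img, c, r, s.get("intensity", 1.0), kind)
        if s.get("expression", 0.0):
            _add_blob(expr, c, r, s["expression"], kind)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, shape)
    mk = dict(spacing=spec.spacing)
    return Phantom(
        image=ImageVolume(img, **mk),
        mask=ImageVolume(mask.astype(np.uint8), **mk),
        expression=ImageVolume(expr, **mk) if expr.any() else None,
    )


# ---------------------------------------------------------------------------
# deformation fields + cohorts
# ---------------------------------------------------------------------------

def smooth_field(shape, max_magnitude: float, sigma: float, rng) -> np.ndarray:
    """Gaussian-smoothed random displacement field, |u| <= max_magnitude."""
    u = rng.standard_normal(tuple(shape) + (len(shape),))
    for d in range(u.shape[-1]):
        u[..., d] = ndimage.gaussian_filter(u[..., d], sigma)
    m = np.abs(u).max()
    if m > 0:
        u *= max_magnitude / m
    return u


def warp_by_field(data: np.ndarray, u: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample ``data`` at x + u(x) (pull-back through the map m(x) = x + u)."""
    shape = data.shape
    mesh = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                indexing="ij"), axis=-1)
    pts = mesh + u
    coords = np.moveaxis(pts.reshape(-1, len(shape)), -1, 0)
    return ndimage.map_coordinates(data, coords, order=order,
                                   mode="nearest").reshape(shape)


def _invert_field(u: np.ndarray, iterations: int = 30) -> np.ndarray:
    """v with (x + u) o (x + v) ~= id, by fixed-point iteration."""
    shape = u.shape[:-1]
    mesh = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                indexing="ij"), axis=-1)
    v = -u
    for _ in range(iterations):
        pts = mesh + v
        coords = np.moveaxis(pts.reshape(-1, len(shape)), -1, 0)
        u_at = np.stack([
            ndimage.map_coordinates(u[..., d], coords, order=1, mode="nearest")
            .reshape(shape) for d in range(u.shape[-1])], axis=-1)
        v = -u_at
    return v


def make_cohort(
    phantom: ImageVolume,
    n: int,
    deform_magnitude: float,
    seed: int = 0,
    sigma: float = 6.0,
    contrasts: dict[str, ImageVolume] | None = None,
) -> tuple[Cohort, list[np.ndarray]]:
    """Cohort of smoothly deformed copies of a phantom + true fields.

    Member i is the phantom pulled through m_i(x) = x + u_i(x); the u_i are
    centered (their mean is subtracted) so the cohort's mean shape is the
    phantom itself, and the list of true fields is returned for recovery
    scoring.  Sibling contrasts, when given, are deformed with the same
    fields.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    if deform_magnitude < 0:
        raise ValueError("deform_magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    shape = phantom.shape
    fields = []
    if deform_magnitude == 0:
        fields = [np.zeros(tuple(shape) + (3,)) for _ in range(n)]
    else:
        raw = [smooth_field(shape, deform_magnitude, sigma, rng) for _ in range(n)]
        mean = np.mean(raw, axis=0)
        for u in raw:
            u = u - mean
            m = np.abs(u).max()
            if m > deform_magnitude and m > 0:
                u = u * (deform_magnitude / m)
            fields.append(u)
    members = []
    for i, u in enumerate(fields):
        # member shows the phantom deformed: member(x) = phantom(m_i^{-1}(x)),
        # so that registering member -> phantom recovers u_i as the map
        v = _invert_field(u)
        data = warp_by_field(np.asarray(phantom.data, dtype=float), v)
        sib = {}
        for name, cvol in (contrasts or {}).items():
            sib[name] = cvol.copy(
                data=warp_by_field(np.asarray(cvol.data, dtype=float), v))
        members.append(SubjectRecord(subject_id=f"s{i:02d}",
                                     primary=phantom.copy(data=data),
                                     contrasts=sib))
    return Cohort(members), fields


def make_texture_phantom(shape=(200, 200, 160), n_blobs: int = 60,
                         noise_sigma: float = 0.02, seed: int = 0) -> Phantom:
    """Texture-rich phantom for stitching fixtures.

    Many small gaussian blobs (radius 3-12 voxels, independent of the grid
    size) over a smooth envelope: the fine structure is what strip
    cross-correlation locks onto, mimicking cells and vessels in cleared
    tissue rather than gross anatomy.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    img = np.zeros(shape)
    center = (np.asarray(shape) - 1) / 2.0
    radii = np.asarray(shape) * 0.45
    img += 0.3 * _gaussian(shape, center, radii)
    mask = _ellipsoid(shape, center, radii)
    for _ in range(n_blobs):
        c = rng.uniform(0.08 * np.asarray(shape), 0.92 * np.asarray(shape))
        r = rng.uniform(3.0, 12.0, 3)
        _add_blob(img, c, r, float(rng.uniform(0.3, 1.0)))
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, shape)
    return Phantom(image=ImageVolume(img),
                   mask=ImageVolume(mask.astype(np.uint8)))


def make_misalignment_pair(
    shape: tuple[int, int, int] = (48, 48, 48),
    displacement: float = 6.0,
    envelope_scale: float = 1.05,
    structure_intensity: float = 0.08,
    seed: int = 0,
) -> dict:
    """Fixture for mask-assisted registration: matching-but-rescaled outer
    surfaces with an internally displaced, low-contrast structure.

    The moving brain's envelope is ``envelope_scale`` times larger and its
    internal structure sits ``displacement`` voxels off the fixed one's —
    the classic multimodal failure mode where surface alignment succeeds
    while an internal structure stays misaligned.  Region masks (spheres
    around each structure, as a manual rater would draw them) are returned
    for carving modified brain masks.
    """
    rng = np.random.default_rng(seed)
    center = (np.asarray(shape) - 1) / 2.0
    sx = float(center[0] - displacement / 2.0)
    mx = float(center[0] + displacement / 2.0)

    def brain(radii_scale, struct_x):
        radii = np.asarray(shape) * 0.40 * radii_scale
        img = 0.3 * _gaussian(shape, center, radii)
        mask = _ellipsoid(shape, center, radii)
        img += structure_intensity * _gaussian(
            shape, (struct_x, center[1], center[2]), (5.0, 5.0, 5.0))
        img += rng.normal(0.0, 0.005, shape)
        return Phantom(image=ImageVolume(img),
                       mask=ImageVolume(mask.astype(np.uint8)))

    fixed = brain(1.0, sx)
    moving = brain(envelope_scale, mx)

    def region(cx):
        m = _ellipsoid(shape, (cx, center[1], center[2]), (9.0, 9.0, 9.0))
        return ImageVolume(m.astype(np.uint8))

    return {
        "fixed": fixed, "moving": moving,
        "fixed_region": region(sx), "moving_region": region(mx),
        "fixed_center": np.array([sx, center[1], center[2]]),
        "moving_center": np.array([mx, center[1], center[2]]),
    }


# ---------------------------------------------------------------------------
# tile grids
# ---------------------------------------------------------------------------

def make_tile_stack(
    vol: ImageVolume,
    grid: tuple[int, int],
    overlap: float = 0.15,
    jitter: int = 0,
    drift_max: float = 0.0,
    seed: int = 0,
    chunk_size: int = 32,
) -> tuple[TileGrid, dict]:
    """Cut a jittered tile grid out of a volume, with optional linear z-drift.

    Tile (c, r) slice k is read from the volume at
    ``(x0+jx+i, y0+jy+j, margin + k + dz_c(k))`` where (jx, jy) is an
    integer per-tile jitter and dz_c is the column's rounded linear drift
    (0 at slice 0, up to ``drift_max`` at the last slice) plus an integer
    per-column z jitter.  Column 0 and tile (0, 0) are the clean anchors
    (zero jitter and drift): inter-tile alignment can only observe offsets
    relative to an anchor, so the truth is expressed in the same gauge.
    Truth is returned as ``{'per_slice': {(c, r): (nz, 3) array}, ...}``
    where the z column already includes the margin (absolute source z of
    slice k is ``k + per_slice[..., 2]``).
    """
    if overlap < 0.05:
        raise ValueError("overlap must be >= 0.05")
    cols, rows = grid
    rng = np.random.default_rng(seed)
    X, Y, Z = vol.shape
    data = np.asarray(vol.data)
    nx = int(X / (1 + (cols - 1) * (1 - overlap)))
    ny = int(Y / (1 + (rows - 1) * (1 - overlap)))
    stride_x = int(round(nx * (1 - overlap)))
    stride_y = int(round(ny * (1 - overlap)))
    margin = jitter + 1
    nz = Z - int(np.ceil(drift_max)) - 2 * margin
    if nz < chunk_size:
        raise ValueError("volume too shallow for the requested drift/jitter")

    col_jz = {c: (int(rng.integers(-jitter, jitter + 1)) if jitter and c else 0)
              for c in range(cols)}
    col_drift = {}
    for c in range(cols):
        if c == 0 or drift_max == 0:
            col_drift[c] = np.zeros(nz, dtype=int)
        else:
            end = drift_max * float(rng.uniform(0.5, 1.0)) * (1 if c % 2 else -1)
            col_drift[c] = np.rint(np.linspace(0.0, end, nz)).astype(int)

    tiles = []
    truth_slices = {}
    truth_xy = {}
    for c in range(cols):
        for r in range(rows):
            anchor = (c == 0 and r == 0)
            jx = int(rng.integers(-jitter, jitter + 1)) if jitter and not anchor else 0
            jy = int(rng.integers(-jitter, jitter + 1)) if jitter and not anchor else 0
            x0 = c * stride_x + jx
            y0 = r * stride_y + jy
            if x0 < -0 or y0 < 0 or x0 + nx > X or y0 + ny > Y:
                jx -= max(0, x0 + nx - X) + min(0, x0)
                jy -= max(0, y0 + ny - Y) + min(0, y0)
                x0 = c * stride_x + jx
                y0 = r * stride_y + jy
            if x0 < 0 or y0 < 0 or x0 + nx > X or y0 + ny > Y:
                raise ValueError("tiles exceed the volume; reduce jitter or grid")
            dz = col_jz[c] + col_drift[c]
            zsrc = np.arange(nz) + margin + dz
            tdat = np.empty((nx, ny, nz), dtype=data.dtype)
            for k in range(nz):
                tdat[:, :, k] = data[x0:x0 + nx, y0:y0 + ny, zsrc[k]]
            reader = CountingReader(tdat, chunk_size=chunk_size)
            tiles.append(Tile(reader=reader, col=c, row=r, overlap=overlap))
            off = np.zeros((nz, 3))
            off[:, 0] = jx
            off[:, 1] = jy
            off[:, 2] = margin + dz  # source z of slice k, minus k
            truth_slices[(c, r)] = off
            truth_xy[(c, r)] = (jx, jy)
    tg = TileGrid(tiles=tiles, cols=cols, rows=rows)
    truth = {"per_slice": truth_slices, "per_tile_xy": truth_xy,
             "z_margin": margin, "col_drift": col_drift, "col_jz": col_jz,
             "tile_shape": (nx, ny, nz)}
    return tg, truth


# ---------------------------------------------------------------------------
# ISH series
# ---------------------------------------------------------------------------

def make_ish_series(
    vol: ImageVolume,
    dz: int = 2,
    drop_fraction: float = 0.2,
    jitter_px: float = 0.0,
    genes: Sequence[str] = ("geneA",),
    seed: int = 0,
    invert: bool = True,
) -> tuple[SliceSeries, dict]:
    """Sample a sparse, jittered section series from a volume.

    Sections are taken every ``dz`` voxels along z, randomly dropped with the
    given fraction (never the first or last), translated in-plane by up to
    ``jitter_px`` and optionally intensity-inverted (so that
    :func:`devatlas.ish.preprocess_slices` undoes the inversion).  Gene
    labels interleave cyclically.  Truth holds the per-section in-plane
    shifts and the clean source stack.
    """
    if not (0.0 <= drop_fraction <= 0.5):
        raise ValueError("drop_fraction must be in [0, 0.5]")
    Z = vol.shape[2]
    if dz >= Z:
        raise ValueError("dz larger than the volume extent")
    rng = np.random.default_rng(seed)
    z_idx = np.arange(0, Z, dz)
    n = len(z_idx)
    drop = np.zeros(n, dtype=bool)
    if drop_fraction > 0 and n > 2:
        k = int(round(drop_fraction * n))
        cand = rng.permutation(np.arange(1, n - 1))[:k]
        drop[cand] = True
    present = ~drop
    data = np.asarray(vol.data, dtype=float)
    lo, hi = data.min(), data.max()
    span = hi - lo if hi - lo > 1e-12 else 1.0
    slices = []
    shifts = []
    labels = []
    for i, zi in enumerate(z_idx):
        if not present[i]:
            continue
        sl = data[:, :, zi]
        shift = rng.uniform(-jitter_px, jitter_px, 2) if jitter_px else np.zeros(2)
        if jitter_px:
            sl = ndimage.shift(sl, shift, order=1, mode="nearest")
        if invert:
            sl = 1.0 - (sl - lo) / span  # raw ISH: signal is dark
        slices.append(sl)
        shifts.append(shift)
        labels.append(genes[i % len(genes)])
    series = SliceSeries(
        slices=slices,
        z_positions=z_idx.astype(float) * vol.spacing[2] + vol.origin[2],
        present_mask=present,
        channel_of_slice=labels,
        in_plane_spacing=vol.spacing[:2],
    )
    truth = {"z_indices": z_idx, "dropped": drop,
             "shifts": np.asarray(shifts),
             "clean_stack": data[:, :, z_idx],
             "gene_of_nominal": [genes[i % len(genes)] for i in range(n)]}
    return series, truth


# ---------------------------------------------------------------------------
# ontologies + annotations
# ---------------------------------------------------------------------------

def make_ontology_and_annotation(
    depth: int = 3,
    branching: int = 2,
    shape: tuple[int, int, int] = (32, 32, 32),
    seed: int = 0,
    corrupt_holes: int = 0,
) -> tuple[Ontology, AnnotationVolume, ImageVolume]:
    """Nested Voronoi parcellation of an ellipsoidal brain mask.

    Level-0 is the root region covering the whole mask; each region is split
    into ``branching`` children by nearest-seed assignment within the parent,
    so children tile their parent exactly and the annotation (whose voxels
    carry leaf labels) is valid by construction.  ``corrupt_holes`` > 0
    punches that many single-voxel label-0 holes inside the mask to seed
    exhaustiveness violations for validator tests.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if branching < 1:
        raise ValueError("branching must be >= 1")
    rng = np.random.default_rng(seed)
    center = (np.asarray(shape) - 1) / 2.0
    mask = _ellipsoid(shape, center, np.asarray(shape) * 0.45)

    next_id = [1]
    regions = [Region(id16=1, name="brain", acronym="Br", parent=None,
                      color="#cccccc")]
    labels = np.where(mask, 1, 0).astype(np.int32)

    def split(region_id: int, level: int) -> None:
        if level >= depth - 1:
            return
        vox = np.argwhere(labels == region_id)
        if len(vox) < branching:
            return
        seeds = vox[rng.choice(len(vox), branching, replace=False)]
        child_ids = []
        for s in seeds:
            next_id[0] += 1
            cid = next_id[0]
            child_ids.append(cid)
            regions.append(Region(
                id16=cid, name=f"region {cid}", acronym=f"R{cid}",
                parent=region_id,
                color="#%06x" % rng.integers(0, 0xFFFFFF)))
        d2 = ((vox[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        owner = np.argmin(d2, axis=1)
        for j, cid in enumerate(child_ids):
            sel = vox[owner == j]
            labels[tuple(sel.T)] = cid
        for cid in child_ids:
            split(cid, level + 1)

    split(1, 0)
    if corrupt_holes > 0:
        inside = np.argwhere(mask & (labels > 0))
        picks = inside[rng.choice(len(inside), corrupt_holes, replace=False)]
        labels[tuple(picks.T)] = 0
    onto = Ontology(regions)
    annot = AnnotationVolume(ImageVolume(labels.astype(np.int32)), onto)
    return onto, annot, ImageVolume(mask.astype(np.uint8))
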