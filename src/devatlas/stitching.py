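"""Two-pass edge-MIP tile stitching for light-sheet stacks.

Large cleared-tissue acquisitions arrive as a grid of overlapping tile
stacks.  Reading raw tiles off storage dominates run time, so the algorithm
touches the raw data exactly twice:

* **pass 1** — for every tile, read each z-block of slices once and keep only
  (a) a maximum-intensity projection (MIP) of the four outer edge strips over
  the block, and (b) a per-slice mean-intensity profile of each strip;
* **alignment** — z offsets are solved per column from the strip profiles,
  then in-plane (x, y) offsets per z-block from MIP cross-correlation of
  facing strips, reconciled globally by least squares over the tile graph,
  and finally smoothed into per-slice offsets by curve fitting;
* **pass 2** — tiles are read a second (and last) time and fused into the
  output canvas with feather or max blending.

All offsets are expressed in voxels relative to the nominal grid placement:
an offset (dx, dy, dz) for slice k means that tile voxel (i, j, k) shows
content located at (x0 + dx + i, y0 + dy + j, k + dz) in the sample, where
(x0, y0) is the nominal tile origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import interpolate, ndimage

from .volume import ImageVolume

log = logging.getLogger(__name__)

__all__ = [
    "CountingReader",
    "Tile",
    "TileGrid",
    "EdgeMIPSet",
    "TileOffsets",
    "extract_edge_mips",
    "align_z_columns",
    "align_xy",
    "refine_slice_offsets",
    "fuse",
    "stitch",
    "DegenerateSignalError",
]


class DegenerateSignalError(RuntimeError):
    """Raised when edge strips carry no signal usable for alignment."""


class CountingReader:
    """Array accessor that counts how often each z-chunk is read.

    The stitching pipeline promises to read raw data at most twice; the
    counter makes that promise testable.  Chunks are z-slabs of
    ``chunk_size`` slices (aligned to multiples of it).
    """

    def __init__(self, data: np.ndarray, chunk_size: int = 32):
        self._data = np.asarray(data)
        self.chunk_size = int(chunk_size)
        self.read_counts: dict[int, int] = {}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self._data.shape  # type: ignore[return-value]

    def read_block(self, z0: int, z1: int) -> np.ndarray:
        """Read slices [z0, z1); every overlapped chunk's counter increments."""
        z0 = max(0, int(z0))
        z1 = min(self._data.shape[2], int(z1))
        for c in range(z0 // self.chunk_size, (max(z1 - 1, z0)) // self.chunk_size + 1):
            self.read_counts[c] = self.read_counts.get(c, 0) + 1
        return self._data[:, :, z0:z1]

    def max_reads(self) -> int:
        return max(self.read_counts.values(), default=0)


@dataclass
class Tile:
    """One stack in the acquisition grid."""

    reader: CountingReader
    col: int
    row: int
    overlap: float  # nominal overlap fraction per in-plane axis

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap <= 0.5):
            raise ValueError(f"overlap fraction must be in (0, 0.5], got {self.overlap}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reader.shape

    @property
    def key(self) -> tuple[int, int]:
        return (self.col, self.row)


@dataclass
class TileGrid:
    """Indexed tiles with their nominal placement."""

    tiles: list[Tile]
    cols: int
    rows: int

    def __post_init__(self) -> None:
        zs = {t.shape[2] for t in self.tiles}
        if max(zs) - min(zs) > 0:
            raise ValueError(f"tiles disagree on slice count: {sorted(zs)}")

    def tile(self, col: int, row: int) -> Tile:
        for t in self.tiles:
            if t.key == (col, row):
                return t
        raise KeyError((col, row))

    def nominal_origin(self, tile: Tile) -> tuple[int, int]:
        """Nominal (x, y) placement of the tile's (0, 0) corner, in voxels."""
        nx, ny, _ = tile.shape
        stride_x = int(round(nx * (1 - tile.overlap)))
        stride_y = int(round(ny * (1 - tile.overlap)))
        return tile.col * stride_x, tile.row * stride_y


@dataclass
class EdgeMIPSet:
    """Pass-1 summary of one tile: per-side block MIPs and slice profiles.

    ``mips[side]`` has shape (n_blocks, strip_w, n) for sides 'left'/'right'
    (strips along x) and (n_blocks, n, strip_w) for 'top'/'bottom' (along y).
    ``profiles[side]`` is the strip's mean intensity across its width, kept
    per in-plane position and slice: shape (ny, n_z) for 'left'/'right' and
    (nx, n_z) for 'top'/'bottom'.  These drive the z alignment.
    """

    mips: dict[str, np.ndarray]
    profiles: dict[str, np.ndarray]
    block_size: int
    edge_fraction: float
    strip_width: tuple[int, int]
    z_count: int

    @property
    def n_blocks(self) -> int:
        return int(np.ceil(self.z_count / self.block_size))

    def block_center(self, b: int) -> float:
        lo = b * self.block_size
        hi = min(self.z_count, lo + self.block_size)
        return (lo + hi - 1) / 2.0


def extract_edge_mips(tile: Tile, edge_fraction: float = 0.10,
                      block_size: int = 32) -> EdgeMIPSet:
    """Pass 1: per-side block MIPs + slice profiles, one read per z-block."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if not (0.0 < edge_fraction <= 0.5):
        raise ValueError("edge_fraction must be in (0, 0.5]")
    nx, ny, nz = tile.shape
    swx = max(1, int(round(edge_fraction * nx)))
    swy = max(1, int(round(edge_fraction * ny)))
    n_blocks = int(np.ceil(nz / block_size))
    mips = {
        "left": np.zeros((n_blocks, swx, ny)),
        "right": np.zeros((n_blocks, swx, ny)),
        "top": np.zeros((n_blocks, nx, swy)),
        "bottom": np.zeros((n_blocks, nx, swy)),
    }
    profiles = {"left": np.zeros((ny, nz)), "right": np.zeros((ny, nz)),
                "top": np.zeros((nx, nz)), "bottom": np.zeros((nx, nz))}
    for b in range(n_blocks):
        z0, z1 = b * block_size, min(nz, (b + 1) * block_size)
        slab = tile.reader.read_block(z0, z1)
        strips = {
            "left": slab[:swx],
            "right": slab[nx - swx:],
            "top": slab[:, :swy],
            "bottom": slab[:, ny - swy:],
        }
        for side, strip in strips.items():
            mips[side][b] = strip.max(axis=2)
            axis = 0 if side in ("left", "right") else 1
            profiles[side][:, z0:z1] = strip.mean(axis=axis)
    return EdgeMIPSet(mips=mips, profiles=profiles, block_size=block_size,
                      edge_fraction=edge_fraction, strip_width=(swx, swy),
                      z_count=nz)


# ---------------------------------------------------------------------------
# z alignment
# ---------------------------------------------------------------------------

def _profile_shift(a: np.ndarray, b: np.ndarray, search_range: int) -> tuple[float, float]:
    """z shift s maximizing NCC of a[:, k+s] against b[:, k].

    ``a`` and ``b`` are strip profiles of shape (in-plane, n_z); the profiles
    are differenced along z before correlating to sharpen the peak.  Returns
    (shift, peak correlation); a positive s means b shows sample z = k + s at
    slice k relative to a.  Parabolic sub-sample refinement; ties break
    toward zero.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if np.ptp(a) < 1e-12 or np.ptp(b) < 1e-12:
        raise DegenerateSignalError("edge profile has no signal")
    a = np.diff(a, axis=-1)
    b = np.diff(b, axis=-1)
    nz = min(a.shape[-1], b.shape[-1])
    shifts = np.arange(-search_range, search_range + 1)
    scores = np.full(len(shifts), -np.inf)
    for i, s in enumerate(shifts):
        if s >= 0:
            aa, bb = a[:, s:nz], b[:, : nz - s]
        else:
            aa, bb = a[:, : nz + s], b[:, -s:nz]
        if aa.shape[-1] < 4:
            continue
        aa = aa.ravel() - aa.mean()
        bb = bb.ravel() - bb.mean()
        denom = np.linalg.norm(aa) * np.linalg.norm(bb)
        if denom < 1e-12:
            continue
        scores[i] = float(aa @ bb / denom)
    i = int(np.argmax(scores))
    # tie toward zero offset
    best = scores[i]
    ties = np.flatnonzero(scores >= best - 1e-12)
    i = ties[np.argmin(np.abs(shifts[ties]))]
    s = float(shifts[i])
    if 0 < i < len(shifts) - 1 and np.isfinite(scores[i - 1]) and np.isfinite(scores[i + 1]):
        y0, y1, y2 = scores[i - 1], scores[i], scores[i + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-12:
            s += 0.5 * (y0 - y2) / denom
    return s, float(scores[int(np.argmax(scores))])


def _column_pair_dz(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                    search_range: int, inplane_range: int,
                    n_blocks: int, bs: int,
                    local_range: int = 4,
                    dy_hints: Sequence[int] | None = None) -> np.ndarray:
    """Per-block z offset between two columns, pooled over their row pairs.

    ``pairs`` holds (right-strip profile of column A, left-strip profile of
    column B) for every shared row.  The z offset is a property of the
    column (all rows of a column were acquired in one sweep), so one shared
    shift s is estimated: a coarse search maximizes the mean over rows of
    the best-over-in-plane-shift NCC of the differenced profiles — the
    in-plane nuisance shift is per row, since x/y jitter is per tile and not
    yet solved — and each z-block then refines s within ``local_range``
    slices, which tracks a slow drift without being fooled by short smooth
    windows.

    s convention: column B shows sample z = k + s at slice k relative to A
    (a[:, k + s] ~ b[:, k]); _overlap_ncc pairs a[p] with b[p + shift], so
    the z component of its shift argument is -s.
    """
    diffed = []
    for pa, pb in pairs:
        da = np.diff(pa, axis=-1)
        db = np.diff(pb, axis=-1)
        if np.ptp(da) < 1e-12 or np.ptp(db) < 1e-12:
            raise DegenerateSignalError("edge profile has no signal")
        diffed.append((da, db))

    if dy_hints is not None:
        row_dys = [range(int(h) - 1, int(h) + 2) for h in dy_hints]
    else:
        row_dys = [range(-inplane_range, inplane_range + 1)] * len(diffed)
    cand_s = np.arange(-search_range, search_range + 1)
    row_best_dy = np.zeros((len(diffed), len(cand_s)), dtype=int)
    pooled = np.full(len(cand_s), -np.inf)
    for i, s in enumerate(cand_s):
        total = 0.0
        ok = True
        for r, (da, db) in enumerate(diffed):
            scores = [(_overlap_ncc(da, db, (dy, -s)), dy) for dy in row_dys[r]]
            sc, dy = max(scores, key=lambda t: (t[0], -abs(t[1])))
            if not np.isfinite(sc):
                ok = False
                break
            row_best_dy[r, i] = dy
            # Fisher z-transform before pooling: rows whose strips overlap
            # widely score near 1 almost everywhere, and on the raw NCC
            # scale their (decisive) small differences would be washed out
            # by weakly discriminating rows
            total += np.arctanh(np.clip(sc, -0.999, 0.999))
        if ok:
            pooled[i] = total / len(diffed)
    if not np.any(np.isfinite(pooled)):
        raise DegenerateSignalError("profiles do not overlap")
    ties = np.flatnonzero(pooled >= np.max(pooled) - 1e-12)
    i0 = ties[np.argmin(np.abs(cand_s[ties]))]
    s0 = int(cand_s[i0])
    dy0 = row_best_dy[:, i0]

    # slow drift: the relative shift s(k) is a step function (both columns
    # round their own drift independently), so fit a piecewise path by
    # dynamic programming over short windows — pooled window scores pin the
    # local shift, and the transition penalty keeps the path slow
    nz_d = diffed[0][0].shape[-1]
    win = max(4, bs // 4)
    starts = np.arange(0, nz_d - win + 1, win)
    cand = np.arange(s0 - 2 * local_range, s0 + 2 * local_range + 1)
    local = np.full((len(starts), len(cand)), -np.inf)
    for wi, w0 in enumerate(starts):
        kk = np.arange(w0, min(nz_d, w0 + win))
        for si, s in enumerate(cand):
            src = kk + s
            vals = []
            for r, (da, db) in enumerate(diffed):
                valid = (src >= 0) & (src < da.shape[-1])
                if valid.sum() < 3:
                    continue
                v = _overlap_ncc(da[:, src[valid]], db[:, kk[valid]],
                                 (dy0[r], 0))
                if np.isfinite(v):
                    vals.append(np.arctanh(np.clip(v, -0.999, 0.999)))
            if vals:
                local[wi, si] = float(np.mean(vals))
    lam = 0.05  # transition penalty per slice of shift change
    cost = np.full_like(local, np.inf)
    back = np.zeros(local.shape, dtype=int)
    cost[0] = -local[0]
    for wi in range(1, len(starts)):
        for si in range(len(cand)):
            prev = cost[wi - 1] + lam * np.abs(cand - cand[si])
            j = int(np.argmin(prev))
            cost[wi, si] = prev[j] - local[wi, si]
            back[wi, si] = j
    path = np.zeros(len(starts), dtype=int)
    path[-1] = int(np.argmin(cost[-1]))
    for wi in range(len(starts) - 1, 0, -1):
        path[wi - 1] = back[wi, path[wi]]
    s_win = cand[path].astype(float)
    win_centers = starts + win / 2.0
    # windows whose comparison region was clipped by the stack boundary at
    # the solved shift have no real evidence; flag them so the caller's
    # curve fit extrapolates the trend instead of trusting a flattened path
    reliable = np.array([
        (w0 + min(s, 0) >= 0) and (w0 + win + max(s, 0) <= nz_d)
        for w0, s in zip(starts, s_win)])
    out = np.full(n_blocks, np.nan)
    for b in range(n_blocks):
        z0, z1 = b * bs, min(nz_d, (b + 1) * bs)
        sel = (win_centers >= z0) & (win_centers < z1) & reliable
        if sel.any():
            out[b] = float(np.mean(s_win[sel]))
    return out


def align_z_columns(
    mips: Mapping[tuple[int, int], EdgeMIPSet],
    search_range: int = 15,
    inplane_range: int = 12,
    per_block: bool = True,
    on_out_of_range: str = "clip",
    xy_offsets: Mapping[tuple[int, int], np.ndarray] | None = None,
    overlap_frac: float | None = None,
) -> dict[int, np.ndarray]:
    """Solve per-column z offsets from facing edge-strip slice profiles.

    Adjacent columns share their left/right overlap strips; the strip
    profiles (in-plane position x z) are cross-correlated — jointly over an
    in-plane shift, since x/y jitter is not yet solved — to find each
    column's z offset relative to column 0 (anchored at 0).  With
    ``per_block=True`` each z-block's offset is refined locally so a slow
    drift survives into the curve-fitting step; otherwise one offset per
    column is used.

    Returns {col: array of dz per block}.
    """
    cols = sorted({c for c, _ in mips})
    if len(cols) < 2:
        return {cols[0]: np.zeros(next(iter(mips.values())).n_blocks)} if cols else {}
    rows_by_col = {c: sorted(r for cc, r in mips if cc == c) for c in cols}
    any_set = next(iter(mips.values()))
    n_blocks, bs, nz = any_set.n_blocks, any_set.block_size, any_set.z_count

    offsets = {cols[0]: np.zeros(n_blocks)}
    for ca, cb in zip(cols[:-1], cols[1:]):
        shared = sorted(set(rows_by_col[ca]) & set(rows_by_col[cb]))
        if not shared:
            raise DegenerateSignalError(f"columns {ca} and {cb} share no rows")
        pairs = [(mips[(ca, r)].profiles["right"], mips[(cb, r)].profiles["left"])
                 for r in shared]
        dy_hints = None
        if xy_offsets is not None:
            # facing strips: profile rows p of A pair with rows p + dy of B,
            # dy = jy_A - jy_B
            dy_hints = [int(round(xy_offsets[(ca, r)][1] - xy_offsets[(cb, r)][1]))
                        for r in shared]
            # the top/bottom profiles of the same tile pair also overlap,
            # across the full inter-column seam (tile-local x shift is
            # jx_A - jx_B - stride) — much wider support than the thin
            # facing strips, which sharpens the drift estimate
            if overlap_frac is not None:
                nx_tile = mips[(ca, shared[0])].profiles["top"].shape[0]
                stride = int(round(nx_tile * (1 - overlap_frac)))
                for r in shared:
                    dx_rel = int(round(xy_offsets[(ca, r)][0]
                                       - xy_offsets[(cb, r)][0]))
                    for side in ("top", "bottom"):
                        pairs.append((mips[(ca, r)].profiles[side],
                                      mips[(cb, r)].profiles[side]))
                        dy_hints.append(dx_rel - stride)
        if per_block and n_blocks > 1:
            pair_dz = _column_pair_dz(pairs, search_range, inplane_range,
                                      n_blocks, bs, dy_hints=dy_hints)
        else:
            pair_dz = np.full(n_blocks, float(np.median(
                [_profile_shift(pa, pb, search_range)[0] for pa, pb in pairs])))
        out_of_range = np.abs(pair_dz) > search_range
        if np.any(out_of_range):
            if on_out_of_range == "error":
                raise DegenerateSignalError(
                    f"z offset between columns {ca},{cb} exceeds search range")
            log.warning("clipping z offsets beyond search range for columns %s-%s",
                        ca, cb)
            pair_dz = np.clip(pair_dz, -search_range, search_range)
        # pb shows sample z = k + s relative to pa's frame; accumulate
        offsets[cb] = offsets[ca] + pair_dz
    return offsets


# ---------------------------------------------------------------------------
# x/y alignment
# ---------------------------------------------------------------------------

def _overlap_ncc(a: np.ndarray, b: np.ndarray, s: tuple[int, int]) -> float:
    """NCC of the overlap of a and b under origin displacement s = oa - ob.

    Pixel a[p] and b[p + s] show the same content; only the in-bounds overlap
    contributes.
    """
    sl_a = []
    sl_b = []
    for d in range(2):
        sd = int(s[d])
        lo = max(0, -sd)
        hi = min(a.shape[d], b.shape[d] - sd)
        if hi - lo < 2:
            return -np.inf
        sl_a.append(slice(lo, hi))
        sl_b.append(slice(lo + sd, hi + sd))
    aa = a[tuple(sl_a)].ravel().astype(float)
    bb = b[tuple(sl_b)].ravel().astype(float)
    aa = aa - aa.mean()
    bb = bb - bb.mean()
    denom = np.linalg.norm(aa) * np.linalg.norm(bb)
    if denom < 1e-12:
        return -np.inf
    return float(aa @ bb / denom)


def _mip_pair_offset(a: np.ndarray, b: np.ndarray, nominal: tuple[int, int],
                     max_shift: int = 8) -> tuple[np.ndarray, float]:
    """Measured origin displacement (oa - ob) of facing strips minus nominal.

    Direct normalized-cross-correlation search on the strip overlap over
    integer shifts within ``max_shift`` of the nominal displacement, with
    parabolic sub-voxel refinement; ties break toward the nominal (zero
    jitter) solution.  FFT correlation is deliberately avoided: the strips
    are only a few voxels wide and circular wrap-around aliases the shift.
    """
    if np.ptp(a) < 1e-12 or np.ptp(b) < 1e-12:
        raise DegenerateSignalError("edge MIP has no signal")
    n0 = np.rint(np.asarray(nominal)).astype(int)
    r = int(max_shift)
    cand = np.arange(-r, r + 1)
    scores = np.full((len(cand), len(cand)), -np.inf)
    for i, dx in enumerate(cand):
        for j, dy in enumerate(cand):
            scores[i, j] = _overlap_ncc(a, b, (n0[0] + dx, n0[1] + dy))
    best = np.max(scores)
    ties = np.argwhere(scores >= best - 1e-12)
    k = ties[np.argmin(np.abs(cand[ties[:, 0]]) + np.abs(cand[ties[:, 1]]))]
    i, j = int(k[0]), int(k[1])
    delta = np.array([cand[i], cand[j]], dtype=float)
    # parabolic refinement per axis
    for axis, idx in ((0, i), (1, j)):
        if 0 < idx < len(cand) - 1:
            tri = scores[idx - 1:idx + 2, j] if axis == 0 else scores[i, idx - 1:idx + 2]
            if np.all(np.isfinite(tri)):
                d = tri[0] - 2 * tri[1] + tri[2]
                if abs(d) > 1e-12:
                    delta[axis] += 0.5 * (tri[0] - tri[2]) / d
    return delta, float(best)


def align_xy(
    grid: TileGrid,
    mips: Mapping[tuple[int, int], EdgeMIPSet],
    z_offsets: Mapping[int, np.ndarray] | None = None,
    max_shift: int = 12,
) -> "TileOffsets":
    """Per-tile, per-block (dx, dy) from facing-strip MIP correlation.

    Pairwise offsets between grid neighbors are reconciled into absolute
    per-tile offsets by least squares over the tile graph, with the (0, 0)
    tile anchored at zero.  The per-column z offsets are carried into the
    result so one :class:`TileOffsets` describes the full block solution.
    """
    tiles = {t.key: t for t in grid.tiles}
    keys = sorted(tiles)
    index = {k: i for i, k in enumerate(keys)}
    any_set = mips[keys[0]]
    n_blocks = any_set.n_blocks
    swx, swy = any_set.strip_width

    # pairwise equations per block: off[ib] - off[ia] = -delta, where delta is
    # the measured-minus-nominal origin displacement (jitter_a - jitter_b)
    pair_eqs: list[tuple[int, int, np.ndarray, np.ndarray]] = []
    for (c, r), t in tiles.items():
        nx, ny, _ = t.shape
        x0, y0 = grid.nominal_origin(t)
        for (nc, nr), side_a, side_b, nominal in (
            ((c + 1, r), "right", "left",
             ((x0 + nx - swx), y0)),
            ((c, r + 1), "bottom", "top",
             (x0, (y0 + ny - swy))),
        ):
            if (nc, nr) not in tiles:
                continue
            xb, yb = grid.nominal_origin(tiles[(nc, nr)])
            nom = (nominal[0] - xb, nominal[1] - yb)
            # whole-stack MIPs are invariant to the pair's z misalignment
            # (block MIPs are not); anchor the search there, then refine per
            # block within a small neighborhood
            full_a = mips[(c, r)].mips[side_a].max(axis=0)
            full_b = mips[(nc, nr)].mips[side_b].max(axis=0)
            d0, sc0 = _mip_pair_offset(full_a, full_b, nom, max_shift)
            deltas = np.zeros((n_blocks, 2))
            scores = np.zeros(n_blocks)
            nom0 = (nom[0] + d0[0], nom[1] + d0[1])
            for b in range(n_blocks):
                ma = mips[(c, r)].mips[side_a][b]
                mb = mips[(nc, nr)].mips[side_b][b]
                d, sc = _mip_pair_offset(ma, mb, nom0, 3)
                sc_zero = _overlap_ncc(ma, mb, tuple(np.rint(nom0).astype(int)))
                # a block may deviate from the whole-stack answer only on
                # clear evidence; block MIPs of z-misaligned neighbors are
                # noisy and would otherwise jitter the solution
                if not np.isfinite(sc_zero) or sc < sc_zero + 0.02 \
                        or sc < 0.85 * sc0:
                    d, sc = np.zeros(2), sc_zero if np.isfinite(sc_zero) else sc0
                deltas[b] = d0 + d
                scores[b] = sc
            pair_eqs.append((index[(c, r)], index[(nc, nr)], -deltas, scores))

    # connectivity check
    import networkx as nx_graph

    g = nx_graph.Graph()
    g.add_nodes_from(range(len(keys)))
    g.add_edges_from((ia, ib) for ia, ib, *_ in pair_eqs)
    if len(keys) > 1 and not nx_graph.is_connected(g):
        raise RuntimeError("tile graph is disconnected; cannot reconcile offsets")

    # weighted least squares per block with iterative outlier down-weighting
    # (a pair whose strips carry little shared content can return a confident
    # wrong offset; cycle redundancy in the tile graph exposes it)
    n = len(keys)
    block_xy = np.zeros((n, n_blocks, 2))
    for b in range(n_blocks):
        rows = []
        rhs = []
        w = []
        for ia, ib, deltas, scores in pair_eqs:
            row = np.zeros(n)
            row[ib] = 1.0
            row[ia] = -1.0
            rows.append(row)
            rhs.append(deltas[b])
            w.append(max(scores[b], 0.05) ** 2)
        rows.append(np.eye(n)[0])  # anchor
        rhs.append(np.zeros(2))
        w.append(1e3)
        A = np.asarray(rows)
        B = np.asarray(rhs)
        w = np.asarray(w)
        for _ in range(3):
            sw_ = np.sqrt(w)[:, None]
            sol, *_ = np.linalg.lstsq(A * sw_, B * sw_, rcond=None)
            resid = np.linalg.norm(A @ sol - B, axis=1)
            w[:-1] = (np.asarray([max(s[b], 0.05) ** 2
                                  for _, _, _, s in pair_eqs])
                      / (1.0 + (resid[:-1] / 1.5) ** 2))
        block_xy[:, b, :] = sol

    block = {}
    centers = np.array([any_set.block_center(b) for b in range(n_blocks)])
    z_offsets = z_offsets or {}
    for k in keys:
        dz = np.asarray(z_offsets.get(k[0], np.zeros(n_blocks)), dtype=float)
        if dz.ndim == 0:
            dz = np.full(n_blocks, float(dz))
        block[k] = np.column_stack([block_xy[index[k]], dz])
    return TileOffsets(block=block, block_centers=centers,
                       z_count=any_set.z_count)


@dataclass
class TileOffsets:
    """Solved offsets: per-block (audit trail) and per-slice (final)."""

    block: dict[tuple[int, int], np.ndarray]      # (n_blocks, 3): dx, dy, dz
    block_centers: np.ndarray                     # z center per block
    z_count: int
    per_slice: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    fit_residual: float = 0.0

    @property
    def n_blocks(self) -> int:
        return len(self.block_centers)


def _hampel(v: np.ndarray, thresh: float = 2.0) -> np.ndarray:
    """Replace isolated outliers by the median of their 3-block neighborhood.

    A single bad block estimate would otherwise be amplified by the
    interpolating spline; smooth drift varies little between neighboring
    blocks, so a point far from its local median is evidence of a failed
    correlation, not of real motion.
    """
    if len(v) < 3:
        return v
    out = v.astype(float).copy()
    for i in range(len(v)):
        lo = max(0, i - 1)
        hi = min(len(v), i + 2)
        med = np.median(v[lo:hi])
        if abs(v[i] - med) > thresh:
            out[i] = med
    return out


def _select_curve(centers: np.ndarray, vals: np.ndarray,
                  z: np.ndarray) -> tuple[np.ndarray, float]:
    """Fit offset-vs-z with complexity chosen by leave-one-out error.

    Candidates are polynomials of degree 0..3 and the interpolating spline;
    block estimates carry correlation noise, and an interpolating curve
    through noisy constant offsets oscillates badly, so the flexible models
    must earn their keep on held-out blocks.
    """
    n = len(centers)
    best = None
    # ascending complexity; a richer model must reduce held-out error by a
    # clear margin, otherwise its extrapolation risk is not worth taking
    for deg in range(0, min(3, n - 2) + 1):
        loo = 0.0
        for i in range(n):
            m = np.ones(n, dtype=bool)
            m[i] = False
            c = np.polyfit(centers[m], vals[m], deg)
            loo += (np.polyval(c, centers[i]) - vals[i]) ** 2
        if best is None or loo < 0.8 * best[0]:
            coeff = np.polyfit(centers, vals, deg)
            r = float(np.max(np.abs(np.polyval(coeff, centers) - vals)))
            best = (loo, np.polyval(coeff, z), r)
    if n >= 5:
        loo = 0.0
        for i in range(1, n - 1):  # interior points only; ends anchor the spline
            m = np.ones(n, dtype=bool)
            m[i] = False
            spl = interpolate.make_interp_spline(centers[m], vals[m],
                                                 k=min(3, n - 2))
            loo += float(spl(centers[i]) - vals[i]) ** 2
        loo *= n / max(n - 2, 1)
        if loo < 0.8 * best[0]:
            spl = interpolate.make_interp_spline(centers, vals, k=min(3, n - 1))
            # clamp extrapolation to the end values: an interpolating spline's
            # cubic tails diverge fast
            fit = spl(np.clip(z, centers[0], centers[-1]))
            best = (loo, fit, 0.0)
    return best[1], best[2]


def refine_slice_offsets(offsets: TileOffsets, model: str = "spline") -> TileOffsets:
    """Fit a smooth curve through block offsets to get per-slice offsets.

    ``model='linear'`` fits a straight line per component; ``'spline'`` an
    interpolating spline of order min(3, n_blocks - 1), which falls back to
    the line when fewer than 4 blocks are available.  With a single block the
    offset is extended as a constant (with a warning).
    """
    if model not in ("linear", "spline"):
        raise ValueError(f"unknown model {model!r}")
    z = np.arange(offsets.z_count, dtype=float)
    centers = offsets.block_centers
    per_slice: dict[tuple[int, int], np.ndarray] = {}
    resid = 0.0
    for key, blk in offsets.block.items():
        out = np.zeros((offsets.z_count, 3))
        for comp in range(3):
            raw = blk[:, comp]
            valid = np.isfinite(raw)  # boundary blocks may carry no evidence
            ctr = centers[valid]
            vals = _hampel(raw[valid])
            if len(ctr) == 0:
                log.warning("no valid block offsets for tile %s; using 0", key)
                continue
            if len(ctr) == 1:
                log.warning("single block for tile %s; constant offset extension", key)
                out[:, comp] = vals[0]
                continue
            if model == "linear" or len(ctr) < 4:
                coeff = np.polyfit(ctr, vals, min(1, len(ctr) - 1))
                fit = np.polyval(coeff, z)
                resid = max(resid, float(np.max(np.abs(
                    np.polyval(coeff, ctr) - vals))))
            else:
                fit, r = _select_curve(ctr, vals, z)
                resid = max(resid, r)
            out[:, comp] = fit
        per_slice[key] = out
    return TileOffsets(block=offsets.block, block_centers=centers,
                       z_count=offsets.z_count, per_slice=per_slice,
                       fit_residual=resid)


# ---------------------------------------------------------------------------
# fusion (pass 2)
# ---------------------------------------------------------------------------

def fuse(grid: TileGrid, offsets: TileOffsets, blend: str = "linear_feather",
         block_size: int = 32, feather: int = 8,
         spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    """Pass 2: place every tile at its per-slice offsets and blend.

    Offsets are rounded to integers at placement so that single-coverage
    voxels reproduce their unique source tile exactly.  Iteration order is
    fixed (sorted tile keys), making the result independent of tile-list
    order.
    """
    if blend not in ("max", "linear_feather"):
        raise ValueError(f"unknown blend {blend!r}")
    for t in grid.tiles:
        if t.key not in offsets.per_slice and t.key not in offsets.block:
            raise ValueError(f"offsets missing for tile {t.key}")

    def slice_offsets(key) -> np.ndarray:
        if key in offsets.per_slice:
            return offsets.per_slice[key]
        blk = offsets.block[key]
        reps = np.zeros((offsets.z_count, 3))
        for k in range(offsets.z_count):
            b = min(len(blk) - 1, k // max(1, int(np.ceil(
                offsets.z_count / len(blk)))))
            reps[k] = blk[b]
        return reps

    # bounding box over integer placements
    placements = {}
    lo = np.array([np.inf] * 3)
    hi = np.array([-np.inf] * 3)
    for t in sorted(grid.tiles, key=lambda t: t.key):
        nx, ny, nz = t.shape
        x0, y0 = grid.nominal_origin(t)
        off = np.rint(slice_offsets(t.key)).astype(int)
        placements[t.key] = off
        xs = x0 + off[:, 0]
        ys = y0 + off[:, 1]
        zs = np.arange(nz) + off[:, 2]
        lo = np.minimum(lo, [xs.min(), ys.min(), zs.min()])
        hi = np.maximum(hi, [xs.max() + nx, ys.max() + ny, zs.max() + 1])
    lo = lo.astype(int)
    shape = tuple((hi - lo).astype(int))

    acc = np.zeros(shape)
    wacc = np.zeros(shape)
    cover = np.zeros(shape, dtype=np.int16)
    last = np.zeros(shape)
    for t in sorted(grid.tiles, key=lambda t: t.key):
        nx, ny, nz = t.shape
        x0, y0 = grid.nominal_origin(t)
        off = placements[t.key]
        if blend == "linear_feather":
            wx = np.minimum.reduce([np.arange(nx) + 1, nx - np.arange(nx),
                                    np.full(nx, feather)]) / feather
            wy = np.minimum.reduce([np.arange(ny) + 1, ny - np.arange(ny),
                                    np.full(ny, feather)]) / feather
            w2d = wx[:, None] * wy[None, :]
        else:
            w2d = np.ones((nx, ny))
        for b in range(int(np.ceil(nz / block_size))):
            z0, z1 = b * block_size, min(nz, (b + 1) * block_size)
            slab = t.reader.read_block(z0, z1)
            for k in range(z0, z1):
                dx, dy, dz = off[k]
                gx, gy, gz = x0 + dx - lo[0], y0 + dy - lo[1], k + dz - lo[2]
                sl = slab[:, :, k - z0]
                if blend == "max":
                    region = acc[gx:gx + nx, gy:gy + ny, gz]
                    np.maximum(region, sl, out=region)
                    wacc[gx:gx + nx, gy:gy + ny, gz] = 1.0
                else:
                    acc[gx:gx + nx, gy:gy + ny, gz] += w2d * sl
                    wacc[gx:gx + nx, gy:gy + ny, gz] += w2d
                cover[gx:gx + nx, gy:gy + ny, gz] += 1
                last[gx:gx + nx, gy:gy + ny, gz] = sl
    if blend == "linear_feather":
        out = np.divide(acc, wacc, out=np.zeros_like(acc), where=wacc > 0)
        # voxels covered by exactly one tile reproduce their source exactly
        # (the feather quotient (w*v)/w is not bit-exact in floating point)
        out = np.where(cover == 1, last, out)
    else:
        out = acc
    return ImageVolume(out, spacing=spacing,
                       origin=tuple(lo * np.asarray(spacing, dtype=float)))


def stitch(grid: TileGrid, edge_fraction: float | None = None,
           block_size: int = 32,
           search_range: int = 15, max_shift: int = 12, model: str = "spline",
           blend: str = "linear_feather",
           z_per_column: bool = False) -> tuple[ImageVolume, TileOffsets]:
    """Full pipeline: pass 1, z alignment, x/y alignment, refinement, fusion.

    ``edge_fraction`` defaults to 0.10 (the classic outer-edge width) or, if
    larger, to the tiles' nominal overlap fraction plus the jitter search
    margin: when the overlap exceeds the collected edge width, jittered
    facing strips may share no physical content at all and no estimator can
    recover their offset, so the collector widens the strips just enough to
    keep the full overlap in view.
    """
    if edge_fraction is None:
        t0 = grid.tiles[0]
        margin = max_shift / min(t0.shape[0], t0.shape[1])
        edge_fraction = min(0.5, max(0.10, t0.overlap + margin))
    mips = {t.key: extract_edge_mips(t, edge_fraction, block_size)
            for t in grid.tiles}
    # x/y first: whole-stack edge MIPs are invariant to the (still unknown)
    # z offsets, and the solved in-plane offsets then pin down the in-plane
    # nuisance shift of the z-profile correlation
    block = align_xy(grid, mips, None, max_shift=max_shift)
    xy_mean = {k: v[:, :2].mean(axis=0) for k, v in block.block.items()}
    z_off = align_z_columns(mips, search_range=search_range,
                            per_block=not z_per_column, xy_offsets=xy_mean,
                            overlap_frac=grid.tiles[0].overlap)
    for k in block.block:
        block.block[k][:, 2] = z_off.get(k[0], np.zeros(block.n_blocks))
    refined = refine_slice_offsets(block, model=model)
    vol = fuse(grid, refined, blend=blend, block_size=block_size)
    return vol, refined
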