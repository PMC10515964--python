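"""Intensity-based image registration: affine + Gaussian-regularized demons.

The engine provides the registration contract used by template building,
multimodal alignment and ISH mapping.  The built-in method is deliberately
desk-scale: a multiresolution affine stage (phase-correlation translation
initialization, then Powell descent on up to 12 parameters of the chosen
similarity metric) followed by demons updates with Gaussian fluid/diffusion
regularization.  An external toolkit can be plugged in behind the same
contract (see :mod:`devatlas.sitk_backend`).

Transform convention
--------------------
A :class:`Transform` is a point mapping from the *fixed* image's world
coordinates to the *moving* image's world coordinates:

    m(x) = A @ x + u(x)

where ``A`` is the affine and ``u`` a dense displacement field (world units,
mm) stored on the fixed/reference grid.  Resampling the moving image onto the
fixed grid samples it at ``m(x)`` — the standard pull-back convention.
``compose([t1, t2])`` chains point mappings in list order (x -> t2(t1(x)), so
for affines the matrix is ``A2 @ A1``); applying the composite to an image
equals applying the list to the image in reverse order.

Mutual information is estimated from a 32-bin joint histogram with Parzen
(Gaussian) smoothing; for nonlinear cross-modality alignment the moving
intensities are first remapped through the conditional-mean transfer function
of that histogram, after which demons operates on matched intensities.
"""

from __future__ import annotations

import logging
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, optimize
from scipy.linalg import expm, logm

from .volume import ImageVolume

log = logging.getLogger(__name__)

__all__ = [
    "Transform",
    "RegistrationSpec",
    "register",
    "apply_transform",
    "compose_transforms",
    "average_transforms",
    "metric_value",
    "save_transform",
    "load_transform",
]


# ---------------------------------------------------------------------------
# Grid + Transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Sampling grid: shape, voxel spacing and world origin."""

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...]

    @classmethod
    def of(cls, vol: ImageVolume) -> "Grid":
        return cls(tuple(vol.shape), tuple(vol.spacing), tuple(vol.origin))

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def world_axes(self) -> list[np.ndarray]:
        return [np.asarray(o) + np.arange(n) * s
                for n, s, o in zip(self.shape, self.spacing, self.origin)]

    def world_mesh(self) -> np.ndarray:
        """Stack of world coordinates, shape (*grid, ndim)."""
        mesh = np.meshgrid(*self.world_axes(), indexing="ij")
        return np.stack(mesh, axis=-1)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def compatible(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class Transform:
    """Affine + optional dense displacement, fixed-world -> moving-world."""

    affine: np.ndarray
    warp: np.ndarray | None = None           # (*grid, ndim) world-unit offsets
    inverse_warp: np.ndarray | None = None   # on the same grid
    grid: Grid | None = None                 # reference (fixed) grid for warp

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        n = self.affine.shape[0] - 1
        if self.affine.shape != (n + 1, n + 1):
            raise ValueError("affine must be square homogeneous matrix")
        if abs(np.linalg.det(self.affine[:n, :n])) < 1e-12:
            raise ValueError("affine is singular")
        if self.warp is not None and self.grid is None:
            raise ValueError("warp requires a reference grid")

    @property
    def ndim(self) -> int:
        return self.affine.shape[0] - 1

    @property
    def is_nonlinear(self) -> bool:
        return self.warp is not None

    @classmethod
    def identity(cls, ndim: int = 3) -> "Transform":
        return cls(np.eye(ndim + 1))

    @classmethod
    def from_translation(cls, t) -> "Transform":
        t = np.asarray(t, dtype=float)
        A = np.eye(len(t) + 1)
        A[:-1, -1] = t
        return cls(A)

    # -- point mapping ------------------------------------------------------
    def _interp_warp(self, pts: np.ndarray, warp: np.ndarray) -> np.ndarray:
        idx = self.grid.world_to_index(pts)  # type: ignore[union-attr]
        coords = np.moveaxis(idx.reshape(-1, self.ndim), -1, 0)
        out = np.empty((pts.reshape(-1, self.ndim).shape[0], self.ndim))
        for d in range(self.ndim):
            out[:, d] = ndimage.map_coordinates(
                warp[..., d], coords, order=1, mode="nearest")
        return out.reshape(pts.shape)

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        """Apply the mapping m(x) = A x + u(x) to world points (..., ndim)."""
        pts = np.asarray(pts, dtype=float)
        n = self.ndim
        out = pts @ self.affine[:n, :n].T + self.affine[:n, n]
        if self.warp is not None:
            out = out + self._interp_warp(pts, self.warp)
        return out

    def inverse(self, grid: Grid | None = None, iterations: int = 30) -> "Transform":
        """Exact affine inverse; displacement inverted by fixed-point iteration."""
        Ainv = np.linalg.inv(self.affine)
        if self.warp is None:
            return Transform(Ainv)
        if self.inverse_warp is not None:
            return Transform(
                Ainv,
                warp=self.inverse_warp,
                inverse_warp=self.warp,
                grid=self.grid if grid is None else grid,
            )
        g = grid or self.grid
        inv_w = invert_displacement(self, g, iterations=iterations)
        return Transform(Ainv, warp=inv_w, inverse_warp=self.warp, grid=g)


def invert_displacement(t: Transform, grid: Grid, iterations: int = 30) -> np.ndarray:
    """Displacement v on `grid` such that (A^-1 y + v(y)) ~= m^{-1}(y)."""
    Ainv = np.linalg.inv(t.affine)
    n = t.ndim
    y = grid.world_mesh()
    x = y @ Ainv[:n, :n].T + Ainv[:n, n]  # initial guess: affine-only inverse
    for _ in range(iterations):
        err = t.map_points(x) - y
        if np.max(np.abs(err)) < 1e-4 * min(grid.spacing):
            break
        x = x - 0.7 * err @ np.linalg.inv(t.affine[:n, :n]).T
    return x - (y @ Ainv[:n, :n].T + Ainv[:n, n])


# ---------------------------------------------------------------------------
# Spec
# ---------------------------------------------------------------------------

@dataclass
class RegistrationSpec:
    """Configuration for :func:`register`.

    mode: 'linear', 'nonlinear' or 'linear_then_nonlinear'.
    metric: 'mutual_information', 'mean_squared_error' or 'cross_correlation'.
    channel_weights: per-channel weights (nonnegative, >=1 positive);
        defaults to equal weights.
    levels: multiresolution shrink factors, coarse to fine.
    iterations: demons iterations per level.
    smoothing_sigmas: pre-smoothing (voxels) per level.
    reg_sigma_fluid / reg_sigma_diffusion: Gaussian regularization of the
        demons update and of the accumulated field, in voxels.
    affine_dof: 3 (translation), 6 (rigid), 9 (+scale) or 12 (full affine).
    """

    mode: str = "linear_then_nonlinear"
    metric: str = "mutual_information"
    channel_weights: Sequence[float] | None = None
    levels: Sequence[int] = (4, 2, 1)
    iterations: Sequence[int] = (60, 40, 20)
    smoothing_sigmas: Sequence[float] = (2.0, 1.0, 0.0)
    affine_levels: Sequence[int] = (4, 2)
    affine_smoothing: Sequence[float] = (2.0, 1.0)
    reg_sigma_fluid: float = 1.0
    reg_sigma_diffusion: float = 1.2
    affine_dof: int = 12
    mi_bins: int = 32
    step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "nonlinear", "linear_then_nonlinear"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.metric not in ("mutual_information", "mean_squared_error",
                               "cross_correlation"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.channel_weights is not None:
            w = np.asarray(self.channel_weights, dtype=float)
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("channel weights must be nonnegative with at least one positive")

    def weights(self, n_channels: int) -> np.ndarray:
        if self.channel_weights is None:
            w = np.ones(n_channels)
        else:
            w = np.asarray(self.channel_weights, dtype=float)
            if len(w) != n_channels:
                raise ValueError("channel_weights length mismatch")
        return w / w.sum()


# ---------------------------------------------------------------------------
# Similarity metrics
# ---------------------------------------------------------------------------

def _normalize(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    lo, hi = np.min(a), np.max(a)
    if hi - lo < 1e-12:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32,
                       parzen_sigma: float = 1.0) -> float:
    """MI of two equally-shaped arrays from a Parzen-smoothed joint histogram."""
    a = _normalize(a).ravel()
    b = _normalize(b).ravel()
    hist, _, _ = np.histogram2d(a, b, bins=bins, range=[[0, 1], [0, 1]])
    if parzen_sigma > 0:
        hist = ndimage.gaussian_filter(hist, parzen_sigma)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def metric_value(fixed: np.ndarray, moving: np.ndarray, metric: str,
                 bins: int = 32) -> float:
    """Raw metric value: higher is better for MI/CC, lower for MSE."""
    if metric == "mutual_information":
        return mutual_information(fixed, moving, bins=bins)
    if metric == "mean_squared_error":
        return float(np.mean((_normalize(fixed) - _normalize(moving)) ** 2))
    if metric == "cross_correlation":
        f = _normalize(fixed).ravel() - _normalize(fixed).mean()
        m = _normalize(moving).ravel() - _normalize(moving).mean()
        denom = np.linalg.norm(f) * np.linalg.norm(m)
        return float(f @ m / denom) if denom > 0 else 0.0
    raise ValueError(f"unknown metric {metric!r}")


def _similarity(fixed: np.ndarray, moving: np.ndarray, spec: RegistrationSpec) -> float:
    """Higher-is-better wrapper used by the optimizer."""
    v = metric_value(fixed, moving, spec.metric, spec.mi_bins)
    return -v if spec.metric == "mean_squared_error" else v


# ---------------------------------------------------------------------------
# Array-level engine (nD)
# ---------------------------------------------------------------------------

def _params_to_affine(p: np.ndarray, ndim: int, center: np.ndarray) -> np.ndarray:
    """Translation / rotation / log-scale / shear parameters -> homogeneous matrix."""
    A = np.eye(ndim + 1)
    t = p[:ndim]
    M = np.eye(ndim)
    k = ndim
    n_rot = ndim * (ndim - 1) // 2
    if len(p) > k:  # rotations
        G = np.zeros((ndim, ndim))
        pairs = [(i, j) for i in range(ndim) for j in range(i + 1, ndim)]
        for (i, j), ang in zip(pairs, p[k:k + n_rot]):
            G[i, j] = -ang
            G[j, i] = ang
        M = expm(G)
        k += n_rot
    if len(p) > k:  # log-scales
        M = M @ np.diag(np.exp(p[k:k + ndim]))
        k += ndim
    if len(p) > k:  # shears
        S = np.eye(ndim)
        pairs = [(i, j) for i in range(ndim) for j in range(i + 1, ndim)]
        for (i, j), s in zip(pairs, p[k:k + n_rot]):
            S[i, j] = s
        M = M @ S
        k += n_rot
    A[:ndim, :ndim] = M
    A[:ndim, ndim] = t + center - M @ center
    return A


def _dof_to_nparams(dof: int, ndim: int) -> int:
    n_rot = ndim * (ndim - 1) // 2
    if dof <= ndim:
        return ndim
    if dof <= ndim + n_rot:
        return ndim + n_rot
    if dof <= 2 * ndim + n_rot:
        return ndim + n_rot + ndim
    return ndim + n_rot + ndim + n_rot


def _shrink(arr: np.ndarray, grid: Grid, factor: int,
            sigma: float) -> tuple[np.ndarray, Grid]:
    """Smooth and downsample onto a *centered* coarse grid.

    The coarse sample positions are symmetric about the volume center
    (start = (N - 1 - (n_c - 1) * factor) / 2), so downsampling commutes
    with grid reflection — the symmetric-template property rests on that —
    while linear interpolation keeps the geometry exact.
    """
    if sigma > 0:
        arr = ndimage.gaussian_filter(arr, sigma)
    if factor <= 1:
        return arr, grid
    shape_c = tuple(int(np.ceil(n / factor)) for n in arr.shape)
    starts = [(n - 1 - (nc - 1) * factor) / 2.0
              for n, nc in zip(arr.shape, shape_c)]
    axes = [s + factor * np.arange(nc) for s, nc in zip(starts, shape_c)]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh])
    out = ndimage.map_coordinates(arr, coords, order=3,
                                  mode="nearest").reshape(shape_c)
    grid_c = Grid(
        shape_c,
        tuple(s * factor for s in grid.spacing),
        tuple(o + st * s for o, st, s in zip(grid.origin, starts, grid.spacing)),
    )
    return out, grid_c


def _sample_moving(moving: np.ndarray, mgrid: Grid, pts: np.ndarray,
                   order: int = 1) -> np.ndarray:
    # nearest-edge extension: a zero fill would fabricate strong gradients
    # at the border for channels whose background is not zero (e.g. the
    # distance maps used in mask-assisted alignment)
    idx = mgrid.world_to_index(pts)
    coords = np.moveaxis(idx.reshape(-1, idx.shape[-1]), -1, 0)
    out = ndimage.map_coordinates(moving, coords, order=order, mode="nearest")
    return out.reshape(pts.shape[:-1])


def _check_inputs(fixed: Sequence[np.ndarray], moving: Sequence[np.ndarray]) -> None:
    if len(fixed) == 0 or len(moving) == 0:
        raise ValueError("empty channel list")
    if len(fixed) != len(moving):
        raise ValueError("fixed and moving channel lists must have equal length")
    for a in list(fixed) + list(moving):
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite voxels in registration input")
    for a in fixed[1:]:
        if a.shape != fixed[0].shape:
            raise ValueError("fixed channels must share a grid")
    for a in moving[1:]:
        if a.shape != moving[0].shape:
            raise ValueError("moving channels must share a grid")


def register_arrays(
    fixed: Sequence[np.ndarray],
    moving: Sequence[np.ndarray],
    spec: RegistrationSpec,
    fgrid: Grid | None = None,
    mgrid: Grid | None = None,
) -> Transform:
    """Register channel lists of plain arrays (2-D or 3-D); see :func:`register`."""
    fixed = [np.asarray(f, dtype=float) for f in fixed]
    moving = [np.asarray(m, dtype=float) for m in moving]
    _check_inputs(fixed, moving)
    ndim = fixed[0].ndim
    fgrid = fgrid or Grid(fixed[0].shape, (1.0,) * ndim, (0.0,) * ndim)
    mgrid = mgrid or Grid(moving[0].shape, (1.0,) * ndim, (0.0,) * ndim)
    fixed_n = [_normalize(f) for f in fixed]
    moving_n = [_normalize(m) for m in moving]
    w = spec.weights(len(fixed_n))

    affine = np.eye(ndim + 1)
    if spec.mode in ("linear", "linear_then_nonlinear"):
        affine = _affine_stage(fixed_n, moving_n, fgrid, mgrid, spec, w)

    t = Transform(affine)
    if spec.mode in ("nonlinear", "linear_then_nonlinear"):
        warp, warp_grid = _demons_stage(fixed_n, moving_n, fgrid, mgrid, spec,
                                        w, affine)
        if not warp_grid.compatible(fgrid):
            warp = _upsample_warp(warp, warp_grid, fgrid)
        t = Transform(affine, warp=warp, grid=fgrid)
        t.inverse_warp = invert_displacement(t, fgrid)

    # metric-monotonicity guarantee: never return a transform worse than identity
    ref = _resample_channels(moving_n, Transform(np.eye(ndim + 1)), fgrid, mgrid)
    out = _resample_channels(moving_n, t, fgrid, mgrid)
    s_id = sum(wi * _similarity(f, r, spec) for wi, f, r in zip(w, fixed_n, ref))
    s_t = sum(wi * _similarity(f, o, spec) for wi, f, o in zip(w, fixed_n, out))
    if s_t < s_id:
        log.warning("registration did not improve metric (%.4f < %.4f); "
                    "returning identity", s_t, s_id)
        ident = Transform(np.eye(ndim + 1))
        if spec.mode != "linear":
            zeros = np.zeros(fgrid.shape + (ndim,))
            ident = Transform(np.eye(ndim + 1), warp=zeros,
                              inverse_warp=zeros.copy(), grid=fgrid)
        return ident
    return t


def _resample_channels(channels, t: Transform, fgrid: Grid, mgrid: Grid):
    pts = t.map_points(fgrid.world_mesh())
    return [_sample_moving(c, mgrid, pts) for c in channels]


def _affine_stage(fixed, moving, fgrid, mgrid, spec, w) -> np.ndarray:
    ndim = fixed[0].ndim
    center = np.asarray(fgrid.origin) + (np.asarray(fgrid.shape) - 1) \
        * np.asarray(fgrid.spacing) / 2.0

    # translation init by phase correlation on the first channel
    t0 = np.zeros(ndim)
    if fixed[0].shape == moving[0].shape:
        try:
            from skimage.registration import phase_cross_correlation

            shift, _, _ = phase_cross_correlation(fixed[0], moving[0],
                                                  upsample_factor=4,
                                                  normalization=None)
            t0 = -np.asarray(shift) * np.asarray(mgrid.spacing)
        except Exception:  # degenerate signal; keep zero init
            pass

    n_params = _dof_to_nparams(spec.affine_dof, ndim)

    def objective(p, level_data, metric=None):
        A = _params_to_affine(np.asarray(p), ndim, center)
        fg, mg, fs, ms = level_data
        t = Transform(A)
        pts = t.map_points(fg.world_mesh())
        score = 0.0
        eff = spec if metric is None else dataclasses.replace(spec,
                                                              metric=metric)
        for wi, f, m in zip(w, fs, ms):
            warped = _sample_moving(m, mg, pts)
            score += wi * _similarity(f, warped, eff)
        return -score

    p = np.zeros(n_params)
    p[:ndim] = t0
    for level, sigma in zip(spec.affine_levels, spec.affine_smoothing):
        fs_g = [_shrink(f, fgrid, level, sigma) for f in fixed]
        ms_g = [_shrink(m, mgrid, level, sigma) for m in moving]
        fs = [a for a, _ in fs_g]
        ms = [a for a, _ in ms_g]
        fg = fs_g[0][1]
        mg = ms_g[0][1]
        data = (fg, mg, fs, ms)
        # candidate comparison: seeded init vs zero init at the coarsest level
        if level == spec.affine_levels[0] and np.any(p[:ndim]):
            if objective(np.zeros(n_params), data) < objective(p, data):
                p = np.zeros(n_params)
        res = optimize.minimize(
            objective, p, args=(data,), method="Powell",
            options={"maxiter": 40 * n_params, "xtol": 1e-3, "ftol": 1e-6},
        )
        p = res.x
    A = _params_to_affine(p, ndim, center)

    # final full-resolution translation polish: the multiresolution stages
    # interpolate twice and can leave a fraction-of-a-voxel bias; one phase
    # correlation between the fixed image and the affinely warped moving
    # image removes it (skipped for cross-modality pairs, where raw phase
    # correlation is unreliable)
    if spec.metric != "mutual_information":
        try:
            from skimage.registration import phase_cross_correlation

            t = Transform(A)
            pts = t.map_points(fgrid.world_mesh())
            warped = _sample_moving(moving[0], mgrid, pts)
            shift, _, _ = phase_cross_correlation(fixed[0], warped,
                                                  upsample_factor=16,
                                                  normalization=None)
            resid = -np.asarray(shift) * np.asarray(fgrid.spacing)
            if np.all(np.abs(resid) < 2 * np.max(fgrid.spacing)):
                A_fix = np.eye(ndim + 1)
                A_fix[:ndim, ndim] = resid
                A = A @ A_fix
        except Exception:  # degenerate signal; keep the Powell answer
            pass
    return A


def _local_normalize(img: np.ndarray, sigma: float = 3.0) -> np.ndarray:
    """Subtract the local mean and divide by the local standard deviation.

    Demons driven by raw intensity differences converts local amplitude
    mismatch (a dim wide blob vs a bright narrow one) into spurious
    geometric deformation; after local normalization only structure shape
    drives the forces — the demons analogue of a local-correlation metric.
    """
    mean = ndimage.gaussian_filter(img, sigma)
    var = ndimage.gaussian_filter(img * img, sigma) - mean ** 2
    return (img - mean) / np.sqrt(np.maximum(var, 1e-6))


def _match_intensities(fixed: np.ndarray, moving: np.ndarray, bins: int) -> np.ndarray:
    """Map moving intensities to the conditional mean of fixed given moving.

    Turns a cross-modality pair (any intensity relationship captured by the
    joint histogram, e.g. an inversion) into a same-modality pair so demons
    forces are meaningful.
    """
    f = fixed.ravel()
    m = moving.ravel()
    edges = np.linspace(0, 1, bins + 1)
    which = np.clip(np.digitize(m, edges) - 1, 0, bins - 1)
    sums = np.bincount(which, weights=f, minlength=bins)
    counts = np.bincount(which, minlength=bins)
    lut = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    # fill empty bins from neighbors
    if np.any(counts == 0) and np.any(counts > 0):
        good = np.flatnonzero(counts > 0)
        lut = np.interp(np.arange(bins), good, lut[good])
    return lut[which].reshape(moving.shape)


def _demons_stage(fixed, moving, fgrid, mgrid, spec, w, affine) -> np.ndarray:
    ndim = fixed[0].ndim
    warp = None  # displacement on the current level's fixed grid, world units
    for level, sigma, iters in zip(spec.levels, spec.smoothing_sigmas,
                                   spec.iterations):
        fs_g = [_shrink(f, fgrid, level, sigma) for f in fixed]
        ms_g = [_shrink(m, mgrid, level, sigma) for m in moving]
        fs = [a for a, _ in fs_g]
        ms = [a for a, _ in ms_g]
        fg = fs_g[0][1]
        mg = ms_g[0][1]
        sp = np.asarray(fg.spacing)
        mesh = fg.world_mesh()
        if warp is None:
            warp = np.zeros(fg.shape + (ndim,))
        else:
            warp = _upsample_warp(warp, last_fg, fg)

        if spec.metric == "cross_correlation":
            fs = [_local_normalize(f) for f in fs]
            ms = [_local_normalize(m) for m in ms]
        # cross-modality: remap moving through the joint-histogram transfer fn
        if spec.metric == "mutual_information":
            t_aff = Transform(affine)
            pts0 = t_aff.map_points(mesh)
            ms = [_match_intensities(f, _sample_moving(m, mg, pts0), spec.mi_bins)
                  if np.ptp(m) > 0 else m for f, m in zip(fs, ms)]
            # after remapping, moving lives on the fixed grid under the affine
            mg_eff, affine_eff = fg, np.eye(ndim + 1)
        else:
            mg_eff, affine_eff = mg, affine

        A = affine_eff
        grads = [np.stack(np.gradient(f, *sp), axis=-1) for f in fs]
        for _ in range(iters):
            pts = mesh @ A[:ndim, :ndim].T + A[:ndim, ndim] + warp
            # vector-valued demons: channels share one normalization, so a
            # channel's pull scales with its actual similarity gradient and
            # the stated weights weight the metric, not per-channel steps
            numer = np.zeros_like(warp)
            denom = np.zeros(warp.shape[:-1])
            for wi, f, m, gf in zip(w, fs, ms, grads):
                if wi == 0:
                    continue
                wm = _sample_moving(m, mg_eff, pts)
                diff = wm - f
                numer += wi * diff[..., None] * gf
                denom += wi * (np.sum(gf ** 2, axis=-1)
                               + (diff ** 2) / (np.mean(sp) ** 2))
            scale = np.where(denom > 1e-9, 1.0 / np.maximum(denom, 1e-9), 0.0)
            update = -scale[..., None] * numer
            if spec.reg_sigma_fluid > 0:
                for d in range(ndim):
                    update[..., d] = ndimage.gaussian_filter(
                        update[..., d], spec.reg_sigma_fluid)
            warp = warp + spec.step * update
            if spec.reg_sigma_diffusion > 0:
                for d in range(ndim):
                    warp[..., d] = ndimage.gaussian_filter(
                        warp[..., d], spec.reg_sigma_diffusion)

        last_fg = fg
    if spec.metric == "mutual_information":
        # demons ran in remapped space where moving was pre-resampled through
        # the affine: the matching point of x is A(x + d(x)); re-express as
        # m(x) = A x + u(x) with u = A(x + d) - A x
        n = ndim
        mesh = last_fg.world_mesh()
        A = np.asarray(affine)
        pts = (mesh + warp) @ A[:n, :n].T + A[:n, n]
        warp = pts - (mesh @ A[:n, :n].T + A[:n, n])
    return warp, last_fg


def _upsample_warp(warp: np.ndarray, src: Grid, dst: Grid) -> np.ndarray:
    """Resample a displacement field between grids, geometry-aware."""
    ndim = warp.shape[-1]
    idx = src.world_to_index(dst.world_mesh())
    coords = np.moveaxis(idx.reshape(-1, ndim), -1, 0)
    out = np.empty(dst.shape + (ndim,))
    for d in range(ndim):
        out[..., d] = ndimage.map_coordinates(
            warp[..., d], coords, order=1, mode="nearest").reshape(dst.shape)
    return out


# ---------------------------------------------------------------------------
# ImageVolume-level API
# ---------------------------------------------------------------------------

def _as_channel_list(v) -> list[ImageVolume]:
    return [v] if isinstance(v, ImageVolume) else list(v)


def register(fixed, moving, spec: RegistrationSpec | None = None) -> Transform:
    """Register moving to fixed; each side is a volume or list of channel volumes.

    Returns the fixed-world -> moving-world mapping; resampling the moving
    image through it (:func:`apply_transform`) aligns it with the fixed image.
    The returned transform is never worse than identity under the requested
    metric, and carries an inverse displacement field in nonlinear modes.
    """
    spec = spec or RegistrationSpec()
    fixed = _as_channel_list(fixed)
    moving = _as_channel_list(moving)
    if not fixed or not moving:
        raise ValueError("empty channel list")
    fgrid = Grid.of(fixed[0])
    mgrid = Grid.of(moving[0])
    for f in fixed[1:]:
        if not Grid.of(f).compatible(fgrid):
            raise ValueError("fixed channels must share one grid")
    for m in moving[1:]:
        if not Grid.of(m).compatible(mgrid):
            raise ValueError("moving channels must share one grid")
    return register_arrays([f.data for f in fixed], [m.data for m in moving],
                           spec, fgrid, mgrid)


def apply_transform(
    vol: ImageVolume,
    t: Transform,
    reference: ImageVolume | Grid,
    interpolation: str = "linear",
    mode: str = "constant",
) -> ImageVolume:
    """Resample `vol` through `t` onto the reference grid.

    Label volumes must use ``interpolation='nearest'`` (the label set is then
    a subset of the input's).  ``mode`` controls out-of-field values
    (scipy extension modes; 'constant' fills 0, 'nearest' extends edges —
    use the latter for images whose background is not zero).
    """
    ref_grid = reference if isinstance(reference, Grid) else Grid.of(reference)
    if t.is_nonlinear and t.warp is None:
        raise ValueError("nonlinear transform lacks a warp field")
    pts = t.map_points(ref_grid.world_mesh())
    order = {"nearest": 0, "linear": 1, "bspline": 3}[interpolation]
    src = Grid.of(vol)
    idx = src.world_to_index(pts)
    coords = np.moveaxis(idx.reshape(-1, idx.shape[-1]), -1, 0)
    data = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float if order > 0 else vol.data.dtype),
        coords, order=order, mode=mode, cval=0.0,
    ).reshape(ref_grid.shape)
    if order == 0:
        data = data.astype(vol.data.dtype)
    return ImageVolume(data, spacing=ref_grid.spacing, origin=ref_grid.origin,
                       orientation=vol.orientation, unit=vol.unit)


def compose_transforms(ts: Sequence[Transform], grid: Grid | None = None) -> Transform:
    """Chain point mappings in list order: x -> t_n(...t_1(x)).

    For affines the composite matrix is ``A_n @ ... @ A_1``.  If any member
    is nonlinear a reference grid is required (defaults to the first
    nonlinear member's grid); the composite displacement is evaluated there.
    """
    if len(ts) == 0:
        raise ValueError("need at least one transform")
    ndim = ts[0].ndim
    if any(t.ndim != ndim for t in ts):
        raise ValueError("incompatible transform dimensions")
    if all(t.warp is None for t in ts):
        A = np.eye(ndim + 1)
        for t in ts:
            A = t.affine @ A
        return Transform(A)
    g = grid
    if g is None:
        g = next(t.grid for t in ts if t.grid is not None)
    mesh = g.world_mesh()
    pts = mesh
    for t in ts:
        pts = t.map_points(pts)
    A = np.eye(ndim + 1)
    for t in ts:
        A = t.affine @ A
    n = ndim
    resid = pts - (mesh @ A[:n, :n].T + A[:n, n])
    out = Transform(A, warp=resid, grid=g)
    out.inverse_warp = invert_displacement(out, g)
    return out


def average_transforms(ts: Sequence[Transform]) -> Transform:
    """Voxel-wise mean displacement + log-domain (matrix-log) mean affine."""
    if len(ts) == 0:
        raise ValueError("need at least one transform")
    ndim = ts[0].ndim
    grids = [t.grid for t in ts if t.grid is not None]
    if grids and not all(g.compatible(grids[0]) for g in grids):
        raise ValueError("transforms live on mixed grids")
    logs = [np.real(logm(t.affine)) for t in ts]
    A = np.real(expm(np.mean(logs, axis=0)))
    A[ndim, :ndim] = 0.0
    A[ndim, ndim] = 1.0
    if not grids:
        return Transform(A)
    g = grids[0]
    warps = [t.warp if t.warp is not None else np.zeros(g.shape + (ndim,))
             for t in ts]
    mean_w = np.mean(warps, axis=0)
    out = Transform(A, warp=mean_w, grid=g)
    out.inverse_warp = invert_displacement(out, g)
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_transform(t: Transform, base) -> None:
    """Write ``<base>_affine.txt`` (+ warp NIfTIs and a grid JSON if nonlinear)."""
    import json

    base = Path(base)
    np.savetxt(str(base) + "_affine.txt", t.affine)
    if t.warp is not None:
        import nibabel as nib

        g = t.grid
        meta = {"shape": list(g.shape), "spacing": list(g.spacing),
                "origin": list(g.origin)}
        Path(str(base) + "_grid.json").write_text(json.dumps(meta))
        affine = np.eye(4)
        for name, w in (("warp", t.warp), ("inverse_warp", t.inverse_warp)):
            if w is None:
                continue
            arr = w[..., None, :] if w.ndim == 4 else w  # (x,y,z,1,3) scanner conv.
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine),
                     str(base) + f"_{name}.nii.gz")


def load_transform(base) -> Transform:
    import json

    base = Path(base)
    affine = np.loadtxt(str(base) + "_affine.txt")
    warp = inv = grid = None
    gpath = Path(str(base) + "_grid.json")
    if gpath.exists():
        import nibabel as nib

        meta = json.loads(gpath.read_text())
        grid = Grid(tuple(meta["shape"]), tuple(meta["spacing"]),
                    tuple(meta["origin"]))
        wpath = Path(str(base) + "_warp.nii.gz")
        if wpath.exists():
            warp = np.asanyarray(nib.load(str(wpath)).dataobj)
            if warp.ndim == 5:
                warp = warp[..., 0, :]
        ipath = Path(str(base) + "_inverse_warp.nii.gz")
        if ipath.exists():
            inv = np.asanyarray(nib.load(str(ipath)).dataobj)
            if inv.ndim == 5:
                inv = inv[..., 0, :]
    return Transform(affine, warp=warp, inverse_warp=inv, grid=grid)
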