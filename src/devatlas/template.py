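"""Symmetric, morphology- and intensity-averaged template construction.

A template is built from a cohort of subject volumes by the classic
three-step groupwise loop: starting from the voxel-wise mean of the inputs,
each iteration (1) registers every input to the current template estimate,
(2) voxel-wise averages the warped inputs, and (3) applies the *inverse of
the average transform* to that intensity average, which removes the cohort's
mean shape bias from the template.  Iterating drives the mean of the
per-subject displacement fields toward zero (shape centering).

Left-right symmetry is obtained by construction: every subject is duplicated
and reflected across the midsagittal plane before building, doubling the
cohort, so the fixed point of the loop is mirror-symmetric.

Sibling contrasts (e.g. T2w, FA, ADC alongside a DWI primary channel) are
never re-registered: the final per-subject warps estimated on the primary
channel are reused to warp each contrast, and the warped contrasts are
averaged into one template per contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .registration import (
    Grid,
    RegistrationSpec,
    Transform,
    apply_transform,
    average_transforms,
    compose_transforms,
    register,
)
from .volume import ImageVolume, resample_volume

log = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord",
    "Cohort",
    "TemplateResult",
    "reflect_midsagittal",
    "symmetrize_cohort",
    "build_template",
    "propagate_contrasts",
    "staged_multires_build",
]

RegisterFn = Callable[..., Transform]


@dataclass
class SubjectRecord:
    """One cohort member: a primary channel plus sibling contrasts."""

    subject_id: str
    primary: ImageVolume
    contrasts: dict[str, ImageVolume] = field(default_factory=dict)
    reflected: bool = False

    @property
    def key(self) -> tuple[str, bool]:
        return (self.subject_id, self.reflected)


@dataclass
class Cohort:
    members: list[SubjectRecord]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def contrast_names(self) -> list[str]:
        names: list[str] = []
        for m in self.members:
            for n in m.contrasts:
                if n not in names:
                    names.append(n)
        return names


@dataclass
class TemplateResult:
    """Templates per contrast, final per-subject transforms, convergence log."""

    templates: dict[str, ImageVolume]
    transforms: dict[tuple[str, bool], Transform]
    convergence: list[dict]
    contrast_counts: dict[str, int] = field(default_factory=dict)

    @property
    def template(self) -> ImageVolume:
        return self.templates["primary"]


# ---------------------------------------------------------------------------
# reflection / symmetrization
# ---------------------------------------------------------------------------

_LR = {"R", "L"}


def reflect_midsagittal(vol: ImageVolume) -> ImageVolume:
    """Mirror across the grid's x-center plane (the left-right axis).

    Voxel (i, j, k) maps to (N-1-i, j, k); the world grid is unchanged.  The
    left-right axis is taken from the orientation code and must be axis 0
    (canonical RAS), otherwise an orientation error is raised.
    """
    if vol.orientation[0] not in _LR:
        raise ValueError(
            f"cannot identify left-right axis from orientation {vol.orientation!r}")
    return vol.copy(data=np.ascontiguousarray(vol.data[::-1]))


def symmetrize_cohort(c: Cohort) -> Cohort:
    """Duplicate every member reflected across the midline; doubles the cohort."""
    out: list[SubjectRecord] = []
    for m in c.members:
        out.append(m)
    for m in c.members:
        out.append(SubjectRecord(
            subject_id=m.subject_id,
            primary=reflect_midsagittal(m.primary),
            contrasts={k: reflect_midsagittal(v) for k, v in m.contrasts.items()},
            reflected=True,
        ))
    return Cohort(out)


# ---------------------------------------------------------------------------
# template loop
# ---------------------------------------------------------------------------

def _rescale01(vol: ImageVolume) -> ImageVolume:
    d = np.asarray(vol.data, dtype=float)
    lo, hi = d.min(), d.max()
    if hi - lo < 1e-12:
        return vol.copy(data=np.zeros_like(d))
    return vol.copy(data=(d - lo) / (hi - lo))


def default_template_spec() -> RegistrationSpec:
    return RegistrationSpec(
        mode="nonlinear",
        metric="mean_squared_error",
        levels=(4, 2),
        iterations=(60, 30),
        smoothing_sigmas=(1.5, 0.5),
    )


def build_template(
    c: Cohort,
    engine: RegisterFn | None = None,
    spec: RegistrationSpec | None = None,
    n_iter: int = 4,
    initial: ImageVolume | None = None,
    early_stop_voxels: float = 0.1,
    sharpen: float = 1.0,
) -> TemplateResult:
    """Iterative register-average-recenter template construction.

    Parameters
    ----------
    c:
        Cohort whose primary channels share one grid.
    engine:
        Registration callable ``(fixed, moving, spec) -> Transform``;
        defaults to the built-in engine.
    n_iter:
        Fixed iteration count (an early stop triggers once the mean update
        displacement falls below ``early_stop_voxels`` voxels).
    initial:
        Optional starting template (used by the staged multiresolution
        build); defaults to the voxel-wise mean of the inputs.
    sharpen:
        Unsharp-mask weight applied to the intensity average each iteration.
        Voxel-wise averaging of imperfectly aligned images blurs the
        template, and registering sharp subjects to a blurred template
        biases every warp coherently inward; sharpening counteracts that
        contraction (0 disables).
    """
    if len(c) == 0:
        raise ValueError("cohort is empty")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    engine = engine or register
    spec = spec or default_template_spec()

    members = [replace(m, primary=_rescale01(m.primary)) for m in c.members]
    grid = Grid.of(members[0].primary)
    for m in members[1:]:
        if not Grid.of(m.primary).compatible(grid):
            raise ValueError(
                f"subject {m.subject_id} not on the common grid; resample first")

    if initial is not None:
        template = _rescale01(initial)
    else:
        template = members[0].primary.copy(
            data=np.mean([m.primary.data for m in members], axis=0))

    transforms: dict[tuple[str, bool], Transform] = {
        m.key: Transform.identity(3) for m in members}
    convergence: list[dict] = []
    vox = float(np.mean(template.spacing))

    for it in range(n_iter):
        warped = []
        for m in members:
            try:
                t = engine(template, m.primary, spec)
            except Exception as exc:  # noqa: BLE001 - annotate failing subject
                raise RuntimeError(
                    f"registration failed for subject {m.subject_id} "
                    f"(reflected={m.reflected}): {exc}") from exc
            transforms[m.key] = t
            warped.append(apply_transform(m.primary, t, template).data)
        avg_t = average_transforms([transforms[m.key] for m in members])
        mean_img = np.mean(warped, axis=0)
        scatter = float(np.mean([
            np.mean(np.linalg.norm(transforms[m.key].warp, axis=-1))
            for m in members
            if transforms[m.key].warp is not None] or [0.0])) / vox
        if sharpen > 0 and scatter > 0.05:
            # voxel-wise averaging of residually misaligned images blurs the
            # template; unsharp masking counters the coherent inward bias
            # that registering sharp subjects to a blurred target creates.
            # The blur grows with the warp scatter, so the strength tracks
            # it — an already-aligned cohort needs none.
            from scipy import ndimage as ndi

            strength = sharpen * min(1.0, scatter)
            mean_img = np.clip(
                mean_img + strength * (mean_img - ndi.gaussian_filter(mean_img, 1.0)),
                0.0, None)
        avg_img = template.copy(data=mean_img)
        new_template = apply_transform(avg_img, avg_t.inverse(grid), template)

        mean_update = 0.0
        if avg_t.warp is not None:
            mean_update = float(np.mean(
                np.linalg.norm(avg_t.warp, axis=-1))) / vox
        intensity_change = float(np.mean(
            np.abs(new_template.data - template.data)))
        convergence.append({"iteration": it, "mean_update_displacement": mean_update,
                            "intensity_change": intensity_change})
        template = _rescale01(new_template)
        last_avg = avg_t
        if mean_update < early_stop_voxels and it > 0:
            log.info("template converged at iteration %d (update %.3f voxels)",
                     it, mean_update)
            break

    # the shape update moved the template by the inverse average transform;
    # the per-subject transforms must be composed with that same inverse so
    # they map the *returned* template to each subject — which also removes
    # the cohort-mean component from the final displacement fields
    if last_avg.warp is not None or not np.allclose(last_avg.affine,
                                                    np.eye(4)):
        avg_inv = last_avg.inverse(grid)
        for key in transforms:
            transforms[key] = compose_transforms([avg_inv, transforms[key]],
                                                 grid=grid)

    return TemplateResult(templates={"primary": template},
                          transforms=transforms, convergence=convergence)


def propagate_contrasts(
    result: TemplateResult,
    c: Cohort,
    policy: str = "skip",
) -> TemplateResult:
    """Warp sibling contrasts through the stored per-subject transforms.

    Transforms are reused, never re-estimated; one template per contrast name
    is added to the result.  ``policy`` controls subjects lacking a contrast:
    ``'skip'`` averages over those that have it (count logged), ``'error'``
    raises.
    """
    if policy not in ("skip", "error"):
        raise ValueError(f"unknown policy {policy!r}")
    template = result.template
    counts: dict[str, int] = {}
    for name in c.contrast_names():
        warped = []
        for m in c.members:
            if name not in m.contrasts:
                if policy == "error":
                    raise ValueError(
                        f"contrast {name!r} missing for subject {m.subject_id}")
                continue
            t = result.transforms[m.key]
            warped.append(apply_transform(m.contrasts[name], t, template).data)
        if not warped:
            continue
        counts[name] = len(warped)
        log.info("contrast %s averaged over %d warped volumes", name, len(warped))
        result.templates[name] = template.copy(data=np.mean(warped, axis=0))
    result.contrast_counts.update(counts)
    return result


def staged_multires_build(
    c: Cohort,
    resolutions: Sequence[float],
    engine: RegisterFn | None = None,
    spec: RegistrationSpec | None = None,
    n_iter: int = 4,
) -> TemplateResult:
    """Coarse-to-fine staged build (e.g. 50 um, then 20 um, then 10 um).

    Each stage resamples the cohort to the stage's spacing and initializes
    from the previous stage's template upsampled to that spacing; the final
    result is at the finest spacing.
    """
    res = [float(r) for r in resolutions]
    if any(b >= a for a, b in zip(res[:-1], res[1:])):
        raise ValueError("resolutions must be strictly decreasing spacings")
    template: ImageVolume | None = None
    result: TemplateResult | None = None
    for spacing in res:
        stage_members = [
            replace(m, primary=resample_volume(m.primary, spacing, "linear"))
            for m in c.members
        ]
        stage = Cohort(stage_members)
        initial = None
        if template is not None:
            initial = resample_volume(template, spacing, "linear")
            ref_shape = stage_members[0].primary.shape
            if initial.shape != ref_shape:  # clip/pad to the cohort grid
                data = np.zeros(ref_shape)
                sl = tuple(slice(0, min(a, b)) for a, b in
                           zip(ref_shape, initial.shape))
                data[sl] = initial.data[sl]
                initial = stage_members[0].primary.copy(data=data)
        result = build_template(stage, engine=engine, spec=spec, n_iter=n_iter,
                                initial=initial)
        template = result.template
    assert result is not None
    return result
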