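"""Optional SimpleITK registration backend.

The registration contract is a callable ``(fixed, moving, spec) ->
Transform``; this module adapts SimpleITK's registration framework to it so
an external, independently implemented optimizer can stand behind the same
interface as the built-in engine.  Only the linear modes are adapted — the
backend exists to cross-check the recovery harness, not to replace the
engine.  Requires the ``SimpleITK`` package (optional extra ``sitk``).
"""

from __future__ import annotations

import numpy as np

from .registration import RegistrationSpec, Transform
from .volume import ImageVolume

__all__ = ["sitk_register"]


def _to_sitk(vol: ImageVolume):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.asarray(vol.data, dtype=np.float64).T))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def sitk_register(fixed: ImageVolume, moving: ImageVolume,
                  spec: RegistrationSpec | None = None) -> Transform:
    """Linear registration via SimpleITK, returned as a :class:`Transform`.

    Uses mean squares with regular-step gradient descent on a translation
    (``affine_dof <= 3``) or full affine transform.  The returned transform
    follows the package convention: a pull-back map from fixed-world to
    moving-world coordinates, which matches SimpleITK's resampling
    convention directly.
    """
    import SimpleITK as sitk

    spec = spec or RegistrationSpec(mode="linear",
                                    metric="mean_squared_error")
    f = _to_sitk(fixed)
    m = _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=300)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    if spec.affine_dof <= 3:
        tx = sitk.TranslationTransform(3)
    else:
        tx = sitk.CenteredTransformInitializer(
            f, m, sitk.AffineTransform(3),
            sitk.CenteredTransformInitializerFilter.GEOMETRY)
    reg.SetInitialTransform(tx, inPlace=True)
    result = reg.Execute(f, m)

    A = np.eye(4)
    if isinstance(result, sitk.TranslationTransform):
        A[:3, 3] = result.GetOffset()
    else:
        flat = sitk.AffineTransform(result)
        A[:3, :3] = np.asarray(flat.GetMatrix()).reshape(3, 3)
        A[:3, 3] = np.asarray(flat.GetTranslation())
        center = np.asarray(flat.GetCenter())
        A[:3, 3] += center - A[:3, :3] @ center
    return Transform(A)
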