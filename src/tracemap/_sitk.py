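"""Bridge to SimpleITK for the mutual-information rigid/affine stages.

SimpleITK registration returns transforms that map *fixed*-space points
into *moving*-space points (the resampling convention).  The helpers here
convert between that convention and the package's forward point maps, and
keep all geometry in world millimetres so SimpleITK physical points
coincide with our world coordinates.
"""

from __future__ import annotations

import logging

import numpy as np
import SimpleITK as sitk

from .transforms import Affine3D, Rigid2D

log = logging.getLogger(__name__)


def volume_to_sitk(vol):
    # our (i,j,k)=(ML,AP,DV) -> sitk (x,y,z); GetImageFromArray expects [z,y,x]
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T).astype(np.float64))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def image2d_to_sitk(arr, spacing, origin):
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(arr).T).astype(np.float64))
    img.SetSpacing(tuple(float(s) for s in np.broadcast_to(spacing, (2,))))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def euler2d_to_rigid(t):
    """SimpleITK Euler2D (fixed->moving map) -> same map as a Rigid2D."""
    angle = t.GetAngle()
    tx, ty = t.GetTranslation()
    cx, cy = t.GetCenter()
    return Rigid2D(angle=angle, translation=np.array([tx, ty]), center=np.array([cx, cy]))


def rigid_to_euler2d(r):
    t = sitk.Euler2DTransform()
    t.SetCenter(tuple(float(c) for c in r.center))
    t.SetAngle(float(r.angle))
    t.SetTranslation(tuple(float(v) for v in r.translation))
    return t


def sitk_affine_to_affine3d(t):
    """SimpleITK AffineTransform (fixed->moving map) -> same map as Affine3D."""
    a = np.array(t.GetMatrix()).reshape(3, 3)
    c = np.array(t.GetCenter())
    tr = np.array(t.GetTranslation())
    return Affine3D(matrix=a, translation=c + tr - a @ c)


def _downcast(t):
    """Unwrap the concrete transform from a registration result."""
    t = t.Downcast()
    if isinstance(t, sitk.CompositeTransform):
        t = t.GetNthTransform(t.GetNumberOfTransforms() - 1).Downcast()
    return t


def _registration(metric_bins, sampling, seed, shrink, sigmas, lr, iters):
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=metric_bins)
    if sampling < 1.0:
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(sampling, seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=lr,
        minStep=1e-4,
        numberOfIterations=iters,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    return reg


def register_rigid2d_sitk(
    fixed_img,
    moving_img,
    geometry,
    init=None,
    bins=32,
    iters=120,
    lr=0.5,
    seed=1,
):
    """MI rigid registration of two 2D images on a shared grid.

    Returns the *resampling* map (fixed -> moving) as a ``Rigid2D``; the
    caller inverts it to obtain the forward section map.  Raises on
    optimizer failure (caller falls back to ``init``).
    """
    shape, spacing, origin = geometry
    f = image2d_to_sitk(fixed_img, spacing, origin)
    m = image2d_to_sitk(moving_img, spacing, origin)
    if init is None:
        center = np.asarray(origin) + 0.5 * np.asarray(spacing) * (np.array(shape) - 1)
        init = Rigid2D(center=center)
    reg = _registration(bins, 1.0, seed, shrink=[2, 1], sigmas=[1, 0], lr=lr, iters=iters)
    reg.SetInitialTransform(rigid_to_euler2d(init), inPlace=False)
    out = _downcast(reg.Execute(f, m))
    return euler2d_to_rigid(out)


def register_affine3d_sitk(
    fixed_vol,
    moving_vol,
    init=None,
    bins=32,
    iters=200,
    lr=1.0,
    sampling=0.25,
    seed=1,
    shrink=(4, 2, 1),
    sigmas=(2, 1, 0),
):
    """MI affine registration; returns the fixed -> moving point map.

    When ``fixed`` is the stack volume and ``moving`` the reference, the
    returned map is directly the forward stack -> template affine.
    """
    f = volume_to_sitk(fixed_vol)
    m = volume_to_sitk(moving_vol)
    if init is None:
        t0 = sitk.CenteredTransformInitializer(
            f,
            m,
            sitk.AffineTransform(3),
            sitk.CenteredTransformInitializerFilter.GEOMETRY,
        )
    else:
        t0 = sitk.AffineTransform(3)
        t0.SetMatrix(tuple(init.matrix.ravel()))
        t0.SetTranslation(tuple(init.translation))
    reg = _registration(bins, sampling, seed, list(shrink), list(sigmas), lr, iters)
    reg.SetInitialTransform(t0, inPlace=False)
    out = _downcast(reg.Execute(f, m))
    return sitk_affine_to_affine3d(out)
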