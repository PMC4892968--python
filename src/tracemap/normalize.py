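"""Coregistration of a reconstructed volume with the reference template.

The reconstructed stack volume is (i) preprocessed — resampled to an
isotropic working resolution and median-filtered, (ii) affinely registered
to the template with mutual information, and (iii) deformably registered
with an objective combining a windowed cross-correlation with a labeled
landmark term (point-set expectation).  The landmark term pulls
corresponding hand-delineated tissue sectors onto each other, which
protects the deformable stage from locking onto the wrong sulcus or bank
when image similarity alone is ambiguous.

The deformable solver is a multi-resolution demons-style iteration: at
each step a local-correlation force (the variational gradient of the
windowed CC) plus a landmark-attraction force is fluid-smoothed, composed
into the running displacement field, and the field is elastically
smoothed.  The running field is a resampling (pull-back) map on the
template grid; it is inverted into a forward point map before being
stored in a transform chain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import _sitk
from .errors import ContractViolation, LandmarkMismatch
from .geometry import Volume, resample
from .metrics import MetricConfig, landmark_volume_to_points, point_set_expectation
from .transforms import DisplacementField, invert_field

log = logging.getLogger(__name__)


@dataclass
class NormalizationConfig:
    """Template-coregistration settings.

    ``working_resolution_mm`` is the isotropic grid on which all 3D
    registration runs (paper-scale default 0.075 mm; phantom runs use the
    phantom's native resolution).  ``metric`` carries the CC kernel radius
    and the CC/PSE weights (equal by default).  ``levels`` are shrink
    factors for the deformable multi-resolution schedule with
    ``iterations`` per level.
    """

    working_resolution_mm: float = 0.075
    median_radius_vox: int = 1
    metric: MetricConfig = field(default_factory=lambda: MetricConfig(cc_kernel_radius=2))
    use_landmarks: bool = True
    levels: tuple = (4, 2, 1)
    iterations: tuple = (40, 25, 12)
    step_vox: float = 0.6
    fluid_sigma_vox: float = 1.0
    field_sigma_vox: float = 1.2
    pse_sigma_vox: float = 2.0
    pse_max_points: int = 1000
    affine_iters: int = 200
    seed: int = 1
    log_path: str | None = None

    def __post_init__(self):
        if self.working_resolution_mm <= 0:
            raise ContractViolation("working resolution must be positive")
        if self.median_radius_vox < 1:
            raise ContractViolation("median radius must be >= 1")


def preprocess_for_registration(vol, cfg=None):
    """Resample to the isotropic working resolution and median-filter.

    Intensity volumes get one pass of a median filter with the configured
    radius (a ``(2r+1)^3`` window); label volumes are resampled with
    nearest-neighbor interpolation and not filtered.
    """
    cfg = cfg or NormalizationConfig()
    res = cfg.working_resolution_mm
    extent = np.asarray(vol.shape) * vol.spacing
    shape = tuple(int(np.ceil(e / res - 1e-9)) for e in extent)
    target = (shape, np.full(3, res), vol.origin.copy())
    interp = "nearest" if vol.kind == "label" else "linear"
    out = resample(vol, target, None, interp=interp)
    if vol.kind != "label":
        size = 2 * cfg.median_radius_vox + 1
        out = out.with_data(ndimage.median_filter(out.data, size=size))
    return out


def register_affine_3d(moving, fixed, cfg=None):
    """12-parameter MI affine registration.

    Returns the forward point map (moving space -> fixed space).  On
    optimizer failure the identity is returned with a warning.
    """
    cfg = cfg or NormalizationConfig()
    from .transforms import Affine3D

    try:
        resampling = _sitk.register_affine3d_sitk(
            fixed, moving, iters=cfg.affine_iters, seed=cfg.seed
        )
    except RuntimeError as exc:
        log.warning("3D affine optimizer failed (%s); returning identity", exc)
        return Affine3D()
    return resampling.inverse()


# ----------------------------------------------------------------------
# Deformable stage
# ----------------------------------------------------------------------
def _downsample(vol, factor):
    if factor == 1:
        return vol
    data = ndimage.gaussian_filter(vol.data.astype(float), sigma=0.5 * factor)
    shape = tuple(max(1, s // factor) for s in vol.shape)
    target = (shape, vol.spacing * factor, vol.origin.copy())
    return resample(Volume(data, vol.spacing, vol.origin), target, None)


def _downsample_labels(vol, factor):
    if factor == 1:
        return vol
    shape = tuple(max(1, s // factor) for s in vol.shape)
    target = (shape, vol.spacing * factor, vol.origin.copy())
    return resample(vol, target, None, interp="nearest")


def _warp_volume_data(data, u_mm, spacing, order=1):
    idx = np.indices(data.shape).astype(float)
    coords = idx + np.moveaxis(u_mm / np.asarray(spacing), -1, 0)
    return ndimage.map_coordinates(data, coords, order=order, mode="nearest")


def _cc_force(warped, fixed_img, radius):
    """Variational gradient of the windowed cross-correlation.

    With window-demeaned images A (warped moving) and B (fixed), the local
    correlation ``sAB^2 / (sAA sBB)`` increases along
    ``(2 sAB / (sAA sBB)) (B - (sAB / sAA) A) grad(A)``.
    """
    size = 2 * radius + 1
    box = lambda img: ndimage.uniform_filter(img, size=size)
    a = warped - box(warped)
    b = fixed_img - box(fixed_img)
    saa = box(a * a)
    sbb = box(b * b)
    sab = box(a * b)
    eps = 1e-6 * (np.mean(np.abs(saa)) + 1e-12)
    denom = saa * sbb
    valid = (saa > eps) & (sbb > eps)
    coef = np.zeros_like(a)
    coef[valid] = 2.0 * sab[valid] / denom[valid]
    inner = np.zeros_like(a)
    inner[valid] = b[valid] - (sab[valid] / saa[valid]) * a[valid]
    grads = np.gradient(a)
    force = np.stack([coef * inner * g for g in grads], axis=-1)
    return force


def _pse_force_and_value(u_mm, moving_lm, fixed_sets, spacing, cfg):
    """Landmark attraction force on the fixed grid + current PSE (mm).

    The moving landmark volume is warped by the current pull-back field;
    each warped landmark voxel is pulled toward its nearest same-label
    fixed landmark point.  In pull-back convention the update at the voxel
    is the negated offset.
    """
    warped = _warp_volume_data(
        moving_lm.data.astype(np.int32), u_mm, spacing, order=0
    ).astype(np.int32)
    warped_vol = Volume(warped, moving_lm.spacing, moving_lm.origin, kind="label")
    moving_sets = landmark_volume_to_points(warped_vol, cfg.pse_max_points)
    if set(moving_sets) != set(fixed_sets):
        # a label vanished under warping at this level: no force this step
        return None, np.nan
    pse = point_set_expectation(moving_sets, fixed_sets)
    force = np.zeros(warped.shape + (3,))
    min_sp = float(np.min(spacing))
    for label, pts in moving_sets.items():
        tree = cKDTree(fixed_sets[label])
        _, nearest = tree.query(pts)
        d = fixed_sets[label][nearest] - pts
        # sub-voxel offsets between voxelized point sets are lattice noise,
        # and nearest-neighbor matching of thin overlapping sets produces
        # spurious tangential sliding: only super-voxel mismatch drives force
        keep = np.linalg.norm(d, axis=1) > min_sp
        pts, d = pts[keep], d[keep]
        if len(pts) == 0:
            continue
        idx = np.rint((pts - moving_lm.origin) / moving_lm.spacing).astype(int)
        idx = np.clip(idx, 0, np.array(warped.shape) - 1)
        force[idx[:, 0], idx[:, 1], idx[:, 2]] = -d
    for d3 in range(3):
        force[..., d3] = ndimage.gaussian_filter(force[..., d3], cfg.pse_sigma_vox)
    return force, pse


def register_deformable_3d(moving, fixed, landmarks_m=None, landmarks_f=None, cfg=None):
    """Deformable registration of ``moving`` onto ``fixed``.

    Maximizes the windowed cross-correlation, optionally combined (equal
    weights after normalizing each update to voxel scale) with the labeled
    landmark point-set expectation, under Gaussian fluid/elastic
    regularization.  Returns ``(forward_field, history)``: the forward
    point map (moving -> fixed space, obtained by inverting the converged
    resampling field) and per-iteration metric values.

    Raises
    ------
    LandmarkMismatch
        If exactly one of the landmark volumes is given, or their label
        inventories differ.
    """
    cfg = cfg or NormalizationConfig()
    use_lm = cfg.use_landmarks and landmarks_m is not None
    if (landmarks_m is None) != (landmarks_f is None):
        raise LandmarkMismatch("need landmark volumes on both sides or neither")
    if use_lm:
        inv_m = set(np.unique(landmarks_m.data)) - {0}
        inv_f = set(np.unique(landmarks_f.data)) - {0}
        if inv_m != inv_f:
            raise LandmarkMismatch(f"label inventories differ: {inv_m} vs {inv_f}")
    w_cc = cfg.metric.weights.get("cc", 1.0)
    w_pse = cfg.metric.weights.get("pse", 1.0) if use_lm else 0.0

    history = {"cc": [], "pse": [], "level": []}
    u = None  # pull-back displacement (mm) on the fixed grid of the level
    for level, iters in zip(cfg.levels, cfg.iterations):
        f_lvl = _downsample(fixed, level)
        m_lvl = _downsample(moving, level)
        lm_m_lvl = lm_f_sets = None
        if use_lm:
            lm_m_lvl = _downsample_labels(landmarks_m, level)
            lm_f_lvl = _downsample_labels(landmarks_f, level)
            lm_f_sets = landmark_volume_to_points(lm_f_lvl, cfg.pse_max_points)
        u = _resize_field(u, f_lvl)
        spacing = f_lvl.spacing
        step_mm = cfg.step_vox * float(np.min(spacing))
        radius = max(1, cfg.metric.cc_kernel_radius)
        for it in range(iters):
            warped = _warp_volume_data(m_lvl.data, u, spacing)
            v = np.zeros_like(u)
            force = _cc_force(warped, f_lvl.data, radius)
            norm = np.max(np.linalg.norm(force, axis=-1))
            if norm > 1e-12:
                v += w_cc * (force / norm)
            pse_val = np.nan
            if use_lm:
                pse_force, pse_val = _pse_force_and_value(
                    u, lm_m_lvl, lm_f_sets, spacing, cfg
                )
                if pse_force is not None:
                    pnorm = np.max(np.linalg.norm(pse_force, axis=-1))
                    if pnorm > 1e-12:
                        v += w_pse * (pse_force / pnorm)
            vnorm = np.max(np.linalg.norm(v, axis=-1))
            if vnorm > 1e-12:
                v *= step_mm / vnorm
            for d in range(3):
                v[..., d] = ndimage.gaussian_filter(v[..., d], cfg.fluid_sigma_vox)
            u = _compose_pullback_mm(u, v, spacing)
            for d in range(3):
                u[..., d] = ndimage.gaussian_filter(u[..., d], cfg.field_sigma_vox)
            cc_val = _masked_cc(warped, f_lvl.data, radius)
            history["cc"].append(cc_val)
            history["pse"].append(pse_val)
            history["level"].append(level)
            _log_iteration(cfg, level, it, cc_val, pse_val)
        u = _enforce_invertibility(u, spacing, cfg)

    pullback = DisplacementField(u, fixed.spacing, fixed.origin)
    forward = invert_field(pullback, tol_voxel=0.01)
    return forward, history


def landmark_pse(forward_field, landmarks_moving, landmarks_fixed, max_points=1000):
    """Landmark PSE (mm) after applying a forward field to the moving side.

    The moving landmark volume is resampled through the field (nearest
    neighbor) onto its own grid, so both sides are voxelized point sets on
    the same lattice and their PSE values are directly comparable with the
    unwarped (e.g. affine-only) value.
    """
    warped = resample(
        landmarks_moving, landmarks_moving.like_geometry(), forward_field, interp="nearest"
    )
    return point_set_expectation(
        landmark_volume_to_points(warped, max_points),
        landmark_volume_to_points(landmarks_fixed, max_points),
    )


def _masked_cc(a, b, radius):
    from .metrics import windowed_cross_correlation

    try:
        return windowed_cross_correlation(a, b, radius=radius)
    except Exception:
        return np.nan


def _log_iteration(cfg, level, it, cc, pse):
    log.debug("deformable level %d iter %d: CC %.4f PSE %s", level, it, cc, pse)
    if cfg.log_path:
        with open(cfg.log_path, "a") as fh:
            fh.write(json.dumps({"level": level, "iter": it, "cc": cc, "pse": pse}) + "\n")


def _resize_field(u, target_vol):
    shape = target_vol.shape
    if u is None:
        return np.zeros(shape + (3,))
    if u.shape[:-1] == shape:
        return u
    factors = np.array(shape) / np.array(u.shape[:-1])
    out = np.empty(shape + (3,))
    for d in range(3):
        out[..., d] = ndimage.zoom(u[..., d], factors, order=1, mode="nearest")
    return out


def _compose_pullback_mm(u, v, spacing):
    """(id+u) after (id+v) in mm on a voxel grid."""
    idx = np.indices(u.shape[:-1]).astype(float)
    coords = idx + np.moveaxis(v / np.asarray(spacing), -1, 0)
    w = np.empty_like(u)
    for d in range(3):
        w[..., d] = v[..., d] + ndimage.map_coordinates(
            u[..., d], coords, order=1, mode="nearest"
        )
    return w


def _enforce_invertibility(u, spacing, cfg, max_grad=0.7):
    sigma = cfg.field_sigma_vox
    for _ in range(6):
        g = 0.0
        for d in range(3):
            grads = np.gradient(u[..., d], *np.asarray(spacing))
            g = max(g, max(np.max(np.abs(gg)) for gg in grads))
        if g < max_grad:
            return u
        sigma *= 1.5
        log.info("field gradient %.2f; smoothing with sigma %.1f", g, sigma)
        for d in range(3):
            u[..., d] = ndimage.gaussian_filter(u[..., d], sigma)
    return u
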