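"""Slice-to-volume reconstruction of a section stack against a reference.

Two stages:

1. **Affine reconstruction** — alternate (i) 3D affine registration of the
   reference volume onto the current stack and (ii) 2D rigid registration
   of each raw section to its *virtual reference* (the affinely mapped
   reference resliced at that section's plane).  Repeating the pair lets
   the stack converge to an anatomically faithful shape while each section
   finds its in-plane pose; mutual information drives both registrations.
2. **Deformable reconstruction** — remove uncorrelated per-section
   distortions by warping every section toward the average of its
   immediate neighbors, iterating over the whole stack.  The prior is that
   anatomy varies more slowly than the section thickness, so neighbors are
   legitimate registration targets.  The warp model is an additive demons
   update with Gaussian field regularization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _sitk
from .errors import TracemapError
from .geometry import SectionStack, Volume, grid_world_points, resample, sample_image
from .metrics import mutual_information
from .transforms import DisplacementField, Rigid2D, invert_field

log = logging.getLogger(__name__)


@dataclass
class ReconstructionConfig:
    """Settings for both reconstruction stages.

    ``n_outer_iterations``: affine reconstruction loop count (the upper
    bound; the loop stops earlier once the mean section MI improves by
    less than ``mi_tolerance_bits``).  ``n_deformable_iterations`` and
    ``neighbor_radius`` control the neighbor-average warping stage.
    """

    n_outer_iterations: int = 10
    n_deformable_iterations: int = 8
    neighbor_radius: int = 1
    mi_tolerance_bits: float = 2e-3
    mi_bins: int = 32
    rigid_iters: int = 120
    affine_iters: int = 200
    affine_sampling: float = 0.25
    demons_field_sigma_vox: float = 2.0
    demons_fluid_sigma_vox: float = 1.0
    demons_step_vox: float = 0.4
    demons_inner_steps: int = 2
    msd_tolerance: float = 1e-6
    seed: int = 1

    def __post_init__(self):
        if not 1 <= self.n_outer_iterations <= 50:
            raise TracemapError("n_outer_iterations must be in [1, 50]")
        if self.neighbor_radius < 1:
            raise TracemapError("neighbor_radius must be >= 1")


# ----------------------------------------------------------------------
# 2D rigid
# ----------------------------------------------------------------------
def register_rigid_2d(moving, fixed, geometry, init=None, cfg=None):
    """MI-driven rigid alignment of ``moving`` onto ``fixed`` (shared grid).

    Returns the forward point map (moving -> fixed space) that maximizes
    mutual information, and never one worse than ``init``: the candidate
    is accepted only if its MI is at least the MI of the initial pose.
    On optimizer failure the initial transform is returned with a warning.
    """
    cfg = cfg or ReconstructionConfig()
    shape, spacing, origin = geometry
    if init is None:
        center = np.asarray(origin) + 0.5 * np.asarray(spacing) * (np.array(shape) - 1)
        init = Rigid2D(center=center)
    if np.std(fixed) < 1e-6 or np.std(moving) < 1e-6:
        return init  # empty/constant section: nothing to register
    pts = grid_world_points(geometry)

    def mi_of(forward):
        warped = sample_image(
            moving, spacing, origin, forward.inverse().apply(pts)
        ).reshape(shape)
        return mutual_information(fixed, warped, bins=cfg.mi_bins)

    mi_init = mi_of(init)
    try:
        resampling = _sitk.register_rigid2d_sitk(
            fixed, moving, geometry, init=init.inverse(),
            bins=cfg.mi_bins, iters=cfg.rigid_iters, seed=cfg.seed,
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer blow-up
        log.warning("2D rigid optimizer failed (%s); keeping initial pose", exc)
        return init
    candidate = resampling.inverse()
    if mi_of(candidate) + 1e-12 < mi_init:
        log.debug("2D rigid result not better than init (MI); keeping initial pose")
        return init
    return candidate


# ----------------------------------------------------------------------
# Stage 1: iterative affine reconstruction
# ----------------------------------------------------------------------
def assemble_stack_volume(stack, rigids=None, fields=None, interp="linear"):
    """Resample sections through their forward transforms into a 3D volume."""
    shape, spacing, origin = stack.section_geometry()
    pts = grid_world_points(stack.section_geometry())
    sections = []
    for s, img in enumerate(stack.sections):
        src = pts
        if fields is not None and fields[s] is not None:
            from .transforms import _invert_points

            src = _invert_points(fields[s], src)
        if rigids is not None and rigids[s] is not None:
            src = rigids[s].inverse().apply(src)
        sections.append(
            sample_image(img, spacing, origin, src, interp=interp).reshape(shape)
        )
    out = SectionStack(
        sections=sections,
        in_plane_spacing=stack.in_plane_spacing,
        section_spacing=stack.section_spacing,
        in_plane_origin=stack.in_plane_origin,
        ap_origin=stack.ap_origin,
    )
    return out.to_volume()


def affine_reconstruction(stack, reference, cfg=None):
    """Iterative 3D-affine / per-section 2D-rigid reconstruction.

    Returns ``(rigids, affine, history)``: per-section forward
    ``Rigid2D`` maps, the forward stack -> reference affine, and a history
    dict with the mean section MI per iteration.  Aborts if the mean MI
    drops by more than 10% between iterations (divergence).
    """
    cfg = cfg or ReconstructionConfig()
    n = len(stack)
    geometry = stack.section_geometry()
    rigids = [None] * n
    affine = None
    history = {"mean_mi": []}
    prev_mi = None
    for it in range(cfg.n_outer_iterations):
        stack_vol = assemble_stack_volume(stack, rigids)
        affine = _sitk.register_affine3d_sitk(
            stack_vol,
            reference,
            init=affine,
            bins=cfg.mi_bins,
            iters=cfg.affine_iters,
            sampling=cfg.affine_sampling,
            seed=cfg.seed,
        )
        # virtual reference: reference pulled into stack space.  The forward
        # reference->stack map is the inverse of the stack->reference affine.
        virtual = resample(reference, stack_vol.like_geometry(), affine.inverse())
        mis = []
        for s in range(n):
            virt_sec = virtual.data[:, s, :]
            rigids[s] = register_rigid_2d(
                stack.sections[s], virt_sec, geometry, init=rigids[s], cfg=cfg
            )
            aligned = _warp_by_rigid(stack.sections[s], rigids[s], geometry)
            mis.append(mutual_information(virt_sec, aligned, bins=cfg.mi_bins))
        mean_mi = float(np.mean(mis))
        history["mean_mi"].append(mean_mi)
        log.info("affine reconstruction iter %d: mean section MI %.4f", it, mean_mi)
        if prev_mi is not None:
            if mean_mi < prev_mi * 0.9:
                raise TracemapError(
                    f"affine reconstruction diverged: MI {prev_mi:.4f} -> {mean_mi:.4f}"
                )
            if mean_mi - prev_mi < cfg.mi_tolerance_bits:
                break
        prev_mi = mean_mi
    return rigids, affine, history


def _warp_by_rigid(img, rigid, geometry):
    shape, spacing, origin = geometry
    pts = grid_world_points(geometry)
    return sample_image(img, spacing, origin, rigid.inverse().apply(pts)).reshape(shape)


# ----------------------------------------------------------------------
# Stage 2: deformable reconstruction
# ----------------------------------------------------------------------
def _warp_image(img, u_vox):
    """Pull-back warp: out[i] = img[i + u_vox[i]] (voxel units)."""
    idx = np.indices(img.shape).astype(float)
    coords = idx + np.moveaxis(u_vox, -1, 0)
    return ndimage.map_coordinates(img, coords, order=1, mode="constant", cval=0.0)


def _demons_update(cur, target, cfg):
    """One Thirion demons force step (voxel units), fluid-smoothed."""
    diff = target - cur
    grads = np.gradient(cur)
    g2 = sum(g * g for g in grads)
    denom = g2 + diff * diff + 1e-9
    v = np.stack([diff * g / denom for g in grads], axis=-1)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    cap = cfg.demons_step_vox
    v *= np.minimum(1.0, cap / np.maximum(norm, 1e-12))
    for d in range(v.shape[-1]):
        v[..., d] = ndimage.gaussian_filter(v[..., d], cfg.demons_fluid_sigma_vox)
    return v


def _compose_pullback(u, v):
    """(id+u) after (id+v): w(x) = v(x) + u(x + v(x)), voxel units."""
    idx = np.indices(u.shape[:-1]).astype(float)
    coords = idx + np.moveaxis(v, -1, 0)
    w = np.empty_like(u)
    for d in range(u.shape[-1]):
        w[..., d] = v[..., d] + ndimage.map_coordinates(
            u[..., d], coords, order=1, mode="nearest"
        )
    return w


def _between_section_msd(imgs):
    return float(
        np.mean([np.mean((imgs[s + 1] - imgs[s]) ** 2) for s in range(len(imgs) - 1)])
    )


def deformable_reconstruction(stack, cfg=None):
    """Warp each section toward the mean of its neighbors, iteratively.

    ``stack`` must already be affinely reconstructed (sections resampled
    through their rigid poses).  Returns ``(fields, history)``: the
    per-section forward 2D displacement fields (mm) and the
    between-section mean squared intensity difference per iteration, which
    is non-increasing up to ``cfg.msd_tolerance`` (the loop reverts the
    last update and stops if it would increase it more than that).
    """
    cfg = cfg or ReconstructionConfig()
    n = len(stack)
    shape, spacing, origin = stack.section_geometry()
    originals = [img.astype(float) for img in stack.sections]
    u = [np.zeros(shape + (2,)) for _ in range(n)]
    cur = list(originals)
    history = {"msd": [_between_section_msd(cur)]}
    r = cfg.neighbor_radius
    for it in range(cfg.n_deformable_iterations):
        u_prev = [x.copy() for x in u]
        targets = []
        for s in range(n):
            nbrs = [cur[t] for t in range(max(0, s - r), min(n, s + r + 1)) if t != s]
            targets.append(np.mean(nbrs, axis=0))
        for s in range(n):
            for _ in range(cfg.demons_inner_steps):
                v = _demons_update(cur[s], targets[s], cfg)
                u[s] = _compose_pullback(u[s], v)
                for d in range(2):
                    u[s][..., d] = ndimage.gaussian_filter(
                        u[s][..., d], cfg.demons_field_sigma_vox
                    )
                cur[s] = _warp_image(originals[s], u[s])
            u[s] = _check_field_gradient(u[s], cfg)
        msd = _between_section_msd(cur)
        if msd > history["msd"][-1] + cfg.msd_tolerance:
            log.info("deformable reconstruction: MSD would increase; stopping")
            u = u_prev
            cur = [_warp_image(originals[s], u[s]) for s in range(n)]
            break
        history["msd"].append(msd)
        log.info("deformable reconstruction iter %d: MSD %.6f", it, msd)

    fields = []
    for s in range(n):
        if np.max(np.abs(u[s])) < 1e-12:
            pullback = DisplacementField(
                np.zeros(shape + (2,)), np.asarray(spacing), np.asarray(origin)
            )
            fields.append(pullback)
            continue
        u_mm = u[s] * np.asarray(spacing)
        pullback = DisplacementField(u_mm, np.asarray(spacing), np.asarray(origin))
        fields.append(invert_field(pullback))
    return fields, history


def _check_field_gradient(u, cfg):
    """Keep the displacement-gradient magnitude below 1 (invertibility)."""
    sigma = cfg.demons_field_sigma_vox
    for _ in range(5):
        g = 0.0
        for d in range(u.shape[-1]):
            g = max(g, max(np.max(np.abs(gg)) for gg in np.gradient(u[..., d])))
        if g < 1.0:
            return u
        sigma *= 1.5
        log.info("field gradient %.2f >= 1; increasing regularization to %.1f", g, sigma)
        for d in range(u.shape[-1]):
            u[..., d] = ndimage.gaussian_filter(u[..., d], sigma)
    return u
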