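"""Synthetic phantom: a parcellated hemispheric template, a distorted
section stack with known ground-truth transforms, and planted cells.

The phantom emulates the geometry of the real problem: a cortical sheet
(a hemispherical shell) parcellated into areas, cut into serial coronal
sections that are individually jittered (mounting misalignment), smoothly
deformed in-plane (compression, stretching and bending of the tissue), and
globally distorted in 3D (brain-scale shape change).  Because every
distortion is drawn and stored as an explicit forward transform chain,
every pipeline stage can be validated against exact ground truth.

All outputs are pure functions of ``(config, seed)``: each stage draws
from its own RNG stream derived from the seed by a fixed offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError
from .geometry import SectionStack, Volume, grid_world_points, sample_volume
from .transforms import Affine3D, DisplacementField, Rigid2D, TransformChain

log = logging.getLogger(__name__)

TRACERS = ("FB", "DY", "FR", "FE")


@dataclass
class PhantomConfig:
    """Study conditions for the synthetic phantom.

    Geometry: a hemispherical cortical shell of ``n_areas`` equal angular
    sectors over a white-matter core, on a cubic grid.  Distortion
    amplitudes emulate the tearing/shearing/displacement seen in mounted
    histological sections, at magnitudes small enough that every drawn
    deformation stays invertible (displacement-gradient magnitude < 0.5).
    """

    grid_size: int = 64
    spacing_mm: float = 0.25
    inner_radius_mm: float = 4.5
    outer_radius_mm: float = 6.0
    n_areas: int = 6
    n_landmarks: int = 3
    # per-section distortions
    rigid_sigma_mm: float = 0.2
    rigid_sigma_rad: float = 0.026  # ~1.5 degrees
    deformation_amplitude_mm: float = 0.15
    deformation_smoothness_mm: float = 1.0
    # global 3D distortions
    affine_scale_range: tuple = (0.97, 1.03)
    affine_shear_max: float = 0.02
    affine_rotation_max_rad: float = 0.05
    affine_translation_max_mm: float = 0.5
    deformation3d_amplitude_mm: float = 0.2
    deformation3d_smoothness_mm: float = 2.5
    # sectioning
    section_spacing_mm: float = 0.25
    # cells
    n_injections: int = 1
    n_cells_per_injection: int = 600
    n_injection_voxels: int = 80
    injection_radius_mm: float = 0.3
    injection_area: int | None = None
    cell_depth_range: tuple = (0.2, 0.8)
    seed: int = 12345
    animal: str = "PH01"

    def __post_init__(self):
        if not (0 < self.inner_radius_mm < self.outer_radius_mm):
            raise ConfigError("need 0 < inner radius < outer radius")
        if self.outer_radius_mm >= 0.5 * self.grid_size * self.spacing_mm:
            raise ConfigError("shell does not fit in the grid")
        if self.n_areas < 1 or self.n_landmarks < 1:
            raise ConfigError("need at least one area and one landmark")

    def rng(self, stage: int):
        """Independent RNG stream for one artifact stage."""
        return np.random.default_rng([self.seed % (2**31), stage])

    @property
    def center(self):
        ext = self.grid_size * self.spacing_mm
        # dome base sits low so the shell fits; apex at center_z + outer
        return np.array([0.5 * ext, 0.5 * ext, 0.28 * ext])


def _shell_coords(cfg, points):
    """Radius, azimuth and height of world points relative to the shell."""
    rel = points - cfg.center
    r = np.linalg.norm(rel, axis=-1)
    theta = np.arctan2(rel[..., 1], rel[..., 0])  # azimuth in the ML-AP plane
    return r, theta, rel[..., 2]


def area_of_theta(theta, n_areas):
    """Angular sector -> area label 1..n_areas."""
    frac = (theta + np.pi) / (2 * np.pi)
    return np.minimum((frac * n_areas).astype(int), n_areas - 1) + 1


def make_template(cfg: PhantomConfig):
    """Build the phantom reference: intensity, parcellation and landmarks.

    Returns ``(intensity, labels, landmarks)`` Volumes on the same grid.
    Labels: 0 background, ``1..n_areas`` cortical sectors,
    ``n_areas + 1`` white matter.  Landmarks: ``n_landmarks`` thin radial
    wedges of cortex straddling area boundaries (the analogue of
    hand-drawn sectors of distinctive tissue).
    """
    n = cfg.grid_size
    shape = (n, n, n)
    spacing = np.full(3, cfg.spacing_mm)
    origin = np.zeros(3)
    geometry = (shape, spacing, origin)
    pts = grid_world_points(geometry).reshape(shape + (3,))
    r, theta, dz = _shell_coords(cfg, pts)

    dome = dz >= 0
    cortex = dome & (r >= cfg.inner_radius_mm) & (r <= cfg.outer_radius_mm)
    wm = dome & (r < cfg.inner_radius_mm)

    labels = np.zeros(shape, dtype=np.int32)
    labels[cortex] = area_of_theta(theta[cortex], cfg.n_areas)
    labels[wm] = cfg.n_areas + 1

    # landmark wedges centered on evenly spread area boundaries
    landmarks = np.zeros(shape, dtype=np.int32)
    half_width = np.deg2rad(4.0)
    boundary_step = max(1, cfg.n_areas // cfg.n_landmarks)
    for i in range(cfg.n_landmarks):
        theta_b = -np.pi + (i * boundary_step + 1) * 2 * np.pi / cfg.n_areas
        dtheta = np.angle(np.exp(1j * (theta - theta_b)))
        landmarks[cortex & (np.abs(dtheta) <= half_width)] = i + 1

    rng = cfg.rng(stage=0)
    intensity = np.zeros(shape)
    intensity[wm] = 0.35
    nd = np.zeros(shape)
    nd[cortex] = (cfg.outer_radius_mm - r[cortex]) / (
        cfg.outer_radius_mm - cfg.inner_radius_mm
    )
    # cortex: depth profile + gentle area contrast + azimuthal modulation
    area_offset = 0.05 * ((labels % 3).astype(float) - 1.0)
    intensity[cortex] = (
        0.65
        + 0.15 * np.cos(np.pi * nd[cortex])
        + area_offset[cortex]
        + 0.06 * np.sin(3.0 * theta[cortex])
    )
    # smooth texture so similarity metrics have gradients everywhere
    noise = ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=0.75 / cfg.spacing_mm
    )
    noise *= 0.10 / max(noise.std(), 1e-9)
    intensity += noise * (labels > 0)
    intensity = ndimage.gaussian_filter(intensity, sigma=0.6)
    intensity = np.clip(intensity, 0.0, None)

    vol_i = Volume(intensity, spacing, origin, kind="intensity")
    vol_l = Volume(labels, spacing, origin, kind="label")
    vol_m = Volume(landmarks, spacing, origin, kind="label")
    return vol_i, vol_l, vol_m


def _smooth_noise_field(rng, shape, spacing, smoothness_mm, amplitude_mm, max_grad=0.4):
    """Gaussian-smoothed white-noise vector field, rescaled to a stated
    peak amplitude and guaranteed displacement-gradient < ``max_grad``."""
    ndim = len(shape)
    sigma_vox = smoothness_mm / np.asarray(spacing)
    u = np.stack(
        [
            ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
            for _ in range(ndim)
        ],
        axis=-1,
    )
    # taper to zero at the grid border so the map is identity outside
    window = np.ones(shape)
    for ax, m in enumerate(shape):
        ramp = np.minimum(np.arange(m), np.arange(m)[::-1]) / max(m * 0.15, 1)
        w = np.clip(ramp, 0, 1)
        window *= w.reshape([-1 if a == ax else 1 for a in range(ndim)])
    u *= window[..., None]
    peak = np.max(np.linalg.norm(u, axis=-1))
    if peak > 0:
        u *= amplitude_mm / peak
    grad = _max_displacement_gradient(u, spacing)
    if grad >= max_grad:
        u *= (max_grad * 0.9) / grad
        log.info("deformation rescaled to keep gradient below %.2f", max_grad)
    return u


def _max_displacement_gradient(u, spacing):
    g = 0.0
    for d in range(u.shape[-1]):
        grads = np.gradient(u[..., d], *np.asarray(spacing), edge_order=1)
        g = max(g, max(np.max(np.abs(gg)) for gg in grads))
    return g


def _draw_affine(cfg, rng):
    """Small random invertible affine about the shell center (forward
    stack -> template)."""
    lo, hi = cfg.affine_scale_range
    scales = rng.uniform(lo, hi, size=3)
    shear = rng.uniform(-cfg.affine_shear_max, cfg.affine_shear_max, size=3)
    m = np.diag(scales)
    m[0, 1] += shear[0]
    m[1, 2] += shear[1]
    m[0, 2] += shear[2]
    angle = rng.uniform(-cfg.affine_rotation_max_rad, cfg.affine_rotation_max_rad)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    mat = rot @ m
    t = rng.uniform(-cfg.affine_translation_max_mm, cfg.affine_translation_max_mm, 3)
    c = cfg.center
    return Affine3D(matrix=mat, translation=c - mat @ c + t)


def slice_and_distort(template: Volume, cfg: PhantomConfig, labels: Volume = None):
    """Reslice the template along AP and apply the drawn distortions.

    Returns ``(stack, chain, mask_stack)`` where ``chain`` is the exact
    forward map (raw distorted section coordinates -> template mm), and
    each raw section holds the template intensity sampled through that
    map: ``section_s(x, y) = template(chain(s, x, y))``.  With all
    amplitudes at zero this reduces to a plain reslicing with an identity
    chain.  Deterministic per seed.
    """
    n = cfg.grid_size
    extent_ap = n * cfg.spacing_mm
    n_sections = int(np.ceil(extent_ap / cfg.section_spacing_mm))
    in_plane_origin = np.array([template.origin[0], template.origin[2]])
    ap_origin = float(template.origin[1])

    rng_aff = cfg.rng(stage=1)
    rng_rig = cfg.rng(stage=2)
    rng_d2 = cfg.rng(stage=3)
    rng_d3 = cfg.rng(stage=4)

    zero_global = (
        cfg.affine_scale_range == (1.0, 1.0)
        and cfg.affine_shear_max == 0
        and cfg.affine_rotation_max_rad == 0
        and cfg.affine_translation_max_mm == 0
    )
    affine = Affine3D() if zero_global else _draw_affine(cfg, rng_aff)

    field3 = None
    if cfg.deformation3d_amplitude_mm > 0:
        u3 = _smooth_noise_field(
            rng_d3,
            template.shape,
            template.spacing,
            cfg.deformation3d_smoothness_mm,
            cfg.deformation3d_amplitude_mm,
        )
        field3 = DisplacementField(u3, template.spacing, template.origin)

    sec_shape = (n, n)
    sec_spacing = np.full(2, cfg.spacing_mm)
    sec_geometry = (sec_shape, sec_spacing, in_plane_origin)
    center2 = np.array([cfg.center[0], cfg.center[2]])

    per_section = {}
    for s in range(n_sections):
        if cfg.rigid_sigma_mm > 0 or cfg.rigid_sigma_rad > 0:
            rigid = Rigid2D(
                angle=rng_rig.normal(0, cfg.rigid_sigma_rad),
                translation=rng_rig.normal(0, cfg.rigid_sigma_mm, size=2),
                center=center2,
            )
        else:
            rigid = Rigid2D(center=center2)
        field2 = None
        if cfg.deformation_amplitude_mm > 0:
            u2 = _smooth_noise_field(
                rng_d2,
                sec_shape,
                sec_spacing,
                cfg.deformation_smoothness_mm,
                cfg.deformation_amplitude_mm,
            )
            field2 = DisplacementField(u2, sec_spacing, in_plane_origin)
        per_section[s] = (rigid, field2)

    chain = TransformChain(
        per_section=per_section,
        reconstruction_affine=affine,
        to_template_affine=Affine3D(),
        to_template_field=field3,
        ap_origin=ap_origin,
        section_spacing=cfg.section_spacing_mm,
    )

    stack = slice_volume_with_chain(template, chain, sec_geometry, n_sections)
    mask_stack = None
    if labels is not None:
        brain = labels.with_data((labels.data > 0).astype(np.int32), kind="label")
        mask_stack = slice_volume_with_chain(
            brain, chain, sec_geometry, n_sections, interp="nearest"
        )
    return stack, chain, mask_stack


def slice_volume_with_chain(vol, chain, sec_geometry, n_sections, interp="linear"):
    """Render the raw distorted sections of any co-registered volume.

    Each raw-section pixel samples ``vol`` at its forward-mapped template
    position; used for the intensity stack, masks and landmark stacks.
    """
    shape, spacing, origin = sec_geometry
    pts2 = grid_world_points(sec_geometry)
    sections = []
    for s in range(n_sections):
        tpts = chain.map_points(s, pts2)
        vals = sample_volume(vol, tpts, interp=interp)
        sections.append(vals.reshape(shape))
    return SectionStack(
        sections=sections,
        in_plane_spacing=float(spacing[0]),
        section_spacing=chain.section_spacing,
        in_plane_origin=origin,
        ap_origin=chain.ap_origin,
    )


def plant_cells(labels: Volume, chain: TransformChain, cfg: PhantomConfig):
    """Plant injections and labeled cells; express them on the raw sections.

    Injection centers are drawn mid-depth inside a chosen area; the cells
    that "project" to each injection are distributed over the other areas
    with per-area counts from a multinomial whose probabilities are drawn
    once per seed from a flat Dirichlet (so some connections are strong
    and some sparse, as in real tracer data).  Cell positions are drawn at
    normalized depths uniform in ``cfg.cell_depth_range``.  Each point is
    pushed through the ground-truth *inverse* chain onto its (quantized)
    section plane, and its ground truth (template coordinates, area,
    normalized depth) is re-derived at the re-mapped position, so truth
    and section coordinates are exactly consistent.

    Returns ``(cells, truth)`` DataFrames sharing a row order.  ``cells``
    has the plotted-point schema (animal, tracer, kind, section, x_mm,
    y_mm); ``truth`` carries template coordinates, area and depth.
    """
    rng = cfg.rng(stage=5)
    n_areas = cfg.n_areas
    sector = 2 * np.pi / n_areas
    margin = np.deg2rad(4.0)
    rows, truth_rows = [], []

    for inj in range(cfg.n_injections):
        tracer = TRACERS[inj % len(TRACERS)]
        inj_area = (
            cfg.injection_area
            if cfg.injection_area is not None
            else 1 + (inj % n_areas)
        )
        # analytic center: mid-sector azimuth, 45 deg elevation, mid depth
        theta_c = -np.pi + (inj_area - 0.5) * sector
        r_c = 0.5 * (cfg.inner_radius_mm + cfg.outer_radius_mm)
        center = _shell_point(cfg, r_c, theta_c, np.deg2rad(45.0))

        # injection voxel cloud
        pts = center + _ball(rng, cfg.n_injection_voxels, cfg.injection_radius_mm)
        _append_points(rows, truth_rows, pts, "injection_voxel", tracer, cfg, chain, labels)

        # extrinsic cells over the other areas
        others = [a for a in range(1, n_areas + 1) if a != inj_area]
        probs = rng.dirichlet(np.ones(len(others)))
        counts = rng.multinomial(cfg.n_cells_per_injection, probs)
        for area, count in zip(others, counts):
            if count == 0:
                continue
            theta = rng.uniform(
                -np.pi + (area - 1) * sector + margin,
                -np.pi + area * sector - margin,
                size=count,
            )
            elev = rng.uniform(np.deg2rad(25.0), np.deg2rad(65.0), size=count)
            nd = rng.uniform(*cfg.cell_depth_range, size=count)
            r = cfg.outer_radius_mm - nd * (cfg.outer_radius_mm - cfg.inner_radius_mm)
            pts = _shell_point(cfg, r, theta, elev)
            _append_points(rows, truth_rows, pts, "cell", tracer, cfg, chain, labels)

    cells = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    order = np.lexsort(
        (cells["y_mm"], cells["x_mm"], cells["section"], cells["kind"], cells["tracer"])
    )
    return cells.iloc[order].reset_index(drop=True), truth.iloc[order].reset_index(
        drop=True
    )


def _shell_point(cfg, r, theta, elev):
    r, theta, elev = np.broadcast_arrays(r, theta, elev)
    xy = np.cos(elev) * r
    out = np.stack(
        [
            cfg.center[0] + xy * np.cos(theta),
            cfg.center[1] + xy * np.sin(theta),
            cfg.center[2] + r * np.sin(elev),
        ],
        axis=-1,
    )
    return out


def _ball(rng, n, radius):
    pts = rng.normal(size=(4 * n, 3))
    pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= radius * rng.uniform(0, 1, size=(4 * n, 1)) ** (1 / 3)
    return pts[:n]


def _append_points(rows, truth_rows, pts, kind, tracer, cfg, chain, labels):
    secs, p2 = chain.inverse_map_points(pts)
    remapped = np.vstack(
        [chain.map_points(int(s), p[None, :])[0] for s, p in zip(secs, p2)]
    )
    r, theta, _ = _shell_coords(cfg, remapped)
    nd = np.clip(
        (cfg.outer_radius_mm - r) / (cfg.outer_radius_mm - cfg.inner_radius_mm),
        0.0,
        1.0,
    )
    lab = sample_volume(labels, remapped, interp="nearest").astype(int)
    # truth area: the angular sector (cortex parcels), robust to points that
    # sample white matter or background at the voxel grid
    area = np.where(
        (lab >= 1) & (lab <= cfg.n_areas), lab, area_of_theta(theta, cfg.n_areas)
    )
    for i in range(len(pts)):
        rows.append(
            {
                "animal": cfg.animal,
                "tracer": tracer,
                "kind": kind,
                "section": int(secs[i]),
                "x_mm": float(p2[i, 0]),
                "y_mm": float(p2[i, 1]),
            }
        )
        truth_rows.append(
            {
                "ml_mm": float(remapped[i, 0]),
                "ap_mm": float(remapped[i, 1]),
                "dv_mm": float(remapped[i, 2]),
                "area": int(area[i]),
                "normalized_depth": float(nd[i]),
            }
        )


def default_phantom(seed=12345, **overrides):
    """The default study conditions with an optional seed override."""
    return replace(PhantomConfig(), seed=seed, **overrides)
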