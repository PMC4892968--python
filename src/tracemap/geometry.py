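"""Volumes, section stacks and resampling.

Conventions used throughout the package:

* Volumes are scalar grids indexed ``(i, j, k)`` whose axes carry the
  stereotaxic meaning ``(ML, AP, DV)`` — medio-lateral, antero-posterior,
  dorso-ventral.  Voxel indices are 0-based; world coordinates are in
  millimetres at voxel centers, ``world = origin + index * spacing``.
* Section stacks are ordered rostro-caudally along the AP axis.  A section
  image is indexed ``(ix, iz)`` where ``ix`` maps to ML and ``iz`` to DV,
  so that section ``s`` of a volume is ``data[:, s, :]``.
* All resampling pulls intensities through the *inverse* of a forward point
  map, so the transforms stored in a chain (which are forward maps) can be
  used directly for point mapping and inverted once for image resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ContractViolation

AXIS_MEANING = ("ML", "AP", "DV")


@dataclass
class Volume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (ni, nj, nk)
        Intensities or integer labels.
    spacing : array-like of 3 floats
        Millimetres per voxel along (ML, AP, DV).  Strictly positive.
    origin : array-like of 3 floats
        World position (mm) of voxel (0, 0, 0).
    kind : {"intensity", "label"}
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    kind: str = "intensity"
    axis_meaning: tuple = AXIS_MEANING

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ContractViolation("Volume data must be 3D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ContractViolation("spacing must be 3 positive floats")
        if self.origin.shape != (3,):
            raise ContractViolation("origin must have 3 components")
        if self.kind not in ("intensity", "label"):
            raise ContractViolation(f"unknown volume kind {self.kind!r}")
        if self.kind == "label":
            if not np.issubdtype(self.data.dtype, np.integer):
                raise ContractViolation("label volume must hold integers")
            if self.data.min() < 0:
                raise ContractViolation("label volume must be non-negative")

    @property
    def shape(self):
        return self.data.shape

    def world_from_voxel(self, idx):
        """Continuous voxel index -> world mm (affine, invertible)."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + idx * self.spacing

    def voxel_from_world(self, world):
        """World mm -> continuous voxel index."""
        world = np.asarray(world, dtype=float)
        return (world - self.origin) / self.spacing

    def with_data(self, data, kind=None):
        return replace(self, data=data, kind=kind or self.kind)

    def like_geometry(self):
        """A (shape, spacing, origin) triple describing this grid."""
        return self.shape, self.spacing.copy(), self.origin.copy()

    # ---- NIfTI I/O -------------------------------------------------
    def to_nifti(self, path):
        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin
        data = self.data
        if self.kind == "label":
            data = data.astype(np.int32)
        img = nib.Nifti1Image(data, affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, kind="intensity"):
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.abs(np.diag(affine)[:3])
        origin = affine[:3, 3].copy()
        data = np.asanyarray(img.dataobj)
        if kind == "label":
            data = np.rint(data).astype(np.int32)
        else:
            data = data.astype(float)
        return cls(data=data, spacing=spacing, origin=origin, kind=kind)


def empty_like_geometry(geometry, fill=0.0, kind="intensity"):
    shape, spacing, origin = geometry
    dtype = np.int32 if kind == "label" else float
    return Volume(np.full(shape, fill, dtype=dtype), spacing, origin, kind=kind)


@dataclass
class SectionStack:
    """An ordered rostro-caudal stack of 2D grayscale sections.

    ``sections[s][ix, iz]`` is the intensity at in-plane position
    ``in_plane_origin + (ix, iz) * in_plane_spacing`` (mm, mapping to the
    ML and DV world axes) on the plane ``AP = ap_origin + s * section_spacing``.
    ``section_spacing`` is the *apparent* thickness: the physical distance
    between consecutive mounted sections.
    """

    sections: list
    in_plane_spacing: float
    section_spacing: float
    in_plane_origin: np.ndarray = field(default_factory=lambda: np.zeros(2))
    ap_origin: float = 0.0
    index_axis: str = "AP"

    def __post_init__(self):
        self.sections = [np.asarray(s, dtype=float) for s in self.sections]
        self.in_plane_origin = np.asarray(self.in_plane_origin, dtype=float)
        if self.section_spacing <= 0 or self.in_plane_spacing <= 0:
            raise ContractViolation("spacings must be positive")
        shapes = {s.shape for s in self.sections}
        if len(shapes) > 1:
            raise ContractViolation("all sections must share one shape")

    def __len__(self):
        return len(self.sections)

    @property
    def section_shape(self):
        return self.sections[0].shape

    def ap_of_section(self, s):
        return self.ap_origin + s * self.section_spacing

    def section_geometry(self):
        """(shape, spacing, origin) of the shared in-plane 2D grid."""
        return (
            self.section_shape,
            np.array([self.in_plane_spacing, self.in_plane_spacing]),
            self.in_plane_origin.copy(),
        )

    def volume_geometry(self):
        """Geometry of the 3D grid the stack occupies."""
        nx, nz = self.section_shape
        shape = (nx, len(self.sections), nz)
        spacing = np.array(
            [self.in_plane_spacing, self.section_spacing, self.in_plane_spacing]
        )
        origin = np.array(
            [self.in_plane_origin[0], self.ap_origin, self.in_plane_origin[1]]
        )
        return shape, spacing, origin

    def to_volume(self, kind="intensity"):
        shape, spacing, origin = self.volume_geometry()
        data = np.stack(self.sections, axis=1)
        if kind == "label":
            data = np.rint(data).astype(np.int32)
        return Volume(data, spacing, origin, kind=kind)

    @classmethod
    def from_volume(cls, vol):
        sections = [vol.data[:, j, :].astype(float) for j in range(vol.shape[1])]
        if not np.isclose(vol.spacing[0], vol.spacing[2]):
            raise ContractViolation("in-plane spacing must be isotropic")
        return cls(
            sections=sections,
            in_plane_spacing=float(vol.spacing[0]),
            section_spacing=float(vol.spacing[1]),
            in_plane_origin=np.array([vol.origin[0], vol.origin[2]]),
            ap_origin=float(vol.origin[1]),
        )


def _clamp_edge_roundoff(idx, shape, eps=1e-6):
    """Snap indices that exceed the valid range by float roundoff only."""
    hi = np.asarray(shape, dtype=float) - 1
    idx = np.where((idx > hi) & (idx < hi + eps), hi, idx)
    idx = np.where((idx < 0) & (idx > -eps), 0.0, idx)
    return idx


def sample_volume(vol, world_points, interp="linear", background=0.0):
    """Sample a volume at world-space points (n, 3) -> values (n,)."""
    pts = np.atleast_2d(np.asarray(world_points, dtype=float))
    idx = _clamp_edge_roundoff((pts - vol.origin) / vol.spacing, vol.shape)
    order = 1 if interp == "linear" else 0
    return ndimage.map_coordinates(
        vol.data.astype(float),
        idx.T,
        order=order,
        mode="constant",
        cval=background,
    )


def sample_image(img, spacing, origin, points, interp="linear", background=0.0):
    """Sample a 2D image with geometry at world points (n, 2)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = _clamp_edge_roundoff(
        (pts - np.asarray(origin)) / np.asarray(spacing), np.asarray(img).shape
    )
    order = 1 if interp == "linear" else 0
    return ndimage.map_coordinates(
        np.asarray(img, dtype=float),
        idx.T,
        order=order,
        mode="constant",
        cval=background,
    )


def grid_world_points(geometry):
    """World coordinates of all voxel centers of a geometry, shape (n, d)."""
    shape, spacing, origin = geometry
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(len(shape))]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def resample(vol, target_geometry, transform=None, interp="linear", background=0.0):
    """Resample ``vol`` onto ``target_geometry`` through a forward point map.

    ``transform`` is a *forward* point map from the input volume's space to
    the output space, matching the transforms stored in a chain.  The
    resampler inverts it (analytically for rigid/affine, by fixed-point
    iteration for displacement fields) and pulls intensities back, so
    ``out(x) = vol(transform^{-1}(x))``.  Out-of-domain voxels receive
    ``background``.  Label volumes require nearest-neighbor interpolation.
    """
    if vol.kind == "label" and interp != "nearest":
        raise ContractViolation("label volumes require nearest interpolation")
    shape, spacing, origin = target_geometry
    pts = grid_world_points(target_geometry)
    if transform is not None:
        from .transforms import as_pullback  # local import avoids a cycle

        pts = as_pullback(transform)(pts)
    vals = sample_volume(vol, pts, interp=interp, background=background)
    data = vals.reshape(shape)
    if vol.kind == "label":
        data = np.rint(data).astype(np.int32)
    return Volume(data, spacing, origin, kind=vol.kind)
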