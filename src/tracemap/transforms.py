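"""Spatial transforms and the per-case transform chain.

Every transform in this module is a **forward point map**: it takes points
in its input space and returns their images in its output space, in
millimetres.  Registration algorithms naturally produce the opposite
(resampling) maps; those are inverted — analytically for rigid/affine,
with :func:`invert_field` for displacement fields — before being stored in
a :class:`TransformChain`, so that mapping plotted cells into template
space is a plain left-to-right composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    ContractViolation,
    InversionFailed,
    MappingDiverged,
    MissingTransform,
)


# ----------------------------------------------------------------------
# Elementary transforms
# ----------------------------------------------------------------------
@dataclass
class Rigid2D:
    """2D rotation + translation about a stated center (all mm / radians)."""

    angle: float = 0.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)

    @property
    def matrix(self):
        c, s = np.cos(self.angle), np.sin(self.angle)
        return np.array([[c, -s], [s, c]])

    def apply(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def inverse(self):
        # x' = R(x-c)+c+t  =>  x = R^T(x'-c)+c - R^T t
        rt = self.matrix.T
        return Rigid2D(
            angle=-self.angle, center=self.center, translation=-(rt @ self.translation)
        )

    def to_dict(self):
        return {
            "type": "rigid2d",
            "angle": float(self.angle),
            "translation": self.translation.tolist(),
            "center": self.center.tolist(),
        }


@dataclass
class Affine3D:
    """General 3D affine map ``x -> A x + t`` (mm)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ContractViolation("Affine3D matrix must be invertible")

    def apply(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.translation

    def inverse(self):
        minv = np.linalg.inv(self.matrix)
        return Affine3D(matrix=minv, translation=-minv @ self.translation)

    def compose(self, other):
        """Return the map ``x -> self(other(x))``."""
        return Affine3D(
            matrix=self.matrix @ other.matrix,
            translation=self.matrix @ other.translation + self.translation,
        )

    def to_dict(self):
        return {
            "type": "affine3d",
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
        }


@dataclass
class DisplacementField:
    """A vector field of mm offsets on a stated grid: ``x -> x + u(x)``.

    ``field[..., d]`` holds the offset along world axis ``d`` at the voxel
    centers of the grid defined by ``spacing``/``origin``.  Works for both
    2D (in-plane) and 3D fields.  Offsets are interpolated linearly; beyond
    the grid the edge value is held (a continuous extension, which keeps
    the map finite everywhere and fixed-point inversion contractive).
    """

    field: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.ndim = self.field.shape[-1]
        if self.field.ndim != self.ndim + 1:
            raise ContractViolation("field must be (grid..., ndim)")
        if not np.all(np.isfinite(self.field)):
            raise ContractViolation("displacement field must be finite")

    def displacement_at(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (pts - self.origin) / self.spacing
        out = np.empty_like(pts)
        for d in range(self.ndim):
            out[:, d] = ndimage.map_coordinates(
                self.field[..., d], idx.T, order=1, mode="nearest"
            )
        return out

    def apply(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts + self.displacement_at(pts)

    def to_dict(self):
        return {
            "type": "field",
            "shape": list(self.field.shape),
            "spacing": self.spacing.tolist(),
            "origin": self.origin.tolist(),
            "data": self.field.ravel().tolist(),
        }

    @classmethod
    def zeros(cls, geometry, ndim=None):
        shape, spacing, origin = geometry
        ndim = ndim if ndim is not None else len(shape)
        return cls(np.zeros(tuple(shape) + (ndim,)), spacing, origin)


def transform_from_dict(d):
    if d is None:
        return None
    t = d["type"]
    if t == "rigid2d":
        return Rigid2D(d["angle"], np.array(d["translation"]), np.array(d["center"]))
    if t == "affine3d":
        return Affine3D(np.array(d["matrix"]), np.array(d["translation"]))
    if t == "field":
        return DisplacementField(
            np.array(d["data"]).reshape(d["shape"]),
            np.array(d["spacing"]),
            np.array(d["origin"]),
        )
    raise ContractViolation(f"unknown transform type {t!r}")


# ----------------------------------------------------------------------
# Field inversion
# ----------------------------------------------------------------------
def invert_field(f, tol_voxel=0.01, max_iter=50):
    """Invert a displacement field by fixed-point iteration.

    Finds ``v`` on the same grid such that ``(id + u) o (id + v) = id``
    within ``tol_voxel`` (fraction of the smallest grid spacing), via
    ``v_{k+1}(x) = -u(x + v_k(x))`` starting from ``v_0 = -u``.  Converges
    for smooth fields whose displacement-gradient magnitude is below one.
    Deterministic: no randomness enters the iteration.

    Raises
    ------
    InversionFailed
        If the round-trip residual is still above tolerance after
        ``max_iter`` iterations.  The residual is reported.
    """
    shape = f.field.shape[:-1]
    geometry = (shape, f.spacing, f.origin)
    from .geometry import grid_world_points

    pts = grid_world_points(geometry)
    tol_mm = tol_voxel * float(np.min(f.spacing))
    v = -f.field.reshape(-1, f.ndim)
    residual = np.inf
    for _ in range(max_iter):
        v_new = -f.displacement_at(pts + v)
        residual = float(np.max(np.linalg.norm(v_new - v, axis=1)))
        v = v_new
        if residual < 0.5 * tol_mm:
            break
    inv = DisplacementField(v.reshape(shape + (f.ndim,)), f.spacing, f.origin)
    # verify the actual contract: forward o inverse displaces < tol
    round_trip = f.apply(inv.apply(pts)) - pts
    err = float(np.max(np.linalg.norm(round_trip, axis=1)))
    if err > tol_mm:
        raise InversionFailed(err, tol_mm, max_iter)
    return inv


def as_pullback(transform):
    """Return a callable mapping output-space points to input-space points.

    Used by the resampler: given a forward point map, produce the inverse
    map that pulls intensities back onto the target grid.
    """
    if isinstance(transform, (Rigid2D, Affine3D)):
        inv = transform.inverse()
        return inv.apply
    if isinstance(transform, DisplacementField):
        inv = invert_field(transform)
        return inv.apply
    if callable(transform):
        return transform  # caller supplied an explicit pull-back
    raise ContractViolation(f"cannot invert {type(transform).__name__}")


# ----------------------------------------------------------------------
# The per-case chain
# ----------------------------------------------------------------------
@dataclass
class TransformChain:
    """All transforms taking raw-section points into template space.

    Composition order for a section point ``(s, x, y)``:

    1. per-section 2D rigid, then per-section 2D displacement field
       (both acting on the in-plane (ML, DV) mm coordinates);
    2. lift to 3D at the section's nominal AP plane
       ``ap_origin + s * section_spacing``;
    3. ``reconstruction_affine`` (stack space -> template-like space);
    4. ``to_template_affine`` then ``to_template_field`` (refinements from
       template coregistration).

    All stages are forward maps; the chain is serializable to JSON and
    reproduces mapped points bit-for-bit after a round trip.
    """

    per_section: dict
    reconstruction_affine: Affine3D = field(default_factory=Affine3D)
    to_template_affine: Affine3D = field(default_factory=Affine3D)
    to_template_field: DisplacementField | None = None
    ap_origin: float = 0.0
    section_spacing: float = 1.0

    def section_ap(self, s):
        return self.ap_origin + s * self.section_spacing

    def map_points(self, section_index, points_2d):
        """Map in-plane points (n, 2) of one section into template mm."""
        if section_index not in self.per_section:
            raise MissingTransform(f"no transforms for section {section_index}")
        rigid, field2d = self.per_section[section_index]
        p = np.atleast_2d(np.asarray(points_2d, dtype=float))
        if rigid is not None:
            p = rigid.apply(p)
        if field2d is not None:
            p = field2d.apply(p)
        ap = self.section_ap(section_index)
        p3 = np.column_stack([p[:, 0], np.full(len(p), ap), p[:, 1]])
        p3 = self.reconstruction_affine.apply(p3)
        p3 = self.to_template_affine.apply(p3)
        if self.to_template_field is not None:
            p3 = self.to_template_field.apply(p3)
        if not np.all(np.isfinite(p3)):
            raise MappingDiverged("non-finite template coordinates")
        return p3

    def inverse_map_points(self, template_points, max_iter=50, tol=1e-6):
        """Map template-space points back to (section index, x, y).

        Affine stages invert analytically; displacement fields invert by
        per-point fixed-point iteration.  The section index is the nearest
        nominal AP plane.  Returns ``(sections (n,), points (n, 2))``.
        """
        t = np.atleast_2d(np.asarray(template_points, dtype=float))
        if self.to_template_field is not None:
            t = _invert_points(self.to_template_field, t, max_iter, tol)
        t = self.to_template_affine.inverse().apply(t)
        t = self.reconstruction_affine.inverse().apply(t)
        secs = np.rint((t[:, 1] - self.ap_origin) / self.section_spacing).astype(int)
        out = np.empty((len(t), 2))
        for i, s in enumerate(secs):
            if s not in self.per_section:
                raise MissingTransform(f"no transforms for section {s}")
            rigid, field2d = self.per_section[s]
            p = t[i, [0, 2]][None, :]
            if field2d is not None:
                p = _invert_points(field2d, p, max_iter, tol)
            if rigid is not None:
                p = rigid.inverse().apply(p)
            out[i] = p[0]
        return secs, out

    # ---- serialization --------------------------------------------
    def to_dict(self):
        return {
            "direction": "forward",
            "ap_origin": float(self.ap_origin),
            "section_spacing": float(self.section_spacing),
            "per_section": {
                str(s): {
                    "rigid": r.to_dict() if r is not None else None,
                    "field": f.to_dict() if f is not None else None,
                }
                for s, (r, f) in sorted(self.per_section.items())
            },
            "reconstruction_affine": self.reconstruction_affine.to_dict(),
            "to_template_affine": self.to_template_affine.to_dict(),
            "to_template_field": (
                self.to_template_field.to_dict()
                if self.to_template_field is not None
                else None
            ),
        }

    def save_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d):
        if d.get("direction") != "forward":
            raise ContractViolation("chain JSON must declare direction=forward")
        per_section = {
            int(s): (
                transform_from_dict(entry["rigid"]),
                transform_from_dict(entry["field"]),
            )
            for s, entry in d["per_section"].items()
        }
        return cls(
            per_section=per_section,
            reconstruction_affine=transform_from_dict(d["reconstruction_affine"]),
            to_template_affine=transform_from_dict(d["to_template_affine"]),
            to_template_field=transform_from_dict(d["to_template_field"]),
            ap_origin=d["ap_origin"],
            section_spacing=d["section_spacing"],
        )

    @classmethod
    def load_json(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def identity(cls, n_sections, ap_origin=0.0, section_spacing=1.0):
        return cls(
            per_section={s: (Rigid2D(), None) for s in range(n_sections)},
            ap_origin=ap_origin,
            section_spacing=section_spacing,
        )


def _invert_points(field, points, max_iter=50, tol=1e-6):
    """Solve ``y + u(y) = p`` for each point by fixed-point iteration."""
    p = np.atleast_2d(points)
    y = p - field.displacement_at(p)
    for _ in range(max_iter):
        y_new = p - field.displacement_at(y)
        if np.max(np.abs(y_new - y)) < tol:
            y = y_new
            break
        y = y_new
    return y


def map_point_through_chain(point, chain):
    """Map one plotted point ``(section_index, x_mm, y_mm)`` to template mm.

    Thin convenience wrapper over :meth:`TransformChain.map_points`; returns
    an (ML, AP, DV) triple.
    """
    s, x, y = point
    return chain.map_points(int(s), np.array([[x, y]]))[0]
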