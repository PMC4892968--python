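"""Image-similarity and landmark metrics driving the registrations.

Three metrics are used across the pipeline: mutual information (for the
rigid/affine stages), a windowed cross-correlation (for the deformable
template coregistration), and a symmetric nearest-neighbor expectation over
labeled landmark point sets that penalizes corresponding landmark sectors
that fail to overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ContractViolation, LandmarkMismatch, MetricUndefined


@dataclass
class MetricConfig:
    """Shared metric settings.

    ``mi_bins``: joint-histogram bin count for mutual information.
    ``cc_kernel_radius``: half-width (voxels) of the local correlation
    window, i.e. a window of ``(2r+1)^d`` voxels; the paper-scale default
    is 5 voxels.  ``weights``: relative weight per metric in combined
    objectives; the deformable coregistration uses equal CC and PSE
    weights.
    """

    mi_bins: int = 32
    cc_kernel_radius: int = 5
    weights: dict = field(default_factory=lambda: {"cc": 1.0, "pse": 1.0})

    def __post_init__(self):
        if self.mi_bins < 2:
            raise ContractViolation("mi_bins must be >= 2")
        if self.cc_kernel_radius < 1:
            raise ContractViolation("cc_kernel_radius must be >= 1")
        if any(w < 0 for w in self.weights.values()) or not any(
            w > 0 for w in self.weights.values()
        ):
            raise ContractViolation("weights must be >= 0 with at least one positive")


def mutual_information(a, b, bins=32, mask=None):
    """Mutual information (bits) between two equally-shaped images.

    A plain joint histogram of ``bins`` equal-width bins per image is used
    (no Parzen smoothing):  ``MI = sum p(i,j) log2[p(i,j) / (p(i) p(j))]``.
    A constant image has a degenerate marginal and yields 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ContractViolation("images must share a shape")
    if mask is not None:
        a, b = a[mask], b[mask]
    a, b = a.ravel(), b.ravel()
    if a.size == 0:
        raise ContractViolation("empty overlap")
    if a.max() == a.min() or b.max() == b.min():
        warnings.warn("constant image: mutual information degenerates to 0")
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def _box_sum(img, radius):
    """Sum of ``img`` over windows of half-width ``radius`` clipped at the
    image boundary, via integral images; matches a truncated-window
    nested-loop implementation exactly."""
    out = img.astype(float)
    for ax in range(img.ndim):
        c = np.cumsum(out, axis=ax)
        n = img.shape[ax]
        hi = np.minimum(np.arange(n) + radius, n - 1)
        lo = np.arange(n) - radius - 1
        c_hi = np.take(c, hi, axis=ax)
        c_lo = np.where(
            (lo >= 0).reshape([-1 if a == ax else 1 for a in range(img.ndim)]),
            np.take(c, np.maximum(lo, 0), axis=ax),
            0.0,
        )
        out = c_hi - c_lo
    return out


def windowed_cross_correlation(a, b, radius=5, return_map=False):
    """Mean local Pearson correlation over ``(2r+1)^d`` windows.

    Windows are clipped at image borders.  Voxels whose window has zero
    variance in either image are excluded from the mean; if no window is
    valid the metric is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ContractViolation("images must share a shape")
    if radius < 1:
        raise ContractViolation("radius must be >= 1")
    n = _box_sum(np.ones_like(a), radius)
    sa, sb = _box_sum(a, radius), _box_sum(b, radius)
    saa, sbb = _box_sum(a * a, radius), _box_sum(b * b, radius)
    sab = _box_sum(a * b, radius)
    var_a = saa - sa * sa / n
    var_b = sbb - sb * sb / n
    cov = sab - sa * sb / n
    valid = (var_a > 1e-12 * np.maximum(saa, 1.0)) & (
        var_b > 1e-12 * np.maximum(sbb, 1.0)
    )
    if not np.any(valid):
        raise MetricUndefined("no window with non-zero variance in both images")
    cc = np.zeros_like(a)
    cc[valid] = cov[valid] / np.sqrt(var_a[valid] * var_b[valid])
    value = float(cc[valid].mean())
    if return_map:
        return value, cc, valid
    return value


def point_set_expectation(a_sets, b_sets):
    """Symmetric labeled nearest-neighbor expectation (mm).

    ``a_sets``/``b_sets`` map a landmark label to an ``(n, d)`` point array.
    For each label, the mean distance from each point of one side to its
    nearest same-label point on the other side is computed in both
    directions and averaged; the metric is the mean over labels.  It is a
    pseudo-metric on labeled point multisets: symmetric, non-negative, and
    zero exactly when the two sides coincide as sets.
    """
    if set(a_sets) != set(b_sets):
        raise LandmarkMismatch(
            f"label inventories differ: {sorted(a_sets)} vs {sorted(b_sets)}"
        )
    if not a_sets:
        raise LandmarkMismatch("no landmark labels supplied")
    per_label = []
    for label in sorted(a_sets):
        pa = np.atleast_2d(np.asarray(a_sets[label], dtype=float))
        pb = np.atleast_2d(np.asarray(b_sets[label], dtype=float))
        if len(pa) == 0 or len(pb) == 0:
            raise LandmarkMismatch(f"label {label} empty on one side")
        d_ab = cKDTree(pb).query(pa)[0].mean()
        d_ba = cKDTree(pa).query(pb)[0].mean()
        per_label.append(0.5 * (d_ab + d_ba))
    return float(np.mean(per_label))


def landmark_volume_to_points(vol, max_points_per_label=2000):
    """Convert a landmark label volume to labeled world-space point sets.

    All labeled voxel centers are taken; labels with more voxels than
    ``max_points_per_label`` are subsampled with a deterministic stride.
    """
    sets = {}
    labels = np.unique(vol.data)
    for label in labels[labels > 0]:
        idx = np.argwhere(vol.data == label)
        if len(idx) > max_points_per_label:
            stride = int(np.ceil(len(idx) / max_points_per_label))
            idx = idx[::stride]
        sets[int(label)] = vol.origin + idx * vol.spacing
    return sets
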