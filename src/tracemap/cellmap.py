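"""Mapping plotted cells into the template: area, depth, summaries.

Once a case's transform chain is known, every plotted point (labeled cell
or injection-site voxel) is mapped into template space and annotated:

* **cortical area** — the parcellation label at the point, or the nearest
  cortical label (Euclidean, in mm) when the point lands just outside the
  delineations, as happens near area boundaries after registration;
* **depth** — a nominal (mm) and normalized (0 pial, 1 white-matter
  border) distance below the pial surface, computed with the
  Laplace-equation thickness method: a harmonic potential is solved over
  the cortical ribbon and streamlines are traced through its gradient
  from each voxel to both boundaries;
* **summary statistics** — per-area counts and percentages of extrinsic
  cells (cells in the injected area are intrinsic and excluded, so the
  injected area's percentage is undefined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg
from scipy.spatial import cKDTree

from .errors import ConfigError, SolverFailed
from .geometry import Volume, sample_volume
from .transforms import MissingTransform

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Area assignment
# ----------------------------------------------------------------------
def assign_area(points, labels, cortex_labels, max_fallback_mm=1.0):
    """Assign each template-space point (n, 3) to a cortical area.

    Points inside a cortical label keep it (distance 0).  Points outside
    are assigned the label of the nearest cortical voxel center by
    Euclidean distance in mm, ties broken toward the smaller label id.
    Beyond ``max_fallback_mm`` the point is left unassigned (area 0).

    Returns ``(areas (n,), fallback_distances (n,))``.
    """
    cortex_labels = sorted(set(int(c) for c in cortex_labels))
    if not cortex_labels:
        raise ConfigError("empty cortex label set")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vox_label = sample_volume(labels, pts, interp="nearest").astype(int)
    in_cortex = np.isin(vox_label, cortex_labels)
    areas = np.where(in_cortex, vox_label, 0)
    dists = np.zeros(len(pts))
    missing = ~in_cortex
    if np.any(missing):
        mask = np.isin(labels.data, cortex_labels)
        idx = np.argwhere(mask)
        centers = labels.origin + idx * labels.spacing
        lab = labels.data[mask]
        tree = cKDTree(centers)
        k = min(8, len(centers))
        d, nn = tree.query(pts[missing], k=k)
        d = np.atleast_2d(d)
        nn = np.atleast_2d(nn)
        for row, (drow, nrow) in enumerate(zip(d, nn)):
            tied = nrow[drow <= drow[0] + 1e-9]
            best = int(np.min(lab[tied]))
            i = np.flatnonzero(missing)[row]
            if drow[0] <= max_fallback_mm:
                areas[i] = best
                dists[i] = drow[0]
            else:
                areas[i] = 0
                dists[i] = drow[0]
    return areas, dists


# ----------------------------------------------------------------------
# Laplace depth
# ----------------------------------------------------------------------
@dataclass
class DepthField:
    """Laplace potential, thickness and normalized depth over the cortex.

    ``phi`` is 0 at the pial boundary and 1 at the gray/white boundary;
    ``thickness`` (mm) and ``normalized_depth`` are defined on cortex
    voxels (NaN elsewhere); ``mid_thickness`` marks the voxels whose
    streamline passes normalized depth 0.5 within half a voxel.
    """

    phi: Volume
    thickness: Volume
    normalized_depth: Volume
    mid_thickness: Volume
    cortex_labels: tuple
    wm_label: int
    n_fallback: int = 0


def solve_depth(
    labels,
    cortex_labels=None,
    wm_label=None,
    tol=1e-4,
    max_iter=5000,
    step_vox=0.25,
):
    """Solve the Laplace equation over the cortex and integrate thickness.

    The potential satisfies the discrete 6-neighbor Laplace equation on
    cortex voxels with Dirichlet values 0 on pial-adjacent (background)
    neighbors and 1 on white-matter-adjacent neighbors, solved by
    conjugate-gradient relaxation to a relative residual below ``tol``.
    From each cortex voxel a streamline is traced through the normalized
    potential gradient (midpoint/RK2 scheme, step ``step_vox`` of the
    smallest voxel dimension) down to the pial surface and up to the
    white matter; thickness is the total streamline length and normalized
    depth the pial-side fraction.  Voxels where the gradient vanishes
    fall back to the potential itself as normalized depth; they are
    counted in ``n_fallback`` and logged.
    """
    data = labels.data
    if wm_label is None:
        wm_label = int(data.max())
    if cortex_labels is None:
        cortex_labels = [int(v) for v in np.unique(data) if v not in (0, wm_label)]
    cortex = np.isin(data, list(cortex_labels))
    wm = data == wm_label
    if not cortex.any() or not wm.any():
        raise ConfigError("need both cortex and white-matter labels")

    phi = _solve_laplace(cortex, wm, labels.spacing, tol, max_iter)

    # extended potential for gradient evaluation: bg=0, wm=1
    phi_ext = np.where(wm, 1.0, 0.0)
    phi_ext[cortex] = phi[cortex]
    spacing = labels.spacing
    grads = np.gradient(phi_ext, *spacing)
    gnorm = np.sqrt(sum(g * g for g in grads))

    starts_idx = np.argwhere(cortex)
    starts = labels.origin + starts_idx * spacing
    step_mm = step_vox * float(np.min(spacing))
    max_steps = int(np.ceil(4.0 * max(labels.shape) / step_vox))

    region = np.zeros_like(data, dtype=np.int8)  # 0 bg, 1 cortex, 2 wm
    region[cortex] = 1
    region[wm] = 2

    down, ok_down = _trace(
        starts, -1.0, grads, gnorm, region, labels, step_mm, max_steps
    )
    up, ok_up = _trace(starts, +1.0, grads, gnorm, region, labels, step_mm, max_steps)
    ok = ok_down & ok_up
    thickness_v = down + up
    nd_v = np.where(thickness_v > 0, down / np.maximum(thickness_v, 1e-12), 0.0)
    n_fallback = int(np.sum(~ok))
    if n_fallback:
        log.info("depth streamlines fell back to potential for %d voxels", n_fallback)
        phi_vals = phi[cortex]
        nd_v[~ok] = phi_vals[~ok]
        med = np.median(thickness_v[ok]) if ok.any() else 0.0
        thickness_v[~ok] = med

    nan = np.full(data.shape, np.nan)
    thickness = nan.copy()
    thickness[cortex] = thickness_v
    ndmap = nan.copy()
    ndmap[cortex] = nd_v
    phimap = nan.copy()
    phimap[cortex] = phi[cortex]

    half_vox = 0.5 * float(np.min(spacing))
    mid = np.zeros(data.shape, dtype=np.int32)
    with np.errstate(invalid="ignore"):
        mid[(np.abs(ndmap - 0.5) * np.where(np.isnan(thickness), np.inf, thickness)) <= half_vox] = 1

    mk = lambda arr, kind="intensity": Volume(
        arr if kind == "intensity" else arr.astype(np.int32),
        labels.spacing,
        labels.origin,
        kind=kind,
    )
    return DepthField(
        phi=mk(phimap),
        thickness=mk(thickness),
        normalized_depth=mk(ndmap),
        mid_thickness=mk(mid, "label"),
        cortex_labels=tuple(cortex_labels),
        wm_label=wm_label,
        n_fallback=n_fallback,
    )


def _solve_laplace(cortex, wm, spacing, tol, max_iter):
    shape = cortex.shape
    n = int(cortex.sum())
    index = -np.ones(shape, dtype=np.int64)
    index[cortex] = np.arange(n)
    w_ax = 1.0 / np.asarray(spacing) ** 2
    rows, cols, vals = [], [], []
    b = np.zeros(n)
    diag = np.zeros(n)
    ci = np.argwhere(cortex)
    for ax in range(3):
        for sign in (-1, 1):
            nb = ci.copy()
            nb[:, ax] += sign
            inside = (nb[:, ax] >= 0) & (nb[:, ax] < shape[ax])
            # out-of-grid neighbors are reflecting (no-flux): skip the term
            diag[inside] += w_ax[ax]
            nb_in = nb[inside]
            flat = index[nb_in[:, 0], nb_in[:, 1], nb_in[:, 2]]
            is_cortex = flat >= 0
            src = np.flatnonzero(inside)[is_cortex]
            rows.append(src)
            cols.append(flat[is_cortex])
            vals.append(-w_ax[ax] * np.ones(len(src)))
            nb_out = nb_in[~is_cortex]
            src_out = np.flatnonzero(inside)[~is_cortex]
            is_wm = wm[nb_out[:, 0], nb_out[:, 1], nb_out[:, 2]]
            b[src_out[is_wm]] += w_ax[ax] * 1.0  # Dirichlet phi=1 at WM
    a = sparse.csr_matrix(
        (
            np.concatenate(vals + [diag]),
            (
                np.concatenate(rows + [np.arange(n)]),
                np.concatenate(cols + [np.arange(n)]),
            ),
        ),
        shape=(n, n),
    )
    x, info = cg(a, b, rtol=tol * 1e-2, maxiter=max_iter)
    residual = np.linalg.norm(a @ x - b) / max(np.linalg.norm(b), 1e-12)
    if info != 0 or residual > tol:
        raise SolverFailed(f"Laplace relaxation residual {residual:.2e} > {tol:.0e}")
    phi = np.zeros(shape)
    phi[cortex] = np.clip(x, 0.0, 1.0)
    return phi


def _trace(starts, direction, grads, gnorm, region, labels, step_mm, max_steps):
    """Batch RK2 streamline tracing; returns (lengths, ok)."""
    spacing = labels.spacing
    origin = labels.origin

    def unit_grad(pos):
        idx = ((pos - origin) / spacing).T
        g = np.stack(
            [
                ndimage.map_coordinates(gr, idx, order=1, mode="nearest")
                for gr in grads
            ],
            axis=-1,
        )
        norm = np.linalg.norm(g, axis=-1, keepdims=True)
        return g / np.maximum(norm, 1e-12), norm[:, 0]

    def region_at(pos):
        idx = np.rint((pos - origin) / spacing).astype(int)
        idx = np.clip(idx, 0, np.array(region.shape) - 1)
        out_of_grid = np.any(
            ((pos - origin) / spacing < -0.5)
            | ((pos - origin) / spacing > np.array(region.shape) - 0.5),
            axis=1,
        )
        reg = region[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.int8)
        reg[out_of_grid] = 0
        return reg

    n = len(starts)
    pos = starts.astype(float).copy()
    length = np.zeros(n)
    active = np.ones(n, dtype=bool)
    ok = np.ones(n, dtype=bool)
    g0, norm0 = unit_grad(starts)
    stuck = norm0 < 1e-8
    ok[stuck] = False
    active[stuck] = False
    for _ in range(max_steps):
        if not active.any():
            break
        g1, n1 = unit_grad(pos[active])
        mid = pos[active] + 0.5 * step_mm * direction * g1
        g2, n2 = unit_grad(mid)
        newpos = pos[active] + step_mm * direction * g2
        reg = region_at(newpos)
        ai = np.flatnonzero(active)
        dead = n2 < 1e-8
        ok[ai[dead]] = False
        active[ai[dead]] = False
        keep = ~dead
        ai = ai[keep]
        reg = reg[keep]
        newpos = newpos[keep]
        crossed = reg != 1
        # one bisection at the crossing: quarter- or three-quarter-step credit
        if crossed.any():
            half = pos[ai[crossed]] + 0.5 * step_mm * direction * g2[keep][crossed]
            still_cortex = region_at(half) == 1
            length[ai[crossed]] += np.where(still_cortex, 0.75, 0.25) * step_mm
        length[ai[~crossed]] += step_mm
        pos[ai] = newpos
        active[ai[crossed]] = False
    ok[active] = False  # ran out of steps
    return length, ok


def depth_at_points(points, labels, depth, cortex_labels=None):
    """Nominal (mm) and normalized depth for template-space points.

    Per the mapping convention: points outside the brain get normalized
    depth 0, points in the subjacent white matter get 1; both clamp the
    nominal depth correspondingly (0, or the local thickness).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cortex_labels = cortex_labels or depth.cortex_labels
    vox_label = sample_volume(labels, pts, interp="nearest").astype(int)
    nd = np.zeros(len(pts))
    nominal = np.zeros(len(pts))
    cortex_mask = np.isfinite(depth.thickness.data)
    idx_c = np.argwhere(cortex_mask)
    tree = cKDTree(labels.origin + idx_c * labels.spacing)
    thick_c = depth.thickness.data[cortex_mask]
    nd_c = depth.normalized_depth.data[cortex_mask]
    for i, (p, lab) in enumerate(zip(pts, vox_label)):
        if lab == depth.wm_label:
            _, j = tree.query(p)
            nd[i] = 1.0
            nominal[i] = thick_c[j]
        elif lab in cortex_labels:
            _, j = tree.query(p)
            nd[i] = nd_c[j]
            nominal[i] = nd_c[j] * thick_c[j]
        else:  # outside the brain
            nd[i] = 0.0
            nominal[i] = 0.0
    return nominal, nd


def shell_flatmap(points, center):
    """Analytic (longitude, latitude) chart for shell phantoms (degrees).

    A synthetic stand-in for surface flattening: on a spherical-shell
    cortex the mid-thickness surface unfolds exactly into azimuth and
    elevation angles, which is sufficient to populate the flat-map
    coordinates of the record schema.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(center)
    lon = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    lat = np.degrees(
        np.arctan2(pts[:, 2], np.linalg.norm(pts[:, :2], axis=1))
    )
    return np.column_stack([lon, lat])


# ----------------------------------------------------------------------
# Records and summaries
# ----------------------------------------------------------------------
def finalize_records(
    cells,
    chain,
    labels,
    depth,
    area_names=None,
    flatmap=None,
    max_fallback_mm=1.0,
):
    """Map every plotted point and build the per-point record table.

    ``cells`` is the plotted-point table (animal, tracer, kind, section,
    x_mm, y_mm).  Each row is pushed through the transform chain, assigned
    an area (with nearest-structure fallback), nominal and normalized
    depths, and optional flat-map coordinates.  Unmappable points (no
    section transform, non-finite output, or fallback beyond the cap) are
    retained with ``flagged=True`` and excluded from summaries.  The
    output is deterministically sorted.
    """
    records = []
    for _, row in cells.iterrows():
        rec = {
            "animal": row["animal"],
            "tracer": row["tracer"],
            "kind": row["kind"],
            "section": int(row["section"]),
            "x_mm": float(row["x_mm"]),
            "y_mm": float(row["y_mm"]),
            "ml_mm": np.nan,
            "ap_mm": np.nan,
            "dv_mm": np.nan,
            "area": 0,
            "fallback_mm": np.nan,
            "nominal_depth_mm": np.nan,
            "normalized_depth": np.nan,
            "flat_u": np.nan,
            "flat_v": np.nan,
            "flagged": False,
        }
        try:
            p = chain.map_points(rec["section"], [[rec["x_mm"], rec["y_mm"]]])[0]
        except MissingTransform:
            rec["flagged"] = True
            records.append(rec)
            continue
        rec["ml_mm"], rec["ap_mm"], rec["dv_mm"] = map(float, p)
        records.append(rec)
    df = pd.DataFrame(records)
    mapped = ~df["flagged"]
    if mapped.any():
        pts = df.loc[mapped, ["ml_mm", "ap_mm", "dv_mm"]].to_numpy()
        areas, dists = assign_area(
            pts, labels, depth.cortex_labels, max_fallback_mm=max_fallback_mm
        )
        nominal, nd = depth_at_points(pts, labels, depth)
        df.loc[mapped, "area"] = areas
        df.loc[mapped, "fallback_mm"] = dists
        df.loc[mapped, "nominal_depth_mm"] = nominal
        df.loc[mapped, "normalized_depth"] = nd
        df.loc[mapped & (df["area"] == 0), "flagged"] = True
        if flatmap is not None:
            uv = flatmap(pts)
            df.loc[mapped, "flat_u"] = uv[:, 0]
            df.loc[mapped, "flat_v"] = uv[:, 1]
    if area_names:
        df["area_name"] = df["area"].map(lambda a: area_names.get(int(a), str(a)))
    df = df.sort_values(
        ["animal", "tracer", "kind", "section", "x_mm", "y_mm"]
    ).reset_index(drop=True)
    n_flagged = int(df["flagged"].sum())
    if n_flagged:
        log.info("%d points flagged as unmappable/unassigned", n_flagged)
    return df


def injection_center_of_mass(records):
    """Unweighted mean template position of each injection's voxel cloud.

    Returns one row per (animal, tracer) with the center coordinates.
    """
    inj = records[(records["kind"] == "injection_voxel") & ~records["flagged"]]
    out = (
        inj.groupby(["animal", "tracer"])[["ml_mm", "ap_mm", "dv_mm"]]
        .mean()
        .reset_index()
    )
    return out


def summarize_areas(records, injected_area, grouping=None):
    """Per-area cell counts and extrinsic percentages.

    ``grouping`` optionally merges areas into supergroups before counting
    (mapping area id or name -> group name).  Percentages are computed
    over extrinsic cells only — cells in the injected area (or its group)
    are intrinsic, and that row's percentage is undefined (NaN, flagged).
    """
    cells = records[(records["kind"] == "cell") & ~records["flagged"]].copy()
    key = cells["area"].astype(object)
    injected_key = injected_area
    if grouping:
        known = set(np.unique(records["area"])) | set(
            records.get("area_name", pd.Series(dtype=object)).dropna().unique()
        )
        for src in grouping:
            if src not in known:
                raise ConfigError(f"grouping refers to unknown area {src!r}")
        key = key.map(lambda a: grouping.get(a, a))
        injected_key = grouping.get(injected_area, injected_area)
    cells["group"] = key
    counts = cells.groupby("group").agg(
        count=("group", "size"), mean_normalized_depth=("normalized_depth", "mean")
    )
    counts = counts.reset_index()
    counts["intrinsic"] = counts["group"] == injected_key
    extrinsic_total = counts.loc[~counts["intrinsic"], "count"].sum()
    counts["percentage"] = np.where(
        counts["intrinsic"],
        np.nan,
        100.0 * counts["count"] / max(extrinsic_total, 1),
    )
    return counts.sort_values("group").reset_index(drop=True)
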