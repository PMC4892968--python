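"""End-to-end driver: stack -> reconstruction -> template coregistration
-> cell mapping, plus ground-truth evaluation on phantom runs.

The full chain for one case composes, in order: per-section 2D rigid
poses, per-section 2D displacement fields (both from reconstruction), the
stack-to-template affine from the iterative affine reconstruction, and
the affine + deformable corrections from template coregistration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cellmap import (
    finalize_records,
    injection_center_of_mass,
    shell_flatmap,
    solve_depth,
    summarize_areas,
)
from .geometry import Volume, resample
from .normalize import (
    NormalizationConfig,
    landmark_pse,
    register_affine_3d,
    register_deformable_3d,
)
from .reconstruct import (
    ReconstructionConfig,
    affine_reconstruction,
    assemble_stack_volume,
    deformable_reconstruction,
)
from .transforms import TransformChain

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    chain: TransformChain
    reconstructed: Volume  # in template space, after all corrections
    history: dict
    landmark_pse_final: float | None = None


def run_case(
    stack,
    template,
    template_labels,
    template_landmarks=None,
    landmark_stack=None,
    recon_cfg=None,
    norm_cfg=None,
):
    """Reconstruct and normalize one case; return the full transform chain.

    ``landmark_stack`` carries the subject-side landmark sectors drawn on
    the raw sections (in the phantom, sliced from the template through the
    ground-truth distortion); it is carried through the recovered
    transforms to serve as the moving landmark volume in the deformable
    stage.
    """
    recon_cfg = recon_cfg or ReconstructionConfig()
    norm_cfg = norm_cfg or NormalizationConfig()

    # stage 1: iterative affine reconstruction
    rigids, recon_affine, hist_aff = affine_reconstruction(stack, template, recon_cfg)
    aligned = _resampled_stack(stack, rigids)

    # stage 2: deformable reconstruction on the aligned stack
    fields, hist_def = deformable_reconstruction(aligned, recon_cfg)

    chain = TransformChain(
        per_section={s: (rigids[s], fields[s]) for s in range(len(stack))},
        reconstruction_affine=recon_affine,
        ap_origin=stack.ap_origin,
        section_spacing=stack.section_spacing,
    )

    # stage 3: coregistration with the template
    recon_vol = assemble_stack_volume(stack, rigids, fields)
    tpl_geom = template.like_geometry()
    recon_tpl = resample(recon_vol, tpl_geom, recon_affine)

    to_tpl_affine = register_affine_3d(recon_tpl, template, norm_cfg)
    recon_tpl2 = resample(recon_tpl, tpl_geom, to_tpl_affine)

    lm_moving = None
    if landmark_stack is not None and template_landmarks is not None:
        lm_vol = assemble_stack_volume(
            landmark_stack, rigids, fields, interp="nearest"
        )
        lm_vol = Volume(
            np.rint(lm_vol.data).astype(np.int32),
            lm_vol.spacing,
            lm_vol.origin,
            kind="label",
        )
        lm_moving = resample(lm_vol, tpl_geom, recon_affine, interp="nearest")
        lm_moving = resample(lm_moving, tpl_geom, to_tpl_affine, interp="nearest")

    to_tpl_field, hist_nrm = register_deformable_3d(
        recon_tpl2,
        template,
        lm_moving,
        template_landmarks if lm_moving is not None else None,
        cfg=norm_cfg,
    )
    chain.to_template_affine = to_tpl_affine
    chain.to_template_field = to_tpl_field

    final = resample(recon_tpl2, tpl_geom, to_tpl_field)
    pse_final = None
    if lm_moving is not None:
        pse_final = landmark_pse(to_tpl_field, lm_moving, template_landmarks)
    return PipelineResult(
        chain=chain,
        reconstructed=final,
        history={
            "affine_reconstruction": hist_aff,
            "deformable_reconstruction": hist_def,
            "normalization": hist_nrm,
        },
        landmark_pse_final=pse_final,
    )


def _resampled_stack(stack, rigids):
    from .geometry import SectionStack

    vol = assemble_stack_volume(stack, rigids)
    out = SectionStack.from_volume(vol)
    return out


def map_cells_for_case(cells, chain, template_labels, depth=None, shell_center=None):
    """Finalize the record table for one case's plotted points."""
    if depth is None:
        depth = solve_depth(template_labels)
    flat = None
    if shell_center is not None:
        flat = lambda pts: shell_flatmap(pts, shell_center)
    return finalize_records(cells, chain, template_labels, depth, flatmap=flat)


# ----------------------------------------------------------------------
# Phantom-run evaluation against ground truth
# ----------------------------------------------------------------------
def evaluate_against_truth(records, truth, injected_area):
    """Recovery statistics of a phantom run.

    Compares mapped records with the planted ground truth (same row
    order): per-cell position errors, the injection-center error, the
    fraction of cells assigned their true area, and the Pearson r between
    recovered and true per-area extrinsic percentages.
    """
    from scipy import stats

    rec = records.reset_index(drop=True)
    tr = truth.reset_index(drop=True)
    ok = ~rec["flagged"]
    pos_err = np.linalg.norm(
        rec.loc[ok, ["ml_mm", "ap_mm", "dv_mm"]].to_numpy()
        - tr.loc[ok, ["ml_mm", "ap_mm", "dv_mm"]].to_numpy(),
        axis=1,
    )
    cells = ok & (rec["kind"] == "cell")
    correct = (
        rec.loc[cells, "area"].to_numpy() == tr.loc[cells, "area"].to_numpy()
    )
    inj = ok & (rec["kind"] == "injection_voxel")
    center_auto = rec.loc[inj, ["ml_mm", "ap_mm", "dv_mm"]].mean().to_numpy()
    center_true = tr.loc[inj, ["ml_mm", "ap_mm", "dv_mm"]].mean().to_numpy()
    center_err = float(np.linalg.norm(center_auto - center_true))

    def percentages(series):
        counts = series.value_counts()
        counts = counts[counts.index != injected_area]
        return 100.0 * counts / counts.sum()

    p_auto = percentages(rec.loc[cells, "area"])
    p_true = percentages(tr.loc[cells, "area"])
    keys = sorted(set(p_auto.index) | set(p_true.index))
    a = np.array([p_auto.get(k, 0.0) for k in keys])
    t = np.array([p_true.get(k, 0.0) for k in keys])
    r = float(stats.pearsonr(a, t)[0]) if len(keys) >= 3 else np.nan
    depth_err = np.abs(
        rec.loc[cells, "normalized_depth"].to_numpy()
        - tr.loc[cells, "normalized_depth"].to_numpy()
    )
    return {
        "n_points": int(ok.sum()),
        "n_flagged": int((~ok).sum()),
        "cell_position_error_median_mm": float(np.median(pos_err)),
        "cell_position_error_p90_mm": float(np.percentile(pos_err, 90)),
        "injection_center_error_mm": center_err,
        "fraction_correct_area": float(np.mean(correct)),
        "area_percentage_pearson_r": r,
        "normalized_depth_error_median": float(np.median(depth_err)),
    }
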