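"""Reconstruction stages: rigid recovery, iterative affine loop, demons."""

import numpy as np
import pytest

from tracemap.geometry import SectionStack, grid_world_points, sample_image
from tracemap.phantom import PhantomConfig, make_template, slice_and_distort
from tracemap.reconstruct import (
    ReconstructionConfig,
    affine_reconstruction,
    assemble_stack_volume,
    deformable_reconstruction,
    register_rigid_2d,
)
from tracemap.transforms import Rigid2D


@pytest.fixture(scope="module")
def section_and_geometry(small_template):
    intensity, _, _ = small_template
    sec = intensity.data[:, intensity.shape[1] // 2, :]
    geom = (
        sec.shape,
        np.array([intensity.spacing[0], intensity.spacing[2]]),
        np.array([intensity.origin[0], intensity.origin[2]]),
    )
    return sec, geom


class TestRegisterRigid2D:
    def test_self_registration_stays_at_identity(self, section_and_geometry):
        sec, geom = section_and_geometry
        r = register_rigid_2d(sec, sec, geom)
        assert np.linalg.norm(r.translation) < 0.05
        assert abs(r.angle) < 0.01

    @pytest.mark.parametrize(
        "gt",
        [
            Rigid2D(angle=0.0, translation=[1.2, -0.8]),
            Rigid2D(angle=np.deg2rad(10.0), translation=[0.0, 0.0]),
        ],
        ids=["translation", "rotation"],
    )
    def test_known_perturbation_recovery(self, section_and_geometry, gt):
        sec, geom = section_and_geometry
        shape, spacing, origin = geom
        center = np.asarray(origin) + 0.5 * spacing * (np.array(shape) - 1)
        gt = Rigid2D(angle=gt.angle, translation=gt.translation, center=center)
        pts = grid_world_points(geom)
        moving = sample_image(sec, spacing, origin, gt.apply(pts)).reshape(shape)
        rec = register_rigid_2d(moving, sec, geom)
        if gt.angle == 0:
            assert np.linalg.norm(rec.translation - gt.translation) < 0.1
        else:
            assert abs(np.rad2deg(rec.angle - gt.angle)) < 0.5

    def test_never_returns_a_transform_worse_than_init(self, section_and_geometry):
        # a far-off init whose basin the optimizer may leave: the returned
        # transform's MI must still be at least the init's MI
        from tracemap.metrics import mutual_information

        sec, geom = section_and_geometry
        shape, spacing, origin = geom
        init = Rigid2D(angle=0.5, translation=[3.0, -3.0])
        rec = register_rigid_2d(sec, sec, geom, init=init)
        pts = grid_world_points(geom)

        def mi_of(t):
            warped = sample_image(sec, spacing, origin, t.inverse().apply(pts)).reshape(shape)
            return mutual_information(sec, warped, bins=32)

        assert mi_of(rec) >= mi_of(init) - 1e-9


@pytest.fixture(scope="module")
def jittered_phantom():
    cfg = PhantomConfig(
        grid_size=48,
        inner_radius_mm=3.2,
        outer_radius_mm=4.4,
        rigid_sigma_mm=0.5,
        deformation_amplitude_mm=0.0,
        deformation3d_amplitude_mm=0.0,
        seed=11,
    )
    intensity, labels, _ = make_template(cfg)
    stack, chain, mask = slice_and_distort(intensity, cfg, labels)
    return cfg, intensity, stack, chain, mask


class TestAffineReconstruction:
    def test_undistorted_stack_needs_no_correction(self, small_cfg):
        cfg = PhantomConfig(
            grid_size=48,
            inner_radius_mm=3.2,
            outer_radius_mm=4.4,
            rigid_sigma_mm=0.0,
            rigid_sigma_rad=0.0,
            deformation_amplitude_mm=0.0,
            deformation3d_amplitude_mm=0.0,
            affine_scale_range=(1.0, 1.0),
            affine_shear_max=0.0,
            affine_rotation_max_rad=0.0,
            affine_translation_max_mm=0.0,
            seed=5,
        )
        intensity, labels, _ = make_template(cfg)
        stack, _, mask = slice_and_distort(intensity, cfg, labels)
        rigids, affine, _ = affine_reconstruction(
            stack, intensity, ReconstructionConfig(n_outer_iterations=2)
        )
        for s, m in enumerate(mask.sections):
            if np.asarray(m).sum() < 100:
                continue
            assert np.linalg.norm(rigids[s].translation) < 0.1
            assert abs(np.rad2deg(rigids[s].angle)) < 0.5

    def test_jittered_sections_recovered_against_ground_truth(self, jittered_phantom):
        cfg, intensity, stack, gt, mask = jittered_phantom
        rigids, affine, hist = affine_reconstruction(
            stack, intensity, ReconstructionConfig(n_outer_iterations=6)
        )
        errs = []
        for s in range(len(stack)):
            m = np.asarray(mask.sections[s]) > 0.5
            if m.sum() < 100:
                continue
            idx = np.argwhere(m)[::7]
            pts = stack.in_plane_origin + idx * stack.in_plane_spacing
            p = rigids[s].apply(pts)
            ap = stack.ap_of_section(s)
            rec = affine.apply(
                np.column_stack([p[:, 0], np.full(len(p), ap), p[:, 1]])
            )
            errs.append(np.linalg.norm(rec - gt.map_points(s, pts), axis=1).mean())
        errs = np.asarray(errs)
        assert np.mean(errs < 0.2) >= 0.9

    def test_mean_mi_improves_over_iterations(self, jittered_phantom):
        cfg, intensity, stack, gt, mask = jittered_phantom
        _, _, hist = affine_reconstruction(
            stack, intensity, ReconstructionConfig(n_outer_iterations=4)
        )
        mi = hist["mean_mi"]
        assert mi[-1] >= mi[0]


class TestDeformableReconstruction:
    def test_identical_sections_yield_zero_fields(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(24, 24))
        stack = SectionStack([img.copy() for _ in range(6)], 0.25, 0.25)
        fields, hist = deformable_reconstruction(
            stack, ReconstructionConfig(n_deformable_iterations=3)
        )
        for f in fields:
            assert np.max(np.abs(f.field)) < 1e-9

    def test_alternating_bulge_reduces_between_section_msd(self, small_template):
        intensity, _, _ = small_template
        clean = SectionStack.from_volume(intensity)
        shape, spacing, origin = clean.section_geometry()
        pts = grid_world_points(clean.section_geometry())
        c2 = np.array([6.0, 4.8])
        bulged = []
        for s, img in enumerate(clean.sections):
            amp = 0.3 if s % 2 == 0 else -0.3
            rel = pts - c2
            rr = np.linalg.norm(rel, axis=1, keepdims=True)
            disp = amp * np.exp(-(((rr - 3.8) / 1.2) ** 2)) * rel / np.maximum(rr, 1e-9)
            bulged.append(sample_image(img, spacing, origin, pts + disp).reshape(shape))
        stack = SectionStack(
            bulged, clean.in_plane_spacing, clean.section_spacing,
            clean.in_plane_origin, clean.ap_origin,
        )
        _, hist = deformable_reconstruction(
            stack, ReconstructionConfig(n_deformable_iterations=8)
        )
        assert hist["msd"][-1] < 0.3 * hist["msd"][0]

    def test_clean_stack_is_left_nearly_untouched(self, small_template):
        intensity, _, _ = small_template
        clean = SectionStack.from_volume(intensity)
        fields, _ = deformable_reconstruction(
            clean, ReconstructionConfig(n_deformable_iterations=4)
        )
        mean_disp = np.mean(
            [np.linalg.norm(f.field, axis=-1).mean() for f in fields]
        )
        assert mean_disp < 0.05

    def test_msd_history_is_non_increasing(self, small_template):
        intensity, _, _ = small_template
        clean = SectionStack.from_volume(intensity)
        _, hist = deformable_reconstruction(
            clean, ReconstructionConfig(n_deformable_iterations=5)
        )
        msd = np.asarray(hist["msd"])
        assert np.all(np.diff(msd) <= 1e-6)
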