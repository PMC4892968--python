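"""Phantom generator: geometry, distortions, ground truth, planted cells."""

import numpy as np
import pytest

from tracemap.errors import ConfigError
from tracemap.geometry import grid_world_points, sample_volume
from tracemap.phantom import (
    PhantomConfig,
    make_template,
    plant_cells,
    slice_and_distort,
)


def undistorted(seed=77, **kw):
    return PhantomConfig(
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
        seed=seed,
        **kw,
    )


class TestMakeTemplate:
    def test_label_inventory_matches_area_count(self, small_cfg, small_template):
        _, labels, landmarks = small_template
        expected = set(range(small_cfg.n_areas + 2))  # bg, areas, white matter
        assert set(np.unique(labels.data)) == expected
        assert set(np.unique(landmarks.data)) == set(range(small_cfg.n_landmarks + 1))

    def test_every_cortex_voxel_lies_within_the_shell(self, small_cfg, small_template):
        _, labels, _ = small_template
        pts = grid_world_points(labels.like_geometry()).reshape(labels.shape + (3,))
        r = np.linalg.norm(pts - small_cfg.center, axis=-1)
        cortex = (labels.data >= 1) & (labels.data <= small_cfg.n_areas)
        half = 0.5 * np.sqrt(3) * small_cfg.spacing_mm
        assert np.all(r[cortex] >= small_cfg.inner_radius_mm - half)
        assert np.all(r[cortex] <= small_cfg.outer_radius_mm + half)

    def test_equal_angular_sectors_have_balanced_volumes(self):
        cfg = PhantomConfig()  # default grid: discretization error is small
        _, labels, _ = make_template(cfg)
        counts = np.array([np.sum(labels.data == a) for a in range(1, cfg.n_areas + 1)])
        assert np.all(np.abs(counts - counts.mean()) / counts.mean() < 0.05)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ConfigError):
            PhantomConfig(inner_radius_mm=5.0, outer_radius_mm=4.0)
        with pytest.raises(ConfigError):
            PhantomConfig(grid_size=16, outer_radius_mm=6.0)


class TestSliceAndDistort:
    def test_zero_amplitudes_reduce_to_plain_reslicing(self):
        cfg = undistorted()
        intensity, labels, _ = make_template(cfg)
        stack, chain, _ = slice_and_distort(intensity, cfg, labels)
        for j in range(0, len(stack), 7):
            np.testing.assert_allclose(stack.sections[j], intensity.data[:, j, :])
        for s, (rigid, field) in chain.per_section.items():
            assert rigid.angle == 0 and np.all(rigid.translation == 0)
            assert field is None
        assert np.array_equal(chain.reconstruction_affine.matrix, np.eye(3))

    def test_section_count_covers_ap_extent(self, small_cfg):
        intensity, labels, _ = make_template(small_cfg)
        stack, _, _ = slice_and_distort(intensity, small_cfg, labels)
        extent = small_cfg.grid_size * small_cfg.spacing_mm
        assert len(stack) == int(np.ceil(extent / small_cfg.section_spacing_mm))

    def test_ground_truth_chain_is_self_consistent(self, small_cfg):
        # raw sections were rendered by sampling the template through the
        # chain, so re-mapping raw pixels must land on matching intensities
        intensity, labels, mask_src = make_template(small_cfg)
        stack, chain, mask = slice_and_distort(intensity, small_cfg, labels)
        rng = np.random.default_rng(0)
        worst = 0.0
        for s in range(10, len(stack) - 10, 5):
            m = np.asarray(mask.sections[s]) > 0.5
            if m.sum() < 50:
                continue
            idx = np.argwhere(m)[:: max(1, m.sum() // 40)]
            pts = stack.in_plane_origin + idx * stack.in_plane_spacing
            tpl_pts = chain.map_points(s, pts)
            vals = sample_volume(intensity, tpl_pts)
            sec_vals = np.asarray(stack.sections[s])[idx[:, 0], idx[:, 1]]
            worst = max(worst, float(np.abs(vals - sec_vals).max()))
        assert worst < 1e-9

    def test_round_trip_through_inverse_chain(self, small_cfg):
        intensity, labels, _ = make_template(small_cfg)
        stack, chain, mask = slice_and_distort(intensity, small_cfg, labels)
        rng = np.random.default_rng(1)
        pts, secs = [], []
        for s in range(12, len(stack) - 12, 4):
            m = np.asarray(mask.sections[s]) > 0.5
            idx = np.argwhere(m)
            if len(idx) < 10:
                continue
            take = idx[rng.integers(0, len(idx), 10)]
            pts.append(stack.in_plane_origin + take * stack.in_plane_spacing)
            secs.extend([s] * 10)
        pts = np.vstack(pts)
        tpl = np.vstack(
            [chain.map_points(s, p[None, :])[0] for s, p in zip(secs, pts)]
        )
        back_secs, back = chain.inverse_map_points(tpl)
        fwd = np.vstack(
            [chain.map_points(int(s), p[None, :])[0] for s, p in zip(back_secs, back)]
        )
        err = np.linalg.norm(fwd - tpl, axis=1)
        assert np.quantile(err, 0.99) < 0.02

    def test_deterministic_per_seed(self, small_cfg):
        intensity, labels, _ = make_template(small_cfg)
        s1, c1, _ = slice_and_distort(intensity, small_cfg, labels)
        s2, c2, _ = slice_and_distort(intensity, small_cfg, labels)
        np.testing.assert_array_equal(s1.sections[20], s2.sections[20])
        assert np.array_equal(
            c1.reconstruction_affine.matrix, c2.reconstruction_affine.matrix
        )


class TestPlantCells:
    @pytest.fixture(scope="class")
    def planted(self, small_cfg):
        intensity, labels, _ = make_template(small_cfg)
        _, chain, _ = slice_and_distort(intensity, small_cfg, labels)
        cells, truth = plant_cells(labels, chain, small_cfg)
        return small_cfg, labels, chain, cells, truth

    def test_schema_and_kinds(self, planted):
        cfg, _, _, cells, truth = planted
        assert list(cells.columns) == ["animal", "tracer", "kind", "section", "x_mm", "y_mm"]
        assert len(cells) == len(truth)
        assert (cells["kind"] == "cell").sum() == cfg.n_cells_per_injection

    def test_cells_restricted_to_one_area(self):
        cfg = undistorted(n_areas=4, n_cells_per_injection=50, injection_area=1)
        intensity, labels, _ = make_template(cfg)
        _, chain, _ = slice_and_distort(intensity, cfg, labels)
        # with the injection in area 1, force all cells into area 2 by
        # leaving only areas {1, 2}: every extrinsic cell must be in 2
        cfg2 = undistorted(n_areas=2, n_cells_per_injection=50, injection_area=1)
        intensity2, labels2, _ = make_template(cfg2)
        _, chain2, _ = slice_and_distort(intensity2, cfg2, labels2)
        cells, truth = plant_cells(labels2, chain2, cfg2)
        assert set(truth.loc[cells["kind"] == "cell", "area"].unique()) == {2}

    def test_depth_sampling_matches_stated_uniform(self, planted):
        cfg, _, _, cells, truth = planted
        nd = truth.loc[cells["kind"] == "cell", "normalized_depth"]
        lo, hi = cfg.cell_depth_range
        mean, n = 0.5 * (lo + hi), len(nd)
        sigma = (hi - lo) / np.sqrt(12 * n)
        # truth depths are re-derived after snapping to section planes, which
        # smears the drawn uniform slightly; the mean is the stated check
        assert abs(nd.mean() - mean) < 3 * sigma + 0.01
        assert nd.min() >= 0.0 and nd.max() <= 1.0

    def test_rerun_reproduces_tables_exactly(self, planted):
        cfg, labels, chain, cells, truth = planted
        cells2, truth2 = plant_cells(labels, chain, cfg)
        assert cells.equals(cells2)
        assert truth.equals(truth2)
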