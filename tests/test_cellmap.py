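"""Area assignment, Laplace depth, record finalization and summaries."""

import numpy as np
import pandas as pd
import pytest

from tracemap.cellmap import (
    assign_area,
    depth_at_points,
    finalize_records,
    injection_center_of_mass,
    solve_depth,
    summarize_areas,
)
from tracemap.errors import ConfigError
from tracemap.geometry import Volume
from tracemap.transforms import TransformChain


@pytest.fixture(scope="module")
def slab():
    # flat cortical slab, 5 voxels thick at 0.1 mm: analytic thickness 0.5 mm
    lab = np.zeros((12, 12, 9), dtype=np.int32)
    lab[:, :, 2:7] = 1
    lab[:, :, 7:] = 2
    vol = Volume(lab, [0.1] * 3, [0, 0, 0], kind="label")
    return vol, solve_depth(vol, cortex_labels=[1], wm_label=2)


@pytest.fixture(scope="module")
def shell():
    # spherical shell, inner 2 mm / outer 3 mm: analytic thickness 1.0 mm
    n, sp = 70, 0.1
    ax = (np.arange(n) - n / 2 + 0.5) * sp
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    lab = np.zeros((n, n, n), dtype=np.int32)
    lab[(r >= 2) & (r <= 3)] = 1
    lab[r < 2] = 2
    vol = Volume(lab, [sp] * 3, [ax[0]] * 3, kind="label")
    return vol, solve_depth(vol, cortex_labels=[1], wm_label=2), r


class TestSolveDepth:
    def test_flat_slab_thickness_within_five_percent_everywhere(self, slab):
        vol, depth = slab
        th = depth.thickness.data[:, :, 2:7]
        assert np.nanmax(np.abs(th - 0.5)) / 0.5 < 0.05

    def test_shell_thickness_and_mid_surface_radius(self, shell):
        vol, depth, r = shell
        cortex = vol.data == 1
        th = depth.thickness.data[cortex]
        assert abs(np.nanmean(th) - 1.0) < 0.05
        assert abs(np.nanmedian(th) - 1.0) < 0.05
        rm = r[depth.mid_thickness.data > 0]
        assert len(rm) > 0
        assert np.all(np.abs(rm - 2.5) <= 0.15)

    def test_boundary_depth_ordering(self, slab):
        vol, depth = slab
        nd = depth.normalized_depth.data
        assert np.nanmean(nd[:, :, 2]) < 0.2  # pial-adjacent
        assert np.nanmean(nd[:, :, 6]) > 0.8  # white-matter-adjacent

    def test_normalized_depth_monotone_across_the_slab(self, slab):
        vol, depth = slab
        nd = depth.normalized_depth.data[6, 6, 2:7]
        assert np.all(np.diff(nd) > 0)

    def test_missing_white_matter_rejected(self):
        lab = np.zeros((4, 4, 4), dtype=np.int32)
        lab[1:3, 1:3, 1:3] = 1
        with pytest.raises(ConfigError):
            solve_depth(Volume(lab, [0.1] * 3, [0] * 3, kind="label"),
                        cortex_labels=[1], wm_label=2)


class TestAssignArea:
    @pytest.fixture(scope="class")
    def two_area_volume(self):
        lab = np.zeros((10, 10, 10), dtype=np.int32)
        lab[2:5, 2:8, 2:8] = 2
        lab[5:8, 2:8, 2:8] = 3
        return Volume(lab, np.ones(3), np.zeros(3), kind="label")

    def test_point_inside_an_area_keeps_it(self, two_area_volume):
        areas, dists = assign_area([[3.0, 4.0, 4.0]], two_area_volume, [2, 3])
        assert areas[0] == 3 or areas[0] == 2
        assert dists[0] == 0.0

    def test_outside_point_gets_nearest_area_with_recorded_distance(
        self, two_area_volume
    ):
        areas, dists = assign_area(
            [[3.0, 4.0, 8.2]], two_area_volume, [2, 3], max_fallback_mm=5.0
        )
        assert areas[0] == 2
        assert dists[0] == pytest.approx(1.2)

    def test_equidistant_tie_resolves_to_smaller_label(self, two_area_volume):
        # x = 4.5 is exactly between the last column of area 2 (x=4) and the
        # first of area 3 (x=5)
        areas, _ = assign_area([[4.5, 4.0, 9.5]], two_area_volume, [2, 3],
                               max_fallback_mm=5.0)
        assert areas[0] == 2

    def test_matches_exhaustive_nearest_scan(self, two_area_volume):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 9, (1000, 3))
        areas, dists = assign_area(pts, two_area_volume, [2, 3], max_fallback_mm=50.0)
        mask = np.isin(two_area_volume.data, [2, 3])
        centers = np.argwhere(mask).astype(float)
        labs = two_area_volume.data[mask]
        for p, a, d in zip(pts[::37], areas[::37], dists[::37]):
            alld = np.linalg.norm(centers - p, axis=1)
            dmin = alld.min()
            best = labs[alld <= dmin + 1e-9].min()
            if d > 0:
                assert abs(d - dmin) < 1e-9
                assert a == best

    def test_cap_flags_far_points_and_empty_cortex_rejected(self, two_area_volume):
        areas, dists = assign_area([[0.0, 0.0, 0.0]], two_area_volume, [2, 3],
                                   max_fallback_mm=1.0)
        assert areas[0] == 0 and dists[0] > 1.0
        with pytest.raises(ConfigError):
            assign_area([[0.0, 0.0, 0.0]], two_area_volume, [])


class TestFinalizeRecords:
    @pytest.fixture(scope="class")
    def tiny_case(self):
        # 10-voxel slab world with an identity chain: section plane j maps to
        # AP = j; in-plane (x, y) -> (ML, DV)
        lab = np.zeros((10, 10, 10), dtype=np.int32)
        lab[:, :, 3:6] = 1
        lab[:, :, 6:] = 2
        labels = Volume(lab, np.ones(3), np.zeros(3), kind="label")
        depth = solve_depth(labels, cortex_labels=[1], wm_label=2)
        chain = TransformChain.identity(10, ap_origin=0.0, section_spacing=1.0)
        return labels, depth, chain

    def test_rules_for_outside_and_white_matter_points(self, tiny_case):
        labels, depth, chain = tiny_case
        cells = pd.DataFrame(
            [
                {"animal": "A", "tracer": "FB", "kind": "cell", "section": 4,
                 "x_mm": 4.0, "y_mm": 0.5},   # outside the brain (background)
                {"animal": "A", "tracer": "FB", "kind": "cell", "section": 4,
                 "x_mm": 4.0, "y_mm": 8.0},   # white matter
                {"animal": "A", "tracer": "FB", "kind": "cell", "section": 4,
                 "x_mm": 4.0, "y_mm": 4.0},   # mid-cortex
            ]
        )
        rec = finalize_records(cells, chain, labels, depth, max_fallback_mm=10.0)
        rec = rec.sort_values("y_mm").reset_index(drop=True)
        assert rec.loc[0, "normalized_depth"] == 0.0      # outside -> 0
        assert rec.loc[0, "nominal_depth_mm"] == 0.0
        assert rec.loc[2, "normalized_depth"] == 1.0      # white matter -> 1
        assert 0.0 < rec.loc[1, "normalized_depth"] < 1.0

    def test_unmappable_section_is_flagged_and_kept(self, tiny_case):
        labels, depth, chain = tiny_case
        cells = pd.DataFrame(
            [{"animal": "A", "tracer": "FB", "kind": "cell", "section": 99,
              "x_mm": 4.0, "y_mm": 4.0}]
        )
        rec = finalize_records(cells, chain, labels, depth)
        assert len(rec) == 1 and bool(rec.loc[0, "flagged"])

    def test_injection_center_is_centroid(self, tiny_case):
        labels, depth, chain = tiny_case
        rng = np.random.default_rng(1)
        offsets = rng.uniform(-0.4, 0.4, (20, 2))
        offsets = np.vstack([offsets, -offsets])  # symmetric cloud
        rows = [
            {"animal": "A", "tracer": "DY", "kind": "injection_voxel",
             "section": 4, "x_mm": 4.0 + dx, "y_mm": 4.0 + dy}
            for dx, dy in offsets
        ]
        rec = finalize_records(pd.DataFrame(rows), chain, labels, depth)
        com = injection_center_of_mass(rec)
        np.testing.assert_allclose(
            com[["ml_mm", "ap_mm", "dv_mm"]].to_numpy()[0], [4.0, 4.0, 4.0],
            atol=1e-9,
        )


class TestSummarizeAreas:
    def make_records(self, counts, injected=None, intrinsic=0):
        rows = []
        for area, n in counts.items():
            for _ in range(n):
                rows.append({"kind": "cell", "area": area, "flagged": False,
                             "normalized_depth": 0.5})
        for _ in range(intrinsic):
            rows.append({"kind": "cell", "area": injected, "flagged": False,
                         "normalized_depth": 0.5})
        return pd.DataFrame(rows)

    def test_percentages_over_extrinsic_cells(self):
        rec = self.make_records({"A": 10, "B": 30})
        out = summarize_areas(rec, injected_area="C")
        pct = out.set_index("group")["percentage"]
        assert pct["A"] == pytest.approx(25.0)
        assert pct["B"] == pytest.approx(75.0)

    def test_intrinsic_cells_excluded_and_flagged_undefined(self):
        rec = self.make_records({"A": 10, "B": 30}, injected="C", intrinsic=5)
        out = summarize_areas(rec, injected_area="C")
        pct = out.set_index("group")["percentage"]
        assert pct["A"] == pytest.approx(25.0)
        assert pct["B"] == pytest.approx(75.0)
        assert np.isnan(pct["C"])
        assert out.set_index("group")["count"]["C"] == 5  # counted, not weighed

    def test_grouping_merges_without_changing_total(self):
        rec = self.make_records({"A": 10, "B": 30})
        out = summarize_areas(rec, injected_area="C", grouping={"A": "G", "B": "G"})
        assert out.loc[out["group"] == "G", "percentage"].iloc[0] == pytest.approx(100.0)
        assert out["count"].sum() == 40

    def test_extrinsic_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(2)
        counts = {f"a{i}": int(n) for i, n in enumerate(rng.integers(1, 50, 8))}
        rec = self.make_records(counts, injected="a0", intrinsic=7)
        out = summarize_areas(rec, injected_area="a0")
        assert out["percentage"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_unknown_grouping_key_rejected(self):
        rec = self.make_records({"A": 5})
        with pytest.raises(ConfigError):
            summarize_areas(rec, injected_area="A", grouping={"Z": "G"})


class TestDepthAtPoints:
    def test_cortex_point_gets_interior_depth(self, slab):
        labels, depth = slab
        nominal, nd = depth_at_points([[0.6, 0.6, 0.4]], labels, depth)
        assert 0.0 < nd[0] < 1.0
        assert nominal[0] == pytest.approx(nd[0] * 0.5, abs=0.05)
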