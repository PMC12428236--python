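import numpy as np
import pytest
from scipy.spatial import Delaunay

from gliamorph import morphometry as mm
from gliamorph.config import PipelineConfig
from gliamorph.segmentation import CellObject, ExclusionReason, LabelMap, cells_from_labels
from gliamorph.synthetic import default_spec, generate_single_cell_stack, render_tubes

SP = (0.5, 0.5, 0.5)


def cell_from_mask(mask: np.ndarray) -> CellObject:
    return CellObject(cell_id=1, voxels=np.argwhere(mask), interior_fraction=1.0)


def ball_mask(radius_vox: int, pad: int = 2) -> np.ndarray:
    n = 2 * (radius_vox + pad) + 1
    c = radius_vox + pad
    zz, yy, xx = np.mgrid[:n, :n, :n]
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2


class TestVolumes:
    def test_cell_volume_formula(self):
        cell = CellObject(1, np.argwhere(np.ones((4, 5, 5), dtype=bool)), 1.0)
        assert cell.voxel_count == 100
        assert mm.cell_volume(cell, (1.0, 0.5, 0.5)) == pytest.approx(25.0)

    def test_single_voxel_volume(self):
        cell = CellObject(1, np.array([[0, 0, 0]]), 1.0)
        assert mm.cell_volume(cell, (0.5, 0.172, 0.172)) == pytest.approx(0.0147920, abs=1e-6)

    def test_volume_linear_in_count(self, rng):
        vox = rng.integers(0, 20, size=(30, 3))
        vox = np.unique(vox, axis=0)
        half = CellObject(1, vox[: len(vox) // 2], 1.0)
        full_vol = mm.cell_volume(CellObject(1, vox, 1.0), SP)
        assert full_vol == pytest.approx(len(vox) / (len(vox) // 2) * mm.cell_volume(half, SP))


class TestTerritory:
    def test_filled_cuboid_hull_is_corner_span(self):
        """Voxel centers of an 11^3 cube at 1 µm span a 10^3 hull."""
        mask = np.zeros((13, 13, 13), dtype=bool)
        mask[1:12, 1:12, 1:12] = True
        terr, degenerate = mm.territory_volume(cell_from_mask(mask), (1, 1, 1))
        assert not degenerate
        assert terr == pytest.approx(1000.0)

    def test_random_cloud_matches_delaunay_oracle(self, rng):
        """Hull volume equals the sum of simplex volumes of an independent
        Delaunay decomposition of the same points."""
        for _ in range(10):
            vox = np.unique(rng.integers(0, 15, size=(50, 3)), axis=0)
            cell = CellObject(1, vox, 1.0)
            terr, degenerate = mm.territory_volume(cell, SP)
            assert not degenerate
            pts = vox * np.array(SP)
            tri = Delaunay(pts)
            vol = 0.0
            for simplex in tri.simplices:
                a, b, c, d = pts[simplex]
                vol += abs(np.linalg.det(np.stack([b - a, c - a, d - a]))) / 6.0
            assert terr == pytest.approx(vol, rel=1e-8)

    def test_hull_monotone_under_subsets(self, rng):
        vox = np.unique(rng.integers(0, 12, size=(60, 3)), axis=0)
        sub = vox[rng.uniform(size=len(vox)) < 0.5]
        if len(sub) < 4:
            sub = vox[:4]
        big, _ = mm.territory_volume(CellObject(1, vox, 1.0), SP)
        small, _ = mm.territory_volume(CellObject(1, sub, 1.0), SP)
        assert small <= big + 1e-9

    def test_collinear_cell_degenerates_to_cell_volume(self):
        vox = np.array([[0, 0, i] for i in range(10)])
        cell = CellObject(1, vox, 1.0)
        terr, degenerate = mm.territory_volume(cell, SP)
        assert degenerate
        assert terr == pytest.approx(mm.cell_volume(cell, SP))


class TestRamificationIndex:
    def test_formula(self):
        assert mm.ramification_index(500.0, 100.0) == pytest.approx(5.0)

    def test_zero_volume_raises(self):
        with pytest.raises(ValueError):
            mm.ramification_index(10.0, 0.0)

    def test_ball_phantom_ri_near_one(self):
        """A solid convex body has RI ~ 1 within discretization error."""
        cell = cell_from_mask(ball_mask(8))
        vol = mm.cell_volume(cell, (1, 1, 1))
        terr, _ = mm.territory_volume(cell, (1, 1, 1))
        ri = mm.ramification_index(max(terr, vol), vol)
        assert 1.0 <= ri <= 1.1

    def test_ramified_exceeds_amoeboid(self):
        """Matched phantom pairs: ramified cells claim far more territory
        per unit volume than amoeboid cells."""
        wins = 0
        for seed in range(8):
            ris = {}
            for arch in ("amoeboid", "ramified"):
                _, _, mask = generate_single_cell_stack(default_spec(arch, seed=seed), spacing=SP)
                cell = cell_from_mask(mask > 0)
                vol = mm.cell_volume(cell, SP)
                terr, _ = mm.territory_volume(cell, SP)
                ris[arch] = terr / vol
            wins += ris["ramified"] > ris["amoeboid"]
        assert wins >= 7


def tube_mask(length_um=20.0, radius_vox=2, spacing=SP):
    """Straight tube along x, capsule-rendered."""
    r = radius_vox * spacing[2]
    pad = 4 * spacing[2]
    shape = (int(2 * (r + pad) / spacing[0]) + 3, int(2 * (r + pad) / spacing[1]) + 3,
             int((length_um + 2 * (r + pad)) / spacing[2]) + 3)
    mid = ((shape[0] - 1) / 2 * spacing[0], (shape[1] - 1) / 2 * spacing[1])
    a = (mid[0], mid[1], r + pad)
    b = (mid[0], mid[1], r + pad + length_um)
    return render_tubes([(a, b)], r, shape, spacing)


class TestSkeleton:
    def test_straight_tube_single_path(self):
        """A 20 µm tube thins to one path: 0 branchpoints, 2 endpoints,
        min = avg = max ~ 20 µm (within 2 voxel pitches)."""
        cell = cell_from_mask(tube_mask(20.0))
        skel = mm.skeletonize(cell, (0, 0, 0), SP, prune_length_um=2.0)
        bm = mm.branch_metrics(skel)
        assert (bm.branchpoints, bm.endpoints) == (0, 2)
        assert bm.min_branch_um == bm.max_branch_um == bm.avg_branch_um
        assert bm.avg_branch_um == pytest.approx(20.0, abs=2 * 0.5 * np.sqrt(3))

    def test_y_phantom_one_bifurcation(self):
        """A Y of three capsules: 1 branchpoint, 3 endpoints."""
        c = 15.0
        segs = [((c, c, 2.0), (c, c, 12.0)),
                ((c, c, 12.0), (c, c + 7.0, 19.0)),
                ((c, c, 12.0), (c, c - 7.0, 19.0))]
        mask = render_tubes(segs, 1.0, (61, 61, 61), SP)
        skel = mm.skeletonize(cell_from_mask(mask), (0, 0, 0), SP)
        bm = mm.branch_metrics(skel)
        assert (bm.branchpoints, bm.endpoints) == (1, 3)

    def test_ball_degenerate(self):
        """A ball has no branches: skeleton flagged degenerate, all zeros."""
        skel = mm.skeletonize(cell_from_mask(ball_mask(6)), (0, 0, 0), (1, 1, 1))
        assert skel.degenerate
        bm = mm.branch_metrics(skel)
        assert (bm.branchpoints, bm.endpoints) == (0, 0)
        assert bm.avg_branch_um == bm.min_branch_um == bm.max_branch_um == 0.0

    def test_tree_identity_on_generated_phantoms(self):
        """endpoints = 2 + sum(degree - 2) over branchpoints, for every
        acyclic measured skeleton (and the generator's own trees)."""
        for seed in range(6):
            for arch in ("intermediate", "ramified"):
                _, truth, mask = generate_single_cell_stack(default_spec(arch, seed=seed), spacing=SP)
                assert truth.tree_identity_holds()
                skel = mm.skeletonize(cell_from_mask(mask > 0), (0, 0, 0), SP)
                import networkx as nx
                g = skel.graph
                if nx.number_connected_components(g) == 1 and g.number_of_edges() == g.number_of_nodes() - 1:
                    assert len(skel.endpoints) == 2 + sum(d - 2 for d in skel.junction_degrees)

    def test_phantom_count_recovery(self):
        """Noise-free phantoms: branchpoint/endpoint counts match ground
        truth exactly; branch lengths match within 2 voxel pitches."""
        pitch = 0.5 * np.sqrt(3)
        for seed in (3, 11, 42):
            for arch in ("amoeboid", "intermediate", "ramified"):
                _, truth, mask = generate_single_cell_stack(default_spec(arch, seed=seed), spacing=SP)
                skel = mm.skeletonize(cell_from_mask(mask > 0), (0, 0, 0), SP)
                bm = mm.branch_metrics(skel)
                assert bm.branchpoints == truth.branchpoints
                assert bm.endpoints == truth.endpoints
                measured = sorted(b.length_um for b in skel.branches)
                for got, want in zip(measured, truth.branch_lengths_um):
                    assert got == pytest.approx(want, abs=2 * pitch)


class TestSoma:
    def test_ball_center_and_bounded_volume(self):
        mask = ball_mask(7)
        cell = cell_from_mask(mask)
        est = mm.soma(cell, (1, 1, 1), soma_fraction=0.5)
        center = np.argwhere(mask).mean(axis=0)
        assert np.linalg.norm(np.array(est.center_voxel) - center) <= 1.0
        assert est.soma_volume_um3 <= mm.cell_volume(cell, (1, 1, 1))

    def test_tube_soma_smaller_than_cell(self):
        cell = cell_from_mask(tube_mask(20.0))
        est = mm.soma(cell, SP)
        assert est.soma_volume_um3 < mm.cell_volume(cell, SP)

    def test_fraction_one_keeps_argmax_set_only(self):
        mask = ball_mask(5)
        cell = cell_from_mask(mask)
        full = mm.soma(cell, (1, 1, 1), soma_fraction=1.0)
        half = mm.soma(cell, (1, 1, 1), soma_fraction=0.5)
        assert full.soma_volume_um3 <= half.soma_volume_um3
        assert full.soma_volume_um3 <= 8.0  # at most a few voxels tie at the max


class TestSholl:
    def test_rod_profile_closed_form(self):
        """A straight 30 µm rod from the center crosses each sphere once."""
        mask = np.zeros((5, 5, 65), dtype=bool)
        mask[2, 2, 2:63] = True  # 61 voxels along x at 0.5 µm = 30 µm span
        skel = mm.skeletonize(cell_from_mask(mask), (0, 0, 0), SP, prune_length_um=0.0)
        center = (2 * 0.5, 2 * 0.5, 2 * 0.5)  # rod start
        profile = mm.sholl(skel, center, step_um=5.0, max_radius_um=30.0)
        assert [n for _, n in profile] == [1, 1, 1, 1, 1, 1]

    def test_y_phantom_profile_steps_up_after_bifurcation(self):
        c = 15.0
        segs = [((c, c, 2.0), (c, c, 12.0)),
                ((c, c, 12.0), (c, c + 8.0, 20.0)),
                ((c, c, 12.0), (c, c - 8.0, 20.0))]
        mask = render_tubes(segs, 1.0, (61, 61, 61), SP)
        skel = mm.skeletonize(cell_from_mask(mask), (0, 0, 0), SP)
        profile = dict(mm.sholl(skel, (c, c, 2.0), step_um=5.0, max_radius_um=20.0))
        assert profile[5.0] == 1  # before the 10 µm bifurcation
        assert profile[15.0] == 2  # between bifurcation and tips

    def test_degenerate_skeleton_all_zero(self):
        skel = mm.skeletonize(cell_from_mask(ball_mask(5)), (0, 0, 0), (1, 1, 1))
        profile = mm.sholl(skel, (0, 0, 0), 5.0, 20.0)
        assert all(n == 0 for _, n in profile)

    def test_step_must_be_positive(self):
        skel = mm.skeletonize(cell_from_mask(ball_mask(5)), (0, 0, 0), (1, 1, 1))
        with pytest.raises(ValueError):
            mm.sholl(skel, (0, 0, 0), 0.0, 20.0)


class TestMeasureCells:
    def test_excluded_cells_not_measured(self, iso_config):
        _, _, mask = generate_single_cell_stack(default_spec("amoeboid", seed=0), spacing=SP)
        vox = np.argwhere(mask > 0)
        cells = [
            CellObject(1, vox, 1.0),
            CellObject(2, vox + 1, 1.0),
            CellObject(3, vox, 0.1, included=False,
                       exclusion_reason=ExclusionReason.INCOMPLETE),
        ]
        records = mm.measure_cells(cells, mask.shape, iso_config)
        assert [r.cell_id for r in records] == [1, 2]

    def test_record_invariants_on_phantoms(self, iso_config):
        """Territory >= volume (so RI >= 1), ordered branch lengths, and
        degenerate rows all-zero, across archetypes and seeds."""
        for seed in range(4):
            for arch in ("amoeboid", "ramified"):
                _, _, mask = generate_single_cell_stack(default_spec(arch, seed=seed), spacing=SP)
                cells = cells_from_labels(LabelMap(mask, 1, 26))
                (rec,) = mm.measure_cells(cells, mask.shape, iso_config)
                assert rec.territory_um3 >= rec.cell_volume_um3 > 0
                assert rec.ramification_index >= 1.0
                if rec.degenerate_skeleton:
                    assert rec.branchpoints == rec.endpoints == 0
                    assert rec.avg_branch_um == 0.0
                else:
                    assert rec.min_branch_um <= rec.avg_branch_um <= rec.max_branch_um
                assert rec.soma_um3 <= rec.cell_volume_um3

    def test_rerun_identical_output(self, iso_config, tmp_path):
        _, _, mask = generate_single_cell_stack(default_spec("intermediate", seed=5), spacing=SP)
        cells = cells_from_labels(LabelMap(mask, 1, 26))
        frames = []
        for name in ("a.csv", "b.csv"):
            records = mm.measure_cells(cells, mask.shape, iso_config)
            path = tmp_path / name
            mm.records_to_frame(records).to_csv(path, index=False)
            frames.append(path.read_bytes())
        assert frames[0] == frames[1]


class TestSpacingScaling:
    def test_volumes_scale_cubically_lengths_linearly(self, iso_config):
        """Doubling all spacing multiplies volumes by 8 and lengths by 2."""
        _, _, mask = generate_single_cell_stack(default_spec("intermediate", seed=9), spacing=SP)
        cells = cells_from_labels(LabelMap(mask, 1, 26))
        cfg2 = PipelineConfig(spacing=(1.0, 1.0, 1.0), prune_length_um=iso_config.prune_length_um * 2)
        (r1,) = mm.measure_cells(cells, mask.shape, iso_config)
        (r2,) = mm.measure_cells(cells, mask.shape, cfg2)
        assert r2.cell_volume_um3 == pytest.approx(8 * r1.cell_volume_um3)
        assert r2.territory_um3 == pytest.approx(8 * r1.territory_um3)
        assert r2.soma_um3 == pytest.approx(8 * r1.soma_um3)
        assert r2.avg_branch_um == pytest.approx(2 * r1.avg_branch_um, rel=1e-9)
        assert (r2.branchpoints, r2.endpoints) == (r1.branchpoints, r1.endpoints)
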