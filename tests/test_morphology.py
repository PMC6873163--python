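"""Skeleton topology, branch ordering, arc lengths and rasterization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synquant import (
    VoxelGridSpec,
    compute_branch_orders,
    make_pyramidal_skeleton,
    rasterize_cell,
    read_swc,
    segment_arc_length,
    soma_surface_area,
    write_swc,
)
from synquant.morphology import NeuronSkeleton

from conftest import build_skeleton


class TestBranchOrders:
    def test_unbranched_apical_stem_is_one_first_order_segment(
        self, straight_apical_skeleton
    ):
        segs = compute_branch_orders(straight_apical_skeleton)
        assert len(segs) == 1
        assert segs[0].lineage == "apical"
        assert segs[0].order == 1
        # path starts at the attachment (soma anchor) node
        assert segs[0].arc_length == pytest.approx(6.5)

    def test_symmetric_binary_tree_orders(self):
        # stem bifurcates twice symmetrically: orders {1, 2, 2, 3, 3, 3, 3}
        nodes = [
            (1, (5.0, 5.0, 5.0), 2.0, -1, "soma"),
            (2, (5.0, 7.0, 5.0), 0.4, 1, "soma"),
            (3, (5.0, 10.0, 5.0), 0.4, 2, "apical"),  # 1deg, branch point
            (4, (5.0, 12.0, 3.0), 0.4, 3, "apical"),  # 2deg a, branch point
            (5, (5.0, 12.0, 7.0), 0.4, 3, "apical"),  # 2deg b, branch point
            (6, (5.0, 14.0, 2.0), 0.4, 4, "apical"),
            (7, (5.0, 14.0, 4.0), 0.4, 4, "apical"),
            (8, (5.0, 14.0, 6.0), 0.4, 5, "apical"),
            (9, (5.0, 14.0, 8.0), 0.4, 5, "apical"),
        ]
        segs = compute_branch_orders(build_skeleton(nodes))
        orders = sorted(s.order for s in segs)
        assert orders == [1, 2, 2, 3, 3, 3, 3]
        assert all(s.lineage == "apical" for s in segs)

    def test_three_bifurcating_basal_stems(self):
        nodes = [(1, (8.0, 8.0, 8.0), 2.0, -1, "soma")]
        nid = 2
        for k, dx in enumerate([-3.0, 0.0, 3.0]):
            anchor = nid
            nodes.append((anchor, (8.0, 5.5, 8.0 + dx), 0.4, 1, "soma"))
            stem = nid + 1
            nodes.append((stem, (8.0, 3.0, 8.0 + dx), 0.4, anchor, "basal"))
            nodes.append((nid + 2, (8.0, 1.0, 7.0 + dx), 0.4, stem, "basal"))
            nodes.append((nid + 3, (8.0, 1.0, 9.0 + dx), 0.4, stem, "basal"))
            nid += 4
        segs = compute_branch_orders(build_skeleton(nodes))
        from collections import Counter

        c = Counter((s.lineage, s.order) for s in segs)
        assert c == {("basal", 1): 3, ("basal", 2): 6}

    def test_arc_length_conservation(self):
        sk = make_pyramidal_skeleton()
        segs = compute_branch_orders(sk)
        assert sum(s.arc_length for s in segs) == pytest.approx(
            sk.total_dendritic_length()
        )

    def test_invariant_under_reindexing_and_rotation(self):
        sk = make_pyramidal_skeleton()
        ref = sorted(
            (s.lineage, s.order, round(s.arc_length, 6))
            for s in compute_branch_orders(sk)
        )
        # re-index: reverse ids
        new_ids = sk.node_ids[::-1].copy()
        remap = dict(zip(sk.node_ids.tolist(), new_ids.tolist()))
        parents = np.array(
            [remap[p] if p != -1 else -1 for p in sk.parents.tolist()]
        )
        # rigid rotation of the lateral plane by 30 degrees about the z axis
        th = np.deg2rad(30)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
        )
        center = sk.positions.mean(axis=0)
        pos = (sk.positions - center) @ rot.T + center
        sk2 = NeuronSkeleton(new_ids, pos, sk.radii, parents, sk.compartments)
        out = sorted(
            (s.lineage, s.order, round(s.arc_length, 6))
            for s in compute_branch_orders(sk2)
        )
        assert out == ref

    def test_disconnected_skeleton_rejected(self):
        with pytest.raises(ValueError, match="root"):
            build_skeleton(
                [
                    (1, (1.0, 1.0, 1.0), 1.0, -1, "soma"),
                    (2, (5.0, 5.0, 5.0), 1.0, -1, "apical"),
                ]
            )

    def test_unknown_compartment_tag_rejected(self):
        with pytest.raises(ValueError, match="compartment"):
            build_skeleton([(1, (1.0, 1.0, 1.0), 1.0, -1, "axon")])


class TestArcLength:
    @pytest.mark.parametrize(
        "path,expected",
        [
            ([(0, 0, 0), (0, 0, 5.0)], 5.0),
            ([(0, 0, 0), (3.0, 0, 0), (3.0, 4.0, 0)], 7.0),  # 3-4-5 geometry
        ],
    )
    def test_known_polylines(self, path, expected):
        assert segment_arc_length(np.array(path, float)) == pytest.approx(expected)

    def test_matches_pairwise_sum_oracle(self):
        rng = np.random.default_rng(42)
        path = rng.uniform(0, 30, size=(100, 3))
        oracle = sum(
            float(np.linalg.norm(path[i + 1] - path[i])) for i in range(99)
        )
        assert segment_arc_length(path) == pytest.approx(oracle, abs=1e-9)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            segment_arc_length(np.array([[1.0, 2.0, 3.0]]))

    @given(
        st.integers(2, 20),
        st.integers(2, 20),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=25, deadline=None)
    def test_additive_under_concatenation(self, n1, n2, rnd):
        rng = np.random.default_rng(rnd.randint(0, 2**31))
        a = rng.uniform(0, 10, size=(n1, 3))
        b = rng.uniform(0, 10, size=(n2, 3))
        whole = np.vstack([a, b])
        split_sum = (
            segment_arc_length(whole[: n1 + 1])
            + segment_arc_length(whole[n1 - 1 + 1 :])
            if n2 >= 2
            else 0
        )
        assert segment_arc_length(whole) == pytest.approx(split_sum)


class TestRasterize:
    def test_sphere_volume_matches_analytic(self):
        grid = VoxelGridSpec(shape=(64, 128, 128))
        r = 5.0
        sk = build_skeleton([(1, (10.24, 8.0, 8.0), r, -1, "soma")])
        mask = rasterize_cell(sk, grid)
        vol = mask.sum() * grid.voxel_volume
        assert vol == pytest.approx(4 / 3 * np.pi * r**3, rel=0.10)

    def test_empty_skeleton_rejected(self):
        with pytest.raises(ValueError, match="no nodes"):
            NeuronSkeleton(
                node_ids=np.zeros(0, int),
                positions=np.zeros((0, 3)),
                radii=np.zeros(0),
                parents=np.zeros(0, int),
                compartments=np.array([], dtype=object),
            )

    def test_out_of_grid_node_reported(self, small_grid):
        sk = build_skeleton([(1, (50.0, 1.0, 1.0), 1.0, -1, "soma")])
        with pytest.raises(ValueError, match=r"outside grid.*\[1\]"):
            rasterize_cell(sk, small_grid)

    def test_thin_dendrite_covers_path(self):
        grid = VoxelGridSpec(shape=(32, 64, 64))
        sk = build_skeleton(
            [
                (1, (5.0, 2.0, 4.0), 1.0, -1, "soma"),
                (2, (5.0, 3.5, 4.0), 0.5, 1, "soma"),
                (3, (5.0, 7.0, 4.5), 0.5, 2, "apical"),
                (4, (4.5, 7.5, 7.0), 0.5, 3, "apical"),
            ]
        )
        mask = rasterize_cell(sk, grid)
        # every skeleton node voxel inside the mask, and the path tube is
        # at least one voxel thick everywhere along sampled points
        for p0, p1 in [(sk.positions[2], sk.positions[3])]:
            for t in np.linspace(0, 1, 25):
                idx = grid.point_to_index((p0 + t * (p1 - p0))[None, :])[0]
                assert mask[tuple(idx)]
        for pos in sk.positions:
            assert mask[tuple(grid.point_to_index(pos[None, :])[0])]

    def test_volume_error_shrinks_with_voxel_size(self):
        # counting voxel centres is unbiased, so average the error over a
        # few off-lattice sphere centres to expose the convergence trend
        r = 4.0
        true_vol = 4 / 3 * np.pi * r**3
        centers = [
            (10.0, 8.0, 8.0),
            (10.11, 8.04, 7.93),
            (9.87, 8.21, 8.17),
            (10.05, 7.88, 8.09),
        ]
        errs = []
        for f in (1.0, 0.5):
            vs = (0.32 * f, 0.13 * f, 0.13 * f)
            grid = VoxelGridSpec(
                shape=(int(64 / f), int(128 / f), int(128 / f)), voxel_size=vs
            )
            tot = 0.0
            for c in centers:
                sk = build_skeleton([(1, c, r, -1, "soma")])
                vol = rasterize_cell(sk, grid).sum() * grid.voxel_volume
                tot += abs(vol - true_vol)
            errs.append(tot / len(centers))
        assert errs[1] < errs[0]


class TestSurfaceArea:
    def test_sphere_area_matches_analytic(self):
        grid = VoxelGridSpec(shape=(64, 128, 128))
        r = 5.0
        sk = build_skeleton([(1, (10.24, 8.0, 8.0), r, -1, "soma")])
        mask = rasterize_cell(sk, grid)
        area = soma_surface_area(mask, grid)
        assert area == pytest.approx(4 * np.pi * r**2, rel=0.15)

    def test_single_voxel_face_count(self, small_grid):
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[5, 5, 5] = True
        dz, dy, dx = small_grid.voxel_size
        expected = 2 * (dy * dx + dz * dx + dz * dy)
        assert soma_surface_area(mask, small_grid) == pytest.approx(expected)

    def test_empty_mask_rejected(self, small_grid):
        with pytest.raises(ValueError):
            soma_surface_area(np.zeros(small_grid.shape, bool), small_grid)

    def test_resolution_consistency(self):
        r = 5.0
        areas = []
        for f in (1.0, 2.0):
            vs = (0.32 * f, 0.13 * f, 0.13 * f)
            grid = VoxelGridSpec(
                shape=(int(64 / f), int(128 / f), int(128 / f)), voxel_size=vs
            )
            sk = build_skeleton([(1, (10.0, 8.0, 8.0), r, -1, "soma")])
            mask = rasterize_cell(sk, grid)
            areas.append(soma_surface_area(mask, grid))
        assert abs(areas[1] - areas[0]) / areas[0] < 0.20


class TestSWC:
    def test_round_trip(self, tmp_path):
        sk = make_pyramidal_skeleton()
        path = tmp_path / "cell.swc"
        write_swc(sk, path)
        back = read_swc(path)
        assert np.array_equal(back.node_ids, sk.node_ids)
        assert np.allclose(back.positions, sk.positions, atol=1e-5)
        assert np.allclose(back.radii, sk.radii, atol=1e-5)
        assert np.array_equal(back.parents, sk.parents)
        assert list(back.compartments) == list(sk.compartments)

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 1\n")
        with pytest.raises(ValueError, match="malformed"):
            read_swc(p)

    def test_unsupported_type_code_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 2 0 0 0 1 -1\n")  # type 2 = axon, unsupported
        with pytest.raises(ValueError, match="type code"):
            read_swc(p)
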