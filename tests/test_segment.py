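"""Puncta detection, split-touching, cell surface and neurite segmentation."""

import numpy as np
import pytest
from scipy import ndimage

from synquant import (
    SceneParams,
    VoxelChannel,
    VoxelGridSpec,
    build_cell_surface,
    detect_puncta,
    make_pyramidal_skeleton,
    puncta_to_spots,
    rasterize_cell,
    reconstruct_neurites,
    render_channels,
    sample_scene,
    split_touching,
)
from synquant.simulate import _add_gaussian_blob

from conftest import build_skeleton


def blob_channel(grid, positions, amplitudes=None, sigma=0.15, background=0.0,
                 role="puncta"):
    data = np.full(grid.shape, float(background))
    amplitudes = amplitudes or [1.0] * len(positions)
    for pos, amp in zip(positions, amplitudes):
        _add_gaussian_blob(data, grid, np.asarray(pos, float), amp, sigma)
    return VoxelChannel(data=data, grid=grid, role=role)


def speck_channel(grid, speck_voxels, role="puncta"):
    """Channel whose only signal is hand-placed bright voxels."""
    data = np.zeros(grid.shape)
    for vox_list in speck_voxels:
        for v in vox_list:
            data[tuple(v)] = 1.0
    return VoxelChannel(data=data, grid=grid, role=role)


class TestDetectPuncta:
    def test_size_filter_strictly_greater_than_three(self, small_grid):
        # 3-voxel component discarded, 4-voxel component retained
        three = [(5, 5, 5), (5, 5, 6), (5, 6, 5)]
        four = [(20, 20, 20), (20, 20, 21), (20, 21, 20), (20, 21, 21)]
        ch = speck_channel(small_grid, [three, four])
        puncta = detect_puncta(ch, min_voxels=3)
        assert len(puncta) == 1
        assert len(puncta[0].voxels) == 4

    def test_all_zero_channel_gives_empty_list(self, small_grid):
        ch = VoxelChannel(np.zeros(small_grid.shape), small_grid, "puncta")
        assert detect_puncta(ch) == []

    def test_wrong_role_rejected(self, small_grid):
        ch = VoxelChannel(np.zeros(small_grid.shape), small_grid, "cellfill")
        with pytest.raises(ValueError, match="puncta/marker"):
            detect_puncta(ch)

    def test_merged_blob_pair_split_into_two(self):
        # two blobs 1.0 um apart laterally merge under the threshold but
        # carry two >=0.5-um-separated maxima -> 2 puncta
        grid = VoxelGridSpec(shape=(16, 64, 64))
        a = (2.5, 4.0, 3.5)
        b = (2.5, 4.0, 4.5)
        ch = blob_channel(grid, [a, b], sigma=0.22)
        puncta = detect_puncta(ch)
        assert len(puncta) == 2
        got = sorted(p.centroid[2] for p in puncta)
        assert got[0] == pytest.approx(3.5, abs=0.15)
        assert got[1] == pytest.approx(4.5, abs=0.15)

    def test_translation_equivariance(self):
        grid = VoxelGridSpec(shape=(24, 64, 64))
        pts = [(3.0, 3.0, 3.0), (4.0, 6.0, 5.0), (2.5, 5.0, 2.0)]
        ch = blob_channel(grid, pts)
        base = sorted(tuple(p.centroid) for p in detect_puncta(ch))
        shift_vox = np.array([2, 5, 7])
        shifted = np.zeros(grid.shape)
        shifted[2:, 5:, 7:] = ch.data[:-2, :-5, :-7]
        ch2 = VoxelChannel(shifted, grid, "puncta")
        moved = sorted(tuple(p.centroid) for p in detect_puncta(ch2))
        delta = shift_vox * np.array(grid.voxel_size)
        assert len(base) == len(moved)
        for c0, c1 in zip(base, moved):
            assert np.allclose(np.array(c1) - np.array(c0), delta, atol=1e-9)

    def test_no_retained_punctum_at_or_below_min_voxels(self):
        grid = VoxelGridSpec(shape=(24, 64, 64))
        rng = np.random.default_rng(8)
        pts = [
            (rng.uniform(2, 5), rng.uniform(2, 6), rng.uniform(2, 6))
            for _ in range(15)
        ]
        data = blob_channel(grid, pts).data + rng.normal(0, 0.01, grid.shape)
        ch = VoxelChannel(np.clip(data, 0, None), grid, "puncta")
        for p in detect_puncta(ch, min_voxels=3):
            assert len(p.voxels) > 3
            assert p.volume > 3 * grid.voxel_volume


class TestSplitTouching:
    def test_single_blob_not_oversplit(self):
        grid = VoxelGridSpec(shape=(16, 48, 48))
        ch = blob_channel(grid, [(2.5, 3.0, 3.0)], sigma=0.2)
        fg = ch.data > 0.1
        comp = np.argwhere(fg)
        parts = split_touching(comp, ch.data[tuple(comp.T)], grid, 0.5)
        assert len(parts) == 1

    def test_dumbbell_splits_into_near_equal_halves(self):
        grid = VoxelGridSpec(shape=(16, 48, 48))
        ch = blob_channel(grid, [(2.5, 3.0, 2.6), (2.5, 3.0, 3.4)], sigma=0.18)
        fg = ch.data > 0.05
        comp = np.argwhere(fg)
        assert ndimage.label(fg)[1] == 1  # genuinely merged
        parts = split_touching(comp, ch.data[tuple(comp.T)], grid, 0.5)
        assert len(parts) == 2
        sizes = sorted(len(p) for p in parts)
        assert sizes[1] / sizes[0] <= 1.5
        assert sum(sizes) == len(comp)  # partition conservation

    def test_sub_diameter_maxima_merge(self):
        # two maxima 0.3 um apart (< 0.5 um split diameter) stay one part
        grid = VoxelGridSpec(shape=(16, 48, 48))
        ch = blob_channel(grid, [(2.5, 3.0, 2.85), (2.5, 3.0, 3.15)], sigma=0.12)
        fg = ch.data > 0.05
        comp = np.argwhere(fg)
        parts = split_touching(comp, ch.data[tuple(comp.T)], grid, 0.5)
        assert len(parts) == 1


class TestSpots:
    def test_empty_input_empty_output(self):
        assert puncta_to_spots([]) == []

    def test_symmetric_blob_spot_at_center(self):
        grid = VoxelGridSpec(shape=(16, 48, 48))
        pos = (2.56, 3.12, 3.12)  # on-lattice center
        ch = blob_channel(grid, [pos])
        spots = puncta_to_spots(detect_puncta(ch))
        assert len(spots) == 1
        assert np.all(
            np.abs(spots[0].centroid - np.array(pos)) <= np.array(grid.voxel_size)
        )
        assert spots[0].radius == 0.25

    def test_centroid_matches_brute_force_weighted_mean(self):
        grid = VoxelGridSpec(shape=(16, 48, 48))
        ch = blob_channel(
            grid, [(2.5, 3.0, 3.0), (2.5, 3.0, 3.6)], amplitudes=[1.0, 0.4]
        )
        puncta = detect_puncta(ch)
        for p in puncta:
            num = np.zeros(3)
            den = 0.0
            for v in p.voxels:
                w = ch.data[tuple(v)]
                c = (np.asarray(v) + 0.5) * np.asarray(grid.voxel_size)
                num += w * c
                den += w
            assert np.allclose(p.centroid, num / den, atol=1e-6)


class TestCellSurface:
    def test_simulator_round_trip_mask_recovery(self):
        grid = VoxelGridSpec(shape=(48, 160, 160))
        sk = make_pyramidal_skeleton(
            extent=tuple(grid.extent),
            soma_radius=3.0,
            apical_lengths=(3.0, 2.5),
            basal_lengths=(2.5, 2.0),
            soma_frac_y=0.45,
        )
        p = SceneParams(
            dendrite_density=0, soma_density=0, n_distractors=0,
            photon_scale=None, read_noise=0.0, psf_sigma=(0.0, 0.0, 0.0),
        )
        truth = sample_scene(sk, p)
        cellfill = [c for c in render_channels(truth, grid) if c.role == "cellfill"][0]
        surf = build_cell_surface(cellfill, soma_hint=sk.soma_center)
        true_mask = rasterize_cell(sk, grid)
        covered = (surf.mask & true_mask).sum() / true_mask.sum()
        assert covered >= 0.99
        assert surf.soma_mask.any() and surf.dendrite_mask.any()
        assert surf.soma_radius == pytest.approx(3.0, abs=0.4)

    def test_signed_distance_outside_flat_face(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[4:28, 4:20, 4:28] = 1.0  # box with a flat face at y index 20
        surf = build_cell_surface(VoxelChannel(data, small_grid, "cellfill"))
        dy = small_grid.voxel_size[1]
        # voxel 8 voxels beyond the last mask voxel ~ 1.04 um outside
        probe = (16, 19 + 8, 16)
        half_diag = 0.5 * np.linalg.norm(small_grid.voxel_size)
        assert abs(surf.sdf[probe] - 8 * dy) <= half_diag
        # inside: strictly negative away from the shell, zero on the shell
        assert surf.sdf[16, 12, 16] < 0
        assert surf.sdf[16, 19, 16] == 0.0

    def test_featureless_channel_rejected(self, small_grid):
        ch = VoxelChannel(np.zeros(small_grid.shape), small_grid, "cellfill")
        with pytest.raises(ValueError):
            build_cell_surface(ch)


class TestNeurites:
    def _tube_channel(self, grid, z_gain=None, radius=0.3):
        from synquant.simulate import TrueNeurite, _rasterize_tubes

        path = np.array([[3.2, 4.0, 1.0], [3.2, 4.0, 11.0]])
        tube = TrueNeurite(0, "PV", path, radius, False, None)
        data = _rasterize_tubes([tube], grid).astype(float)
        if z_gain is not None:
            nz = grid.shape[0]
            gain = z_gain(np.arange(nz))
            data *= gain[:, None, None]
        return VoxelChannel(data, grid, "presyn:PV")

    def test_min_voxel_filter_at_six(self, small_grid):
        five = [(5, 5, 5), (5, 5, 6), (5, 6, 5), (5, 6, 6), (5, 5, 7)]
        six = [(20, 20, 20 + i) for i in range(5)] + [(20, 21, 20)]
        ch = speck_channel(small_grid, [five, six], role="presyn:PV")
        objs = reconstruct_neurites(ch, min_voxels=6)
        assert len(objs) == 1
        assert len(objs[0].voxels) == 6
        assert objs[0].cell_type == "PV"

    def test_empty_channel_gives_empty_list(self, small_grid):
        ch = VoxelChannel(np.zeros(small_grid.shape), small_grid, "presyn:SST")
        assert reconstruct_neurites(ch) == []

    def test_z_blocks_handle_axial_falloff(self):
        grid = VoxelGridSpec(shape=(20, 48, 96))
        ch = self._tube_channel(
            grid, z_gain=lambda z: 1.2 - 0.8 * z / grid.shape[0]
        )
        objs = reconstruct_neurites(ch, z_blocks=2)
        tags = {o.z_block for o in objs}
        assert tags == {"superficial", "deep"}

        def mean_radius(objs_in_block):
            vox = np.vstack([o.voxels for o in objs_in_block])
            # cross-section area per unit length -> effective radius
            length_um = np.ptp(vox[:, 2]) * grid.voxel_size[2]
            area = len(vox) * grid.voxel_volume / max(length_um, 1e-9)
            return np.sqrt(area / np.pi)

        r_sup = mean_radius([o for o in objs if o.z_block == "superficial"])
        r_deep = mean_radius([o for o in objs if o.z_block == "deep"])
        assert abs(r_sup - r_deep) / max(r_sup, r_deep) < 0.30

    def test_z_blocks_exceeding_depth_rejected(self, small_grid):
        ch = VoxelChannel(np.zeros(small_grid.shape), small_grid, "presyn:PV")
        with pytest.raises(ValueError, match="z_blocks"):
            reconstruct_neurites(ch, z_blocks=64)

    def test_surface_voxels_subset_with_background_neighbor(self):
        grid = VoxelGridSpec(shape=(20, 48, 96))
        objs = reconstruct_neurites(self._tube_channel(grid))
        assert objs
        for o in objs:
            all_vox = {tuple(v) for v in o.voxels}
            surf = {tuple(v) for v in o.surface_voxels}
            assert surf <= all_vox
            for v in list(surf)[:50]:
                neighbors = [
                    (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                    for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                              (0, -1, 0), (0, 0, 1), (0, 0, -1)]
                ]
                assert any(nb not in all_vox for nb in neighbors)
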