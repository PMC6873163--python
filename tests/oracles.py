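"""Brute-force reference implementations for distance decisions.

These recompute every membrane / input / marker decision by explicit
all-pairs scans over voxel centres, independently of the EDT- and
KD-tree-based implementation paths they validate.
"""

import numpy as np

from synquant.assign import AssignmentParams


def brute_punctum_status(punctum_voxels, surface, params: AssignmentParams):
    """Membrane status by explicit scans over submask voxel centres."""
    grid = surface.grid
    vox = np.asarray(punctum_voxels)
    centers = grid.voxel_centers(vox)

    def min_dist_to(mask_voxels):
        if len(mask_voxels) == 0:
            return np.inf
        pts = grid.voxel_centers(mask_voxels)
        d = np.linalg.norm(centers[:, None, :] - pts[None, :, :], axis=2)
        return float(d.min())

    # signed depth per voxel, recomputed from scratch: positive outside
    # (distance to the mask), zero on the shell, negative inside
    # (distance to the nearest non-interior voxel)
    from scipy import ndimage

    mask = surface.mask
    shell = mask & ~ndimage.binary_erosion(mask)
    interior = mask & ~shell
    mask_vox = np.argwhere(mask)
    noninterior_vox = np.argwhere(~interior)
    sdf_vals = []
    for v, c in zip(vox, centers):
        if not mask[tuple(v)]:
            pts = grid.voxel_centers(mask_vox)
            sdf_vals.append(float(np.linalg.norm(pts - c, axis=1).min()))
        elif shell[tuple(v)]:
            sdf_vals.append(0.0)
        else:
            pts = grid.voxel_centers(noninterior_vox)
            sdf_vals.append(-float(np.linalg.norm(pts - c, axis=1).min()))
    if np.all(np.asarray(sdf_vals) < -params.cytosolic_depth):
        return "cytosolic"
    soma_vox = np.argwhere(surface.soma_mask)
    dend_vox = np.argwhere(surface.dendrite_mask)
    in_soma = surface.soma_mask[tuple(vox.T)]
    d_soma = 0.0 if in_soma.any() else min_dist_to(soma_vox)
    if d_soma <= params.soma_edge:
        return "somatic"
    in_dend = surface.dendrite_mask[tuple(vox.T)]
    d_dend = 0.0 if in_dend.any() else min_dist_to(dend_vox)
    if d_dend < params.dendrite_edge:
        return "dendritic"
    return "unassociated"


def brute_input_label(centroid, neurites, grid, threshold):
    """(label, distance, ambiguous) by scanning every surface voxel.

    Distances go to the voxel's physical extent (axis-aligned box),
    computed here per voxel without any spatial index.
    """
    vs = np.asarray(grid.voxel_size)
    origin = np.asarray(grid.origin)
    p = np.asarray(centroid, dtype=float)
    best: dict[str, float] = {}
    for n in neurites:
        if len(n.surface_voxels) == 0:
            continue
        dmin = np.inf
        for v in n.surface_voxels:
            lo = origin + np.asarray(v) * vs
            hi = lo + vs
            gap = np.maximum(np.maximum(lo - p, p - hi), 0.0)
            dmin = min(dmin, float(np.sqrt((gap**2).sum())))
        d = dmin
        if n.cell_type not in best or d < best[n.cell_type]:
            best[n.cell_type] = d
    if not best:
        return None, None, False
    dmin = min(best.values())
    if dmin > threshold:
        return None, None, False
    winners = sorted(t for t, d in best.items() if d == dmin)
    return winners[0], dmin, len(winners) > 1


def brute_marker_aligned(centroid, reference_points, threshold):
    if len(reference_points) == 0:
        return False
    d = np.linalg.norm(
        np.asarray(reference_points) - np.asarray(centroid), axis=1
    ).min()
    return bool(d < threshold)
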