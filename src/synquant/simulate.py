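"""Synthetic confocal synapse scenes with known ground truth.

The simulator emulates the imaging experiment the analysis pipeline is
built for: a sparsely labelled layer-2/3 pyramidal-like neuron (cytosolic
fill channel) decorated with postsynaptic puncta along its membrane at
per-compartment densities, presynaptic interneuron neurites (PV / SST /
VIP) routed through a controllable fraction of the true synapses plus
non-synaptic "passer-by" distractors near the soma, and an active-zone
marker channel co-localized with true release sites up to sub-voxel
jitter.  Rendering applies a separable anisotropic Gaussian PSF, Poisson
shot noise and additive Gaussian read noise.

Every random draw is derived from one master seed through per-stage
sub-streams, so a scene is fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import VoxelGridSpec, VoxelChannel
from .morphology import (
    CompartmentSegment,
    NeuronSkeleton,
    compute_branch_orders,
    rasterize_cell,
    _stamp_capsule,
)

INPUT_TYPES = ("PV", "SST", "VIP")


@dataclass
class SceneParams:
    """Generation parameters for one synthetic scene.

    Defaults reproduce the statistical structure of the tissue data the
    pipeline targets: mean dendritic puncta density 2.3 puncta/um,
    somatic density 0.35 puncta/um^2, and input fractions dominated by PV
    (25%) over SST (5%) and VIP (2%), the remainder unassigned.

    Parameters
    ----------
    dendrite_density : float
        Puncta per um of dendritic arc length.
    density_overrides : dict
        Optional per-segment-label densities, e.g. ``{"apical1": 5.0}``.
    soma_density : float
        Puncta per um^2 of soma surface.
    input_fractions : dict
        Fraction of synapses contacted by each presynaptic type; must sum
        to <= 1, remainder stays unassigned.
    min_separation : float
        Hard-core minimum 3D distance between synapse centres (um).
        Distinct ~0.5 um puncta cannot overlap, so centres keep at least
        ~0.7 um apart.
    spine_reach : tuple
        (min, max) radial offset (um) of a dendritic synapse beyond the
        shaft surface.  Spines are not modelled explicitly; puncta
        occupy this band of the 1 um capture radius instead, which is
        also what lets multiple puncta per micron coexist under the
        hard core.
    neurite_radius : float
        Presynaptic axon tube radius (um).
    n_distractors : int
        Non-synaptic neurites grazing the soma within the apposition
        range but carrying no synapse.
    marker_jitter, marker_miss_rate : float
        Gaussian sigma (um) of marker displacement from its parent
        synapse, and the fraction of synapses with no marker.
    emission_sigma : float
        Isotropic sigma (um) of a punctum's rendered emission blob.
    psf_sigma : tuple
        Anisotropic PSF sigma (z, y, x) in um.
    photon_scale : float or None
        Photons per intensity unit for shot noise; ``None`` disables
        Poisson noise (ideal detector).
    read_noise : float
        Additive Gaussian read-noise sigma (intensity units).
    background : float
        Uniform background level added to every channel before noise.
    amplitude_sigma : float
        Log-normal sigma of per-punctum amplitude heterogeneity.
    seed : int
        Master seed for all sub-streams.
    """

    dendrite_density: float = 2.3
    density_overrides: dict = field(default_factory=dict)
    soma_density: float = 0.35
    input_fractions: dict = field(
        default_factory=lambda: {"PV": 0.25, "SST": 0.05, "VIP": 0.02}
    )
    min_separation: float = 0.7
    spine_reach: tuple[float, float] = (0.05, 0.6)
    neurite_radius: float = 0.25
    neurite_length: float = 10.0
    contact_gap: float = 0.03
    n_distractors: int = 4
    distractor_gap: float = 0.05
    marker_jitter: float = 0.05
    marker_miss_rate: float = 0.15
    emission_sigma: float = 0.15
    psf_sigma: tuple[float, float, float] = (0.4, 0.1, 0.1)
    photon_scale: float | None = 300.0
    read_noise: float = 0.01
    background: float = 0.02
    amplitude_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dendrite_density < 0 or self.soma_density < 0:
            raise ValueError("densities must be >= 0")
        if any(v < 0 for v in self.input_fractions.values()):
            raise ValueError("input fractions must be >= 0")
        if sum(self.input_fractions.values()) > 1.0 + 1e-12:
            raise ValueError("input fractions must sum to <= 1")
        if self.marker_jitter < 0:
            raise ValueError("marker jitter must be >= 0")
        if not 0.0 <= self.marker_miss_rate <= 1.0:
            raise ValueError("marker miss rate must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["psf_sigma"] = list(self.psf_sigma)
        d["spine_reach"] = list(self.spine_reach)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        d = dict(d)
        for key in ("psf_sigma", "spine_reach"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TrueSynapse:
    id: int
    position: np.ndarray  # (3,) um, (z, y, x)
    input_type: str | None
    compartment: str  # segment label ("apical1", "basal2", ...) or "soma"
    segment_id: int  # -1 for soma
    on_soma: bool


@dataclass
class TrueMarker:
    id: int
    position: np.ndarray
    parent_synapse: int | None


@dataclass
class TrueNeurite:
    id: int
    cell_type: str
    path: np.ndarray  # (m, 3) um centerline
    radius: float
    is_distractor: bool
    contact_synapse: int | None


@dataclass
class GroundTruthScene:
    """Simulator ground truth: who synapses where, and with whom."""

    skeleton: NeuronSkeleton
    segments: list[CompartmentSegment]
    params: SceneParams
    synapses: list[TrueSynapse]
    markers: list[TrueMarker]
    neurites: list[TrueNeurite]

    def synapse_positions(self) -> np.ndarray:
        if not self.synapses:
            return np.zeros((0, 3))
        return np.array([s.position for s in self.synapses])

    def marker_positions(self) -> np.ndarray:
        if not self.markers:
            return np.zeros((0, 3))
        return np.array([m.position for m in self.markers])

    @property
    def input_types_present(self) -> list[str]:
        types = {n.cell_type for n in self.neurites}
        return [t for t in INPUT_TYPES if t in types]

    def to_tables(self) -> dict:
        """Truth as plain-python tables for JSON/CSV serialization."""
        return {
            "synapses": [
                {
                    "id": s.id,
                    "z": float(s.position[0]),
                    "y": float(s.position[1]),
                    "x": float(s.position[2]),
                    "input_type": s.input_type,
                    "compartment": s.compartment,
                    "segment_id": s.segment_id,
                    "on_soma": bool(s.on_soma),
                }
                for s in self.synapses
            ],
            "markers": [
                {
                    "id": m.id,
                    "z": float(m.position[0]),
                    "y": float(m.position[1]),
                    "x": float(m.position[2]),
                    "parent_synapse": m.parent_synapse,
                }
                for m in self.markers
            ],
            "neurites": [
                {
                    "id": n.id,
                    "cell_type": n.cell_type,
                    "radius": n.radius,
                    "is_distractor": bool(n.is_distractor),
                    "contact_synapse": n.contact_synapse,
                    "path": [[float(v) for v in p] for p in n.path],
                }
                for n in self.neurites
            ],
            "params": self.params.to_dict(),
        }

    def save_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_tables(), indent=1))


# -- skeleton factory ------------------------------------------------------


def _lat_dir(theta: float, z_tilt: float) -> np.ndarray:
    """Unit direction from a lateral angle (in the y-x plane) and a z tilt."""
    d = np.array([z_tilt, np.cos(theta), np.sin(theta)])
    return d / np.linalg.norm(d)


def make_pyramidal_skeleton(
    extent: tuple[float, float, float] = (20.48, 33.28, 33.28),
    soma_radius: float = 4.0,
    apical_lengths: tuple[float, ...] = (4.0, 3.5, 3.0, 2.5),
    basal_lengths: tuple[float, ...] = (3.5, 3.0, 2.5, 2.0),
    n_basal_stems: int = 3,
    deep_basal_stems: int = 1,
    dendrite_radius: float = 0.35,
    stem_radius: float = 0.45,
    stem_setback: float = 0.8,
    soma_frac_y: float = 0.42,
) -> NeuronSkeleton:
    """Deterministic branched pyramidal-like skeleton fitting ``extent``.

    One apical stem pointing pia-ward (+y) that bifurcates into 2deg-4deg
    branches, plus ``n_basal_stems`` basal stems of which
    ``deep_basal_stems`` branch down to 4deg.  Dendritic stems attach to
    soma-tagged anchor nodes placed ``stem_setback`` um beyond the soma
    sphere, so the ambiguous perisomatic collar carries no dendritic arc
    length.  Branch angles spread laterally with mild alternating z tilt
    so the arbour stays inside a typical confocal stack.
    """
    ez, ey, ex = extent
    center = np.array([ez / 2.0, ey * soma_frac_y, ex / 2.0])

    ids: list[int] = []
    pos: list[np.ndarray] = []
    rad: list[float] = []
    par: list[int] = []
    comp: list[str] = []

    def add(p, r, parent, c) -> int:
        nid = len(ids) + 1
        ids.append(nid)
        pos.append(np.asarray(p, dtype=float))
        rad.append(float(r))
        par.append(int(parent))
        comp.append(c)
        return nid

    root = add(center, soma_radius, -1, "soma")

    def grow(parent_id, start, direction, lengths, level, lineage, sign):
        """Recursively grow a binary subtree; returns nothing."""
        if level >= len(lengths):
            return
        end = start + direction * lengths[level]
        mid = add((start + end) / 2.0,
                  dendrite_radius if level > 0 else stem_radius,
                  parent_id, lineage)
        tip = add(end, dendrite_radius if level > 0 else stem_radius,
                  mid, lineage)
        if level + 1 < len(lengths):
            theta = np.arctan2(direction[2], direction[1])
            spread = np.deg2rad(38.0 - 6.0 * level)
            for k, s in enumerate((+1, -1)):
                z_tilt = 0.22 * sign * (1 if k == 0 else -1)
                child_dir = _lat_dir(theta + s * spread, z_tilt)
                grow(tip, end, child_dir, lengths, level + 1, lineage, -sign)

    # apical stem: straight up (+y)
    ap_dir = _lat_dir(0.0, 0.0)
    ap_anchor = center + ap_dir * (soma_radius + stem_setback)
    a = add(ap_anchor, stem_radius, root, "soma")
    grow(a, ap_anchor, ap_dir, apical_lengths, 0, "apical", +1)

    # basal stems: spread through the lower hemisphere, mild z tilt
    # lateral-ish stems first so deeper subtrees cannot curl out of the box
    thetas = np.deg2rad(np.array([130.0, 230.0, 180.0, 155.0, 205.0][:n_basal_stems]))
    tilts = [0.18, -0.18, 0.0, 0.12, -0.12][:n_basal_stems]
    for i, (th, tl) in enumerate(zip(thetas, tilts)):
        b_dir = _lat_dir(th, tl)
        b_anchor = center + b_dir * (soma_radius + stem_setback)
        b = add(b_anchor, stem_radius, root, "soma")
        lengths = basal_lengths if i < deep_basal_stems else basal_lengths[:2]
        grow(b, b_anchor, b_dir, lengths, 0, "basal", +1 if i % 2 == 0 else -1)

    skel = NeuronSkeleton(
        node_ids=np.array(ids),
        positions=np.array(pos),
        radii=np.array(rad),
        parents=np.array(par),
        compartments=np.array(comp, dtype=object),
    )
    lo = skel.positions.min(axis=0)
    hi = skel.positions.max(axis=0)
    if np.any(lo < 0) or np.any(hi > np.array(extent)):
        raise ValueError(
            f"skeleton exceeds extent {extent}: bounds {lo} .. {hi}"
        )
    return skel


# -- scene sampling --------------------------------------------------------


def _perp_basis(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(t, a)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def _segment_point(
    seg: CompartmentSegment, radii: np.ndarray, s: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Point, tangent and local radius at arc position ``s`` along a segment."""
    d = np.linalg.norm(np.diff(seg.path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(d)])
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(d) - 1)
    frac = (s - cum[i]) / d[i] if d[i] > 0 else 0.0
    point = seg.path[i] + frac * (seg.path[i + 1] - seg.path[i])
    tangent = (seg.path[i + 1] - seg.path[i]) / (d[i] if d[i] > 0 else 1.0)
    radius = radii[i] + frac * (radii[i + 1] - radii[i])
    return point, tangent, radius


class _HardCore:
    """Spatial-hash point set supporting minimum-distance queries."""

    def __init__(self, min_dist: float) -> None:
        self.min_dist = float(min_dist)
        self.cell = max(self.min_dist, 1e-9) / np.sqrt(3.0)
        self.buckets: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def ok(self, p: np.ndarray) -> bool:
        if self.min_dist <= 0:
            return True
        key = np.floor(p / self.cell).astype(int)
        for dz in (-2, -1, 0, 1, 2):
            for dy in (-2, -1, 0, 1, 2):
                for dx in (-2, -1, 0, 1, 2):
                    for q in self.buckets.get(
                        (key[0] + dz, key[1] + dy, key[2] + dx), ()
                    ):
                        if np.linalg.norm(p - q) < self.min_dist:
                            return False
        return True

    def add(self, p: np.ndarray) -> None:
        key = tuple(np.floor(p / self.cell).astype(int))
        self.buckets.setdefault(key, []).append(p)


def sample_scene(skeleton: NeuronSkeleton, params: SceneParams) -> GroundTruthScene:
    """Draw a ground-truth scene: synapses, input identities, neurites, markers.

    Dendritic synapse counts per segment are Poisson(density x arc length)
    and somatic counts Poisson(density x 4 pi r^2); positions sit on the
    membrane surface under a hard-core minimum separation.  Each typed
    synapse gets a presynaptic tube of its type routed through a contact
    point within the input-assignment range; distractor tubes graze the
    soma without a synapse.  Markers follow synapses with Gaussian jitter
    (truncated at 3 sigma) except a missed fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(0,)))
    segments = compute_branch_orders(skeleton)
    if not segments and params.dendrite_density > 0:
        raise ValueError("nonzero dendritic density but skeleton has no dendrites")

    soma_center = skeleton.soma_center
    soma_radius = skeleton.soma_radius
    node_radius = {int(i): float(r) for i, r in zip(skeleton.node_ids, skeleton.radii)}

    core = _HardCore(params.min_separation)
    synapses: list[TrueSynapse] = []

    def accept(p: np.ndarray, meta_fn) -> None:
        core.add(p)
        synapses.append(meta_fn(len(synapses), p))

    # somatic synapses on the soma sphere surface
    soma_area = 4.0 * np.pi * soma_radius**2
    n_soma = rng.poisson(params.soma_density * soma_area)
    placed = 0
    attempts = 0
    while placed < int(n_soma) and attempts < 400 * max(int(n_soma), 1):
        attempts += 1
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        p = soma_center + v * (soma_radius + 0.05)
        if core.ok(p):
            accept(p, lambda i, p: TrueSynapse(i, p, None, "soma", -1, True))
            placed += 1

    # dendritic synapses per segment; at the requested densities the
    # membrane ring is crowded, so each draw searches stratified angular
    # offsets around the ring for a free slot before resampling its arc
    # position — plain dart throwing jams well below the target density
    for seg in segments:
        radii = np.array([node_radius[i] for i in seg.node_ids])
        dens = params.density_overrides.get(seg.label, params.dendrite_density)
        n_seg = rng.poisson(dens * seg.arc_length)
        def place_at(s: float, phi: float, off: float, seg=seg, radii=radii) -> bool:
            point, tangent, radius = _segment_point(seg, radii, s)
            u, v = _perp_basis(tangent)
            normal = np.cos(phi) * u + np.sin(phi) * v
            p = point + normal * (radius + off)
            if core.ok(p):
                accept(
                    p,
                    lambda i, p, seg=seg: TrueSynapse(
                        i, p, None, seg.label, seg.segment_id, False
                    ),
                )
                return True
            return False

        lo_reach, hi_reach = params.spine_reach
        for _ in range(int(n_seg)):
            placed_here = False
            for _ in range(40):  # arc-position resamples
                s = rng.uniform(0.0, seg.arc_length)
                off = rng.uniform(lo_reach, hi_reach)
                phi0 = rng.uniform(0.0, 2.0 * np.pi)
                for k in range(24):  # stratified ring angles
                    if place_at(s, phi0 + 2.0 * np.pi * k / 24.0, off):
                        placed_here = True
                        break
                if placed_here:
                    break
            if not placed_here:
                # near jamming random search stalls; scan a fine
                # (arc, angle, reach) grid for any remaining free slot
                s_off = rng.uniform()
                phi_off = rng.uniform(0.0, 2.0 * np.pi)
                n_s = max(int(seg.arc_length / 0.1), 1)
                for si in range(n_s):
                    s = (si + s_off) / n_s * seg.arc_length
                    if any(
                        place_at(
                            s,
                            phi_off + 2.0 * np.pi * k / 12.0,
                            lo_reach + (hi_reach - lo_reach) * j / 3.0,
                        )
                        for j in range(4)
                        for k in range(12)
                    ):
                        placed_here = True
                        break

    # input identities
    fracs = [params.input_fractions.get(t, 0.0) for t in INPUT_TYPES]
    p_unassigned = max(0.0, 1.0 - sum(fracs))
    probs = np.array(fracs + [p_unassigned])
    for syn in synapses:
        k = rng.choice(len(probs), p=probs)
        syn.input_type = INPUT_TYPES[k] if k < len(INPUT_TYPES) else None

    # presynaptic tubes through typed synapses
    neurites: list[TrueNeurite] = []
    for syn in synapses:
        if syn.input_type is None:
            continue
        phi = rng.uniform(0.0, 2.0 * np.pi)
        offset = np.array([0.0, np.cos(phi), np.sin(phi)])  # lateral offset
        c = syn.position + offset * (params.neurite_radius + params.contact_gap)
        d = np.array([0.0, -np.sin(phi), np.cos(phi)])  # lateral, perp to offset
        d = d + np.array([rng.uniform(-0.15, 0.15), 0.0, 0.0])
        d /= np.linalg.norm(d)
        path = _wobbly_tube_path(c, d, params.neurite_length, rng)
        neurites.append(
            TrueNeurite(
                id=len(neurites),
                cell_type=syn.input_type,
                path=path,
                radius=params.neurite_radius,
                is_distractor=False,
                contact_synapse=syn.id,
            )
        )

    # distractor passers-by grazing the soma
    active_types = [t for t, f in params.input_fractions.items() if f > 0]
    if params.n_distractors > 0 and not active_types:
        active_types = ["PV"]
    for j in range(params.n_distractors):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        offset = np.array([0.0, np.cos(phi), np.sin(phi)])
        c = soma_center + offset * (
            soma_radius + params.neurite_radius + params.distractor_gap
        )
        d = np.array([0.0, -np.sin(phi), np.cos(phi)])
        path = _wobbly_tube_path(c, d, params.neurite_length, rng, wobble=0.1)
        neurites.append(
            TrueNeurite(
                id=len(neurites),
                cell_type=active_types[j % len(active_types)],
                path=path,
                radius=params.neurite_radius,
                is_distractor=True,
                contact_synapse=None,
            )
        )

    # markers: jittered copies of synapses, minus a missed fraction
    markers: list[TrueMarker] = []
    for syn in synapses:
        if rng.uniform() < params.marker_miss_rate:
            continue
        while True:
            jitter = (
                rng.normal(0.0, params.marker_jitter, size=3)
                if params.marker_jitter > 0
                else np.zeros(3)
            )
            if np.linalg.norm(jitter) <= 3.0 * params.marker_jitter + 1e-12:
                break
        markers.append(
            TrueMarker(id=len(markers), position=syn.position + jitter,
                       parent_synapse=syn.id)
        )

    return GroundTruthScene(
        skeleton=skeleton,
        segments=segments,
        params=params,
        synapses=synapses,
        markers=markers,
        neurites=neurites,
    )


def _wobbly_tube_path(
    center: np.ndarray,
    direction: np.ndarray,
    length: float,
    rng: np.random.Generator,
    wobble: float = 0.25,
    n_ctrl: int = 5,
) -> np.ndarray:
    """Near-straight tube centerline through ``center``: straight run with
    small perpendicular perturbations away from the contact point."""
    ts = np.linspace(-length / 2.0, length / 2.0, n_ctrl)
    u, v = _perp_basis(direction)
    pts = []
    for t in ts:
        p = center + direction * t
        if abs(t) > 1e-9:  # keep the contact point exact
            amp = wobble * abs(t) / (length / 2.0)
            p = p + u * rng.uniform(-amp, amp) + v * rng.uniform(-amp, amp)
        pts.append(p)
    return np.array(pts)


# -- rendering -------------------------------------------------------------


def _add_gaussian_blob(
    data: np.ndarray,
    grid: VoxelGridSpec,
    position: np.ndarray,
    amplitude: float,
    sigma: float,
) -> None:
    vs = np.asarray(grid.voxel_size)
    origin = np.asarray(grid.origin)
    lo = position - 4.0 * sigma
    hi = position + 4.0 * sigma
    i0 = np.maximum(np.floor((lo - origin) / vs - 0.5).astype(int), 0)
    i1 = np.minimum(
        np.ceil((hi - origin) / vs + 0.5).astype(int) + 1, np.asarray(grid.shape)
    )
    if np.any(i0 >= i1):
        return
    axes = [origin[a] + (np.arange(i0[a], i1[a]) + 0.5) * vs[a] for a in range(3)]
    sq = [((ax - position[a]) / sigma) ** 2 for a, ax in enumerate(axes)]
    blob = amplitude * np.exp(
        -0.5 * (sq[0][:, None, None] + sq[1][None, :, None] + sq[2][None, None, :])
    )
    data[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] += blob


def _rasterize_tubes(
    neurites: list[TrueNeurite], grid: VoxelGridSpec
) -> np.ndarray:
    mask = np.zeros(grid.shape, dtype=bool)
    for n in neurites:
        for a, b in zip(n.path[:-1], n.path[1:]):
            _stamp_capsule(mask, grid, a, b, n.radius, n.radius)
    return mask


def render_channels(
    truth: GroundTruthScene, grid: VoxelGridSpec
) -> list[VoxelChannel]:
    """Render a truth scene into noisy multi-channel stacks.

    Returns cellfill, puncta, one ``presyn:<type>`` channel per input type
    present, and the marker channel.  With ``photon_scale=None`` and
    ``read_noise=0`` the render is fully deterministic.
    """
    p = truth.params
    rng = np.random.default_rng(np.random.SeedSequence(p.seed, spawn_key=(1,)))

    signals: list[tuple[str, np.ndarray]] = []
    cellfill = rasterize_cell(truth.skeleton, grid).astype(np.float64)
    signals.append(("cellfill", cellfill))

    puncta = np.zeros(grid.shape)
    for syn in truth.synapses:
        amp = (
            float(rng.lognormal(0.0, p.amplitude_sigma))
            if p.amplitude_sigma > 0
            else 1.0
        )
        _add_gaussian_blob(puncta, grid, syn.position, amp, p.emission_sigma)
    signals.append(("puncta", puncta))

    for t in truth.input_types_present:
        tubes = [n for n in truth.neurites if n.cell_type == t]
        signals.append((f"presyn:{t}", _rasterize_tubes(tubes, grid).astype(float)))

    marker = np.zeros(grid.shape)
    for m in truth.markers:
        amp = (
            float(rng.lognormal(0.0, p.amplitude_sigma))
            if p.amplitude_sigma > 0
            else 1.0
        )
        _add_gaussian_blob(marker, grid, m.position, amp, p.emission_sigma)
    signals.append(("marker", marker))

    vs = np.asarray(grid.voxel_size)
    psf_vox = np.asarray(p.psf_sigma) / vs
    channels = []
    for role, img in signals:
        img = img + p.background
        if np.any(psf_vox > 0):
            img = ndimage.gaussian_filter(img, sigma=psf_vox)
        if p.photon_scale is not None and np.isfinite(p.photon_scale):
            img = rng.poisson(np.clip(img, 0, None) * p.photon_scale) / p.photon_scale
        if p.read_noise > 0:
            img = img + rng.normal(0.0, p.read_noise, size=img.shape)
        img = np.clip(img, 0.0, None)
        channels.append(VoxelChannel(data=img, grid=grid, role=role))
    return channels
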