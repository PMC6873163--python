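"""End-to-end orchestration: simulate -> segment -> assign -> quantify.

A :class:`PipelineConfig` captures everything a run needs — grid,
scene-generation parameters, segmentation knobs, assignment thresholds,
seed and paths — and round-trips losslessly through YAML.  Every run
writes its resolved config next to its outputs together with a
structured log of per-stage counts, so a run can be reproduced and
diagnosed without the images.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assign import (
    AssignmentParams,
    PunctumAssignment,
    align_marker,
    assign_inputs,
    assign_puncta_to_cell,
    contact_counts,
)
from .grid import VoxelGridSpec, VoxelChannel
from .io import write_json, write_stack, write_table
from .morphology import read_swc, soma_surface_area
from .quantify import (
    DensityReport,
    branch_order_density,
    evaluate_detection,
    input_proportions,
    soma_density,
)
from .segment import (
    build_cell_surface,
    detect_puncta,
    puncta_to_spots,
    reconstruct_neurites,
)
from .simulate import (
    GroundTruthScene,
    SceneParams,
    make_pyramidal_skeleton,
    render_channels,
    sample_scene,
)


@dataclass
class SegmentationParams:
    """Knobs of the detection stage (voxel counts, split diameters in um)."""

    puncta_min_voxels: int = 3
    puncta_split_diameter: float = 0.5
    neurite_min_voxels: int = 6
    neurite_split_diameter: float = 1.0
    z_blocks: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineConfig:
    """Complete, serializable description of one pipeline run."""

    grid: VoxelGridSpec = field(
        default_factory=lambda: VoxelGridSpec(shape=(64, 256, 256))
    )
    scene: SceneParams = field(default_factory=SceneParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    assignment: AssignmentParams = field(default_factory=AssignmentParams)
    swc_path: str | None = None  # skeleton source; None -> built-in pyramidal
    simulate: bool = True
    write_stacks: bool = False
    skeleton_kwargs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "scene": self.scene.to_dict(),
            "segmentation": self.segmentation.to_dict(),
            "assignment": self.assignment.to_dict(),
            "swc_path": self.swc_path,
            "simulate": self.simulate,
            "write_stacks": self.write_stacks,
            "skeleton_kwargs": {
                k: list(v) if isinstance(v, (tuple, list)) else v
                for k, v in self.skeleton_kwargs.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            grid=VoxelGridSpec.from_dict(d.get("grid", {"shape": (64, 256, 256)})),
            scene=SceneParams.from_dict(d.get("scene", {})),
            segmentation=SegmentationParams(**d.get("segmentation", {})),
            assignment=AssignmentParams(**d.get("assignment", {})),
            swc_path=d.get("swc_path"),
            simulate=bool(d.get("simulate", True)),
            write_stacks=bool(d.get("write_stacks", False)),
            skeleton_kwargs=dict(d.get("skeleton_kwargs", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    config: PipelineConfig
    truth: GroundTruthScene | None
    channels: list[VoxelChannel]
    puncta: list
    spots: list
    surface: object
    neurites: list
    assignments: list[PunctumAssignment]
    density: DensityReport
    soma_area: float
    proportions: dict
    counts: object
    detection: object | None
    marker_alignment: object | None
    log: dict


def _skeleton_for(config: PipelineConfig):
    if config.swc_path:
        return read_swc(config.swc_path)
    extent = tuple(config.grid.extent)
    return make_pyramidal_skeleton(extent=extent, **config.skeleton_kwargs)


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Run the full analysis and (optionally) write all outputs to ``outdir``.

    Stages: simulate (or load stacks) -> detect puncta and build the cell
    surface -> reconstruct presynaptic neurites -> membrane and input
    assignment -> densities, proportions, contact counts -> evaluation
    against ground truth when it exists.  Deterministic given the config
    seed.
    """
    if not config.simulate:
        raise ValueError(
            "run_pipeline orchestrates simulated scenes; for existing "
            "stacks use analyze_channels (CLI `assign`)"
        )
    skeleton = _skeleton_for(config)
    truth = sample_scene(skeleton, config.scene)
    channels = render_channels(truth, config.grid)
    result = analyze_channels(
        channels,
        skeleton,
        config,
        truth=truth,
        presimulate_log={
            "synapses": len(truth.synapses),
            "markers": len(truth.markers),
            "neurites": len(truth.neurites),
        },
    )
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def analyze_channels(
    channels: list[VoxelChannel],
    skeleton,
    config: PipelineConfig,
    truth: GroundTruthScene | None = None,
    presimulate_log: dict | None = None,
) -> PipelineResult:
    """Segment, assign and quantify a set of channels against a skeleton.

    ``channels`` must include a ``cellfill`` and a ``puncta`` channel;
    ``presyn:<type>`` and ``marker`` channels are optional.  When
    simulator ``truth`` is supplied, detection is scored against it.
    """
    from .morphology import compute_branch_orders

    log: dict = {"stages": {}}
    t_start = time.time()

    def stage(name: str, **info) -> None:
        log["stages"][name] = {**info, "t": round(time.time() - t_start, 2)}

    if presimulate_log:
        stage("simulate", **presimulate_log)
    segments = truth.segments if truth is not None else compute_branch_orders(skeleton)
    by_role = {c.role: c for c in channels}
    if "cellfill" not in by_role or "puncta" not in by_role:
        raise ValueError("analysis needs cellfill and puncta channels")
    seg = config.segmentation
    puncta = detect_puncta(
        by_role["puncta"],
        min_voxels=seg.puncta_min_voxels,
        split_diameter=seg.puncta_split_diameter,
    )
    spots = puncta_to_spots(puncta)
    surface = build_cell_surface(
        by_role["cellfill"], soma_hint=skeleton.soma_center
    )
    stage("segment_puncta", detected=len(puncta))

    neurites = []
    for role, ch in by_role.items():
        if role.startswith("presyn:"):
            neurites.extend(
                reconstruct_neurites(
                    ch,
                    split_diameter=seg.neurite_split_diameter,
                    min_voxels=seg.neurite_min_voxels,
                    z_blocks=seg.z_blocks,
                )
            )
    for i, n in enumerate(neurites):
        n.id = i
    stage("segment_neurites", objects=len(neurites))

    grid = by_role["puncta"].grid
    assignments = assign_puncta_to_cell(
        puncta, surface, segments, config.assignment
    )
    assignments = assign_inputs(
        assignments, spots, neurites, grid,
        threshold=config.assignment.input_threshold,
    )
    status_counts = {
        s: sum(1 for a in assignments if a.status == s)
        for s in ("somatic", "dendritic", "cytosolic", "unassociated")
    }
    stage("assign", **status_counts)

    density = branch_order_density(assignments, segments)
    soma_area = soma_surface_area(surface.soma_mask, grid)
    density.soma_area = soma_area
    density.soma_count = status_counts["somatic"]
    density.soma_density_value = soma_density(assignments, soma_area)
    proportions = input_proportions(assignments, segments)
    counts = contact_counts(
        neurites, surface, assignments, config.assignment.apposition_threshold
    )
    stage("quantify", dendritic_summary=density.dendritic_summary)

    detection = (
        evaluate_detection(truth.synapse_positions(), spots, tolerance=0.3)
        if truth is not None
        else None
    )
    marker_alignment = None
    if "marker" in by_role:
        marker_puncta = detect_puncta(
            by_role["marker"],
            min_voxels=seg.puncta_min_voxels,
            split_diameter=seg.puncta_split_diameter,
        )
        associated = [
            s
            for s, a in zip(spots, assignments)
            if a.status in ("somatic", "dendritic")
        ]
        if associated:
            marker_alignment = align_marker(
                np.array([s.centroid for s in associated]),
                marker_puncta,
                grid,
                threshold=config.assignment.marker_threshold,
            )
    stage(
        "evaluate",
        precision=None if detection is None else detection.precision,
        recall=None if detection is None else detection.recall,
        marker_rate=None if marker_alignment is None else marker_alignment.rate,
    )

    result = PipelineResult(
        config=config,
        truth=truth,
        channels=channels,
        puncta=puncta,
        spots=spots,
        surface=surface,
        neurites=neurites,
        assignments=assignments,
        density=density,
        soma_area=soma_area,
        proportions=proportions,
        counts=counts,
        detection=detection,
        marker_alignment=marker_alignment,
        log=log,
    )
    return result


def assignments_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    spot_by_id = {s.punctum_id: s for s in result.spots}
    for a in result.assignments:
        c = spot_by_id[a.punctum_id].centroid
        rows.append(
            {
                "punctum_id": a.punctum_id,
                "z": c[0], "y": c[1], "x": c[2],
                "status": a.status,
                "segment_id": a.segment_id,
                "input_label": a.input_label if a.input_label else "",
                "input_distance": a.input_distance
                if a.input_distance is not None
                else "",
                "ambiguous": a.ambiguous,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "punctum_id", "z", "y", "x", "status", "segment_id",
            "input_label", "input_distance", "ambiguous",
        ],
    )


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    """Write the CSV/JSON output bundle (and stacks when configured)."""
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    cfg.to_yaml(outdir / "resolved_config.yaml")

    puncta_rows = [
        {
            "id": p.id,
            "z": p.centroid[0], "y": p.centroid[1], "x": p.centroid[2],
            "volume_um3": p.volume,
            "n_voxels": len(p.voxels),
            "peak": p.peak_intensity,
            "mean": p.mean_intensity,
        }
        for p in result.puncta
    ]
    write_table(
        pd.DataFrame(
            puncta_rows,
            columns=["id", "z", "y", "x", "volume_um3", "n_voxels", "peak", "mean"],
        ),
        outdir / "puncta.csv",
    )
    write_table(assignments_table(result), outdir / "assignments.csv")
    write_table(result.density.segments, outdir / "density.csv")
    write_table(result.proportions["bins"], outdir / "proportions_bins.csv")
    write_table(result.proportions["per_order"], outdir / "proportions_per_order.csv")

    neurite_rows = [
        {
            "id": n.id,
            "cell_type": n.cell_type,
            "n_voxels": len(n.voxels),
            "n_surface": len(n.surface_voxels),
            "z_block": n.z_block,
        }
        for n in result.neurites
    ]
    write_table(
        pd.DataFrame(
            neurite_rows,
            columns=["id", "cell_type", "n_voxels", "n_surface", "z_block"],
        ),
        outdir / "neurites.csv",
    )

    contact_rows = [
        {
            "input_type": t,
            "surface_contacts": result.counts.surface_contacts.get(t, 0),
            "puncta_contacts": result.counts.puncta_contacts.get(t, 0),
        }
        for t in sorted(
            set(result.counts.surface_contacts) | set(result.counts.puncta_contacts)
        )
    ]
    write_table(
        pd.DataFrame(
            contact_rows,
            columns=["input_type", "surface_contacts", "puncta_contacts"],
        ),
        outdir / "contacts.csv",
    )

    summary = {
        "dendritic_summary_density": result.density.dendritic_summary,
        "dendritic_sem": result.density.dendritic_sem,
        "summary_rule": result.density.summary_rule,
        "soma_area_um2": result.soma_area,
        "soma_density": result.density.soma_density_value,
        "marker_alignment_rate": None
        if result.marker_alignment is None
        else result.marker_alignment.rate,
    }
    if result.detection is not None:
        summary["detection"] = {
            "tp": result.detection.tp,
            "fp": result.detection.fp,
            "fn": result.detection.fn,
            "precision": result.detection.precision,
            "recall": result.detection.recall,
            "f1": result.detection.f1,
            "tolerance_um": result.detection.tolerance,
        }
    write_json(summary, outdir / "summary.json")
    write_json(result.log, outdir / "pipeline_log.json")
    if result.truth is not None:
        result.truth.save_truth(outdir / "truth.json")
    if cfg.write_stacks:
        for ch in result.channels:
            name = ch.role.replace(":", "_")
            write_stack(ch, outdir / f"{name}.tif")
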