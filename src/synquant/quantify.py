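"""Density, proportion and comparison statistics over assignments.

Dendritic puncta density is the count of membrane-associated puncta on a
segment divided by its arc length (puncta/um); somatic density is the
somatic count divided by soma surface area (puncta/um^2).  The
cell-level dendritic summary is the mean of per-segment densities,
excluding the soma and the 1deg apical segment (a perisomatic,
unusually synapse-dense compartment), replaced by the median when the
per-segment densities fail Shapiro-Wilk normality at p < 0.05.

Evaluation against simulator ground truth uses greedy one-to-one
centroid matching at a physical tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assign import ContactCounts, PunctumAssignment
from .morphology import CompartmentSegment
from .segment import Spot

PERISOMATIC_BIN = "perisomatic"
HIGHER_APICAL_BIN = "higher_apical"
HIGHER_BASAL_BIN = "higher_basal"


@dataclass
class DensityReport:
    """Per-segment densities plus the cell-level dendritic summary."""

    segments: pd.DataFrame  # lineage, order, arc_length, count, density
    soma_count: int | None = None
    soma_area: float | None = None
    soma_density_value: float | None = None
    dendritic_summary: float | None = None
    dendritic_sem: float | None = None
    summary_rule: str = "mean"  # mean | median
    excluded_primary_apical: bool = True


def branch_order_density(
    assignments: list[PunctumAssignment],
    segments: list[CompartmentSegment],
    shapiro_alpha: float = 0.05,
) -> DensityReport:
    """Per-branch-order densities and the cell-level summary.

    The summary averages per-segment densities over all dendritic
    segments except the 1deg apical; when the per-segment density set is
    non-normal (Shapiro-Wilk p < alpha) the median is reported instead
    of the mean.
    """
    counts: dict[int, int] = {}
    for a in assignments:
        if a.status == "dendritic" and a.segment_id >= 0:
            counts[a.segment_id] = counts.get(a.segment_id, 0) + 1
    rows = []
    for seg in segments:
        if seg.arc_length <= 0:
            raise ValueError(f"segment {seg.segment_id} has zero arc length")
        c = counts.get(seg.segment_id, 0)
        rows.append(
            {
                "segment_id": seg.segment_id,
                "lineage": seg.lineage,
                "order": seg.order,
                "label": seg.label,
                "arc_length": seg.arc_length,
                "count": c,
                "density": c / seg.arc_length,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "segment_id", "lineage", "order", "label",
            "arc_length", "count", "density",
        ],
    )
    include = df[~((df["lineage"] == "apical") & (df["order"] == 1))]
    summary = sem = None
    rule = "mean"
    if len(include):
        dens = include["density"].to_numpy(dtype=float)
        if len(dens) >= 3 and np.ptp(dens) > 0:
            _, p = stats.shapiro(dens)
            if p < shapiro_alpha:
                rule = "median"
        summary = float(np.median(dens)) if rule == "median" else float(dens.mean())
        sem = float(dens.std(ddof=1) / np.sqrt(len(dens))) if len(dens) > 1 else 0.0
    return DensityReport(
        segments=df,
        dendritic_summary=summary,
        dendritic_sem=sem,
        summary_rule=rule,
    )


def soma_density(assignments: list[PunctumAssignment], surface_area: float) -> float:
    """Somatic spot count divided by soma surface area (puncta/um^2)."""
    if surface_area <= 0:
        raise ValueError("soma surface area must be positive")
    n = sum(1 for a in assignments if a.status == "somatic")
    return n / surface_area


def input_proportions(
    assignments: list[PunctumAssignment],
    segments: list[CompartmentSegment],
) -> dict[str, pd.DataFrame]:
    """Input-assigned puncta as percentages of total puncta per bin.

    Two groupings are emitted: compartment bins — perisomatic (soma plus
    1deg apical), higher-order apical (3deg + 4deg) and higher-order
    basal (3deg + 4deg) — and a full per-(lineage, order) table.
    Percentages per input type plus the unassigned remainder sum to 100
    within each non-empty bin; empty bins carry NaN.
    """
    seg_info = {s.segment_id: s for s in segments}

    def bin_of(a: PunctumAssignment) -> str | None:
        if a.status == "somatic":
            return PERISOMATIC_BIN
        if a.status != "dendritic":
            return None
        seg = seg_info.get(a.segment_id)
        if seg is None:
            return None
        if seg.lineage == "apical" and seg.order == 1:
            return PERISOMATIC_BIN
        if seg.order >= 3:
            return HIGHER_APICAL_BIN if seg.lineage == "apical" else HIGHER_BASAL_BIN
        return None

    labels = sorted(
        {a.input_label for a in assignments if a.input_label is not None}
    )
    bins = [PERISOMATIC_BIN, HIGHER_APICAL_BIN, HIGHER_BASAL_BIN]
    bin_rows = []
    for b in bins:
        members = [a for a in assignments if bin_of(a) == b]
        total = len(members)
        row: dict = {"bin": b, "total": total}
        for lab in labels:
            n = sum(1 for a in members if a.input_label == lab)
            row[lab] = 100.0 * n / total if total else float("nan")
        n_un = sum(1 for a in members if a.input_label is None)
        row["unassigned"] = 100.0 * n_un / total if total else float("nan")
        bin_rows.append(row)

    order_rows = []
    for seg_key in sorted(
        {(s.lineage, s.order) for s in segments}
    ):
        lineage, order = seg_key
        members = [
            a
            for a in assignments
            if a.status == "dendritic"
            and a.segment_id in seg_info
            and seg_info[a.segment_id].lineage == lineage
            and seg_info[a.segment_id].order == order
        ]
        total = len(members)
        row = {"lineage": lineage, "order": order, "total": total}
        for lab in labels:
            n = sum(1 for a in members if a.input_label == lab)
            row[lab] = 100.0 * n / total if total else float("nan")
        row["unassigned"] = (
            100.0 * sum(1 for a in members if a.input_label is None) / total
            if total
            else float("nan")
        )
        order_rows.append(row)

    return {
        "bins": pd.DataFrame(bin_rows),
        "per_order": pd.DataFrame(order_rows),
    }


@dataclass
class OverestimationStats:
    """Surface-minus-puncta contact differences and percent error rates."""

    per_cell: pd.DataFrame  # cell, input_type, surface, puncta, difference, error_rate
    group: pd.DataFrame  # input_type, mean_difference, sem_difference, mean_error_rate, sem_error_rate


def overestimation(counts_per_cell: list[ContactCounts]) -> OverestimationStats:
    """Two-feature vs three-feature contact comparison across cells.

    Per cell and input type: difference = surface - puncta contacts and
    error rate = difference / puncta x 100 (undefined, NaN, when the
    puncta count is zero).  Group statistics are means +/- SEM of the
    per-cell values, not ratios of group means.
    """
    if not counts_per_cell:
        raise ValueError("need at least one cell")
    rows = []
    for ci, cc in enumerate(counts_per_cell):
        types = sorted(set(cc.surface_contacts) | set(cc.puncta_contacts))
        for t in types:
            s = int(cc.surface_contacts.get(t, 0))
            p = int(cc.puncta_contacts.get(t, 0))
            rows.append(
                {
                    "cell": ci,
                    "input_type": t,
                    "surface": s,
                    "puncta": p,
                    "difference": s - p,
                    "error_rate": 100.0 * (s - p) / p if p > 0 else float("nan"),
                }
            )
    per_cell = pd.DataFrame(
        rows,
        columns=["cell", "input_type", "surface", "puncta", "difference", "error_rate"],
    )
    groups = []
    for t, sub in per_cell.groupby("input_type"):
        diff = sub["difference"].to_numpy(dtype=float)
        err = sub["error_rate"].to_numpy(dtype=float)
        err = err[np.isfinite(err)]
        groups.append(
            {
                "input_type": t,
                "mean_difference": float(diff.mean()),
                "sem_difference": float(diff.std(ddof=1) / np.sqrt(len(diff)))
                if len(diff) > 1
                else 0.0,
                "mean_error_rate": float(err.mean()) if len(err) else float("nan"),
                "sem_error_rate": float(err.std(ddof=1) / np.sqrt(len(err)))
                if len(err) > 1
                else 0.0,
            }
        )
    return OverestimationStats(per_cell=per_cell, group=pd.DataFrame(groups))


@dataclass
class DetectionScore:
    """One-to-one matching of detections against ground-truth positions."""

    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None
    tolerance: float
    match_distances: np.ndarray = field(default_factory=lambda: np.zeros(0))


def evaluate_detection(
    truth_positions: np.ndarray,
    spots: list[Spot] | np.ndarray,
    tolerance: float = 0.3,
) -> DetectionScore:
    """Greedy one-to-one matching of detected spots to true positions.

    Candidate pairs within ``tolerance`` um are accepted in order of
    increasing centroid distance, each point used at most once.
    Precision and recall are None (flagged undefined) when their
    denominator is zero.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    truth = np.atleast_2d(np.asarray(truth_positions, dtype=float))
    if truth.size == 0:
        truth = truth.reshape(0, 3)
    if isinstance(spots, np.ndarray):
        det = np.atleast_2d(spots) if spots.size else spots.reshape(0, 3)
    else:
        det = (
            np.array([s.centroid for s in spots]) if spots else np.zeros((0, 3))
        )
    pairs = []
    if len(truth) and len(det):
        diff = truth[:, None, :] - det[None, :, :]
        dist = np.sqrt((diff * diff).sum(axis=2))
        ti, di = np.nonzero(dist <= tolerance)
        order = np.argsort(dist[ti, di], kind="stable")
        used_t: set[int] = set()
        used_d: set[int] = set()
        for k in order:
            t, d = int(ti[k]), int(di[k])
            if t in used_t or d in used_d:
                continue
            used_t.add(t)
            used_d.add(d)
            pairs.append(dist[t, d])
    tp = len(pairs)
    fp = len(det) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision and recall and (precision + recall) > 0
        else (0.0 if precision is not None and recall is not None else None)
    )
    return DetectionScore(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        tolerance=tolerance,
        match_distances=np.asarray(pairs),
    )


def correlate_soma_dendrite(reports: list[DensityReport]) -> dict:
    """Pearson correlation between somatic and dendritic summary densities."""
    pairs = [
        (r.soma_density_value, r.dendritic_summary)
        for r in reports
        if r.soma_density_value is not None and r.dendritic_summary is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 cells with both densities")
    soma = np.array([p[0] for p in pairs])
    dend = np.array([p[1] for p in pairs])
    if np.ptp(soma) == 0 or np.ptp(dend) == 0:
        return {"r": float("nan"), "r2": float("nan"), "p": float("nan"),
                "n": len(pairs), "defined": False}
    r, p = stats.pearsonr(soma, dend)
    return {"r": float(r), "r2": float(r**2), "p": float(p),
            "n": len(pairs), "defined": True}
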