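"""Per-hemisphere substantia-nigra quantification.

Implements the composite-marker recipe: pick three analysis slices from the
red-nucleus landmark, compute thresholded QSM- and NMS-based SN volumes (low
susceptibility / high neuromelanin), the NMS contrast range (P90/P10 inside
the SN), their product (the QSM-NMS composite; lower = more PD-like), an
SMWI-based N1-volume stand-in, and left/right aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Sequence

import numpy as np

from .core import SMWIVolume, VoxelGrid


@dataclass
class HemisphereMeasures:
    subject_id: str
    side: Literal["L", "R"]
    qsm_based_volume: float  # mm^3
    nms_based_volume: float  # mm^3
    nms_contrast_range: float  # P90/P10 ratio
    n1_volume: float  # mm^3
    composite: float = math.nan

    def __post_init__(self) -> None:
        for v in (self.qsm_based_volume, self.nms_based_volume, self.n1_volume):
            if v < 0:
                raise ValueError("volumes must be nonnegative")
        if math.isnan(self.composite):
            self.composite = composite_score(
                self.qsm_based_volume, self.nms_based_volume, self.nms_contrast_range
            )


@dataclass
class ThresholdSearchResult:
    threshold: float
    objective: float  # PD-vs-HC AUC at the selected threshold
    grid: list[tuple[float, float]]  # (threshold, objective) pairs evaluated


def select_analysis_slices(
    rn_mask: np.ndarray, grid: VoxelGrid, fraction: float = 0.1
) -> tuple[int, int, int]:
    """Select the three analysis slices from the red-nucleus landmark.

    Scanning cranio-caudally (increasing slice index), the first slice on
    which the RN is barely or no longer visible — per-slice RN voxel count
    below ceil(fraction x the RN's maximum per-slice count) — is taken,
    together with the next two inferior (caudal) slices.
    """
    rn_mask = np.asarray(rn_mask, dtype=bool)
    if not np.any(rn_mask):
        raise ValueError("empty RN mask")
    axis = grid.slice_axis
    sum_axes = tuple(a for a in range(3) if a != axis)
    counts = rn_mask.sum(axis=sum_axes)
    cutoff = math.ceil(fraction * counts.max())
    visible = counts >= cutoff
    first_visible = int(np.argmax(visible))
    below = np.nonzero(~visible[first_visible:])[0]
    if below.size == 0:
        raise ValueError("RN never fades caudally: no landmark slice")
    first = first_visible + int(below[0])
    if first + 2 >= counts.size:
        raise ValueError("fewer than 3 slices inferior to the RN landmark")
    return (first, first + 1, first + 2)


def _slice_selector(slices: Sequence[int], grid: VoxelGrid, shape: tuple[int, ...]) -> np.ndarray:
    sel = np.zeros(shape, dtype=bool)
    idx: list[slice | list[int]] = [slice(None)] * 3
    for s in slices:
        if not 0 <= s < shape[grid.slice_axis]:
            raise IndexError(f"slice {s} outside grid")
    idx[grid.slice_axis] = list(slices)
    sel[tuple(idx)] = True
    return sel


def thresholded_volume(
    image: np.ndarray,
    region: np.ndarray,
    slices: Sequence[int],
    threshold: float,
    direction: Literal["below", "above"],
    grid: VoxelGrid,
) -> float:
    """Volume (mm^3) of region voxels on the given slices beyond the threshold.

    direction="below" counts voxels with value < threshold (low-susceptibility
    QSM tissue); "above" counts value > threshold (high neuromelanin signal).
    """
    image = np.asarray(image, dtype=float)
    region = np.asarray(region, dtype=bool)
    sel = region & _slice_selector(slices, grid, image.shape)
    if not np.any(sel):
        raise ValueError("region empty on the selected slices")
    vals = image[sel]
    n = int((vals < threshold).sum() if direction == "below" else (vals > threshold).sum())
    return n * grid.voxel_volume_mm3


def optimize_threshold(
    values_per_subject: Mapping[str, np.ndarray],
    labels: Mapping[str, str],
    threshold_grid: Sequence[float],
    direction: Literal["below", "above"],
    voxel_volume_mm3: float = 1.0,
    objective: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> ThresholdSearchResult:
    """Group-difference-maximizing threshold search.

    For each candidate threshold, computes every subject's thresholded volume
    and scores the PD-vs-HC separation as the AUC of those volumes (lower
    volume = more PD-like).  Returns the maximizing threshold; ties break
    toward the smallest threshold.
    """
    if len(threshold_grid) == 0:
        raise ValueError("empty threshold grid")
    subject_ids = list(values_per_subject)
    y = np.array([labels[s] == "PD" for s in subject_ids])
    if y.all() or not y.any():
        raise ValueError("both PD and HC groups must be present")
    if objective is None:
        from .classification import auc_of_scores

        objective = lambda scores, is_pd: auc_of_scores(scores, is_pd, orientation="lower_is_positive")
    grid_eval: list[tuple[float, float]] = []
    best_t, best_obj = None, -np.inf
    for t in threshold_grid:
        vols = np.array([
            (np.asarray(values_per_subject[s]) < t).sum() if direction == "below"
            else (np.asarray(values_per_subject[s]) > t).sum()
            for s in subject_ids
        ], dtype=float) * voxel_volume_mm3
        obj = float(objective(vols, y))
        grid_eval.append((float(t), obj))
        if obj > best_obj:  # strict: ties keep the smallest threshold
            best_t, best_obj = float(t), obj
    return ThresholdSearchResult(threshold=best_t, objective=best_obj, grid=grid_eval)


def nms_contrast_range(nms: np.ndarray, region: np.ndarray, slices: Sequence[int],
                       grid: VoxelGrid) -> float:
    """P90/P10 ratio of NMS signal within the SN region on the analysis slices.

    Percentiles use linear interpolation between order statistics.
    """
    sel = np.asarray(region, bool) & _slice_selector(slices, grid, np.asarray(nms).shape)
    vals = np.asarray(nms, dtype=float)[sel]
    if vals.size < 10:
        raise ValueError(f"need >= 10 region voxels on the analysis slices, got {vals.size}")
    p10, p90 = np.percentile(vals, [10.0, 90.0])
    if p10 <= 0:
        raise ValueError("10th percentile of NMS signal is nonpositive: ratio undefined")
    return float(p90 / p10)


def composite_score(qsm_vol: float, nms_vol: float, contrast: float) -> float:
    """QSM-NMS composite: product of the two volumes and the contrast range.

    Lower values indicate a higher likelihood of PD.
    """
    if qsm_vol < 0 or nms_vol < 0 or contrast < 0:
        raise ValueError("composite inputs must be nonnegative")
    return float(qsm_vol * nms_vol * contrast)


def n1_volume_smwi(
    smwi: SMWIVolume,
    sn_mask: np.ndarray,
    slices: Sequence[int],
    rel_threshold: float = 0.7,
    brain_mask: np.ndarray | None = None,
) -> float:
    """Rule-based N1 volume (mm^3): SMWI hyperintensity inside the dark SN.

    Counts SN voxels on the analysis slices whose SMWI exceeds
    ``rel_threshold`` times the slice-wise robust background level (median
    SMWI over brain tissue outside the SN on the same slice).
    """
    grid = smwi.grid
    sn_mask = np.asarray(sn_mask, dtype=bool)
    values = smwi.values
    axis = grid.slice_axis
    n_vox = 0
    for s in slices:
        sl: list[slice | int] = [slice(None)] * 3
        sl[axis] = s
        plane_vals = values[tuple(sl)]
        plane_sn = sn_mask[tuple(sl)]
        if not np.any(plane_sn):
            raise ValueError(f"SN empty on slice {s}")
        if brain_mask is not None:
            plane_bg = np.asarray(brain_mask, bool)[tuple(sl)] & ~plane_sn
        else:
            plane_bg = (plane_vals > 0) & ~plane_sn
        bg_level = np.median(plane_vals[plane_bg]) if np.any(plane_bg) else np.median(plane_vals)
        n_vox += int((plane_vals[plane_sn] > rel_threshold * bg_level).sum())
    return n_vox * grid.voxel_volume_mm3


def aggregate_hemispheres(left, right, mode: Literal["mean", "both_normal"] = "mean"):
    """Combine left/right values: arithmetic mean, or Normal iff both Normal."""
    if left is None:
        raise ValueError("missing left-side value")
    if right is None:
        raise ValueError("missing right-side value")
    if mode == "mean":
        return (left + right) / 2.0
    if mode == "both_normal":
        return "Normal" if (left == "Normal" and right == "Normal") else "Abnormal"
    raise ValueError(f"unknown aggregation mode {mode!r}")
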