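"""Tumor-likelihood heatmap summarization and anatomical segment assignment.

The heatmap is a voxelwise likelihood map in [0, 1] produced upstream (e.g.
by a segmentation CNN); the case-level score is its maximum, optionally
restricted to a region of interest.  The peak location can be mapped onto the
centerline to name the pancreatic segment (head/body/tail) the detection
falls in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .centerline import CenterlinePath
from .phantom import DEFAULT_BREAKPOINTS, segment_from_fraction
from .volume import ImageVolume

__all__ = ["HeatmapResult", "heatmap_score", "assign_segment"]


@dataclass(frozen=True)
class HeatmapResult:
    """Maximum likelihood, its location, and the size of the responding region."""

    max_value: float
    peak_coordinate_mm: tuple[float, float, float]
    peak_index: tuple[int, int, int]
    component_voxel_count: int | None = None


def heatmap_score(
    heatmap: ImageVolume,
    roi_mask: ImageVolume | None = None,
    component_threshold: float | None = None,
) -> HeatmapResult:
    """Maximum of the likelihood volume, optionally inside an ROI.

    Ties resolve to the smallest linear voxel index.  When
    ``component_threshold`` is given, the supra-threshold (strict ``>``)
    connected component containing the peak is sized; a peak at or below the
    threshold yields a component count of 0.
    """
    data = np.asarray(heatmap.data, float)
    lo, hi = float(data.min()), float(data.max())
    if lo < 0.0 or hi > 1.0:
        raise ValueError(f"heatmap values outside [0, 1]: observed range [{lo}, {hi}]")
    if roi_mask is not None:
        if not heatmap.same_grid(roi_mask):
            raise ValueError("roi mask must share the heatmap grid")
        roi = np.asarray(roi_mask.data) > 0
        if not roi.any():
            raise ValueError("roi mask is empty")
        masked = np.where(roi, data, -1.0)
    else:
        masked = data
    flat = int(np.argmax(masked))  # first occurrence = smallest linear index
    idx = np.unravel_index(flat, data.shape)
    result_max = float(data[idx])

    count = None
    if component_threshold is not None:
        if result_max > component_threshold:
            comps = cc_label(data > component_threshold, connectivity=3)
            count = int((comps == comps[idx]).sum())
        else:
            count = 0
    return HeatmapResult(
        max_value=result_max,
        peak_coordinate_mm=tuple(heatmap.index_to_mm(np.asarray(idx)).tolist()),
        peak_index=tuple(int(i) for i in idx),
        component_voxel_count=count,
    )


def assign_segment(
    location,
    path: CenterlinePath,
    breakpoints: tuple[float, float] = DEFAULT_BREAKPOINTS,
    max_distance_mm: float = 30.0,
) -> str:
    """Name the pancreatic segment (head/body/tail) of a location.

    ``location`` is either an arclength fraction in [0, 1] or a 3-D mm point,
    which is projected to its nearest centerline station (ties to the lower
    index).  A point farther than ``max_distance_mm`` from the path is
    rejected.  "head (uncinate process)" is a truth-label-only category and is
    never produced geometrically.
    """
    if np.isscalar(location):
        return segment_from_fraction(float(location), breakpoints)
    i, dist = path.nearest_station(np.asarray(location, float))
    if dist > max_distance_mm:
        raise ValueError(
            f"location off-pancreas: {dist:.1f} mm from the centerline "
            f"(limit {max_distance_mm} mm)"
        )
    return segment_from_fraction(float(path.fractions[i]), breakpoints)
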