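"""Head-to-tail centerline estimation for an elongated organ mask.

The pancreas is an elongated, gently curved organ; its medial axis is
recovered from the union of the parenchyma and main-pancreatic-duct (MPD)
segmentations by 3-D skeletonization followed by extraction of the skeleton
graph's geodesic diameter (the longest shortest path between skeleton
endpoints).  Skeletonization erodes roughly one organ radius at each end of a
tubular mask, so the geodesic path is extended along its end tangents until
it exits the mask before smoothing and arclength resampling.

Orientation (which end is the pancreatic head) is not decidable from the mask
alone and is applied separately by :func:`orient_path`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from .volume import ImageVolume

__all__ = ["CenterlinePath", "estimate_centerline", "orient_path"]

# offsets of the 26-neighbourhood, precomputed once
_NEIGHBOR_OFFSETS = np.array(
    [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
)


@dataclass(frozen=True)
class CenterlinePath:
    """An ordered 3-D polyline through the organ, in physical mm coordinates.

    Index 0 is the head end once the path has been oriented.  ``tangents``
    are unit central-difference tangents and ``arclength_mm`` is the
    cumulative arclength from the first point.
    """

    points: np.ndarray  # (N, 3) mm
    tangents: np.ndarray  # (N, 3) unit vectors
    arclength_mm: np.ndarray  # (N,)
    step_mm: float

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a centerline needs at least two points")
        if np.any(np.diff(self.arclength_mm) <= 0):
            raise ValueError("arclength must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_length_mm(self) -> float:
        return float(self.arclength_mm[-1] - self.arclength_mm[0])

    @property
    def fractions(self) -> np.ndarray:
        """Arclength fraction s in [0, 1] per station, 0 at the head."""
        a = self.arclength_mm - self.arclength_mm[0]
        return a / a[-1]

    def nearest_station(self, point_mm: np.ndarray) -> tuple[int, float]:
        """Index of the station closest to ``point_mm`` and its distance.

        Ties resolve to the lower station index.
        """
        d = np.linalg.norm(self.points - np.asarray(point_mm, float), axis=1)
        i = int(np.argmin(d))  # argmin takes the first minimum: lower index
        return i, float(d[i])

    def reversed(self) -> "CenterlinePath":
        pts = self.points[::-1].copy()
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        return CenterlinePath(pts, -self.tangents[::-1].copy(), arc, self.step_mm)

    # --- CSV round trip for inspection/replay ----------------------------

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        df = pd.DataFrame(
            {
                "station_index": np.arange(len(self)),
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
                "arclength_mm": self.arclength_mm,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase, step_mm: float | None = None) -> "CenterlinePath":
        df = pd.read_csv(path)
        pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        arc = df["arclength_mm"].to_numpy(float)
        if step_mm is None:
            step_mm = float(np.median(np.diff(arc)))
        return cls(pts, _central_difference_tangents(pts), arc, step_mm)


def _central_difference_tangents(points: np.ndarray) -> np.ndarray:
    t = np.gradient(points, axis=0)
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return t / norms


def _skeleton_graph(skel_idx: np.ndarray, shape: tuple[int, ...], spacing: np.ndarray):
    """Sparse 26-connectivity graph over skeleton voxels, physical edge weights."""
    lin = np.ravel_multi_index(skel_idx.T, shape)
    lookup = {v: i for i, v in enumerate(lin)}
    rows, cols, w = [], [], []
    for off in _NEIGHBOR_OFFSETS:
        nb = skel_idx + off
        ok = np.all((nb >= 0) & (nb < np.asarray(shape)), axis=1)
        nb_lin = np.ravel_multi_index(nb[ok].T, shape)
        dist = float(np.linalg.norm(off * spacing))
        for i_src, v in zip(np.nonzero(ok)[0], nb_lin):
            j = lookup.get(v)
            if j is not None:
                rows.append(i_src)
                cols.append(j)
                w.append(dist)
    n = len(skel_idx)
    return coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr(), lin


def _geodesic_diameter_path(graph, lin_idx: np.ndarray) -> np.ndarray:
    """Longest shortest path between endpoint voxels; deterministic tie-break.

    Ties are broken by the lexicographically smallest (source, target) pair of
    linear voxel indices.  Falls back to all nodes as candidates when the
    skeleton has no degree-1 node (a pure cycle).
    """
    deg = np.diff(graph.indptr)
    candidates = np.nonzero(deg == 1)[0]
    if candidates.size < 2:  # looped or blob-like skeleton: consider every node
        candidates = np.arange(graph.shape[0])
    # order candidates by linear voxel index for the tie-break
    candidates = candidates[np.argsort(lin_idx[candidates], kind="stable")]
    best = None  # (length, src_lin, dst_lin, src, dst, predecessors)
    for src in candidates:
        d, pred = dijkstra(graph, indices=src, return_predecessors=True)
        d[~np.isfinite(d)] = -1.0
        reach = candidates[(d[candidates] >= 0) & (candidates != src)]
        if reach.size == 0:
            continue
        dst_order = reach[np.argsort(lin_idx[reach], kind="stable")]
        dmax = d[dst_order].max()
        dst = dst_order[d[dst_order] == dmax][0]  # first = smallest lin index
        key = (dmax, -lin_idx[src], -lin_idx[dst])
        if best is None or (key[0] > best[0][0] + 1e-12) or (
            abs(key[0] - best[0][0]) <= 1e-12 and key[1:] > best[0][1:]
        ):
            best = ((dmax, -lin_idx[src], -lin_idx[dst]), src, int(dst), pred)
    if best is None:
        raise ValueError("skeleton graph has no connected pair of voxels")
    _, src, dst, pred = best
    path = [dst]
    while path[-1] != src:
        path.append(int(pred[path[-1]]))
    return np.asarray(path[::-1])


def _extend_to_boundary(points: np.ndarray, union: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Prolong both path ends along their local direction until leaving the mask."""
    step = float(spacing.min()) / 2.0
    shape = np.asarray(union.shape)

    def march(anchor: np.ndarray, direction: np.ndarray) -> list[np.ndarray]:
        n = np.linalg.norm(direction)
        if n == 0:
            return []
        direction = direction / n
        out = []
        p = anchor.copy()
        for _ in range(int(shape.max() * spacing.max() / step)):
            p = p + direction * step
            idx = p / spacing
            if np.any(idx < -0.5) or np.any(idx > shape - 0.5):
                break
            inside = map_coordinates(
                union.astype(np.uint8), idx.reshape(3, 1), order=0, mode="constant", cval=0
            )[0]
            if not inside:
                break
            out.append(p.copy())
        return out

    k = min(5, len(points) - 1)
    head_ext = march(points[0], points[0] - points[k])
    tail_ext = march(points[-1], points[-1] - points[-1 - k])
    parts = [np.asarray(head_ext[::-1]).reshape(-1, 3), points, np.asarray(tail_ext).reshape(-1, 3)]
    return np.vstack([p for p in parts if p.size])


def _moving_average(points: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return points
    pad = window // 2
    padded = np.vstack([np.repeat(points[:1], pad, 0), points, np.repeat(points[-1:], pad, 0)])
    kernel = np.ones(window) / window
    return np.column_stack(
        [np.convolve(padded[:, a], kernel, mode="valid") for a in range(3)]
    )


def _resample(points: np.ndarray, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    points = points[keep]
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    grid = np.arange(0.0, total, step_mm)
    if total - grid[-1] > 1e-9:
        grid = np.append(grid, total)
    res = np.column_stack([np.interp(grid, arc, points[:, a]) for a in range(3)])
    return res, grid


def estimate_centerline(
    pancreas_mask: ImageVolume,
    mpd_mask: ImageVolume,
    step_mm: float = 1.0,
    smoothing_window: int = 5,
) -> CenterlinePath:
    """Estimate the organ centerline from parenchyma + duct masks.

    Pipeline: union -> largest connected component -> 3-D skeletonization ->
    skeleton graph (26-connectivity, physical edge weights) -> geodesic
    diameter path -> end extension to the mask boundary -> moving-average
    smoothing -> arclength resampling at ``step_mm`` -> central-difference
    tangents.  The result is unoriented; apply :func:`orient_path`.
    """
    if not pancreas_mask.same_grid(mpd_mask):
        raise ValueError("pancreas and MPD masks must share one voxel grid")
    union = (np.asarray(pancreas_mask.data) > 0) | (np.asarray(mpd_mask.data) > 0)
    if not union.any():
        raise ValueError("union of pancreas and MPD masks is empty")
    spacing = np.asarray(pancreas_mask.spacing)

    labels = cc_label(union, connectivity=3)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    union = labels == int(np.argmax(counts))

    skel = skeletonize(union)
    skel_idx = np.argwhere(skel)
    if len(skel_idx) < 2:
        raise ValueError(
            f"skeleton degenerated to {len(skel_idx)} voxel(s); the mask is too "
            "small or too round for centerline extraction"
        )
    graph, lin_idx = _skeleton_graph(skel_idx, union.shape, spacing)
    order = _geodesic_diameter_path(graph, lin_idx)
    pts_mm = skel_idx[order] * spacing

    pts_mm = _extend_to_boundary(pts_mm, union, spacing)
    pts_mm = _moving_average(pts_mm, smoothing_window)
    pts_mm, arc = _resample(pts_mm, step_mm)
    return CenterlinePath(pts_mm, _central_difference_tangents(pts_mm), arc, float(step_mm))


def orient_path(
    path: CenterlinePath,
    head_rule: np.ndarray | tuple | dict,
) -> CenterlinePath:
    """Return the path with index 0 at the pancreatic-head end.

    ``head_rule`` is one of:

    * ``{"point": (x, y, z)}`` or a 3-vector dict value — the head end is the
      endpoint closer to this explicit coordinate;
    * ``{"vector": (x, y, z)}`` — the head end is the endpoint with the larger
      projection onto this anatomical direction;
    * a bare 3-sequence, interpreted as ``{"vector": ...}``.

    Idempotent; applying the rule with a negated vector reverses the path.
    """
    if not isinstance(head_rule, dict):
        head_rule = {"vector": np.asarray(head_rule, float)}
    a, b = path.points[0], path.points[-1]
    if "point" in head_rule:
        target = np.asarray(head_rule["point"], float)
        da, db = np.linalg.norm(a - target), np.linalg.norm(b - target)
        if np.isclose(da, db):
            raise ValueError("head rule is ambiguous: both endpoints are equidistant "
                             "from the given point; supply an explicit head coordinate")
        head_is_first = da < db
    elif "vector" in head_rule:
        v = np.asarray(head_rule["vector"], float)
        pa, pb = float(a @ v), float(b @ v)
        if np.isclose(pa, pb):
            raise ValueError("head rule is ambiguous: both endpoints project equally "
                             "onto the direction vector; supply an explicit head coordinate")
        head_is_first = pa > pb
    else:
        raise ValueError("head_rule must contain 'point' or 'vector'")
    return replace(path) if head_is_first else path.reversed()
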