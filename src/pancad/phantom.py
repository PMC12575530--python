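"""Synthetic pancreas phantoms: curved parenchyma, coaxial duct, tumor heatmaps.

The generator emulates what contrast-CT segmentation of the pancreas yields:
a binary parenchyma mask shaped as a curved, tapering tube; a binary main
pancreatic duct (MPD) mask running inside it; and a voxelwise tumor-likelihood
heatmap in [0, 1].  Cancer cases carry a focal tumor at arclength fraction
``s0`` whose obstruction dilates the duct tail-ward (s > s0) and atrophies the
parenchyma there — exactly the geometry the D/P-ratio indirect indicator is
designed to detect.  Every case is accompanied by a ground-truth record and an
analytic D/P profile, which serves as a voxelization-free oracle for the
measurement pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import binary_dilation, binary_erosion
from scipy.spatial import cKDTree

from .sections import DPProfile, dp_score
from .volume import ImageVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CohortParams",
    "DEFAULT_BREAKPOINTS",
    "segment_from_fraction",
    "generate_phantom",
    "analytic_dp_profile",
    "generate_cohort",
    "generate_study",
]

# arclength-fraction breakpoints: head [0, 0.40), body [0.40, 0.70), tail [0.70, 1]
DEFAULT_BREAKPOINTS: tuple[float, float] = (0.40, 0.70)

RadiusProfile = Callable[[np.ndarray], np.ndarray]

_DEFAULT_CONTROL_POINTS = (
    (15.0, 40.0, 24.0),
    (45.0, 58.0, 22.0),
    (80.0, 55.0, 26.0),
    (112.0, 34.0, 26.0),
)


def segment_from_fraction(s: float, breakpoints: tuple[float, float] = DEFAULT_BREAKPOINTS) -> str:
    """Map an arclength fraction (0 = head) to head/body/tail.

    The uncinate process cannot be told apart from the rest of the head by
    arclength alone, so "head (uncinate process)" is only ever assigned by
    explicit truth labeling, never here.
    """
    b1, b2 = breakpoints
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"arclength fraction {s} outside [0, 1]")
    if s < b1:
        return "head"
    if s < b2:
        return "body"
    return "tail"


def _as_profile(p: float | Sequence[float] | RadiusProfile) -> RadiusProfile:
    """Accept a constant, a (start, end) linear ramp, or a callable of s."""
    if callable(p):
        return p
    if np.isscalar(p):
        c = float(p)
        return lambda s: np.full_like(np.asarray(s, float), c)
    lo, hi = (float(x) for x in p)
    return lambda s: lo + (hi - lo) * np.asarray(s, float)


@dataclass
class PhantomSpec:
    """Full description of one synthetic case.

    Radii are in mm; ``parenchyma_radius_profile`` and ``duct_radius_profile``
    may be constants, (head, tail) linear ramps, or callables of the arclength
    fraction s in [0, 1].  For cancers, the duct radius is multiplied by
    ``dilation_factor`` and the parenchyma radius by ``atrophy_factor`` for
    s > ``tumor_arclength_fraction``.
    """

    grid_shape: tuple[int, int, int] = (128, 80, 48)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    curve_control_points: Sequence[Sequence[float]] = _DEFAULT_CONTROL_POINTS
    parenchyma_radius_profile: object = (11.0, 8.0)
    duct_radius_profile: object = (1.6, 2.0)
    duct_offset: tuple[float, float] = (0.0, 0.0)
    tumor_present: bool = False
    tumor_arclength_fraction: float = 0.5
    tumor_radius_mm: float = 8.0
    dilation_factor: float = 1.0
    atrophy_factor: float = 1.0
    surface_noise_sd: float = 0.0
    heatmap_tumor_amplitude: float = 0.9
    heatmap_noise_sd: float = 0.02
    n_distractor_blobs: int = 2
    distractor_amplitude_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    # --- derived geometry -------------------------------------------------

    def _curve(self, n_dense: int = 512) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense head->tail polyline (points, cumulative arclength, tangents)."""
        cp = np.asarray(self.curve_control_points, float)
        if len(cp) < 2:
            raise ValueError("need at least two control points")
        chord = cp[-1] - cp[0]
        proj = cp @ (chord / np.linalg.norm(chord))
        if np.any(np.diff(proj) <= 0):
            raise ValueError(
                "control polygon is non-monotone or self-intersecting along the "
                "head-to-tail chord; supply monotone control points"
            )
        t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))])
        if len(cp) == 2:
            u = np.linspace(0, 1, n_dense)
            pts = cp[0] + u[:, None] * (cp[1] - cp[0])
        else:
            spl = CubicSpline(t, cp, axis=0)
            pts = spl(np.linspace(t[0], t[-1], n_dense))
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        tang = np.gradient(pts, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        return pts, arc, tang

    def effective_radii(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Duct and parenchyma radii at fractions s after disease scaling."""
        s = np.asarray(s, float)
        r = _as_profile(self.duct_radius_profile)(s).astype(float).copy()
        R = _as_profile(self.parenchyma_radius_profile)(s).astype(float).copy()
        if self.tumor_present:
            tail = s > self.tumor_arclength_fraction
            r[tail] *= self.dilation_factor
            R[tail] *= self.atrophy_factor
        return r, R

    def validate(self) -> None:
        s = np.linspace(0, 1, 201)
        r0 = _as_profile(self.duct_radius_profile)(s)
        R0 = _as_profile(self.parenchyma_radius_profile)(s)
        if np.any(r0 <= 0) or np.any(R0 <= 0):
            raise ValueError("all radii must be positive")
        if np.any(r0 >= R0):
            raise ValueError("duct radius must stay strictly inside the parenchyma radius")
        if self.tumor_present:
            if not 0.0 < self.tumor_arclength_fraction < 1.0:
                raise ValueError("tumor_arclength_fraction must lie strictly in (0, 1)")
            if self.dilation_factor < 1.0:
                raise ValueError("dilation_factor must be >= 1")
            if self.atrophy_factor > 1.0 or self.atrophy_factor <= 0:
                raise ValueError("atrophy_factor must lie in (0, 1]")
            tail = s > self.tumor_arclength_fraction
            if tail.any() and (
                self.dilation_factor * r0[tail].max()
                >= self.atrophy_factor * R0[tail].min()
            ):
                raise ValueError(
                    f"dilated duct radius {self.dilation_factor * r0[tail].max():.2f} mm "
                    f"would reach the atrophied parenchyma radius "
                    f"{self.atrophy_factor * R0[tail].min():.2f} mm"
                )
        pts, _, _ = self._curve()
        _, R = self.effective_radii(np.linspace(0, 1, len(pts)))
        margin = R.max() + 2.0
        extent = np.asarray(self.grid_shape) * np.asarray(self.voxel_spacing)
        lo, hi = pts.min(axis=0) - margin, pts.max(axis=0) + margin
        if np.any(lo < 0) or np.any(hi > extent):
            raise ValueError(
                f"phantom geometry overflows the grid: curve plus max radius "
                f"{R.max():.1f} mm needs extent {hi}, grid provides {extent}"
            )


@dataclass
class GroundTruth:
    """Per-case truth record written alongside the generated volumes."""

    label: str  # "cancer" | "control"
    head_point_mm: tuple[float, float, float]
    analytic_curve_length_mm: float
    tumor_arclength_fraction: float | None = None
    tumor_center_mm: tuple[float, float, float] | None = None
    segment_label: str | None = None
    dilation_factor: float | None = None
    analytic_dp_p90: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        for k in ("head_point_mm", "tumor_center_mm"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def analytic_dp_profile(spec: PhantomSpec, n_stations: int = 101) -> DPProfile:
    """Exact D/P profile from the radius profiles, with no voxelization.

    At fraction s the duct cross-section is a disc of radius r(s) and the
    parenchyma an annulus between r(s) and R(s), so the ratio is
    r^2 / (R^2 - r^2).  Serves as the brute-force oracle for the
    measurement pipeline.
    """
    spec.validate()
    _, arc, _ = spec._curve()
    total = arc[-1]
    s = np.linspace(0.0, 1.0, n_stations)
    r, R = spec.effective_radii(s)
    duct = math.pi * r**2
    par = math.pi * R**2 - duct
    df = pd.DataFrame(
        {
            "arclength_mm": s * total,
            "arclength_fraction": s,
            "duct_area_mm2": duct,
            "parenchyma_area_mm2": par,
            "dp_ratio": duct / par,
            "valid": True,
        }
    )
    return DPProfile(df)


def _tube_geometry(
    pts: np.ndarray, arc: np.ndarray, vox: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Perpendicular distance and arclength fraction of voxels w.r.t. a polyline.

    The nearest dense sample is refined by exact projection onto its two
    adjacent segments, so boundary voxels are not lost to sampling jitter.
    Returns (distance_mm, fraction, beyond_end) where ``beyond_end`` marks
    voxels past the flat planes through the curve endpoints — the tube is
    truncated there rather than capped with hemispheres.
    """
    tree = cKDTree(pts)
    _, nearest = tree.query(vox, workers=-1)
    n_seg = len(pts) - 1
    total = arc[-1]

    best_d = np.full(len(vox), np.inf)
    best_s = np.zeros(len(vox))
    beyond = np.zeros(len(vox), dtype=bool)
    for cand in (nearest - 1, nearest):
        j = np.clip(cand, 0, n_seg - 1)
        p0, p1 = pts[j], pts[j + 1]
        seg = p1 - p0
        seg_len2 = np.einsum("ij,ij->i", seg, seg)
        t_raw = np.einsum("ij,ij->i", vox - p0, seg) / seg_len2
        t = np.clip(t_raw, 0.0, 1.0)
        closest = p0 + t[:, None] * seg
        d = np.linalg.norm(vox - closest, axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        seg_len = np.sqrt(seg_len2)
        best_s[upd] = (arc[j][upd] + t[upd] * seg_len[upd]) / total
        beyond[upd] = ((j[upd] == 0) & (t_raw[upd] < 0.0)) | (
            (j[upd] == n_seg - 1) & (t_raw[upd] > 1.0)
        )
    return best_d, best_s, beyond


def _boundary_flip(mask: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip inner and outer boundary voxels independently at the given rate."""
    if rate <= 0:
        return mask
    inner = mask & ~binary_erosion(mask)
    outer = binary_dilation(mask) & ~mask
    out = mask.copy()
    out[inner & (rng.random(mask.shape) < rate)] = False
    out[outer & (rng.random(mask.shape) < rate)] = True
    return out


def _add_blob(field: np.ndarray, spacing: np.ndarray, center: np.ndarray,
              sigma: float, amplitude: float) -> None:
    """Add a Gaussian likelihood blob in place, evaluated on a local box."""
    shape = np.asarray(field.shape)
    c_idx = center / spacing
    half = np.ceil(4 * sigma / spacing).astype(int)
    lo = np.maximum(0, np.floor(c_idx - half).astype(int))
    hi = np.minimum(shape, np.ceil(c_idx + half).astype(int) + 1)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) * spacing[a] for a in range(3)], indexing="ij")
    d2 = sum((g - center[a]) ** 2 for a, g in enumerate(grids))
    field[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(-d2 / (2 * sigma**2))


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, ImageVolume, ImageVolume, GroundTruth]:
    """Rasterize one case: (pancreas mask, MPD mask, heatmap, truth).

    The masks are made disjoint by removing duct voxels from the parenchyma
    mask; the duct always lies inside the (possibly atrophied) parenchyma
    envelope.  Deterministic for a fixed spec (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.voxel_spacing, float)
    shape = spec.grid_shape

    pts, arc, tang = spec._curve()
    total = arc[-1]
    s_dense = arc / total

    # duct axis: main axis displaced in-plane by duct_offset along a
    # deterministic frame (tangent x least-aligned coordinate axis)
    off = np.asarray(spec.duct_offset, float)
    if np.any(off != 0):
        duct_pts = np.empty_like(pts)
        for i in range(len(pts)):
            t = tang[i]
            axis = np.zeros(3)
            axis[int(np.argmin(np.abs(t)))] = 1.0
            u = np.cross(t, axis)
            u /= np.linalg.norm(u)
            v = np.cross(t, u)
            duct_pts[i] = pts[i] + off[0] * u + off[1] * v
    else:
        duct_pts = pts

    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    vox = np.column_stack([ii.ravel() * spacing[0], jj.ravel() * spacing[1], kk.ravel() * spacing[2]])

    r_prof = _as_profile(spec.duct_radius_profile)
    R_prof = _as_profile(spec.parenchyma_radius_profile)

    def scaled(profile_fn, s, factor):
        vals = profile_fn(np.clip(s, 0.0, 1.0)).astype(float)
        if spec.tumor_present:
            vals[s > spec.tumor_arclength_fraction] *= factor
        return vals

    dist, s_vox, beyond = _tube_geometry(pts, arc, vox)
    envelope = (
        (dist <= scaled(R_prof, s_vox, spec.atrophy_factor)) & ~beyond
    ).reshape(shape)

    ddist, ds_vox, dbeyond = _tube_geometry(duct_pts, arc, vox)
    duct = (
        (ddist <= scaled(r_prof, ds_vox, spec.dilation_factor)) & ~dbeyond
    ).reshape(shape)

    flip_rate = min(0.5, spec.surface_noise_sd / float(spacing.min()))
    envelope = _boundary_flip(envelope, flip_rate, rng)
    duct = _boundary_flip(duct, flip_rate, rng)
    duct &= envelope  # duct stays inside the parenchyma envelope
    parenchyma = envelope & ~duct  # exclusive labels, like real segmentations

    # --- heatmap ----------------------------------------------------------
    heat = np.zeros(shape, float)
    tumor_center = None
    if spec.tumor_present:
        i0 = int(np.argmin(np.abs(s_dense - spec.tumor_arclength_fraction)))
        tumor_center = pts[i0]
        _add_blob(heat, spacing, tumor_center, spec.tumor_radius_mm / 2.0,
                  spec.heatmap_tumor_amplitude)
    env_idx = np.argwhere(envelope)
    for _ in range(spec.n_distractor_blobs):
        if len(env_idx) == 0:
            break
        c = env_idx[rng.integers(len(env_idx))] * spacing
        amp = rng.uniform(*spec.distractor_amplitude_range)
        _add_blob(heat, spacing, c, rng.uniform(2.0, 5.0), amp)
    if spec.heatmap_noise_sd > 0:
        heat += rng.normal(0.0, spec.heatmap_noise_sd, shape)
    np.clip(heat, 0.0, 1.0, out=heat)

    truth = GroundTruth(
        label="cancer" if spec.tumor_present else "control",
        head_point_mm=tuple(float(x) for x in pts[0]),
        analytic_curve_length_mm=float(total),
    )
    if spec.tumor_present:
        truth.tumor_arclength_fraction = float(spec.tumor_arclength_fraction)
        truth.tumor_center_mm = tuple(float(x) for x in tumor_center)
        truth.segment_label = segment_from_fraction(spec.tumor_arclength_fraction)
        truth.dilation_factor = float(spec.dilation_factor)
        truth.analytic_dp_p90 = dp_score(analytic_dp_profile(spec))

    make = lambda a: ImageVolume(a.astype(np.uint8) if a.dtype == bool else a,
                                 tuple(spacing))
    return make(parenchyma), make(duct), ImageVolume(heat, tuple(spacing)), truth


# --- cohorts --------------------------------------------------------------


@dataclass
class CohortParams:
    """Sampling ranges for per-case phantom parameters.

    Defaults are the study conditions the generator emulates: tumor diameters
    7-20 mm, tail-ward duct dilation with parenchymal atrophy, heatmap blobs
    whose amplitude overlaps the distractor range so that a minority of
    cancers are mass-invisible (detectable only through the D/P channel).
    """

    tumor_diameter_mm: tuple[float, float] = (7.0, 20.0)
    tumor_fraction: tuple[float, float] = (0.15, 0.85)
    dilation_factor: tuple[float, float] = (1.3, 2.5)
    atrophy_factor: tuple[float, float] = (0.75, 0.95)
    heatmap_tumor_amplitude: tuple[float, float] = (0.2, 0.95)
    distractor_amplitude: tuple[float, float] = (0.05, 0.5)
    n_distractor_blobs: tuple[int, int] = (1, 3)
    duct_radius_scale: tuple[float, float] = (0.8, 1.2)
    parenchyma_radius_scale: tuple[float, float] = (0.9, 1.1)
    surface_noise_sd: float = 0.05
    heatmap_noise_sd: float = 0.02


def _draw_spec(params: CohortParams, cancer: bool, rng: np.random.Generator) -> PhantomSpec:
    rs = rng.uniform(*params.duct_radius_scale)
    Rs = rng.uniform(*params.parenchyma_radius_scale)
    spec = PhantomSpec(
        duct_radius_profile=(1.6 * rs, 2.0 * rs),
        parenchyma_radius_profile=(11.0 * Rs, 8.0 * Rs),
        surface_noise_sd=params.surface_noise_sd,
        heatmap_noise_sd=params.heatmap_noise_sd,
        n_distractor_blobs=int(rng.integers(params.n_distractor_blobs[0],
                                            params.n_distractor_blobs[1] + 1)),
        distractor_amplitude_range=params.distractor_amplitude,
        seed=int(rng.integers(2**31 - 1)),
    )
    if cancer:
        spec.tumor_present = True
        spec.tumor_arclength_fraction = float(rng.uniform(*params.tumor_fraction))
        spec.tumor_radius_mm = float(rng.uniform(*params.tumor_diameter_mm)) / 2.0
        spec.dilation_factor = float(rng.uniform(*params.dilation_factor))
        spec.atrophy_factor = float(rng.uniform(*params.atrophy_factor))
        spec.heatmap_tumor_amplitude = float(rng.uniform(*params.heatmap_tumor_amplitude))
    return spec


def generate_cohort(
    n_cancer: int,
    n_control: int,
    out_dir: str | Path,
    params: CohortParams | None = None,
    seed: int = 0,
    split: str = "test",
    case_prefix: str = "case",
    start_index: int = 0,
) -> pd.DataFrame:
    """Write NIfTI triplets, truth JSONs and a manifest for a synthetic cohort.

    Cancer cases draw tumor diameter, location, dilation/atrophy strength and
    heatmap amplitude from ``params``; reproducible for a fixed seed.  Returns
    the manifest as a DataFrame (also written to ``manifest.csv``).
    """
    if n_cancer < 0 or n_control < 0:
        raise ValueError("cohort counts must be nonnegative")
    if params is None:
        params = CohortParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    labels = ["cancer"] * n_cancer + ["control"] * n_control
    for i, lab in enumerate(labels):
        cid = f"{case_prefix}{start_index + i:04d}"
        spec = _draw_spec(params, lab == "cancer", rng)
        par, duct, heat, truth = generate_phantom(spec)
        paths = {k: out / f"{cid}_{k}.nii.gz" for k in ("pancreas", "mpd", "heatmap")}
        par.save(paths["pancreas"])
        duct.save(paths["mpd"])
        heat.save(paths["heatmap"])
        (out / f"{cid}_truth.json").write_text(truth.to_json())
        rows.append(
            {
                "case_id": cid,
                "label": lab,
                "pancreas_path": str(paths["pancreas"]),
                "mpd_path": str(paths["mpd"]),
                "heatmap_path": str(paths["heatmap"]),
                "segment_truth": truth.segment_label or "",
                "split": split,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def generate_study(
    n_cal_cancer: int,
    n_cal_control: int,
    n_test_cancer: int,
    n_test_control: int,
    out_dir: str | Path,
    params: CohortParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibration + test cohorts in one manifest, mirroring a threshold-setting
    set followed by an evaluation set."""
    out = Path(out_dir)
    cal = generate_cohort(n_cal_cancer, n_cal_control, out, params, seed=seed,
                          split="calibration", case_prefix="cal")
    test = generate_cohort(n_test_cancer, n_test_control, out, params, seed=seed + 1,
                           split="test", case_prefix="tst")
    manifest = pd.concat([cal, test], ignore_index=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
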