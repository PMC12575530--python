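"""End-to-end cohort processing: manifests, configuration, scoring, reports.

``run_pipeline`` drives the whole method on a case manifest: per case it
estimates the centerline, computes the D/P profile and its 90th-percentile
score, summarizes the heatmap, then calibrates the two thresholds on the
``calibration`` split, classifies the ``test`` split with the disjunction
rule, and evaluates (confusion metrics with CIs, ROC, decision curves,
localization concordance).  All intermediates are persisted as plain text so
any reported number can be recomputed from the scores CSV and thresholds
JSON alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centerline import estimate_centerline, orient_path
from .detector import DisjunctionDetector, Thresholds, classify_cohort
from .heatmap import assign_segment, heatmap_score
from .phantom import DEFAULT_BREAKPOINTS
from .sections import DPParams, compute_dp_profile, dp_score, localize_dp_jump
from .stats import confusion_metrics, decision_curve, roc_curve
from .volume import ImageVolume

__all__ = [
    "PipelineConfig",
    "read_manifest",
    "score_case",
    "run_pipeline",
    "localization_concordance",
]

log = logging.getLogger("pancad")

MANIFEST_COLUMNS = (
    "case_id",
    "label",
    "pancreas_path",
    "mpd_path",
    "heatmap_path",
    "segment_truth",
    "split",
)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, persistable as one JSON file."""

    step_mm: float = 1.0
    smoothing_window: int = 5
    percentile_q: float = 90.0
    min_parenchyma_area_mm2: float = 20.0
    extent_mm: float = 40.0
    in_plane_spacing_mm: float | None = None
    denominator: str = "parenchyma"
    jump_smooth_window: int = 5
    min_jump: float = 0.01
    breakpoints: tuple[float, float] = DEFAULT_BREAKPOINTS
    # the head end is the endpoint with the larger projection onto this vector;
    # the phantom generator lays the organ head-to-tail along +x, so its head
    # is the extreme point of -x
    head_vector: tuple[float, float, float] = (-1.0, 0.0, 0.0)
    target_mass_sensitivity: float = 0.80
    target_dp_specificity: float = 1.00
    concordance_include_undetected: bool = False
    seed: int = 0

    def dp_params(self) -> DPParams:
        return DPParams(
            percentile_q=self.percentile_q,
            min_parenchyma_area_mm2=self.min_parenchyma_area_mm2,
            extent_mm=self.extent_mm,
            in_plane_spacing_mm=self.in_plane_spacing_mm,
            denominator=self.denominator,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        for k in ("breakpoints", "head_vector"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a case manifest CSV."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    if df["case_id"].duplicated().any():
        raise ValueError("manifest contains duplicate case_id values")
    bad = set(df["split"]) - {"calibration", "test"}
    if bad:
        raise ValueError(f"invalid split values {sorted(bad)}")
    return df


def score_case(
    pancreas: ImageVolume,
    mpd: ImageVolume,
    heatmap: ImageVolume | None,
    config: PipelineConfig,
) -> dict:
    """Run the geometric pipeline on one case's volumes.

    Returns a flat record with the two channel scores and localization
    inputs (heatmap peak segment; D/P jump segment and fraction).
    """
    path = estimate_centerline(pancreas, mpd, config.step_mm, config.smoothing_window)
    path = orient_path(path, {"vector": np.asarray(config.head_vector)})
    profile = compute_dp_profile(path, pancreas, mpd, config.dp_params())
    rec: dict = {
        "dp_p90": dp_score(profile),
        "centerline_length_mm": path.total_length_mm,
        "n_valid_stations": int(profile.stations["valid"].sum()),
    }
    jump = localize_dp_jump(profile, config.jump_smooth_window, config.min_jump)
    if jump is not None:
        rec["jump_fraction"] = jump[1]
        rec["dp_segment"] = assign_segment(jump[1], path, config.breakpoints)
    if heatmap is not None:
        hm = heatmap_score(heatmap)
        rec["heatmap_max"] = hm.max_value
        try:
            rec["mass_segment"] = assign_segment(
                np.asarray(hm.peak_coordinate_mm), path, config.breakpoints
            )
        except ValueError:
            # peak far off the organ (a distractor outside reach): no segment
            rec["mass_segment"] = None
    return rec


def _score_manifest(manifest: pd.DataFrame, config: PipelineConfig) -> tuple[pd.DataFrame, list[str]]:
    rows, failures = [], []
    for _, case in manifest.iterrows():
        rec = {"case_id": case["case_id"], "label": case["label"], "split": case["split"]}
        try:
            pancreas = ImageVolume.load(case["pancreas_path"])
            mpd = ImageVolume.load(case["mpd_path"])
            heat = (
                ImageVolume.load(case["heatmap_path"]) if case["heatmap_path"] else None
            )
            rec.update(score_case(pancreas, mpd, heat, config))
            rec["evaluable"] = True
        except Exception as exc:  # noqa: BLE001 — per-case failures must not abort the cohort
            log.warning("case %s unevaluable: %s", case["case_id"], exc)
            rec["evaluable"] = False
            rec["error"] = str(exc)
            failures.append(case["case_id"])
        rows.append(rec)
    return pd.DataFrame(rows), failures


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Score, calibrate, classify and evaluate a full cohort.

    Calibration uses the ``calibration`` split, classification and all
    metrics the ``test`` split.  Per-case failures are logged and reported as
    unevaluable rather than aborting the run.  When ``out_dir`` is given,
    scores CSV, thresholds JSON, classification CSV, metrics JSON and a run
    log are persisted there.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    if config is None:
        config = PipelineConfig()

    scores, failures = _score_manifest(manifest, config)
    ok = scores[scores["evaluable"]].copy()

    cal = ok[ok["split"] == "calibration"]
    test = ok[ok["split"] == "test"]
    report: dict = {
        "n_cases": int(len(manifest)),
        "n_unevaluable": len(failures),
        "unevaluable": failures,
        "config_hash": config.hash(),
        "version": __version__,
    }

    thresholds = None
    if len(cal) > 0:
        fit = DisjunctionDetector(cal).fit(
            config.target_mass_sensitivity, config.target_dp_specificity
        )
        thresholds = fit.thresholds
        report["thresholds"] = json.loads(thresholds.to_json())

    results = tables = None
    if thresholds is not None and len(test) > 0:
        results, tables = classify_cohort(test, thresholds)
        metrics = {
            name: {
                "counts": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn},
                **{
                    m: dict(zip(("percent", "ci_low", "ci_high"), est.as_percent()))
                    for m, est in confusion_metrics(t).items()
                    if est.defined
                },
            }
            for name, t in tables.items()
        }
        report["metrics"] = metrics
        for channel in ("heatmap_max", "dp_p90"):
            sub = test.dropna(subset=[channel])
            if sub["label"].nunique() == 2:
                *_, auc = roc_curve(sub[channel], sub["label"])
                report.setdefault("auc", {})[channel] = auc
        nb = decision_curve(tables)
        report["net_benefit_at_0.1"] = {
            k: float(np.interp(0.1, nb.threshold_probabilities, v))
            for k, v in nb.curves.items()
        }
        merged = results.merge(
            manifest[["case_id", "segment_truth"]], on="case_id"
        ).merge(test[["case_id", "label"]], on="case_id")
        conc = localization_concordance(
            merged, include_undetected=config.concordance_include_undetected
        )
        report["localization_concordance"] = conc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scores.sort_values("case_id").to_csv(out / "scores.csv", index=False, float_format="%.10g")
        config.to_json(out / "config.json")
        if thresholds is not None:
            thresholds.to_json(out / "thresholds.json")
        if results is not None:
            results.sort_values("case_id").to_csv(out / "classification.csv", index=False,
                                                  float_format="%.10g")
            nb.to_csv(out / "decision_curve.csv")
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    report["scores"] = scores
    if results is not None:
        report["classification"] = results
        report["tables"] = tables
    return report


def localization_concordance(
    results: pd.DataFrame,
    include_undetected: bool = False,
    head_granularity: bool = True,
) -> dict:
    """Agreement between predicted and true tumor segments among cancers.

    ``results`` needs columns ``label``, ``verdict``, ``segment`` and
    ``segment_truth``.  By default only detected cancers enter the
    denominator (an undetected case has no predicted location); with
    ``include_undetected`` they count as discordant.  With
    ``head_granularity`` a truth of "head (uncinate process)" matches a
    predicted "head".
    """
    cancers = results[results["label"] == "cancer"]
    if len(cancers) == 0:
        raise ValueError("no cancer cases: concordance undefined")
    detected = cancers[cancers["verdict"] == "positive"]
    denom = cancers if include_undetected else detected

    def match(row) -> bool:
        truth = str(row["segment_truth"])
        pred = str(row["segment"])
        if head_granularity and truth.startswith("head"):
            truth = "head"
        return bool(pred) and pred == truth

    n_match = int(detected.apply(match, axis=1).sum()) if len(detected) else 0
    n_denom = len(denom)
    return {
        "concordance": n_match / n_denom if n_denom else float("nan"),
        "n_match": n_match,
        "n_discordant": n_denom - n_match,
        "n_denominator": n_denom,
        "n_cancers": int(len(cancers)),
    }
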