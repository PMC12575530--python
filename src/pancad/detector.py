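"""Two-channel disjunction classifier with data-driven threshold calibration.

A case is called positive when its heatmap maximum exceeds the mass-channel
threshold OR its D/P-ratio 90th-percentile score exceeds the duct-channel
threshold.  The thresholds are calibrated on a labelled threshold-setting set:
the mass cutoff is the largest value keeping cancer sensitivity at or above a
target (default 80%), and the duct cutoff is set so control specificity meets
its target (default 100%, i.e. the maximum control score under a strict
comparison).  The model/results pair (`DisjunctionDetector` /
`DetectorResults`) wraps calibration, classification and evaluation in the
fit-then-inspect idiom common to statistical modelling libraries.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import ConfusionTable, confusion_metrics

__all__ = [
    "CaseScores",
    "Thresholds",
    "DetectionResult",
    "calibrate_thresholds",
    "classify_case",
    "classify_cohort",
    "DisjunctionDetector",
    "DetectorResults",
]


@dataclass
class CaseScores:
    """Per-case channel scores plus optional localization inputs."""

    case_id: str
    heatmap_max: float | None = None
    dp_p90: float | None = None
    mass_segment: str | None = None
    dp_segment: str | None = None
    jump_fraction: float | None = None


@dataclass
class Thresholds:
    """Calibrated channel cutoffs with calibration provenance."""

    heatmap_thr: float
    dp_thr: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in (("heatmap_thr", self.heatmap_thr), ("dp_thr", self.dp_thr)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v}")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Thresholds":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


@dataclass
class DetectionResult:
    """Verdict for one case: which channels fired and where the lesion sits."""

    case_id: str
    verdict: str  # "positive" | "negative"
    fired_channels: tuple[str, ...]
    segment: str | None = None
    fraction: float | None = None
    localization_source: str = "none"  # "mass" | "dp" | "none"


def _largest_cutoff_for_sensitivity(scores: np.ndarray, target: float) -> tuple[float, float]:
    """Largest t with frac(score > t) >= target, as a midpoint between
    adjacent distinct observed scores.  Returns (cutoff, achieved fraction)."""
    s = np.sort(scores)[::-1]
    n = len(s)
    k = math.ceil(target * n)  # cancers that must exceed the cutoff
    k = max(k, 1)
    pivot = s[k - 1]  # k-th largest score; cutoff must sit strictly below it
    if pivot <= 0:
        achieved = float(np.mean(scores > 0.0))
        raise ValueError(
            f"target sensitivity {target:.0%} unattainable: the required cutoff "
            f"would be <= 0 (achieved at cutoff 0: {achieved:.0%})"
        )
    lower = s[s < pivot]
    cutoff = (pivot + (lower.max() if lower.size else 0.0)) / 2.0
    return float(cutoff), float(np.mean(scores > cutoff))


def calibrate_thresholds(
    calibration_scores: pd.DataFrame,
    target_mass_sensitivity: float = 0.80,
    target_dp_specificity: float = 1.00,
) -> Thresholds:
    """Set the channel cutoffs on a labelled threshold-setting set.

    ``calibration_scores`` needs columns ``label`` ("cancer"/"control"),
    ``heatmap_max`` and ``dp_p90``.  The mass cutoff keeps the fraction of
    cancers with ``heatmap_max`` strictly above it at or above the sensitivity
    target; the duct cutoff is the smallest value holding control specificity
    at its target under strict ``>`` — for a 100% target that is exactly the
    maximum control score.
    """
    df = calibration_scores
    if len(df) == 0:
        raise ValueError("empty calibration set")
    cancers = df[df["label"] == "cancer"]
    controls = df[df["label"] == "control"]
    if len(cancers) == 0 or len(controls) == 0:
        raise ValueError(
            f"calibration set must contain both classes "
            f"(got {len(cancers)} cancers, {len(controls)} controls)"
        )
    heat = cancers["heatmap_max"].to_numpy(float)
    heatmap_thr, achieved_sens = _largest_cutoff_for_sensitivity(
        heat, target_mass_sensitivity
    )

    dp_controls = np.sort(controls["dp_p90"].to_numpy(float))[::-1]
    m = math.floor((1.0 - target_dp_specificity) * len(dp_controls))
    dp_thr = float(dp_controls[m])  # m controls may exceed it under strict >
    achieved_spec = float(np.mean(dp_controls <= dp_thr))

    return Thresholds(
        heatmap_thr=heatmap_thr,
        dp_thr=dp_thr,
        provenance={
            "n_cancer": int(len(cancers)),
            "n_control": int(len(controls)),
            "target_mass_sensitivity": target_mass_sensitivity,
            "target_dp_specificity": target_dp_specificity,
            "achieved_mass_sensitivity": achieved_sens,
            "achieved_dp_specificity": achieved_spec,
        },
    )


def classify_case(scores: CaseScores, thresholds: Thresholds) -> DetectionResult:
    """Disjunction verdict for one case; strict ``>`` on both channels.

    Localization follows the mass channel when it fired, otherwise the
    D/P-jump location when the duct channel fired.  A missing channel score is
    treated as not fired, with a warning.
    """
    fired = []
    if scores.heatmap_max is None or (isinstance(scores.heatmap_max, float)
                                      and math.isnan(scores.heatmap_max)):
        warnings.warn(f"case {scores.case_id}: missing heatmap score; mass channel not fired")
    elif scores.heatmap_max > thresholds.heatmap_thr:
        fired.append("mass")
    if scores.dp_p90 is None or (isinstance(scores.dp_p90, float)
                                 and math.isnan(scores.dp_p90)):
        warnings.warn(f"case {scores.case_id}: missing D/P score; duct channel not fired")
    elif scores.dp_p90 > thresholds.dp_thr:
        fired.append("dp")

    segment, fraction, source = None, None, "none"
    if "mass" in fired and scores.mass_segment is not None:
        segment, source = scores.mass_segment, "mass"
    elif "dp" in fired and scores.dp_segment is not None:
        segment, fraction, source = scores.dp_segment, scores.jump_fraction, "dp"
    return DetectionResult(
        case_id=scores.case_id,
        verdict="positive" if fired else "negative",
        fired_channels=tuple(fired),
        segment=segment,
        fraction=fraction,
        localization_source=source,
    )


_SCORE_COLUMNS = ("heatmap_max", "dp_p90", "mass_segment", "dp_segment", "jump_fraction")


def classify_cohort(
    scores: pd.DataFrame, thresholds: Thresholds
) -> tuple[pd.DataFrame, dict[str, ConfusionTable] | None]:
    """Row-wise classification of a scores table.

    Returns the per-case results and, when the table has a ``label`` column,
    per-channel and combined confusion tables against it.
    """
    if scores["case_id"].duplicated().any():
        dupes = scores.loc[scores["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case_id(s): {dupes}")
    results = []
    for _, row in scores.iterrows():
        kw = {c: row[c] for c in _SCORE_COLUMNS if c in scores.columns and pd.notna(row[c])}
        res = classify_case(CaseScores(case_id=row["case_id"], **kw), thresholds)
        results.append(
            {
                "case_id": res.case_id,
                "verdict": res.verdict,
                "fired_channels": "+".join(res.fired_channels),
                "segment": res.segment or "",
                "fraction": res.fraction,
                "localization_source": res.localization_source,
            }
        )
    out = pd.DataFrame(results)
    tables = None
    if "label" in scores.columns:
        truth = scores["label"].to_numpy() == "cancer"
        tables = {}
        for name, fired in (
            ("mass", out["fired_channels"].str.contains("mass")),
            ("dp", out["fired_channels"].str.contains("dp")),
            ("combined", out["verdict"] == "positive"),
        ):
            pred = fired.to_numpy()
            tables[name] = ConfusionTable(
                tp=int((pred & truth).sum()),
                fp=int((pred & ~truth).sum()),
                fn=int((~pred & truth).sum()),
                tn=int((~pred & ~truth).sum()),
            )
    return out, tables


class DisjunctionDetector:
    """Model object: a two-channel disjunction classifier to be calibrated.

    Built from a scores table (columns ``case_id``, ``label``,
    ``heatmap_max``, ``dp_p90`` and optional localization columns);
    :meth:`fit` calibrates the thresholds and returns a
    :class:`DetectorResults`.
    """

    def __init__(self, scores: pd.DataFrame):
        required = {"case_id", "label", "heatmap_max", "dp_p90"}
        missing = required - set(scores.columns)
        if missing:
            raise ValueError(f"scores table is missing columns {sorted(missing)}")
        self.scores = scores.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DisjunctionDetector":
        return cls(df)

    def fit(
        self,
        target_mass_sensitivity: float = 0.80,
        target_dp_specificity: float = 1.00,
    ) -> "DetectorResults":
        thr = calibrate_thresholds(
            self.scores, target_mass_sensitivity, target_dp_specificity
        )
        return DetectorResults(self, thr)


class DetectorResults:
    """Calibrated thresholds plus classification/evaluation on new cohorts."""

    def __init__(self, model: DisjunctionDetector, thresholds: Thresholds):
        self.model = model
        self.thresholds = thresholds

    def classify(self, scores: pd.DataFrame | None = None) -> pd.DataFrame:
        df = self.model.scores if scores is None else scores
        out, _ = classify_cohort(df, self.thresholds)
        return out

    def evaluate(self, scores: pd.DataFrame | None = None) -> dict:
        """Confusion tables and metric/CI estimates per channel and combined."""
        df = self.model.scores if scores is None else scores
        _, tables = classify_cohort(df, self.thresholds)
        if tables is None:
            raise ValueError("evaluation needs a 'label' column")
        return {
            name: {"table": t, "metrics": confusion_metrics(t)}
            for name, t in tables.items()
        }

    def summary(self, scores: pd.DataFrame | None = None) -> str:
        prov = self.thresholds.provenance
        lines = [
            "Disjunction detector calibration",
            "=" * 48,
            f"mass-channel threshold (heatmap max) : {self.thresholds.heatmap_thr:.4f}",
            f"duct-channel threshold (D/P p90)     : {self.thresholds.dp_thr:.4f}",
        ]
        if prov:
            lines += [
                f"calibration set: {prov['n_cancer']} cancers, {prov['n_control']} controls",
                f"achieved mass sensitivity : {prov['achieved_mass_sensitivity']:.1%}"
                f" (target {prov['target_mass_sensitivity']:.0%})",
                f"achieved D/P specificity  : {prov['achieved_dp_specificity']:.1%}"
                f" (target {prov['target_dp_specificity']:.0%})",
            ]
        try:
            ev = self.evaluate(scores)
        except (ValueError, KeyError):
            return "\n".join(lines)
        lines.append("-" * 48)
        lines.append(f"{'channel':<10}{'sens':>8}{'spec':>8}{'ppv':>8}{'npv':>8}")
        for name, d in ev.items():
            m = d["metrics"]
            vals = [
                f"{m[k].estimate * 100:.1f}" if m[k].defined else "--"
                for k in ("sensitivity", "specificity", "ppv", "npv")
            ]
            lines.append(f"{name:<10}" + "".join(f"{v:>8}" for v in vals))
        return "\n".join(lines)
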