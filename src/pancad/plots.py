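"""Diagnostic figures: D/P profile per case, ROC curve, decision curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .sections import DPProfile
from .stats import NetBenefitCurve

__all__ = ["plot_dp_profile", "plot_roc", "plot_decision_curve"]


def plot_dp_profile(profile: DPProfile, threshold: float | None = None,
                    jump_mm: float | None = None, ax=None):
    """D/P ratio against arclength, with optional threshold and jump markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    st = profile.valid_stations
    ax.plot(st["arclength_mm"], st["dp_ratio"], lw=1.5, color="tab:blue")
    if threshold is not None:
        ax.axhline(threshold, ls=":", color="red", label="threshold")
    if jump_mm is not None:
        ax.axvline(jump_mm, ls="--", color="gray", label="D/P jump")
    ax.set_xlabel("arclength from head (mm)")
    ax.set_ylabel("D/P ratio")
    if threshold is not None or jump_mm is not None:
        ax.legend(frameon=False)
    return ax


def plot_roc(fpr: np.ndarray, tpr: np.ndarray, auc: float | None = None,
             label: str = "", ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    name = f"{label} (AUC {auc:.3f})" if auc is not None else label
    ax.plot(fpr, tpr, lw=1.5, label=name or None)
    ax.plot([0, 1], [0, 1], ls=":", color="gray", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if name:
        ax.legend(frameon=False, loc="lower right")
    return ax


def plot_decision_curve(nb: NetBenefitCurve, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for name, curve in nb.curves.items():
        style = {"treat_all": dict(ls="--", color="gray"),
                 "treat_none": dict(ls=":", color="black")}.get(name, {})
        ax.plot(nb.threshold_probabilities, curve, label=name, lw=1.5, **style)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=max(-0.05, ax.get_ylim()[0]))
    ax.legend(frameon=False)
    return ax
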