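"""Diagnostic-test statistics: confusion metrics with CIs, exact McNemar,
Fisher exact R x C by full enumeration, ROC sweep and decision-curve analysis.

Everything here is deterministic and exact where exactness is cheap: the
Fisher R x C p-value is computed by complete enumeration over tables with the
observed margins using integer arithmetic (the tables this package meets are
at most 4 x 2 with n around 100), and the McNemar p-value is a closed-form
binomial tail.  Confidence intervals default to the Wald normal approximation
p +/- 1.96 sqrt(p(1-p)/n) clipped to [0, 1]; Wilson and Clopper-Pearson are
available behind a flag.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from itertools import count
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta, binom

__all__ = [
    "ConfusionTable",
    "ProportionEstimate",
    "NetBenefitCurve",
    "proportion_ci",
    "confusion_metrics",
    "mcnemar_exact",
    "fisher_exact_rxc",
    "roc_curve",
    "decision_curve",
    "stratified_compare",
]

_Z95 = 1.96  # conventional two-sided 95% normal quantile, as printed in reports


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 detection counts: tp/fn split the positives, fp/tn the negatives."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    @property
    def prevalence(self) -> float:
        return self.positives / self.n

    @classmethod
    def from_predictions(cls, truth, predicted) -> "ConfusionTable":
        t = np.asarray(truth, bool)
        p = np.asarray(predicted, bool)
        return cls(
            tp=int((t & p).sum()),
            fp=int((~t & p).sum()),
            fn=int((t & ~p).sum()),
            tn=int((~t & ~p).sum()),
        )


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion k/n with a two-sided 95% CI, clipped to [0, 1].

    ``defined`` is False when the denominator is zero, in which case the
    numeric fields are NaN rather than silently 0.
    """

    estimate: float
    ci_low: float
    ci_high: float
    k: int
    n: int
    defined: bool = True

    def as_percent(self, digits: int = 1) -> tuple[float, float, float]:
        """(value, lo, hi) in percent, rounded for report display."""
        if not self.defined:
            return (math.nan,) * 3
        r = lambda x: round(x * 100, digits)
        return r(self.estimate), r(self.ci_low), r(self.ci_high)


def proportion_ci(k: int, n: int, method: str = "wald") -> ProportionEstimate:
    """95% CI for a binomial proportion.

    ``wald`` (default): p +/- 1.96 sqrt(p(1-p)/n), clipped — the convention
    used for every interval this package reports.  ``wilson`` and
    ``clopper-pearson`` are provided for sensitivity analyses.
    """
    if n == 0:
        return ProportionEstimate(math.nan, math.nan, math.nan, k, 0, defined=False)
    p = k / n
    if method == "wald":
        half = _Z95 * math.sqrt(p * (1 - p) / n)
        lo, hi = p - half, p + half
    elif method == "wilson":
        z2 = _Z95**2
        denom = 1 + z2 / n
        center = (p + z2 / (2 * n)) / denom
        half = _Z95 * math.sqrt(p * (1 - p) / n + z2 / (4 * n**2)) / denom
        lo, hi = center - half, center + half
    elif method == "clopper-pearson":
        lo = beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
        hi = beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return ProportionEstimate(p, max(0.0, float(lo)), min(1.0, float(hi)), k, n)


def confusion_metrics(
    table: ConfusionTable, ci_method: str = "wald"
) -> dict[str, ProportionEstimate]:
    """Sensitivity, specificity, PPV and NPV, each with a 95% CI.

    A metric whose denominator is zero comes back with ``defined=False``.
    """
    pairs = {
        "sensitivity": (table.tp, table.tp + table.fn),
        "specificity": (table.tn, table.tn + table.fp),
        "ppv": (table.tp, table.tp + table.fp),
        "npv": (table.tn, table.tn + table.fn),
    }
    return {name: proportion_ci(k, n, ci_method) for name, (k, n) in pairs.items()}


def mcnemar_exact(b: int, c: int) -> float:
    """Two-sided exact McNemar p-value from the discordant-pair counts.

    p = min(1, 2 P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2); equals 1
    when b = c or there are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    n = b + c
    if n == 0:
        return 1.0
    return min(1.0, 2.0 * float(binom.cdf(min(b, c), n, 0.5)))


def fisher_exact_rxc(table) -> float:
    """Fisher's exact test for an R x 2 contingency table, two-sided.

    Full enumeration of all tables with the observed margins; the p-value is
    the total conditional (multivariate hypergeometric) probability of tables
    no more probable than the observed one.  Probabilities are compared as
    exact integer numerators over the common denominator C(N, c1), so no
    floating-point tolerance is needed; reduces to the textbook test on 2 x 2
    input.
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.ndim != 2 or tab.shape[1] != 2 or tab.shape[0] < 2:
        raise ValueError("expected an R x 2 table with R >= 2")
    if np.any(tab < 0):
        raise ValueError("counts must be nonnegative")
    if tab.sum() == 0:
        raise ValueError("all-zero table")
    rows = tab.sum(axis=1)
    c1 = int(tab[:, 0].sum())
    obs_weight = math.prod(math.comb(int(r), int(a)) for r, a in zip(rows, tab[:, 0]))

    total = 0  # sum of weights over tables at least as "extreme" (<= obs weight)
    rows_list = [int(r) for r in rows]
    suffix = np.concatenate([np.cumsum(rows_list[::-1])[::-1][1:], [0]])

    def recurse(i: int, remaining: int, weight: int) -> None:
        nonlocal total
        if i == len(rows_list):
            if remaining == 0 and weight <= obs_weight:
                total += weight
            return
        lo = max(0, remaining - int(suffix[i]))
        hi = min(rows_list[i], remaining)
        for a in range(lo, hi + 1):
            recurse(i + 1, remaining - a, weight * math.comb(rows_list[i], a))

    recurse(0, c1, 1)
    return total / math.comb(int(rows.sum()), c1)


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC sweep over all distinct score cutoffs under strict ``>``.

    Returns (fpr, tpr, thresholds, auc); the curve includes (0, 0) and (1, 1)
    and tied scores move together.  AUC is the trapezoidal area.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = y == "cancer"
    y = y.astype(bool)
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    cuts = np.unique(s)[::-1]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    tpr = [0.0]
    fpr = [0.0]
    thr = [math.inf]
    for t in cuts:
        pred = s > t
        tpr.append(float((pred & y).sum() / n_pos))
        fpr.append(float((pred & ~y).sum() / n_neg))
        thr.append(float(t))
    if tpr[-1] != 1.0 or fpr[-1] != 1.0:
        tpr.append(1.0)
        fpr.append(1.0)
        thr.append(-math.inf)
    fpr_a, tpr_a = np.asarray(fpr), np.asarray(tpr)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    return fpr_a, tpr_a, np.asarray(thr), auc


@dataclass
class NetBenefitCurve:
    """Net benefit per model over a grid of threshold probabilities.

    ``curves`` always includes the ``treat_all`` and ``treat_none`` references;
    ``treat_none`` is identically zero.
    """

    threshold_probabilities: np.ndarray
    curves: dict[str, np.ndarray]

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        df = pd.DataFrame({"pt": self.threshold_probabilities, **self.curves})
        df.to_csv(path, index=False)

    def crossing(self, a: str, b: str) -> float | None:
        """First grid pt where curve a drops to or below curve b (None if never)."""
        d = self.curves[a] - self.curves[b]
        idx = np.nonzero(d <= 0)[0]
        return float(self.threshold_probabilities[idx[0]]) if idx.size else None


def decision_curve(
    tables: dict[str, ConfusionTable],
    pt_grid: np.ndarray | None = None,
) -> NetBenefitCurve:
    """Decision-curve analysis for binary tests evaluated on one cohort.

    NB(pt) = TP/N - (FP/N) pt/(1-pt) per model; treat-all uses prevalence in
    place of TP/N and (1 - prevalence) in place of FP/N; treat-none is zero.
    All tables must describe the same N.
    """
    if pt_grid is None:
        pt_grid = np.arange(0.01, 1.0, 0.01)
    pt = np.asarray(pt_grid, float)
    if np.any((pt <= 0) | (pt >= 1)):
        raise ValueError("threshold probabilities must lie strictly in (0, 1)")
    ns = {t.n for t in tables.values()}
    if len(ns) > 1:
        raise ValueError(f"all models must share one cohort size, got {sorted(ns)}")
    n = ns.pop()
    odds = pt / (1 - pt)
    curves = {
        name: t.tp / n - (t.fp / n) * odds for name, t in tables.items()
    }
    prev = next(iter(tables.values())).prevalence
    curves["treat_all"] = prev - (1 - prev) * odds
    curves["treat_none"] = np.zeros_like(pt)
    return NetBenefitCurve(pt, curves)


_METRIC_CELLS = {
    "sensitivity": lambda t: (t.tp, t.fn),
    "specificity": lambda t: (t.tn, t.fp),
    "ppv": lambda t: (t.tp, t.fp),
    "npv": lambda t: (t.tn, t.fn),
}


def stratified_compare(
    tables: dict[str, ConfusionTable],
    metric: str = "sensitivity",
    bonferroni_k: int = 1,
) -> dict:
    """Compare one metric across strata with Fisher's exact R x 2 test.

    Builds the success/failure table for the chosen metric (one row per
    stratum), drops strata where the metric is undefined (zero denominator,
    with a warning), and flags significance at the Bonferroni-adjusted level
    0.05 / ``bonferroni_k``.
    """
    if metric not in _METRIC_CELLS:
        raise ValueError(f"unknown metric {metric!r}")
    rows, names = [], []
    for name, t in tables.items():
        succ, fail = _METRIC_CELLS[metric](t)
        if succ + fail == 0:
            warnings.warn(f"stratum {name!r}: {metric} undefined (empty denominator); dropped")
            continue
        rows.append((succ, fail))
        names.append(name)
    if len(rows) < 2:
        raise ValueError("need at least two strata with a defined metric")
    p = fisher_exact_rxc(rows)
    alpha = 0.05 / bonferroni_k
    return {
        "metric": metric,
        "strata": names,
        "table": rows,
        "p_value": p,
        "alpha": alpha,
        "significant": p < alpha,
    }
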