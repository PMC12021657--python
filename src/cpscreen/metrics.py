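"""Evaluation metrics for conformal screening predictors.

Counts follow conformal-prediction error semantics: a compound errs iff its
true class is absent from its prediction set, so ``both`` never errs and
``null`` always errs. Note the precision definition: FP counts true
inactives assigned to the predicted-active set *or* the null set — not the
conventional contingency-table FP — which lowers precision whenever the
null set is populated. This matches the error-rate bookkeeping used for
screening triage and is kept deliberately.

With AP/AN the true active/inactive totals and {1}/{0} the single-label
predicted-active/-inactive set sizes:

    sensitivity          = TP / AP
    precision            = TP / (TP + FP)
    efficiency           = ({1} + {0}) / (AP + AN)
    overall error rate   = (FP + FN) / (AP + AN)
    actives error rate   = FN / AP
    inactives error rate = FP / AN
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .conformal import PredictionSet, assign_prediction_sets
from .labeling import ScoredLibrary

logger = logging.getLogger(__name__)

__all__ = ["ConfusionSummary", "MetricReport", "summarize_confusion",
           "compute_metrics", "calibration_curve", "recall_top_n",
           "RecallCurve"]


@dataclass(frozen=True)
class ConfusionSummary:
    """CP-semantics confusion counts.

    TP: true actives in {active, both}; FP: true inactives in {active, null};
    FN: true actives in {inactive, null}; AP/AN: class totals.
    """

    TP: int
    FP: int
    FN: int
    AP: int
    AN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.AP, self.AN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP + self.FN != self.AP:
            raise ValueError("TP + FN must equal AP")


@dataclass(frozen=True)
class MetricReport:
    """Metric values at one significance level; undefined ratios are None."""

    sensitivity: float
    precision: float | None
    efficiency: float
    overall_error_rate: float
    actives_error_rate: float
    inactives_error_rate: float
    epsilon: float | None = None


def _set_values(sets: Sequence[PredictionSet]) -> np.ndarray:
    """Normalize prediction sets to their plain string values."""
    return np.array([s.value if isinstance(s, PredictionSet) else str(s)
                     for s in sets])


def summarize_confusion(sets: Sequence[PredictionSet],
                        truth: Sequence[int]) -> ConfusionSummary:
    """Count TP/FP/FN/AP/AN from prediction sets and true labels."""
    vals = _set_values(sets)
    truth = np.asarray(truth)
    if vals.shape != truth.shape:
        raise ValueError("sets and truth must align")
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes must be present in truth")
    active = truth == 1
    in_act = (vals == "active") | (vals == "both")
    in_null = vals == "null"
    in_inact = (vals == "inactive") | in_null
    return ConfusionSummary(
        TP=int(np.sum(active & in_act)),
        FP=int(np.sum(~active & ((vals == "active") | in_null))),
        FN=int(np.sum(active & in_inact)),
        AP=int(np.sum(active)),
        AN=int(np.sum(~active)),
    )


def compute_metrics(summary: ConfusionSummary, n_single_label: int,
                    epsilon: float | None = None) -> MetricReport:
    """Evaluate the six screening metrics from a confusion summary.

    ``n_single_label`` is {1} + {0}, the number of compounds receiving a
    single-label prediction. Precision is reported as None (with a warning)
    when TP + FP = 0, never coerced to zero.
    """
    if summary.AP <= 0 or summary.AN <= 0:
        raise ValueError("AP and AN must both be positive")
    total = summary.AP + summary.AN
    if summary.TP + summary.FP > 0:
        precision = summary.TP / (summary.TP + summary.FP)
    else:
        precision = None
        logger.warning("precision undefined (TP + FP = 0); reported as absent")
    return MetricReport(
        sensitivity=summary.TP / summary.AP,
        precision=precision,
        efficiency=n_single_label / total,
        overall_error_rate=(summary.FP + summary.FN) / total,
        actives_error_rate=summary.FN / summary.AP,
        inactives_error_rate=summary.FP / summary.AN,
        epsilon=epsilon,
    )


def calibration_curve(p1: np.ndarray, p0: np.ndarray, truth: Sequence[int],
                      eps_grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Error rates (overall / actives / inactives) across significance levels.

    For a valid conformal predictor each error rate tracks epsilon. Default
    grid: 0.01 .. 0.30 in steps of 0.01. Returns one row per epsilon,
    ordered by epsilon, with the full metric set (plot-ready CSV layout).
    """
    if eps_grid is None:
        eps_grid = np.arange(0.01, 0.301, 0.01)
    eps_grid = sorted(float(e) for e in eps_grid)
    if any(not 0.0 <= e < 1.0 for e in eps_grid):
        raise ValueError("grid values must lie in [0, 1)")
    truth = np.asarray(truth)
    rows = []
    for eps in eps_grid:
        vals = _set_values(assign_prediction_sets(p1, p0, eps))
        summary = summarize_confusion(vals, truth)
        n_single = int(np.sum((vals == "active") | (vals == "inactive")))
        rep = compute_metrics(summary, n_single, epsilon=eps)
        rows.append({"epsilon": eps,
                     "overall_error_rate": rep.overall_error_rate,
                     "actives_error_rate": rep.actives_error_rate,
                     "inactives_error_rate": rep.inactives_error_rate,
                     "efficiency": rep.efficiency,
                     "sensitivity": rep.sensitivity,
                     "precision": rep.precision,
                     "n_active": int(np.sum(vals == "active")),
                     "n_inactive": int(np.sum(vals == "inactive")),
                     "n_both": int(np.sum(vals == "both")),
                     "n_null": int(np.sum(vals == "null"))})
    return pd.DataFrame(rows)


@dataclass
class RecallCurve:
    """Recall of the n best-scoring compounds vs fraction of library evaluated."""

    fraction_evaluated: np.ndarray
    recall: np.ndarray
    checkpoints: dict[float, float]
    n: int


def recall_top_n(ranking: Sequence[str], library: ScoredLibrary,
                 n: int = 10_000,
                 checkpoints: Sequence[float] = (0.01, 0.03, 0.05),
                 thin_to: int = 2_000) -> RecallCurve:
    """Fraction of the n best-scoring compounds recovered while walking a
    ranked list.

    ``ranking`` must be a permutation of the library's ids. The curve is
    non-decreasing and ends at 1.0; for large libraries it is computed at
    every rank but reported on a thinned grid of at most ``thin_to`` points
    (checkpoint values are exact regardless of thinning).
    """
    N = len(library)
    if n > N:
        raise ValueError("n exceeds library size")
    order = np.argsort(library.scores, kind="stable")
    if not library.lower_is_better:
        order = order[::-1]
    top_ids = set(library.ids[i] for i in order[:n])
    lib_ids = set(library.ids)
    if len(ranking) != N or set(ranking) != lib_ids:
        raise ValueError("ranking must be a permutation of library ids")
    hits = np.fromiter((rid in top_ids for rid in ranking), dtype=bool, count=N)
    cum = np.cumsum(hits) / n
    frac = np.arange(1, N + 1) / N
    cps = {}
    for c in checkpoints:
        idx = max(int(np.ceil(c * N)) - 1, 0)
        cps[float(c)] = float(cum[idx])
    if N > thin_to:
        keep = np.unique(np.linspace(0, N - 1, thin_to).astype(int))
        frac, cum = frac[keep], cum[keep]
    return RecallCurve(fraction_evaluated=frac, recall=cum,
                       checkpoints=cps, n=n)
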