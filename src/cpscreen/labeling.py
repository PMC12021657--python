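"""Docking-score labeling and stratified split planning.

A docking screen assigns each compound an energy-like score (kcal/mol,
lower = better). The top-scoring fraction of the screen (default 1%)
defines the "virtual active" class; everything else is "virtual inactive".
The threshold is the score at the quantile boundary, and only compounds
*strictly better* than it are actives — ties at the boundary fall into the
inactive class, so the realized active fraction never exceeds the target.

The split planner produces k independent stratified 80/20
proper-training/calibration partitions of the labeled set, one per ensemble
member, each from its own derived random seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

__all__ = ["ScoredLibrary", "SplitPlan", "compute_score_threshold",
           "assign_labels", "make_split_plan"]


@dataclass
class ScoredLibrary:
    """Compounds with docking scores and, after labeling, binary labels.

    ``lower_is_better`` flips for scoring functions where higher is better;
    all thresholding logic respects it.
    """

    ids: list[str]
    scores: np.ndarray
    smiles: list[str] | None = None
    labels: np.ndarray | None = None
    lower_is_better: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.ids),):
            raise ValueError("scores must align 1:1 with ids")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != self.scores.shape:
                raise ValueError("labels must align 1:1 with ids")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class SplitPlan:
    """k disjoint (proper, calibration) index-set pairs covering all indices."""

    k: int
    proper_fraction: float
    seed: int
    splits: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for proper, calib in self.splits:
            n = len(proper) + len(calib)
            joined = np.union1d(proper, calib)
            if len(joined) != n:
                raise ValueError("proper and calibration sets overlap")


def compute_score_threshold(scores: np.ndarray, top_fraction: float = 0.01,
                            lower_is_better: bool = True) -> float:
    """Score threshold separating the top ``top_fraction`` of a screen.

    With scores sorted best-first, the threshold is the value at 0-based
    index ``floor(top_fraction * N)``. Compounds strictly better than it
    become virtual actives, so the active fraction is at most
    ``top_fraction`` (boundary ties collapse into the inactive class).
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    n = len(scores)
    if n < math.ceil(1.0 / top_fraction):
        raise ValueError(
            f"need at least {math.ceil(1.0 / top_fraction)} scores for "
            f"top_fraction={top_fraction}, got {n}")
    ordered = np.sort(scores)
    if not lower_is_better:
        ordered = ordered[::-1]
    return float(ordered[int(top_fraction * n)])


def assign_labels(library: ScoredLibrary, threshold: float) -> ScoredLibrary:
    """Label compounds: 1 iff strictly better than threshold, else 0.

    A score exactly at the threshold is "equal or worse", hence inactive.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if library.lower_is_better:
        labels = (library.scores < threshold).astype(np.int8)
    else:
        labels = (library.scores > threshold).astype(np.int8)
    return ScoredLibrary(ids=library.ids, scores=library.scores,
                         smiles=library.smiles, labels=labels,
                         lower_is_better=library.lower_is_better)


def make_split_plan(labels: np.ndarray, k: int = 5,
                    proper_fraction: float = 0.8, seed: int = 0) -> SplitPlan:
    """Plan k independent stratified proper/calibration splits.

    Each split preserves the class ratio in both parts up to rounding
    (±1 member) and uses its own derived seed (``seed + split index``), so
    the plan is a pure function of ``(labels, k, proper_fraction, seed)``.
    """
    labels = np.asarray(labels)
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < proper_fraction < 1.0:
        raise ValueError("proper_fraction must lie in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2 * k:
        raise ValueError(
            f"minority class has {counts.min()} members; "
            f"stratified splitting into {k} proper/calibration pairs "
            f"needs at least {2 * k}")
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(k):
        splitter = StratifiedShuffleSplit(n_splits=1,
                                          train_size=proper_fraction,
                                          random_state=seed + i)
        proper, calib = next(splitter.split(np.zeros(len(labels)), labels))
        splits.append((np.sort(proper), np.sort(calib)))
    return SplitPlan(k=k, proper_fraction=proper_fraction, seed=seed,
                     splits=splits)
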