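"""Aggregated Mondrian inductive conformal prediction for screening triage.

The predictor wraps k independently trained binary classifiers (default 5).
Each member is fit on its proper-training part and calibrated on its held-out
calibration part, separately per class (the Mondrian, class-conditional
variant — so the error guarantee holds for the rare virtual-active class, not
just on average). The nonconformity of a compound for a hypothesized class c
is ``1 - p_hat(c | x)``, the standard choice in conformal QSAR.

For a test compound, each member produces a p-value per class by ranking the
compound's nonconformity among that class's calibration scores:

    p = (#{calibration scores >= alpha} + 1) / (n_calib + 1)

The k per-class p-values are aggregated by coordinate-wise median into a
single (P1, P0) pair. At a significance level epsilon, class c enters the
prediction set iff p_c > epsilon, yielding the four-way assignment
{active, inactive, both, null}. The p-value is the non-smoothed
(deterministic, slightly conservative) variant, so repeated runs with the
same seed give identical predictions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Callable, Sequence

import joblib
import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression

from .chem_io import FeatureMatrix, FingerprintConfig
from .labeling import SplitPlan

__all__ = [
    "PValuePair",
    "PredictionSet",
    "CalibratedClassifier",
    "AggregatedConformalPredictor",
    "make_backend",
    "fit_conformal_ensemble",
    "pvalue_from_calibration",
    "predict_pvalues",
    "assign_prediction_set",
    "assign_prediction_sets",
    "find_epsilon_opt",
    "save_predictor",
    "load_predictor",
]


class PredictionSet(str, Enum):
    """Four-way Mondrian set assignment at a significance level."""

    ACTIVE = "active"
    INACTIVE = "inactive"
    BOTH = "both"
    NULL = "null"


@dataclass(frozen=True)
class PValuePair:
    """Per-compound conformal confidences for class 1 and class 0.

    Both may be large (compound conforms to both classes) or both small
    (conforms to neither) simultaneously.
    """

    p1: float
    p0: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p0 <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def quality(self) -> float:
        """Quality of information, P1 - P0."""
        return self.p1 - self.p0


def make_backend(name: str = "gbt", seed: int = 0,
                 class_weight: str | dict | None = "balanced",
                 **options: Any):
    """Construct a classifier backend.

    ``gbt`` (default): sklearn histogram gradient-boosted trees, with
    inverse-class-frequency weighting to handle the ~1:99 imbalance.
    ``lightgbm``: LightGBM, if installed. ``logistic``: fast linear model,
    handy for tests. All are deterministic given ``seed``.
    """
    if name == "gbt":
        opts = dict(max_iter=100, learning_rate=0.1, max_leaf_nodes=31,
                    early_stopping=False)
        opts.update(options)
        return HistGradientBoostingClassifier(random_state=seed,
                                              class_weight=class_weight,
                                              **opts)
    if name == "logistic":
        opts = dict(max_iter=1000, C=1.0)
        opts.update(options)
        return LogisticRegression(random_state=seed, class_weight=class_weight,
                                  **opts)
    if name == "lightgbm":
        import lightgbm  # optional backend

        opts = dict(n_estimators=200, num_leaves=31, deterministic=True,
                    n_jobs=1, verbose=-1)
        opts.update(options)
        return lightgbm.LGBMClassifier(random_state=seed,
                                       class_weight=class_weight, **opts)
    raise ValueError(f"unknown backend {name!r}")


def _proba1(model, X: np.ndarray) -> np.ndarray:
    """Probability of class 1 for each row, robust to class ordering."""
    proba = model.predict_proba(X)
    idx = int(np.where(np.asarray(model.classes_) == 1)[0][0])
    return proba[:, idx]


@dataclass
class CalibratedClassifier:
    """A trained backend plus its per-class sorted calibration scores."""

    backend: Any
    calib_scores_1: np.ndarray
    calib_scores_0: np.ndarray

    def __post_init__(self) -> None:
        self.calib_scores_1 = np.sort(np.asarray(self.calib_scores_1, float))
        self.calib_scores_0 = np.sort(np.asarray(self.calib_scores_0, float))
        if self.calib_scores_1.size == 0 or self.calib_scores_0.size == 0:
            raise ValueError("both calibration score lists must be non-empty")


@dataclass
class AggregatedConformalPredictor:
    """k calibrated members whose per-class p-values are median-aggregated."""

    members: list[CalibratedClassifier]
    fingerprint: FingerprintConfig | None = None
    threshold: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("need at least one member")

    @property
    def k(self) -> int:
        return len(self.members)


def fit_conformal_ensemble(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    plan: SplitPlan,
    backend: str = "gbt",
    backend_options: dict | None = None,
    seed: int = 0,
    threshold: float | None = None,
    backend_factory: Callable[[int], Any] | None = None,
) -> AggregatedConformalPredictor:
    """Train one calibrated classifier per split in ``plan``.

    Member i is fit only on its proper part and calibrated only on its
    calibration part; the nonconformity of a calibration compound with true
    class c is ``1 - p_hat(c | x)``. ``backend_factory(member_index)`` can
    supply arbitrary pre-configured models; otherwise ``make_backend`` is
    used with a per-member derived seed.
    """
    X = features.bits if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must align")
    covered = np.union1d(plan.splits[0][0], plan.splits[0][1])
    if len(covered) != X.shape[0]:
        raise ValueError("split plan does not cover all indices")

    members: list[CalibratedClassifier] = []
    for i, (proper, calib) in enumerate(plan.splits):
        model = (backend_factory(i) if backend_factory is not None
                 else make_backend(backend, seed=seed + i,
                                   **(backend_options or {})))
        try:
            model.fit(X[proper], y[proper])
        except Exception as exc:  # pragma: no cover - backend dependent
            raise RuntimeError(f"training failed for member {i}") from exc
        p1 = _proba1(model, X[calib])
        y_cal = y[calib]
        members.append(CalibratedClassifier(
            backend=model,
            calib_scores_1=1.0 - p1[y_cal == 1],
            calib_scores_0=p1[y_cal == 0],  # 1 - p_hat(0|x) = p_hat(1|x)
        ))
    fp = features.config if isinstance(features, FeatureMatrix) else None
    meta = {"k": plan.k, "seed": seed, "backend": backend,
            "proper_fraction": plan.proper_fraction,
            "n_train": int(X.shape[0]),
            "n_active": int((y == 1).sum())}
    return AggregatedConformalPredictor(members=members, fingerprint=fp,
                                        threshold=threshold, metadata=meta)


def pvalue_from_calibration(alpha: float | np.ndarray,
                            calib_scores: np.ndarray) -> float | np.ndarray:
    """Rank-based conformal p-value of nonconformity ``alpha``.

    ``p = (#{calibration scores >= alpha} + 1) / (n + 1)``. Accepts a scalar
    or an array of alphas; ``calib_scores`` must be sorted ascending.
    """
    calib = np.asarray(calib_scores, dtype=float)
    if calib.size == 0:
        raise ValueError("calibration score list is empty")
    a = np.asarray(alpha, dtype=float)
    n_ge = calib.size - np.searchsorted(calib, a, side="left")
    p = (n_ge + 1.0) / (calib.size + 1.0)
    return float(p) if np.isscalar(alpha) else p


def predict_pvalues(predictor: AggregatedConformalPredictor,
                    features: FeatureMatrix | np.ndarray) -> list[PValuePair]:
    """Median-aggregated (P1, P0) pairs for a batch of compounds."""
    p1, p0 = predict_pvalue_arrays(predictor, features)
    return [PValuePair(p1=float(a), p0=float(b)) for a, b in zip(p1, p0)]


def predict_pvalue_arrays(predictor: AggregatedConformalPredictor,
                          features: FeatureMatrix | np.ndarray,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized form of :func:`predict_pvalues`: two (n,) arrays."""
    X = features.bits if isinstance(features, FeatureMatrix) else np.asarray(features)
    if (predictor.fingerprint is not None
            and isinstance(features, FeatureMatrix)
            and features.config is not None
            and features.config != predictor.fingerprint):
        raise ValueError("feature space does not match training "
                         f"({features.config} != {predictor.fingerprint})")
    p1s = np.empty((predictor.k, X.shape[0]))
    p0s = np.empty((predictor.k, X.shape[0]))
    for i, member in enumerate(predictor.members):
        prob1 = _proba1(member.backend, X)
        p1s[i] = pvalue_from_calibration(1.0 - prob1, member.calib_scores_1)
        p0s[i] = pvalue_from_calibration(prob1, member.calib_scores_0)
    return np.median(p1s, axis=0), np.median(p0s, axis=0)


def assign_prediction_set(pair: PValuePair, epsilon: float) -> PredictionSet:
    """Four-way set at significance ``epsilon``: class c included iff p_c > epsilon."""
    _check_epsilon(epsilon)
    in1 = pair.p1 > epsilon
    in0 = pair.p0 > epsilon
    if in1 and in0:
        return PredictionSet.BOTH
    if in1:
        return PredictionSet.ACTIVE
    if in0:
        return PredictionSet.INACTIVE
    return PredictionSet.NULL


def assign_prediction_sets(p1: np.ndarray, p0: np.ndarray,
                           epsilon: float) -> np.ndarray:
    """Vectorized set assignment; returns an object array of PredictionSet."""
    _check_epsilon(epsilon)
    p1 = np.asarray(p1, float)
    p0 = np.asarray(p0, float)
    out = np.empty(p1.shape, dtype=object)
    in1 = p1 > epsilon
    in0 = p0 > epsilon
    out[in1 & in0] = PredictionSet.BOTH
    out[in1 & ~in0] = PredictionSet.ACTIVE
    out[~in1 & in0] = PredictionSet.INACTIVE
    out[~in1 & ~in0] = PredictionSet.NULL
    return out


def _check_epsilon(epsilon: float) -> None:
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")


def find_epsilon_opt(pairs: Sequence[PValuePair] | tuple[np.ndarray, np.ndarray],
                     grid_step: float = 0.01) -> float:
    """Significance level maximizing the number of single-label predictions.

    Scans a uniform grid (default step 0.01 on (0, 1)); ties break toward
    the smaller epsilon. The count of single-label (active-only or
    inactive-only) assignments at each epsilon is the efficiency numerator.
    """
    if not 0.0 < grid_step <= 0.5:
        raise ValueError("grid_step must lie in (0, 0.5]")
    if isinstance(pairs, tuple):
        p1, p0 = (np.asarray(a, float) for a in pairs)
    else:
        p1 = np.array([p.p1 for p in pairs])
        p0 = np.array([p.p0 for p in pairs])
    if p1.size == 0:
        raise ValueError("no p-value pairs given")
    grid = np.arange(grid_step, 1.0, grid_step)
    best_eps, best_count = None, -1
    for eps in grid:
        single = int(np.sum((p1 > eps) != (p0 > eps)))
        if single > best_count:
            best_eps, best_count = float(eps), single
    return float(best_eps)


# ---------------------------------------------------------------------------
# serialization

_MANIFEST = "manifest.json"


def save_predictor(predictor: AggregatedConformalPredictor,
                   path: str | Path) -> None:
    """Serialize to a directory bundle: per-member model files plus a
    plain-text manifest holding calibration scores at full precision."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "k": predictor.k,
        "threshold": predictor.threshold,
        "fingerprint": (None if predictor.fingerprint is None else
                        {"radius": predictor.fingerprint.radius,
                         "n_bits": predictor.fingerprint.n_bits}),
        "metadata": predictor.metadata,
        "members": [],
    }
    for i, member in enumerate(predictor.members):
        model_file = f"member_{i:03d}.joblib"
        joblib.dump(member.backend, path / model_file)
        manifest["members"].append({
            "model_file": model_file,
            "calib_scores_1": [float(v) for v in member.calib_scores_1],
            "calib_scores_0": [float(v) for v in member.calib_scores_0],
        })
    with open(path / _MANIFEST, "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_predictor(path: str | Path) -> AggregatedConformalPredictor:
    path = Path(path)
    with open(path / _MANIFEST) as fh:
        manifest = json.load(fh)
    members = []
    for entry in manifest["members"]:
        members.append(CalibratedClassifier(
            backend=joblib.load(path / entry["model_file"]),
            calib_scores_1=np.array(entry["calib_scores_1"]),
            calib_scores_0=np.array(entry["calib_scores_0"])))
    fp = manifest["fingerprint"]
    return AggregatedConformalPredictor(
        members=members,
        fingerprint=None if fp is None else FingerprintConfig(**fp),
        threshold=manifest["threshold"],
        metadata=manifest["metadata"])


def bundle_digest(path: str | Path) -> str:
    """SHA-256 over the bundle's files (sorted), for reproducibility checks."""
    path = Path(path)
    h = hashlib.sha256()
    for f in sorted(p for p in path.iterdir() if p.is_file()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()
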