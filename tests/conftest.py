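import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cpscreen.conformal import fit_conformal_ensemble, predict_pvalue_arrays
from cpscreen.labeling import (ScoredLibrary, assign_labels,
                               compute_score_threshold, make_split_plan)
from cpscreen.synthetic import SyntheticScreenConfig, generate_screen

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_screen():
    """6k-compound synthetic screen, split in half for train/test."""
    return generate_screen(SyntheticScreenConfig(n_compounds=6000, seed=11))


@pytest.fixture(scope="session")
def small_fit(small_screen):
    """Conformal ensemble (fast logistic backend) on the small screen.

    Conformal validity does not depend on backend quality, so the linear
    model is enough for every statistical check that is not about
    enrichment strength.
    """
    screen = small_screen
    n_train = 3000
    train_scores = screen.scores[:n_train]
    threshold = compute_score_threshold(train_scores, 0.05)
    train = ScoredLibrary(ids=screen.ids[:n_train], scores=train_scores)
    train = assign_labels(train, threshold)
    plan = make_split_plan(train.labels, k=5, proper_fraction=0.8, seed=3)
    predictor = fit_conformal_ensemble(
        screen.features.subset(range(n_train)), train.labels, plan,
        backend="logistic", seed=3, threshold=threshold)
    test_features = screen.features.subset(range(n_train, len(screen)))
    p1, p0 = predict_pvalue_arrays(predictor, test_features)
    truth = (screen.scores[n_train:] < threshold).astype(int)
    return {
        "screen": screen,
        "threshold": threshold,
        "predictor": predictor,
        "p1": p1,
        "p0": p0,
        "truth": truth,
        "test_scores": screen.scores[n_train:],
        "test_ids": screen.ids[n_train:],
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_919)
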