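import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cpscreen.chem_io import FeatureMatrix, FingerprintConfig
from cpscreen.conformal import (AggregatedConformalPredictor,
                                CalibratedClassifier, PredictionSet,
                                PValuePair, assign_prediction_set,
                                assign_prediction_sets, find_epsilon_opt,
                                fit_conformal_ensemble, load_predictor,
                                predict_pvalue_arrays, predict_pvalues,
                                pvalue_from_calibration, save_predictor)
from cpscreen.labeling import make_split_plan


def brute_force_pvalue(alpha, calib):
    return (sum(1 for c in calib if c >= alpha) + 1) / (len(calib) + 1)


class _StubBackend:
    """Backend returning fixed class-1 probabilities, keyed by row hash."""

    classes_ = np.array([0, 1])

    def __init__(self, proba1):
        self.proba1 = np.asarray(proba1, dtype=float)

    def predict_proba(self, X):
        p1 = self.proba1[: len(X)]
        return np.column_stack([1 - p1, p1])


def _stub_predictor(member_probas, calib1, calib0):
    members = [CalibratedClassifier(backend=_StubBackend(p),
                                    calib_scores_1=calib1,
                                    calib_scores_0=calib0)
               for p in member_probas]
    return AggregatedConformalPredictor(members=members)


class TestPValue:
    def test_interior_alpha(self):
        assert pvalue_from_calibration(0.25, np.array([0.1, 0.2, 0.3, 0.4])) \
            == pytest.approx(3 / 5)

    def test_alpha_above_all_scores_gives_minimal_rank(self):
        calib = np.array([0.1, 0.2, 0.3, 0.4])
        assert pvalue_from_calibration(0.9, calib) == pytest.approx(1 / 5)

    def test_alpha_at_or_below_all_scores_gives_one(self):
        calib = np.array([0.1, 0.2, 0.3, 0.4])
        assert pvalue_from_calibration(0.1, calib) == 1.0
        assert pvalue_from_calibration(0.0, calib) == 1.0

    def test_empty_calibration_raises(self):
        with pytest.raises(ValueError):
            pvalue_from_calibration(0.5, np.array([]))

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=60),
           st.floats(0, 1, allow_nan=False))
    def test_matches_brute_force_count(self, calib, alpha):
        calib_sorted = np.sort(calib)
        assert pvalue_from_calibration(alpha, calib_sorted) == pytest.approx(
            brute_force_pvalue(alpha, calib))

    def test_vectorized_matches_scalar(self, rng):
        calib = np.sort(rng.random(30))
        alphas = rng.random(20)
        vec = pvalue_from_calibration(alphas, calib)
        assert np.allclose(vec, [pvalue_from_calibration(a, calib)
                                 for a in alphas])


class TestAggregation:
    def test_median_of_five_members(self):
        probas = [0.9, 0.8, 0.7, 0.6, 0.5]  # distinct p1-hat per member
        calib1 = np.linspace(0.01, 0.99, 9)
        calib0 = np.linspace(0.01, 0.99, 9)
        pred = _stub_predictor([[p] for p in probas], calib1, calib0)
        fm = np.zeros((1, 4))
        p1, p0 = predict_pvalue_arrays(pred, fm)
        member_p1 = [brute_force_pvalue(1 - p, calib1) for p in probas]
        member_p0 = [brute_force_pvalue(p, calib0) for p in probas]
        assert p1[0] == pytest.approx(np.median(member_p1))
        assert p0[0] == pytest.approx(np.median(member_p0))

    def test_single_member_aggregation_is_identity(self):
        pred = _stub_predictor([[0.7]], np.array([0.2, 0.5]),
                               np.array([0.3, 0.6]))
        pairs = predict_pvalues(pred, np.zeros((1, 2)))
        assert pairs[0].p1 == brute_force_pvalue(0.3, [0.2, 0.5])
        assert pairs[0].p0 == brute_force_pvalue(0.7, [0.3, 0.6])

    def test_identical_members_aggregate_to_member_value(self):
        pred = _stub_predictor([[0.7]] * 5, np.array([0.2, 0.5]),
                               np.array([0.3, 0.6]))
        single = _stub_predictor([[0.7]], np.array([0.2, 0.5]),
                                 np.array([0.3, 0.6]))
        np.testing.assert_array_equal(
            predict_pvalue_arrays(pred, np.zeros((1, 2))),
            predict_pvalue_arrays(single, np.zeros((1, 2))))

    def test_even_member_count_uses_mean_of_central_values(self):
        # medians {0.1,0.2,0.3,0.4} -> 0.25 for p1
        calib = np.array([0.5])  # p = 1 if alpha <= 0.5 else 0.5
        probas = [[0.2], [0.4], [0.6], [0.8]]
        pred = _stub_predictor(probas, calib, calib)
        p1, _ = predict_pvalue_arrays(pred, np.zeros((1, 1)))
        member_p1 = [brute_force_pvalue(1 - p[0], calib) for p in probas]
        assert p1[0] == pytest.approx(
            (sorted(member_p1)[1] + sorted(member_p1)[2]) / 2)


class TestPredictionSets:
    def test_confident_active_at_headline_significance(self):
        pair = PValuePair(p1=0.5, p0=0.01)
        assert assign_prediction_set(pair, 0.12) is PredictionSet.ACTIVE

    def test_both_when_both_exceed(self):
        assert assign_prediction_set(PValuePair(1, 1), 0.5) \
            is PredictionSet.BOTH

    def test_null_when_neither_exceeds(self):
        assert assign_prediction_set(PValuePair(0, 0), 0.05) \
            is PredictionSet.NULL

    def test_epsilon_zero_yields_both_for_everyone(self, rng):
        p1 = np.maximum(rng.random(50), 1e-9)
        p0 = np.maximum(rng.random(50), 1e-9)
        sets = assign_prediction_sets(p1, p0, 0.0)
        assert all(s is PredictionSet.BOTH for s in sets)

    def test_every_compound_gets_exactly_one_set(self, rng):
        p1, p0 = rng.random(200), rng.random(200)
        for eps in (0.01, 0.1, 0.5):
            sets = assign_prediction_sets(p1, p0, eps)
            assert all(isinstance(s, PredictionSet) for s in sets)

    def test_raising_epsilon_never_moves_null_to_both(self, rng):
        p1, p0 = rng.random(300), rng.random(300)
        lo = assign_prediction_sets(p1, p0, 0.05)
        hi = assign_prediction_sets(p1, p0, 0.2)
        was_null = np.array([s is PredictionSet.NULL for s in lo])
        now_both = np.array([s is PredictionSet.BOTH for s in hi])
        assert not np.any(was_null & now_both)


class TestEpsilonOpt:
    def test_all_certain_pairs_tie_break_to_smallest_grid_value(self):
        pairs = [PValuePair(1.0, 0.0)] * 10
        assert find_epsilon_opt(pairs) == pytest.approx(0.01)

    def test_matches_exhaustive_scan(self, rng):
        p1, p0 = rng.random(400), rng.random(400)
        grid = np.arange(0.01, 1.0, 0.01)
        singles = [int(np.sum((p1 > e) != (p0 > e))) for e in grid]
        oracle = float(grid[int(np.argmax(singles))])
        assert find_epsilon_opt((p1, p0)) == pytest.approx(oracle)

    def test_grid_step_bounds(self):
        with pytest.raises(ValueError):
            find_epsilon_opt([PValuePair(1, 0)], grid_step=0.7)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(17)
    n = 400
    y = (np.arange(n) < 80).astype(int)
    X = np.zeros((n, 8))
    X[:, 0] = y + rng.normal(0, 0.05, n)  # almost perfectly separable
    order = rng.permutation(n)
    return X[order], y[order]


class TestFitEnsemble:
    def test_separable_data_gives_small_calibration_nonconformity(
            self, separable):
        X, y = separable
        plan = make_split_plan(y, k=1, seed=0)
        pred = fit_conformal_ensemble(X, y, plan, backend="logistic", seed=0)
        member = pred.members[0]
        # calibration nonconformity = 1 - p_hat(true class); recompute by hand
        proper, calib = plan.splits[0]
        proba1 = member.backend.predict_proba(X[calib])[:, 1]
        expect_1 = np.sort(1 - proba1[y[calib] == 1])
        expect_0 = np.sort(proba1[y[calib] == 0])
        np.testing.assert_allclose(member.calib_scores_1, expect_1)
        np.testing.assert_allclose(member.calib_scores_0, expect_0)
        assert np.median(member.calib_scores_1) < 0.1
        assert np.median(member.calib_scores_0) < 0.1

    def test_identical_seed_and_data_reproduce_calibration_lists(
            self, separable):
        X, y = separable
        plan = make_split_plan(y, k=3, seed=5)
        a = fit_conformal_ensemble(X, y, plan, backend="logistic", seed=5)
        b = fit_conformal_ensemble(X, y, plan, backend="logistic", seed=5)
        for ma, mb in zip(a.members, b.members):
            np.testing.assert_array_equal(ma.calib_scores_1, mb.calib_scores_1)
            np.testing.assert_array_equal(ma.calib_scores_0, mb.calib_scores_0)

    def test_default_member_count_is_five(self, separable):
        X, y = separable
        plan = make_split_plan(y, k=5, seed=1)
        pred = fit_conformal_ensemble(X, y, plan, backend="logistic", seed=1)
        assert pred.k == 5

    def test_serialization_round_trip_reproduces_pvalues(self, separable,
                                                         tmp_path):
        X, y = separable
        plan = make_split_plan(y, k=2, seed=2)
        pred = fit_conformal_ensemble(X, y, plan, backend="logistic", seed=2)
        save_predictor(pred, tmp_path / "bundle")
        back = load_predictor(tmp_path / "bundle")
        np.testing.assert_array_equal(
            np.array(predict_pvalue_arrays(pred, X)),
            np.array(predict_pvalue_arrays(back, X)))

    def test_fingerprint_mismatch_rejected(self, separable):
        X, y = separable
        plan = make_split_plan(y, k=1, seed=0)
        pred = fit_conformal_ensemble(X, y, plan, backend="logistic", seed=0)
        pred.fingerprint = FingerprintConfig(radius=2, n_bits=2048)
        fm = FeatureMatrix(ids=[str(i) for i in range(len(X))],
                           bits=X.astype(np.uint8),
                           config=FingerprintConfig(radius=3, n_bits=1024))
        with pytest.raises(ValueError, match="does not match"):
            predict_pvalue_arrays(pred, fm)


class TestValidityOnExchangeableData:
    def test_single_member_class_conditional_error_bound(self, small_screen):
        """Mondrian guarantee: per-class error rate <= eps + 3 binomial sd."""
        from cpscreen.labeling import (ScoredLibrary, assign_labels,
                                       compute_score_threshold)

        screen = small_screen
        n = 3000
        thr = compute_score_threshold(screen.scores[:n], 0.05)
        train = assign_labels(
            ScoredLibrary(ids=screen.ids[:n], scores=screen.scores[:n]), thr)
        plan = make_split_plan(train.labels, k=1, seed=7)
        pred = fit_conformal_ensemble(screen.features.subset(range(n)),
                                      train.labels, plan, backend="logistic",
                                      seed=7)
        p1, p0 = predict_pvalue_arrays(
            pred, screen.features.subset(range(n, len(screen))))
        truth = (screen.scores[n:] < thr).astype(int)
        for eps in np.arange(0.01, 0.31, 0.01):
            sets = assign_prediction_sets(p1, p0, eps)
            for cls in (1, 0):
                mask = truth == cls
                n_c = int(mask.sum())
                wrong = sum(
                    1 for s, t in zip(sets[mask], truth[mask])
                    if (t == 1 and s in (PredictionSet.INACTIVE,
                                         PredictionSet.NULL))
                    or (t == 0 and s in (PredictionSet.ACTIVE,
                                         PredictionSet.NULL)))
                bound = eps + 3 * np.sqrt(eps * (1 - eps) / n_c)
                assert wrong / n_c <= bound, (
                    f"class {cls} error {wrong / n_c:.3f} > {bound:.3f} "
                    f"at eps={eps:.2f}")

    def test_both_set_shrinks_and_null_set_grows_with_epsilon(self, small_fit):
        """Guaranteed monotonicity: raising eps can only shrink the both set
        (intersection of two shrinking families) and grow the null set."""
        p1, p0 = small_fit["p1"], small_fit["p0"]
        both_sizes, null_sizes = [], []
        for eps in np.arange(0.01, 0.31, 0.01):
            sets = assign_prediction_sets(p1, p0, eps)
            both_sizes.append(sum(1 for s in sets if s is PredictionSet.BOTH))
            null_sizes.append(sum(1 for s in sets if s is PredictionSet.NULL))
        assert both_sizes == sorted(both_sizes, reverse=True)
        assert null_sizes == sorted(null_sizes)
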