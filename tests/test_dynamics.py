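import numpy as np
import pytest

from vmtopics.data_model import CompositionMatrix, DataError
from vmtopics.dynamics import (
    TransitionPair,
    classify_stability,
    evaluate_dominance,
    f1_score_from_counts,
    fit_dominance_model,
    make_transition_pairs,
    predict_from_subcst,
    predict_from_topics,
    representation_error,
)
from vmtopics.lda import TopicModelFit
from vmtopics.reference import ReferenceCentroids, bray_curtis


def _fit(gamma, beta):
    gamma, beta = np.asarray(gamma, float), np.asarray(beta, float)
    return TopicModelFit(
        K=beta.shape[0], beta=beta, gamma=gamma, alpha=0.5, eta=0.01, seed=0,
        n_iterations=1, burn_in=0, log_likelihood=np.zeros(1),
        sample_ids=[f"s{i}" for i in range(len(gamma))],
        taxon_ids=[f"t{j}" for j in range(beta.shape[1])],
    )


BETA = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])


class TestPredict:
    def test_one_hot_returns_beta_row(self):
        fit = _fit([[0, 1, 0]], BETA)
        np.testing.assert_allclose(predict_from_topics(fit).values[0], BETA[1])

    def test_even_mixture_is_mean_of_rows(self):
        fit = _fit([[0.5, 0.5]], BETA[:2])
        np.testing.assert_allclose(predict_from_topics(fit).values[0], BETA[:2].mean(0))

    def test_matches_triple_loop_oracle(self, rng):
        G = rng.dirichlet(np.ones(3), size=6)
        fit = _fit(G, BETA)
        pred = predict_from_topics(fit).values
        oracle = np.zeros((6, 3))
        for i in range(6):
            for j in range(3):
                for k in range(3):
                    oracle[i, j] += G[i, k] * BETA[k, j]
        assert np.abs(pred - oracle).max() < 1e-12

    def test_subcst_prediction_copies_centroid_rows(self):
        cents = ReferenceCentroids(["I-A", "III-A"], ["a", "b"], np.array([[0.9, 0.1], [0.2, 0.8]]))
        pred = predict_from_subcst(["III-A", "I-A", "III-A"], cents)
        np.testing.assert_allclose(pred.values[0], [0.2, 0.8])
        np.testing.assert_allclose(pred.values[1], [0.9, 0.1])
        np.testing.assert_allclose(pred.values[0], pred.values[2])
        np.testing.assert_allclose(pred.values.sum(1), 1.0)

    def test_unknown_label_rejected(self):
        cents = ReferenceCentroids(["I-A"], ["a", "b"], np.array([[0.9, 0.1]]))
        with pytest.raises(DataError):
            predict_from_subcst(["X"], cents)

    def test_consistency_bridge_with_one_hot_assignment(self, rng):
        """Topic prediction equals centroid prediction when β = centroids and γ one-hot."""
        cents = ReferenceCentroids(["I-A", "III-A", "IV-B"], ["a", "b", "c"], BETA)
        z = rng.integers(0, 3, size=10)
        G = np.zeros((10, 3)); G[np.arange(10), z] = 1.0
        fit = _fit(G, BETA)
        pt = predict_from_topics(fit)
        ps = predict_from_subcst([cents.labels[k] for k in z], cents)
        np.testing.assert_allclose(pt.values, ps.values, atol=1e-12)


class TestRepresentationError:
    def _comp(self, vals, ids=None):
        vals = np.asarray(vals, float)
        return CompositionMatrix(ids or [f"s{i}" for i in range(len(vals))],
                                 [f"t{j}" for j in range(vals.shape[1])], vals)

    def test_perfect_prediction_gives_zero(self):
        a = self._comp(np.tile([0.5, 0.5], (5, 1)))
        res = representation_error(a, a, a)
        assert np.allclose(res.bc_topics, 0) and res.mean_difference == 0

    def test_identical_sources_give_half_p(self):
        rng = np.random.default_rng(0)
        a = self._comp(rng.dirichlet(np.ones(3), size=5))
        b = self._comp(rng.dirichlet(np.ones(3), size=5))
        res = representation_error(a, b, b)
        assert res.p_value == pytest.approx(0.5)

    def test_exact_topics_vs_off_subcst_is_significant(self, rng):
        actual = self._comp(rng.dirichlet(np.ones(4), size=50))
        off = actual.values.copy()[:, ::-1]  # systematically wrong
        res = representation_error(actual, actual, self._comp(off))
        assert res.mean_difference > 0 and res.p_value < 0.05

    def test_small_n_refuses_test(self):
        a = self._comp(np.tile([0.5, 0.5], (2, 1)))
        res = representation_error(a, a, a)
        assert res.p_value is None


class TestStability:
    def _series(self, vals):
        vals = np.asarray(vals, float)
        return CompositionMatrix([f"s{i}" for i in range(len(vals))],
                                 [f"t{j}" for j in range(vals.shape[1])], vals)

    def test_constant_series_all_stable(self):
        s = self._series(np.tile([0.6, 0.4], (6, 1)))
        assert classify_stability(s).all()

    def test_alternating_disjoint_all_unstable(self):
        s = self._series([[1, 0], [0, 1]] * 3)
        assert not classify_stability(s).any()

    def test_matches_exhaustive_run_enumeration(self):
        """8-sample series with one jump: flags equal brute force over all windows."""
        vals = np.array([[0.9, 0.1]] * 5 + [[0.1, 0.9]] * 3)
        s = self._series(vals)
        got = classify_stability(s, threshold=0.25, window=5)
        pair_bc = [bray_curtis(vals[i], vals[i + 1]) for i in range(7)]
        expected = np.zeros(8, bool)
        for start in range(4):
            if all(b < 0.25 for b in pair_bc[start:start + 4]):
                expected[start:start + 5] = True
        np.testing.assert_array_equal(got, expected)

    def test_short_series_all_unstable(self):
        s = self._series(np.tile([1.0, 0.0], (3, 1)))
        assert not classify_stability(s).any()

    def test_monotone_in_threshold(self, rng):
        vals = rng.dirichlet(np.ones(3), size=30)
        s = self._series(vals)
        s15 = classify_stability(s, 0.15)
        s25 = classify_stability(s, 0.25)
        s35 = classify_stability(s, 0.35)
        assert (s15 <= s25).all() and (s25 <= s35).all()


class TestTransitionPairs:
    def _pairs(self, lacto_series):
        n = len(lacto_series)
        vals = np.column_stack([lacto_series, 1 - np.asarray(lacto_series)])
        comp = CompositionMatrix([f"s{i}" for i in range(n)], ["Lacto", "Other"], vals)
        gamma = np.tile([1.0], (n, 1))
        return make_transition_pairs(comp, ["p1"] * n, gamma, {"Lacto"})

    def test_loss_pair(self):
        (p,) = self._pairs([0.8, 0.3])
        assert p.current_dominant and p.outcome_loss

    def test_retained_dominance(self):
        (p,) = self._pairs([0.8, 0.9])
        assert p.current_dominant and not p.outcome_loss

    def test_non_dominant_pair_flagged(self):
        (p,) = self._pairs([0.4, 0.3])
        assert not p.current_dominant

    def test_no_cross_participant_pairs(self):
        vals = np.tile([0.8, 0.2], (4, 1))
        comp = CompositionMatrix([f"s{i}" for i in range(4)], ["Lacto", "O"], vals)
        pairs = make_transition_pairs(comp, ["a", "a", "b", "b"], np.ones((4, 1)), {"Lacto"})
        assert len(pairs) == 2

    def test_empty_lacto_set_rejected(self):
        comp = CompositionMatrix(["s0", "s1"], ["A", "B"], np.tile([0.5, 0.5], (2, 1)))
        with pytest.raises(DataError):
            make_transition_pairs(comp, ["p", "p"], np.ones((2, 1)), set())


def _toy_pairs(rng, n=80, beta0=-1.0, beta1=3.0):
    pairs = []
    for i in range(n):
        x = rng.uniform(0, 1)
        p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        pairs.append(TransitionPair(
            participant=f"p{i % 8}", current_id=f"c{i}", next_id=f"n{i}",
            features_gamma=np.array([x, 1 - x]), subcst_label="I-A" if x < 0.5 else "IV-B",
            current_dominant=True, outcome_loss=bool(rng.random() < p)))
    return pairs


class TestDominanceModel:
    def test_separable_data_perfectly_ordered(self):
        pairs = []
        for i in range(20):
            x = i / 19
            pairs.append(TransitionPair("p", f"c{i}", f"n{i}", np.array([x, 1 - x]),
                                        None, True, x > 0.5))
        m = fit_dominance_model(pairs, "topics")
        probs = m.predict_proba(np.array([[p.features_gamma[0]] for p in pairs]))[:, 1]
        y = np.array([p.outcome_loss for p in pairs])
        assert probs[y].min() > probs[~y].max()  # AUC = 1 on train

    def test_minority_weight_one_equals_unweighted(self, rng):
        pairs = _toy_pairs(rng)
        import statsmodels.api as sm

        m = fit_dominance_model(pairs, "topics", minority_weight=1.0)
        X = np.array([[p.features_gamma[0]] for p in pairs])
        y = np.array([p.outcome_loss for p in pairs], dtype=int)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert m.coef_[0][0] == pytest.approx(ref.params[1], abs=1e-4)
        assert m.intercept_[0] == pytest.approx(ref.params[0], abs=1e-4)

    def test_weighted_fit_matches_grid_search_oracle(self, rng):
        """10× minority weighting equals the argmax of the weighted log-likelihood."""
        pairs = _toy_pairs(rng, n=60)
        m = fit_dominance_model(pairs, "topics", minority_weight=10.0)
        X = np.array([p.features_gamma[0] for p in pairs])
        y = np.array([p.outcome_loss for p in pairs], dtype=int)
        w = np.where(y == int(np.argmin(np.bincount(y))), 10.0, 1.0)

        def wll(b0, b1):
            eta = b0 + b1 * X
            return np.sum(w * (y * eta - np.log1p(np.exp(eta))))

        b0_hat, b1_hat = m.intercept_[0], m.coef_[0][0]
        best = wll(b0_hat, b1_hat)
        for db0 in (-1e-3, 1e-3):
            for db1 in (-1e-3, 1e-3):
                assert wll(b0_hat + db0, b1_hat + db1) <= best + 1e-9

    def test_single_class_rejected(self):
        pairs = [TransitionPair("p", "c", "n", np.array([0.5, 0.5]), None, True, False)] * 5
        with pytest.raises(DataError):
            fit_dominance_model(pairs, "topics")


class TestEvaluation:
    def test_f1_formula(self):
        assert f1_score_from_counts(3, 1, 5) == pytest.approx(0.5)
        assert f1_score_from_counts(0, 0, 4) == 0.0  # all-negative convention
        assert f1_score_from_counts(4, 0, 0) == 1.0

    def test_perfect_classifier_scores_one(self, rng):
        pairs = []
        for i in range(200):
            x = rng.uniform()
            pairs.append(TransitionPair(f"p{i % 10}", f"c{i}", f"n{i}",
                                        np.array([x, 1 - x]), "I-A" if x < 0.5 else "IV-B",
                                        True, x > 0.5))
        res = evaluate_dominance(pairs, n_repeats=3, seed=1)
        topics = res[(res.source == "topics") & res.valid]
        assert (topics.f1 == 1.0).all()

    def test_needs_two_participants(self):
        pairs = [TransitionPair("p", f"c{i}", f"n{i}", np.array([0.5, 0.5]), "I-A", True, i % 2 == 0)
                 for i in range(6)]
        with pytest.raises(DataError):
            evaluate_dominance(pairs)
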