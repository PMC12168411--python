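"""Topic pipeline: LDA inference, fold-in, forests, CV, candidate selection."""

import numpy as np
import pytest

from plaquetopics import (
    CVSpec,
    GenusCountTable,
    HyperGrid,
    cv_evaluate,
    extract_candidate_topic,
    fit_lda,
    fit_rf,
    infer_theta,
    select_best,
    topic_share_all_visits,
)


def _two_block_corpus(rng, n_per=30, noise=0):
    """Samples drawn from either of two disjoint single-genus communities."""
    X = np.zeros((2 * n_per, 4), dtype=np.int64)
    X[:n_per, 0] = rng.integers(200, 400, n_per)
    X[n_per:, 1] = rng.integers(200, 400, n_per)
    X[:, 2] += noise
    return X


class TestFitLda:
    def test_separable_corpus_recovers_pure_topics(self, rng):
        X = _two_block_corpus(rng)
        model = fit_lda(X, K=2, seed=1)
        tops = model.phi.argmax(axis=1)
        assert sorted(tops.tolist()) == [0, 1]
        assert (model.phi.max(axis=1) > 0.95).all()

    def test_k1_matches_smoothed_pooled_frequencies(self, rng):
        X = rng.integers(0, 40, size=(20, 6)).astype(np.int64)
        model = fit_lda(X, K=1, eta=0.01, seed=2)
        pooled = (X.sum(axis=0) + 0.01) / (X.sum() + 0.01 * 6)
        assert np.allclose(model.phi[0], pooled, atol=1e-6)

    def test_same_seed_bit_identical(self, rng):
        X = rng.integers(0, 30, size=(25, 10)).astype(np.int64)
        m1 = fit_lda(X, K=3, seed=7)
        m2 = fit_lda(X, K=3, seed=7)
        assert np.array_equal(m1.phi, m2.phi)

    def test_phi_independent_of_heldout_content(self, rng):
        """Leakage-safety: training phi never sees the held-out fold."""
        train = rng.integers(0, 30, size=(30, 8)).astype(np.int64)
        m1 = fit_lda(train, K=3, seed=5)
        held_a = rng.integers(0, 30, size=(10, 8)).astype(np.int64)
        infer_theta(m1, held_a)
        m2 = fit_lda(train, K=3, seed=5)
        held_b = rng.integers(0, 999, size=(4, 8)).astype(np.int64)
        infer_theta(m2, held_b)
        assert np.array_equal(m1.phi, m2.phi)

    def test_k_exceeding_genera_rejected(self, rng):
        X = rng.integers(1, 5, size=(10, 3)).astype(np.int64)
        with pytest.raises(ValueError, match="exceeds"):
            fit_lda(X, K=4)
        with pytest.raises(ValueError, match="samples"):
            fit_lda(X[:2], K=3)


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(3)
    X = _two_block_corpus(rng)
    return fit_lda(X, K=2, seed=1)


class TestInferTheta:

    def test_all_zero_sample_gets_prior_mean(self, model):
        theta = infer_theta(model, np.zeros((1, 4)))
        assert np.allclose(theta[0], [0.5, 0.5], atol=1e-12)

    def test_topic_pure_sample_concentrates(self, model, rng):
        k = 0
        counts = rng.multinomial(100_000, model.phi[k] / model.phi[k].sum())
        theta = infer_theta(model, counts)
        assert theta[0, k] > 0.9

    def test_doubling_counts_leaves_theta_stable(self, model, rng):
        counts = rng.multinomial(5000, np.array([0.5, 0.3, 0.1, 0.1]))
        t1 = infer_theta(model, counts)
        t2 = infer_theta(model, 2 * counts)
        assert np.allclose(t1, t2, atol=1e-3)

    def test_rows_on_simplex(self, model, rng):
        X = rng.integers(0, 50, size=(12, 4))
        theta = infer_theta(model, X)
        assert np.allclose(theta.sum(axis=1), 1.0, atol=1e-9)
        assert (theta >= 0).all()

    def test_genus_mismatch_rejected(self, model):
        table = GenusCountTable(["a"], ["x1", "x2"], np.array([[1, 2]]))
        with pytest.raises(ValueError, match="genus set mismatch"):
            infer_theta(model, table)


class TestFitRf:
    def test_constant_target(self, rng):
        theta = rng.dirichlet(np.ones(4), 30)
        forest, imp = fit_rf(theta, np.full(30, 7.0), trees=100, seed=0)
        assert np.allclose(imp, 0.0)
        assert np.allclose(forest.predict(theta[:3]), 7.0)

    def test_informative_feature_wins(self, rng):
        theta = rng.dirichlet(np.ones(5), 150)
        y = 100 * theta[:, 2] + rng.normal(0, 1, 150)
        _, imp = fit_rf(theta, y, trees=300, mtry=2, seed=0)
        assert imp.argmax() == 2

    def test_sample_order_invariance_with_ids(self, rng):
        theta = rng.dirichlet(np.ones(4), 40)
        y = rng.normal(size=40)
        ids = [f"s{i:02d}" for i in range(40)]
        _, imp1 = fit_rf(theta, y, trees=100, seed=3, sample_ids=ids)
        perm = rng.permutation(40)
        _, imp2 = fit_rf(
            theta[perm], y[perm], trees=100, seed=3, sample_ids=[ids[i] for i in perm]
        )
        assert np.array_equal(imp1, imp2)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_rf(np.ones((1, 2)), np.ones(1))


class TestGridAndSelection:
    def test_grid_validation(self):
        with pytest.raises(ValueError, match="empty"):
            HyperGrid(trees=()).validate()
        assert HyperGrid().n_combinations == 4 * 3 * 4 * 6

    def test_single_combination_single_row(self, small_cohort):
        _, dataset, _ = small_cohort
        base = dataset.baseline()
        grid = HyperGrid(trees=(100,), mtry=(2,), min_node=(5,), K=(3,))
        res = cv_evaluate(
            base.counts,
            base.metadata["oleary_pct"].to_numpy(float),
            base.metadata["subject_id"].to_numpy(),
            grid,
            CVSpec(n_folds=3, seed=1),
        )
        assert len(res) == 1

    def test_select_best_tie_breaks(self):
        import pandas as pd

        df = pd.DataFrame(
            [
                {"K": 20, "trees": 500, "mtry": 5, "min_node": 1, "mean_cv_rmse": 1.0},
                {"K": 10, "trees": 900, "mtry": 5, "min_node": 1, "mean_cv_rmse": 1.0},
                {"K": 10, "trees": 700, "mtry": 5, "min_node": 1, "mean_cv_rmse": 1.0},
                {"K": 10, "trees": 700, "mtry": 5, "min_node": 1, "mean_cv_rmse": 2.0},
            ]
        )
        assert select_best(df) == {"K": 10, "trees": 700, "mtry": 5, "min_node": 1}

    def test_monotone_rmse_prefers_smallest(self):
        import pandas as pd

        df = pd.DataFrame(
            [{"K": k, "trees": 500, "mtry": 5, "min_node": 1, "mean_cv_rmse": k * 1.0}
             for k in (5, 10, 15)]
        )
        assert select_best(df)["K"] == 5


class TestEndToEnd:
    def test_noiseless_planted_signal_gives_small_cv_error(self, small_cohort):
        """When y is a noiseless function of a topic share, CV RMSE << sd(y)."""
        _, dataset, truth = small_cohort
        base = dataset.baseline()
        base_idx = [truth.sample_ids.index(s) for s in base.counts.sample_ids]
        y = 100 * truth.theta_true[base_idx, truth.planted_topic_index]
        grid = HyperGrid(trees=(300,), mtry=(2,), min_node=(2,), K=(4,))
        res = cv_evaluate(
            base.counts, y, base.metadata["subject_id"].to_numpy(), grid,
            CVSpec(n_folds=5, seed=2), base_seed=2,
        )
        assert res["mean_cv_rmse"].iloc[0] < 0.2 * y.std()

    def test_shuffled_labels_give_chance_error(self, small_cohort, rng):
        _, dataset, _ = small_cohort
        base = dataset.baseline()
        y = base.metadata["oleary_pct"].to_numpy(float).copy()
        rng.shuffle(y)
        grid = HyperGrid(trees=(300,), mtry=(2,), min_node=(5,), K=(4,))
        res = cv_evaluate(
            base.counts, y, base.metadata["subject_id"].to_numpy(), grid,
            CVSpec(n_folds=5, seed=3), base_seed=3,
        )
        assert abs(res["mean_cv_rmse"].iloc[0] - y.std()) < 0.3 * y.std()

    def test_candidate_is_the_coupled_topic(self):
        """Minimal two-topic cohort: one plaque-coupled topic, one null topic;
        the pipeline must select the coupled one."""
        from plaquetopics import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(
            n_subjects=100, n_placebo=50, n_genera=20, k_true=2,
            theta_concentration=1.0, beta_plaque=np.log(1.45),
            library_size_median=4000, rng_seed=31,
        )
        dataset, truth = simulate_cohort(cfg)
        base = dataset.baseline()
        y = base.metadata["oleary_pct"].to_numpy(float)
        # fitted K=3: with K=2 the two shares are exactly collinear
        # (theta_0 = 1 - theta_1) and importance cannot separate them
        cand, model = extract_candidate_topic(
            base.counts, y, {"K": 3, "trees": 300, "mtry": 2, "min_node": 5}, seed=4
        )
        planted = truth.phi_true[truth.planted_topic_index]
        fitted = cand.genus_contributions
        cos = planted @ fitted / np.sqrt((planted @ planted) * (fitted @ fitted))
        assert cos > 0.9
        dom = {f"g{i + 1:03d}" for i in (0, 1)}
        assert set(cand.top_genera(2)) == dom

    def test_topic_shares_all_visits(self, small_cohort):
        _, dataset, truth = small_cohort
        base = dataset.baseline()
        y = base.metadata["oleary_pct"].to_numpy(float)
        cand, model = extract_candidate_topic(
            base.counts, y, {"K": 4, "trees": 100, "mtry": 2, "min_node": 5}, seed=4
        )
        shares = topic_share_all_visits(model, dataset, cand.topic_index)
        assert len(shares) == dataset.counts.n_samples
        assert ((shares >= 0) & (shares <= 1)).all()
        # baseline fold-in agrees with the training-time proportions
        train_theta = infer_theta(model, base.counts)[:, cand.topic_index]
        np.testing.assert_allclose(
            shares.loc[base.counts.sample_ids].to_numpy(), train_theta, atol=1e-6
        )
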