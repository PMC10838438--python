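"""Bayesian LASSO classifier and the repeated-split protocol."""

import numpy as np
import pandas as pd
import pytest

from bulbarvoice import CohortConfig, generate_cohort
from bulbarvoice.model import (
    ModelConfig,
    PosteriorFit,
    compute_auroc,
    fit_lasso_logistic,
    make_splits,
    predict_probability,
    run_binary_comparison,
    standardize_features,
    stratify_cohort,
)


def toy_fit(alpha, beta, names=("x0",)):
    alpha = np.asarray(alpha, float)
    beta = np.atleast_2d(np.asarray(beta, float))
    return PosteriorFit(alpha, beta, tuple(names),
                        np.zeros((alpha.size, 1)), 1.0, True, ModelConfig())


class TestStratify:
    def test_cutoff(self):
        df = pd.DataFrame({
            "group": ["ALS", "ALS", "ALS", "control"],
            "frs_bulb": [11, 10, np.nan, np.nan],
        })
        s = stratify_cohort(df)
        assert list(s) == ["ALS-E", "ALS-L", "ALS-unknown", "control"]

    def test_out_of_range_rejected(self):
        df = pd.DataFrame({"group": ["ALS"], "frs_bulb": [13]})
        with pytest.raises(ValueError, match=r"\[0, 12\]"):
            stratify_cohort(df)


class TestSplits:
    def test_half_split_exhaustive(self):
        y = np.array([0] * 24 + [1] * 22)
        plans = make_splits(y, n_reps=10, seed=1)
        assert len(plans) == 10
        for p in plans:
            assert p.train_idx.size == 23 and p.test_idx.size == 23
            assert np.intersect1d(p.train_idx, p.test_idx).size == 0
            union = np.union1d(p.train_idx, p.test_idx)
            assert np.array_equal(union, np.arange(46))
            # both classes in both halves
            assert 0 < y[p.train_idx].sum() < p.train_idx.size
            assert 0 < y[p.test_idx].sum() < p.test_idx.size

    def test_deterministic_and_varied(self):
        y = np.array([0] * 20 + [1] * 20)
        a = make_splits(y, seed=7)
        b = make_splits(y, seed=7)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.train_idx, pb.train_idx)
        distinct = {tuple(p.train_idx) for p in a}
        assert len(distinct) >= 2

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            make_splits(np.array([0, 0, 0, 1]))


class TestStandardize:
    def test_train_moments(self):
        rng = np.random.default_rng(0)
        tr = pd.DataFrame(rng.normal(5, 3, size=(30, 4)), columns=list("abcd"))
        te = pd.DataFrame(rng.normal(5, 3, size=(10, 4)), columns=list("abcd"))
        tr_t, te_t, rec = standardize_features(tr, te)
        assert np.allclose(tr_t.mean(), 0, atol=1e-10)
        assert np.allclose(tr_t.var(ddof=0), 1, atol=1e-10)

    def test_shifted_test_column(self):
        rng = np.random.default_rng(1)
        tr = pd.DataFrame({"a": rng.normal(size=50)})
        te = tr + 2.0
        _, te_t, rec = standardize_features(tr, te)
        sd = tr["a"].std(ddof=0)
        assert te_t["a"].mean() == pytest.approx(2.0 / sd, abs=1e-10)

    def test_constant_column_dropped(self):
        tr = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        te = pd.DataFrame({"a": np.ones(4), "b": np.arange(4.0)})
        tr_t, te_t, rec = standardize_features(tr, te)
        assert "a" not in tr_t.columns and "a" in rec.dropped

    def test_imputation_uses_train_median(self):
        tr = pd.DataFrame({"a": [1.0, 2.0, 3.0, np.nan]})
        te = pd.DataFrame({"a": [np.nan]})
        tr_t, te_t, rec = standardize_features(tr, te)
        # test NaN imputed with train median (2.0), then standardized
        assert te_t["a"].iloc[0] == pytest.approx(
            (2.0 - tr["a"].fillna(2.0).mean()) / tr["a"].fillna(2.0).std(ddof=0)
        )


class TestAuroc:
    def test_hand_example(self):
        assert compute_auroc(np.array([0.9, 0.8, 0.4, 0.3]),
                             np.array([1, 0, 1, 0])) == pytest.approx(0.75)

    def test_perfect_and_ties(self):
        assert compute_auroc(np.array([0.9, 0.8, 0.2, 0.1]),
                             np.array([1, 1, 0, 0])) == 1.0
        assert compute_auroc(np.full(6, 0.5),
                             np.array([1, 0, 1, 0, 1, 0])) == 0.5

    def test_single_class_flagged(self):
        assert np.isnan(compute_auroc(np.array([0.1, 0.2]), np.array([1, 1])))

    def test_matches_pair_counting_oracle(self):
        """Mann-Whitney AUROC equals exhaustive pair counting on 200 instances."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(4, 21))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            oracle = wins / (len(pos) * len(neg))
            assert compute_auroc(s, y) == pytest.approx(oracle, abs=1e-12)


class TestPredict:
    def test_zero_posterior_gives_half(self):
        fit = toy_fit([0.0], [[0.0]])
        assert predict_probability(fit, np.array([[3.0]]))[0] == 0.5

    def test_symmetric_draws_cancel(self):
        fit = toy_fit([0.0, 0.0], [[1.0], [-1.0]])
        assert predict_probability(fit, np.array([[1.0]]))[0] == pytest.approx(0.5)

    def test_monotone_in_feature(self):
        fit = toy_fit([0.0, 0.0], [[1.0], [0.5]])
        p = predict_probability(fit, np.array([[0.0], [1.0], [2.0]]))
        assert p[0] < p[1] < p[2]

    def test_column_mismatch_rejected(self):
        fit = toy_fit([0.0], [[0.0, 0.0]], names=("a", "b"))
        with pytest.raises(ValueError, match="column"):
            predict_probability(fit, np.zeros((2, 3)))


class TestFit:
    def test_recovery_small(self):
        """Single strong coefficient recovered; nulls shrunk; deterministic."""
        rng = np.random.default_rng(0)
        n, J = 150, 5
        X = rng.standard_normal((n, J))
        X = (X - X.mean(0)) / X.std(0)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * X[:, 0]))).astype(float)
        cfg = ModelConfig()
        fit = fit_lasso_logistic(X, y, cfg, seed=5)
        assert fit.converged and fit.max_rhat < 1.01
        med = fit.beta_median
        assert med[0] > 0.5
        assert np.all(np.abs(med[1:]) < 0.4)
        fit2 = fit_lasso_logistic(X, y, cfg, seed=5)
        assert np.array_equal(fit.beta, fit2.beta)

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_lasso_logistic(np.zeros((4, 1)), np.array([0, 1, 2, 1.0]))


@pytest.fixture(scope="module")
def separable_comparison():
    table = generate_cohort(CohortConfig(
        n_control=16, n_als=40, frs_missing_fraction=0.0,
        effect_map={"speech_rate": 1.5, "int_mean": 1.2, "word_dur_mean": -1.5},
        seed=13,
    ))
    res = run_binary_comparison(table, "control_vs_als", ModelConfig(),
                                n_reps=4, seed=3)
    return table, res


class TestComparison:
    def test_structure_and_signal(self, separable_comparison):
        table, res = separable_comparison
        assert len(res.fold_aurocs) == 4
        assert all(0 <= a <= 1 for a in res.fold_aurocs)
        assert res.auroc_mean > 0.7
        assert res.median_coefficients["speech_rate"] > 0
        assert res.median_coefficients["word_dur_mean"] < 0

    def test_protocol_hygiene(self, separable_comparison):
        """Scaler constants and imputation come from train rows only."""
        import hashlib
        from bulbarvoice.manifest import load_manifest
        from bulbarvoice.model import select_contrast

        table, res = separable_comparison
        sub, y = select_contrast(table, "control_vs_als")
        names = list(load_manifest().names)
        for rec in res.fold_records:
            tr = np.asarray(rec["train_idx"])
            te = np.asarray(rec["test_idx"])
            assert np.intersect1d(tr, te).size == 0
            block = sub.iloc[tr][names]
            block = block.fillna(block.median())
            h = hashlib.sha256(
                np.ascontiguousarray(block.to_numpy(), dtype=np.float64).tobytes()
            ).hexdigest()
            assert h == rec["train_hash"]

    def test_deterministic_across_runs(self, separable_comparison):
        table, res = separable_comparison
        res2 = run_binary_comparison(table, "control_vs_als", ModelConfig(),
                                     n_reps=4, seed=3)
        assert res.fold_aurocs == res2.fold_aurocs
        pd.testing.assert_series_equal(res.median_coefficients,
                                       res2.median_coefficients)
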