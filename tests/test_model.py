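"""Tests of the nested cross-validated ridge pipeline and its inference.

The independent oracle is an sklearn re-implementation (StandardScaler +
Ridge, explicit fold loops) evaluated on the identical fold assignment.
"""

import numpy as np
import pandas as pd
import pytest

from netfa import (
    ConnectomePredictiveModel,
    RidgeCVConfig,
    fit_predict_cv,
    run_outcome_family,
)
from netfa._engine import DesignCache, make_folds
from netfa.synthetic import substream


def _toy_problem(rng, n=40, p=5, noise=0.5):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"net::t{i}" for i in range(p)],
                     index=[f"s{i}" for i in range(n)])
    beta = rng.normal(size=p)
    y = pd.Series(X.to_numpy() @ beta + noise * rng.normal(size=n),
                  index=X.index, name="m")
    return X, y


def _replicate_folds(n, cfg):
    """Reproduce the engine's fold construction (same substream draws)."""
    rng = substream(cfg.seed, "folds")
    outer = make_folds(n, cfg.outer_folds, rng)
    inner = []
    for te in outer:
        tr = np.setdiff1d(np.arange(n), te)
        inner.append((tr, te, make_folds(len(tr), cfg.inner_folds, rng)))
    return inner


def _sklearn_nested_cv(X, y, cfg):
    """Naive per-fold sklearn pipeline; the oracle for the fast engine."""
    from sklearn.linear_model import Ridge
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    lambdas = cfg.lambda_grid
    preds = np.empty_like(y)
    for tr, te, inner_tests in _replicate_folds(len(y), cfg):
        mse = np.zeros(len(lambdas))
        for val_pos in inner_tests:
            sub_pos = np.setdiff1d(np.arange(len(tr)), val_pos)
            Xs, Xv = X[tr][sub_pos], X[tr][val_pos]
            ys, yv = y[tr][sub_pos], y[tr][val_pos]
            scaler = StandardScaler().fit(Xs)
            for li, lam in enumerate(lambdas):
                model = Ridge(alpha=lam).fit(scaler.transform(Xs), ys)
                pv = model.predict(scaler.transform(Xv))
                mse[li] += np.mean((pv - yv) ** 2)
        best = lambdas[int(np.argmin(mse))]
        scaler = StandardScaler().fit(X[tr])
        model = Ridge(alpha=best).fit(scaler.transform(X[tr]), y[tr])
        preds[te] = model.predict(scaler.transform(X[te]))
    return preds


class TestEngineCorrectness:
    def test_matches_sklearn_pipeline_exactly(self, rng):
        X, y = _toy_problem(rng)
        cfg = RidgeCVConfig(outer_folds=4, inner_folds=3, seed=9,
                            explicit_lambda_grid=tuple(np.logspace(-4, 1, 8)))
        res = fit_predict_cv(X, y, cfg)
        oracle = _sklearn_nested_cv(X, y, cfg)
        np.testing.assert_allclose(res.predicted, oracle, atol=1e-8)

    def test_noiseless_signal_recovered(self, rng):
        X, y = _toy_problem(rng, n=100, p=8, noise=0.0)
        res = fit_predict_cv(X, y, RidgeCVConfig(seed=2))
        assert res.r_observed > 0.99

    def test_deterministic_given_seed(self, rng):
        X, y = _toy_problem(rng)
        cfg = RidgeCVConfig(seed=5, n_permutations=50)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = ConnectomePredictiveModel(X, y, config=cfg).permutation_test()
            r2 = ConnectomePredictiveModel(X, y, config=cfg).permutation_test()
        np.testing.assert_array_equal(r1.predicted, r2.predicted)
        np.testing.assert_array_equal(r1.null_r, r2.null_r)
        np.testing.assert_array_equal(r1.lambda_per_fold, r2.lambda_per_fold)

    def test_affine_rescaling_of_predictor_absorbed(self, rng):
        X, y = _toy_problem(rng)
        res1 = fit_predict_cv(X, y, RidgeCVConfig(seed=3))
        X2 = X.copy()
        X2.iloc[:, 0] = 1000.0 * X2.iloc[:, 0] - 7.5
        res2 = fit_predict_cv(X2, y, RidgeCVConfig(seed=3))
        np.testing.assert_allclose(res1.predicted, res2.predicted, atol=1e-8)

    def test_no_leakage_probe_test_fold_corruption(self, rng):
        # corrupting outcome values in one fold's *test* set must leave that
        # fold's trained artifacts (chosen lambda, predictions) unchanged
        X, y = _toy_problem(rng)
        cfg = RidgeCVConfig(outer_folds=5, inner_folds=4, seed=13)
        cache = DesignCache(X.to_numpy(), cfg)
        fold = cache.outer[0]
        y1 = y.to_numpy().copy()
        y2 = y1.copy()
        y2[fold.test] += 100.0 * rng.normal(size=len(fold.test))
        p1, _, l1 = cache.evaluate(y1)
        p2, _, l2 = cache.evaluate(y2)
        assert l1[0] == l2[0]
        np.testing.assert_array_equal(p1[fold.test], p2[fold.test])

    def test_errors_for_degenerate_inputs(self, rng):
        X, y = _toy_problem(rng, n=8)
        with pytest.raises(ValueError, match="fewer subjects"):
            fit_predict_cv(X, y, RidgeCVConfig(outer_folds=10))
        Xc = X.copy()
        Xc.iloc[:, 2] = 1.0
        with pytest.raises(ValueError, match="constant predictor"):
            fit_predict_cv(Xc, y, RidgeCVConfig(outer_folds=4, inner_folds=3))
        with pytest.raises(ValueError, match="constant outcome"):
            fit_predict_cv(X, pd.Series(1.0, index=X.index),
                           RidgeCVConfig(outer_folds=4, inner_folds=3))

    def test_loocv_via_outer_folds_equal_n(self, rng):
        X, y = _toy_problem(rng, n=25, noise=0.2)
        cfg = RidgeCVConfig(outer_folds=25, inner_folds=5, seed=1,
                            explicit_lambda_grid=(0.1, 1.0))
        res = fit_predict_cv(X, y, cfg)
        assert res.r_observed > 0.8

    def test_pearson_inner_criterion_runs(self, rng):
        X, y = _toy_problem(rng)
        cfg = RidgeCVConfig(outer_folds=4, inner_folds=3, seed=2,
                            inner_criterion="pearson_r")
        assert np.isfinite(fit_predict_cv(X, y, cfg).r_observed)


class TestCovariateControl:
    def _confounded_problem(self, rng, n=60, p=4):
        cov = pd.DataFrame({
            "age": rng.integers(24, 36, n),
            "gender": rng.choice(["f", "m"], n),
            "extraversion": rng.normal(size=n),
        }, index=[f"s{i}" for i in range(n)])
        y = pd.Series(2.0 * cov["extraversion"] + rng.normal(size=n),
                      index=cov.index, name="m")
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"net::t{i}" for i in range(p)],
                         index=cov.index)
        # FA loads on the confounder only: association disappears once
        # extraversion is controlled
        X = X.add(0.8 * cov["extraversion"], axis=0)
        return X, y, cov

    def test_residualization_removes_confounded_association(self, rng):
        X, y, cov = self._confounded_problem(rng)
        naive = fit_predict_cv(X, y, RidgeCVConfig(seed=4))
        controlled = fit_predict_cv(
            X, y, RidgeCVConfig(seed=4, covariate_mode="residualize_outcome"),
            covariates=cov)
        assert naive.r_observed > 0.5
        assert controlled.r_observed < 0.35

    def test_unpenalized_covariates_mode_runs_and_controls(self, rng):
        X, y, cov = self._confounded_problem(rng)
        res = fit_predict_cv(
            X, y, RidgeCVConfig(seed=4, covariate_mode="unpenalized_covariates"),
            covariates=cov)
        # covariate part of the prediction tracks y, but the FA part adds
        # nothing systematic: r should be dominated by the covariate model
        assert res.r_observed > 0.5

    def test_covariate_mode_without_table_rejected(self, rng):
        X, y = _toy_problem(rng)
        with pytest.raises(ValueError, match="covariate"):
            fit_predict_cv(X, y,
                           RidgeCVConfig(covariate_mode="residualize_outcome"))


class TestPermutationInference:
    def test_add_one_boundary_and_raw_convention(self, rng):
        X, y = _toy_problem(rng, n=50, p=4, noise=0.05)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ConnectomePredictiveModel(
                X, y, config=RidgeCVConfig(seed=6)
            ).permutation_test(n_permutations=60)
        # strong signal beats every permutation: p at the add-one boundary
        assert res.p_perm == pytest.approx(1 / 61)
        from netfa.stats import permutation_pvalue
        assert permutation_pvalue(res.r_observed, res.null_r, "raw") == 0.0

    def test_small_permutation_count_warns(self, rng):
        X, y = _toy_problem(rng)
        with pytest.warns(UserWarning, match="permutations"):
            ConnectomePredictiveModel(
                X, y, config=RidgeCVConfig(seed=1)
            ).permutation_test(n_permutations=20)

    def test_null_r_centered_near_zero(self, rng):
        X, y = _toy_problem(rng, n=60, noise=10.0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ConnectomePredictiveModel(
                X, y, config=RidgeCVConfig(seed=8)
            ).permutation_test(n_permutations=150)
        assert abs(np.mean(res.null_r)) < 0.15


class TestOutcomeFamily:
    def test_family_bh_and_alignment(self, small_spec, small_cohorts):
        from netfa import generate_dataset
        from netfa.graph import METRICS
        from netfa.stats import bh_adjust

        ds = generate_dataset(small_spec, cohorts=small_cohorts)
        outcomes = ds.metrics_transformed.loc[ds.features.subject_ids,
                                              list(METRICS)]
        cfg = RidgeCVConfig(seed=2, outer_folds=5, inner_folds=3,
                            n_lambdas=10)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fam = run_outcome_family(ds.features, outcomes, cfg,
                                     networks=["mirroring"],
                                     n_permutations=60)
        df = fam.to_frame()
        assert len(df) == 5
        np.testing.assert_allclose(
            df["p_fdr"], bh_adjust(df["p_perm"].to_numpy()), atol=1e-12
        )
        assert "mirroring" in fam.summary()

    def test_misaligned_subjects_named_in_error(self, small_spec,
                                                small_cohorts):
        from netfa import generate_dataset
        from netfa.graph import METRICS

        ds = generate_dataset(small_spec, cohorts=small_cohorts)
        outcomes = ds.metrics_transformed.loc[ds.features.subject_ids,
                                              list(METRICS)]
        bad = outcomes.rename(index={outcomes.index[0]: "ghost"})
        with pytest.raises(ValueError, match="ghost"):
            run_outcome_family(ds.features, bad, RidgeCVConfig())

    def test_bh_tie_handling_in_family(self):
        from netfa.stats import bh_adjust
        np.testing.assert_allclose(bh_adjust([0.01] * 5), [0.01] * 5)
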