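"""Batched nested cross-validation engine.

The predictive pipeline (per outer fold: fold-wise standardization, ridge
with the penalty chosen by an inner grid search, prediction of the held-out
subjects) must be re-run hundreds of times per analysis: once for the
observed outcome and once per permuted outcome.  The design matrix, fold
assignment and therefore every fold-wise standardization and SVD are
identical across those re-runs, so this module factors the computation into

* :class:`DesignCache` — everything that depends only on (X, covariate
  design, fold structure): per-fold imputation means, scaler statistics,
  SVD factors of the standardized training design, and the pre-contracted
  validation operator for the whole lambda grid; and
* :meth:`DesignCache.evaluate` — the outcome-dependent part, vectorized
  over an (n, m) matrix of outcome columns (observed + permutations) with
  one GEMM per inner fold.

For a single outcome column this reproduces, value for value, the naive
pipeline of per-fold StandardScaler + ridge fits (asserted against an
sklearn reimplementation in the test suite); caching changes nothing about
which data each fold may see, so the no-leakage property holds by
construction and is probed explicitly in tests.

Ridge solution via SVD of the standardized training design X = U S V':
beta(lambda) = V diag(s / (s^2 + lambda)) U' y_centered, intercept = mean
of the training outcome.  This equals the usual penalized least squares
solution with unpenalized intercept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import substream

__all__ = ["DesignCache", "make_folds", "encode_covariates",
           "single_predictor_cv"]


def make_folds(n: int, k: int, rng: np.random.Generator):
    """Seeded uniform shuffle split into k near-equal test folds."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def encode_covariates(cov: pd.DataFrame, train_idx: np.ndarray):
    """Design-matrix encoding of a covariate table, fit on training rows.

    Numeric columns pass through; categorical columns become indicator
    columns for every category observed in the training rows except the
    first (the intercept absorbs it).  Categories unseen in training
    encode as all-zero.  Returns the full (n, q) design including an
    intercept column; slice rows as needed.
    """
    n = len(cov)
    blocks = [np.ones((n, 1))]
    for col in cov.columns:
        s = cov[col]
        if pd.api.types.is_numeric_dtype(s):
            blocks.append(s.to_numpy(dtype=float)[:, None])
        else:
            cats = sorted(pd.unique(s.iloc[train_idx].astype(str)))
            for cat in cats[1:]:
                blocks.append((s.astype(str) == cat).to_numpy(float)[:, None])
    return np.hstack(blocks)


class _Fold:
    __slots__ = ("train", "test", "U", "F", "Xtest_rot", "inner",
                 "Ztr", "Zte", "Qz")


class _Inner:
    __slots__ = ("sub", "val", "U", "A", "n_lambda", "n_val")


class DesignCache:
    """Precomputed fold-wise factorization of one predictor design.

    Parameters
    ----------
    X : (n, P) array
        Predictor matrix (may contain NaN; imputed with training-fold
        column means within each outer fold).
    cfg : RidgeCVConfig
        Fold counts, lambda grid, covariate mode, inner criterion, seed.
    covariates : DataFrame, optional
        Required unless ``cfg.covariate_mode == "none"``.
    """

    def __init__(self, X, cfg, covariates: pd.DataFrame | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (subjects x tracts)")
        n, self.P = X.shape
        self.n = n
        self.cfg = cfg
        self.mode = cfg.covariate_mode
        if self.mode not in ("none", "residualize_outcome", "unpenalized_covariates"):
            raise ValueError(f"unknown covariate_mode {self.mode!r}")
        if self.mode != "none" and covariates is None:
            raise ValueError(f"covariate_mode {self.mode!r} requires covariates")
        if n < cfg.outer_folds:
            raise ValueError(
                f"fewer subjects ({n}) than outer folds ({cfg.outer_folds})"
            )
        lambdas = np.asarray(cfg.lambda_grid, dtype=float)
        if np.any(lambdas <= 0) or np.any(np.diff(lambdas) < 0):
            raise ValueError("lambda grid must be positive and ascending")
        self.lambdas = lambdas

        rng = substream(cfg.seed, "folds")
        tests = make_folds(n, cfg.outer_folds, rng)
        self.outer = []
        for te in tests:
            fold = _Fold()
            tr = np.setdiff1d(np.arange(n), te)
            fold.train, fold.test = tr, te

            Xtr, Xte = X[tr].copy(), X[te].copy()
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(Xtr, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            for M in (Xtr, Xte):
                nanmask = np.isnan(M)
                if nanmask.any():
                    M[nanmask] = np.broadcast_to(col_mean, M.shape)[nanmask]

            fold.Ztr = fold.Zte = fold.Qz = None
            if self.mode != "none":
                Z = encode_covariates(covariates, tr)
                fold.Ztr, fold.Zte = Z[tr], Z[te]
                fold.Qz = np.linalg.pinv(fold.Ztr)
                if self.mode == "unpenalized_covariates":
                    # Frisch-Waugh: ridge on covariate-residualized X
                    coef = fold.Qz @ Xtr
                    Xtr = Xtr - fold.Ztr @ coef
                    Xte = Xte - fold.Zte @ coef

            mu, sd = Xtr.mean(0), Xtr.std(0)
            sd = np.where(sd > 0, sd, 1.0)
            Xtr_s = (Xtr - mu) / sd
            U, s, Vt = np.linalg.svd(Xtr_s, full_matrices=False)
            fold.U = U
            fold.F = s / (s**2 + lambdas[:, None])  # (L, r)
            fold.Xtest_rot = ((Xte - mu) / sd) @ Vt.T

            fold.inner = []
            inner_tests = make_folds(len(tr), cfg.inner_folds, rng)
            for val_pos in inner_tests:
                sub_pos = np.setdiff1d(np.arange(len(tr)), val_pos)
                inn = _Inner()
                inn.sub, inn.val = sub_pos, val_pos
                Xsub, Xval = Xtr[sub_pos], Xtr[val_pos]
                mu_i, sd_i = Xsub.mean(0), Xsub.std(0)
                sd_i = np.where(sd_i > 0, sd_i, 1.0)
                Ui, si, Vti = np.linalg.svd((Xsub - mu_i) / sd_i,
                                            full_matrices=False)
                Fi = si / (si**2 + lambdas[:, None])  # (L, r)
                Xval_rot = ((Xval - mu_i) / sd_i) @ Vti.T  # (v, r)
                inn.U = Ui
                # validation operator for every lambda at once:
                # pred[l, v, :] = (F[l] * Xval_rot[v]) @ C
                inn.A = (Fi[:, None, :] * Xval_rot[None, :, :]).reshape(
                    -1, Fi.shape[1]
                )
                inn.n_lambda = len(lambdas)
                inn.n_val = len(val_pos)
                fold.inner.append(inn)
            self.outer.append(fold)

    # ------------------------------------------------------------------
    def evaluate(self, Y):
        """Run the full nested-CV pipeline for every outcome column of Y.

        Returns ``(preds, y_eval, lambda_idx)``: out-of-sample predictions,
        the outcome values they should be correlated with (covariate-
        residualized when the mode asks for it), and the chosen lambda grid
        index per (outer fold, column).
        """
        Y = np.asarray(Y, dtype=float)
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        if len(Y) != self.n:
            raise ValueError("outcome length does not match the design")
        if np.isnan(Y).any():
            raise ValueError("outcome contains NaN; drop those subjects first")
        n, m = Y.shape
        const = Y.std(axis=0) == 0
        if const.any():
            raise ValueError("constant outcome column(s): nothing to predict")

        preds = np.empty((n, m))
        y_eval = np.empty((n, m))
        lam_idx = np.empty((len(self.outer), m), dtype=int)
        criterion = self.cfg.inner_criterion

        for oi, fold in enumerate(self.outer):
            Ytr, Yte = Y[fold.train], Y[fold.test]
            if self.mode != "none":
                G = fold.Qz @ Ytr
                covpred_te = fold.Zte @ G
                Ytr = Ytr - fold.Ztr @ G
                if self.mode == "residualize_outcome":
                    y_eval[fold.test] = Yte - covpred_te
                else:
                    y_eval[fold.test] = Yte
            else:
                y_eval[fold.test] = Yte

            score = np.zeros((len(self.lambdas), m))
            for inn in fold.inner:
                Ysub, Yval = Ytr[inn.sub], Ytr[inn.val]
                ym = Ysub.mean(0)
                C = inn.U.T @ (Ysub - ym)  # (r, m)
                pv = (inn.A @ C).reshape(inn.n_lambda, inn.n_val, m) + ym
                if criterion == "mse":
                    score += ((pv - Yval[None, :, :]) ** 2).mean(axis=1)
                elif criterion == "pearson_r":
                    pc = pv - pv.mean(axis=1, keepdims=True)
                    yc = Yval - Yval.mean(axis=0)
                    num = np.einsum("lvm,vm->lm", pc, yc)
                    den = np.sqrt((pc**2).sum(axis=1) * (yc**2).sum(axis=0))
                    r = np.divide(num, den, out=np.zeros_like(num),
                                  where=den > 0)
                    score -= r  # maximize mean validation r
                else:
                    raise ValueError(
                        f"unknown inner criterion {criterion!r}"
                    )
            li = score.argmin(axis=0)  # ties -> smallest lambda
            lam_idx[oi] = li

            ym = Ytr.mean(0)
            C = fold.U.T @ (Ytr - ym)  # (r, m)
            beta_rot = fold.F[li].T * C  # (r, m)
            pt = fold.Xtest_rot @ beta_rot + ym
            if self.mode == "unpenalized_covariates":
                pt = pt + covpred_te
            preds[fold.test] = pt

        if squeeze:
            return preds[:, 0], y_eval[:, 0], lam_idx[:, 0]
        return preds, y_eval, lam_idx


def single_predictor_cv(X, Y, cfg, covariates: pd.DataFrame | None = None):
    """Cross-validated simple OLS for every (tract, outcome-column) pair.

    Uses the same seeded outer-fold assignment as :class:`DesignCache`
    (identical first draws from the fold substream) and the same covariate
    handling, but fits ordinary least squares on a single standardized
    predictor — there is no hyperparameter, so the inner search is trivial
    and skipped.

    Parameters
    ----------
    X : (n, T) array of single-tract predictors
    Y : (n, m) array of outcome columns (observed + permutations)

    Returns
    -------
    r : (T, m) array of out-of-sample Pearson correlations.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, T = X.shape
    m = Y.shape[1]
    mode = cfg.covariate_mode
    rng = substream(cfg.seed, "folds")
    tests = make_folds(n, cfg.outer_folds, rng)

    preds = np.empty((n, T, m))
    y_eval = np.empty((n, m))
    for te in tests:
        tr = np.setdiff1d(np.arange(n), te)
        Xtr, Xte = X[tr].copy(), X[te].copy()
        col_mean = np.nanmean(Xtr, axis=0)
        for M in (Xtr, Xte):
            nanmask = np.isnan(M)
            if nanmask.any():
                M[nanmask] = np.broadcast_to(col_mean, M.shape)[nanmask]
        Ytr, Yte = Y[tr], Y[te]
        if mode != "none":
            Z = encode_covariates(covariates, tr)
            Ztr, Zte = Z[tr], Z[te]
            Qz = np.linalg.pinv(Ztr)
            G = Qz @ Ytr
            covpred_te = Zte @ G
            Ytr = Ytr - Ztr @ G
            y_eval[te] = (Yte - covpred_te if mode == "residualize_outcome"
                          else Yte)
            if mode == "unpenalized_covariates":
                coef = Qz @ Xtr
                Xtr = Xtr - Ztr @ coef
                Xte = Xte - Zte @ coef
        else:
            y_eval[te] = Yte

        mu, sd = Xtr.mean(0), Xtr.std(0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr_s = (Xtr - mu) / sd
        Xte_s = (Xte - mu) / sd
        ym = Ytr.mean(0)
        slope = Xtr_s.T @ (Ytr - ym) / len(tr)  # (T, m); Xtr_s has unit pop-var
        pt = Xte_s[:, :, None] * slope[None, :, :] + ym[None, None, :]
        if mode == "unpenalized_covariates":
            pt = pt + covpred_te[:, None, :]
        preds[te] = pt

    # columnwise r per tract
    pc = preds - preds.mean(axis=0)
    yc = y_eval - y_eval.mean(axis=0)
    num = np.einsum("ntm,nm->tm", pc, yc)
    den = np.sqrt((pc**2).sum(axis=0) * (yc**2).sum(axis=0)[None, :])
    r = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return np.clip(r, -1.0, 1.0)
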