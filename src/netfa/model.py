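"""Connectome-based predictive modeling of network position characteristics.

The core model: within each brain network, the subjects x tracts FA matrix
predicts one transformed social network position characteristic through a
nested cross-validated ridge pipeline —

* 10 outer folds estimate out-of-sample performance;
* within each outer training fold, 10 inner folds grid-search the ridge
  penalty lambda over 100 log-spaced values in [1e-5, 10];
* predictors are standardized with training-fold statistics only;
* performance is the Pearson r between out-of-sample predictions and the
  actual outcome;
* inference is a one-sided permutation test: the whole pipeline is re-run
  on outcome vectors shuffled across subjects, and p is the (add-one
  smoothed) fraction of permuted r values at or above the observed one;
* across the five outcomes of one network, p-values are FDR-adjusted
  (Benjamini-Hochberg).

Covariates (age, gender, handedness, cohort, extraversion) are controlled
either by residualizing the outcome on them (fit on training folds only;
the default choice in connectome-based predictive modeling) or by entering
them as unpenalized regressors.

Usage follows the statsmodels convention: build a
:class:`ConnectomePredictiveModel` from data, call :meth:`fit`, and read
estimates and diagnostics off the returned results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._engine import DesignCache
from .features import TractFeatureMatrix
from .stats import bh_adjust, colwise_pearson, permutation_pvalue
from .synthetic import substream

__all__ = [
    "RidgeCVConfig",
    "ConnectomePredictiveModel",
    "ConnectomePredictionResults",
    "FamilyResults",
    "fit_predict_cv",
    "permutation_test",
    "run_outcome_family",
]


@dataclass
class RidgeCVConfig:
    """Configuration of the nested cross-validated ridge pipeline.

    Defaults follow the study design: 10 outer folds, 10 inner folds, 100
    log-spaced penalties between 1e-5 and 10, 1000 permutations.  Set
    ``outer_folds = n`` for leave-one-subject-out.
    """

    outer_folds: int = 10
    inner_folds: int = 10
    lambda_min: float = 1e-5
    lambda_max: float = 10.0
    n_lambdas: int = 100
    n_permutations: int = 1000
    seed: int = 0
    covariate_mode: str = "none"  # none | residualize_outcome | unpenalized_covariates
    inner_criterion: str = "mse"  # mse | pearson_r
    p_value_convention: str = "add_one"  # add_one | raw
    fdr_family: str = "within"  # within (per network) | pooled (across networks)
    explicit_lambda_grid: tuple | None = None

    @property
    def lambda_grid(self) -> np.ndarray:
        if self.explicit_lambda_grid is not None:
            return np.asarray(self.explicit_lambda_grid, dtype=float)
        return np.logspace(np.log10(self.lambda_min), np.log10(self.lambda_max),
                           self.n_lambdas)

    def validate(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        grid = self.lambda_grid
        if np.any(grid <= 0) or np.any(np.diff(grid) < 0):
            raise ValueError("lambda grid must be positive and sorted ascending")

    def replace(self, **kw) -> "RidgeCVConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        if d["explicit_lambda_grid"] is not None:
            d["explicit_lambda_grid"] = [float(v) for v in d["explicit_lambda_grid"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RidgeCVConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        if known.get("explicit_lambda_grid") is not None:
            known["explicit_lambda_grid"] = tuple(known["explicit_lambda_grid"])
        return cls(**known)


def _permutation_matrix(y: np.ndarray, n_perm: int, seed: int) -> np.ndarray:
    """Columns: the observed outcome followed by n_perm shuffles of it."""
    rng = substream(seed, "permutations")
    n = len(y)
    cols = [y]
    for _ in range(n_perm):
        cols.append(y[rng.permutation(n)])
    return np.column_stack(cols)


@dataclass
class ConnectomePredictionResults:
    """Fitted out-of-sample predictions for one (network, outcome) pair.

    ``r_observed`` is the Pearson correlation between out-of-sample
    predictions and the (possibly covariate-residualized) actual outcome;
    ``p_perm`` and ``null_r`` are present after permutation inference,
    ``p_fdr`` after family-level adjustment.
    """

    outcome: str
    network: str | None
    subject_ids: list
    predicted: np.ndarray
    actual: np.ndarray
    r_observed: float
    lambda_per_fold: np.ndarray
    config: RidgeCVConfig
    null_r: np.ndarray | None = None
    p_perm: float | None = None
    p_fdr: float | None = None

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        """One-row summary table (r, p, p_fdr, mean lambda, n)."""
        return pd.DataFrame([{
            "network": self.network,
            "outcome": self.outcome,
            "n": self.n,
            "r": self.r_observed,
            "p_perm": self.p_perm,
            "p_fdr": self.p_fdr,
            "mean_lambda": float(np.mean(self.lambda_per_fold)),
        }])

    def prediction_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"predicted": self.predicted, "actual": self.actual},
            index=pd.Index(self.subject_ids, name="subject_id"),
        )

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Connectome-based prediction results",
            "===================================",
            f"outcome:            {self.outcome}",
            f"network:            {self.network or '(all tracts)'}",
            f"n subjects:         {self.n}",
            f"out-of-sample r:    {self.r_observed:.4f}",
        ]
        if self.p_perm is not None:
            lines.append(
                f"permutation p:      {self.p_perm:.4f} "
                f"(one-sided, {len(self.null_r)} permutations)"
            )
        if self.p_fdr is not None:
            lines.append(f"FDR-adjusted p:     {self.p_fdr:.4f}")
        lam = np.asarray(self.lambda_per_fold, dtype=float)
        lines += [
            f"outer folds:        {cfg.outer_folds} "
            f"(inner {cfg.inner_folds}, grid {len(cfg.lambda_grid)} lambdas)",
            f"chosen lambda:      median {np.median(lam):.3g}, "
            f"range [{lam.min():.3g}, {lam.max():.3g}]",
            f"covariate mode:     {cfg.covariate_mode}",
        ]
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Scatter of actual vs predicted values with the identity trend."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(self.predicted, self.actual, s=18, alpha=0.7)
        ax.set_xlabel("predicted")
        ax.set_ylabel("actual")
        title = f"{self.network or 'all'} / {self.outcome}: r = {self.r_observed:.3f}"
        if self.p_perm is not None:
            title += f", p = {self.p_perm:.3g}"
        ax.set_title(title)
        return ax


class ConnectomePredictiveModel:
    """Ridge-based multivariate prediction of one position characteristic.

    Parameters
    ----------
    features : TractFeatureMatrix or DataFrame
        Subjects x tracts FA values.  With a :class:`TractFeatureMatrix`
        and ``network=...``, only that network's tracts enter the model.
    outcome : Series or array
        Transformed position characteristic, aligned to the feature rows.
        Subjects with a missing outcome (isolates' constraint) are dropped
        from this model only.
    covariates : DataFrame, optional
        Subject covariates; how they enter is set by
        ``config.covariate_mode``.
    config : RidgeCVConfig
    network : str, optional
    outcome_name : str, optional
    """

    def __init__(self, features, outcome, covariates=None,
                 config: RidgeCVConfig | None = None, network=None,
                 outcome_name=None):
        self.config = config or RidgeCVConfig()
        self.config.validate()
        if isinstance(features, TractFeatureMatrix):
            frame = features.network(network) if network else features.values
        else:
            frame = pd.DataFrame(features)
        self.network = network

        y = pd.Series(np.asarray(outcome, dtype=float),
                      index=frame.index if not isinstance(outcome, pd.Series)
                      else outcome.index)
        if isinstance(outcome, pd.Series):
            missing = [s for s in frame.index if s not in y.index]
            if missing:
                raise ValueError(f"outcome missing for subjects: {missing}")
            y = y.loc[frame.index]
        self.outcome_name = outcome_name or getattr(outcome, "name", None) or "outcome"

        keep = ~y.isna().to_numpy()
        if keep.sum() < len(y):
            dropped = list(frame.index[~keep])
            warnings.warn(
                f"{self.outcome_name}: dropping {len(dropped)} subject(s) with "
                f"undefined outcome: {dropped}", stacklevel=2,
            )
        frame = frame.loc[keep]
        y = y.loc[keep]

        overall_sd = np.nanstd(frame.to_numpy(), axis=0)
        if np.any(overall_sd == 0):
            bad = list(frame.columns[overall_sd == 0])
            raise ValueError(f"constant predictor column(s): {bad}")

        self.exog = frame
        self.endog = y
        if covariates is not None:
            cov = covariates.loc[frame.index]
            self.covariates = cov
        else:
            self.covariates = None
            if self.config.covariate_mode != "none":
                raise ValueError("covariate_mode set but no covariates supplied")
        self._cache = None

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, tracts: list,
                       covariate_cols=(), **kw):
        """Build from a single tidy DataFrame naming outcome/tract columns."""
        cov = data[list(covariate_cols)] if covariate_cols else None
        return cls(data[tracts], data[outcome], covariates=cov,
                   outcome_name=outcome, **kw)

    # ------------------------------------------------------------------
    def _design(self) -> DesignCache:
        if self._cache is None:
            self._cache = DesignCache(self.exog.to_numpy(), self.config,
                                      covariates=self.covariates)
        return self._cache

    def fit(self) -> ConnectomePredictionResults:
        """Nested-CV out-of-sample predictions and observed r (no inference)."""
        preds, y_eval, lam_idx = self._design().evaluate(self.endog.to_numpy())
        r = float(colwise_pearson(preds[:, None], y_eval[:, None])[0])
        return ConnectomePredictionResults(
            outcome=self.outcome_name, network=self.network,
            subject_ids=list(self.exog.index), predicted=preds, actual=y_eval,
            r_observed=r, lambda_per_fold=self.config.lambda_grid[lam_idx],
            config=self.config,
        )

    def permutation_test(self, n_permutations=None) -> ConnectomePredictionResults:
        """Fit plus one-sided permutation inference on the observed r.

        The full pipeline (standardization, inner lambda search, outer
        refit) is re-run for every outcome shuffle; fold assignment stays
        fixed, so the null reflects exchangeability of subjects' outcomes.
        """
        cfg = self.config
        B = cfg.n_permutations if n_permutations is None else int(n_permutations)
        if B < 100:
            warnings.warn(
                f"only {B} permutations: p-value resolution is coarse/unstable",
                stacklevel=2,
            )
        Y = _permutation_matrix(self.endog.to_numpy(), B, cfg.seed)
        preds, y_eval, lam_idx = self._design().evaluate(Y)
        r = colwise_pearson(preds, y_eval)
        p = permutation_pvalue(r[0], r[1:], cfg.p_value_convention)
        return ConnectomePredictionResults(
            outcome=self.outcome_name, network=self.network,
            subject_ids=list(self.exog.index), predicted=preds[:, 0],
            actual=y_eval[:, 0], r_observed=float(r[0]),
            lambda_per_fold=cfg.lambda_grid[lam_idx[:, 0]], config=cfg,
            null_r=r[1:], p_perm=float(p),
        )


@dataclass
class FamilyResults:
    """Permutation results for the five outcomes (per network), with FDR."""

    results: list = field(default_factory=list)
    fdr_family: str = "within"

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([r.to_frame() for r in self.results],
                         ignore_index=True)

    def summary(self) -> str:
        df = self.to_frame()
        with pd.option_context("display.float_format", "{:.4f}".format):
            return (f"Outcome-family prediction results "
                    f"(FDR grouping: {self.fdr_family})\n" + df.to_string(index=False))


def fit_predict_cv(X, y, cfg: RidgeCVConfig | None = None, covariates=None,
                   network=None):
    """Functional wrapper: nested-CV predictions for one network/outcome."""
    return ConnectomePredictiveModel(X, y, covariates=covariates, config=cfg,
                                     network=network).fit()


def permutation_test(X, y, cfg: RidgeCVConfig | None = None, covariates=None,
                     network=None, n_permutations=None):
    """Functional wrapper: fit + one-sided permutation inference."""
    return ConnectomePredictiveModel(
        X, y, covariates=covariates, config=cfg, network=network
    ).permutation_test(n_permutations=n_permutations)


def run_outcome_family(features: TractFeatureMatrix, outcomes: pd.DataFrame,
                       cfg: RidgeCVConfig | None = None, covariates=None,
                       networks=None, n_permutations=None) -> FamilyResults:
    """Permutation tests for every (network, outcome) pair, with FDR.

    ``outcomes`` holds one column per transformed position characteristic,
    indexed by subject id and aligned with ``features`` (misalignment is an
    error naming the offending subjects).  With ``fdr_family="within"``
    (default) BH runs across the five outcomes of each network separately;
    ``"pooled"`` adjusts across all network x outcome tests at once.
    """
    cfg = cfg or RidgeCVConfig()
    feat_ids = list(features.subject_ids)
    out_ids = list(outcomes.index)
    if set(feat_ids) != set(out_ids):
        only_f = sorted(set(feat_ids) - set(out_ids))
        only_o = sorted(set(out_ids) - set(feat_ids))
        raise ValueError(
            "feature matrix and outcome table are misaligned; "
            f"subjects only in features: {only_f}; only in outcomes: {only_o}"
        )
    outcomes = outcomes.loc[feat_ids]
    networks = list(networks) if networks is not None else features.networks

    fam = FamilyResults(fdr_family=cfg.fdr_family)
    for network in networks:
        group = []
        for outcome in outcomes.columns:
            res = ConnectomePredictiveModel(
                features, outcomes[outcome], covariates=covariates,
                config=cfg, network=network, outcome_name=outcome,
            ).permutation_test(n_permutations=n_permutations)
            group.append(res)
        if cfg.fdr_family == "within":
            adj = bh_adjust([r.p_perm for r in group])
            for r, a in zip(group, adj):
                r.p_fdr = float(a)
        fam.results.extend(group)
    if cfg.fdr_family == "pooled":
        adj = bh_adjust([r.p_perm for r in fam.results])
        for r, a in zip(fam.results, adj):
            r.p_fdr = float(a)
    return fam
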