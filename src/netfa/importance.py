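"""Single-tract necessity and sufficiency analyses.

Necessity ("does the model need this tract?"): for each tract t of a
network whose full P-tract model predicts an outcome, refit the identical
nested-CV pipeline on the remaining P-1 tracts and form
delta_r = r_full - r_leave-t-out.  Significance comes from a permutation
null of *difference* values: for every outcome shuffle, both the full and
the leave-t-out model are re-evaluated and their r difference collected.
One seeded permutation schedule is shared by the full model and every
ablation within a run, so the null isolates the effect of removing the
tract rather than permutation noise.

Sufficiency ("is this tract enough on its own?"): every tract x outcome
pair is tested with cross-validated simple OLS on the single standardized
predictor, using the same fold structure and covariate handling as the
multivariate models.  One-sided permutation p-values are FDR-adjusted two
ways: strictly across all executed tract x outcome tests (865 when all
173 tracts are present), and relaxed within each outcome's family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._engine import DesignCache, single_predictor_cv
from .features import TractFeatureMatrix
from .model import RidgeCVConfig, _permutation_matrix
from .stats import bh_adjust, colwise_pearson, permutation_pvalue

__all__ = [
    "NecessityResult",
    "SufficiencyResult",
    "necessity_analysis",
    "sufficiency_analysis",
]


@dataclass
class NecessityResult:
    """Leave-one-tract-out record: performance drop and its permutation p."""

    tract_id: str
    r_full: float
    r_loo: float
    delta_r: float
    p_perm: float


@dataclass
class SufficiencyResult:
    """Single-tract OLS record with strict and relaxed FDR adjustment."""

    tract_id: str
    outcome: str
    r: float
    p: float
    p_fdr_strict: float | None = None
    p_fdr_relaxed: float | None = None


def _as_frame(features, network):
    if isinstance(features, TractFeatureMatrix):
        return features.network(network) if network else features.values
    return pd.DataFrame(features)


def necessity_analysis(features, y, cfg: RidgeCVConfig | None = None,
                       covariates=None, network=None,
                       n_permutations=None) -> pd.DataFrame:
    """Leave-one-tract-out necessity test for one network/outcome model.

    Returns a DataFrame with one row per tract: ``tract``, ``r_full``,
    ``r_loo``, ``delta_r`` and the one-sided permutation ``p_perm`` of the
    difference.  The full-model r is recomputed here with the same
    configuration (not read from a previous run) so full and ablated
    models share folds and permutation schedule.
    """
    cfg = cfg or RidgeCVConfig()
    cfg.validate()
    frame = _as_frame(features, network)
    y = pd.Series(np.asarray(y, float), index=frame.index) \
        if not isinstance(y, pd.Series) else y.loc[frame.index]
    keep = ~y.isna().to_numpy()
    frame, y = frame.loc[keep], y.loc[keep]
    P = frame.shape[1]
    if P < 2:
        raise ValueError("leave-one-tract-out undefined with a single tract")
    B = cfg.n_permutations if n_permutations is None else int(n_permutations)
    if B < 100:
        warnings.warn(f"only {B} permutations: difference null is coarse",
                      stacklevel=2)

    if covariates is not None:
        covariates = covariates.loc[frame.index]
    Y = _permutation_matrix(y.to_numpy(), B, cfg.seed)

    X = frame.to_numpy()
    preds, y_eval, _ = DesignCache(X, cfg, covariates=covariates).evaluate(Y)
    r_full = colwise_pearson(preds, y_eval)

    rows = []
    cols = np.arange(P)
    for t, tract in enumerate(frame.columns):
        Xt = X[:, cols != t]
        preds, y_eval, _ = DesignCache(Xt, cfg, covariates=covariates).evaluate(Y)
        r_loo = colwise_pearson(preds, y_eval)
        delta = r_full - r_loo
        p = permutation_pvalue(delta[0], delta[1:], cfg.p_value_convention)
        rows.append(NecessityResult(
            tract_id=str(tract), r_full=float(r_full[0]),
            r_loo=float(r_loo[0]), delta_r=float(delta[0]), p_perm=float(p),
        ))
    df = pd.DataFrame([vars(r) for r in rows]).rename(columns={"tract_id": "tract"})
    df.attrs["n_permutations"] = B
    df.attrs["network"] = network
    return df


def sufficiency_analysis(features: TractFeatureMatrix, outcomes: pd.DataFrame,
                         cfg: RidgeCVConfig | None = None, covariates=None,
                         n_permutations=None) -> pd.DataFrame:
    """Single-tract sufficiency screen over every tract x outcome pair.

    Returns a DataFrame with columns ``tract``, ``network``, ``outcome``,
    ``r``, ``p``, ``p_fdr_strict``, ``p_fdr_relaxed``.  ``attrs`` records
    the executed/strict family size and any skipped (constant) tracts.
    With all 173 study tracts and five outcomes this executes exactly 865
    tests.
    """
    cfg = cfg or RidgeCVConfig()
    cfg.validate()
    B = cfg.n_permutations if n_permutations is None else int(n_permutations)
    net_of = features.network_of

    # constant tract columns cannot be standardized -> skipped with warning
    vals = features.values
    sds = vals.std(axis=0, ddof=0)
    skipped = [t for t in vals.columns if sds[t] == 0 or vals[t].isna().all()]
    if skipped:
        warnings.warn(f"skipping constant/empty tract column(s): {skipped}",
                      stacklevel=2)
    tracts = [t for t in vals.columns if t not in set(skipped)]

    rows = []
    for outcome in outcomes.columns:
        y = outcomes[outcome].loc[vals.index]
        keep = ~y.isna().to_numpy()
        X = vals.loc[keep, tracts].to_numpy()
        cov = covariates.loc[vals.index[keep]] if covariates is not None else None
        Y = _permutation_matrix(y.to_numpy()[keep], B, cfg.seed)
        r = single_predictor_cv(X, Y, cfg, covariates=cov)  # (T, B+1)
        exceed = (r[:, 1:] >= r[:, :1]).sum(axis=1)
        if cfg.p_value_convention == "add_one":
            p = (1 + exceed) / (1 + B)
        else:
            p = exceed / B
        for k, tract in enumerate(tracts):
            rows.append(SufficiencyResult(
                tract_id=str(tract), outcome=outcome,
                r=float(r[k, 0]), p=float(p[k]),
            ))

    df = pd.DataFrame([{
        "tract": s.tract_id,
        "network": net_of[s.tract_id],
        "outcome": s.outcome,
        "r": s.r,
        "p": s.p,
    } for s in rows])
    df["p_fdr_strict"] = bh_adjust(df["p"].to_numpy())
    df["p_fdr_relaxed"] = np.nan
    for outcome in outcomes.columns:
        mask = df["outcome"] == outcome
        df.loc[mask, "p_fdr_relaxed"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    df.attrs["n_tests"] = len(df)
    df.attrs["strict_family_size"] = len(df)
    df.attrs["skipped_tracts"] = skipped
    df.attrs["n_permutations"] = B
    return df
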