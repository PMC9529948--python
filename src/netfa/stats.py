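"""Shared statistical primitives.

Small, oracle-tested building blocks used throughout the package:
standardization (population-variance convention), Pearson correlation,
Benjamini-Hochberg step-up FDR adjustment, and the one-sided permutation
p-value conventions used by every resampling test in the pipeline.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "zscore",
    "pearson_r",
    "colwise_pearson",
    "bh_adjust",
    "permutation_pvalue",
]


def zscore(x, nan_policy: str = "raise") -> np.ndarray:
    """Standardize ``x`` to mean 0, standard deviation 1.

    Uses the population (1/n) variance convention, consistently with the
    fold-wise scaling applied inside the predictive models, so that e.g.
    ``zscore([0, 1, 2]) == [-1.2247, 0, 1.2247]``.

    Parameters
    ----------
    x : array-like, length >= 2
    nan_policy : {"raise", "omit"}
        With ``"omit"``, NaN entries are ignored when computing the mean and
        standard deviation and propagated to the output.

    Raises
    ------
    ValueError
        If ``x`` is constant (z-score undefined) or too short.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("zscore expects a 1-d array")
    if nan_policy == "omit":
        finite = x[~np.isnan(x)]
    else:
        if np.isnan(x).any():
            raise ValueError("input contains NaN (use nan_policy='omit')")
        finite = x
    if finite.size < 2:
        raise ValueError("need at least 2 observations to standardize")
    mu = finite.mean()
    sd = finite.std()
    if sd == 0:
        raise ValueError("constant input: z-score undefined")
    return (x - mu) / sd


def pearson_r(x, y) -> float:
    """Product-moment correlation between two equal-length vectors.

    Raises ``ValueError`` for length < 3, mismatched lengths, or constant
    input (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise ValueError("constant input: correlation undefined")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def colwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlation of two (n, m) matrices.

    Degenerate columns (zero variance in either input) yield 0 rather than
    an error: inside permutation loops a perfectly constant prediction
    carries no evidence of association.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = (ac * bc).sum(axis=0)
    den = np.sqrt((ac * ac).sum(axis=0) * (bc * bc).sum(axis=0))
    out = np.zeros(a.shape[1])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def bh_adjust(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank downwards, cap at 1, and restore the input order.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~(p > 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def permutation_pvalue(observed: float, null: np.ndarray,
                       convention: str = "add_one") -> float:
    """One-sided permutation p-value for ``observed`` against ``null``.

    ``"add_one"`` uses (1 + #{null >= observed}) / (1 + B), which can never
    return 0; ``"raw"`` returns the plain exceedance proportion
    #{null >= observed} / B.
    """
    null = np.asarray(null, dtype=float)
    b = null.size
    if b == 0:
        raise ValueError("empty null distribution")
    exceed = int((null >= observed).sum())
    if convention == "add_one":
        return (1 + exceed) / (1 + b)
    if convention == "raw":
        return exceed / b
    raise ValueError(f"unknown p-value convention: {convention!r}")
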