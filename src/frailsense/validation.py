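"""Cross-modality statistical comparison of feature tables.

The robot's contactless measurements are validated against the wearable
reference route feature-by-feature: a Kolmogorov-Smirnov normality check
decides the (non-parametric) route, a two-sided Mann-Whitney U test asks
whether the two samples could come from the same population, and ordinary
least squares on the per-subject paired means quantifies agreement (R, its
p-value, RMSE and MAE), optionally alongside Spearman's rank correlation.

The exact Mann-Whitney path enumerates the permutation distribution of U
over all rank assignments, which handles ties exactly (two identical
samples give p = 1); the large-sample path uses the tie-corrected normal
approximation.  No multiple-testing correction is applied; significance is
flagged at alpha = 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normality",
    "mann_whitney",
    "linear_fit",
    "spearman",
    "compare_modalities",
    "LinearFit",
    "ALPHA",
]

ALPHA = 0.05
#: Largest per-group size for which the exact permutation distribution is used.
EXACT_MAX_N = 8


def normality(sample: np.ndarray) -> float:
    """One-sample Kolmogorov-Smirnov p-value against a fitted normal.

    The reference normal uses the sample mean and SD.  A degenerate
    (zero-variance) sample has no defined test; NaN is returned with a
    warning.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    s = x.std(ddof=1)
    if s == 0:
        warnings.warn("zero-variance sample: normality undefined", stacklevel=2)
        return float("nan")
    return float(stats.kstest(x, "norm", args=(x.mean(), s)).pvalue)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    For group sizes up to 8 the exact permutation distribution of U is
    enumerated over all C(n1+n2, n1) rank assignments (midranks for ties);
    larger samples use the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    n1, n2 = a.size, b.size
    if max(n1, n2) > EXACT_MAX_N:
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )

    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    total = math.comb(n1 + n2, n1)
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


@dataclass(frozen=True)
class LinearFit:
    R: float
    p: float
    rmse: float
    mae: float
    slope: float
    intercept: float


def linear_fit(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least squares of y on x: correlation R, slope-test p, errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of size >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return LinearFit(
        R=float(res.rvalue),
        p=float(res.pvalue),
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        slope=float(res.slope),
        intercept=float(res.intercept),
    )


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def compare_modalities(
    table_a: pd.DataFrame, table_b: pd.DataFrame, *, with_spearman: bool = True
) -> pd.DataFrame:
    """Feature-by-feature comparison of two matched subject x feature tables.

    Rows are subjects, columns feature names; the two tables must share both.
    Returns one report row per feature with the normality p-values, the
    Mann-Whitney p, OLS agreement statistics on the paired per-subject
    values, Spearman's rho, and alpha=0.05 significance flags.
    """
    mismatched = sorted(set(table_a.columns) ^ set(table_b.columns))
    if mismatched:
        raise ValueError(f"feature names differ between tables: {mismatched}")
    if len(table_a) != len(table_b):
        raise ValueError("tables must contain the same subjects")

    rows = []
    for feat in table_a.columns:
        xa = table_a[feat].to_numpy(dtype=float)
        xb = table_b[feat].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_norm_a = normality(xa) if xa.size >= 5 else float("nan")
            p_norm_b = normality(xb) if xb.size >= 5 else float("nan")
            rho = spearman(xa, xb) if with_spearman else float("nan")
        p_mw = mann_whitney(xa, xb)
        try:
            fit = linear_fit(xa, xb)
            r_val, r_p, rmse, mae = fit.R, fit.p, fit.rmse, fit.mae
        except ValueError:
            r_val = r_p = rmse = mae = float("nan")
        rows.append(
            {
                "feature": feat,
                "normality_p_a": p_norm_a,
                "normality_p_b": p_norm_b,
                "mw_p": p_mw,
                "mw_significant": bool(p_mw < ALPHA),
                "R": r_val,
                "R_p": r_p,
                "R_significant": bool(r_p < ALPHA) if np.isfinite(r_p) else False,
                "spearman_rho": rho,
                "rmse": rmse,
                "mae": mae,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
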