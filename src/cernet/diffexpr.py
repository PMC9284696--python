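"""Differential-expression screening with a moderated t-statistic.

Each feature is tested case vs control with a two-sample t whose residual
variance is shrunk toward a common prior by empirical Bayes: the per-feature
pooled variances s^2 (d = n1 + n2 - 2 residual df) are modelled as scaled
F draws around a prior (d0, s0^2), the prior is fitted by the method of
moments on log variances, and the posterior variance

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

replaces s^2 in the t statistic, which is then referred to a t distribution
with d + d0 degrees of freedom.  Shrinkage stabilises variance estimates in
small designs (here 5 vs 5) and is the standard screen for microarray data.

Features are retained when FDR < ``fdr_max`` (Benjamini-Hochberg) and
|log2FC| > ``lfc_min``, both strict, and labelled ``up`` or ``down``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .datatypes import CASE, CONTROL, ExpressionMatrix, InputError

logger = logging.getLogger(__name__)

DE_COLUMNS = ["log2fc", "t", "p", "fdr", "direction"]


def log2_fold_change(m: ExpressionMatrix) -> pd.Series:
    """Per-feature log2 fold change: mean(case) - mean(control).

    Inputs are already log2-scale, so the difference of group means is
    the log2 of the (geometric-mean) fold change.
    """
    case = m.group_values(CASE).mean(axis=1)
    control = m.group_values(CONTROL).mean(axis=1)
    return (case - control).rename("log2fc")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Works on z = log(s^2): after centring by the known chi-square bias
    ``digamma(df/2) - log(df/2)``, the excess spread of z beyond
    ``trigamma(df/2)`` identifies the prior df d0 via the trigamma
    function, and the mean identifies s0^2.  When there is no excess
    spread the prior is degenerate (d0 = inf) at the geometric mean of
    the observed variances.
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    if len(e) > 1:
        evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    else:
        evar = -1.0
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(z)))
    return d0, s0_2


def moderated_t_test(m: ExpressionMatrix, moderated: bool = True) -> pd.DataFrame:
    """Per-feature moderated (or plain) two-sample t test.

    Returns a DataFrame indexed by feature id with columns ``log2fc``,
    ``t`` and two-sided ``p``.  With ``moderated=False`` no shrinkage is
    applied (ordinary equal-variance t), for oracle comparisons.
    """
    case = m.group_values(CASE).to_numpy(dtype=float)
    control = m.group_values(CONTROL).to_numpy(dtype=float)
    n1, n2 = case.shape[1], control.shape[1]
    df = n1 + n2 - 2
    lfc = case.mean(axis=1) - control.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + control.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df

    zero = s2 <= 0
    if zero.all():
        raise InputError("all features have zero residual variance; cannot test")
    if zero.any():
        floor = float(s2[~zero].min())
        logger.warning("flooring %d zero residual variances at %.3g",
                       int(zero.sum()), floor)
        s2 = np.where(zero, floor, s2)

    if moderated:
        d0, s0_2 = fit_variance_prior(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
        else:
            s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        total_df = df + d0
    else:
        s2_post = s2
        total_df = df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = lfc / se
    p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return pd.DataFrame({"log2fc": lfc, "t": t, "p": p}, index=m.values.index)


def adjust_bh(p: np.ndarray | list[float] | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adj_i = min_{j: p_j >= p_i} (p_j * m / rank_j), clipped at 1.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise InputError("p-values must be one-dimensional")
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise InputError("p-values must lie in [0, 1]")
    m_ = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m_ / np.arange(1, m_ + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m_)
    out[order] = adjusted
    return out


def de_table(m: ExpressionMatrix, moderated: bool = True,
             fdr_max: float = 0.05, lfc_min: float = 1.0) -> pd.DataFrame:
    """Full DE result table: statistics, BH FDR and direction labels."""
    tab = moderated_t_test(m, moderated=moderated)
    tab["fdr"] = adjust_bh(tab["p"].to_numpy())
    return screen_de(tab, fdr_max=fdr_max, lfc_min=lfc_min)


def screen_de(results: pd.DataFrame, fdr_max: float = 0.05,
              lfc_min: float = 1.0) -> pd.DataFrame:
    """Assign direction labels using strict FDR and fold-change cutoffs.

    Retained iff fdr < fdr_max and |log2fc| > lfc_min; retained features
    are labelled by the sign of log2fc, all others ``ns``.
    """
    tab = results.copy()
    keep = (tab["fdr"] < fdr_max) & (tab["log2fc"].abs() > lfc_min)
    tab["direction"] = np.where(~keep, "ns",
                                np.where(tab["log2fc"] > 0, "up", "down"))
    return tab


def retained(tab: pd.DataFrame) -> pd.DataFrame:
    """The screened-in subset of a DE table."""
    return tab[tab["direction"] != "ns"]


def directions(tab: pd.DataFrame) -> dict[str, str]:
    """feature id -> 'up'/'down' for the retained features."""
    sub = retained(tab)
    return dict(zip(sub.index, sub["direction"]))


def cluster_order(m: ExpressionMatrix, features: list[str] | None = None,
                  method: str = "complete") -> tuple[list[int], list[int]]:
    """Leaf orders of bidirectional hierarchical clustering.

    Agglomerative clustering on Euclidean distances across both axes of
    the (subset) matrix, as used to order heatmap rows and columns.
    Returns (row order, column order) as positional indices into the
    subset; ties resolved by input order (scipy's deterministic rule).
    """
    sub = m.values.loc[features] if features is not None else m.values
    if sub.shape[0] < 2:
        raise InputError("clustering needs at least 2 features")
    arr = sub.to_numpy(dtype=float)
    row_order = leaves_list(linkage(arr, method=method, metric="euclidean"))
    col_order = leaves_list(linkage(arr.T, method=method, metric="euclidean"))
    return list(map(int, row_order)), list(map(int, col_order))
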