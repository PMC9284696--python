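"""circRNA-mRNA co-expression network from Pearson correlation.

Expression of each differentially expressed circRNA is correlated with
each differentially expressed mRNA across all samples (both groups
pooled); pairs with a correlation above the threshold (default 0.9,
signed and strict) become co-expression edges.  An ``absolute=True``
mode thresholds |r| instead, for the reading in which anti-correlated
pairs also count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, InputError


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("vectors must be one-dimensional and equal length")
    if x.size < 3:
        raise InputError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0 or sy == 0:
        raise InputError("correlation undefined for a constant vector")
    return float((xc @ yc) / np.sqrt(sx * sy))


def build_coexpression_network(circ: ExpressionMatrix, mrna: ExpressionMatrix,
                               circ_features: list[str], mrna_features: list[str],
                               threshold: float = 0.9,
                               absolute: bool = False) -> pd.DataFrame:
    """Score all DE-circRNA x DE-mRNA pairs; keep edges with r > threshold.

    Returns a DataFrame with columns (circ_id, mrna_id, pcc) sorted by
    (circ_id, mrna_id).  The threshold is strict and, by default, signed.
    """
    if list(circ.sample_ids) != list(mrna.sample_ids):
        extra = sorted(set(circ.sample_ids) ^ set(mrna.sample_ids))
        raise InputError(
            f"circRNA and mRNA matrices must share sample columns in the same "
            f"order; mismatched: {extra or circ.sample_ids}")
    c = circ.values.loc[circ_features].to_numpy(dtype=float)
    g = mrna.values.loc[mrna_features].to_numpy(dtype=float)
    cc = c - c.mean(axis=1, keepdims=True)
    gc = g - g.mean(axis=1, keepdims=True)
    cn = np.sqrt((cc ** 2).sum(axis=1))
    gn = np.sqrt((gc ** 2).sum(axis=1))
    if np.any(cn == 0) or np.any(gn == 0):
        bad = [f for f, s in zip(circ_features, cn) if s == 0]
        bad += [f for f, s in zip(mrna_features, gn) if s == 0]
        raise InputError(f"constant expression vectors: {bad}")
    r = (cc @ gc.T) / np.outer(cn, gn)
    keep = np.abs(r) > threshold if absolute else r > threshold
    rows = [(circ_features[i], mrna_features[j], float(r[i, j]))
            for i, j in np.argwhere(keep)]
    edges = pd.DataFrame(rows, columns=["circ_id", "mrna_id", "pcc"])
    return edges.sort_values(["circ_id", "mrna_id"], ignore_index=True)
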