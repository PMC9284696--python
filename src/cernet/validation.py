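"""Cross-dataset validation of network features.

Each miRNA/mRNA of the final network is re-tested in an independent
cohort (emulating a 3 vs 3 validation design) with an equal-variance
two-sample Student's t test; a feature is *consistent* when the sign of
its validation log2 fold change matches its training direction, and
*significant* when the two-sided p < 0.05.  Features absent from the
validation platform are reported as untested rather than dropped — real
validation arrays rarely cover every network feature.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (CASE, CONTROL, ConsistencyRecord, ExpressionMatrix,
                        InputError)

logger = logging.getLogger(__name__)


def student_t_test(x, y) -> tuple[float, float]:
    """Equal-variance two-sample t test (x vs y), two-sided.

    t = (mean x - mean y) / (s_p * sqrt(1/n1 + 1/n2)) with the pooled
    variance s_p^2 on n1 + n2 - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("each group needs at least 2 values")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 <= 0:
        raise InputError("zero pooled variance; t test undefined")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def cross_dataset_consistency(network_features: dict[str, tuple[str, str]],
                              validation: ExpressionMatrix) -> list[ConsistencyRecord]:
    """Direction consistency of network features in a validation cohort.

    ``network_features`` maps feature id -> (rna_class, training
    direction).  Returns one record per feature; features missing from
    the validation matrix are reported untested.  Logs the summary
    funnel (tested / consistent / consistent-and-significant).
    """
    if not network_features:
        raise InputError("no network features to validate")
    records: list[ConsistencyRecord] = []
    case = validation.group_values(CASE)
    control = validation.group_values(CONTROL)
    present = set(validation.feature_ids)
    for fid in sorted(network_features):
        cls, direction = network_features[fid]
        if fid not in present:
            records.append(ConsistencyRecord(fid, cls, direction,
                                             None, None, None, tested=False))
            continue
        x = case.loc[fid].to_numpy(dtype=float)
        y = control.loc[fid].to_numpy(dtype=float)
        t, p = student_t_test(x, y)
        lfc = float(x.mean() - y.mean())
        records.append(ConsistencyRecord(fid, cls, direction, lfc, t, p,
                                         tested=True))
    tested = [r for r in records if r.tested]
    if not tested:
        logger.warning("no network feature overlaps the validation matrix")
    n_cons = sum(bool(r.consistent) for r in tested)
    n_sig = sum(bool(r.consistent and r.significant) for r in tested)
    logger.info("validation: %d/%d tested, %d consistent, %d consistent+significant",
                len(tested), len(records), n_cons, n_sig)
    return records


def consistency_table(records: list[ConsistencyRecord]) -> pd.DataFrame:
    """Flat DataFrame rendering of consistency records."""
    return pd.DataFrame(
        [(r.feature_id, r.rna_class, r.training_direction,
          r.validation_log2fc, r.t, r.p, r.tested, r.consistent, r.significant)
         for r in records],
        columns=["feature_id", "rna_class", "training_direction",
                 "validation_log2fc", "t", "p", "tested", "consistent",
                 "significant"])


def summarize(records: list[ConsistencyRecord]) -> str:
    """Plain-text validation summary."""
    tested = [r for r in records if r.tested]
    n_cons = sum(bool(r.consistent) for r in tested)
    n_sig = sum(bool(r.consistent and r.significant) for r in tested)
    lines = [
        f"network features: {len(records)}",
        f"tested in validation cohort: {len(tested)}",
        f"untested (absent from platform): {len(records) - len(tested)}",
        f"direction-consistent: {n_cons}",
        f"consistent and significant (p < 0.05): {n_sig}",
    ]
    return "\n".join(lines)
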