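"""Gene-set over-representation and disease-pathway filtering.

Network mRNAs are tested for over-representation in each gene set of a
collection with the one-sided hypergeometric upper tail,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

where k genes of the n-gene query fall in a K-gene set drawn from an
N-gene background (the union of all annotated genes and the tested
mRNAs).  Sets with p < 0.05 (strict, unadjusted) are significant.  The
EASE variant (k - 1 in the tail, DAVID's conservative score) is
available but off by default.

Significant sets are intersected with a disease-pathway id list (a file
standing in for a CTD keyword search); triplets whose mRNA belongs to a
flagged set form the disease-related subnetwork.
"""

from __future__ import annotations

import logging

from scipy.special import gammaln, logsumexp
import numpy as np

from .datatypes import CeRNATriplet, EnrichmentResult, InputError

logger = logging.getLogger(__name__)


def _log_binom(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k), computed in log space.

    Parameters are the overlap k, set size K, query size n and
    background size N.  k = 0 returns exactly 1.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise InputError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrich_gene_sets(query: set[str] | list[str],
                     collection: dict[str, tuple[str, list[str]]],
                     background: set[str] | list[str],
                     ease: bool = False) -> list[EnrichmentResult]:
    """Over-representation of a gene query in each set of a collection.

    ``collection`` maps set_id -> (description, member gene ids).  One
    result per set with at least one overlapping gene; sorted by (p,
    set_id).  With ``ease=True`` the tail is computed at k - 1.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise InputError("empty query gene list")
    if not query <= background:
        raise InputError(f"query genes outside background: "
                         f"{sorted(query - background)[:5]}")
    if not collection:
        raise InputError("empty gene-set collection")
    N = len(background)
    n = len(query)
    results = []
    for set_id in sorted(collection):
        name, members = collection[set_id]
        members_bg = set(members) & background
        overlap = sorted(query & members_bg)
        k = len(overlap)
        if k == 0:
            continue
        k_eff = k - 1 if ease else k
        p = hypergeometric_tail(k_eff, len(members_bg), n, N)
        results.append(EnrichmentResult(
            set_id=set_id, set_name=name, k=k, K=len(members_bg),
            n=n, N=N, p=p, overlap=tuple(overlap)))
    results.sort(key=lambda r: (r.p, r.set_id))
    return results


def intersect_disease_pathways(enriched: list[EnrichmentResult],
                               disease_ids: set[str] | list[str]) -> list[EnrichmentResult]:
    """Flag enriched sets present in the disease-pathway id list.

    Sets ``disease_flag`` on every result and returns the flagged subset
    (all results mutated in place keep their flags for reporting).
    """
    disease_ids = set(disease_ids)
    flagged = []
    for r in enriched:
        r.disease_flag = r.set_id in disease_ids
        if r.disease_flag:
            flagged.append(r)
    return flagged


def extract_disease_subnetwork(
        triplets: list[CeRNATriplet],
        flagged: list[EnrichmentResult],
        collection: dict[str, tuple[str, list[str]]]) -> tuple[list[CeRNATriplet], list[tuple[str, str]]]:
    """Triplets whose mRNA belongs to >= 1 flagged (disease) pathway.

    Also returns the pathway-mRNA membership pairs of the subnetwork,
    the quadripartite pathway/circRNA/miRNA/mRNA view.
    """
    disease_genes: set[str] = set()
    memberships: list[tuple[str, str]] = []
    sub_mrnas = {t.mrna_id for t in triplets}
    for r in flagged:
        members = set(collection[r.set_id][1])
        disease_genes |= members
        memberships += [(r.set_id, g) for g in sorted(members & sub_mrnas)]
    kept = [t for t in triplets if t.mrna_id in disease_genes]
    if not kept:
        logger.warning("disease subnetwork is empty")
    kept_mrnas = {t.mrna_id for t in kept}
    memberships = sorted((p, g) for p, g in memberships if g in kept_mrnas)
    return kept, memberships
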