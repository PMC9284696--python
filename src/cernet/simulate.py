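"""Synthetic multi-omic benchmark with planted ceRNA triplets.

Emulates the structure of a matched circRNA/miRNA/mRNA microarray study
of degenerate vs control nucleus pulposus tissue: three expression
profiles over the same 10 samples (five per group, log2 scale), sequence
pools for the miRNAs and candidate targets, a five-database miRNA-target
evidence table, gene-set collections and a disease-pathway list.

``n_planted_triplets`` sponge triplets are planted with full ground
truth: the circRNA and mRNA of a triplet are shifted by ``de_effect``
log2 units in one direction and its miRNA by the same amount in the
other; both the circRNA and the mRNA carry an exact reverse-complement
binding site for the miRNA; the (miRNA, mRNA) pair appears in the
evidence table; and at least one gene set containing planted mRNAs is
flagged in the disease list.  All other sequence windows are kept below
a complementarity cap so that decoys cannot pass the binding filters.

Expression is generated directly on the log2 scale with i.i.d. Gaussian
noise; there are no batch effects or correlation structure beyond the
planted shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import CASE, CONTROL, ExpressionMatrix

_BASES = np.array(list("ACGU"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGU")}
# compat[i, j]: miRNA base i can pair (WC or wobble) with target base j
_COMPAT = np.zeros((4, 4), dtype=bool)
for _m, _t in ("AU", "UA", "GC", "CG", "GU", "UG"):
    _COMPAT[_BASE_INDEX[_m], _BASE_INDEX[_t]] = True


class ConfigError(ValueError):
    """A SynthConfig field violates its documented range."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Counts and group sizes default to a desk-scale rendering of a
    10-sample (5 IDD vs 5 control) three-profile design; ``de_effect``
    and ``noise_sd`` are in log2 units.
    """

    n_circ: int = 60
    n_mir: int = 40
    n_mrna: int = 150
    n_per_group: int = 5
    n_planted_triplets: int = 20
    de_effect: float = 3.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    mir_length: int = 22
    target_length: int = 120
    seed: int = 0
    # plumbing beyond the planted triplets: independent DE features per
    # profile and evidence-flagged distractor target pairs, so that the
    # screening and evidence funnels discard something.
    n_extra_de: int = 5
    n_flagged_distractors: int = 30
    n_unflagged_distractors: int = 20
    n_gene_sets: int = 8
    decoy_max_complementarity: float = 0.6

    def __post_init__(self) -> None:
        for name in ("n_circ", "n_mir", "n_mrna", "n_per_group",
                     "n_planted_triplets", "mir_length", "target_length"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.n_planted_triplets > min(self.n_circ, self.n_mir, self.n_mrna):
            raise ConfigError(
                "n_planted_triplets exceeds the smallest feature pool: "
                f"{self.n_planted_triplets} > "
                f"{min(self.n_circ, self.n_mir, self.n_mrna)}")
        if self.target_length < self.mir_length:
            raise ConfigError("target_length must be >= mir_length")
        if self.n_per_group < 2:
            raise ConfigError(f"n_per_group must be >= 2, got {self.n_per_group}")


@dataclass
class GroundTruth:
    """What was planted: triplets, DE features and binding intervals."""

    # (circ_id, mir_id, mrna_id, circ/mrna direction 'up' or 'down')
    planted_triplets: list[tuple[str, str, str, str]]
    # profile name -> list of (feature_id, true log2 shift)
    de_features: dict[str, list[tuple[str, float]]]
    # (target_id, mir_id, start, end) 0-based half-open on the target
    planted_sites: list[tuple[str, str, int, int]]

    def triplet_set(self) -> set[tuple[str, str, str]]:
        return {(c, m, g) for c, m, g, _ in self.planted_triplets}


PROFILES = ("circ", "mir", "mrna")


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:04d}" for i in range(1, n + 1)]


def _sample_ids(n_per_group: int) -> tuple[list[str], pd.Series]:
    ids = [f"CTRL_{i:02d}" for i in range(1, n_per_group + 1)] + \
          [f"IDD_{i:02d}" for i in range(1, n_per_group + 1)]
    groups = pd.Series([CONTROL] * n_per_group + [CASE] * n_per_group,
                       index=ids, name="group")
    return ids, groups


def generate_expression(config: SynthConfig) -> tuple[
        ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Three matched expression matrices plus the planted ground truth.

    Returns (circ, mir, mrna, truth); matrices share sample columns.
    Planted triplet members are shifted by +/- ``de_effect`` between
    groups (circRNA and mRNA together, miRNA oppositely); extra DE
    features are shifted independently; everything else is null.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ids = {"circ": _feature_ids("circ", config.n_circ),
           "mir": _feature_ids("mir", config.n_mir),
           "mrna": _feature_ids("gene", config.n_mrna)}
    sample_ids, groups = _sample_ids(config.n_per_group)

    planted_idx = {p: rng.choice(len(ids[p]), size=config.n_planted_triplets,
                                 replace=False)
                   for p in PROFILES}
    signs = rng.choice([-1.0, 1.0], size=config.n_planted_triplets)

    shifts = {p: np.zeros(len(ids[p])) for p in PROFILES}
    for t in range(config.n_planted_triplets):
        shifts["circ"][planted_idx["circ"][t]] = signs[t] * config.de_effect
        shifts["mrna"][planted_idx["mrna"][t]] = signs[t] * config.de_effect
        shifts["mir"][planted_idx["mir"][t]] = -signs[t] * config.de_effect

    # independent (non-triplet) DE features per profile
    for p in PROFILES:
        free = np.setdiff1d(np.arange(len(ids[p])), planted_idx[p])
        n_extra = min(config.n_extra_de, free.size)
        extra = rng.choice(free, size=n_extra, replace=False)
        shifts[p][extra] = rng.choice([-1.0, 1.0], size=n_extra) * config.de_effect

    matrices = {}
    de_features: dict[str, list[tuple[str, float]]] = {}
    for p in PROFILES:
        n_feat = len(ids[p])
        baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_feat)
        noise = rng.normal(0.0, config.noise_sd,
                           (n_feat, 2 * config.n_per_group))
        values = baseline[:, None] + noise
        values[:, config.n_per_group:] += shifts[p][:, None]
        matrices[p] = ExpressionMatrix(
            pd.DataFrame(values, index=ids[p], columns=sample_ids), groups)
        de_features[p] = [(ids[p][i], float(shifts[p][i]))
                          for i in np.flatnonzero(shifts[p])]

    triplets = []
    for t in range(config.n_planted_triplets):
        direction = "up" if signs[t] > 0 else "down"
        triplets.append((ids["circ"][planted_idx["circ"][t]],
                         ids["mir"][planted_idx["mir"][t]],
                         ids["mrna"][planted_idx["mrna"][t]],
                         direction))

    # pre-draw binding-site intervals; sequences are embedded later
    sites = []
    max_start = config.target_length - config.mir_length
    for circ_id, mir_id, mrna_id, _ in triplets:
        for target_id in (circ_id, mrna_id):
            start = int(rng.integers(0, max_start + 1))
            sites.append((target_id, mir_id, start, start + config.mir_length))

    truth = GroundTruth(planted_triplets=triplets, de_features=de_features,
                        planted_sites=sites)
    return matrices["circ"], matrices["mir"], matrices["mrna"], truth


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _random_mir(rng: np.random.Generator, length: int) -> np.ndarray:
    """A miRNA with moderate base composition, by rejection sampling.

    G+U is kept within 30-60% (G and U each pair two of the four target
    bases, so a G/U-rich miRNA pairs half of any random sequence and
    makes the decoy cap unenforceable) and G+C within 25-75% (an A-rich
    miRNA's perfect-complement duplex stacks only weakly and could miss
    the energy filter).  Real mature miRNAs sit comfortably inside both
    bands.
    """
    # index space ACGU: C=1, G=2, U=3
    while True:
        s = rng.integers(0, 4, size=length)
        n_gu = int(np.isin(s, (2, 3)).sum())
        n_gc = int(np.isin(s, (1, 2)).sum())
        if 0.30 * length <= n_gu <= 0.60 * length and \
                0.25 * length <= n_gc <= 0.75 * length:
            return s


def _window_match_counts(mir_idx: np.ndarray, target_idx: np.ndarray) -> np.ndarray:
    """Pairable-base count of each ungapped full-length window.

    Window starting at s pairs target position s+k with the reversed
    miRNA position k (a binding site is the reverse complement, so the
    miRNA 3' end pairs the 5' end of the site).
    """
    L, T = mir_idx.size, target_idx.size
    mir_rev = mir_idx[::-1]
    n_win = T - L + 1
    if n_win <= 0:
        return np.zeros(0, dtype=int)
    counts = np.zeros(n_win, dtype=int)
    for k in range(L):
        counts += _COMPAT[mir_rev[k], target_idx[k:k + n_win]]
    return counts


# bases that cannot pair (WC or wobble) with a given miRNA base
_NONPAIR = {b: np.array([t for t in range(4) if not _COMPAT[b, t]])
            for b in range(4)}
_CAP_SLACK = 4  # drive violating windows this far below the cap


def _enforce_decoy_cap(rng: np.random.Generator, target_idx: np.ndarray,
                       mirs: dict[str, np.ndarray],
                       excluded_mirs: set[str],
                       protected: list[tuple[int, int]],
                       cap: float, max_rounds: int = 200) -> np.ndarray:
    """Mutate a target until no window over-pairs with any foreign miRNA.

    Windows overlapping a ``protected`` interval (a planted site, whose
    bases are immutable) are exempt -- the cap is a guarantee about
    decoy windows, and on a fully decoy target every window is enforced.
    ``excluded_mirs`` (the site owners) are not checked.  Each violating
    window is driven a few matches *below* the cap (a mutation elsewhere
    can re-raise nearby windows, so clipping exactly to the cap
    oscillates); mutated positions get a random non-pairing base.
    """
    target_idx = target_idx.copy()
    prot = np.zeros(target_idx.size, dtype=bool)
    for s, e in protected:
        prot[s:e] = True
    for _ in range(max_rounds):
        dirty = False
        for mir_id, mir_idx in mirs.items():
            if mir_id in excluded_mirs:
                continue
            L = mir_idx.size
            mir_rev = mir_idx[::-1]
            max_matches = int(np.floor(cap * L))
            counts = _window_match_counts(mir_idx, target_idx)
            for s in np.flatnonzero(counts > max_matches):
                if prot[s:s + L].any():
                    continue
                matches = [k for k in range(L)
                           if _COMPAT[mir_rev[k], target_idx[s + k]]]
                need = len(matches) - (max_matches - _CAP_SLACK)
                for k in rng.permutation(np.array(matches, dtype=int))[:max(0, need)]:
                    choices = _NONPAIR[mir_rev[k]]
                    target_idx[s + k] = choices[rng.integers(0, choices.size)]
                    dirty = True
        if not dirty:
            return target_idx
    raise RuntimeError("decoy complementarity cap not reachable")  # pragma: no cover


def _complement_idx(idx: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0])  # A<->U, C<->G in ACGU index space
    return comp[idx]


def generate_sequences(config: SynthConfig, truth: GroundTruth) -> tuple[
        dict[str, str], dict[str, str], dict[str, str]]:
    """Sequence pools: (miRNAs, circRNA targets, mRNA 3'-region targets).

    Each planted (target, miRNA) site is an embedded exact reverse
    complement of the miRNA at the recorded interval; every other
    (target, miRNA) combination is kept below the decoy complementarity
    cap outside planted intervals.  All sequences use the ACGU alphabet.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    mir_ids = _feature_ids("mir", config.n_mir)
    circ_ids = _feature_ids("circ", config.n_circ)
    gene_ids = _feature_ids("gene", config.n_mrna)

    mirs = {mid: _random_mir(rng, config.mir_length) for mid in mir_ids}

    sites_by_target: dict[str, list[tuple[str, int, int]]] = {}
    for target_id, mir_id, start, end in truth.planted_sites:
        if end > config.target_length:
            raise ConfigError(
                f"planted site {target_id}:{start}-{end} exceeds "
                f"target_length={config.target_length}")
        sites_by_target.setdefault(target_id, []).append((mir_id, start, end))

    targets: dict[str, np.ndarray] = {}
    for tid in circ_ids + gene_ids:
        owners = set()
        protected = []
        for mir_id, start, end in sites_by_target.get(tid, []):
            owners.add(mir_id)
            protected.append((start, end))

        def fresh_draw() -> np.ndarray:
            seq = _random_seq(rng, config.target_length)
            for mir_id, start, end in sites_by_target.get(tid, []):
                # binding site = reverse complement of the miRNA
                seq[start:end] = _complement_idx(mirs[mir_id])[::-1]
            return seq

        # the stochastic repair converges almost always; on the rare
        # non-converging draw, resample the target and try again (the
        # shared rng stream keeps the whole procedure seed-deterministic)
        for _ in range(8):
            try:
                targets[tid] = _enforce_decoy_cap(
                    rng, fresh_draw(), mirs, owners, protected,
                    cap=config.decoy_max_complementarity)
                break
            except RuntimeError:
                continue
        else:  # pragma: no cover - probability ~(per-draw failure)^8
            raise RuntimeError(f"could not generate a cap-respecting "
                               f"sequence for {tid}")

    def decode(idx: np.ndarray) -> str:
        return "".join(_BASES[idx])

    mir_seqs = {mid: decode(a) for mid, a in mirs.items()}
    circ_seqs = {tid: decode(targets[tid]) for tid in circ_ids}
    mrna_seqs = {tid: decode(targets[tid]) for tid in gene_ids}
    return mir_seqs, circ_seqs, mrna_seqs


def generate_annotations(config: SynthConfig, truth: GroundTruth) -> tuple[
        pd.DataFrame, dict[str, tuple[str, list[str]]], pd.DataFrame]:
    """Evidence table, gene-set collection and disease-pathway list.

    Every planted (miRNA, mRNA) pair gets >= 1 of five database flags;
    flagged and zero-flag distractor pairs are added.  At least one gene
    set contains planted mRNAs and appears in the disease list, and at
    least one set is absent from it.
    """
    rng = np.random.default_rng(config.seed + 2_000_003)
    mir_ids = _feature_ids("mir", config.n_mir)
    gene_ids = _feature_ids("gene", config.n_mrna)
    planted_pairs = [(m, g) for _, m, g, _ in truth.planted_triplets]

    def draw_flags(force: bool) -> list[int]:
        flags = (rng.random(5) < 0.4).astype(int)
        if force and flags.sum() == 0:
            flags[rng.integers(0, 5)] = 1
        return list(flags)

    rows = []
    seen = set(planted_pairs)
    for m, g in planted_pairs:
        rows.append((m, g, *draw_flags(force=True)))
    n_flagged = 0
    while n_flagged < config.n_flagged_distractors:
        m = mir_ids[rng.integers(0, len(mir_ids))]
        g = gene_ids[rng.integers(0, len(gene_ids))]
        if (m, g) in seen:
            continue
        seen.add((m, g))
        rows.append((m, g, *draw_flags(force=True)))
        n_flagged += 1
    n_plain = 0
    while n_plain < config.n_unflagged_distractors:
        m = mir_ids[rng.integers(0, len(mir_ids))]
        g = gene_ids[rng.integers(0, len(gene_ids))]
        if (m, g) in seen:
            continue
        seen.add((m, g))
        rows.append((m, g, 0, 0, 0, 0, 0))
        n_plain += 1
    interactions = pd.DataFrame(
        rows, columns=["mir_id", "gene_id", "targetscan", "pictar", "rna22",
                       "pita", "miranda"])

    planted_genes = [g for _, g in planted_pairs]
    collection: dict[str, tuple[str, list[str]]] = {}
    # disease-relevant set: planted mRNAs plus random background genes
    core = list(dict.fromkeys(planted_genes))
    pad = [g for g in gene_ids if g not in core]
    pad_pick = list(rng.choice(pad, size=min(10, len(pad)), replace=False))
    collection["path_0001"] = ("disc degeneration signalling (synthetic)",
                               sorted(core + pad_pick))
    # a set deliberately absent from the disease list
    other = list(rng.choice(gene_ids, size=min(15, len(gene_ids)), replace=False))
    collection["path_0002"] = ("housekeeping metabolism (synthetic)", sorted(other))
    for i in range(3, config.n_gene_sets + 1):
        size = int(rng.integers(8, 25))
        members = list(rng.choice(gene_ids, size=min(size, len(gene_ids)),
                                  replace=False))
        collection[f"path_{i:04d}"] = (f"synthetic pathway {i}", sorted(members))

    disease_ids = ["path_0001"] + \
        [f"path_{i:04d}" for i in range(3, config.n_gene_sets + 1, 2)] + \
        ["path_9001", "path_9002"]  # ids outside the collection, as a real
                                    # keyword search would return
    disease = pd.DataFrame({"pathway_id": disease_ids,
                            "name": [f"disease pathway {p}" for p in disease_ids]})
    return interactions, collection, disease


def generate_validation(config: SynthConfig, truth: GroundTruth,
                        n_per_group: int = 3,
                        seed_offset: int = 7_000_003) -> tuple[
        ExpressionMatrix, ExpressionMatrix]:
    """Independent validation cohort (miRNA and mRNA profiles, 3 vs 3).

    Reuses the planted truth (same true shifts) with fresh noise and an
    independent seed, emulating small external validation datasets;
    circRNAs get no validation profile, as none existed for the study
    design being emulated.
    """
    vconfig = replace(config, n_per_group=n_per_group,
                      seed=config.seed + seed_offset)
    rng = np.random.default_rng(vconfig.seed)
    sample_ids, groups = _sample_ids(n_per_group)
    out = []
    for profile, n_feat in (("mir", config.n_mir), ("mrna", config.n_mrna)):
        ids = _feature_ids("mir" if profile == "mir" else "gene", n_feat)
        shift = np.zeros(n_feat)
        for fid, s in truth.de_features[profile]:
            shift[ids.index(fid)] = s
        baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_feat)
        noise = rng.normal(0.0, config.noise_sd, (n_feat, 2 * n_per_group))
        values = baseline[:, None] + noise
        values[:, n_per_group:] += shift[:, None]
        out.append(ExpressionMatrix(
            pd.DataFrame(values, index=ids, columns=sample_ids), groups))
    return out[0], out[1]
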