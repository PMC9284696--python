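"""miRNA-target binding prediction by complementarity alignment.

A miRNA binds where its sequence, read 3'->5', is complementary to the
target read 5'->3'.  We score that complementarity with a Smith-Waterman
style local dynamic programme over the reversed miRNA versus the target:
Watson-Crick pairs score ``match``, G:U wobbles ``wobble``, other
juxtapositions ``mismatch``, and gaps carry affine penalties
(``gap_open`` for the first column of a run, ``gap_extend`` for each
further column).  Pair scores (not gaps) are multiplied by
``seed_weight`` when the miRNA base lies in the seed region, positions
2-8 from the 5' end, reflecting the dominant role of seed pairing in
target recognition.

A candidate site is retained when its score reaches ``score_fraction``
(default 80%) of the miRNA's maximal attainable score -- the score of a
gap-free perfect complement of the full miRNA under the same weighting --
and when the duplex free energy, a nearest-neighbour stacking sum, is at
most ``energy_max`` (default -20 kcal/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

from .datatypes import AlignParams, BindingSite, InputError

RNA_ALPHABET = frozenset("ACGU")
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

GAP = "-"
_MASK = "N"  # masked target positions can never pair


def _load_stacking_table() -> dict[str, float]:
    """Nearest-neighbour RNA/RNA stack free energies, dG37 in kcal/mol.

    Keyed by the 5'->3' dinucleotide on the target strand; the 16 entries
    are the Watson-Crick values of Xia et al. (1998), symmetry-expanded.
    """
    text = resources.files("cernet").joinpath("data/rna_stacking.tsv").read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        dinuc, dg = line.split("\t")
        table[dinuc] = float(dg)
    if len(table) != 16:
        raise RuntimeError(f"stacking table must have 16 entries, found {len(table)}")
    return table


STACKING_DG = _load_stacking_table()


def clean_sequence(seq: str, what: str = "sequence") -> str:
    """Upper-case, map T->U, and validate against the RNA alphabet."""
    if not seq:
        raise InputError(f"empty {what}")
    s = seq.upper().replace("T", "U")
    for pos, ch in enumerate(s):
        if ch not in RNA_ALPHABET:
            raise InputError(f"invalid character {ch!r} at position {pos} in {what}")
    return s


def pair_kind(mir_base: str, target_base: str) -> str:
    """Classify one alignment column: 'match', 'wobble' or 'mismatch'."""
    if (mir_base, target_base) in _WC:
        return "match"
    if (mir_base, target_base) in _WOBBLE:
        return "wobble"
    return "mismatch"


def _pair_score(mir_base: str, target_base: str, params: AlignParams) -> float:
    kind = pair_kind(mir_base, target_base)
    if kind == "match":
        return params.match
    if kind == "wobble":
        return params.wobble
    return params.mismatch


def _seed_weights(mir_len: int, params: AlignParams) -> list[float]:
    """Per-base weight indexed by position in the *reversed* miRNA."""
    weights = []
    for i in range(mir_len):
        pos_5p = mir_len - i  # 1-based position from the miRNA 5' end
        in_seed = params.seed_start <= pos_5p <= params.seed_end
        weights.append(params.seed_weight if in_seed else 1.0)
    return weights


@dataclass(frozen=True)
class Alignment:
    """Best local alignment of a (reversed) miRNA against a target."""

    score: float
    target_start: int  # 0-based half-open on the target sense strand
    target_end: int
    mir_aligned: str    # miRNA 3'->5', with '-' for gaps
    target_aligned: str  # target 5'->3', with '-' for gaps


def align_mirna_target(mir_seq: str, target_seq: str, params: AlignParams | None = None,
                       *, _validated: bool = False) -> Alignment:
    """Locally align a miRNA (reversed, 3'->5') against a target (5'->3').

    Returns the maximal-scoring local alignment under the affine-gap,
    seed-weighted complementarity score.  Ties are broken toward the
    leftmost target interval (smallest end, then shortest alignment).
    """
    params = params or AlignParams()
    if not _validated:
        mir_seq = clean_sequence(mir_seq, "miRNA")
        target_seq = clean_sequence(target_seq, "target")
    a = mir_seq[::-1]  # miRNA 3'->5'
    b = target_seq
    n, m = len(a), len(b)
    w = _seed_weights(n, params)
    go, ge = params.gap_open, params.gap_extend
    neg = -math.inf

    # Gotoh local alignment. H: best ending at (i, j); X: ends with a gap in
    # the miRNA (consumes target); Y: ends with a gap in the target.
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]

    # per-row lookup: score of miRNA base i against each target symbol
    row_scores = []
    for i in range(n):
        tab = {sym: _pair_score(a[i], sym, params) * w[i] for sym in "ACGU"}
        tab[_MASK] = neg
        row_scores.append(tab)

    best, best_i, best_j = 0.0, 0, 0
    for i in range(1, n + 1):
        tab = row_scores[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Xi, Yi, Yp = X[i], Y[i], Y[i - 1]
        for j in range(1, m + 1):
            s = tab[b[j - 1]]
            x = Hi[j - 1] + go
            xe = Xi[j - 1] + ge
            if xe > x:
                x = xe
            y = Hp[j] + go
            ye = Yp[j] + ge
            if ye > y:
                y = ye
            h = Hp[j - 1] + s
            if x > h:
                h = x
            if y > h:
                h = y
            if h < 0.0:
                h = 0.0
            Xi[j] = x
            Yi[j] = y
            Hi[j] = h
            if h > best:
                best, best_i, best_j = h, i, j
    if best <= 0.0:
        return Alignment(0.0, 0, 0, "", "")

    # Traceback from (best_i, best_j), preferring pair columns on ties.
    mir_al: list[str] = []
    tgt_al: list[str] = []
    i, j, state = best_i, best_j, "H"
    while True:
        if state == "H":
            h = H[i][j]
            if h == 0.0:
                break
            s = _pair_score(a[i - 1], b[j - 1], params) * w[i - 1] \
                if b[j - 1] != _MASK else neg
            if i > 0 and j > 0 and h == H[i - 1][j - 1] + s:
                mir_al.append(a[i - 1])
                tgt_al.append(b[j - 1])
                i, j = i - 1, j - 1
            elif h == X[i][j]:
                state = "X"
            elif h == Y[i][j]:
                state = "Y"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed")
        elif state == "X":
            mir_al.append(GAP)
            tgt_al.append(b[j - 1])
            if X[i][j] == H[i][j - 1] + go:
                state = "H"
            j -= 1
        else:  # Y
            mir_al.append(a[i - 1])
            tgt_al.append(GAP)
            if Y[i][j] == H[i - 1][j] + go:
                state = "H"
            i -= 1
    target_start = j
    return Alignment(best, target_start, best_j,
                     "".join(reversed(mir_al)), "".join(reversed(tgt_al)))


def max_attainable_score(mir_seq: str, params: AlignParams | None = None) -> float:
    """Score of a gap-free perfect complement of the full miRNA."""
    params = params or AlignParams()
    mir_seq = clean_sequence(mir_seq, "miRNA")
    n = len(mir_seq)
    in_seed = sum(1 for p in range(1, n + 1)
                  if params.seed_start <= p <= params.seed_end)
    return params.match * (params.seed_weight * in_seed + (n - in_seed))


def duplex_energy(mir_aligned: str, target_aligned: str) -> float:
    """Duplex free energy of an alignment, kcal/mol.

    Sums nearest-neighbour stack energies over adjacent paired columns
    (Watson-Crick or wobble).  Gap and mismatch columns break stacks; an
    isolated pair contributes nothing.  The stack between paired columns
    j and j+1 is looked up by the target-strand dinucleotide 5'->3'.
    """
    if len(mir_aligned) != len(target_aligned):
        raise InputError("aligned strings differ in length")
    paired = []
    for mb, tb in zip(mir_aligned, target_aligned):
        if mb == GAP or tb == GAP:
            paired.append(False)
        else:
            paired.append(pair_kind(mb, tb) in ("match", "wobble"))
    if not any(paired):
        raise InputError("alignment has no paired column")
    dg = 0.0
    for j in range(len(paired) - 1):
        if paired[j] and paired[j + 1]:
            dg += STACKING_DG[target_aligned[j] + target_aligned[j + 1]]
    return dg


def _score_threshold(mir_seq: str, params: AlignParams) -> float:
    if params.absolute_score_min is not None:
        return params.absolute_score_min
    return params.score_fraction * max_attainable_score(mir_seq, params)


def predict_binding_sites(mir_seq: str, target_seq: str,
                          params: AlignParams | None = None,
                          max_sites: int = 32) -> list[BindingSite]:
    """All binding sites of a miRNA on one target passing both filters.

    Sites are discovered by repeated local alignment, masking each
    reported target interval before realigning, until the alignment score
    drops below the score threshold.  Candidates must reach the score
    threshold AND have duplex energy <= ``energy_max``.  Sorted by
    descending score (ties by target start).
    """
    params = params or AlignParams()
    mir_seq = clean_sequence(mir_seq, "miRNA")
    target_seq = clean_sequence(target_seq, "target")
    max_score = max_attainable_score(mir_seq, params)
    threshold = _score_threshold(mir_seq, params)

    sites: list[BindingSite] = []
    masked = list(target_seq)
    for _ in range(max_sites):
        aln = align_mirna_target(mir_seq, "".join(masked), params, _validated=True)
        if aln.score < threshold or aln.target_end <= aln.target_start:
            break
        energy = duplex_energy(aln.mir_aligned, aln.target_aligned)
        if energy <= params.energy_max:
            sites.append(BindingSite(
                mir_id="", target_id="",
                target_start=aln.target_start, target_end=aln.target_end,
                score=aln.score, max_score=max_score, energy=energy,
                mir_aligned=aln.mir_aligned, target_aligned=aln.target_aligned,
            ))
        for p in range(aln.target_start, aln.target_end):
            masked[p] = _MASK
    sites.sort(key=lambda s: (-s.score, s.target_start))
    return sites


def predict_pairs(mirnas: dict[str, str], targets: dict[str, str],
                  params: AlignParams | None = None) -> list[BindingSite]:
    """Best binding site for every (miRNA, target) pair that has one.

    The pair-level score used for network edges is the maximum site
    score; all sites can be recovered with :func:`predict_binding_sites`.
    """
    params = params or AlignParams()
    pairs: list[BindingSite] = []
    for tid in sorted(targets):
        for mid in sorted(mirnas):
            sites = predict_binding_sites(mirnas[mid], targets[tid], params)
            if sites:
                best = sites[0]
                pairs.append(BindingSite(
                    mir_id=mid, target_id=tid,
                    target_start=best.target_start, target_end=best.target_end,
                    score=best.score, max_score=best.max_score,
                    energy=best.energy, mir_aligned=best.mir_aligned,
                    target_aligned=best.target_aligned,
                ))
    return pairs


def revcomp_rna(seq: str) -> str:
    """Reverse complement on the RNA alphabet (A<->U, C<->G)."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in reversed(seq))
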