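"""Core data containers shared across the pipeline stages.

The canonical in-memory container for expression data is a pandas DataFrame
(features x samples, log2 scale) plus a per-sample group label.  Small value
objects (alignment parameters, binding sites, ceRNA triplets) are frozen
dataclasses so they can be collected, sorted and compared deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"
GROUPS = (CONTROL, CASE)


class InputError(ValueError):
    """Raised when user-supplied data violates a documented precondition."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values (features x samples) with group labels.

    Parameters
    ----------
    values : DataFrame
        Features in rows, samples in columns, finite log2 intensities.
    groups : Series
        One label per sample, ``"control"`` or ``"case"``, indexed by
        sample id in the same order as the columns of ``values``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate feature ids: {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample ids: {dup}")
        missing = [s for s in v.columns if s not in self.groups.index]
        if missing:
            raise InputError(f"samples without a group label: {missing}")
        self.groups = self.groups.reindex(v.columns)
        bad = sorted(set(self.groups.unique()) - set(GROUPS))
        if bad:
            raise InputError(f"unknown group labels: {bad} (expected {GROUPS})")
        for g in GROUPS:
            if int((self.groups == g).sum()) < 2:
                raise InputError(f"group {g!r} has fewer than 2 samples")
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise InputError(
                f"non-finite value at feature {v.index[i]!r}, sample {v.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix of the samples belonging to ``group``."""
        return self.values.loc[:, self.groups[self.groups == group].index]

    @property
    def n_control(self) -> int:
        return int((self.groups == CONTROL).sum())

    @property
    def n_case(self) -> int:
        return int((self.groups == CASE).sum())


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme for miRNA-target complementarity alignment.

    Defaults follow the published convention of seed-weighted local
    complementarity scanners: Watson-Crick match +5, G:U wobble +1,
    mismatch -3, affine gaps (first gap column ``gap_open``, each further
    column ``gap_extend``), with pair scores doubled when the miRNA base
    lies in the seed region (positions 2-8 from the 5' end).  Sites are
    retained when the alignment score reaches ``score_fraction`` of the
    miRNA's maximal attainable score and the duplex energy is at most
    ``energy_max`` kcal/mol.
    """

    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_weight: float = 2.0
    seed_start: int = 2   # 1-based, inclusive, from miRNA 5' end
    seed_end: int = 8     # 1-based, inclusive
    score_fraction: float = 0.80
    energy_max: float = -20.0
    absolute_score_min: float | None = None  # alternative to score_fraction

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise InputError(
                f"require gap_open <= gap_extend <= 0, got "
                f"({self.gap_open}, {self.gap_extend})"
            )
        if not (0 < self.score_fraction <= 1):
            raise InputError(f"score_fraction must be in (0, 1], got {self.score_fraction}")
        if not (1 <= self.seed_start <= self.seed_end):
            raise InputError("seed interval must satisfy 1 <= start <= end")


@dataclass(frozen=True)
class BindingSite:
    """A scored, energy-filtered miRNA-target duplex.

    Coordinates are 0-based half-open on the target sense strand; the
    aligned miRNA string runs 3'->5' against the target 5'->3'.
    """

    mir_id: str
    target_id: str
    target_start: int
    target_end: int
    score: float
    max_score: float
    energy: float
    mir_aligned: str
    target_aligned: str

    @property
    def ratio(self) -> float:
        return self.score / self.max_score


@dataclass(frozen=True)
class CeRNATriplet:
    """A direction-consistent circRNA-miRNA-mRNA sponge triple.

    By construction the circRNA and mRNA share a direction and the miRNA
    has the opposite one (the sponge hypothesis: the circRNA sequesters
    the miRNA, de-repressing the mRNA).
    """

    circ_id: str
    mir_id: str
    mrna_id: str
    circ_direction: str
    mir_direction: str
    mrna_direction: str
    binding_score: float
    evidence_count: int

    def __post_init__(self) -> None:
        if self.circ_direction != self.mrna_direction or (
            self.mir_direction == self.circ_direction
        ):
            raise AssertionError(
                f"direction-inconsistent triplet {self.circ_id}-{self.mir_id}-"
                f"{self.mrna_id}: {self.circ_direction}/{self.mir_direction}/"
                f"{self.mrna_direction}"
            )


@dataclass(frozen=True)
class InteractionRecord:
    """One row of the miRNA-target evidence table (starBase-like schema)."""

    mir_id: str
    gene_id: str
    flags: tuple[bool, bool, bool, bool, bool]

    @property
    def evidence_count(self) -> int:
        return sum(self.flags)


EVIDENCE_SOURCES = ("targetscan", "pictar", "rna22", "pita", "miranda")


@dataclass
class EnrichmentResult:
    """Gene-set over-representation result (one gene set)."""

    set_id: str
    set_name: str
    k: int           # overlap count
    K: int           # set size within background
    n: int           # query size
    N: int           # background size
    p: float
    overlap: tuple[str, ...] = ()
    disease_flag: bool = False

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class ConsistencyRecord:
    """Direction agreement of one network feature in a validation cohort."""

    feature_id: str
    rna_class: str
    training_direction: str
    validation_log2fc: float | None
    t: float | None
    p: float | None
    tested: bool

    @property
    def consistent(self) -> bool | None:
        if not self.tested:
            return None
        sign = "up" if self.validation_log2fc > 0 else "down"
        return sign == self.training_direction

    @property
    def significant(self) -> bool | None:
        if not self.tested:
            return None
        return self.p < 0.05
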