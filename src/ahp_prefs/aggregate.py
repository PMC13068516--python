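"""Group aggregation, consistency classification, stratification and
rank-reversal detection.

Two aggregation routes exist in the AHP literature.  Aggregation of
individual priorities (AIP) takes component-wise geometric means of the
respondents' priority vectors and renormalizes; aggregation of individual
judgments (AIJ) takes element-wise geometric means of the raw judgment
matrices and re-derives the eigenvector.  The two coincide exactly when
every respondent is perfectly consistent.  AIP is the default here because
the published study data consist of individual priority vectors; AIJ is
available for matrix-level data (simulated cohorts or raw judgment files).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, CohortWeightTable
from .core import (
    ConsistencyReport,
    PairwiseComparisonMatrix,
    PriorityVector,
    consistency_report,
    principal_eigenvector,
)

__all__ = [
    "GroupWeightResult",
    "InconsistencyBreakdown",
    "aggregate_priorities",
    "aggregate_judgments",
    "classify_inconsistency",
    "filter_consistent",
    "stratify_by_vas",
    "detect_rank_reversal",
]


@dataclass(frozen=True)
class GroupWeightResult:
    """Aggregated group weights for one respondent subset.

    ``consistency_level1``/``consistency_level2`` are populated only in AIJ
    mode, where a group matrix exists to diagnose.
    """

    mode: str                 # "aip" or "aij"
    subset: str               # human-readable subset description
    n: int
    level1: PriorityVector | None = None
    level2: PriorityVector | None = None
    consistency_level1: ConsistencyReport | None = None
    consistency_level2: ConsistencyReport | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("aip", "aij"):
            raise ValueError(f"unknown aggregation mode {self.mode!r}")
        if self.n < 1:
            raise ValueError("a group result needs at least one respondent")


@dataclass(frozen=True)
class InconsistencyBreakdown:
    """Counts of respondents exceeding the individual CR threshold.

    Identities: ``level1_only + level2_only + both_levels == any_level`` and
    ``level1_only + both_levels == level1_total``.
    """

    n: int
    any_level: int
    level1_only: int
    level2_only: int
    both_levels: int
    level1_total: int

    def __post_init__(self) -> None:
        if self.level1_only + self.level2_only + self.both_levels \
                != self.any_level:
            raise ValueError("breakdown counts violate the any-level identity")
        if self.level1_only + self.both_levels != self.level1_total:
            raise ValueError("breakdown counts violate the level-1 identity")


def aggregate_priorities(
    vectors: Sequence[PriorityVector],
) -> PriorityVector:
    """AIP: component-wise geometric mean of priority vectors, renormalized.

    All vectors must cover the same criteria in the same order and have
    strictly positive weights (renormalized fixture rows satisfy this; a
    zero weight has no geometric mean and must be handled upstream).
    """
    if not vectors:
        raise ValueError("cannot aggregate an empty collection of vectors")
    criteria = vectors[0].criteria
    for v in vectors[1:]:
        if v.criteria != criteria:
            raise ValueError(
                f"criteria mismatch: {v.criteria} vs {criteria}"
            )
    stacked = np.stack([v.weights for v in vectors])
    if np.any(stacked <= 0):
        raise ValueError(
            "zero weight encountered; renormalize or epsilon-adjust "
            "upstream before aggregating"
        )
    log_mean = np.log(stacked).mean(axis=0)
    return PriorityVector.from_raw(criteria, np.exp(log_mean))


def aggregate_judgments(
    matrices: Sequence[PairwiseComparisonMatrix],
) -> tuple[PairwiseComparisonMatrix, PriorityVector, ConsistencyReport]:
    """AIJ: element-wise geometric mean matrix, then the eigenvector.

    The geometric mean of reciprocal matrices is automatically reciprocal.
    Returns the group matrix, its priority vector and its consistency
    report.
    """
    if not matrices:
        raise ValueError("cannot aggregate an empty collection of matrices")
    criteria = matrices[0].criteria
    for m in matrices[1:]:
        if m.criteria != criteria:
            raise ValueError(f"criteria mismatch: {m.criteria} vs {criteria}")
    logs = np.stack([np.log(m.entries) for m in matrices]).mean(axis=0)
    group_entries = np.exp(logs)
    np.fill_diagonal(group_entries, 1.0)
    group = PairwiseComparisonMatrix(criteria, group_entries)
    priorities, _ = principal_eigenvector(group)
    return group, priorities, consistency_report(group)


def _flags(table: CohortWeightTable, threshold: float | None):
    """Per-respondent inconsistency flags: fixture flags by default, or
    recomputed from the stored CRs when an explicit threshold is given."""
    if threshold is None:
        return (
            table.frame["inc_l1"].to_numpy(),
            table.frame["inc_l2"].to_numpy(),
        )
    return (
        (table.frame["cr_l1"].to_numpy() > threshold),
        (table.frame["cr_l2"].to_numpy() > threshold),
    )


def classify_inconsistency(
    table: CohortWeightTable, threshold: float | None = None
) -> InconsistencyBreakdown:
    """Count respondents above the individual CR threshold per level.

    With ``threshold=None`` (default) the table's stored flags are used —
    for the bundled fixture these reproduce the published asterisks, which
    is deliberate because two respondents print CR exactly at the 0.20
    boundary.  An explicit ``threshold`` recomputes flags as ``cr >
    threshold``.
    """
    inc1, inc2 = _flags(table, threshold)
    both = int(np.sum(inc1 & inc2))
    only1 = int(np.sum(inc1 & ~inc2))
    only2 = int(np.sum(~inc1 & inc2))
    return InconsistencyBreakdown(
        n=len(table),
        any_level=only1 + only2 + both,
        level1_only=only1,
        level2_only=only2,
        both_levels=both,
        level1_total=only1 + both,
    )


def filter_consistent(
    table: CohortWeightTable,
    level: int | str = 1,
    threshold: float | None = None,
) -> CohortWeightTable:
    """Subset of respondents consistent at the requested level(s).

    ``level`` is 1, 2, or ``"either"`` (consistent at both levels).  Raises
    if nobody survives, since aggregation over an empty set is undefined.
    """
    inc1, inc2 = _flags(table, threshold)
    if level == 1:
        keep = ~inc1
    elif level == 2:
        keep = ~inc2
    elif level == "either":
        keep = ~(inc1 | inc2)
    else:
        raise ValueError("level must be 1, 2 or 'either'")
    ids = [pid for pid, k in zip(table.ids, keep) if k]
    if not ids:
        raise ValueError("no consistent respondents remain; aggregation "
                         "over an empty subset is undefined")
    return table.subset(ids)


def stratify_by_vas(
    cohort: Cohort, threshold: float = 75.0
) -> tuple[Cohort, Cohort]:
    """Split a cohort at a VAS utility threshold.

    Respondents with VAS strictly below ``threshold`` form the first
    (lower health-related quality of life) stratum; the threshold value
    itself belongs to the upper stratum.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("VAS threshold must lie in [0, 100]")
    below = [p.id for p in cohort.participants if p.vas < threshold]
    above = [p.id for p in cohort.participants if p.vas >= threshold]
    return cohort.subset(below), cohort.subset(above)


def detect_rank_reversal(
    reference: PriorityVector, comparison: PriorityVector
) -> list[tuple[str, str]]:
    """Unordered criterion pairs whose strict order differs between vectors.

    A pair counts as reversed only when both vectors order it strictly and
    the orders disagree; ties never count.
    """
    if reference.criteria != comparison.criteria:
        raise ValueError("vectors must cover the same criteria")
    crit = reference.criteria
    reversals = []
    for i in range(len(crit)):
        for j in range(i + 1, len(crit)):
            d_ref = reference.weights[i] - reference.weights[j]
            d_cmp = comparison.weights[i] - comparison.weights[j]
            if d_ref * d_cmp < 0:
                reversals.append((crit[i], crit[j]))
    return reversals
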