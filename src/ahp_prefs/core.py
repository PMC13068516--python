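"""Pairwise-comparison matrices, principal-eigenvector priorities and
consistency diagnostics.

This is the mathematical core of the Analytic Hierarchy Process (AHP): a
respondent compares criteria pairwise on the multiplicative Saaty scale
(integers 1..9 and their reciprocals), the judgments are assembled into a
positive reciprocal matrix, and the priority weights are the normalized
principal right eigenvector of that matrix.  Deviation of the principal
eigenvalue from the matrix order measures how far the judgments are from
transitive; normalized against the expected deviation of random matrices
(the random index) it yields the consistency ratio CR.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SAATY_VALUES",
    "DEFAULT_RI",
    "SaatyJudgment",
    "PairwiseComparisonMatrix",
    "PriorityVector",
    "ConsistencyReport",
    "ConvergenceError",
    "build_matrix",
    "principal_eigenvector",
    "consistency_report",
    "random_index",
    "read_judgments_csv",
]

#: The 17 admissible Saaty judgment values: 1/9 ... 1/2, 1, 2 ... 9.
SAATY_VALUES: np.ndarray = np.array(
    [1.0 / k for k in range(9, 1, -1)] + [float(k) for k in range(1, 10)]
)

_LOG_SAATY = np.log(SAATY_VALUES)

#: Classical published random-index table (mean consistency index of random
#: Saaty-scale reciprocal matrices, by order).  Values for order <= 2 are
#: exactly zero; the table can be re-derived by :func:`random_index`.
DEFAULT_RI: Mapping[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
}


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within the iteration budget."""


def _is_saaty(value: float, tol: float = 1e-9) -> bool:
    return bool(np.min(np.abs(SAATY_VALUES - value)) <= tol)


@dataclass(frozen=True)
class SaatyJudgment:
    """One pairwise comparison: how much more important ``criterion_a`` is
    than ``criterion_b``, as one of the 17 admissible Saaty ratios."""

    criterion_a: str
    criterion_b: str
    value: float

    def __post_init__(self) -> None:
        if self.criterion_a == self.criterion_b:
            raise ValueError(
                f"judgment compares {self.criterion_a!r} with itself"
            )
        if not _is_saaty(self.value):
            raise ValueError(
                f"{self.value!r} is not an admissible Saaty value "
                "(integers 1-9 or their reciprocals)"
            )


@dataclass(frozen=True)
class PairwiseComparisonMatrix:
    """A positive reciprocal judgment matrix over an ordered criterion set.

    Invariants enforced at construction: unit diagonal, reciprocity
    (``entries[i, j] * entries[j, i] == 1``) and all entries in ``[1/9, 9]``.
    Entries need not lie exactly on the Saaty scale: element-wise geometric
    means of judgment matrices (group aggregation) are also valid instances.
    """

    criteria: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "criteria", tuple(self.criteria))
        n = len(self.criteria)
        if n < 2:
            raise ValueError("a comparison matrix needs at least 2 criteria")
        if entries.shape != (n, n):
            raise ValueError(
                f"entries shape {entries.shape} does not match {n} criteria"
            )
        if len(set(self.criteria)) != n:
            raise ValueError("criteria identifiers must be unique")
        if not np.allclose(np.diag(entries), 1.0, atol=1e-12):
            raise ValueError("diagonal entries must all equal 1 (reflexivity)")
        if np.any(entries <= 0):
            raise ValueError("all entries must be positive")
        if not np.allclose(entries * entries.T, 1.0, atol=1e-9):
            raise ValueError("entries[i][j] * entries[j][i] must equal 1 "
                             "(reciprocity)")
        if np.any(entries < 1.0 / 9 - 1e-9) or np.any(entries > 9 + 1e-9):
            raise ValueError("entries must lie within [1/9, 9]")

    @property
    def order(self) -> int:
        return len(self.criteria)

    @classmethod
    def from_weights(
        cls, criteria: Sequence[str], weights: Sequence[float]
    ) -> "PairwiseComparisonMatrix":
        """Perfectly consistent matrix of ratios ``w_i / w_j``.

        Ratios are clipped to the admissible range [1/9, 9]; weight vectors
        with spread beyond 9:1 therefore lose information.
        """
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        ratios = np.clip(w[:, None] / w[None, :], 1.0 / 9, 9.0)
        np.fill_diagonal(ratios, 1.0)
        # restore exact reciprocity after clipping
        iu = np.triu_indices(len(w), 1)
        ratios[iu[1], iu[0]] = 1.0 / ratios[iu]
        return cls(tuple(criteria), ratios)

    def permuted(self, order: Sequence[int]) -> "PairwiseComparisonMatrix":
        """Simultaneous row/column permutation (same judgments, reordered)."""
        idx = np.asarray(order)
        return PairwiseComparisonMatrix(
            tuple(self.criteria[i] for i in idx),
            self.entries[np.ix_(idx, idx)],
        )


@dataclass(frozen=True)
class PriorityVector:
    """Nonnegative criterion weights summing to one (local or global)."""

    criteria: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "criteria", tuple(self.criteria))
        if len(self.criteria) != w.shape[0] or w.ndim != 1:
            raise ValueError("one weight per criterion required")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")

    @classmethod
    def from_raw(
        cls, criteria: Sequence[str], raw: Sequence[float]
    ) -> "PriorityVector":
        """Normalize an arbitrary positive vector to sum 1."""
        raw = np.asarray(raw, dtype=float)
        total = raw.sum()
        if total <= 0:
            raise ValueError("raw weights must have a positive sum")
        return cls(tuple(criteria), raw / total)

    def __getitem__(self, criterion: str) -> float:
        return float(self.weights[self.criteria.index(criterion)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.criteria, map(float, self.weights)))

    def ranking(self) -> list[str]:
        """Criteria ordered by decreasing weight (stable for ties)."""
        order = np.argsort(-self.weights, kind="stable")
        return [self.criteria[i] for i in order]


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency diagnostics for one judgment matrix.

    ``ci = (lambda_max - n) / (n - 1)`` and ``cr = ci / ri``; ``cr`` is 0 by
    definition for orders <= 2 (reciprocal matrices of order 2 are always
    transitive).  The verdicts apply Saaty's classical bound 0.1 and the
    relaxed bound 0.2 used for complex surveys that cannot be revised during
    the interview.
    """

    n: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    consistent_strict: bool
    consistent_relaxed: bool


def build_matrix(
    judgments: Iterable[SaatyJudgment], criteria: Sequence[str]
) -> PairwiseComparisonMatrix:
    """Assemble a full reciprocal matrix from one judgment per unordered pair.

    Exactly ``n(n-1)/2`` judgments are required; the reciprocal of each
    judgment and the unit diagonal are filled in automatically.
    """
    criteria = tuple(criteria)
    n = len(criteria)
    index = {c: i for i, c in enumerate(criteria)}
    entries = np.ones((n, n))
    seen: set[frozenset[str]] = set()
    for j in judgments:
        for c in (j.criterion_a, j.criterion_b):
            if c not in index:
                raise ValueError(f"unknown criterion {c!r}")
        pair = frozenset((j.criterion_a, j.criterion_b))
        if pair in seen:
            raise ValueError(
                f"duplicate judgment for pair "
                f"({j.criterion_a!r}, {j.criterion_b!r})"
            )
        seen.add(pair)
        a, b = index[j.criterion_a], index[j.criterion_b]
        entries[a, b] = j.value
        entries[b, a] = 1.0 / j.value
    expected = {
        frozenset((criteria[i], criteria[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }
    missing = expected - seen
    if missing:
        names = sorted(tuple(sorted(p)) for p in missing)
        raise ValueError(f"missing comparisons: {names}")
    return PairwiseComparisonMatrix(criteria, entries)


def principal_eigenvector(
    matrix: PairwiseComparisonMatrix,
    tolerance: float = 1e-10,
    max_iterations: int = 10_000,
) -> tuple[PriorityVector, float]:
    """Normalized principal right eigenvector and eigenvalue of ``matrix``.

    Power iteration starting from the uniform vector, renormalizing to sum 1
    each step and stopping when successive iterates differ by less than
    ``tolerance`` in max-norm.  ``lambda_max`` is estimated as the mean of
    the component-wise Rayleigh ratios ``(Mw)_i / w_i`` at convergence.
    Positive matrices always converge (Perron-Frobenius); the iteration
    budget is a guard only.
    """
    m = matrix.entries
    w = np.full(matrix.order, 1.0 / matrix.order)
    residual = np.inf
    for _ in range(max_iterations):
        mw = m @ w
        w_new = mw / mw.sum()
        residual = float(np.max(np.abs(w_new - w)))
        w = w_new
        if residual < tolerance:
            mw = m @ w
            lambda_max = float(np.mean(mw / w))
            return PriorityVector(matrix.criteria, w), lambda_max
    raise ConvergenceError(
        f"power iteration did not converge within {max_iterations} "
        f"iterations (last residual {residual:.3e})"
    )


def consistency_report(
    matrix: PairwiseComparisonMatrix,
    ri_table: Mapping[int, float] = DEFAULT_RI,
    tolerance: float = 1e-10,
) -> ConsistencyReport:
    """Consistency index/ratio of ``matrix`` against a random-index table."""
    n = matrix.order
    if n not in ri_table:
        raise KeyError(f"no random index available for matrix order {n}")
    _, lambda_max = principal_eigenvector(matrix, tolerance=tolerance)
    # lambda_max >= n holds analytically; clamp the numerical residue
    ci = max((lambda_max - n) / (n - 1), 0.0)
    ri = float(ri_table[n])
    cr = 0.0 if n <= 2 else ci / ri
    return ConsistencyReport(
        n=n,
        lambda_max=lambda_max,
        ci=ci,
        ri=ri,
        cr=cr,
        consistent_strict=cr <= 0.1,
        consistent_relaxed=cr <= 0.2,
    )


def random_index(n: int, n_samples: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo random index: mean consistency index of random matrices.

    Upper-triangle entries are drawn uniformly from the 17 admissible Saaty
    ratios, reciprocals filled in, and the mean CI over ``n_samples``
    matrices of order ``n`` is returned.  Orders 1 and 2 are exactly 0.
    """
    if n < 1:
        raise ValueError("matrix order must be >= 1")
    if n_samples < 1000:
        raise ValueError("need at least 1000 samples for a stable estimate")
    if n <= 2:
        return 0.0
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    total = 0.0
    chunk = 50_000
    remaining = n_samples
    while remaining > 0:
        size = min(chunk, remaining)
        vals = rng.choice(SAATY_VALUES, size=(size, len(iu[0])))
        mats = np.ones((size, n, n))
        mats[:, iu[0], iu[1]] = vals
        mats[:, iu[1], iu[0]] = 1.0 / vals
        lam = np.linalg.eigvals(mats).real.max(axis=1)
        total += float(((lam - n) / (n - 1)).sum())
        remaining -= size
    return total / n_samples


def _parse_saaty(text: str) -> float:
    """Parse a CSV judgment value: an integer ``k`` or the string ``1/k``."""
    text = text.strip()
    if "/" in text:
        num, den = text.split("/", 1)
        value = float(int(num)) / float(int(den))
    else:
        value = float(int(text))
    if not _is_saaty(value):
        raise ValueError(f"{text!r} is not an admissible Saaty value")
    return value


def read_judgments_csv(
    path,
) -> dict[int, dict[int, list[SaatyJudgment]]]:
    """Read raw pairwise judgments, keyed by participant id then level.

    Expected columns: ``participant_id, level, criterion_a, criterion_b,
    value`` with ``level`` in {1, 2} and ``value`` an integer ``k`` or the
    string ``1/k``.
    """
    required = {"participant_id", "level", "criterion_a", "criterion_b",
                "value"}
    out: dict[int, dict[int, list[SaatyJudgment]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            row for row in fh if not row.lstrip().startswith("#")
        )
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"judgments CSV must have columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                pid = int(row["participant_id"])
                level = int(row["level"])
                if level not in (1, 2):
                    raise ValueError("level must be 1 or 2")
                judgment = SaatyJudgment(
                    row["criterion_a"].strip(),
                    row["criterion_b"].strip(),
                    _parse_saaty(row["value"]),
                )
            except ValueError as exc:
                raise ValueError(f"judgments CSV line {lineno}: {exc}") from exc
            out.setdefault(pid, {}).setdefault(level, []).append(judgment)
    return out
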