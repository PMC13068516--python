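"""Synthetic-respondent generator.

Emulates the statistical structure the analysis pipeline assumes: each
respondent holds true criterion weights, and their pairwise judgments are
the true ratios ``w_i / w_j`` perturbed by multiplicative log-normal noise
and then discretized to the nearest admissible Saaty value on the log
scale.  Inconsistency arises from the noise (and, mildly, from the
discretization); its magnitude is linked to covariates through a
log-linear model on the per-respondent noise scale, so that the
inconsistency regression has a recoverable ground truth.

Seed protocol (kept stable because tests cross-check it against an
independent re-implementation): one ``numpy.random.Generator`` seeded from
``config.seed`` drives the whole cohort; covariates are drawn first for
all respondents (age, duration, VAS, gender, scheme — in that order, as
vectors), then per respondent the level-1 matrix draws its upper-triangle
noise row-major, followed by the level-2 matrix.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortWeightTable, ParticipantRecord
from .core import (
    SAATY_VALUES,
    PairwiseComparisonMatrix,
    PriorityVector,
    SaatyJudgment,
    consistency_report,
    principal_eigenvector,
)
from .hierarchy import LEVEL1_CRITERIA, LEVEL2_CRITERIA

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_respondent",
    "simulate_cohort",
    "paper_like_config",
    "load_simulation_config",
    "write_judgments_csv",
]

_LOG_SAATY = np.log(SAATY_VALUES)

#: Default group-level true weights: the published aggregated group weights
#: of the survey (level 1: mortality, MI, stroke, heart failure, adverse
#: events; level 2: pain, dyspnea, cough, edema).
DEFAULT_TRUE_L1 = (0.297, 0.202, 0.320, 0.119, 0.062)
DEFAULT_TRUE_L2 = (0.316, 0.397, 0.122, 0.165)

#: Fixture VAS utilities; the generator resamples these as its empirical
#: VAS distribution.
_FIXTURE_VAS = (60, 60, 50, 75, 40, 80, 80, 95, 75, 70, 70, 50, 80, 70, 50,
                65, 90, 90, 50, 80, 90, 80, 90, 90, 70, 80)

# Nominal locations/scales used both to draw covariates and to standardize
# them inside the inconsistency link (fixture-matched marginals).
_AGE_MEAN, _AGE_SD = 61.0, 12.0
_DUR_MEAN, _DUR_SD = 9.8, 6.9
_VAS_MEAN, _VAS_SD = 72.3, 15.3
_P_MALE, _P_COMBI = 0.5, 0.65


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings.

    ``sigma`` is the standard deviation of the log-ratio perturbation; the
    per-respondent scale is ``sigma * exp(linear predictor)`` where the
    linear predictor applies ``link`` coefficients to standardized
    continuous covariates (age, duration, vas) and centered 0/1 indicators
    (gender = male - 0.5, scheme = combi - 0.65).
    """

    n: int = 26
    true_level1: tuple[float, ...] = DEFAULT_TRUE_L1
    true_level2: tuple[float, ...] = DEFAULT_TRUE_L2
    sigma: float = 0.9
    link: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one respondent")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        for name, w in (("true_level1", self.true_level1),
                        ("true_level2", self.true_level2)):
            arr = np.asarray(w, dtype=float)
            if np.any(arr <= 0) or abs(arr.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name} must be positive and sum to 1")
        unknown = set(self.link) - {"vas", "gender", "age", "duration",
                                    "scheme"}
        if unknown:
            raise ValueError(f"unknown link covariates {sorted(unknown)}")
        object.__setattr__(self, "link", dict(self.link))

    @property
    def level1_vector(self) -> PriorityVector:
        return PriorityVector.from_raw(LEVEL1_CRITERIA, self.true_level1)

    @property
    def level2_vector(self) -> PriorityVector:
        return PriorityVector.from_raw(LEVEL2_CRITERIA, self.true_level2)


def _round_to_saaty(log_ratio: np.ndarray) -> np.ndarray:
    """Nearest admissible Saaty value, measured on the log scale (which
    also clips to [1/9, 9])."""
    idx = np.abs(
        np.asarray(log_ratio)[..., None] - _LOG_SAATY[None, :]
    ).argmin(axis=-1)
    return SAATY_VALUES[idx]


def _noisy_matrix(
    criteria: Sequence[str],
    weights: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> PairwiseComparisonMatrix:
    n = len(weights)
    iu = np.triu_indices(n, 1)
    log_ratio = np.log(weights[iu[0]] / weights[iu[1]])
    eps = rng.normal(0.0, sigma, size=len(iu[0]))
    vals = _round_to_saaty(log_ratio + eps)
    entries = np.ones((n, n))
    entries[iu] = vals
    entries[iu[1], iu[0]] = 1.0 / vals
    return PairwiseComparisonMatrix(tuple(criteria), entries)


def simulate_respondent(
    true_l1: PriorityVector,
    true_l2: PriorityVector,
    sigma: float,
    rng: np.random.Generator | int,
) -> tuple[PairwiseComparisonMatrix, PairwiseComparisonMatrix]:
    """One respondent's level-1 and level-2 judgment matrices.

    Each upper-triangle entry is ``(w_i / w_j) * exp(eps)`` with ``eps ~
    Normal(0, sigma^2)``, rounded to the nearest Saaty value on the log
    scale; reciprocals are filled in.  With ``sigma = 0`` and true ratios
    on the Saaty scale this is exactly the consistent ratio matrix.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m1 = _noisy_matrix(true_l1.criteria, true_l1.weights, sigma, rng)
    m2 = _noisy_matrix(true_l2.criteria, true_l2.weights, sigma, rng)
    return m1, m2


@dataclass(frozen=True)
class SimulatedCohort:
    """A generated cohort plus its raw matrices and generator ground truth."""

    cohort: Cohort
    matrices_level1: tuple[PairwiseComparisonMatrix, ...]
    matrices_level2: tuple[PairwiseComparisonMatrix, ...]
    sigmas: tuple[float, ...]
    config: SimulationConfig


def _draw_participants(
    n: int, rng: np.random.Generator
) -> list[ParticipantRecord]:
    age = np.clip(rng.normal(_AGE_MEAN, _AGE_SD, n), 18.0, 100.0)
    duration = np.maximum(rng.normal(_DUR_MEAN, _DUR_SD, n), 0.0)
    vas = rng.choice(np.asarray(_FIXTURE_VAS, dtype=float), size=n)
    male = rng.random(n) < _P_MALE
    combi = rng.random(n) < _P_COMBI
    return [
        ParticipantRecord(
            id=i + 1,
            age=float(round(age[i])),
            gender="m" if male[i] else "f",
            duration_years=float(round(duration[i], 1)),
            scheme="combi" if combi[i] else "mono",
            vas=float(vas[i]),
        )
        for i in range(n)
    ]


def _linear_predictor(
    p: ParticipantRecord, link: Mapping[str, float]
) -> float:
    z = {
        "vas": (p.vas - _VAS_MEAN) / _VAS_SD,
        "gender": (1.0 if p.gender == "m" else 0.0) - _P_MALE,
        "age": (p.age - _AGE_MEAN) / _AGE_SD,
        "duration": (p.duration_years - _DUR_MEAN) / _DUR_SD,
        "scheme": (1.0 if p.scheme == "combi" else 0.0) - _P_COMBI,
    }
    return sum(beta * z[name] for name, beta in link.items())


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort and push it through the weighting pipeline.

    Covariates are drawn per the fixture-matched marginals, each
    respondent's noise scale is ``sigma * exp(linear predictor)``, the two
    judgment matrices are generated, and the downstream weight table
    (eigenvector weights, CRs, CR > 0.2 flags) is computed with the core
    machinery.  Same seed, same cohort — bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    participants = _draw_participants(config.n, rng)
    true_l1 = config.level1_vector
    true_l2 = config.level2_vector

    rows = []
    mats1, mats2, sigmas = [], [], []
    for p in participants:
        sigma_i = config.sigma * float(
            np.exp(_linear_predictor(p, config.link))
        )
        m1, m2 = simulate_respondent(true_l1, true_l2, sigma_i, rng)
        w1, _ = principal_eigenvector(m1)
        w2, _ = principal_eigenvector(m2)
        r1 = consistency_report(m1)
        r2 = consistency_report(m2)
        rows.append({
            "id": p.id,
            **dict(zip(("w_mortality", "w_mi", "w_stroke", "w_hf", "w_ae"),
                       map(float, w1.weights))),
            **dict(zip(("w_pain", "w_dyspnea", "w_cough", "w_edema"),
                       map(float, w2.weights))),
            "cr_l1": r1.cr,
            "cr_l2": r2.cr,
            "inc_l1": not r1.consistent_relaxed,
            "inc_l2": not r2.consistent_relaxed,
        })
        mats1.append(m1)
        mats2.append(m2)
        sigmas.append(sigma_i)

    table = CohortWeightTable(pd.DataFrame(rows).set_index("id"))
    return SimulatedCohort(
        cohort=Cohort(tuple(participants), table),
        matrices_level1=tuple(mats1),
        matrices_level2=tuple(mats2),
        sigmas=tuple(sigmas),
        config=config,
    )


def paper_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration echoing the study conditions: 26 respondents, true
    weights equal to the published group weights, and a noise scale at
    which roughly 46% of respondents exceed CR 0.2 at the first level."""
    return replace(SimulationConfig(seed=seed), **overrides)


def load_simulation_config(path) -> SimulationConfig:
    """Read a generator config from a YAML key-value file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("simulation config must be a key-value mapping")
    kwargs = {}
    for key in ("n", "sigma", "seed"):
        if key in cfg:
            kwargs[key] = cfg[key]
    for key in ("true_level1", "true_level2"):
        if key in cfg:
            kwargs[key] = tuple(float(v) for v in cfg[key])
    if "link" in cfg:
        kwargs["link"] = {k: float(v) for k, v in (cfg["link"] or {}).items()}
    return SimulationConfig(**kwargs)


def _format_saaty(value: float) -> str:
    if value >= 1.0 - 1e-9:
        return str(int(round(value)))
    return f"1/{int(round(1.0 / value))}"


def write_judgments_csv(
    path,
    matrices: Mapping[int, Mapping[int, PairwiseComparisonMatrix]],
) -> None:
    """Write judgment matrices as upper-triangle rows in the CSV dialect
    read by :func:`ahp_prefs.core.read_judgments_csv`."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["participant_id", "level", "criterion_a", "criterion_b",
             "value"]
        )
        for pid in sorted(matrices):
            for level in sorted(matrices[pid]):
                m = matrices[pid][level]
                for i in range(m.order):
                    for j in range(i + 1, m.order):
                        writer.writerow([
                            pid, level, m.criteria[i], m.criteria[j],
                            _format_saaty(float(m.entries[i, j])),
                        ])


def judgments_from_matrix(
    matrix: PairwiseComparisonMatrix,
) -> list[SaatyJudgment]:
    """Upper-triangle judgments of a Saaty-valued matrix."""
    out = []
    for i in range(matrix.order):
        for j in range(i + 1, matrix.order):
            out.append(SaatyJudgment(
                matrix.criteria[i], matrix.criteria[j],
                float(matrix.entries[i, j]),
            ))
    return out
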