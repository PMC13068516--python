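"""Study-cohort data model: participants, per-respondent weights, fixtures.

The bundled fixtures transcribe the published baseline-characteristics and
individual-weight tables of the 26-respondent hypertension preference
survey.  Weight rows are stored at their printed 3-dp precision, so they
sum to 1 only approximately; :func:`validate_weight_rows` flags rows whose
deviation exceeds a tolerance and all downstream consumers renormalize.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Sequence
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .core import PriorityVector
from .hierarchy import LEVEL1_CRITERIA, LEVEL2_CRITERIA

__all__ = [
    "ParticipantRecord",
    "CohortWeightTable",
    "Cohort",
    "CohortSummary",
    "load_cohort",
    "load_fixture_cohort",
    "validate_weight_rows",
    "write_cohort",
    "cohort_summary",
]

logger = logging.getLogger(__name__)

GENDERS = ("m", "f")
SCHEMES = ("mono", "combi")

LEVEL1_COLUMNS = ("w_mortality", "w_mi", "w_stroke", "w_hf", "w_ae")
LEVEL2_COLUMNS = ("w_pain", "w_dyspnea", "w_cough", "w_edema")
WEIGHT_COLUMNS = LEVEL1_COLUMNS + LEVEL2_COLUMNS + (
    "cr_l1", "cr_l2", "inc_l1", "inc_l2",
)
PARTICIPANT_COLUMNS = ("id", "age", "gender", "duration_years", "scheme",
                       "vas")


@dataclass(frozen=True)
class ParticipantRecord:
    """One respondent's covariates.

    ``vas`` is the EQ-5D visual analogue scale utility in percent (0-100);
    ``scheme`` distinguishes antihypertensive mono- from combination
    therapy.
    """

    id: int
    age: float
    gender: str
    duration_years: float
    scheme: str
    vas: float

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError(f"participant {self.id}: age {self.age} below "
                             "the adult inclusion criterion")
        if self.gender not in GENDERS:
            raise ValueError(f"participant {self.id}: gender must be one of "
                             f"{GENDERS}, got {self.gender!r}")
        if self.duration_years < 0:
            raise ValueError(f"participant {self.id}: negative treatment "
                             "duration")
        if self.scheme not in SCHEMES:
            raise ValueError(f"participant {self.id}: scheme must be one of "
                             f"{SCHEMES}, got {self.scheme!r}")
        if not 0 <= self.vas <= 100:
            raise ValueError(f"participant {self.id}: VAS {self.vas} outside "
                             "[0, 100]")


class CohortWeightTable:
    """Per-respondent level-1/level-2 weights, consistency ratios and flags.

    Wraps a :class:`pandas.DataFrame` indexed by participant id with columns
    ``w_mortality, w_mi, w_stroke, w_hf, w_ae, w_pain, w_dyspnea, w_cough,
    w_edema, cr_l1, cr_l2, inc_l1, inc_l2``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(WEIGHT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"weight table missing columns {sorted(missing)}")
        frame = frame.copy()
        frame.index.name = "id"
        frame["inc_l1"] = frame["inc_l1"].astype(bool)
        frame["inc_l2"] = frame["inc_l2"].astype(bool)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> list[int]:
        return [int(i) for i in self.frame.index]

    def subset(self, ids: Sequence[int]) -> "CohortWeightTable":
        return CohortWeightTable(self.frame.loc[list(ids)])

    def _vectors(self, columns, criteria) -> list[PriorityVector]:
        return [
            PriorityVector.from_raw(criteria, row)
            for row in self.frame[list(columns)].to_numpy(dtype=float)
        ]

    def level1_vectors(self) -> list[PriorityVector]:
        """Per-respondent level-1 priority vectors, renormalized to sum 1."""
        return self._vectors(LEVEL1_COLUMNS, LEVEL1_CRITERIA)

    def level2_vectors(self) -> list[PriorityVector]:
        """Per-respondent level-2 local priority vectors, renormalized."""
        return self._vectors(LEVEL2_COLUMNS, LEVEL2_CRITERIA)


@dataclass(frozen=True)
class Cohort:
    """Participants joined with their weight table (matching ids)."""

    participants: tuple[ParticipantRecord, ...]
    weights: CohortWeightTable

    def __post_init__(self) -> None:
        object.__setattr__(self, "participants", tuple(self.participants))
        pids = [p.id for p in self.participants]
        if len(set(pids)) != len(pids):
            raise ValueError("duplicate participant ids")
        if pids != self.weights.ids:
            raise ValueError(
                "participant ids do not match weight-table ids"
            )

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def ids(self) -> list[int]:
        return [p.id for p in self.participants]

    def subset(self, ids: Sequence[int]) -> "Cohort":
        keep = set(ids)
        parts = tuple(p for p in self.participants if p.id in keep)
        return Cohort(parts, self.weights.subset([p.id for p in parts]))

    def to_json(self, path=None) -> str:
        """Serialize the full cohort (participants + weights) as JSON."""
        payload = {
            "participants": [asdict(p) for p in self.participants],
            "weights": json.loads(
                self.weights.frame.reset_index().to_json(orient="records")
            ),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    missing = set(required) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def load_cohort(participants_path, weights_path) -> Cohort:
    """Load and validate a cohort from the two CSV dialects.

    Raises ``ValueError`` naming the offending row for missing columns,
    unparseable cells, or id mismatches between the two files.
    """
    pframe = _read_csv(participants_path, PARTICIPANT_COLUMNS)
    participants = []
    for pos, row in enumerate(pframe.itertuples(index=False)):
        try:
            participants.append(ParticipantRecord(
                id=int(row.id),
                age=float(row.age),
                gender=str(row.gender),
                duration_years=float(row.duration_years),
                scheme=str(row.scheme),
                vas=float(row.vas),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{participants_path}: data row {pos + 1}: {exc}"
            ) from exc

    wframe = _read_csv(weights_path, ("id",) + WEIGHT_COLUMNS)
    try:
        wframe["id"] = wframe["id"].astype(int)
        for col in WEIGHT_COLUMNS:
            if col in ("inc_l1", "inc_l2"):
                wframe[col] = wframe[col].astype(int).astype(bool)
            else:
                wframe[col] = wframe[col].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{weights_path}: unparseable cell: {exc}") from exc
    if wframe["id"].duplicated().any():
        dup = wframe.loc[wframe["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{weights_path}: duplicate ids {dup}")
    table = CohortWeightTable(wframe.set_index("id"))

    pids = [p.id for p in participants]
    if pids != table.ids:
        extra = sorted(set(table.ids) - set(pids))
        absent = sorted(set(pids) - set(table.ids))
        raise ValueError(
            f"participant/weight id mismatch: only in weights {extra}, "
            f"only in participants {absent}"
        )
    return Cohort(tuple(participants), table)


def load_fixture_cohort() -> Cohort:
    """The bundled 26-respondent cohort transcribed from the published
    study tables."""
    data = resources.files("ahp_prefs.data")
    with resources.as_file(data.joinpath("participants.csv")) as ppath, \
            resources.as_file(data.joinpath("weights.csv")) as wpath:
        return load_cohort(ppath, wpath)


def validate_weight_rows(
    table: CohortWeightTable, tolerance: float = 0.01
) -> list[tuple[int, int, float]]:
    """Flag weight rows deviating from sum 1 by more than ``tolerance``.

    Returns ``(participant id, level, deviation)`` tuples.  Flagged rows are
    renormalized by downstream vector accessors in any case; a warning is
    logged here so silent transcription damage cannot propagate.
    """
    flagged = []
    for level, columns in ((1, LEVEL1_COLUMNS), (2, LEVEL2_COLUMNS)):
        sums = table.frame[list(columns)].sum(axis=1)
        for pid, total in sums.items():
            dev = abs(float(total) - 1.0)
            if dev > tolerance:
                flagged.append((int(pid), level, dev))
                logger.warning(
                    "participant %s level-%d weights sum to %.3f "
                    "(deviation %.3f > %.3f); row is renormalized before "
                    "aggregation", pid, level, total, dev, tolerance,
                )
    return flagged


def write_cohort(cohort: Cohort, participants_path, weights_path) -> None:
    """Write a cohort back to the two CSV dialects (round-trip safe)."""
    pd.DataFrame([asdict(p) for p in cohort.participants]).rename(
        columns={}
    ).to_csv(participants_path, index=False)
    out = cohort.weights.frame.copy()
    out["inc_l1"] = out["inc_l1"].astype(int)
    out["inc_l2"] = out["inc_l2"].astype(int)
    out.reset_index().to_csv(weights_path, index=False)


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean_age: float
    sd_age: float
    pct_male: float
    mean_duration: float
    sd_duration: float
    pct_combination: float
    mean_vas: float
    sd_vas: float
    n_vas_ge_90: int
    n_vas_le_60: int


def cohort_summary(participants: Sequence[ParticipantRecord]) -> CohortSummary:
    """Descriptive statistics of the participant table (sample SD)."""
    if not participants:
        raise ValueError("empty participant list")
    age = np.array([p.age for p in participants], dtype=float)
    dur = np.array([p.duration_years for p in participants], dtype=float)
    vas = np.array([p.vas for p in participants], dtype=float)
    male = np.array([p.gender == "m" for p in participants])
    combi = np.array([p.scheme == "combi" for p in participants])
    ddof = 1 if len(participants) > 1 else 0
    return CohortSummary(
        n=len(participants),
        mean_age=float(age.mean()),
        sd_age=float(age.std(ddof=ddof)),
        pct_male=float(male.mean() * 100),
        mean_duration=float(dur.mean()),
        sd_duration=float(dur.std(ddof=ddof)),
        pct_combination=float(combi.mean() * 100),
        mean_vas=float(vas.mean()),
        sd_vas=float(vas.std(ddof=ddof)),
        n_vas_ge_90=int((vas >= 90).sum()),
        n_vas_le_60=int((vas <= 60).sum()),
    )
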