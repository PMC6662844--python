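"""Cohort data model, tabular I/O, exclusion rule and median split.

A *cohort* is a list of :class:`Participant` records, each carrying an
inattention/hyperactivity trait score on the ADHD rating scale (integer,
0-54) given by the child's teacher and, optionally, by a parent.  The
parent score is used only as a control: children whose parent rating
exceeds the teacher rating by more than one standard deviation are
excluded, and the retained cohort is dichotomised at the median of the
teacher scores into ``low`` / ``high`` groups for the tail analyses.

Search productions are stored as :class:`SearchPath` objects: ordered
:class:`Event` records that carry 2-D board coordinates (visual
cancellation task) or lower-cased tokens (semantic fluency task), with
optional timestamps.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Maximum attainable score on the 18-item rating scale (9 inattention +
#: 9 hyperactivity/impulsivity items, each 0-3).
SCALE_MAX = 54

COHORT_COLUMNS = ["id", "teacher_score", "parent_score", "age_months"]
PATH_COLUMNS = ["participant_id", "task", "index", "x_mm", "y_mm", "token", "t_sec"]


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the score/shape contract."""


class Group(str, enum.Enum):
    LOW = "low"
    HIGH = "high"
    UNASSIGNED = "unassigned"


class Task(str, enum.Enum):
    VISUAL = "visual"
    SEMANTIC = "semantic"


@dataclasses.dataclass
class Participant:
    id: str
    teacher_score: int
    parent_score: int | None = None
    age_months: int | None = None
    included: bool = True
    group: Group = Group.UNASSIGNED

    def __post_init__(self) -> None:
        self.teacher_score = _validate_score(self.teacher_score, "teacher_score")
        if self.parent_score is not None:
            self.parent_score = _validate_score(self.parent_score, "parent_score")


@dataclasses.dataclass
class Event:
    """One production event: a cancelled target or an uttered token."""

    index: int
    x: float | None = None
    y: float | None = None
    token: str | None = None
    t: float | None = None

    @property
    def has_coordinates(self) -> bool:
        return self.x is not None and self.y is not None


@dataclasses.dataclass
class SearchPath:
    participant_id: str
    task: Task
    events: list[Event]
    duration_budget: float = 120.0

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        for ev in self.events:
            spatial = ev.has_coordinates
            lexical = ev.token is not None
            if spatial == lexical:
                raise ValueError(
                    f"event {ev.index} of {self.participant_id}/{self.task.value}: "
                    "exactly one of coordinates or token must be populated"
                )
            if self.task is Task.VISUAL and not spatial:
                raise ValueError("visual events must carry coordinates")
            if self.task is Task.SEMANTIC and not lexical:
                raise ValueError("semantic events must carry a token")
        ts = [ev.t for ev in self.events if ev.t is not None]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"timestamps of {self.participant_id} are not non-decreasing")

    @property
    def tokens(self) -> list[str]:
        return [ev.token for ev in self.events if ev.token is not None]

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([[ev.x, ev.y] for ev in self.events if ev.has_coordinates], dtype=float)


def _validate_score(value, field: str) -> int:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise CohortValidationError(f"missing {field}")
    if float(value) != int(value):
        raise CohortValidationError(f"{field} must be an integer, got {value!r}")
    value = int(value)
    if not 0 <= value <= SCALE_MAX:
        raise CohortValidationError(f"{field}={value} outside [0, {SCALE_MAX}]")
    return value


def _opt_int(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return int(value)


def read_cohort(path: str | Path) -> list[Participant]:
    """Read a cohort CSV (columns ``id,teacher_score[,parent_score,age_months]``).

    Raises :class:`CohortValidationError` naming the offending row for a
    missing teacher score, a fractional score, or a score outside
    ``[0, 54]``.
    """
    df = pd.read_csv(path, comment="#")
    if "id" not in df.columns or "teacher_score" not in df.columns:
        raise CohortValidationError("cohort file must have columns 'id' and 'teacher_score'")
    cohort: list[Participant] = []
    for i, row in df.iterrows():
        try:
            cohort.append(
                Participant(
                    id=str(row["id"]),
                    teacher_score=row["teacher_score"],
                    parent_score=_validate_score(row["parent_score"], "parent_score")
                    if "parent_score" in df.columns and not pd.isna(row.get("parent_score"))
                    else None,
                    age_months=_opt_int(row.get("age_months")),
                )
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"row {i}: {exc}") from None
    return cohort


def write_cohort(cohort: Sequence[Participant], path: str | Path, seed: int | None = None) -> None:
    """Write a cohort CSV with a provenance comment header."""
    from . import __version__

    df = pd.DataFrame(
        {
            "id": [p.id for p in cohort],
            "teacher_score": [p.teacher_score for p in cohort],
            "parent_score": [p.parent_score for p in cohort],
            "age_months": [p.age_months for p in cohort],
        }
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# generated-by foragetails {__version__} seed={seed}\n")
        df.to_csv(fh, index=False)


def write_paths(paths: Iterable[SearchPath], path: str | Path, seed: int | None = None) -> None:
    """Write search paths as long-format CSV (one row per event)."""
    from . import __version__

    rows = []
    for sp in paths:
        for ev in sp.events:
            rows.append(
                {
                    "participant_id": sp.participant_id,
                    "task": sp.task.value,
                    "index": ev.index,
                    "x_mm": ev.x,
                    "y_mm": ev.y,
                    "token": ev.token,
                    "t_sec": ev.t,
                }
            )
    df = pd.DataFrame(rows, columns=PATH_COLUMNS)
    out = Path(path)
    with out.open("w") as fh:
        fh.write(f"# generated-by foragetails {__version__} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_paths(path: str | Path) -> list[SearchPath]:
    """Read a long-format path CSV back into :class:`SearchPath` objects."""
    df = pd.read_csv(path, comment="#")
    paths: list[SearchPath] = []
    for (pid, task), grp in df.groupby(["participant_id", "task"], sort=False):
        grp = grp.sort_values("index")
        events = []
        for _, row in grp.iterrows():
            token = row["token"] if isinstance(row["token"], str) else None
            x = None if pd.isna(row["x_mm"]) else float(row["x_mm"])
            y = None if pd.isna(row["y_mm"]) else float(row["y_mm"])
            t = None if pd.isna(row["t_sec"]) else float(row["t_sec"])
            events.append(Event(index=int(row["index"]), x=x, y=y, token=token, t=t))
        paths.append(SearchPath(participant_id=str(pid), task=Task(task), events=events))
    return paths


def apply_exclusion_rule(
    cohort: list[Participant], sd_reference: str = "teacher"
) -> list[Participant]:
    """Flag participants whose parent score exceeds the teacher score by > 1 SD.

    ``sd_reference`` selects which standard deviation defines the cut:
    ``teacher`` (default; the analysis covariate), ``parent``, or
    ``difference`` (SD of parent - teacher).  Sample SD (n-1 denominator)
    over currently included participants.  Participants without a parent
    score are never excluded; a cohort with no parent scores at all is a
    no-op with a warning.
    """
    if sd_reference not in {"teacher", "parent", "difference"}:
        raise ValueError(f"unknown sd_reference {sd_reference!r}")
    included = [p for p in cohort if p.included]
    with_parent = [p for p in included if p.parent_score is not None]
    if not with_parent:
        warnings.warn("no parent scores present; exclusion rule is a no-op", stacklevel=2)
        return cohort
    if sd_reference == "teacher":
        ref = [p.teacher_score for p in included]
    elif sd_reference == "parent":
        ref = [p.parent_score for p in with_parent]
    else:
        ref = [p.parent_score - p.teacher_score for p in with_parent]
    sd = float(np.std(ref, ddof=1)) if len(ref) > 1 else 0.0
    n_excluded = 0
    for p in with_parent:
        if p.parent_score - p.teacher_score > sd:
            p.included = False
            n_excluded += 1
    logger.info(
        "exclusion rule (sd_reference=%s, sd=%.3f): excluded %d of %d",
        sd_reference, sd, n_excluded, len(included),
    )
    return cohort


def cohort_median(cohort: Sequence[Participant]) -> float:
    """Median teacher score over included participants."""
    scores = [p.teacher_score for p in cohort if p.included]
    if not scores:
        raise CohortValidationError("no included participants")
    return float(np.median(scores))


def median_split(cohort: list[Participant]) -> list[Participant]:
    """Assign ``low``/``high`` groups by the median of included teacher scores.

    Scores strictly greater than the median go to ``high``; ties at the
    median stay ``low``.  Excluded participants remain ``unassigned``.
    """
    m = cohort_median(cohort)
    scores = {p.teacher_score for p in cohort if p.included}
    if len(scores) == 1:
        warnings.warn("all scores identical; every participant assigned to 'low'", stacklevel=2)
    for p in cohort:
        if p.included:
            p.group = Group.HIGH if p.teacher_score > m else Group.LOW
    logger.info("median split at m=%.1f", m)
    return cohort
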