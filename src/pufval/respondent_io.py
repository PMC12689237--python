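"""Respondent-level survey records: data model, validation, CSV/JSON I/O.

One record per completed interview: the respondent's own EQ-5D-5L state,
the dimension-weighting (swing) task, the within-dimension level ratings,
the dead-vs-55555 anchoring task, demographics and timestamps. Records are
flat rows in CSV (the shape survey exports arrive in); JSON carries the
same field names, with nested ``swing``/``levels``/``anchor`` maps accepted
as an alternative schema on read.

Validation is collect-then-fail: a file is scanned completely and every
violation is reported with its row number before a
:class:`CohortValidationError` is raised.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .descriptive_system import (
    DIMENSIONS,
    Dimension,
    HealthState,
    StateCodeError,
    parse_state,
)

LANGUAGES = ("English", "Afrikaans", "Zulu", "Tswana")
AGE_GROUPS = ("20-39", "40-59", "60+")
GENDERS = ("male", "female")
ETHNICITIES = ("Black African", "Coloured", "Asian/Indian", "White")
INCOME_AREAS = ("low", "other")
WAVES = ("pilot", "1", "2", "3")
ASSISTANCE_LEVELS = ("none_minimal", "some", "a_lot")

_TIME_FORMAT = "seconds"  # ISO-8601, 1-second precision


class AnchorPreference(str, Enum):
    """Outcome of the dead-vs-55555 choice.

    ``DEAD_OVER_PITS``: dead preferred; 55555 is fixed at zero on the VAS
    and ``vas`` rates dead (the paper's *a*). ``PITS_OVER_DEAD_OR_INDIFFERENT``:
    55555 preferred or indifferent; dead is fixed at zero and ``vas`` rates
    55555 (*b*). Indifference is folded into the second branch with vas = 0.
    """

    DEAD_OVER_PITS = "DEAD_OVER_PITS"
    PITS_OVER_DEAD_OR_INDIFFERENT = "PITS_OVER_DEAD_OR_INDIFFERENT"


class CohortValidationError(ValueError):
    """Validation failure; ``errors`` lists every offending row/field."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        preview = "\n  ".join(self.errors[:20])
        more = "" if len(self.errors) <= 20 else f"\n  ... {len(self.errors) - 20} more"
        super().__init__(f"{len(self.errors)} validation error(s):\n  {preview}{more}")


@dataclass(frozen=True)
class SwingResponse:
    """Dimension-weighting task: the most important dimension is the
    measuring stick fixed at 100; the other four are rated 0-100 against it."""

    most_important: Dimension
    rating: Mapping[Dimension, float]

    def validate(self) -> list[str]:
        errs = []
        for d in DIMENSIONS:
            r = self.rating.get(d)
            if r is None:
                errs.append(f"swing rating missing for {d.value}")
            elif not (0.0 <= r <= 100.0):
                errs.append(f"swing_{d.value}={r} outside [0, 100]")
        mi = self.rating.get(self.most_important)
        if mi is not None and mi != 100.0:
            errs.append(
                f"most important dimension {self.most_important.value} must be "
                f"rated exactly 100, got {mi}"
            )
        return errs


@dataclass(frozen=True)
class LevelResponse:
    """Level-rating task: per dimension the VAS ratings of levels 2-4.

    Level 1 is automatically 100 and level 5 automatically 0; only the three
    free ratings are stored. ``ratings[d]`` is the (r2, r3, r4) triple.
    """

    ratings: Mapping[Dimension, tuple[float, float, float]]

    def rating(self, dim: Dimension, level: int) -> float:
        """VAS rating of ``level`` in ``dim``, including the implied endpoints."""
        if level == 1:
            return 100.0
        if level == 5:
            return 0.0
        return self.ratings[dim][level - 2]

    def validate(self) -> list[str]:
        errs = []
        for d in DIMENSIONS:
            triple = self.ratings.get(d)
            if triple is None or len(triple) != 3:
                errs.append(f"level ratings missing for {d.value}")
                continue
            for lev, r in zip((2, 3, 4), triple):
                if not (0.0 <= r <= 100.0):
                    errs.append(f"r{lev}_{d.value}={r} outside [0, 100]")
        return errs


@dataclass(frozen=True)
class AnchorResponse:
    """Anchoring task outcome: preference branch plus the single free VAS
    rating (dead's rating *a*, or the 55555 rating *b*; see
    :class:`AnchorPreference`)."""

    preference: AnchorPreference
    vas: float

    def validate(self) -> list[str]:
        if not (0.0 <= self.vas <= 100.0):
            return [f"anchor_vas={self.vas} outside [0, 100]"]
        return []


@dataclass(frozen=True)
class Respondent:
    id: str
    language: str
    age_group: str
    gender: str
    ethnicity: str
    income_area: str
    wave: str
    self_state: HealthState
    swing: SwingResponse
    levels: LevelResponse
    anchor: AnchorResponse
    start_time: datetime
    end_time: datetime
    assistance: str

    def validate(self) -> list[str]:
        errs = []
        if not self.id:
            errs.append("id is empty")
        for val, allowed, name in (
            (self.language, LANGUAGES, "language"),
            (self.age_group, AGE_GROUPS, "age_group"),
            (self.gender, GENDERS, "gender"),
            (self.ethnicity, ETHNICITIES, "ethnicity"),
            (self.income_area, INCOME_AREAS, "income_area"),
            (self.wave, WAVES, "wave"),
            (self.assistance, ASSISTANCE_LEVELS, "assistance"),
        ):
            if val not in allowed:
                errs.append(f"{name}={val!r} not one of {allowed}")
        errs.extend(self.swing.validate())
        errs.extend(self.levels.validate())
        errs.extend(self.anchor.validate())
        if self.end_time < self.start_time:
            errs.append(
                f"end_time {self.end_time.isoformat()} before start_time "
                f"{self.start_time.isoformat()}"
            )
        return errs


def duration_minutes(r: Respondent) -> float:
    """Survey duration in minutes from the first/last answer timestamps."""
    delta = (r.end_time - r.start_time).total_seconds()
    if delta < 0:
        raise CohortValidationError(
            [f"respondent {r.id}: end_time before start_time"]
        )
    return delta / 60.0


# ---------------------------------------------------------------------------
# Flat-row serialization

CSV_COLUMNS: tuple[str, ...] = (
    "id",
    "language",
    "age_group",
    "gender",
    "ethnicity",
    "income_area",
    "wave",
    "self_state",
    "most_important",
    *(f"swing_{d.value}" for d in DIMENSIONS),
    *(f"r{lev}_{d.value}" for d in DIMENSIONS for lev in (2, 3, 4)),
    "anchor_preference",
    "anchor_vas",
    "start_time",
    "end_time",
    "assistance",
)


def _to_row(r: Respondent) -> dict[str, object]:
    row: dict[str, object] = {
        "id": r.id,
        "language": r.language,
        "age_group": r.age_group,
        "gender": r.gender,
        "ethnicity": r.ethnicity,
        "income_area": r.income_area,
        "wave": r.wave,
        "self_state": r.self_state.code,
        "most_important": r.swing.most_important.value,
        "anchor_preference": r.anchor.preference.value,
        "anchor_vas": r.anchor.vas,
        "start_time": r.start_time.isoformat(timespec=_TIME_FORMAT),
        "end_time": r.end_time.isoformat(timespec=_TIME_FORMAT),
        "assistance": r.assistance,
    }
    for d in DIMENSIONS:
        row[f"swing_{d.value}"] = r.swing.rating[d]
    for d in DIMENSIONS:
        r2, r3, r4 = r.levels.ratings[d]
        row[f"r2_{d.value}"], row[f"r3_{d.value}"], row[f"r4_{d.value}"] = r2, r3, r4
    return row


def _parse_float(raw: object, name: str, errs: list[str]) -> float:
    try:
        return float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        errs.append(f"{name}={raw!r} is not a number")
        return float("nan")


def _from_row(row: Mapping[str, object], where: str) -> tuple[Respondent | None, list[str]]:
    errs: list[str] = []
    missing = [c for c in CSV_COLUMNS if c not in row]
    if missing:
        return None, [f"{where}: missing column(s) {missing}"]

    try:
        self_state = parse_state(str(row["self_state"]))
    except StateCodeError as e:
        errs.append(f"{where}: self_state {e}")
        self_state = HealthState((1, 1, 1, 1, 1))

    mi_raw = str(row["most_important"])
    try:
        most_important = Dimension(mi_raw)
    except ValueError:
        errs.append(f"{where}: most_important={mi_raw!r} not a dimension code")
        most_important = Dimension.MO

    swing_ratings = {
        d: _parse_float(row[f"swing_{d.value}"], f"{where}: swing_{d.value}", errs)
        for d in DIMENSIONS
    }
    level_ratings = {
        d: tuple(
            _parse_float(row[f"r{lev}_{d.value}"], f"{where}: r{lev}_{d.value}", errs)
            for lev in (2, 3, 4)
        )
        for d in DIMENSIONS
    }

    pref_raw = str(row["anchor_preference"])
    try:
        preference = AnchorPreference(pref_raw)
    except ValueError:
        errs.append(f"{where}: anchor_preference={pref_raw!r} unknown")
        preference = AnchorPreference.PITS_OVER_DEAD_OR_INDIFFERENT
    anchor_vas = _parse_float(row["anchor_vas"], f"{where}: anchor_vas", errs)

    times = {}
    for name in ("start_time", "end_time"):
        try:
            times[name] = datetime.fromisoformat(str(row[name]))
        except ValueError:
            errs.append(f"{where}: {name}={row[name]!r} is not ISO-8601")
            times[name] = datetime(1970, 1, 1)

    if errs:
        return None, errs

    resp = Respondent(
        id=str(row["id"]),
        language=str(row["language"]),
        age_group=str(row["age_group"]),
        gender=str(row["gender"]),
        ethnicity=str(row["ethnicity"]),
        income_area=str(row["income_area"]),
        wave=str(row["wave"]),
        self_state=self_state,
        swing=SwingResponse(most_important=most_important, rating=swing_ratings),
        levels=LevelResponse(ratings=level_ratings),  # type: ignore[arg-type]
        anchor=AnchorResponse(preference=preference, vas=anchor_vas),
        start_time=times["start_time"],
        end_time=times["end_time"],
        assistance=str(row["assistance"]),
    )
    errs = [f"{where}: {e}" for e in resp.validate()]
    return (resp if not errs else None), errs


def _from_nested(obj: Mapping[str, object], where: str) -> tuple[Respondent | None, list[str]]:
    """Accept the nested JSON schema: swing/levels/anchor as sub-objects."""
    flat = dict(obj)
    swing = flat.pop("swing", None)
    if isinstance(swing, Mapping):
        flat["most_important"] = swing.get("most_important")
        for d in DIMENSIONS:
            flat[f"swing_{d.value}"] = swing.get("rating", {}).get(d.value)
    levels = flat.pop("levels", None)
    if isinstance(levels, Mapping):
        for d in DIMENSIONS:
            triple = levels.get(d.value, [None, None, None])
            for lev, val in zip((2, 3, 4), triple):
                flat[f"r{lev}_{d.value}"] = val
    anchor = flat.pop("anchor", None)
    if isinstance(anchor, Mapping):
        flat["anchor_preference"] = anchor.get("preference")
        flat["anchor_vas"] = anchor.get("vas")
    return _from_row(flat, where)


def read_respondents(path: str | Path, format: str | None = None) -> list[Respondent]:
    """Read and validate a cohort from CSV or JSON.

    The whole file is scanned before failing; the raised
    :class:`CohortValidationError` lists every offending row and field.
    ``format`` defaults to the file extension.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("csv", "json"):
        raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'json'")

    records: list[Respondent] = []
    errors: list[str] = []
    if fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in CSV_COLUMNS if c not in header]
            if missing:
                raise CohortValidationError([f"header missing column(s) {missing}"])
            for i, row in enumerate(reader, start=2):  # header is line 1
                resp, errs = _from_row(row, f"row {i}")
                errors.extend(errs)
                if resp is not None:
                    records.append(resp)
    else:
        with path.open() as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise CohortValidationError(["JSON root must be an array of records"])
        for i, obj in enumerate(data):
            parse = _from_nested if "swing" in obj else _from_row
            resp, errs = parse(obj, f"record {i}")
            errors.extend(errs)
            if resp is not None:
                records.append(resp)

    if errors:
        raise CohortValidationError(errors)
    return records


def write_respondents(
    records: Iterable[Respondent], path: str | Path, format: str | None = None
) -> None:
    """Write a cohort to CSV or JSON; round-trips losslessly through
    :func:`read_respondents` (scores bit-exact, timestamps to 1 s)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("csv", "json"):
        raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'json'")
    rows = [_to_row(r) for r in records]
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            # QUOTE_NONNUMERIC keeps state codes quoted so spreadsheets do
            # not coerce "11111" to an integer.
            writer = csv.DictWriter(
                fh, fieldnames=list(CSV_COLUMNS), quoting=csv.QUOTE_NONNUMERIC
            )
            writer.writeheader()
            writer.writerows(rows)
    else:
        with path.open("w") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")
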