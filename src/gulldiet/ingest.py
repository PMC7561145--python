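"""Typed records and CSV input/output for the four field tables.

The pipeline consumes four tabular inputs collected at a breeding colony:

``pellets.csv``
    One row per regurgitated pellet: territory, date, the fraction of the
    pellet made up of each of six prey categories, and an optional
    unidentifiable residual.
``carcasses.csv``
    One row per territory search visit: date, days since the territory was
    last searched, a baseline flag (first visit, old remains destroyed and
    excluded from rates), and one count column per prey species/age class.
``territories.csv``
    Per-territory covariates: the four nest-to-boundary axis distances,
    shoreline access, nearest-neighbor distance, treatment group and the
    Julian hatch date of the first egg.
``behavior_events.csv`` / ``behavior_effort.csv``
    Annotated attack/aggression events and the observation effort
    (territory-hours) they were drawn from.

All fractions, counts and distances are validated on read; malformed rows
raise :class:`ValidationError` with the offending row number.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Fixed prey-category order used by every 6-vector in the package.
CATEGORIES: tuple[str, ...] = (
    "fish",
    "plant",
    "invertebrate",
    "mammal",
    "bird",
    "garbage",
)

BIRD_INDEX = CATEGORIES.index("bird")

_FRACTION_TOL = 1e-9


class SchemaError(ValueError):
    """A CSV is missing a declared column or has an unusable layout."""


class ValidationError(ValueError):
    """A row violates a record invariant; the message names the row."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PelletRecord:
    """One regurgitated pellet as a fractional composition over six categories.

    ``fractions`` follows :data:`CATEGORIES` order.  An optional
    ``unidentifiable`` residual is carried separately and never folded back
    into the category vector: ``sum(fractions) + unidentifiable == 1``.
    """

    territory_id: str
    date: _dt.date
    fractions: tuple[float, ...]
    unidentifiable: float = 0.0

    def __post_init__(self) -> None:
        if len(self.fractions) != len(CATEGORIES):
            raise ValidationError(
                f"pellet needs {len(CATEGORIES)} fractions, got {len(self.fractions)}"
            )
        if any(f < -_FRACTION_TOL or f > 1 + _FRACTION_TOL for f in self.fractions):
            raise ValidationError(f"pellet fractions outside [0,1]: {self.fractions}")
        if not (-_FRACTION_TOL <= self.unidentifiable <= 1 + _FRACTION_TOL):
            raise ValidationError(
                f"unidentifiable residual outside [0,1]: {self.unidentifiable}"
            )
        total = sum(self.fractions) + self.unidentifiable
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"pellet fractions + residual sum to {total!r}, expected 1"
            )


@dataclass(frozen=True)
class CarcassVisit:
    """Carcasses found at one territory on one search visit.

    ``counts`` maps a species/age label (e.g. ``ring_billed_gull_chick``) to
    a non-negative integer.  The first visit per territory is flagged
    ``baseline``: old remains were destroyed, so it anchors the search clock
    but is excluded from kill-rate computations.
    """

    territory_id: str
    date: _dt.date
    days_since_last_search: float
    counts: Mapping[str, int]
    baseline: bool = False

    def __post_init__(self) -> None:
        if not self.baseline and self.days_since_last_search <= 0:
            raise ValidationError(
                f"days_since_last_search must be > 0, got {self.days_since_last_search}"
            )
        for key, value in self.counts.items():
            if value < 0:
                raise ValidationError(f"negative carcass count for {key}: {value}")
        # canonical form: positive counts only (zero entries carry no information)
        object.__setattr__(
            self, "counts", {k: int(v) for k, v in self.counts.items() if v > 0}
        )

    @property
    def total_carcasses(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class TerritoryCovariates:
    """Per-territory covariates used by the GLM covariate screen.

    ``axis_lengths`` holds the four nest-to-defense-boundary distances (m),
    two per orthogonal axis; territory area is the product of the two summed
    axis extents.  ``hatch_date`` is the Julian day (Jan 1 = 1) of the first
    egg hatching, or None when unknown.
    """

    territory_id: str
    axis_lengths: tuple[float, float, float, float]
    shoreline_access: bool
    nearest_neighbor_distance: float
    treatment: str | None = None  # "near" | "away" | None
    hatch_date: int | None = None

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.axis_lengths):
            raise ValidationError(f"negative axis length: {self.axis_lengths}")
        if self.nearest_neighbor_distance < 0:
            raise ValidationError("nearest_neighbor_distance must be >= 0")
        if self.treatment is not None and self.treatment not in ("near", "away"):
            raise ValidationError(f"unknown treatment {self.treatment!r}")

    @property
    def area(self) -> float:
        return territory_area(self.axis_lengths)


@dataclass(frozen=True)
class BehaviorEvent:
    """One interaction between a focal adult and an intruder/prey bird.

    The four booleans are the criteria separating a predatory attack from
    ordinary territorial aggression; ``behaviors`` lists (label, minutes
    since the initial attack) pairs for the timing histogram.
    """

    territory_id: str
    start_time: _dt.datetime
    actor: str  # "focal_adult" | "intruder"
    behaviors: tuple[tuple[str, float], ...] = ()
    chased_into_territory: bool = False
    pursued_after_escape: bool = False
    drowning_attempt: bool = False
    eating_attempt: bool = False
    outcome: str = "unresolved"  # "kill" | "escape" | "unresolved"
    duration_min: float | None = None

    def __post_init__(self) -> None:
        for label, minutes in self.behaviors:
            if minutes < 0:
                raise ValidationError(
                    f"behavior {label!r} at negative minutes {minutes}"
                )
        if self.outcome not in ("kill", "escape", "unresolved"):
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.duration_min is not None and self.duration_min < 0:
            raise ValidationError("duration_min must be >= 0")


@dataclass(frozen=True)
class ObservationEffort:
    """Observation effort at one territory: method and territory-hours."""

    territory_id: str
    method: str  # "in_person" | "video" | "colony_camera"
    hours: float

    def __post_init__(self) -> None:
        if self.hours <= 0:
            raise ValidationError(f"effort hours must be > 0, got {self.hours}")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def territory_area(axis_lengths: Sequence[float]) -> float:
    """Territory area (m²) from four nest-to-boundary distances.

    The defended territory is approximated as a rectangle whose side lengths
    are the summed extents along two orthogonal axes measured from the nest:
    ``area = (d_N + d_S) * (d_E + d_W)``.
    """
    if len(axis_lengths) != 4:
        raise ValueError("territory_area needs exactly four distances")
    d1, d2, d3, d4 = axis_lengths
    if min(axis_lengths) < 0:
        raise ValueError(f"negative axis length: {axis_lengths}")
    return (d1 + d2) * (d3 + d4)


def dichotomize_area(area: float, threshold: float) -> str:
    """Classify a territory as ``"large"`` (area >= threshold) or ``"small"``.

    The boundary is inclusive: an area exactly at the threshold is large.
    The conventional threshold is the sample mean area.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return "large" if area >= threshold else "small"


def julian_day(date: _dt.date) -> int:
    """Day-of-year with January 1 = 1."""
    return date.timetuple().tm_yday


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

_PELLET_FIXED = ["territory_id", "date"]
_CARCASS_FIXED = ["territory_id", "date", "days_since_last_search", "baseline"]
_TERRITORY_COLUMNS = [
    "territory_id",
    "axis_1",
    "axis_2",
    "axis_3",
    "axis_4",
    "shoreline_access",
    "nearest_neighbor_distance",
    "treatment",
    "hatch_date",
]
_EVENT_COLUMNS = [
    "territory_id",
    "start_time",
    "actor",
    "behaviors",
    "chased_into_territory",
    "pursued_after_escape",
    "drowning_attempt",
    "eating_attempt",
    "outcome",
    "duration_min",
]
_EFFORT_COLUMNS = ["territory_id", "method", "hours"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def _parse_date(value: str, row: int, name: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"{name} row {row}: bad ISO date {value!r}") from exc


def read_pellets(path: str | Path) -> list[PelletRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _PELLET_FIXED + list(CATEGORIES), "pellets")
    has_resid = "unidentifiable" in df.columns
    records: list[PelletRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = row 1
        row = row._asdict()
        fractions = tuple(float(row[c]) for c in CATEGORIES)
        resid = float(row["unidentifiable"]) if has_resid else 0.0
        try:
            records.append(
                PelletRecord(
                    territory_id=row["territory_id"],
                    date=_parse_date(row["date"], i, "pellets"),
                    fractions=fractions,
                    unidentifiable=resid,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"pellets row {i}: {exc}") from exc
    return records


def read_carcasses(path: str | Path) -> list[CarcassVisit]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _CARCASS_FIXED, "carcasses")
    count_cols = [c for c in df.columns if c not in _CARCASS_FIXED]
    visits: list[CarcassVisit] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        counts = {
            c: int(row[c]) for c in count_cols if str(row[c]) not in ("", "0")
        }
        try:
            visits.append(
                CarcassVisit(
                    territory_id=row["territory_id"],
                    date=_parse_date(row["date"], i, "carcasses"),
                    days_since_last_search=float(row["days_since_last_search"]),
                    counts=counts,
                    baseline=_parse_bool(row["baseline"], i, "carcasses"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"carcasses row {i}: {exc}") from exc
    return visits


def read_territories(path: str | Path) -> list[TerritoryCovariates]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _TERRITORY_COLUMNS, "territories")
    out: list[TerritoryCovariates] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            out.append(
                TerritoryCovariates(
                    territory_id=row["territory_id"],
                    axis_lengths=tuple(
                        float(row[f"axis_{k}"]) for k in (1, 2, 3, 4)
                    ),
                    shoreline_access=_parse_bool(
                        row["shoreline_access"], i, "territories"
                    ),
                    nearest_neighbor_distance=float(
                        row["nearest_neighbor_distance"]
                    ),
                    treatment=row["treatment"] or None,
                    hatch_date=int(row["hatch_date"]) if row["hatch_date"] else None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"territories row {i}: {exc}") from exc
    return out


def read_behavior_events(path: str | Path) -> list[BehaviorEvent]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _EVENT_COLUMNS, "behavior_events")
    events: list[BehaviorEvent] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            events.append(
                BehaviorEvent(
                    territory_id=row["territory_id"],
                    start_time=_dt.datetime.fromisoformat(row["start_time"]),
                    actor=row["actor"],
                    behaviors=_parse_behaviors(row["behaviors"], i),
                    chased_into_territory=_parse_bool(
                        row["chased_into_territory"], i, "behavior_events"
                    ),
                    pursued_after_escape=_parse_bool(
                        row["pursued_after_escape"], i, "behavior_events"
                    ),
                    drowning_attempt=_parse_bool(
                        row["drowning_attempt"], i, "behavior_events"
                    ),
                    eating_attempt=_parse_bool(
                        row["eating_attempt"], i, "behavior_events"
                    ),
                    outcome=row["outcome"],
                    duration_min=float(row["duration_min"])
                    if row["duration_min"]
                    else None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"behavior_events row {i}: {exc}") from exc
    return events


def read_effort(path: str | Path) -> list[ObservationEffort]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _EFFORT_COLUMNS, "behavior_effort")
    return [
        ObservationEffort(r.territory_id, r.method, float(r.hours))
        for r in df.itertuples(index=False)
    ]


def read_tables(paths: Mapping[str, str | Path]) -> dict[str, list]:
    """Read and validate every table present in ``paths``.

    ``paths`` maps table names (``pellets``, ``carcasses``, ``territories``,
    ``behavior_events``, ``behavior_effort``) to CSV files; only the tables
    provided are read.
    """
    readers = {
        "pellets": read_pellets,
        "carcasses": read_carcasses,
        "territories": read_territories,
        "behavior_events": read_behavior_events,
        "behavior_effort": read_effort,
    }
    unknown = set(paths) - set(readers)
    if unknown:
        raise SchemaError(f"unknown tables: {sorted(unknown)}")
    return {name: readers[name](path) for name, path in paths.items()}


# -- writers (round-trip exact: floats serialized via repr) -----------------


def _fmt(value: float) -> str:
    return repr(float(value))


def write_pellets(records: Sequence[PelletRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"territory_id": r.territory_id, "date": r.date.isoformat()}
        row.update({c: _fmt(f) for c, f in zip(CATEGORIES, r.fractions)})
        row["unidentifiable"] = _fmt(r.unidentifiable)
        rows.append(row)
    pd.DataFrame(rows, columns=_PELLET_FIXED + list(CATEGORIES) + ["unidentifiable"]).to_csv(
        path, index=False
    )


def write_carcasses(visits: Sequence[CarcassVisit], path: str | Path) -> None:
    count_cols = sorted({k for v in visits for k in v.counts})
    rows = []
    for v in visits:
        row = {
            "territory_id": v.territory_id,
            "date": v.date.isoformat(),
            "days_since_last_search": _fmt(v.days_since_last_search),
            "baseline": str(v.baseline),
        }
        row.update({c: str(int(v.counts.get(c, 0))) for c in count_cols})
        rows.append(row)
    pd.DataFrame(rows, columns=_CARCASS_FIXED + count_cols).to_csv(path, index=False)


def write_territories(recs: Sequence[TerritoryCovariates], path: str | Path) -> None:
    rows = []
    for t in recs:
        rows.append(
            {
                "territory_id": t.territory_id,
                **{f"axis_{k + 1}": _fmt(d) for k, d in enumerate(t.axis_lengths)},
                "shoreline_access": str(t.shoreline_access),
                "nearest_neighbor_distance": _fmt(t.nearest_neighbor_distance),
                "treatment": t.treatment or "",
                "hatch_date": "" if t.hatch_date is None else str(t.hatch_date),
            }
        )
    pd.DataFrame(rows, columns=_TERRITORY_COLUMNS).to_csv(path, index=False)


def write_behavior_events(events: Sequence[BehaviorEvent], path: str | Path) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "territory_id": e.territory_id,
                "start_time": e.start_time.isoformat(),
                "actor": e.actor,
                "behaviors": ";".join(f"{lab}@{_fmt(m)}" for lab, m in e.behaviors),
                "chased_into_territory": str(e.chased_into_territory),
                "pursued_after_escape": str(e.pursued_after_escape),
                "drowning_attempt": str(e.drowning_attempt),
                "eating_attempt": str(e.eating_attempt),
                "outcome": e.outcome,
                "duration_min": "" if e.duration_min is None else _fmt(e.duration_min),
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def write_effort(efforts: Sequence[ObservationEffort], path: str | Path) -> None:
    rows = [
        {"territory_id": e.territory_id, "method": e.method, "hours": _fmt(e.hours)}
        for e in efforts
    ]
    pd.DataFrame(rows, columns=_EFFORT_COLUMNS).to_csv(path, index=False)


def write_tables(tables: Mapping[str, Sequence], outdir: str | Path) -> dict[str, Path]:
    """Write every provided record collection as CSV into ``outdir``."""
    writers = {
        "pellets": write_pellets,
        "carcasses": write_carcasses,
        "territories": write_territories,
        "behavior_events": write_behavior_events,
        "behavior_effort": write_effort,
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, records in tables.items():
        if name not in writers:
            raise SchemaError(f"unknown table {name!r}")
        paths[name] = outdir / f"{name}.csv"
        writers[name](records, paths[name])
    return paths


def _parse_bool(value: str, row: int, name: str) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise ValidationError(f"{name} row {row}: bad boolean {value!r}")


def _parse_behaviors(raw: str, row: int) -> tuple[tuple[str, float], ...]:
    if not raw:
        return ()
    out = []
    for item in raw.split(";"):
        try:
            label, minutes = item.rsplit("@", 1)
            out.append((label, float(minutes)))
        except ValueError as exc:
            raise ValidationError(
                f"behavior_events row {row}: bad behaviors entry {item!r}"
            ) from exc
    return tuple(out)
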