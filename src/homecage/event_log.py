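"""Canonical event-log data model and TSV I/O.

One row per corner visit, with per-side nose-poke and lick counts.  Times are
float seconds since experiment start; all windowing downstream uses half-open
intervals [start, end) so an event at a bottle-exchange instant belongs to
exactly one session.

The canonical dialect is tab-separated with columns::

    animal_id  corner  t_start  t_end  nosepokes_left  nosepokes_right  licks_left  licks_right

Rows that violate a model invariant (negative counts, t_end < t_start, corner
outside 1-4) are rejected and reported on the returned table rather than
raising, because real cage logs contain transponder glitches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, ValidationError

#: Canonical column order of the event TSV dialect.
COLUMNS = [
    "animal_id",
    "corner",
    "t_start",
    "t_end",
    "nosepokes_left",
    "nosepokes_right",
    "licks_left",
    "licks_right",
]

_COUNT_COLUMNS = ["nosepokes_left", "nosepokes_right", "licks_left", "licks_right"]

SIDES = ("left", "right")


@dataclass
class VisitRecord:
    """A single corner visit by one animal."""

    animal_id: str
    corner: int
    t_start: float
    t_end: float
    nosepokes_left: int = 0
    nosepokes_right: int = 0
    licks_left: int = 0
    licks_right: int = 0

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def licks(self) -> int:
        return self.licks_left + self.licks_right

    @property
    def nosepokes(self) -> int:
        return self.nosepokes_left + self.nosepokes_right

    def bottle_index(self, side: str) -> int:
        """Bottle number 1-8, numbered clockwise: corner k owns 2k-1 (left), 2k (right)."""
        if side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {side!r}")
        return 2 * self.corner - 1 if side == "left" else 2 * self.corner

    def validate(self) -> None:
        if self.corner not in (1, 2, 3, 4):
            raise ValidationError(f"corner must be 1-4, got {self.corner}")
        if self.t_end < self.t_start:
            raise ValidationError(
                f"t_end < t_start ({self.t_end} < {self.t_start}) for {self.animal_id}"
            )
        for col in _COUNT_COLUMNS:
            if getattr(self, col) < 0:
                raise ValidationError(f"{col} negative for {self.animal_id}")


def empty_frame() -> pd.DataFrame:
    """An empty event frame with canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "animal_id": pd.Series(dtype=str),
            "corner": pd.Series(dtype=np.int64),
            "t_start": pd.Series(dtype=float),
            "t_end": pd.Series(dtype=float),
            "nosepokes_left": pd.Series(dtype=np.int64),
            "nosepokes_right": pd.Series(dtype=np.int64),
            "licks_left": pd.Series(dtype=np.int64),
            "licks_right": pd.Series(dtype=np.int64),
        }
    )


def make_roster(
    animal_ids: Sequence[str],
    sex: Sequence[str] | str | None = None,
    weight_g: Sequence[float] | float | None = None,
) -> pd.DataFrame:
    """Build a roster frame (animal_id, sex, weight_g) from parallel sequences."""
    n = len(animal_ids)
    if len(set(animal_ids)) != n:
        raise ValidationError("duplicate animal_id in roster")
    if sex is None:
        sex = ["?"] * n
    elif isinstance(sex, str):
        sex = [sex] * n
    if weight_g is None:
        weight_g = [float("nan")] * n
    elif np.isscalar(weight_g):
        weight_g = [float(weight_g)] * n
    return pd.DataFrame(
        {"animal_id": list(animal_ids), "sex": list(sex), "weight_g": list(weight_g)}
    )


@dataclass
class EventTable:
    """Time-ordered corner-visit records for one cage cohort.

    Attributes
    ----------
    df : pandas.DataFrame
        Canonical-column frame, sorted by ``t_start`` (stable sort; ties keep
        input order).
    roster : pandas.DataFrame
        Columns ``animal_id``, ``sex``, ``weight_g``; every ``animal_id`` in
        ``df`` must appear here.
    light_offset_h : float
        Clock hour (0-24) at which the light phase starts, relative to
        experiment start; dark phase is assumed to span 12 h starting 12 h
        later.
    rejected : pandas.DataFrame
        Rows dropped during validation, with a ``reason`` column.  Empty for
        tables built programmatically.
    """

    df: pd.DataFrame
    roster: pd.DataFrame
    light_offset_h: float = 0.0
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.roster) < 1:
            raise ValidationError("roster must contain at least one animal")
        known = set(self.roster["animal_id"])
        unknown = set(self.df["animal_id"]) - known
        if unknown:
            raise ValidationError(f"animal_id not in roster: {sorted(unknown)}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[VisitRecord],
        roster: pd.DataFrame | None = None,
        light_offset_h: float = 0.0,
    ) -> "EventTable":
        rows = []
        for rec in records:
            rec.validate()
            rows.append(
                {
                    "animal_id": rec.animal_id,
                    "corner": rec.corner,
                    "t_start": rec.t_start,
                    "t_end": rec.t_end,
                    "nosepokes_left": rec.nosepokes_left,
                    "nosepokes_right": rec.nosepokes_right,
                    "licks_left": rec.licks_left,
                    "licks_right": rec.licks_right,
                }
            )
        df = pd.DataFrame(rows, columns=COLUMNS) if rows else empty_frame()
        df = df.sort_values("t_start", kind="stable").reset_index(drop=True)
        if roster is None:
            seen = list(dict.fromkeys(df["animal_id"]))
            roster = make_roster(seen if seen else ["unknown"])
        return cls(df=df, roster=roster, light_offset_h=light_offset_h)

    # -- views -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def animals(self) -> list[str]:
        return list(self.roster["animal_id"])

    def records(self) -> Iterator[VisitRecord]:
        for row in self.df.itertuples(index=False):
            yield VisitRecord(
                animal_id=row.animal_id,
                corner=int(row.corner),
                t_start=float(row.t_start),
                t_end=float(row.t_end),
                nosepokes_left=int(row.nosepokes_left),
                nosepokes_right=int(row.nosepokes_right),
                licks_left=int(row.licks_left),
                licks_right=int(row.licks_right),
            )

    def equals(self, other: "EventTable") -> bool:
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        return a.equals(b)

    def for_animal(self, animal_id: str) -> pd.DataFrame:
        return self.df[self.df["animal_id"] == animal_id]


# ---------------------------------------------------------------------------
# I/O


def write_events(table: EventTable, path) -> None:
    """Write an EventTable to the canonical TSV dialect (UTF-8)."""
    table.df.to_csv(path, sep="\t", index=False, columns=COLUMNS, encoding="utf-8")


def read_events(path, roster: pd.DataFrame | None = None) -> EventTable:
    """Read an event TSV, validate rows and return a sorted :class:`EventTable`.

    Invalid rows are dropped and collected on ``table.rejected`` with a
    ``reason`` column.  Unsorted input is repaired with a warning.  If a
    roster is supplied, an animal_id absent from it raises
    :class:`ValidationError`.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"animal_id": str},
            encoding="utf-8",
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty (no header)") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[COLUMNS]

    reasons = pd.Series("", index=df.index, dtype=str)
    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & ~bad
        reasons[fresh] = reason
        bad[fresh] = True

    if len(df):
        flag(~df["corner"].isin([1, 2, 3, 4]), "corner outside 1-4")
        flag(df["t_end"] < df["t_start"], "t_end < t_start")
        for col in _COUNT_COLUMNS:
            flag(df[col] < 0, f"negative {col}")
        flag(df[["t_start", "t_end"]].isna().any(axis=1), "missing timestamp")

    rejected = df[bad].copy()
    if len(rejected):
        rejected["reason"] = reasons[bad]
        warnings.warn(f"{path}: rejected {len(rejected)} invalid row(s)", stacklevel=2)
    df = df[~bad].reset_index(drop=True)

    if len(df) and not df["t_start"].is_monotonic_increasing:
        warnings.warn(f"{path}: timestamps not sorted; repairing", stacklevel=2)
        df = df.sort_values("t_start", kind="stable").reset_index(drop=True)

    for col in ["corner"] + _COUNT_COLUMNS:
        df[col] = df[col].astype(np.int64)
    df["t_start"] = df["t_start"].astype(float)
    df["t_end"] = df["t_end"].astype(float)

    if roster is None:
        seen = list(dict.fromkeys(df["animal_id"]))
        roster = make_roster(seen if seen else ["unknown"])
    table = EventTable(df=df, roster=roster, rejected=rejected)
    return table


def read_roster(path) -> pd.DataFrame:
    """Read a roster config block (YAML: list of {animal_id, sex, weight_g})."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict) and "animals" in data:
        data = data["animals"]
    if not isinstance(data, list) or not data:
        raise FormatError(f"{path}: roster must be a non-empty list of animals")
    ids = [str(a["animal_id"]) for a in data]
    sex = [str(a.get("sex", "?")) for a in data]
    weight = [float(a.get("weight_g", "nan")) for a in data]
    return make_roster(ids, sex, weight)


def write_roster(roster: pd.DataFrame, path) -> None:
    animals = [
        {
            "animal_id": str(r.animal_id),
            "sex": str(r.sex),
            "weight_g": float(r.weight_g),
        }
        for r in roster.itertuples(index=False)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"animals": animals}, fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# Interval slicing


def slice_intervals(table: EventTable, sessions, selector="all") -> EventTable:
    """Restrict a table to records whose ``t_start`` lies in selected sessions.

    ``selector`` is forwarded to :func:`homecage.schedule.select_sessions`;
    typical values: ``"all"``, ``"alcohol"``, ``"last 4 alcohol"``, or an
    explicit list of 1-based session indices.  Session windows are half-open
    ``[start, end)``.
    """
    from .schedule import select_sessions

    chosen = select_sessions(sessions, selector)
    if not chosen:
        raise DataError("selector matched no sessions")
    t = table.df["t_start"].to_numpy()
    mask = np.zeros(len(table.df), dtype=bool)
    for ses in chosen:
        mask |= (t >= ses.t_start) & (t < ses.t_end)
    df = table.df[mask].reset_index(drop=True)
    return EventTable(df=df, roster=table.roster, light_offset_h=table.light_offset_h)
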