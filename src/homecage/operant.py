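"""Progressive-ratio breakpoint extraction and punishment-risk analysis.

PR semantics follow the 24 h free-moving variant: there is no time limit,
but a stage must be completed within one continuous corner visit, and the
animal must leave and re-enter before the next attempt, so consecutive
completions always come from distinct visits.  Nose pokes beyond the
current criterion within a visit have no consequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import pandas as pd

from .errors import ConfigError, DataError
from .event_log import EventTable
from .schedule import SessionSpec


def pr_criteria(start: int, increment: int, n_stages: int) -> List[int]:
    """Arithmetic criterion sequence: start, start+inc, ... (n_stages terms)."""
    if start < 1:
        raise ConfigError("start must be >= 1")
    if increment < 1:
        raise ConfigError("increment must be >= 1")
    if n_stages < 0:
        raise ConfigError("n_stages must be >= 0")
    return [start + increment * k for k in range(n_stages)]


@dataclass
class StageResult:
    """One completed PR stage."""

    criterion: int
    visits_to_reach: int  # reward-corner visits since previous completion (excl. this one)
    licks: int  # licks during the completing visit


@dataclass
class PROutcome:
    """Per-mouse progressive-ratio session outcome.

    ``breakpoint`` is the highest completed criterion (0 when nothing was
    completed — distinct from a missing mouse, which yields no outcome).
    ``post_breakpoint_visits`` counts reward-corner visits after the last
    completion.
    """

    animal_id: str
    breakpoint: int = 0
    stages: List[StageResult] = field(default_factory=list)
    post_breakpoint_visits: int = 0

    @property
    def inter_criterion_visits(self) -> List[int]:
        return [s.visits_to_reach for s in self.stages]


def extract_breakpoint(
    table: EventTable, session: SessionSpec, mouse: str
) -> PROutcome:
    """Walk one mouse's visits through a PR session and extract the outcome.

    A stage completes when a single visit to a PR corner contains at least
    the current criterion of nose pokes on one side.  The criterion then
    advances; completions must come from distinct visits by construction
    (one completion is credited per visit).
    """
    pr_corners = [
        k for k in (1, 2, 3, 4) if session.contingency(k).mode == "PR"
    ]
    if not pr_corners:
        raise DataError(f"session {session.index} has no PR contingency")
    if mouse not in set(table.roster["animal_id"]):
        raise DataError(f"unknown mouse {mouse!r}")
    cont = session.contingency(pr_corners[0])
    criterion = cont.pr_start
    increment = cont.pr_increment

    df = table.df
    sub = df[
        (df["animal_id"] == mouse)
        & (df["t_start"] >= session.t_start)
        & (df["t_start"] < session.t_end)
        & (df["corner"].isin(pr_corners))
    ].sort_values("t_start", kind="stable")

    outcome = PROutcome(animal_id=mouse)
    visits_since = 0
    for row in sub.itertuples(index=False):
        pokes = max(int(row.nosepokes_left), int(row.nosepokes_right))
        if pokes >= criterion:
            outcome.stages.append(
                StageResult(
                    criterion=criterion,
                    visits_to_reach=visits_since,
                    licks=int(row.licks_left + row.licks_right),
                )
            )
            outcome.breakpoint = criterion
            criterion += increment
            visits_since = 0
        else:
            visits_since += 1
    outcome.post_breakpoint_visits = visits_since
    return outcome


def extract_breakpoints(table: EventTable, session: SessionSpec) -> pd.DataFrame:
    """Breakpoint table for every rostered mouse in a PR session."""
    rows = []
    for mouse in table.animals:
        out = extract_breakpoint(table, session, mouse)
        rows.append(
            {
                "animal_id": mouse,
                "breakpoint": out.breakpoint,
                "stages_completed": len(out.stages),
                "post_breakpoint_visits": out.post_breakpoint_visits,
                "mean_inter_criterion_visits": (
                    sum(out.inter_criterion_visits) / len(out.stages)
                    if out.stages
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def risk_session_licks(table: EventTable, session: SessionSpec) -> pd.DataFrame:
    """Per-mouse licks split between punishment-risk corners and safe corners."""
    risk_corners = [
        k for k in (1, 2, 3, 4) if session.contingency(k).risk_pct > 0
    ]
    if not risk_corners:
        raise DataError(f"session {session.index} has no punishment-risk contingency")
    df = table.df
    sub = df[(df["t_start"] >= session.t_start) & (df["t_start"] < session.t_end)].copy()
    sub["licks"] = sub["licks_left"] + sub["licks_right"]
    sub["at_risk"] = sub["corner"].isin(risk_corners)
    rows = []
    for mouse in table.animals:
        mine = sub[sub["animal_id"] == mouse]
        rows.append(
            {
                "animal_id": mouse,
                "licks_risk": int(mine.loc[mine["at_risk"], "licks"].sum()),
                "licks_safe": int(mine.loc[~mine["at_risk"], "licks"].sum()),
            }
        )
    return pd.DataFrame(rows)
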