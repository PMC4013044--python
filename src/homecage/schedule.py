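"""Machine-readable experiment schedules.

Builders for the four experimental designs — intermittent two-bottle access,
quinine adulteration, progressive-ratio testing, and punishment-risk
sessions — plus content/contingency lookup by time.  All session windows are
half-open ``[start, end)`` in seconds since experiment start, and access
sessions are 24 h long.

Conventions:

* corners are numbered 1-4; bottle sides are ``left``/``right``;
* intermittent alcohol sessions alternate reward corners {1, 3} (odd
  sessions) and {2, 4} (even sessions);
* alcohol concentration ramps 4% -> 8% -> 12% (v/v) and stays at 12%;
* sessions start at a configurable exchange clock hour (default 16:00, with
  15:00 used by later cohorts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import yaml

from .errors import ConfigError, DataError

DAY_S = 24 * 3600.0

CORNERS = (1, 2, 3, 4)
ODD_CORNERS = (1, 3)
EVEN_CORNERS = (2, 4)


# ---------------------------------------------------------------------------
# Contents


@dataclass(frozen=True)
class Content:
    """What a bottle contains: water, alcohol (% v/v) and/or saccharin
    (% w/v), optionally adulterated with quinine (% w/v)."""

    alcohol_pct: float = 0.0
    saccharin_pct: float = 0.0
    quinine_pct: float = 0.0

    @property
    def kind(self) -> str:
        if self.alcohol_pct > 0:
            return "alcohol"
        if self.saccharin_pct > 0:
            return "saccharin"
        return "water"

    def __str__(self) -> str:
        parts = []
        if self.alcohol_pct > 0:
            parts.append(f"alcohol:{self.alcohol_pct:g}")
        if self.saccharin_pct > 0:
            parts.append(f"saccharin:{self.saccharin_pct:g}")
        if self.quinine_pct > 0:
            parts.append(f"quinine:{self.quinine_pct:g}")
        return "+".join(parts) if parts else "water"

    @classmethod
    def parse(cls, text: str) -> "Content":
        text = text.strip()
        if text in ("water", ""):
            return WATER
        kwargs = {}
        for part in text.split("+"):
            name, _, val = part.partition(":")
            name = name.strip()
            if name not in ("alcohol", "saccharin", "quinine"):
                raise ConfigError(f"unknown content component {name!r}")
            kwargs[f"{name}_pct"] = float(val)
        return cls(**kwargs)


WATER = Content()


def alcohol(pct: float, quinine: float = 0.0) -> Content:
    return Content(alcohol_pct=pct, quinine_pct=quinine)


def saccharin(pct: float = 0.02, quinine: float = 0.0) -> Content:
    return Content(saccharin_pct=pct, quinine_pct=quinine)


# ---------------------------------------------------------------------------
# Contingencies


@dataclass(frozen=True)
class Contingency:
    """Reinforcement contingency at one corner.

    mode: ``free`` (gate always open), ``FR`` (fixed ratio ``n``) or ``PR``
    (progressive ratio starting at ``pr_start`` and growing by
    ``pr_increment`` per completion).  FR corners may carry a punishment
    risk: each completion is punished with probability ``risk_pct``/100 by a
    ``puff_bar`` air puff delivered ``delay_s`` seconds after completion.
    """

    mode: str = "free"
    n: int = 0
    pr_start: int = 0
    pr_increment: int = 0
    risk_pct: float = 0.0
    delay_s: float = 0.0
    puff_bar: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("free", "FR", "PR"):
            raise ConfigError(f"unknown contingency mode {self.mode!r}")
        if self.mode == "FR" and self.n < 1:
            raise ConfigError("FR contingency requires n >= 1")
        if self.mode == "PR" and (self.pr_start < 1 or self.pr_increment < 1):
            raise ConfigError("PR contingency requires pr_start >= 1 and pr_increment >= 1")

    def __str__(self) -> str:
        if self.mode == "free":
            return "free"
        if self.mode == "FR":
            s = f"FR{self.n}"
            if self.risk_pct > 0:
                s += f"+risk:{self.risk_pct:g}%:delay:{self.delay_s:g}s:puff:{self.puff_bar:g}bar"
            return s
        return f"PR(start={self.pr_start},inc={self.pr_increment})"


FREE = Contingency("free")
FR3 = Contingency("FR", n=3)


def pr(increment: int, start: int = 3) -> Contingency:
    """Progressive-ratio contingency; default start 3 (animals pre-trained on FR3)."""
    return Contingency("PR", pr_start=start, pr_increment=increment)


def fr_risk(n: int = 3, risk_pct: float = 25.0, delay_s: float = 2.0, puff_bar: float = 0.5) -> Contingency:
    return Contingency("FR", n=n, risk_pct=risk_pct, delay_s=delay_s, puff_bar=puff_bar)


# ---------------------------------------------------------------------------
# Sessions


@dataclass
class SessionSpec:
    """One access session: a time window plus per-corner bottle contents and
    contingencies."""

    index: int
    t_start: float
    t_end: float
    corner_contents: Dict[int, Tuple[Content, Content]]
    corner_contingency: Dict[int, Contingency] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ConfigError("session window must have positive length")
        for corner in self.corner_contents:
            if corner not in CORNERS:
                raise ConfigError(f"corner must be 1-4, got {corner}")
        for corner in CORNERS:
            self.corner_contents.setdefault(corner, (WATER, WATER))
            self.corner_contingency.setdefault(corner, FREE)

    def content(self, corner: int, side: str) -> Content:
        left, right = self.corner_contents[corner]
        return left if side == "left" else right

    def contingency(self, corner: int) -> Contingency:
        return self.corner_contingency[corner]

    @property
    def is_alcohol(self) -> bool:
        return any(
            c.alcohol_pct > 0 for pair in self.corner_contents.values() for c in pair
        )

    def corners_with(self, kind: str) -> List[int]:
        """Corners where at least one bottle has content of the given kind."""
        return [
            k
            for k in CORNERS
            if any(c.kind == kind for c in self.corner_contents[k])
        ]

    @property
    def reward_corners(self) -> List[int]:
        """Corners offering a non-water reward (alcohol or saccharin)."""
        return [
            k
            for k in CORNERS
            if any(c.kind != "water" for c in self.corner_contents[k])
        ]

    def contains(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


def _session(index, start, contents, contingencies=None, label=""):
    return SessionSpec(
        index=index,
        t_start=start,
        t_end=start + DAY_S,
        corner_contents=dict(contents),
        corner_contingency=dict(contingencies or {}),
        label=label,
    )


def _reward_corner_pair(session_number: int) -> Tuple[int, ...]:
    """Odd-numbered sessions use corners {1,3}; even use {2,4}."""
    return ODD_CORNERS if session_number % 2 == 1 else EVEN_CORNERS


# ---------------------------------------------------------------------------
# Builders


def build_intermittent(
    weeks: int,
    exchange_hour: int = 16,
    access_mode: str = "free",
    start_day: int = 0,
) -> List[SessionSpec]:
    """Intermittent-access schedule: three 24 h alcohol sessions per week
    (Mon/Wed/Fri starting at ``exchange_hour``), reward corners alternating
    {1,3}/{2,4}, alcohol ramping 4 -> 8 -> 12 % v/v and 12% thereafter.

    ``access_mode`` is ``"free"`` or ``"FR3"`` and applies to every corner.
    t=0 is midnight of the first Monday.
    """
    if weeks < 0:
        raise ConfigError("weeks must be >= 0")
    if not 0 <= exchange_hour <= 23:
        raise ConfigError("exchange_hour must be within 0-23")
    if access_mode not in ("free", "FR3"):
        raise ConfigError("access_mode must be 'free' or 'FR3'")
    cont = FREE if access_mode == "free" else FR3
    sessions: List[SessionSpec] = []
    idx = 0
    for week in range(weeks):
        for day in (0, 2, 4):  # Mon, Wed, Fri
            idx += 1
            conc = 4.0 if idx == 1 else 8.0 if idx == 2 else 12.0
            corners = _reward_corner_pair(idx)
            contents = {
                k: (alcohol(conc), alcohol(conc)) if k in corners else (WATER, WATER)
                for k in CORNERS
            }
            start = (start_day + week * 7 + day) * DAY_S + exchange_hour * 3600.0
            sessions.append(
                _session(
                    idx,
                    start,
                    contents,
                    {k: cont for k in CORNERS},
                    label=f"alcohol {conc:g}%",
                )
            )
    return sessions


def build_quinine_sequence(exchange_hour: int = 16, start_day: int = 0) -> List[SessionSpec]:
    """The seven consecutive 24 h adulteration sessions (i)-(vii).

    Reward bottles sit in two corners (positions switched after each
    session); the remaining two corners carry water.  Session (i) offers 12%
    alcohol and 0.02% saccharin in opposite corners; later sessions carry a
    single reward in both reward corners with rising quinine.
    """
    specs = [
        ("i", None),  # special-cased: alcohol and saccharin in opposite corners
        ("ii", saccharin(0.02, quinine=0.01)),
        ("iii", alcohol(12, quinine=0.01)),
        ("iv", saccharin(0.02, quinine=0.03)),
        ("v", alcohol(12, quinine=0.03)),
        ("vi", saccharin(0.02, quinine=0.03)),
        ("vii", alcohol(12, quinine=0.03)),
    ]
    sessions = []
    for i, (roman, content) in enumerate(specs, start=1):
        corners = _reward_corner_pair(i)
        if content is None:
            contents = {
                corners[0]: (alcohol(12), alcohol(12)),
                corners[1]: (saccharin(0.02), saccharin(0.02)),
            }
            label = "adulteration i: alcohol 12% / saccharin 0.02%"
        else:
            contents = {k: (content, content) for k in corners}
            label = f"adulteration {roman}: {content}"
        start = (start_day + i - 1) * DAY_S + exchange_hour * 3600.0
        sessions.append(_session(i, start, contents, label=label))
    return sessions


def build_pr_sequence(
    variant: str,
    reward: Content | None = None,
    pr_start: int = 3,
    exchange_hour: int = 16,
    start_day: int = 0,
) -> List[SessionSpec]:
    """Progressive-ratio session lists.

    ``variant="male-cohort"``: five sessions — (i) alcohol and saccharin in
    opposite corners under FR3, (ii) saccharin PR1, (iii) alcohol PR1,
    (iv) saccharin PR3, (v) alcohol PR3 — rewards in both reward corners,
    FR3 water in the remaining corners, reward positions switched each
    session.

    ``variant="female-cohorts"``: three sessions — (i) ``reward`` under PR1
    in two corners with FR3 water elsewhere, (ii) FR3 water in all corners,
    (iii) ``reward`` under PR3 in two corners.  ``reward`` defaults to 12%
    alcohol.
    """
    if variant not in ("male-cohort", "female-cohorts"):
        raise ConfigError(f"unknown PR variant {variant!r}")
    sessions = []
    if variant == "male-cohort":
        plan = [
            ("mixed", FR3),
            (saccharin(0.02), pr(1, pr_start)),
            (alcohol(12), pr(1, pr_start)),
            (saccharin(0.02), pr(3, pr_start)),
            (alcohol(12), pr(3, pr_start)),
        ]
        for i, (content, cont) in enumerate(plan, start=1):
            corners = _reward_corner_pair(i)
            if content == "mixed":
                contents = {
                    corners[0]: (alcohol(12), alcohol(12)),
                    corners[1]: (saccharin(0.02), saccharin(0.02)),
                }
            else:
                contents = {k: (content, content) for k in corners}
            contingencies = {
                k: (cont if k in corners else FR3) for k in CORNERS
            }
            start = (start_day + i - 1) * DAY_S + exchange_hour * 3600.0
            sessions.append(
                _session(i, start, contents, contingencies, label=f"PR male session {i}")
            )
    else:
        reward = alcohol(12) if reward is None else reward
        plan = [(reward, pr(1, pr_start)), (None, FR3), (reward, pr(3, pr_start))]
        for i, (content, cont) in enumerate(plan, start=1):
            if content is None:
                contents = {k: (WATER, WATER) for k in CORNERS}
                contingencies = {k: FR3 for k in CORNERS}
            else:
                corners = _reward_corner_pair(i)
                contents = {k: (content, content) for k in corners}
                contingencies = {k: (cont if k in corners else FR3) for k in CORNERS}
            start = (start_day + i - 1) * DAY_S + exchange_hour * 3600.0
            sessions.append(
                _session(i, start, contents, contingencies, label=f"PR female day {i}")
            )
    return sessions


def build_punishment_sequence(
    variant: str,
    reward: Content | None = None,
    exchange_hour: int = 16,
    start_day: int = 0,
) -> List[SessionSpec]:
    """Punishment-risk sessions (0.5 bar air puff).

    ``variant="male-cohort"``: three sessions — session 1 with 100% risk
    delivered immediately on FR3 completion, sessions 2-3 with 25% risk
    delivered after a 2 s delay; 12% alcohol in one risk corner and 0.02%
    saccharin in the opposite one, FR3 water without risk elsewhere.

    ``variant="female-cohorts"``: a single session with 25% risk and 2 s
    delay; ``reward`` (default 12% alcohol) in both risk corners.
    """
    if variant not in ("male-cohort", "female-cohorts"):
        raise ConfigError(f"unknown punishment variant {variant!r}")
    sessions = []
    if variant == "male-cohort":
        risk_plan = [(100.0, 0.0), (25.0, 2.0), (25.0, 2.0)]
        for i, (risk, delay) in enumerate(risk_plan, start=1):
            corners = _reward_corner_pair(i)
            contents = {
                corners[0]: (alcohol(12), alcohol(12)),
                corners[1]: (saccharin(0.02), saccharin(0.02)),
            }
            cont = fr_risk(3, risk_pct=risk, delay_s=delay, puff_bar=0.5)
            contingencies = {k: (cont if k in corners else FR3) for k in CORNERS}
            start = (start_day + i - 1) * DAY_S + exchange_hour * 3600.0
            sessions.append(
                _session(i, start, contents, contingencies, label=f"risk {risk:g}%")
            )
    else:
        reward = alcohol(12) if reward is None else reward
        corners = _reward_corner_pair(1)
        contents = {k: (reward, reward) for k in corners}
        cont = fr_risk(3, risk_pct=25.0, delay_s=2.0, puff_bar=0.5)
        contingencies = {k: (cont if k in corners else FR3) for k in CORNERS}
        start = start_day * DAY_S + exchange_hour * 3600.0
        sessions.append(_session(1, start, contents, contingencies, label="risk 25%"))
    return sessions


# ---------------------------------------------------------------------------
# Lookup & selection


def session_at(sessions: Sequence[SessionSpec], t: float) -> SessionSpec | None:
    for ses in sessions:
        if ses.contains(t):
            return ses
    return None


def content_at(
    sessions: Sequence[SessionSpec],
    corner: int,
    side: str,
    t: float,
    warn: bool = True,
) -> Content:
    """Bottle content at (corner, side) at time ``t``.

    Outside all session windows bottles default to water; a warning is
    emitted unless ``warn=False``.  Windows are half-open, so at a boundary
    instant the next session's contents apply.
    """
    ses = session_at(sessions, t)
    if ses is None:
        if warn:
            warnings.warn(f"t={t} outside all sessions; defaulting to water", stacklevel=2)
        return WATER
    return ses.content(corner, side)


def contingency_at(sessions: Sequence[SessionSpec], corner: int, t: float) -> Contingency:
    ses = session_at(sessions, t)
    return FREE if ses is None else ses.contingency(corner)


def select_sessions(sessions: Sequence[SessionSpec], selector="all") -> List[SessionSpec]:
    """Resolve a session selector.

    Accepts ``"all"``, ``"alcohol"``, ``"first K alcohol"``, ``"last K
    alcohol"`` (also compact forms like ``"last4alcohol"``), or an explicit
    iterable of 1-based session indices.
    """
    sessions = list(sessions)
    if not sessions:
        raise DataError("empty session list")
    if not isinstance(selector, str):
        wanted = set(int(i) for i in selector)
        chosen = [s for s in sessions if s.index in wanted]
        if len(chosen) != len(wanted):
            raise DataError(f"session indices not found: {wanted - {s.index for s in chosen}}")
        return chosen
    text = selector.strip().lower().replace("_", " ")
    if text == "all":
        return sessions
    if text == "alcohol":
        return [s for s in sessions if s.is_alcohol]
    import re

    m = re.fullmatch(r"(first|last)\s*(\d+)\s*(alcohol)?", text)
    if not m:
        raise ConfigError(f"unrecognised session selector {selector!r}")
    which, k, alcohol_only = m.group(1), int(m.group(2)), bool(m.group(3))
    pool = [s for s in sessions if s.is_alcohol] if alcohol_only else sessions
    if len(pool) < k:
        raise DataError(
            f"selector {selector!r} needs {k} sessions but only {len(pool)} available"
        )
    return pool[:k] if which == "first" else pool[-k:]


# ---------------------------------------------------------------------------
# Serialization


def _content_pair_to_str(pair: Tuple[Content, Content]) -> List[str]:
    return [str(pair[0]), str(pair[1])]


def _contingency_to_dict(c: Contingency) -> dict:
    d = {"mode": c.mode}
    if c.mode == "FR":
        d["n"] = c.n
    if c.mode == "PR":
        d["pr_start"] = c.pr_start
        d["pr_increment"] = c.pr_increment
    if c.risk_pct > 0:
        d.update(risk_pct=c.risk_pct, delay_s=c.delay_s, puff_bar=c.puff_bar)
    return d


def _contingency_from_dict(d: dict) -> Contingency:
    return Contingency(
        mode=d.get("mode", "free"),
        n=int(d.get("n", 0)),
        pr_start=int(d.get("pr_start", 0)),
        pr_increment=int(d.get("pr_increment", 0)),
        risk_pct=float(d.get("risk_pct", 0.0)),
        delay_s=float(d.get("delay_s", 0.0)),
        puff_bar=float(d.get("puff_bar", 0.0)),
    )


def sessions_to_dict(sessions: Sequence[SessionSpec]) -> dict:
    return {
        "sessions": [
            {
                "index": s.index,
                "t_start": s.t_start,
                "t_end": s.t_end,
                "label": s.label,
                "corner_contents": {
                    str(k): _content_pair_to_str(v) for k, v in s.corner_contents.items()
                },
                "corner_contingency": {
                    str(k): _contingency_to_dict(v)
                    for k, v in s.corner_contingency.items()
                },
            }
            for s in sessions
        ]
    }


def sessions_from_dict(data: dict) -> List[SessionSpec]:
    out = []
    for entry in data["sessions"]:
        contents = {
            int(k): (Content.parse(v[0]), Content.parse(v[1]))
            for k, v in entry["corner_contents"].items()
        }
        contingencies = {
            int(k): _contingency_from_dict(v)
            for k, v in entry.get("corner_contingency", {}).items()
        }
        out.append(
            SessionSpec(
                index=int(entry["index"]),
                t_start=float(entry["t_start"]),
                t_end=float(entry["t_end"]),
                corner_contents=contents,
                corner_contingency=contingencies,
                label=entry.get("label", ""),
            )
        )
    return out


def write_schedule(sessions: Sequence[SessionSpec], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(sessions_to_dict(sessions), fh, sort_keys=False)


def read_schedule(path) -> List[SessionSpec]:
    with open(path, "r", encoding="utf-8") as fh:
        return sessions_from_dict(yaml.safe_load(fh))
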