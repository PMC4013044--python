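"""Agent-based generator of synthetic cohort event tables.

The simulator produces corner-visit logs with the statistical structure the
downstream analyses assume, so every stage of the pipeline can be exercised
without real cage data:

* per-mouse circadian activity with two dark-phase peaks and a light-phase
  floor (inhomogeneous Poisson visit process, hourly rate);
* log-normal visit durations (mode well under a minute, rare long visits);
* drinking-intent visits that pick a bottle content (alcohol with the
  mouse's true preference probability, otherwise water/other) and then a
  side according to the mouse's side bias;
* FR / PR / punishment-risk contingencies with a per-mouse persistence
  parameter and post-punishment visit-rate suppression;
* optional directed follow edges: after a leader's corner entry the
  follower enters the same corner at a latency drawn inside the social
  analysis window [1 s, 60 s].

All randomness flows from a single integer seed through
``numpy.random.default_rng`` sub-streams keyed by mouse order, so a fixed
config is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .event_log import COLUMNS, EventTable, empty_frame, make_roster
from .schedule import (
    CORNERS,
    SessionSpec,
    build_intermittent,
    session_at,
    sessions_from_dict,
)

SOCIAL_WINDOW = (1.0, 60.0)  # analysis gap filter; injected latencies must fit


@dataclass
class ActivityCurve:
    """Hourly visit rate: two truncated-Gaussian dark-phase peaks plus a
    uniform light-phase floor.  Hours are clock hours (0-24); the dark phase
    is taken as [dark_start, dark_start+12)."""

    peak1_h: float = 13.5
    peak2_h: float = 22.5
    width1_h: float = 1.5
    width2_h: float = 1.5
    amp1: float = 10.0  # visits/h at peak
    amp2: float = 8.0
    floor: float = 0.5  # visits/h during the light phase
    dark_start_h: float = 12.0

    def rate(self, clock_h: float) -> float:
        def bump(peak, width, amp):
            d = abs(clock_h - peak)
            d = min(d, 24.0 - d)  # circular distance
            return amp * math.exp(-0.5 * (d / width) ** 2)

        return self.floor + bump(self.peak1_h, self.width1_h, self.amp1) + bump(
            self.peak2_h, self.width2_h, self.amp2
        )


@dataclass
class FollowEdge:
    """Directed social edge: after each of the target's corner entries the
    owner follows into the same corner with probability ``p_follow`` at a
    latency drawn uniformly from [latency_lo, latency_hi] seconds."""

    target_id: str
    p_follow: float
    latency_lo: float = 2.0
    latency_hi: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_follow <= 1.0:
            raise ConfigError("p_follow must lie in [0, 1]")
        lo, hi = SOCIAL_WINDOW
        if not (lo <= self.latency_lo <= self.latency_hi <= hi):
            raise ConfigError(
                f"follow latency support [{self.latency_lo}, {self.latency_hi}] must "
                f"lie inside the social analysis window [{lo}, {hi}] s"
            )


@dataclass
class MouseProfile:
    """Generative parameters of one simulated animal."""

    animal_id: str
    sex: str = "F"
    weight_g: float = 25.0
    p_alcohol: float = 0.5  # true alcohol-choice probability
    side_bias: float = 0.0  # -1 (all left) .. +1 (all right)
    activity: ActivityCurve = field(default_factory=ActivityCurve)
    licks_per_event_mean: float = 30.0
    p_drink: float = 0.6  # probability a visit carries drinking intent
    persistence: float = 0.9  # PR stage-completion decay parameter
    follow_edges: List[FollowEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_alcohol <= 1.0:
            raise ConfigError("p_alcohol must lie in [0, 1]")
        if not -1.0 <= self.side_bias <= 1.0:
            raise ConfigError("side_bias must lie in [-1, 1]")
        if self.weight_g <= 0:
            raise ConfigError("weight_g must be positive")
        if self.licks_per_event_mean < 1:
            raise ConfigError("licks_per_event_mean must be >= 1")


@dataclass
class CohortConfig:
    """A cohort of profiles, a session schedule, and visit-duration shape.

    Durations are log-normal with parameters chosen so the majority of
    visits last under a minute and visits over ten minutes are rare.
    """

    profiles: List[MouseProfile]
    sessions: List[SessionSpec]
    seed: int = 0
    duration_log_mean: float = math.log(10.0)
    duration_log_sd: float = 0.9
    punishment_suppression: float = 0.3

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ConfigError("cohort needs at least one mouse profile")
        ids = [p.animal_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate animal_id among profiles")
        known = set(ids)
        for p in self.profiles:
            for edge in p.follow_edges:
                if edge.target_id not in known:
                    raise ConfigError(f"follow edge target {edge.target_id!r} not in cohort")
                if edge.target_id == p.animal_id:
                    raise ConfigError("a mouse cannot follow itself")
        if not self.sessions:
            raise ConfigError("cohort needs at least one session")

    @property
    def roster(self) -> pd.DataFrame:
        return make_roster(
            [p.animal_id for p in self.profiles],
            [p.sex for p in self.profiles],
            [p.weight_g for p in self.profiles],
        )

    # -- config file support ----------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        prof = []
        for m in data.get("mice", []):
            act = ActivityCurve(**m.get("activity", {}))
            edges = [
                FollowEdge(
                    target_id=str(e["target"]),
                    p_follow=float(e["p_follow"]),
                    latency_lo=float(e.get("latency_lo", 2.0)),
                    latency_hi=float(e.get("latency_hi", 40.0)),
                )
                for e in m.get("follow", [])
            ]
            prof.append(
                MouseProfile(
                    animal_id=str(m["animal_id"]),
                    sex=str(m.get("sex", "F")),
                    weight_g=float(m.get("weight_g", 25.0)),
                    p_alcohol=float(m.get("p_alcohol", 0.5)),
                    side_bias=float(m.get("side_bias", 0.0)),
                    activity=act,
                    licks_per_event_mean=float(m.get("licks_per_event_mean", 30.0)),
                    p_drink=float(m.get("p_drink", 0.6)),
                    persistence=float(m.get("persistence", 0.9)),
                    follow_edges=edges,
                )
            )
        sched = data.get("schedule")
        if isinstance(sched, dict) and "sessions" in sched:
            sessions = sessions_from_dict(sched)
        elif isinstance(sched, dict):
            sessions = build_intermittent(
                weeks=int(sched.get("weeks", 1)),
                exchange_hour=int(sched.get("exchange_hour", 16)),
                access_mode=str(sched.get("access_mode", "free")),
            )
        else:
            raise ConfigError("cohort config needs a 'schedule' block")
        return cls(
            profiles=prof,
            sessions=sessions,
            seed=int(data.get("seed", 0)),
            duration_log_mean=float(data.get("duration_log_mean", math.log(10.0))),
            duration_log_sd=float(data.get("duration_log_sd", 0.9)),
            punishment_suppression=float(data.get("punishment_suppression", 0.3)),
        )

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if "cohort" in data:
            data = data["cohort"]
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Visit-time generation


def _visit_times(profile: MouseProfile, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous-Poisson visit start times over [t0, t1), hourly rate."""
    times = []
    h0 = int(math.floor(t0 / 3600.0))
    h1 = int(math.ceil(t1 / 3600.0))
    for h in range(h0, h1):
        lo = max(t0, h * 3600.0)
        hi = min(t1, (h + 1) * 3600.0)
        frac = (hi - lo) / 3600.0
        if frac <= 0:
            continue
        lam = profile.activity.rate((h + 0.5) % 24.0) * frac
        n = rng.poisson(lam)
        if n:
            times.append(rng.uniform(lo, hi, size=n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def _resolve_overlaps(t_start: np.ndarray, durations: np.ndarray) -> np.ndarray:
    """Keep-first overlap resolution: a mouse occupies one corner at a time."""
    keep = np.ones(len(t_start), dtype=bool)
    t_free = -np.inf
    for i in range(len(t_start)):
        if t_start[i] < t_free:
            keep[i] = False
        else:
            t_free = t_start[i] + durations[i]
    return keep


# ---------------------------------------------------------------------------
# Simulation


def _simulate_mouse(
    profile: MouseProfile,
    config: CohortConfig,
    rng: np.random.Generator,
) -> List[dict]:
    """Generate one mouse's base visits (no social edges) across the whole
    span covered by the schedule."""
    t0 = min(s.t_start for s in config.sessions)
    t1 = max(s.t_end for s in config.sessions)
    starts = _visit_times(profile, t0, t1, rng)
    if len(starts) == 0:
        return []
    durations = rng.lognormal(config.duration_log_mean, config.duration_log_sd, len(starts))
    keep = _resolve_overlaps(starts, durations)
    starts, durations = starts[keep], durations[keep]

    rows: List[dict] = []
    pr_stage = 0  # per-mouse PR progress (criterion index, 0-based)
    punished_corners: set[int] = set()

    for t, dur in zip(starts, durations):
        ses = session_at(config.sessions, t)
        drink = rng.random() < profile.p_drink
        corner = None
        content_kind = None
        if drink and ses is not None:
            want_alcohol = rng.random() < profile.p_alcohol
            kind = "alcohol" if want_alcohol else "water"
            options = ses.corners_with(kind)
            if not options:
                # fall back to whatever non-chosen content exists
                kind = "water" if kind == "alcohol" else "alcohol"
                options = ses.corners_with(kind)
            if not options:
                drink = False
            else:
                corner = int(options[rng.integers(len(options))])
                content_kind = kind
        if corner is None:
            corner = int(rng.integers(1, 5))
            drink = False

        if corner in punished_corners and rng.random() > config.punishment_suppression:
            continue  # suppressed visit after punishment at this corner

        row = {
            "animal_id": profile.animal_id,
            "corner": corner,
            "t_start": float(t),
            "t_end": float(t + dur),
            "nosepokes_left": 0,
            "nosepokes_right": 0,
            "licks_left": 0,
            "licks_right": 0,
        }

        if drink and ses is not None:
            # side choice among sides carrying the chosen content
            left_ok = ses.content(corner, "left").kind == content_kind
            right_ok = ses.content(corner, "right").kind == content_kind
            if left_ok and right_ok:
                side = "right" if rng.random() < (1.0 + profile.side_bias) / 2.0 else "left"
            else:
                side = "right" if right_ok else "left"

            cont = ses.contingency(corner)
            completed = True
            pokes = 0
            punished = False
            if cont.mode == "FR":
                pokes = cont.n
                if cont.risk_pct > 0 and rng.random() < cont.risk_pct / 100.0:
                    punished = True
                    punished_corners.add(corner)
            elif cont.mode == "PR":
                criterion = cont.pr_start + cont.pr_increment * pr_stage
                p_complete = profile.persistence ** (pr_stage + 1)
                if rng.random() < p_complete:
                    pokes = criterion
                    pr_stage += 1
                else:
                    completed = False
                    pokes = int(rng.integers(0, criterion))

            licks = 0
            if completed and not (punished and cont.delay_s == 0):
                licks = 1 + int(rng.poisson(profile.licks_per_event_mean - 1.0))
            row[f"nosepokes_{side}"] = pokes
            row[f"licks_{side}"] = licks

        rows.append(row)
    return rows


def simulate_cohort(config: CohortConfig) -> EventTable:
    """Run the agent-based simulation and return a sorted :class:`EventTable`.

    Deterministic for a fixed config and seed.  Follow edges are applied
    after base generation: each leader entry triggers, with probability
    ``p_follow``, an inserted follower visit to the same corner at the
    drawn latency.
    """
    root = np.random.default_rng(config.seed)
    streams = root.spawn(len(config.profiles) + 1)
    frames: List[pd.DataFrame] = []
    for profile, rng in zip(config.profiles, streams):
        rows = _simulate_mouse(profile, config, rng)
        if rows:
            frames.append(pd.DataFrame(rows, columns=COLUMNS))
    df = pd.concat(frames, ignore_index=True) if frames else empty_frame()
    df = df.sort_values("t_start", kind="stable").reset_index(drop=True)
    table = EventTable(df=df, roster=config.roster)

    follow_rng = streams[-1]
    for profile in config.profiles:
        for edge in profile.follow_edges:
            table = inject_follower(
                table,
                leader=edge.target_id,
                follower=profile.animal_id,
                p_follow=edge.p_follow,
                latency=(edge.latency_lo, edge.latency_hi),
                rng=follow_rng,
            )
    return table


def inject_follower(
    table: EventTable,
    leader: str,
    follower: str,
    p_follow: float,
    latency: Tuple[float, float] = (2.0, 40.0),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    visit_duration: float = 10.0,
) -> EventTable:
    """Insert follower visits after leader visits.

    For every leader visit, with probability ``p_follow``, a follower visit
    to the same corner is inserted at ``leader.t_start + latency`` with the
    latency drawn uniformly from the given support (which must lie inside
    the [1 s, 60 s] social analysis window).  The result is re-sorted.
    """
    if leader == follower:
        raise ConfigError("leader and follower must differ")
    known = set(table.roster["animal_id"])
    for who in (leader, follower):
        if who not in known:
            raise ConfigError(f"{who!r} not in roster")
    lo, hi = latency
    if not (SOCIAL_WINDOW[0] <= lo <= hi <= SOCIAL_WINDOW[1]):
        raise ConfigError(
            f"latency support [{lo}, {hi}] must lie inside {list(SOCIAL_WINDOW)} s"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    leader_starts = table.df.loc[table.df["animal_id"] == leader, "t_start"].to_numpy()
    fire = rng.random(len(leader_starts)) < p_follow
    lags = rng.uniform(lo, hi, len(leader_starts))
    starts = leader_starts[fire] + lags[fire]
    corners = table.df.loc[table.df["animal_id"] == leader, "corner"].to_numpy()[fire]
    if len(starts) == 0:
        return table
    inserted = pd.DataFrame(
        {
            "animal_id": follower,
            "corner": corners.astype(np.int64),
            "t_start": starts,
            "t_end": starts + visit_duration,
            "nosepokes_left": 0,
            "nosepokes_right": 0,
            "licks_left": 0,
            "licks_right": 0,
        },
        columns=COLUMNS,
    )
    df = pd.concat([table.df, inserted], ignore_index=True)
    df = df.sort_values("t_start", kind="stable").reset_index(drop=True)
    return EventTable(df=df, roster=table.roster, light_offset_h=table.light_offset_h)
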