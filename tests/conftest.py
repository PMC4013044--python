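"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use plain-Python loops and exhaustive enumeration,
independent of the vectorised implementations they check.
"""

from __future__ import annotations

import itertools
import math
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
import pytest

from homecage.event_log import EventTable, VisitRecord, make_roster
from homecage.schedule import build_intermittent
from homecage.synthetic import ActivityCurve, CohortConfig, MouseProfile


# ---------------------------------------------------------------------------
# Table builders


def visit(
    animal: str,
    corner: int,
    t: float,
    dur: float = 10.0,
    licks_left: int = 0,
    licks_right: int = 0,
    nosepokes_left: int = 0,
    nosepokes_right: int = 0,
) -> VisitRecord:
    return VisitRecord(
        animal_id=animal,
        corner=corner,
        t_start=t,
        t_end=t + dur,
        nosepokes_left=nosepokes_left,
        nosepokes_right=nosepokes_right,
        licks_left=licks_left,
        licks_right=licks_right,
    )


def table_from(records: Sequence[VisitRecord], roster=None) -> EventTable:
    return EventTable.from_records(records, roster=roster)


@pytest.fixture
def three_row_table() -> EventTable:
    roster = make_roster(["m1", "m2"], sex="M", weight_g=26.0)
    return table_from(
        [
            visit("m1", 1, 0.0, licks_left=5),
            visit("m2", 2, 15.0, nosepokes_right=3, licks_right=7),
            visit("m1", 3, 42.5),
        ],
        roster=roster,
    )


def quick_cohort(
    n_mice: int = 6,
    seed: int = 0,
    weeks: int = 1,
    n_sessions: int | None = 1,
    amp: float = 10.0,
    floor: float = 0.5,
    p_alcohol: float = 0.5,
    side_bias: float = 0.0,
    p_drink: float = 0.6,
    profiles_override: List[MouseProfile] | None = None,
) -> CohortConfig:
    """Small single-cage cohort on an intermittent schedule."""
    sessions = build_intermittent(weeks=weeks)
    if n_sessions is not None:
        sessions = sessions[:n_sessions]
    if profiles_override is not None:
        profiles = profiles_override
    else:
        profiles = [
            MouseProfile(
                animal_id=f"m{i}",
                p_alcohol=p_alcohol,
                side_bias=side_bias,
                p_drink=p_drink,
                activity=ActivityCurve(amp1=amp, amp2=amp * 0.8, floor=floor),
            )
            for i in range(n_mice)
        ]
    return CohortConfig(profiles=profiles, sessions=sessions, seed=seed)


# ---------------------------------------------------------------------------
# Pair-counting oracle (plain loops)


def brute_force_pairs(
    codes: Sequence[int],
    times: Sequence[float],
    n_animals: int,
    min_gap: float = 1.0,
    max_gap: float = 60.0,
    drop_repeats: bool = False,
) -> np.ndarray:
    """Adjacent-pair enumerator; matrix[second, first]."""
    codes = list(codes)
    times = list(times)
    if drop_repeats:
        kept_c: List[int] = []
        kept_t: List[float] = []
        for c, t in zip(codes, times):
            if kept_c and kept_c[-1] == c:
                continue
            kept_c.append(c)
            kept_t.append(t)
        codes, times = kept_c, kept_t
    mat = np.zeros((n_animals, n_animals), dtype=int)
    for i in range(len(codes) - 1):
        gap = times[i + 1] - times[i]
        if min_gap <= gap <= max_gap:
            mat[codes[i + 1], codes[i]] += 1
    return mat


# ---------------------------------------------------------------------------
# Exact permutation-null oracle (exhaustive enumeration)


def exact_null(
    codes: Sequence[int],
    times: Sequence[float],
    n_animals: int,
    min_gap: float = 1.0,
    max_gap: float = 60.0,
    drop_repeats: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact per-cell mean and population SD of pair counts under uniform
    shuffling of the letter multiset over fixed time slots.

    Uniformity over distinct arrangements holds because every distinct
    arrangement of a multiset corresponds to the same number of raw
    permutations.
    """
    arrangements = sorted(set(itertools.permutations(codes)))
    stack = np.stack(
        [
            brute_force_pairs(arr, times, n_animals, min_gap, max_gap, drop_repeats)
            for arr in arrangements
        ]
    ).astype(float)
    return stack.mean(axis=0), stack.std(axis=0, ddof=0)


def random_sequence(
    rng: np.random.Generator, n_animals: int, max_len: int = 50
) -> Tuple[np.ndarray, np.ndarray]:
    """Random letter sequence with gaps straddling both filter boundaries."""
    length = int(rng.integers(2, max_len + 1))
    codes = rng.integers(0, n_animals, size=length)
    # mixture of sub-second, in-window and over-a-minute gaps
    gaps = rng.choice(
        [0.2, 0.9, 1.0, 5.0, 30.0, 59.9, 60.0, 61.0, 300.0],
        size=length - 1,
        p=[0.1, 0.1, 0.1, 0.2, 0.2, 0.1, 0.05, 0.05, 0.1],
    )
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    return codes.astype(np.int64), times
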