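"""Per-mouse behavioral measures: preference, side bias, activity summaries,
distributions, and intake/dose conversions.

Conventions
-----------
* A *drinking episode* is a corner visit containing at least one lick.
* ``preference_ratio`` and ``side_bias`` are undefined (NaN) when both lick
  counts are zero — "no drinking" must stay distinct from "no preference".
* Intake converts licks to mass via a 3 µl/lick volume and an ethanol
  density of 0.789 g/ml (v/v to mass).  A directly measured intake mass may
  be supplied instead of licks.
* The blood-ethanol estimate scales linearly through the calibration point
  300 licks over 1 h <-> 0.1 permille w/v, and is an estimate only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .event_log import EventTable
from .schedule import SessionSpec, session_at

LICK_VOLUME_UL = 3.0
ETHANOL_DENSITY_G_PER_ML = 0.789
BEC_CALIBRATION_LICKS_PER_H = 300.0
BEC_CALIBRATION_PERMILLE = 0.1
DAY_S = 24 * 3600.0


# ---------------------------------------------------------------------------
# Ratio metrics


def preference_ratio(licks_alcohol: int, licks_water: int) -> float:
    """Alcohol preference: alcohol licks / (alcohol + water licks).

    NaN when both counts are zero.
    """
    if licks_alcohol < 0 or licks_water < 0:
        raise ValueError("lick counts must be non-negative")
    total = licks_alcohol + licks_water
    if total == 0:
        return float("nan")
    return licks_alcohol / total


def side_bias(licks_left: int, licks_right: int) -> float:
    """Side-bias index: (right - left) / (right + left); NaN when both zero."""
    if licks_left < 0 or licks_right < 0:
        raise ValueError("lick counts must be non-negative")
    total = licks_left + licks_right
    if total == 0:
        return float("nan")
    return (licks_right - licks_left) / total


def classify_bias(index: float) -> str:
    """'strong_left' iff index < -0.6; 'strong_right' iff index > 0.6; else 'none'.

    Thresholds are strict: exactly +-0.6 classifies as 'none'.
    """
    if math.isnan(index):
        return "none"
    if not -1.0 <= index <= 1.0:
        raise ValueError("bias index must lie in [-1, 1]")
    if index < -0.6:
        return "strong_left"
    if index > 0.6:
        return "strong_right"
    return "none"


# ---------------------------------------------------------------------------
# Intake / dose


def intake_dose(
    licks: int = 0,
    concentration_pct: float = 0.0,
    weight_g: float = 25.0,
    lick_volume_ul: float = LICK_VOLUME_UL,
    ethanol_density_g_per_ml: float = ETHANOL_DENSITY_G_PER_ML,
    intake_g: float | None = None,
) -> tuple[float, float]:
    """Ethanol intake mass (g) and dose (g/kg) for one interval.

    From licks: ``intake = licks x volume_ml x (concentration/100) x density``.
    If ``intake_g`` is given the lick conversion is bypassed and the dose is
    computed directly from the supplied mass (the exactly reproducible
    step).
    """
    if weight_g <= 0:
        raise ValueError("weight_g must be positive")
    if intake_g is None:
        if licks < 0:
            raise ValueError("licks must be non-negative")
        volume_ml = licks * lick_volume_ul / 1000.0
        intake_g = volume_ml * (concentration_pct / 100.0) * ethanol_density_g_per_ml
    dose_g_per_kg = intake_g / (weight_g / 1000.0)
    return intake_g, dose_g_per_kg


def estimate_bec(licks_in_window: int, window_h: float) -> float:
    """Rough blood-ethanol concentration (permille w/v) by linear scaling
    through the 300 licks/h <-> 0.1 permille calibration point."""
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    rate = licks_in_window / window_h
    return rate / BEC_CALIBRATION_LICKS_PER_H * BEC_CALIBRATION_PERMILLE


# ---------------------------------------------------------------------------
# Activity summaries


def daily_summary(table: EventTable) -> pd.DataFrame:
    """Per-mouse, per-day corner time, visit count and drinking episodes.

    A day is a 24 h window aligned to experiment start (day 1 covers
    [0, 86400)).  Returns a frame indexed by (animal_id, day).
    """
    df = table.df
    if df.empty:
        return pd.DataFrame(
            columns=["animal_id", "day", "corner_time_s", "visits", "drinking_episodes"]
        )
    work = df.copy()
    work["day"] = (work["t_start"] // DAY_S).astype(int) + 1
    work["duration"] = work["t_end"] - work["t_start"]
    work["episode"] = (work["licks_left"] + work["licks_right"]) >= 1
    out = (
        work.groupby(["animal_id", "day"], as_index=False)
        .agg(
            corner_time_s=("duration", "sum"),
            visits=("animal_id", "size"),
            drinking_episodes=("episode", "sum"),
        )
        .astype({"visits": int, "drinking_episodes": int})
    )
    return out


def circadian_profile(
    table: EventTable, interval_indices: Sequence[int] = (7, 14, 21, 28)
) -> pd.DataFrame:
    """24-point hourly visit profile per mouse, averaged over the chosen
    24 h intervals (1-based day indices).

    Bin ``h`` (1..24) holds visits whose start clock time lies in the
    preceding hour ``(h-1, h]``.
    """
    animals = table.animals
    profile = pd.DataFrame(
        0.0, index=animals, columns=pd.RangeIndex(1, 25, name="hour")
    )
    df = table.df
    if df.empty or not interval_indices:
        return profile
    for day in interval_indices:
        lo, hi = (day - 1) * DAY_S, day * DAY_S
        sub = df[(df["t_start"] >= lo) & (df["t_start"] < hi)]
        if sub.empty:
            continue
        clock_h = (sub["t_start"].to_numpy() - lo) / 3600.0
        # (h-1, h] binning: hour 24 takes clock 23..24, clock 0.0 exactly -> bin 24
        bins = np.ceil(clock_h).astype(int)
        bins[bins == 0] = 24
        for animal, b in zip(sub["animal_id"], bins):
            profile.loc[animal, b] += 1
    return profile / max(len(interval_indices), 1)


def duration_distributions(
    table: EventTable, bins_per_decade: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-binned histograms of visit durations and same-mouse same-corner
    revisit intervals (next t_start - current t_end).

    Returns ``(durations, intervals)`` frames with columns
    ``bin_lo, bin_hi, count``.  Non-positive values (zero-length visits,
    overlapping revisits) fall into the lowest bin.
    """
    df = table.df
    durations = (df["t_end"] - df["t_start"]).to_numpy()
    gaps = []
    for (_, _), sub in df.groupby(["animal_id", "corner"], sort=False):
        t_start = sub["t_start"].to_numpy()
        t_end = sub["t_end"].to_numpy()
        if len(sub) > 1:
            gaps.append(t_start[1:] - t_end[:-1])
    intervals = np.concatenate(gaps) if gaps else np.empty(0)

    def hist(values: np.ndarray) -> pd.DataFrame:
        if len(values) == 0:
            return pd.DataFrame(columns=["bin_lo", "bin_hi", "count"])
        vmax = max(values.max(), 1.0)
        top = math.ceil(math.log10(vmax)) + 1
        edges = np.logspace(-1, top, bins_per_decade * (top + 1) + 1)
        clipped = np.clip(values, edges[0] * 1.0000001, None)
        counts, _ = np.histogram(clipped, bins=edges)
        return pd.DataFrame(
            {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
        )

    return hist(durations), hist(intervals)


# ---------------------------------------------------------------------------
# Full metrics table


def summarize_metrics(
    table: EventTable,
    sessions: Sequence[SessionSpec],
    lick_volume_ul: float = LICK_VOLUME_UL,
    ethanol_density_g_per_ml: float = ETHANOL_DENSITY_G_PER_ML,
) -> pd.DataFrame:
    """Per-mouse x per-session metrics table.

    Columns: licks by bottle content (alcohol/saccharin/water), visits,
    corner time, drinking episodes, preference, side bias, ethanol intake
    and dose.  Content is resolved per visit side via the schedule.
    """
    if not sessions:
        raise DataError("no sessions supplied")
    weights = dict(zip(table.roster["animal_id"], table.roster["weight_g"]))
    rows = []
    df = table.df
    for ses in sessions:
        sub = df[(df["t_start"] >= ses.t_start) & (df["t_start"] < ses.t_end)]
        per: Dict[str, dict] = {
            a: {
                "licks_alcohol": 0,
                "licks_saccharin": 0,
                "licks_water": 0,
                "licks_left": 0,
                "licks_right": 0,
                "visits": 0,
                "corner_time_s": 0.0,
                "drinking_episodes": 0,
                "alcohol_pct": 0.0,
            }
            for a in table.animals
        }
        for row in sub.itertuples(index=False):
            acc = per[row.animal_id]
            acc["visits"] += 1
            acc["corner_time_s"] += row.t_end - row.t_start
            total_licks = row.licks_left + row.licks_right
            if total_licks >= 1:
                acc["drinking_episodes"] += 1
            for side, licks in (("left", row.licks_left), ("right", row.licks_right)):
                if licks == 0:
                    continue
                content = ses.content(int(row.corner), side)
                acc[f"licks_{content.kind}"] += int(licks)
                acc[f"licks_{side}"] += int(licks)
                if content.kind == "alcohol":
                    acc["alcohol_pct"] = max(acc["alcohol_pct"], content.alcohol_pct)
        for animal, acc in per.items():
            weight = float(weights.get(animal, float("nan")))
            if weight > 0:
                intake_g, dose = intake_dose(
                    licks=acc["licks_alcohol"],
                    concentration_pct=acc["alcohol_pct"],
                    weight_g=weight,
                    lick_volume_ul=lick_volume_ul,
                    ethanol_density_g_per_ml=ethanol_density_g_per_ml,
                )
            else:
                intake_g, dose = float("nan"), float("nan")
            rows.append(
                {
                    "animal_id": animal,
                    "session": ses.index,
                    "licks_alcohol": acc["licks_alcohol"],
                    "licks_saccharin": acc["licks_saccharin"],
                    "licks_water": acc["licks_water"],
                    "visits": acc["visits"],
                    "corner_time_s": acc["corner_time_s"],
                    "drinking_episodes": acc["drinking_episodes"],
                    "preference": preference_ratio(acc["licks_alcohol"], acc["licks_water"]),
                    "side_bias": side_bias(acc["licks_left"], acc["licks_right"]),
                    "intake_g": intake_g,
                    "dose_g_per_kg": dose,
                }
            )
    return pd.DataFrame(rows)
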