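"""Continental-shelf use: run-length-encoded detection of on-shelf benthic
runs in the departure and arrival phases of a trip, shelf-use durations and
transition times, and on/off-shelf dive-metric summaries.

A dive counts as *on-shelf* when it is benthic with max depth <= 140 m (the
shelf-break isobath). Within the first and last 72 h of a trip, a
*qualifying block* is a run of at least five consecutive on-shelf dives; a
*sustained off-shelf run* is, symmetrically, at least five consecutive
dives that are not on-shelf.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SHELF_BREAK_M = 140.0
MIN_RUN = 5
WINDOW_H = 72.0

METRIC_COLUMNS = ("ascent_rate", "bottom_time", "descent_rate", "max_depth",
                  "post_dive_interval")


@dataclass
class ShelfCrossing:
    animal_id: str
    phase: str  # departure | arrival
    on_shelf_duration_h: Optional[float]
    transition_time: Optional[pd.Timestamp]
    qualifying_block_start: Optional[pd.Timestamp]
    qualifying_block_end: Optional[pd.Timestamp]
    n_qualifying_dives: int
    missing: bool = False


def run_length_encode(flags: Sequence[bool]) -> list[tuple[bool, int, int]]:
    """RLE of a boolean sequence as (value, start_index, length) runs.

    Concatenating the runs reproduces the sequence exactly.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) == 0:
        return []
    change = np.flatnonzero(np.diff(flags.astype(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(flags)]))
    return [(bool(flags[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def find_qualifying_blocks(flags: Sequence[bool], min_run: int = MIN_RUN
                           ) -> list[tuple[int, int]]:
    """Index ranges (first, last inclusive) of runs of >= min_run True flags."""
    return [(s, s + n - 1) for val, s, n in run_length_encode(flags)
            if val and n >= min_run]


def flag_on_shelf(dive, shelf_depth: float = SHELF_BREAK_M) -> bool:
    """On-shelf iff the dive is benthic and its max depth <= 140 m."""
    return dive.type == "benthic" and dive.max_depth <= shelf_depth


def extract_phase_window(dives: list, phase: str, window_h: float = WINDOW_H
                         ) -> tuple[list, bool]:
    """Dives whose start falls in the first (departure) or last (arrival)
    ``window_h`` hours of the trip. Trips shorter than the window return the
    whole trip, flagged."""
    if not dives:
        return [], False
    t0 = pd.Timestamp(dives[0].start_time)
    t1 = pd.Timestamp(dives[-1].start_time)
    short = (t1 - t0) <= pd.Timedelta(hours=window_h)
    if phase == "departure":
        cut = t0 + pd.Timedelta(hours=window_h)
        sel = [d for d in dives if pd.Timestamp(d.start_time) <= cut]
    elif phase == "arrival":
        cut = t1 - pd.Timedelta(hours=window_h)
        sel = [d for d in dives if pd.Timestamp(d.start_time) >= cut]
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return sel, short


def shelf_duration(window_dives: list, phase: str, animal_id: str = "",
                   shelf_depth: float = SHELF_BREAK_M, min_run: int = MIN_RUN,
                   ) -> ShelfCrossing:
    """Shelf-use duration and transition time for one phase window.

    Departure: time from the first dive of the first qualifying block to
    the last on-shelf dive preceding the first sustained off-shelf run;
    the transition is the first dive of that off-shelf run. Arrival: the
    span of on-shelf dives from the first qualifying block that follows a
    sustained off-shelf run to the last such dive in the window; the
    transition is the first dive of that block. Windows with no qualifying
    block yield a missing record (excluded from duration summaries).
    """
    flags = [flag_on_shelf(d, shelf_depth) for d in window_dives]
    runs = run_length_encode(flags)
    missing = ShelfCrossing(animal_id, phase, None, None, None, None, 0, missing=True)

    def t(i):
        return pd.Timestamp(window_dives[i].start_time)

    if phase == "departure":
        blocks = find_qualifying_blocks(flags, min_run)
        if not blocks:
            return missing
        first, _ = blocks[0]
        # first sustained off-shelf run after the qualifying block
        off = next(((s, s + n - 1) for val, s, n in runs
                    if not val and n >= min_run and s > first), None)
        if off is None:
            return missing
        # last on-shelf dive before that run
        before = [i for i, f in enumerate(flags) if f and i < off[0]]
        last = before[-1]
        return ShelfCrossing(
            animal_id, phase,
            on_shelf_duration_h=(t(last) - t(first)).total_seconds() / 3600.0,
            transition_time=t(off[0]),
            qualifying_block_start=t(first), qualifying_block_end=t(last),
            n_qualifying_dives=sum(1 for i in range(first, last + 1) if flags[i]),
        )

    if phase == "arrival":
        # first qualifying block preceded by a sustained off-shelf run
        start_block = None
        for val, s, n in runs:
            if not val and n >= min_run:
                for b0, b1 in find_qualifying_blocks(flags, min_run):
                    if b0 > s:
                        start_block = (b0, b1)
                        break
                if start_block:
                    break
        if start_block is None:
            return missing
        first = start_block[0]
        after = [i for i, f in enumerate(flags) if f and i >= first]
        last = after[-1]
        return ShelfCrossing(
            animal_id, phase,
            on_shelf_duration_h=(t(last) - t(first)).total_seconds() / 3600.0,
            transition_time=t(first),
            qualifying_block_start=t(first), qualifying_block_end=t(last),
            n_qualifying_dives=sum(1 for i in range(first, last + 1) if flags[i]),
        )

    raise ValueError(f"unknown phase {phase!r}")


def trip_shelf_crossings(dives: list, animal_id: str = "",
                         shelf_depth: float = SHELF_BREAK_M,
                         min_run: int = MIN_RUN,
                         window_h: float = WINDOW_H) -> list[ShelfCrossing]:
    out = []
    for phase in ("departure", "arrival"):
        window, _ = extract_phase_window(dives, phase, window_h)
        out.append(shelf_duration(window, phase, animal_id, shelf_depth, min_run))
    return out


def phase_shelf_table(dives: list, crossings: list[ShelfCrossing],
                      animal_id: str = "",
                      window_h: float = WINDOW_H) -> pd.DataFrame:
    """Per-dive table of phase (departure/arrival) and shelf status (on/off)
    around each crossing, with the Figure-style dive metrics.

    Shelf status splits the phase window at the transition time: departure
    dives before the transition are on-shelf; arrival dives from the
    transition onward are on-shelf.
    """
    rows = []
    by_phase = {c.phase: c for c in crossings}
    for phase in ("departure", "arrival"):
        c = by_phase.get(phase)
        if c is None or c.missing:
            continue
        window, _ = extract_phase_window(dives, phase, window_h)
        for d in window:
            ts = pd.Timestamp(d.start_time)
            if phase == "departure":
                status = "on" if ts < c.transition_time else "off"
            else:
                status = "on" if ts >= c.transition_time else "off"
            m = d.metrics
            rows.append({
                "animal_id": animal_id, "phase": phase, "shelf_status": status,
                "start_time": ts, "type": d.type,
                "ascent_rate": m.ascent_rate, "bottom_time": m.bottom_time,
                "descent_rate": m.descent_rate, "max_depth": d.max_depth,
                "post_dive_interval": m.post_dive_interval,
            })
    return pd.DataFrame(rows)


def phase_shelf_metric_summary(dive_table: pd.DataFrame,
                               metrics: Sequence[str] = METRIC_COLUMNS
                               ) -> pd.DataFrame:
    """Grand mean +/- SE of each seal's mean metric, by phase and shelf
    status (two-stage aggregation: per-seal means first, then mean and SE
    across seals). Cells with one seal get SE = 0 and a flag."""
    rows = []
    seal_means = (dive_table
                  .groupby(["phase", "shelf_status", "animal_id"])[list(metrics)]
                  .mean())
    for (phase, status), grp in seal_means.groupby(level=["phase", "shelf_status"]):
        for metric in metrics:
            vals = grp[metric].dropna().to_numpy()
            if len(vals) == 0:
                continue
            se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            rows.append({"phase": phase, "shelf_status": status, "metric": metric,
                         "grand_mean": float(np.mean(vals)), "se": se,
                         "n_seals": len(vals), "single_seal": len(vals) == 1})
    return pd.DataFrame(rows)


def crossings_to_frame(crossings: list[ShelfCrossing]) -> pd.DataFrame:
    return pd.DataFrame([{
        "animal_id": c.animal_id, "phase": c.phase,
        "on_shelf_duration_h": c.on_shelf_duration_h,
        "transition_time": c.transition_time,
        "qualifying_block_start": c.qualifying_block_start,
        "qualifying_block_end": c.qualifying_block_end,
        "n_qualifying_dives": c.n_qualifying_dives,
        "missing": c.missing,
    } for c in crossings])
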