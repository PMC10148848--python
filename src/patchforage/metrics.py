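"""Dependent measures and deviation-from-optimality statistics.

Five primary measures per rat and changeover delay, computed from session
event logs with the task's exclusion and averaging rules:

* patch changes (PC) — number of leave choices, excluding the leaves that
  bound a session's first and final patches;
* time in patch (TIP, s) — mean stay duration over complete patch visits;
* rejection volume (uL) — the "indifference point": the volume scheduled
  next at the moment of leaving, averaged over complete visits;
* water rate (WR, uL/min/kg) — total earned volume over the time taken to
  earn it, normalized by body weight;
* percent deviations from the MVT optimum — volume deviation
  (VD = (optimal − observed)/optimal x 100, positive = overharvesting)
  and time deviation (TD = (observed − optimal)/optimal x 100, positive =
  staying longer than optimal).

A session's first and final patches (and their bounding patch changes) are
excluded: the first patch predates any experienced COD, the final one is cut
off by session termination. Each week's first 0-s session is a warm-up and
excluded; per-rat values average the remaining sessions of the last two
weekly cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulator import RatRecord, SessionLog
from .task_core import TaskConfig, optimal_curves, reward_volume, solve_optimal_policy

__all__ = [
    "PatchVisit",
    "extract_patch_visits",
    "session_metrics",
    "aggregate_rat",
    "cohort_metrics",
    "percent_volume_deviation",
    "percent_time_deviation",
    "harvest_classification",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ["rat_id", "sex", "cod_s", "pc", "tip_s", "rejection_ul",
                  "wr_ul_min_kg", "vd_pct", "td_pct", "n_sessions"]

#: |VD| below this counts as exactly optimal (deterministic simulations);
#: noisy cohorts effectively classify by sign.
OPTIMALITY_TOL = 1e-9


@dataclass(frozen=True)
class PatchVisit:
    """One patch occupancy: entry to leave (or to session end)."""

    start_time: float
    end_time: float
    n_rewards: int
    volumes: tuple[float, ...]
    rejection_volume: float  # volume scheduled next at the moment of leaving
    complete: bool  # False for a session's first and final patches


def extract_patch_visits(
    log: SessionLog, config: TaskConfig = TaskConfig()
) -> list[PatchVisit]:
    """Partition a session's reward events into ordered patch visits.

    The first visit and the visit in progress at session end are flagged
    ``complete=False``. The rejection volume of a visit with ``n`` rewards
    is ``reward_volume(n + 1)`` — e.g. leaving after earning 120 uL rejects
    the scheduled 96 uL.
    """
    visits: list[PatchVisit] = []
    cur_start: Optional[float] = None
    cur_volumes: list[float] = []
    ended_by_leave = False

    def close(end_time: float, by_leave: bool) -> None:
        nonlocal cur_start, cur_volumes
        if cur_start is None:
            return
        n = len(cur_volumes)
        visits.append(
            PatchVisit(
                start_time=cur_start,
                end_time=end_time,
                n_rewards=n,
                volumes=tuple(cur_volumes),
                rejection_volume=reward_volume(n + 1, config),
                complete=by_leave,  # first-visit flag fixed below
            )
        )
        cur_start = None
        cur_volumes = []

    for e in log.events:
        if e.event_type == "patch_entry":
            if cur_start is not None:
                raise ValueError(f"event {e.index}: patch entered before previous leave")
            cur_start = e.time
        elif e.event_type == "reward":
            if cur_start is None:
                raise ValueError(f"event {e.index}: reward outside a patch visit")
            cur_volumes.append(e.volume)
        elif e.event_type == "leave":
            close(e.time, by_leave=True)
        elif e.event_type == "session_end":
            close(e.time, by_leave=False)
    if visits:
        first = visits[0]
        visits[0] = PatchVisit(
            first.start_time, first.end_time, first.n_rewards,
            first.volumes, first.rejection_volume, complete=False,
        )
    return visits


def session_metrics(
    log: SessionLog,
    body_weight: float,
    config: TaskConfig = TaskConfig(),
) -> dict:
    """Per-session PC, TIP, rejection volume and WR.

    WR uses the elapsed time from session start to the final reward event —
    the span over which the reinforcers were actually earned — not the full
    cap when the volume cap ends the session early. Sessions without a
    complete visit yield NaN (missing), never zero, for the visit-based
    measures; a degenerate zero-elapsed session (possible at COD 0 under
    the idealized timing) yields NaN WR.
    """
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    visits = extract_patch_visits(log, config)
    complete = [v for v in visits if v.complete]
    reward_times = [e.time for e in log.events if e.event_type == "reward"]
    total_ul = sum(v for vis in visits for v in vis.volumes)
    if reward_times and reward_times[-1] > 0:
        wr = total_ul / (reward_times[-1] / 60.0) / body_weight
    else:
        wr = float("nan")
    if complete:
        pc = float(len(complete))  # one terminating leave per complete visit
        tip = float(np.mean([v.end_time - v.start_time for v in complete]))
        rejection = float(np.mean([v.rejection_volume for v in complete]))
    else:
        pc = tip = rejection = float("nan")
    return {
        "cod_s": log.cod,
        "session_index": log.session_index,
        "pc": pc,
        "tip_s": tip,
        "rejection_ul": rejection,
        "wr_ul_min_kg": wr,
        "n_complete": len(complete),
    }


def percent_volume_deviation(observed: float, optimal: float) -> float:
    """(optimal − observed)/optimal x 100; positive = overharvesting."""
    if optimal <= 0:
        raise ValueError("optimal rejection volume must be positive")
    if math.isnan(observed):
        return float("nan")
    return (optimal - observed) / optimal * 100.0


def percent_time_deviation(observed: float, optimal: float) -> float:
    """(observed − optimal)/optimal x 100; positive = staying too long.

    Undefined (NaN) when the optimal time is zero, which happens at COD 0
    where the optimal stay is a single reward; surfaced as missing rather
    than infinite.
    """
    if optimal < 0:
        raise ValueError("optimal time in patch must be non-negative")
    if optimal == 0:
        return float("nan")
    if math.isnan(observed):
        return float("nan")
    return (observed - optimal) / optimal * 100.0


def _included_sessions(config: TaskConfig) -> list[int]:
    """1-based indices of analyzed sessions: last two cycles, week-first excluded."""
    week = len(config.weekly_cod_sequence)
    total = week * config.n_cycles
    first_kept_cycle = max(config.n_cycles - 2, 0)
    out = []
    for i in range(1, total + 1):
        cycle = (i - 1) // week  # 0-based
        pos = (i - 1) % week  # 0-based within week; 0 = excluded warm-up
        if cycle >= first_kept_cycle and pos != 0:
            out.append(i)
    return out


def aggregate_rat(
    logs: Sequence[SessionLog],
    rat: RatRecord,
    config: TaskConfig = TaskConfig(),
) -> pd.DataFrame:
    """Per-rat x per-COD dependent measures (tidy, one row per COD).

    Averages session metrics over the analyzed sessions of the last two
    cycles at each COD (two sessions per COD under the default protocol),
    then attaches the MVT deviations. Missing per-session values are
    skipped; ``n_sessions`` records how many sessions contributed. Raises
    if any expected (cycle, COD) session is absent.
    """
    total = len(config.weekly_cod_sequence) * config.n_cycles
    by_index = {log.session_index: log for log in logs}
    expected = set(range(1, total + 1))
    missing = sorted(expected - set(by_index))
    if missing:
        week = len(config.weekly_cod_sequence)
        pairs = [(1 + (i - 1) // week, config.weekly_cod_sequence[(i - 1) % week]) for i in missing]
        raise ValueError(f"protocol incomplete; missing (cycle, COD) sessions: {pairs}")

    rows = []
    for i in _included_sessions(config):
        log = by_index[i]
        rows.append(session_metrics(log, rat.body_weight, config))
    per_session = pd.DataFrame(rows)
    agg = (
        per_session.groupby("cod_s", sort=True)
        .agg(
            pc=("pc", "mean"),
            tip_s=("tip_s", "mean"),
            rejection_ul=("rejection_ul", "mean"),
            wr_ul_min_kg=("wr_ul_min_kg", "mean"),
            n_sessions=("session_index", "size"),
        )
        .reset_index()
    )
    opt = {c: solve_optimal_policy(c, config) for c in agg["cod_s"].unique()}
    agg["vd_pct"] = [
        percent_volume_deviation(r.rejection_ul, opt[r.cod_s].optimal_rejection_volume)
        for r in agg.itertuples()
    ]
    agg["td_pct"] = [
        percent_time_deviation(r.tip_s, opt[r.cod_s].optimal_time_in_patch)
        for r in agg.itertuples()
    ]
    agg.insert(0, "rat_id", rat.rat_id)
    agg.insert(1, "sex", rat.sex)
    return agg[METRIC_COLUMNS]


def cohort_metrics(
    logs_by_rat: dict[str, Sequence[SessionLog]],
    rats: Sequence[RatRecord],
    config: TaskConfig = TaskConfig(),
) -> pd.DataFrame:
    """Stack :func:`aggregate_rat` over a cohort into one tidy table."""
    by_id = {r.rat_id: r for r in rats}
    frames = [aggregate_rat(logs, by_id[rid], config) for rid, logs in logs_by_rat.items()]
    return pd.concat(frames, ignore_index=True)


def harvest_classification(
    metrics: pd.DataFrame,
    tol: float = OPTIMALITY_TOL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each rat x COD as over/under/optimal and tally the cohort.

    Overharvesting is VD > 0 (stayed past the optimal leave point), under-
    harvesting VD < 0; |VD| <= tol counts as optimal. Returns ``(labels,
    frequencies)`` where frequencies give per-COD percentages by sex.
    """
    labels = metrics[["rat_id", "sex", "cod_s", "vd_pct"]].copy()

    def classify(vd: float) -> str:
        if math.isnan(vd):
            return "missing"
        if vd > tol:
            return "over"
        if vd < -tol:
            return "under"
        return "optimal"

    labels["harvest"] = labels["vd_pct"].map(classify)
    counted = labels[labels["harvest"] != "missing"]
    freq = (
        counted.groupby(["sex", "cod_s"])["harvest"]
        .value_counts(normalize=True)
        .mul(100.0)
        .rename("percent")
        .reset_index()
    )
    return labels, freq
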