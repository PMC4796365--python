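"""Passage-event classification and cohort passage statistics.

Each transit is reduced to the four-phase event structure — (i) cell entry,
(ii) nuclear entry, (iii) nuclear exit, (iv) cell exit — using the
half-open constriction interval: an edge exactly at the entry plane counts
as having entered.  The percentage of passage is the ratio of cells that
passed to cells that encountered the constriction, with censored cells
(movie ends while the cell is engaged) excluded from both numerator and
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NotEncountered
from .microdevice import ChannelGeometry
from .stats import summarize

__all__ = ["EventParams", "PassageEvent", "classify_passage",
           "cohort_passage_stats"]

OUTCOMES = ("passed", "reversed_no_nuclear_entry",
            "reversed_after_nuclear_entry", "censored")


@dataclass(frozen=True)
class EventParams:
    """Classifier margins (micrometres), both above pixel/jitter scale.

    reversal_margin_um : retreat of the cell front behind the entrance that
        confirms a direction change.
    nuclear_entry_margin_um : protrusion of the nucleus front beyond the
        entrance that counts as nuclear entry.
    """
    reversal_margin_um: float = 2.0
    nuclear_entry_margin_um: float = 0.5


@dataclass
class PassageEvent:
    """Times are minutes from movie start; None when the phase never
    occurred within the movie."""
    t_cell_entry_min: float | None
    t_nuc_entry_min: float | None
    t_nuc_exit_min: float | None
    t_cell_exit_min: float | None
    outcome: str
    nuclear_entry_flag: bool
    cell_passage_time_min: float | None = None
    nuc_passage_time_min: float | None = None
    non_passage_time_min: float | None = None


def _first_at_or_after(series: pd.Series, threshold: float):
    hit = series.index[series >= threshold]
    return int(hit[0]) if len(hit) else None


def classify_passage(track: pd.DataFrame, geometry: ChannelGeometry,
                     frame_interval_min: float,
                     params: EventParams = EventParams()) -> PassageEvent:
    """Classify one track into a PassageEvent.

    Only the first engagement is scored: if the cell confirms a reversal
    (front retreats ``reversal_margin_um`` behind the entrance) before any
    cell exit, the outcome is the reversal even if the cell later returns.
    The non-passage time runs from cell entry to the frame of maximal front
    advance (the direction change), not to the confirmation frame.

    Raises
    ------
    NotEncountered
        If the cell front never reached the entrance (such cells are
        excluded from passage denominators upstream).
    """
    d = geometry.migration_direction
    dt = frame_interval_min
    s_entr = geometry.entrance_x_um * d
    s_exit = geometry.exit_x_um * d
    cell_front = track["cell_front_x_um"] * d
    cell_back = track["cell_back_x_um"] * d
    nuc_front = track["nuc_front_x_um"] * d
    nuc_back = track["nuc_back_x_um"] * d

    f_cell_entry = _first_at_or_after(cell_front, s_entr)
    if f_cell_entry is None:
        raise NotEncountered("cell front never reached the entrance")
    f_nuc_entry = _first_at_or_after(nuc_front, s_entr)
    f_nuc_exit = _first_at_or_after(nuc_back, s_exit)
    f_cell_exit = _first_at_or_after(cell_back, s_exit)

    # first confirmed reversal after entry and before any exit
    after_entry = cell_front.loc[f_cell_entry:]
    retreat = after_entry.index[after_entry < s_entr - params.reversal_margin_um]
    f_retreat = int(retreat[0]) if len(retreat) else None

    nuclear_entry = bool(
        (nuc_front >= s_entr + params.nuclear_entry_margin_um).any())

    if f_cell_exit is not None and (f_retreat is None
                                    or f_cell_exit <= f_retreat):
        outcome = "passed"
        f_retreat = None
    elif f_retreat is not None:
        outcome = ("reversed_after_nuclear_entry" if nuclear_entry
                   else "reversed_no_nuclear_entry")
        f_cell_exit = None
        if f_nuc_exit is not None and f_nuc_exit > f_retreat:
            f_nuc_exit = None
    else:
        outcome = "censored"

    ev = PassageEvent(
        t_cell_entry_min=f_cell_entry * dt,
        t_nuc_entry_min=None if f_nuc_entry is None else f_nuc_entry * dt,
        t_nuc_exit_min=None if f_nuc_exit is None else f_nuc_exit * dt,
        t_cell_exit_min=None if f_cell_exit is None else f_cell_exit * dt,
        outcome=outcome,
        nuclear_entry_flag=nuclear_entry,
    )
    if outcome == "passed":
        ev.cell_passage_time_min = ev.t_cell_exit_min - ev.t_cell_entry_min
        if ev.t_nuc_entry_min is not None and ev.t_nuc_exit_min is not None:
            ev.nuc_passage_time_min = ev.t_nuc_exit_min - ev.t_nuc_entry_min
    elif outcome.startswith("reversed"):
        # direction change = last frame at (near) maximal front advance
        # before the confirmation: a cell dwelling with a stationary front
        # has not yet changed direction, and slow retreats afterwards do
        # not inflate the dwell either
        engaged = cell_front.loc[f_cell_entry:f_retreat].dropna()
        tol = 2.0 * geometry.pixel_size_um
        near_max = engaged[engaged >= engaged.max() - tol]
        f_turn = int(near_max.index[-1])
        ev.non_passage_time_min = (f_turn - f_cell_entry) * dt
    return ev


def cohort_passage_stats(events: list[PassageEvent]) -> dict:
    """Cohort summary of a list of classified events.

    Percentage of passage = passed / (passed + reversed); censored events
    are excluded from both numerator and denominator.  Means carry s.e.m.
    computed with the n-1 sample standard deviation.
    """
    if not events:
        raise ValueError("no events to summarize")
    resolved = [e for e in events if e.outcome != "censored"]
    if not resolved:
        raise ValueError("all events censored; passage rate undefined")
    n_passed = sum(e.outcome == "passed" for e in resolved)
    reversed_ev = [e for e in resolved if e.outcome.startswith("reversed")]

    def _summ(values):
        values = [v for v in values if v is not None and np.isfinite(v)]
        if not values:
            return {"mean": None, "sem": None, "n": 0}
        s = summarize(values)
        return {"mean": s.mean,
                "sem": None if np.isnan(s.sem) else s.sem,
                "n": s.n}

    out = {
        "n_encountered": len(resolved),
        "n_passed": n_passed,
        "n_reversed": len(reversed_ev),
        "n_censored": len(events) - len(resolved),
        "percent_passage": 100.0 * n_passed / len(resolved),
        "cell_passage_time_min": _summ(
            [e.cell_passage_time_min for e in resolved]),
        "nuc_passage_time_min": _summ(
            [e.nuc_passage_time_min for e in resolved]),
        "non_passage_time_min": _summ(
            [e.non_passage_time_min for e in reversed_ev]),
    }
    if reversed_ev:
        out["fraction_nonpassers_with_nuclear_entry"] = (
            sum(e.nuclear_entry_flag for e in reversed_ev) / len(reversed_ev))
    else:
        out["fraction_nonpassers_with_nuclear_entry"] = None
    return out
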