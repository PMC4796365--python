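"""Mask-derived kinematics: centers, edges, velocities.

A track is a pandas DataFrame with one row per movie frame (missing frames
are rows of NaN — gaps are recorded, never interpolated, so every number is
traceable to an observed mask pair).  Coordinates are physical micrometres;
"front" and "back" are the leading and trailing axial mask edges along the
migration direction.

Velocities use the backward difference assigned to the later frame, with no
smoothing — the simplest estimator at the 2-minute sampling used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TrackTooShort, UndefinedBaseline
from .microdevice import ChannelGeometry
from .movieio import Movie

__all__ = ["build_track", "instantaneous_velocity",
           "mean_speed_before_touch", "normalized_velocity_variation",
           "nuclear_transit_slowdown", "Kinematics", "TRACK_COLUMNS"]

TRACK_COLUMNS = [
    "t_min", "cell_com_x_um", "cell_com_y_um", "nuc_com_x_um", "nuc_com_y_um",
    "cell_front_x_um", "cell_back_x_um", "nuc_front_x_um", "nuc_back_x_um",
    "cell_area_um2", "nuc_area_um2", "cell_mean_actin", "nuc_mean_dna",
    "cell_touches_xborder",
]


def _mask_stats(mask: np.ndarray, pixel_size: float, direction: int):
    ys, xs = np.nonzero(mask)
    cx = (xs.mean() + 0.5) * pixel_size
    cy = (ys.mean() + 0.5) * pixel_size
    coords = (xs + 0.5) * pixel_size
    if direction > 0:
        front, back = coords.max(), coords.min()
    else:
        front, back = coords.min(), coords.max()
    area = mask.sum() * pixel_size ** 2
    touches = xs.min() == 0 or xs.max() == mask.shape[1] - 1
    return cx, cy, front, back, area, touches


def build_track(masks, movie: Movie, geometry: ChannelGeometry) -> pd.DataFrame:
    """One TrackPoint row per frame from a sequence of FrameMasks.

    ``masks`` is a sequence (len == movie.n_frames) of FrameMasks or None
    for frames where segmentation failed.  Requires at least two valid
    frames with both cell and nucleus masks... the nucleus may be absent
    (None) throughout, in which case nucleus columns stay NaN.

    Raises
    ------
    TrackTooShort
        If fewer than two frames have a valid cell mask.
    """
    px = geometry.pixel_size_um
    d = geometry.migration_direction
    actin = movie.channel("actin")
    dna = movie.channel("dna") if "dna" in movie.channel_map else None
    rows = []
    n_valid = 0
    for t, fm in enumerate(masks):
        row = {c: np.nan for c in TRACK_COLUMNS}
        row["t_min"] = t * movie.frame_interval_min
        row["cell_touches_xborder"] = False
        if fm is not None and fm.cell is not None and fm.cell.any():
            cx, cy, front, back, area, touches = _mask_stats(fm.cell, px, d)
            row.update(cell_com_x_um=cx, cell_com_y_um=cy,
                       cell_front_x_um=front, cell_back_x_um=back,
                       cell_area_um2=area, cell_touches_xborder=touches,
                       cell_mean_actin=float(actin[t][fm.cell].mean()))
            n_valid += 1
            if fm.nucleus is not None and fm.nucleus.any():
                nx_, ny_, nf, nb, narea, _ = _mask_stats(fm.nucleus, px, d)
                row.update(nuc_com_x_um=nx_, nuc_com_y_um=ny_,
                           nuc_front_x_um=nf, nuc_back_x_um=nb,
                           nuc_area_um2=narea)
                if dna is not None:
                    row["nuc_mean_dna"] = float(dna[t][fm.nucleus].mean())
        rows.append(row)
    if n_valid < 2:
        raise TrackTooShort(f"only {n_valid} frames with a valid cell mask")
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.index.name = "frame"
    return df


def instantaneous_velocity(track: pd.DataFrame, frame_interval_min: float,
                           *, direction: int = 1,
                           column: str = "cell_com_x_um") -> pd.Series:
    """Signed axial speed (um/min) from backward com differences.

    Positive along the migration direction; assigned to the later frame;
    missing frames propagate NaN.
    """
    if len(track) < 2:
        raise TrackTooShort("need at least two track points")
    v = track[column].diff() * direction / frame_interval_min
    v.name = "v_um_min"
    return v


def _axial(x, direction: int):
    return x * direction


def first_touch_frame(track: pd.DataFrame, geometry: ChannelGeometry):
    """First frame where the nucleus front reached the constriction
    entrance (half-open convention: exactly at the plane counts)."""
    d = geometry.migration_direction
    s_front = _axial(track["nuc_front_x_um"], d)
    s_entr = _axial(geometry.entrance_x_um, d)
    hit = track.index[s_front >= s_entr]
    return int(hit[0]) if len(hit) else None


def mean_speed_before_touch(track: pd.DataFrame, geometry: ChannelGeometry,
                            frame_interval_min: float) -> float:
    """Mean cell velocity over frames strictly before the nucleus touched
    the constriction (the baseline of the velocity-variation ratio)."""
    touch = first_touch_frame(track, geometry)
    if touch is None:
        raise UndefinedBaseline("nucleus never touched the constriction")
    v = instantaneous_velocity(track, frame_interval_min,
                               direction=geometry.migration_direction)
    pre = v.loc[:touch - 1].dropna()
    if pre.empty:
        raise UndefinedBaseline("no valid displacement before nuclear touch")
    return float(pre.mean())


@dataclass
class Kinematics:
    """Per-cell velocity summary."""
    v_pre_um_min: float
    velocity: pd.Series
    normalized_variation: pd.Series


def normalized_velocity_variation(track: pd.DataFrame,
                                  geometry: ChannelGeometry,
                                  frame_interval_min: float,
                                  v_pre: float | None = None) -> pd.Series:
    """(v_inst - v_pre) / v_pre for frames with the cell in the constriction.

    ``v_pre`` is the mean cell velocity before the nucleus touched the
    constriction; frames where the cell does not overlap the constriction
    interval are NaN.
    """
    if v_pre is None:
        v_pre = mean_speed_before_touch(track, geometry, frame_interval_min)
    if not np.isfinite(v_pre) or v_pre <= 0:
        raise UndefinedBaseline(f"non-positive baseline speed {v_pre}")
    d = geometry.migration_direction
    v = instantaneous_velocity(track, frame_interval_min, direction=d)
    s_front = _axial(track["cell_front_x_um"], d)
    s_back = _axial(track["cell_back_x_um"], d)
    in_constriction = (s_front >= _axial(geometry.entrance_x_um, d)) & \
                      (s_back < _axial(geometry.exit_x_um, d))
    out = (v - v_pre) / v_pre
    out[~in_constriction] = np.nan
    out.name = "normalized_velocity_variation"
    return out


def nuclear_transit_slowdown(track: pd.DataFrame, geometry: ChannelGeometry,
                             frame_interval_min: float) -> float:
    """Mean normalized velocity variation during nuclear transit.

    Restricted to displacements that lie entirely inside the nuclear
    transit window (after the measured nuclear-entry frame and before the
    measured nuclear-exit/turn frame), so that boundary frames mixing free
    and constricted motion do not dilute the ratio.

    Raises
    ------
    UndefinedBaseline
        If there is no pre-touch baseline or no clean transit displacement.
    """
    d = geometry.migration_direction
    v_pre = mean_speed_before_touch(track, geometry, frame_interval_min)
    if v_pre <= 0:
        raise UndefinedBaseline("non-positive baseline speed")
    entry = first_touch_frame(track, geometry)
    s_back = _axial(track["nuc_back_x_um"], d)
    s_exit = _axial(geometry.exit_x_um, d)
    exited = track.index[s_back >= s_exit]
    last = int(exited[0]) if len(exited) else int(track.index[-1])
    v = instantaneous_velocity(track, frame_interval_min, direction=d)
    window = v.loc[entry + 1:last - 1].dropna()
    if window.empty:
        raise UndefinedBaseline("no clean displacement inside nuclear transit")
    return float(((window - v_pre) / v_pre).mean())
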