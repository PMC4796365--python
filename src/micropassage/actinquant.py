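"""Normalized actin-enrichment metrics, nuclear shape metrics and the
DNA-thickness/actin relation.

All intensity metrics are ratios against the mean intensity of the whole
cell mask, which makes them invariant under global multiplicative intensity
scaling and exactly 1 for a uniformly bright cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import find_contours

from .errors import (BorderTouchWarning, CellNotInConstriction,
                     InsufficientColumns, NaNIntensity, UndefinedBaseline)
from .microdevice import ChannelGeometry, constriction_mask, pixel_centers
from .segment import FrameMasks, bead_in_cell

__all__ = ["EnrichmentParams", "normalized_actin_in_constriction",
           "normalized_perinuclear_actin", "enrichment_flag",
           "actin_vs_position_profile", "nuclear_circularity",
           "dna_thickness_actin_relation", "actin_around_bead",
           "series_enrichment_flag"]


@dataclass(frozen=True)
class EnrichmentParams:
    """Adaptive enrichment criterion: a cell is scored as accumulating
    actin when the peak normalized signal inside the scoring window exceeds
    the pre-entry baseline by ``k_sd`` baseline standard deviations and an
    absolute floor."""
    k_sd: float = 2.0
    floor: float = 1.2
    min_baseline_frames: int = 3


def normalized_actin_in_constriction(actin_frame: np.ndarray,
                                     cell_mask: np.ndarray,
                                     geometry: ChannelGeometry) -> float:
    """Mean actin over cell-in-constriction, normalized by whole-cell mean.

    (total actin in cell-and-constriction / that area) / mean actin in cell.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    region = cell_mask & constriction_mask(geometry, cell_mask.shape)
    if not region.any():
        raise CellNotInConstriction("cell mask does not reach the constriction")
    frame = np.asarray(actin_frame, dtype=float)
    cell_mean = frame[cell_mask].mean()
    if cell_mean == 0:
        raise NaNIntensity("zero whole-cell mean intensity")
    return float(frame[region].mean() / cell_mean)


def normalized_perinuclear_actin(actin_frame: np.ndarray,
                                 masks: FrameMasks) -> float:
    """Mean actin over the perinuclear cortex / mean actin over the cell."""
    if masks.perinuclear_cortex is None or not masks.perinuclear_cortex.any():
        raise ValueError("masks.perinuclear_cortex missing or empty")
    frame = np.asarray(actin_frame, dtype=float)
    cell_mean = frame[masks.cell].mean()
    if cell_mean == 0:
        raise NaNIntensity("zero whole-cell mean intensity")
    return float(frame[masks.perinuclear_cortex].mean() / cell_mean)


def series_enrichment_flag(values: pd.Series, baseline_frames,
                           window_frames,
                           params: EnrichmentParams = EnrichmentParams()
                           ) -> tuple[bool, float]:
    """Generic baseline-vs-window enrichment call on a per-frame series."""
    base = values.loc[values.index.isin(baseline_frames)].dropna()
    if len(base) < params.min_baseline_frames:
        raise UndefinedBaseline(
            f"only {len(base)} baseline frames, need "
            f"{params.min_baseline_frames}")
    win = values.loc[values.index.isin(window_frames)].dropna()
    if win.empty:
        return False, float("nan")
    peak = float(win.max())
    threshold = max(base.mean() + params.k_sd * base.std(ddof=1), params.floor)
    return bool(peak >= threshold), peak


def enrichment_flag(perinuclear_series: pd.Series, event,
                    frame_interval_min: float,
                    params: EnrichmentParams = EnrichmentParams()
                    ) -> tuple[bool, float]:
    """Binary perinuclear actin-accumulation call for one cell.

    The scoring window is the nuclear engagement interval
    ``[t_nuc_entry, min(t_nuc_exit, turn))``; the baseline is every frame
    strictly before nuclear entry.  Returns ``(flag, peak)``.

    Raises
    ------
    UndefinedBaseline
        With fewer than ``min_baseline_frames`` valid pre-entry frames.
    """
    if event.t_nuc_entry_min is None:
        raise UndefinedBaseline("no nuclear entry; nothing to score")
    dt = frame_interval_min
    entry = int(round(event.t_nuc_entry_min / dt))
    if event.t_nuc_exit_min is not None:
        last = int(round(event.t_nuc_exit_min / dt))
    elif event.non_passage_time_min is not None:
        last = int(round((event.t_cell_entry_min
                          + event.non_passage_time_min) / dt))
    else:
        last = int(perinuclear_series.index[-1])
    baseline = [i for i in perinuclear_series.index if i < entry]
    window = [i for i in perinuclear_series.index if entry <= i <= last]
    return series_enrichment_flag(perinuclear_series, baseline, window, params)


def actin_vs_position_profile(records: list[tuple[pd.Series, pd.Series]],
                              geometry: ChannelGeometry,
                              bin_width_um: float = 2.0) -> pd.DataFrame:
    """Cohort profile of normalized perinuclear actin vs nuclear position.

    ``records`` holds per-cell pairs of aligned series
    ``(nuc_com_x_um, normalized_perinuclear_actin)``.  The alignment
    coordinate is the nuclear center of mass minus the constriction center,
    signed along the migration direction, binned at ``bin_width_um``.
    Empty bins are reported with n=0 and NaN mean.
    """
    if bin_width_um <= 0:
        raise ValueError("bin width must be > 0")
    xs, vs = [], []
    for pos, val in records:
        rel = (pos - geometry.constriction_center_x_um) \
            * geometry.migration_direction
        ok = rel.notna() & val.notna()
        xs.append(rel[ok].to_numpy())
        vs.append(val[ok].to_numpy())
    x = np.concatenate(xs) if xs else np.array([])
    v = np.concatenate(vs) if vs else np.array([])
    if x.size == 0:
        raise ValueError("no valid (position, value) samples")
    lo = np.floor(x.min() / bin_width_um) * bin_width_um
    hi = np.ceil(x.max() / bin_width_um) * bin_width_um
    edges = np.arange(lo, hi + bin_width_um, bin_width_um)
    idx = np.digitize(x, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = v[idx == b]
        rows.append({
            "bin_center_um": (edges[b] + edges[b + 1]) / 2,
            "mean_norm_actin": sel.mean() if sel.size else np.nan,
            "sd": sel.std(ddof=1) if sel.size > 1 else np.nan,
            "n": int(sel.size),
        })
    return pd.DataFrame(rows)


def nuclear_circularity(nucleus_mask: np.ndarray,
                        pixel_size_um: float = 1.0) -> float:
    """Circularity 4*pi*A/P^2: 1 for a disk, smaller with elongation.

    Area is the pixel count at the 0.5 level; the perimeter is the
    sub-pixel marching-squares contour length at the same level
    (pixel-edge counting overestimates P and fails the disk identity).
    The input may be a binary mask or a sub-pixel coverage image in
    [0, 1]; coverage input recovers smooth boundaries (e.g. disks) to
    sub-percent accuracy, while hard binary masks carry the usual
    staircase overestimate of P for curved shapes.  A mask touching the
    image border triggers a warning since the closed contour is then
    unreliable.
    """
    img = np.asarray(nucleus_mask, dtype=float)
    mask = img >= 0.5
    if not mask.any():
        raise ValueError("empty mask")
    if (mask[0].any() or mask[-1].any()
            or mask[:, 0].any() or mask[:, -1].any()):
        warnings.warn("mask touches the image border; perimeter unreliable",
                      BorderTouchWarning, stacklevel=2)
    area = mask.sum() * pixel_size_um ** 2
    perim = 0.0
    for contour in find_contours(img, 0.5):
        perim += np.hypot(*np.diff(contour, axis=0).T).sum() * pixel_size_um
    if perim == 0:
        raise ValueError("mask has no contour")
    return float(4 * np.pi * area / perim ** 2)


def dna_thickness_actin_relation(masks: FrameMasks, dna_frame: np.ndarray,
                                 actin_frame: np.ndarray,
                                 geometry: ChannelGeometry,
                                 *, min_columns: int = 3):
    """Per-axial-column nucleus thickness, DNA density and cortex actin.

    For each column where the nucleus intersects the constriction:
    thickness = transverse nucleus extent (um), mean DNA intensity over the
    nucleus pixels, mean actin intensity over the cortex pixels of that
    column.  The regression (ordinary least squares, actin vs thickness) is
    restricted to columns thinner than the constriction width.

    Returns ``(table, slope, intercept)``.
    """
    nuc = masks.nucleus
    cortex = masks.cortex
    if nuc is None or cortex is None:
        raise ValueError("masks must include nucleus and cortex")
    px = geometry.pixel_size_um
    inside_cols = constriction_mask(geometry, nuc.shape)[0]
    dna = np.asarray(dna_frame, dtype=float)
    actin = np.asarray(actin_frame, dtype=float)
    rows = []
    for j in np.flatnonzero(nuc.any(axis=0) & inside_cols):
        col_n = nuc[:, j]
        thick = col_n.sum() * px
        rows.append({
            "x_um": pixel_centers(nuc.shape[1], px)[j],
            "dna_thickness_um": thick,
            "dna_mean_intensity": dna[col_n, j].mean(),
            "actin_mean_intensity": (actin[cortex[:, j], j].mean()
                                     if cortex[:, j].any() else np.nan),
        })
    if len(rows) < min_columns:
        raise InsufficientColumns(
            f"{len(rows)} qualifying columns, need {min_columns}")
    table = pd.DataFrame(rows)
    fit = table.dropna(subset=["actin_mean_intensity"])
    fit = fit[fit["dna_thickness_um"] < geometry.constriction_width_um]
    if len(fit) < min_columns:
        raise InsufficientColumns(
            f"{len(fit)} columns thinner than W, need {min_columns}")
    slope, intercept = np.polyfit(fit["dna_thickness_um"],
                                  fit["actin_mean_intensity"], 1)
    return table, float(slope), float(intercept)


def actin_around_bead(actin_frame: np.ndarray, bead_labeled: np.ndarray,
                      bead_id: int, cell_mask: np.ndarray,
                      *, annulus_px: int = 3) -> float:
    """Mean actin in an annulus around the bead / mean actin in the cell.

    The annulus is dilate(bead, annulus_px) minus the bead, clipped to the
    cell mask.  Raises BeadOutsideCell if the bead is not inside the cell.
    """
    bead_in_cell(bead_labeled, bead_id, cell_mask)
    bead = bead_labeled == bead_id
    se = np.ones((3, 3), dtype=bool)
    annulus = ndimage.binary_dilation(bead, structure=se,
                                      iterations=annulus_px) & ~bead
    annulus &= np.asarray(cell_mask, dtype=bool)
    if not annulus.any():
        raise NaNIntensity("empty bead annulus")
    frame = np.asarray(actin_frame, dtype=float)
    cell_mean = frame[np.asarray(cell_mask, dtype=bool)].mean()
    if cell_mean == 0:
        raise NaNIntensity("zero whole-cell mean intensity")
    return float(frame[annulus].mean() / cell_mean)
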