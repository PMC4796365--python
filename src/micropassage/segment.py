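"""Cell, nucleus, cortex and bead segmentation.

The measurement chain mirrors a classical fluorescence workflow: the actin
reporter channel yields the cell mask, the DNA channel the nucleus mask, and
the cell cortex is the morphological shell obtained by subtracting a
six-times-eroded from a once-dilated cell mask.  All operations are pure
functions of their inputs.

Morphology uses a 3x3 square (8-connected) structuring element by default,
one iteration per erosion/dilation count; connectivity is exposed because
tool lineages differ on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

from .errors import (BeadOutsideCell, EmptyPerinuclearRegion, NoCellDetected,
                     NoNucleusDetected)
from .microdevice import ChannelGeometry

__all__ = ["SegmentationParams", "FrameMasks", "segment_cell",
           "segment_nucleus", "cortex_mask", "perinuclear_cortex_mask",
           "segment_beads", "link_bead_labels"]


def _selem(connectivity: int = 8) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the threshold segmentation.

    smooth_sigma_px : Gaussian pre-smoothing width.
    fixed_threshold : absolute intensity threshold; None selects Otsu.
    min_area_px : smallest accepted component.
    min_contrast_snr : required foreground contrast, in units of the
        background standard deviation; rejects frames that contain only
        camera noise (where Otsu would still split the histogram).
    connectivity : structuring-element connectivity (4 or 8).
    """

    smooth_sigma_px: float = 1.0
    fixed_threshold: float | None = None
    refine_midpoint: bool = True
    min_area_px: int = 30
    min_contrast_snr: float = 3.0
    connectivity: int = 8


@dataclass
class FrameMasks:
    """Per-frame mask bundle; all masks share the frame shape."""

    cell: np.ndarray
    nucleus: np.ndarray | None = None
    cortex: np.ndarray | None = None
    perinuclear_cortex: np.ndarray | None = None
    beads: np.ndarray | None = None  # labeled int mask
    extras: dict = field(default_factory=dict)


def _threshold_mask(frame: np.ndarray, params: SegmentationParams) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if frame.max() == frame.min():
        raise NoCellDetected("constant image has no foreground")
    sm = gaussian(frame, sigma=params.smooth_sigma_px, preserve_range=True)
    thr = params.fixed_threshold
    if thr is None:
        thr = threshold_otsu(sm)
        if params.refine_midpoint:
            # place the threshold midway between the background and
            # foreground levels so blurred edges land at half-amplitude;
            # plain Otsu sits far below that when background dominates the
            # histogram, inflating thin objects by their blur skirt
            fg0 = sm > thr
            if fg0.any() and not fg0.all():
                # foreground level = median over the eroded foreground:
                # dropping the one-pixel boundary ring excludes the blur
                # skirt that otherwise drags the level (and the threshold)
                # down and inflates thin objects
                interior = ndimage.binary_erosion(fg0, structure=_selem(8))
                ref = sm[interior] if interior.any() else sm[fg0]
                thr = 0.5 * (np.median(sm[~fg0]) + np.median(ref))
    fg = sm > thr
    if not fg.any() or fg.all():
        raise NoCellDetected("thresholding produced no usable foreground")
    if params.min_contrast_snr > 0:
        bg = sm[~fg]
        bg_sd = bg.std()
        if bg_sd == 0:
            bg_sd = 1e-12
        if sm[fg].mean() - bg.mean() < params.min_contrast_snr * bg_sd:
            raise NoCellDetected("foreground indistinguishable from noise")
    return ndimage.binary_fill_holes(fg)


def _largest_component(mask: np.ndarray, min_area: int,
                       err: type[Exception]) -> np.ndarray:
    lab = label(mask, connectivity=2)
    if lab.max() == 0:
        raise err("no foreground component")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    best = int(sizes.argmax())
    if sizes[best] < min_area:
        raise err(f"largest component {sizes[best]} px < min area {min_area}")
    return lab == best


def segment_cell(actin_frame: np.ndarray,
                 params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Binary cell mask from the actin-reporter channel.

    Gaussian-smoothed frame, thresholded (Otsu unless a fixed threshold is
    configured), holes filled, largest connected component kept.

    Raises
    ------
    NoCellDetected
        If no component reaches ``min_area_px`` or the frame lacks contrast.
    """
    fg = _threshold_mask(actin_frame, params)
    return _largest_component(fg, params.min_area_px, NoCellDetected)


def segment_nucleus(dna_frame: np.ndarray, cell_mask: np.ndarray,
                    params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Binary nucleus mask from the DNA channel, constrained to the cell.

    The thresholded DNA foreground is intersected with the once-dilated cell
    mask before the largest component is kept, so the nucleus is always a
    subset of ``dilate(cell, 1)``.
    """
    try:
        fg = _threshold_mask(dna_frame, params)
    except NoCellDetected as exc:
        raise NoNucleusDetected(str(exc)) from None
    se = _selem(params.connectivity)
    fg &= ndimage.binary_dilation(cell_mask, structure=se)
    if not fg.any():
        raise NoNucleusDetected("no DNA signal inside the cell mask")
    return _largest_component(fg, params.min_area_px, NoNucleusDetected)


def cortex_mask(cell_mask: np.ndarray, *, dilate_iterations: int = 1,
                erode_iterations: int = 6, connectivity: int = 8) -> np.ndarray:
    """Cell-cortex shell: dilate(cell, 1) AND NOT erode(cell, 6).

    The shell always contains every boundary pixel of the cell mask; thin
    cell regions (narrower than twice the erosion depth) are entirely
    cortex.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    se = _selem(connectivity)
    dil = ndimage.binary_dilation(cell_mask, structure=se,
                                  iterations=dilate_iterations) \
        if dilate_iterations else cell_mask
    ero = ndimage.binary_erosion(cell_mask, structure=se,
                                 iterations=erode_iterations) \
        if erode_iterations else cell_mask
    return dil & ~ero


def perinuclear_cortex_mask(cortex: np.ndarray, nucleus_mask: np.ndarray,
                            *, margin_px: int = 1) -> np.ndarray:
    """Cortex restricted to the axial span of the nucleus (+/- a margin).

    "Around the nucleus" is interpreted along the migration (x) axis: cortex
    pixels in columns ``[nucleus back - margin, nucleus front + margin]``
    are kept.

    Raises
    ------
    EmptyPerinuclearRegion
        If the restriction is empty (nucleus outside the cortex span).
    """
    cortex = np.asarray(cortex, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not cortex.any() or not nucleus_mask.any():
        raise ValueError("cortex and nucleus masks must be nonempty")
    cols = np.flatnonzero(nucleus_mask.any(axis=0))
    lo = max(cols[0] - margin_px, 0)
    hi = min(cols[-1] + margin_px, cortex.shape[1] - 1)
    keep = np.zeros_like(cortex)
    keep[:, lo:hi + 1] = True
    out = cortex & keep
    if not out.any():
        raise EmptyPerinuclearRegion(
            "nucleus axial span does not intersect the cortex")
    return out


def device_interior_mask(geometry: ChannelGeometry,
                         image_shape: tuple[int, int]) -> np.ndarray:
    """Pixels inside the channel lumen (width ``d`` outside the
    constriction, ``W`` inside), centered vertically in the frame.

    Cells cannot occupy the device walls; clipping segmentation output to
    this region removes out-of-wall blur halos around bright structures.
    """
    ny, nx = image_shape
    px = geometry.pixel_size_um
    xs = (np.arange(nx) + 0.5) * px
    ys = (np.arange(ny) + 0.5) * px
    yc = ny * px / 2.0
    lo, hi = geometry.inside_interval_um
    w = np.where((xs >= lo) & (xs < hi), geometry.constriction_width_um,
                 geometry.channel_width_um)
    return np.abs(ys[:, None] - yc) <= w[None, :] / 2.0


def segment_beads(bead_frame: np.ndarray, known_radius_um: float,
                  geometry: ChannelGeometry, *,
                  threshold_rel: float = 0.5) -> np.ndarray:
    """Labeled bead mask from intensity peaks of known radius.

    Beads are internalized rigid spheres; their contours were traced by hand
    in the original workflow, replaced here by automated detection: local
    maxima of the smoothed bead channel seed circles of the configured
    radius.  An empty labeling is a valid result.
    """
    r_px = known_radius_um / geometry.pixel_size_um
    if r_px <= 1:
        raise ValueError("bead radius must exceed one pixel")
    frame = np.asarray(bead_frame, dtype=float)
    sm = gaussian(frame, sigma=1.0, preserve_range=True)
    lo, hi = float(sm.min()), float(sm.max())
    if hi <= lo:
        return np.zeros(frame.shape, dtype=int)
    thr = lo + threshold_rel * (hi - lo)
    fg = sm > thr
    lab = label(fg, connectivity=2)
    out = np.zeros(frame.shape, dtype=int)
    yy, xx = np.mgrid[0:frame.shape[0], 0:frame.shape[1]]
    next_id = 1
    for region in regionprops(lab, intensity_image=sm):
        if region.area < 0.3 * np.pi * r_px ** 2:
            continue
        cy, cx = region.centroid_weighted
        out[(yy - cy) ** 2 + (xx - cx) ** 2 <= r_px ** 2] = next_id
        next_id += 1
    return out


def link_bead_labels(prev_labeled: np.ndarray,
                     curr_labeled: np.ndarray) -> np.ndarray:
    """Relabel ``curr_labeled`` so bead ids follow nearest centroids of the
    previous frame; unmatched beads get fresh ids above the previous max."""
    if prev_labeled.max() == 0 or curr_labeled.max() == 0:
        return curr_labeled
    prev_c = {r.label: r.centroid for r in regionprops(prev_labeled)}
    out = np.zeros_like(curr_labeled)
    used = set()
    fresh = max(prev_c) + 1
    for r in regionprops(curr_labeled):
        cy, cx = r.centroid
        best, best_d = None, np.inf
        for pid, (py, px) in prev_c.items():
            d = (py - cy) ** 2 + (px - cx) ** 2
            if d < best_d and pid not in used:
                best, best_d = pid, d
        if best is None:
            best = fresh
            fresh += 1
        used.add(best)
        out[curr_labeled == r.label] = best
    return out


def bead_in_cell(bead_labeled: np.ndarray, bead_id: int,
                 cell_mask: np.ndarray, *, min_overlap: float = 0.5) -> None:
    """Raise ``BeadOutsideCell`` unless the bead overlaps the cell mask."""
    bead = bead_labeled == bead_id
    if not bead.any():
        raise BeadOutsideCell(f"bead id {bead_id} not present")
    frac = (bead & np.asarray(cell_mask, dtype=bool)).sum() / bead.sum()
    if frac < min_overlap:
        raise BeadOutsideCell(
            f"bead {bead_id} overlaps cell by only {frac:.0%}")
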