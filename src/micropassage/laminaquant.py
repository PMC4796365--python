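"""Nuclear-lamina ring morphometry on fixed-cell still images.

The ring-like lamina staining around a nucleus is reduced to a 360-bin
angular intensity profile along the nucleus boundary band; interruptions
(gaps) are contiguous circular runs of bins falling below a fraction of the
median ring intensity.  The rupture perimeter is the arc length of the gap
fraction of the nucleus boundary, and a rupture is tip-localized when its
largest gap centers within a cone around the leading nuclear pole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import NoRingSignal
from .microdevice import ChannelGeometry

__all__ = ["LaminaParams", "LaminaRingReport", "angular_intensity_profile",
           "detect_rupture", "tip_localization", "cohort_rupture_stats"]

_SE8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class LaminaParams:
    """Rupture-detection tunables.

    alpha : a bin is part of a gap when below ``alpha * median(profile)``.
    theta_min_deg : smallest angular span scored as a rupture.
    tip_cone_half_angle_deg : half-angle of the leading-pole cone.
    n_bins : angular resolution of the profile.
    """
    alpha: float = 0.5
    theta_min_deg: float = 15.0
    tip_cone_half_angle_deg: float = 45.0
    n_bins: int = 360


@dataclass
class LaminaRingReport:
    """Gap spans are half-open degree intervals (start, extent)."""
    angular_profile: np.ndarray
    gaps: list[tuple[float, float]]          # (start_deg, span_deg)
    ruptured: bool
    rupture_perimeter_um: float
    boundary_length_um: float
    tip_localized: bool | None = None
    meta: dict = field(default_factory=dict)

    @property
    def gap_spans_deg(self) -> list[float]:
        return [s for _, s in self.gaps]

    def largest_gap_center_deg(self) -> float | None:
        if not self.gaps:
            return None
        start, span = max(self.gaps, key=lambda g: g[1])
        return (start + span / 2.0) % 360.0


def angular_intensity_profile(lamina_frame: np.ndarray,
                              nucleus_mask: np.ndarray,
                              n_bins: int = 360) -> np.ndarray:
    """Mean lamina intensity in the nucleus boundary band, binned by angle.

    The band is dilate(nucleus, 1) minus erode(nucleus, 1); angles are
    measured about the nucleus centroid from the +x axis; empty bins are
    filled by circular linear interpolation from their neighbours.
    """
    mask = np.asarray(nucleus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    if (mask[0].any() or mask[-1].any()
            or mask[:, 0].any() or mask[:, -1].any()):
        raise ValueError("nucleus mask touches the image border")
    band = ndimage.binary_dilation(mask, structure=_SE8) \
        & ~ndimage.binary_erosion(mask, structure=_SE8)
    ys, xs = np.nonzero(band)
    cy, cx = ndimage.center_of_mass(mask)
    ang = np.degrees(np.arctan2(ys - cy, xs - cx)) % 360.0
    idx = np.minimum((ang / 360.0 * n_bins).astype(int), n_bins - 1)
    frame = np.asarray(lamina_frame, dtype=float)
    sums = np.bincount(idx, weights=frame[ys, xs], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    profile = np.full(n_bins, np.nan)
    nz = counts > 0
    profile[nz] = sums[nz] / counts[nz]
    if not nz.all():
        # circular linear interpolation across empty bins
        bins = np.arange(n_bins)
        good = np.flatnonzero(nz)
        profile = np.interp((bins - good[0]) % n_bins,
                            (good - good[0]) % n_bins,
                            profile[good], period=n_bins)
        profile = np.roll(profile, 0)
    return profile


def _circular_runs(below: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous circular runs of True; (start, length) in bins."""
    n = below.size
    if below.all():
        return [(0, n)]
    if not below.any():
        return []
    # rotate so position 0 is False, then find linear runs
    first_false = int(np.flatnonzero(~below)[0])
    rolled = np.roll(below, -first_false)
    runs = []
    start = None
    for i, b in enumerate(rolled):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append(((start + first_false) % n, i - start))
            start = None
    if start is not None:
        runs.append(((start + first_false) % n, rolled.size - start))
    return runs


def detect_rupture(profile: np.ndarray, boundary_length_um: float,
                   params: LaminaParams = LaminaParams()) -> LaminaRingReport:
    """Detect angular gaps in a ring profile.

    A gap is a maximal contiguous circular run of bins below
    ``alpha * median(profile)``; the ring is ruptured when the longest gap
    spans at least ``theta_min_deg``.  The rupture perimeter is
    ``sum(span)/360 * boundary_length``.

    Raises
    ------
    NoRingSignal
        When the profile median is indistinguishable from zero.
    """
    profile = np.asarray(profile, dtype=float)
    med = float(np.median(profile))
    if med <= 1e-9:
        raise NoRingSignal("ring median intensity is zero")
    deg_per_bin = 360.0 / profile.size
    below = profile < params.alpha * med
    gaps = [(start * deg_per_bin, length * deg_per_bin)
            for start, length in _circular_runs(below)
            if length * deg_per_bin >= params.theta_min_deg]
    span_total = sum(s for _, s in gaps)
    return LaminaRingReport(
        angular_profile=profile,
        gaps=gaps,
        ruptured=bool(gaps),
        rupture_perimeter_um=span_total / 360.0 * boundary_length_um,
        boundary_length_um=boundary_length_um,
    )


def leading_pole_angle(nucleus_mask: np.ndarray,
                       geometry: ChannelGeometry | None = None) -> float:
    """Angle (degrees, about the centroid) of the boundary point with the
    maximal axial coordinate along the migration direction."""
    mask = np.asarray(nucleus_mask, dtype=bool)
    direction = 1 if geometry is None else geometry.migration_direction
    boundary = mask & ~ndimage.binary_erosion(mask, structure=_SE8)
    ys, xs = np.nonzero(boundary)
    cy, cx = ndimage.center_of_mass(mask)
    k = int(np.argmax(xs * direction))
    return float(np.degrees(np.arctan2(ys[k] - cy, xs[k] - cx)) % 360.0)


def tip_localization(report: LaminaRingReport, nucleus_mask: np.ndarray,
                     geometry: ChannelGeometry | None = None,
                     params: LaminaParams = LaminaParams()) -> bool:
    """True iff the largest gap centers within the leading-pole cone."""
    center = report.largest_gap_center_deg()
    if center is None:
        raise ValueError("tip localization requires a ruptured report")
    pole = leading_pole_angle(nucleus_mask, geometry)
    dist = abs((center - pole + 180.0) % 360.0 - 180.0)
    return bool(dist <= params.tip_cone_half_angle_deg)


def cohort_rupture_stats(reports_by_condition: dict[str,
                                                    list[LaminaRingReport]]
                         ) -> dict:
    """Per-condition rupture fraction, perimeters and tip fraction."""
    out = {}
    for condition, reports in reports_by_condition.items():
        if not reports:
            raise ValueError(f"no reports for condition {condition!r}")
        n_rupt = sum(r.ruptured for r in reports)
        tip_known = [r for r in reports if r.ruptured
                     and r.tip_localized is not None]
        out[condition] = {
            "n": len(reports),
            "n_ruptured": n_rupt,
            "fraction_ruptured": n_rupt / len(reports),
            "rupture_perimeters_um": [r.rupture_perimeter_um
                                      for r in reports if r.ruptured],
            "fraction_tip_localized": (
                sum(r.tip_localized for r in tip_known) / len(tip_known)
                if tip_known else None),
        }
    return out
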