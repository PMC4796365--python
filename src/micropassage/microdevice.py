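"""Microdevice coordinate frame.

The migration channel is described in continuous micrometre coordinates.
The axial (migration) axis is the image x axis (array axis 1); pixel index
``i`` maps to the coordinate ``(i + 0.5) * pixel_size_um`` (pixel-center
convention), which makes the um <-> px mapping unambiguous.

The constriction occupies the half-open axial interval
``[center - L/2, center + L/2)``: a front exactly at the entry plane counts
as having entered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = ["ChannelGeometry", "classify_axial_position", "constriction_mask",
           "pixel_centers"]


@dataclass(frozen=True)
class ChannelGeometry:
    """Geometry of a straight migration channel with one constriction.

    Parameters
    ----------
    channel_width_um : float
        Width ``d`` of the channel (transverse, the image y axis).
    channel_height_um : float
        Device height. Carried as metadata only: all implemented metrics are
        2-D projections, but cross-sectional areas are width x height.
    constriction_width_um : float
        Constriction width ``W``.  ``W == d`` denotes a straight channel with
        no effective narrowing (used for free-migration controls).
    constriction_length_um : float
        Constriction length ``L`` along the migration axis.
    constriction_center_x_um : float
        Axial coordinate of the constriction midpoint.
    pixel_size_um : float
        Physical size of one pixel.
    migration_direction : int
        +1 if cells travel toward increasing x, -1 otherwise.  Flipping the
        sign swaps the before/after labels but leaves the inside interval
        unchanged.
    """

    channel_width_um: float
    channel_height_um: float
    constriction_width_um: float
    constriction_length_um: float
    constriction_center_x_um: float
    pixel_size_um: float
    migration_direction: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.constriction_width_um <= self.channel_width_um):
            raise ConfigError(
                f"require 0 < W <= d, got W={self.constriction_width_um}, "
                f"d={self.channel_width_um}")
        if self.constriction_length_um <= 0:
            raise ConfigError("constriction_length_um must be > 0")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        if self.migration_direction not in (-1, 1):
            raise ConfigError("migration_direction must be +1 or -1")

    @property
    def entrance_x_um(self) -> float:
        """Axial coordinate of the upstream constriction plane."""
        if self.migration_direction > 0:
            return self.constriction_center_x_um - self.constriction_length_um / 2
        return self.constriction_center_x_um + self.constriction_length_um / 2

    @property
    def exit_x_um(self) -> float:
        """Axial coordinate of the downstream constriction plane."""
        if self.migration_direction > 0:
            return self.constriction_center_x_um + self.constriction_length_um / 2
        return self.constriction_center_x_um - self.constriction_length_um / 2

    @property
    def inside_interval_um(self) -> tuple[float, float]:
        """The half-open inside interval ``[lo, hi)`` in +x order."""
        half = self.constriction_length_um / 2
        return (self.constriction_center_x_um - half,
                self.constriction_center_x_um + half)

    def is_straight(self) -> bool:
        """True when the constriction does not narrow the channel."""
        return self.constriction_width_um >= self.channel_width_um


def pixel_centers(n: int, pixel_size_um: float) -> np.ndarray:
    """Continuous coordinates of ``n`` pixel centers along one axis."""
    return (np.arange(n) + 0.5) * pixel_size_um


def classify_axial_position(geometry: ChannelGeometry, x: float) -> str:
    """Classify an axial coordinate as ``before``/``inside``/``after``.

    ``before`` is upstream relative to ``migration_direction``.  The inside
    interval is half-open: ``lo <= x < hi``.
    """
    if not math.isfinite(x):
        raise ValueError(f"x must be finite, got {x}")
    lo, hi = geometry.inside_interval_um
    if lo <= x < hi:
        return "inside"
    if x < lo:
        return "before" if geometry.migration_direction > 0 else "after"
    return "after" if geometry.migration_direction > 0 else "before"


def constriction_mask(geometry: ChannelGeometry,
                      image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the constriction region for an image of ``(ny, nx)``.

    A pixel is true iff its center's axial coordinate classifies as inside.
    If the constriction is narrower than one pixel the nearest single column
    is used so the mask is never empty.
    """
    ny, nx = image_shape
    xs = pixel_centers(nx, geometry.pixel_size_um)
    lo, hi = geometry.inside_interval_um
    if hi <= xs[0] - 0.5 * geometry.pixel_size_um or \
            lo >= xs[-1] + 0.5 * geometry.pixel_size_um:
        raise ConfigError("constriction lies outside the image axial extent")
    cols = (xs >= lo) & (xs < hi)
    if not cols.any():
        cols[np.argmin(np.abs(xs - geometry.constriction_center_x_um))] = True
    return np.broadcast_to(cols, (ny, nx)).copy()
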