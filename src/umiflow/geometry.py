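"""Vessel lumen geometry and the staggered computational grid.

Coordinate convention (fixed throughout the package): 0-based indices,
``x`` (columns) increases downstream, ``y`` (rows) increases with depth,
matching the ultrasound display where larger row index is deeper tissue.
Scalar quantities (pressure) live at cell centers; velocity components live
on cell faces (staggered arrangement, see :mod:`umiflow.solver`).

Walls are represented stair-step: each column of the grid carries the first
and last *fluid* row index.  ``wall_lower_y(x) < wall_upper_y(x)`` always
holds for these index bounds; note that in display terms the "lower"
(deeper) vessel wall is the ``wall_upper_y`` side.  All lengths are meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised for invalid lumen masks or grid requests."""


# Minimum lumen thickness, in grid cells, accepted by build_grid.
MIN_LUMEN_CELLS = 3

# Second-moment eccentricity below which a component has no dominant axis.
ECCENTRICITY_THRESHOLD = 0.9


@dataclass(frozen=True)
class VesselGeometry:
    """A binary lumen raster with physical pixel pitch.

    Parameters
    ----------
    lumen_mask:
        2D boolean raster, rows = depth (y), cols = axial (x); True = lumen.
        Must contain exactly one 4-connected foreground component spanning
        the full x extent.
    pixel_pitch_x, pixel_pitch_y:
        Pixel size in meters.
    rotation_angle:
        Rotation (radians) that was applied to align the vessel axis with
        the x-axis; 0 for natively horizontal masks.
    """

    lumen_mask: np.ndarray
    pixel_pitch_x: float
    pixel_pitch_y: float
    rotation_angle: float = 0.0

    def __post_init__(self) -> None:
        mask = np.asarray(self.lumen_mask, dtype=bool)
        object.__setattr__(self, "lumen_mask", mask)
        if mask.ndim != 2:
            raise GeometryError("lumen_mask must be 2D")
        if self.pixel_pitch_x <= 0 or self.pixel_pitch_y <= 0:
            raise GeometryError("pixel pitches must be positive")
        if not mask.any():
            raise GeometryError("lumen_mask has no foreground")
        labels, n = ndimage.label(mask, structure=_FOUR_CONNECTED)
        if n != 1:
            raise GeometryError(f"lumen_mask must be a single 4-connected component, found {n}")
        if not mask.any(axis=0).all():
            raise GeometryError("lumen must span the full x extent of the mask")


_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass(frozen=True)
class Grid2D:
    """Orthogonal equidistant staggered grid over a stair-step channel.

    ``wall_lower_y[j]`` / ``wall_upper_y[j]`` are the first / last fluid row
    of column ``j`` (index bounds, ``lower < upper``); the fluid band of a
    column is contiguous.  ``dx``/``dy`` in meters.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    wall_lower_y: np.ndarray
    wall_upper_y: np.ndarray
    fluid: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        lo = np.asarray(self.wall_lower_y, dtype=int)
        hi = np.asarray(self.wall_upper_y, dtype=int)
        object.__setattr__(self, "wall_lower_y", lo)
        object.__setattr__(self, "wall_upper_y", hi)
        if self.nx < 4 or self.ny < 4:
            raise GeometryError("grid must be at least 4x4")
        if self.dx <= 0 or self.dy <= 0:
            raise GeometryError("grid spacing must be positive")
        if lo.shape != (self.nx,) or hi.shape != (self.nx,):
            raise GeometryError("wall arrays must have shape (nx,)")
        if not (lo < hi).all():
            raise GeometryError("wall_lower_y must be strictly below wall_upper_y")
        if lo.min() < 0 or hi.max() > self.ny - 1:
            raise GeometryError("wall rows outside grid")
        fluid = np.zeros((self.ny, self.nx), dtype=bool)
        rows = np.arange(self.ny)[:, None]
        fluid[(rows >= lo[None, :]) & (rows <= hi[None, :])] = True
        object.__setattr__(self, "fluid", fluid)

    @property
    def n_fluid(self) -> int:
        return int(self.fluid.sum())

    def column_height(self, j: int) -> float:
        """Lumen height (m) of column ``j``, wall face to wall face."""
        return (self.wall_upper_y[j] - self.wall_lower_y[j] + 1) * self.dy


def build_grid(geometry: VesselGeometry, dx: float, dy: float) -> Grid2D:
    """Build the staggered grid tracing the lumen mask boundary per column.

    The grid covers the mask extent with spacing ``dx`` x ``dy`` (meters);
    a grid cell is fluid when the mask pixel under its center is foreground.
    Rejects lumina that become disconnected or thinner than
    ``MIN_LUMEN_CELLS`` cells anywhere on the grid.
    """
    if dx <= 0 or dy <= 0:
        raise GeometryError("dx, dy must be positive")
    mask = geometry.lumen_mask
    h_px, w_px = mask.shape
    width = w_px * geometry.pixel_pitch_x
    height = h_px * geometry.pixel_pitch_y
    nx = max(int(round(width / dx)), 1)
    ny = max(int(round(height / dy)), 1)
    if nx < 4 or ny < 4:
        raise GeometryError("requested spacing yields a grid smaller than 4x4")

    jc = np.minimum(((np.arange(nx) + 0.5) * dx / geometry.pixel_pitch_x).astype(int), w_px - 1)
    ic = np.minimum(((np.arange(ny) + 0.5) * dy / geometry.pixel_pitch_y).astype(int), h_px - 1)
    fluid = mask[np.ix_(ic, jc)]

    lo = np.empty(nx, dtype=int)
    hi = np.empty(nx, dtype=int)
    for j in range(nx):
        rows = np.flatnonzero(fluid[:, j])
        if rows.size == 0:
            raise GeometryError(f"column {j} has no fluid cells (disconnected lumen)")
        if not np.array_equal(rows, np.arange(rows[0], rows[-1] + 1)):
            raise GeometryError(f"column {j} has a non-contiguous fluid band")
        if rows.size < MIN_LUMEN_CELLS:
            raise GeometryError(
                f"lumen thinner than {MIN_LUMEN_CELLS} cells at column {j}"
            )
        lo[j], hi[j] = rows[0], rows[-1]
    # Columns must overlap so the channel is one 4-connected band.
    if ((lo[1:] > hi[:-1]) | (hi[1:] < lo[:-1])).any():
        raise GeometryError("adjacent columns do not overlap (disconnected lumen)")
    return Grid2D(nx=nx, ny=ny, dx=dx, dy=dy, wall_lower_y=lo, wall_upper_y=hi)


def _principal_axis(mask: np.ndarray, pitch_x: float, pitch_y: float) -> tuple[float, float]:
    """Angle (rad, from +x axis, y measured downward) and eccentricity of the
    dominant foreground component, via physical-coordinate second moments."""
    rows, cols = np.nonzero(mask)
    x = cols * pitch_x
    y = rows * pitch_y
    x = x - x.mean()
    y = y - y.mean()
    mxx = np.mean(x * x)
    myy = np.mean(y * y)
    mxy = np.mean(x * y)
    theta = 0.5 * np.arctan2(2.0 * mxy, mxx - myy)
    common = np.sqrt(((mxx - myy) / 2) ** 2 + mxy**2)
    lam1 = (mxx + myy) / 2 + common
    lam2 = (mxx + myy) / 2 - common
    ecc = np.sqrt(1.0 - lam2 / lam1) if lam1 > 0 else 0.0
    return float(theta), float(ecc)


def rotate_and_extract(
    raw_mask: np.ndarray, pitch_x: float, pitch_y: float
) -> VesselGeometry:
    """Rotate a raw lumen mask so the vessel axis is horizontal.

    The principal axis of the dominant 4-connected component is found from
    image second moments; the mask is rotated by the negative of that angle
    and cropped to the component's bounding box.  Components with
    eccentricity below ``ECCENTRICITY_THRESHOLD`` (no dominant axis, e.g. a
    circular blob) are rejected.
    """
    mask = np.asarray(raw_mask, dtype=bool)
    if not mask.any():
        raise GeometryError("raw_mask has no foreground")
    labels, n = ndimage.label(mask, structure=_FOUR_CONNECTED)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    if pitch_x != pitch_y:
        # Resample to square pixels so rotation in pixel space is valid.
        pitch = min(pitch_x, pitch_y)
        zoom = (pitch_y / pitch, pitch_x / pitch)
        mask = ndimage.zoom(mask.astype(float), zoom, order=1) > 0.5
        pitch_x = pitch_y = pitch
    theta, ecc = _principal_axis(mask, pitch_x, pitch_y)
    if ecc < ECCENTRICITY_THRESHOLD:
        raise GeometryError(
            f"no dominant axis (eccentricity {ecc:.3f} < {ECCENTRICITY_THRESHOLD})"
        )
    # Array row index grows downward, so a +theta axis in (x, y-down)
    # coordinates is rotated back to horizontal by ndimage's CCW angle +theta
    # measured in standard orientation == -theta in display orientation.
    rotated = ndimage.rotate(mask.astype(float), np.degrees(theta), reshape=True, order=1) > 0.5
    if not rotated.any():
        raise GeometryError("rotation produced an empty mask")
    rows = np.flatnonzero(rotated.any(axis=1))
    cols = np.flatnonzero(rotated.any(axis=0))
    cropped = rotated[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    cropped = _fill_columns(cropped)
    return VesselGeometry(
        lumen_mask=cropped,
        pixel_pitch_x=pitch_x,
        pixel_pitch_y=pitch_y,
        rotation_angle=-theta,
    )


def _fill_columns(mask: np.ndarray) -> np.ndarray:
    """Fill per-column gaps introduced by rasterized rotation and drop
    columns with no foreground at the ends (keeps the mask a single band)."""
    keep = mask.any(axis=0)
    first, last = np.flatnonzero(keep)[[0, -1]]
    mask = mask[:, first : last + 1].copy()
    for j in range(mask.shape[1]):
        rows = np.flatnonzero(mask[:, j])
        if rows.size:
            mask[rows[0] : rows[-1] + 1, j] = True
        else:
            # interior empty column: interpolate from neighbors
            mask[:, j] = mask[:, j - 1]
    return mask
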