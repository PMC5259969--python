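"""Region-based shape descriptors for a binary region of interest.

Seven size-and-shape descriptors are computed from a single 8-connected
foreground component: area, convex area, major/minor axis length of the
moment-equivalent ellipse, perimeter, equivalent diameter and extent.
They are the feature vector that downstream classifiers consume; their
order is frozen (see :data:`FEATURE_NAMES`) so trained networks stay
portable across runs.

Conventions
-----------
* Coordinates are 0-based ``(row, col)``; measurements are in pixel units
  on pixel-center coordinates.
* ``convex_area`` counts pixels whose centers lie inside or on the convex
  hull of the foreground pixel centers (hull-covered pixel counting, not
  the real polygon area).
* Axis lengths come from the normalized second central moments with the
  +1/12 per-pixel variance correction, so a single pixel has the axes of
  a unit square's moment ellipse (2*sqrt(2/3) ~ 1.1547) instead of zero.
* ``perimeter`` is the length of the traced 8-connected outer boundary
  polygon through boundary pixel centers: axis steps contribute 1,
  diagonal steps sqrt(2); an isolated pixel is 4 by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "FEATURE_NAMES",
    "RegionOfInterest",
    "FeatureVector",
    "area",
    "convex_area",
    "axis_lengths",
    "perimeter",
    "equivalent_diameter",
    "extent",
    "extract_features",
]

#: Frozen descriptor order used in vectors and CSV columns.
FEATURE_NAMES = (
    "area",
    "convex_area",
    "major_axis_length",
    "minor_axis_length",
    "perimeter",
    "equivalent_diameter",
    "extent",
)

_STRUCT8 = np.ones((3, 3), dtype=bool)


class EmptyRegionError(ValueError):
    """Raised when a descriptor is requested for an empty mask."""


@dataclass(frozen=True)
class RegionOfInterest:
    """A validated single-component binary region.

    Attributes
    ----------
    mask : (H, W) bool array, True = foreground.
    pixels : (n, 2) int array of 0-based (row, col) foreground coordinates.
    bbox : (min_row, min_col, max_row, max_col), inclusive and tight.
    """

    mask: np.ndarray
    pixels: np.ndarray
    bbox: tuple[int, int, int, int]

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "RegionOfInterest":
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not mask.any():
            raise EmptyRegionError("region of interest is empty")
        _, n_comp = ndimage.label(mask, structure=_STRUCT8)
        if n_comp != 1:
            raise ValueError(
                f"region of interest must be one 8-connected component, got {n_comp}"
            )
        rows, cols = np.nonzero(mask)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))
        return cls(mask=mask, pixels=np.column_stack([rows, cols]), bbox=bbox)

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class FeatureVector:
    """The seven descriptors of one region, in the frozen order."""

    area: float
    convex_area: float
    major_axis_length: float
    minor_axis_length: float
    perimeter: float
    equivalent_diameter: float
    extent: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_array())

    def validate(self) -> None:
        v = self.as_array()
        if not np.all(np.isfinite(v)) or not np.all(v > 0):
            raise ValueError("all descriptors must be finite and positive")
        if self.convex_area < self.area - 1e-9:
            raise ValueError("convex_area must be >= area")
        if self.minor_axis_length > self.major_axis_length + 1e-9:
            raise ValueError("major axis must be >= minor axis")
        if not (0 < self.extent <= 1 + 1e-12):
            raise ValueError("extent must lie in (0, 1]")
        expected = math.sqrt(4.0 * self.area / math.pi)
        if abs(self.equivalent_diameter - expected) > 1e-9:
            raise ValueError("equivalent_diameter inconsistent with area")


def area(roi: RegionOfInterest) -> int:
    """Foreground pixel count."""
    return int(roi.n_pixels)


def _collinear_convex_area(pts: np.ndarray) -> int:
    # Degenerate hull: pixels on one lattice line. The hull is the segment
    # between the two extreme pixels; count lattice centers on it.
    d = pts.max(axis=0) - pts.min(axis=0)
    return int(max(d[0], d[1])) + 1


def convex_area(roi: RegionOfInterest) -> int:
    """Pixels whose centers lie inside or on the hull of the foreground centers."""
    pts = roi.pixels.astype(float)
    if len(pts) <= 2:
        return _collinear_convex_area(roi.pixels)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return _collinear_convex_area(roi.pixels)
    r0, c0, r1, c1 = roi.bbox
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    cand = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    # hull.equations: A @ x + b <= 0 inside; tolerance admits on-boundary centers
    inside = (cand @ hull.equations[:, :2].T + hull.equations[:, 2] <= 1e-9).all(axis=1)
    return int(inside.sum())


def axis_lengths(roi: RegionOfInterest) -> tuple[float, float]:
    """Major/minor axes of the moment-equivalent ellipse.

    Uses normalized second central moments of the pixel-center cloud plus
    the 1/12 variance of a unit pixel:

        u_xx = sum((x - xbar)^2)/n + 1/12   (x = columns; u_yy likewise)
        major = 2*sqrt(2)*sqrt(u_xx + u_yy + sqrt((u_xx - u_yy)^2 + 4 u_xy^2))

    and the minor axis with the inner minus sign.
    """
    y = roi.pixels[:, 0].astype(float)
    x = roi.pixels[:, 1].astype(float)
    xc = x - x.mean()
    yc = y - y.mean()
    n = len(x)
    uxx = float(xc @ xc) / n + 1.0 / 12.0
    uyy = float(yc @ yc) / n + 1.0 / 12.0
    uxy = float(xc @ yc) / n
    common = math.sqrt((uxx - uyy) ** 2 + 4.0 * uxy**2)
    major = 2.0 * math.sqrt(2.0) * math.sqrt(uxx + uyy + common)
    minor = 2.0 * math.sqrt(2.0) * math.sqrt(max(uxx + uyy - common, 0.0))
    return major, minor


# Moore neighborhood in clockwise order starting from west.
_RING = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_RING_INDEX = {d: i for i, d in enumerate(_RING)}


def _trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbor trace of the outer boundary, clockwise.

    Returns the closed boundary cycle of pixel centers (start of the cycle
    not repeated at the end). The walk is deterministic given the state
    (current pixel, backtrack direction), so the first repeated state
    delimits the boundary cycle exactly; this terminates correctly on
    one-pixel-wide spurs where the classic stopping rules can stall.
    """
    h, w = mask.shape
    rows, cols = np.nonzero(mask)
    # first foreground pixel in raster order: its west neighbor is background
    i0 = np.lexsort((cols, rows))[0]
    start = (int(rows[i0]), int(cols[i0]))

    def fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    if not any(fg((start[0] + dr, start[1] + dc)) for dr, dc in _RING):
        return [start]

    cur = start
    back = (0, -1)  # came from the west
    chain: list[tuple[int, int]] = []
    seen: dict[tuple[tuple[int, int], tuple[int, int]], int] = {}
    max_steps = 8 * (len(rows) + 4)
    for _ in range(max_steps):
        state = (cur, back)
        if state in seen:
            return chain[seen[state]:]
        seen[state] = len(chain)
        chain.append(cur)
        k = _RING_INDEX[back]
        for step in range(1, 9):
            d = _RING[(k + step) % 8]
            p = (cur[0] + d[0], cur[1] + d[1])
            if fg(p):
                prev = _RING[(k + step - 1) % 8]
                # backtrack for the next pixel: direction from it to the
                # last background cell scanned before it was found
                bg_cell = (cur[0] + prev[0], cur[1] + prev[1])
                back = (bg_cell[0] - p[0], bg_cell[1] - p[1])
                cur = p
                break
    raise RuntimeError("boundary trace failed to terminate")  # pragma: no cover


def perimeter(roi: RegionOfInterest) -> float:
    """Chain length of the traced outer boundary polygon.

    Axis steps contribute 1, diagonal steps sqrt(2). A single isolated
    pixel has no chain and is assigned 4 (its square outline) by
    convention. The chain estimator carries the well-known ~5% positive
    bias against the true perimeter of smooth shapes; see the disc tests.
    """
    if roi.n_pixels == 1:
        return 4.0
    chain = _trace_boundary(roi.mask)
    if len(chain) == 1:
        return 4.0
    pts = np.array(chain + [chain[0]], dtype=float)
    steps = np.diff(pts, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def equivalent_diameter(roi: RegionOfInterest) -> float:
    """Diameter of the circle with the region's area: sqrt(4*area/pi)."""
    return math.sqrt(4.0 * roi.n_pixels / math.pi)


def extent(roi: RegionOfInterest) -> float:
    """Area divided by the area of the tight axis-aligned bounding box."""
    r0, c0, r1, c1 = roi.bbox
    return roi.n_pixels / float((r1 - r0 + 1) * (c1 - c0 + 1))


def extract_features(roi: RegionOfInterest | np.ndarray) -> FeatureVector:
    """Assemble the seven descriptors in the frozen order."""
    if not isinstance(roi, RegionOfInterest):
        roi = RegionOfInterest.from_mask(roi)
    major, minor = axis_lengths(roi)
    fv = FeatureVector(
        area=float(area(roi)),
        convex_area=float(convex_area(roi)),
        major_axis_length=major,
        minor_axis_length=minor,
        perimeter=perimeter(roi),
        equivalent_diameter=equivalent_diameter(roi),
        extent=extent(roi),
    )
    fv.validate()
    return fv
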