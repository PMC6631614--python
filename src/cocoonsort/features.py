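"""Shape descriptors of a single segmented cocoon silhouette.

All descriptors operate on a :class:`RegionShape` — the filled pixel set of
one connected component plus its boundary pixels (pixels with at least one
4-neighbour outside the region).  Conventions, pinned because they matter for
reproducibility:

* pixel (r, c) occupies the unit square [r-1/2, r+1/2) x [c-1/2, c+1/2);
  the minimum-area rectangle is computed over the four corners of each
  boundary pixel (so the rectangle always contains the whole region and
  rectangularity stays in (0, 1]), while the convex hull AREA is the convex
  image pixel count — pixel centers covered by the hull polygon of the
  boundary-pixel centers — so solidity is a pixel-count ratio in (0, 1]
  that reaches ~1 for convex digital shapes;
* perimeter is, by default, the boundary pixel COUNT (the definition used by
  the sorter this package models); a Euclidean contour-length alternative
  (``method="euclidean"``) is available for sensitivity checks — note the two
  differ systematically (a digital disc has ~4*sqrt(2)*r boundary pixels vs
  contour length 2*pi*r, so circularity A/P^2 tends to pi/32, not 1/(4*pi));
* the moment ellipse uses the region's central second moments with the +1/12
  per-pixel correction, so a single pixel has nonzero extent; axis lengths
  are 4*sqrt(eigenvalue), the ellipse with the same normalized second central
  moments as the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon
from skimage.measure import perimeter_crofton as _sk_crofton_perimeter

from .errors import DegenerateRegionError

#: column order of the feature CSV emitted by this module
FEATURE_COLUMNS = ("A", "P", "lambda1", "lambda2", "axis_ratio", "E", "C", "R", "S", "AC")


@dataclass
class RegionShape:
    """One 8-connected component: filled pixels and boundary pixels."""

    filled: np.ndarray  # (N, 2) int array of (row, col)
    boundary: np.ndarray  # (M, 2) int array, subset of filled

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "RegionShape":
        """Build a region from a boolean mask containing one component."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise DegenerateRegionError("empty mask has no region")
        filled = np.argwhere(mask)
        pad = np.pad(mask, 1)
        interior = (
            pad[:-2, 1:-1] & pad[2:, 1:-1] & pad[1:-1, :-2] & pad[1:-1, 2:]
        )
        boundary = np.argwhere(mask & ~interior)
        return cls(filled=filled, boundary=boundary)

    def to_mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        if shape is None:
            shape = tuple(self.filled.max(axis=0) + 1)
        mask = np.zeros(shape, dtype=bool)
        mask[self.filled[:, 0], self.filled[:, 1]] = True
        return mask


@dataclass(frozen=True)
class ShapeFeatureVector:
    """The descriptor suite of one silhouette (see module docstring)."""

    A: float  # region area, px
    P: float  # region perimeter, px
    lambda1: float  # moment-ellipse major axis length, px
    lambda2: float  # moment-ellipse minor axis length, px
    axis_ratio: float  # lambda1 / lambda2
    E: float  # aspect ratio of the minimum bounding rectangle, Lb/Wb
    C: float  # circularity A / P^2
    R: float  # rectangularity A / Ar
    S: float  # solidity A / H
    AC: float  # convexity: hull perimeter / region perimeter

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_COLUMNS], dtype=float)


def area(region: RegionShape) -> int:
    """Number of pixels in the region."""
    n = len(region.filled)
    if n == 0:
        raise DegenerateRegionError("empty region has no area")
    return n


def perimeter(region: RegionShape, method: str = "pixel_count") -> float:
    """Region perimeter.

    ``pixel_count`` (default): number of boundary pixels.  ``euclidean``:
    contour length estimated from the region mask.
    """
    if len(region.filled) == 0:
        raise DegenerateRegionError("empty region has no perimeter")
    if method == "pixel_count":
        return float(len(region.boundary))
    if method == "euclidean":
        return float(_sk_crofton_perimeter(region.to_mask(), directions=4))
    raise ValueError(f"unknown perimeter method {method!r}")


def moment_ellipse(region: RegionShape) -> tuple[float, float]:
    """Axis lengths (major, minor) of the moment-equivalent ellipse.

    Eigen-decomposition of the central second-moment matrix with the +1/12
    per-pixel variance correction; axis length = 4*sqrt(eigenvalue).
    """
    pts = region.filled.astype(float)
    if len(pts) < 2:
        raise DegenerateRegionError("moment ellipse needs >= 2 pixels")
    cov = np.cov(pts, rowvar=False, bias=True) + np.eye(2) / 12.0
    evals = np.linalg.eigvalsh(cov)
    lam2, lam1 = 4.0 * np.sqrt(evals)
    if lam2 <= 0 or not np.isfinite(lam2):
        raise DegenerateRegionError("region has zero spatial variance")
    return float(lam1), float(lam2)


def _boundary_corner_points(region: RegionShape) -> np.ndarray:
    """Corners of the unit squares of all boundary pixels (pixel convention)."""
    b = region.boundary.astype(float)
    if len(b) == 0:
        raise DegenerateRegionError("region has no boundary pixels")
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    return (b[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


def _corner_hull_polygon(region: RegionShape) -> Polygon:
    hull = MultiPoint(_boundary_corner_points(region)).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateRegionError("degenerate (collinear) region has no hull polygon")
    return hull


def convex_hull_polygon(region: RegionShape) -> Polygon:
    """Convex hull polygon over boundary-pixel centers.

    May be degenerate (a segment) for 1-px-wide regions; those are rejected.
    """
    hull = MultiPoint(region.boundary.astype(float)).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateRegionError("degenerate (collinear) region has no hull polygon")
    return hull


def min_bounding_rectangle(region: RegionShape) -> tuple[float, float, float]:
    """Minimum-area rotated bounding rectangle: (Lb, Wb, Ar), Lb >= Wb."""
    rect = shapely.minimum_rotated_rectangle(_corner_hull_polygon(region))
    if not isinstance(rect, Polygon):
        raise DegenerateRegionError("degenerate region has no bounding rectangle")
    coords = np.asarray(rect.exterior.coords)
    s1 = float(np.linalg.norm(coords[1] - coords[0]))
    s2 = float(np.linalg.norm(coords[2] - coords[1]))
    lb, wb = max(s1, s2), min(s1, s2)
    if wb <= 0:
        raise DegenerateRegionError("degenerate region: zero-width bounding rectangle")
    return lb, wb, lb * wb


def convex_hull_geometry(region: RegionShape) -> tuple[float, float]:
    """Convex hull area H (convex-image pixel count) and hull perimeter.

    H counts the pixel centers covered by the hull polygon of the
    boundary-pixel centers — the number of pixels in the convex image — so
    H >= A for every region with equality for digitally convex ones.  The
    perimeter is the Euclidean length of that hull polygon.
    """
    hull = convex_hull_polygon(region)
    rmin, cmin = region.filled.min(axis=0)
    rmax, cmax = region.filled.max(axis=0)
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    pts = shapely.points(np.column_stack([rr.ravel(), cc.ravel()]))
    covered = shapely.covers(hull, pts)
    return float(np.count_nonzero(covered)), float(hull.length)


def compute_shape_features(
    region: RegionShape, perimeter_method: str = "pixel_count"
) -> ShapeFeatureVector:
    """Assemble the full descriptor vector for one accepted silhouette."""
    a = float(area(region))
    p = perimeter(region, method=perimeter_method)
    lam1, lam2 = moment_ellipse(region)
    lb, wb, ar = min_bounding_rectangle(region)
    h, p_hull = convex_hull_geometry(region)
    return ShapeFeatureVector(
        A=a,
        P=p,
        lambda1=lam1,
        lambda2=lam2,
        axis_ratio=lam1 / lam2,
        E=lb / wb,
        C=a / p**2,
        R=a / ar,
        S=a / h,
        AC=p_hull / p,
    )
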