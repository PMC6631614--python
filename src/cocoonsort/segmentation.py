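"""Backlit-image segmentation: Otsu threshold, components, single-cocoon gate.

The camera images a dark shell against a bright backlight, so the histogram
is essentially bimodal and a global Otsu threshold separates shell from
backlight (floss strands, being closer to the backlight intensity, fall on
the background side).  The FOREGROUND is the dark side of the threshold
(intensity <= t).

The single-cocoon gate reproduces the sorter's feed check: at the reference
camera standoff a single cocoon silhouette covers 500-550 px, so a total
foreground area above the band means more than one cocoon entered the imaging
station (reject and eject), and an area below it means no cocoon is present.
The band is camera-geometry-specific; :func:`calibrate_area_gate` re-derives
it from a reference batch of known singletons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DataError
from .features import RegionShape

#: single-cocoon area band (px) at the reference 18 cm camera standoff
DEFAULT_AREA_BOUNDS = (500, 550)
#: components smaller than this are discarded as residual floss specks
DEFAULT_MIN_COMPONENT_SIZE = 10


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's global threshold for an 8-bit image.

    Returns the level t maximizing the between-class variance of the split
    {intensity <= t} vs {intensity > t}; ties break toward the smaller t.
    Raises :class:`DataError` on a constant image (no valid split).
    """
    img = np.asarray(img)
    if img.size == 0:
        raise DataError("cannot threshold an empty image")
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DataError("constant image: Otsu threshold undefined")
    prob = hist / hist.sum()
    levels = np.arange(256, dtype=float)
    omega = np.cumsum(prob)  # class-0 mass for t = 0..255
    mu = np.cumsum(prob * levels)
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    # t = 255 leaves class 1 empty and is never a valid split
    return int(np.argmax(sigma_b[:255]))


def binarize(img: np.ndarray, t: int) -> np.ndarray:
    """Boolean foreground mask: dark pixels (intensity <= t) are foreground."""
    return np.asarray(img) <= t


def extract_components(
    mask: np.ndarray, min_size: int = DEFAULT_MIN_COMPONENT_SIZE
) -> list[RegionShape]:
    """8-connected components of a mask, sorted by area descending.

    Components smaller than ``min_size`` pixels (floss specks) are dropped.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    regions = []
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() < min_size:
            continue
        regions.append(RegionShape.from_mask(comp))
    regions.sort(key=lambda r: len(r.filled), reverse=True)
    return regions


@dataclass(frozen=True)
class GateVerdict:
    """Outcome of the single-cocoon feed check."""

    verdict: str  # accept | reject_multiple | reject_empty
    total_area: int
    component_count: int
    cocoon: RegionShape | None = None  # largest component when accepted


def single_cocoon_gate(
    components: list[RegionShape],
    area_bounds: tuple[int, int] = DEFAULT_AREA_BOUNDS,
    mode: str = "total",
) -> GateVerdict:
    """Decide accept / reject_multiple / reject_empty from component areas.

    ``mode="total"`` (default) gates on the total foreground area across
    components; ``mode="largest"`` gates on the largest component only.
    """
    lo, hi = area_bounds
    if not lo < hi:
        raise DataError(f"area bounds must satisfy lo < hi, got ({lo}, {hi})")
    if mode not in ("total", "largest"):
        raise DataError(f"unknown gate mode {mode!r}")
    areas = [len(r.filled) for r in components]
    total = sum(areas)
    gated = total if mode == "total" else (max(areas) if areas else 0)
    if gated > hi:
        verdict = "reject_multiple"
    elif gated < lo:
        verdict = "reject_empty"
    else:
        verdict = "accept"
    return GateVerdict(
        verdict=verdict,
        total_area=total,
        component_count=len(components),
        cocoon=components[0] if verdict == "accept" else None,
    )


def calibrate_area_gate(singleton_areas: np.ndarray, k: float = 3.0) -> tuple[int, int]:
    """Area band (mean ± k·sd) from a reference batch of known singletons."""
    a = np.asarray(singleton_areas, dtype=float)
    if a.size < 2:
        raise DataError("gate calibration needs >= 2 singleton areas")
    lo = int(np.floor(a.mean() - k * a.std()))
    hi = int(np.ceil(a.mean() + k * a.std()))
    if not lo < hi:
        raise DataError("calibration produced an empty area band")
    return max(lo, 1), hi


def segment_image(
    img: np.ndarray,
    area_bounds: tuple[int, int] = DEFAULT_AREA_BOUNDS,
    min_size: int = DEFAULT_MIN_COMPONENT_SIZE,
    gate_mode: str = "total",
) -> GateVerdict:
    """Full segmentation of one image: threshold, components, gate."""
    t = otsu_threshold(img)
    components = extract_components(binarize(img, t), min_size=min_size)
    return single_cocoon_gate(components, area_bounds=area_bounds, mode=gate_mode)
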