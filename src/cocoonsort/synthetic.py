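"""Synthetic cocoon specimens: backlit silhouette images, weights, labels.

No public cocoon image/weight dataset exists, so every downstream stage is
exercised on generated specimens that reproduce the statistical structure the
classifier relies on:

* gender- and breed-conditional weight distributions over the documented
  ranges (Pure Mysore male 0.8-1.1 g, female 1.2-1.4 g; CSR2 male 0.7-1.4 g,
  female 1.5-2.0 g), quantized to the 0.01 g load-sensor resolution;
* dark ovoid silhouettes on a bright backlight, with females rendered
  slightly larger than males (females are bulkier);
* low-contrast fibrous floss strands whose intensity lies strictly between
  shell and backlight, so a correct global threshold assigns them to the
  background;
* additive sensor noise.

The silhouette model is a superellipse with an optional cosine waist pinch
(cocoons range from ovoid to peanut-shaped); the unpinched case has a
closed-form area, used as an oracle by the test suite.  All randomness flows
from explicit seeds / generators; there is no global random state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.special import gamma

from .errors import ConfigError, DataError

MALE = 1
FEMALE = 0

# Backlit 8-bit intensity convention: bright background, dark rigid shell.
BACKGROUND_INTENSITY = 230
SHELL_INTENSITY = 25
# Floss strands sit between shell and backlight but closer to the backlight;
# at this level a bimodal global threshold reliably assigns them to background.
FIBER_INTENSITY = 160

# Base silhouette geometry at unit size scale: semi-axes 16 x 10 px with
# superellipse exponent 2.5 -> ~541 px area, matching the documented
# 500-550 px single-cocoon area band at the reference camera standoff.
BASE_SCALE = 10.0
BASE_ELONGATION = 1.6
SUPERELLIPSE_EXPONENT = 2.5

WEIGHT_RESOLUTION = 0.01  # grams, load-sensor resolution


@dataclass(frozen=True)
class BreedSpec:
    """Breed-level generative parameters.

    Weight ranges are in grams; size scales are dimensionless multipliers on
    the base silhouette scale.  The female scale must exceed the male scale
    (female cocoons have the larger circumference).
    """

    breed_name: str
    male_weight_range: tuple[float, float]
    female_weight_range: tuple[float, float]
    male_size_scale: float = 0.975
    female_size_scale: float = 0.995
    size_noise_sd: float = 0.005

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("male_weight_range", self.male_weight_range),
            ("female_weight_range", self.female_weight_range),
        ):
            if not (0 < lo <= hi):
                raise ConfigError(f"{name}: need 0 < lo <= hi, got ({lo}, {hi})")
        if not self.female_size_scale > self.male_size_scale > 0:
            raise ConfigError(
                "size scales must satisfy female > male > 0, got "
                f"{self.female_size_scale} vs {self.male_size_scale}"
            )
        if self.size_noise_sd < 0:
            raise ConfigError("size_noise_sd must be >= 0")

    def weight_range(self, gender: int) -> tuple[float, float]:
        _check_gender(gender)
        return self.male_weight_range if gender == MALE else self.female_weight_range

    def size_scale(self, gender: int) -> float:
        _check_gender(gender)
        return self.male_size_scale if gender == MALE else self.female_size_scale


CSR2 = BreedSpec("CSR2", male_weight_range=(0.7, 1.4), female_weight_range=(1.5, 2.0))
PURE_MYSORE = BreedSpec(
    "PureMysore", male_weight_range=(0.8, 1.1), female_weight_range=(1.2, 1.4)
)

BREEDS = {"CSR2": CSR2, "PureMysore": PURE_MYSORE}


@dataclass
class CocoonRecord:
    """One generated specimen: image + weight + breed + optional label."""

    index: int
    breed: str
    weight: float
    image: np.ndarray
    true_label: int | None = None
    geometry: dict = field(default_factory=dict)
    image_ref: Path | None = None

    def __post_init__(self) -> None:
        if self.index <= 0:
            raise DataError(f"record index must be positive, got {self.index}")
        if self.weight <= 0:
            raise DataError(f"weight must be positive, got {self.weight}")
        q = round(self.weight / WEIGHT_RESOLUTION)
        if abs(self.weight - q * WEIGHT_RESOLUTION) > 1e-9:
            raise DataError(
                f"weight {self.weight} is not a multiple of {WEIGHT_RESOLUTION} g"
            )
        if self.true_label is not None and self.true_label not in (MALE, FEMALE):
            raise DataError(f"label must be 0 or 1, got {self.true_label}")


def _check_gender(gender: int) -> None:
    if gender not in (MALE, FEMALE):
        raise ConfigError(f"gender must be {MALE} (male) or {FEMALE} (female), got {gender!r}")


def sample_weight(
    spec: BreedSpec,
    gender: int,
    rng: np.random.Generator,
    distribution: str = "uniform",
) -> float:
    """Draw one cocoon weight in grams, quantized to 0.01 g.

    ``distribution`` is ``"uniform"`` over the configured range (default) or
    ``"truncnorm"`` — a normal centred on the range midpoint with sd one
    quarter of the range width, redrawn until inside the range — for overlap
    experiments.
    """
    _check_gender(gender)
    lo, hi = spec.weight_range(gender)
    if distribution == "uniform":
        w = rng.uniform(lo, hi)
    elif distribution == "truncnorm":
        mid, sd = (lo + hi) / 2.0, max((hi - lo) / 4.0, 1e-9)
        w = rng.normal(mid, sd)
        while not lo <= w <= hi:
            w = rng.normal(mid, sd)
    else:
        raise ConfigError(f"unknown weight distribution {distribution!r}")
    # round half away from the draw direction is irrelevant at 0.01 g; clip so
    # quantization cannot step outside the configured support
    return float(np.clip(round(w / WEIGHT_RESOLUTION) * WEIGHT_RESOLUTION, lo, hi).round(2))


def superellipse_area(a: float, b: float, n: float) -> float:
    """Closed-form area of |x/a|^n + |y/b|^n <= 1."""
    return 4.0 * a * b * gamma(1.0 + 1.0 / n) ** 2 / gamma(1.0 + 2.0 / n)


def _half_width_profile(u: np.ndarray, waist: float, n: float) -> np.ndarray:
    """Normalized half-width of the (possibly pinched) superellipse at |x/a|=u."""
    base = np.clip(1.0 - np.abs(u) ** n, 0.0, None) ** (1.0 / n)
    if waist:
        base = base * (1.0 - waist * np.cos(np.pi * u / 2.0) ** 2)
    return base


def render_silhouette(
    center: tuple[float, float],
    scale: float,
    elongation: float = BASE_ELONGATION,
    waist: float = 0.0,
    angle: float = 0.0,
    fiber_density: float = 0.0,
    noise_sd: float = 0.0,
    image_size: tuple[int, int] = (64, 64),
    rng: np.random.Generator | None = None,
    exponent: float = SUPERELLIPSE_EXPONENT,
    radial_harmonics: tuple[tuple[int, float, float], ...] = (),
) -> np.ndarray:
    """Render one backlit cocoon silhouette as an 8-bit grayscale image.

    ``scale`` is the semi-minor axis in pixels; the semi-major axis is
    ``scale * elongation``.  ``waist`` in [0, 1) pinches the mid-section into
    a peanut profile.  ``radial_harmonics`` is a tuple of (order, amplitude,
    phase) cosine terms modulating the half-width around the outline — real
    shells are lumpy, not perfect superellipses — and is part of a specimen's
    fixed geometry, not of the imaging noise.  ``fiber_density`` is the
    expected number of floss strands.  Raises :class:`ConfigError` if the
    shape does not fit in the frame with a 2 px margin.
    """
    if scale <= 0 or elongation < 1.0 or not 0.0 <= waist < 1.0:
        raise ConfigError(
            f"invalid silhouette parameters scale={scale}, elongation={elongation}, waist={waist}"
        )
    h, w = image_size
    cy, cx = center
    a = scale * elongation
    radius = np.hypot(a, scale)  # conservative rotated extent
    if cy - radius < 2 or cx - radius < 2 or cy + radius > h - 3 or cx + radius > w - 3:
        raise ConfigError(
            f"silhouette (extent {radius:.1f} px at center {center}) exceeds the "
            f"{h}x{w} frame margin"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    ca, sa = np.cos(angle), np.sin(angle)
    xr = ca * (xx - cx) + sa * (yy - cy)
    yr = -sa * (xx - cx) + ca * (yy - cy)
    u = xr / a
    half_width = scale * _half_width_profile(u, waist, exponent)
    if radial_harmonics:
        theta = np.arctan2(yr / scale, u)
        lumps = sum(amp * np.cos(k * theta + phase) for k, amp, phase in radial_harmonics)
        half_width = half_width * (1.0 + lumps)
    inside = (np.abs(u) <= 1.0) & (np.abs(yr) <= half_width)

    img = np.full((h, w), float(BACKGROUND_INTENSITY))
    if fiber_density > 0:
        if rng is None:
            raise ConfigError("fiber rendering requires an rng")
        _draw_fibers(img, inside, center, radius, int(round(fiber_density)), rng)
    img[inside] = SHELL_INTENSITY
    if noise_sd > 0:
        if rng is None:
            raise ConfigError("noise rendering requires an rng")
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _draw_fibers(
    img: np.ndarray,
    shell: np.ndarray,
    center: tuple[float, float],
    radius: float,
    n_strands: int,
    rng: np.random.Generator,
) -> None:
    """Random-walk floss strands emanating from the shell boundary, 1 px wide."""
    h, w = img.shape
    cy, cx = center
    for _ in range(n_strands):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        y = cy + (radius * 0.75) * np.sin(theta)
        x = cx + (radius * 0.75) * np.cos(theta)
        direction = theta + rng.normal(0.0, 0.4)
        for _ in range(rng.integers(10, 25)):
            direction += rng.normal(0.0, 0.35)
            y += np.sin(direction)
            x += np.cos(direction)
            r, c = int(round(y)), int(round(x))
            if not (0 <= r < h and 0 <= c < w):
                break
            if not shell[r, c]:
                img[r, c] = FIBER_INTENSITY


def _sample_geometry(
    spec: BreedSpec,
    gender: int,
    rng: np.random.Generator,
    image_size: tuple[int, int],
    fiber_density: float,
    noise_sd: float,
) -> dict:
    scale = BASE_SCALE * spec.size_scale(gender) * (1.0 + rng.normal(0.0, spec.size_noise_sd))
    # lumpy outline + a variable waist pinch: real shells are not perfect
    # superellipses, and the resulting mild concavities spread solidity and
    # convexity across specimens
    harmonics = tuple(
        (int(k), float(rng.normal(0.0, 0.02)), float(rng.uniform(0.0, 2.0 * np.pi)))
        for k in (3, 4, 5)
    )
    return {
        "radial_harmonics": harmonics,
        "center": (image_size[0] / 2.0, image_size[1] / 2.0),
        "scale": float(scale),
        "elongation": float(BASE_ELONGATION * (1.0 + rng.normal(0.0, 0.02))),
        "waist": float(rng.uniform(0.0, 0.25)),
        "angle": float(rng.uniform(0.0, np.pi)),
        "fiber_density": fiber_density,
        "noise_sd": noise_sd,
        "image_size": image_size,
    }


def render_record_image(geometry: dict, rng: np.random.Generator) -> np.ndarray:
    """Re-render a record's silhouette (used by repeated-trial protocols)."""
    return render_silhouette(rng=rng, **geometry)


def generate_batch(
    spec: BreedSpec,
    n_male: int,
    n_female: int,
    seed: int,
    out_dir: str | Path | None = None,
    image_size: tuple[int, int] = (64, 64),
    fiber_density: float = 4.0,
    noise_sd: float = 6.0,
    weight_distribution: str = "uniform",
) -> tuple[list[CocoonRecord], pd.DataFrame]:
    """Generate a labelled batch of cocoon specimens.

    Returns the records (images held in memory) and the ground-truth table
    with columns ``index,breed,weight_g,label``.  When ``out_dir`` is given,
    images are written as ``<index>.png`` alongside ``truth.csv``.
    """
    if n_male < 0 or n_female < 0:
        raise ConfigError("n_male and n_female must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[CocoonRecord] = []
    idx = 0
    for gender, count in ((MALE, n_male), (FEMALE, n_female)):
        for _ in range(count):
            idx += 1
            geom = _sample_geometry(spec, gender, rng, image_size, fiber_density, noise_sd)
            img = render_record_image(geom, rng)
            records.append(
                CocoonRecord(
                    index=idx,
                    breed=spec.breed_name,
                    weight=sample_weight(spec, gender, rng, weight_distribution),
                    image=img,
                    true_label=gender,
                    geometry=geom,
                )
            )
    truth = pd.DataFrame(
        {
            "index": [r.index for r in records],
            "breed": [r.breed for r in records],
            "weight_g": [r.weight for r in records],
            "label": [r.true_label for r in records],
        }
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for r in records:
            r.image_ref = out / f"{r.index}.png"
            iio.imwrite(r.image_ref, r.image)
        truth.to_csv(out / "truth.csv", index=False)
    return records, truth


def generate_multi_cocoon_image(
    spec: BreedSpec,
    k: int,
    rng: np.random.Generator,
    fiber_density: float = 0.0,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Image with ``k`` >= 2 well-separated silhouettes (tests the area gate)."""
    if k < 2:
        raise ConfigError(f"a multi-cocoon image needs k >= 2, got k={k}")
    cell = 48
    h, w = 64, cell * k + 16
    img = np.full((h, w), float(BACKGROUND_INTENSITY))
    for i in range(k):
        gender = int(rng.integers(0, 2))
        geom = _sample_geometry(spec, gender, rng, (h, w), fiber_density, noise_sd)
        geom["center"] = (h / 2.0, cell * i + cell / 2.0 + 8)
        sub = render_record_image(geom, rng).astype(float)
        img = np.minimum(img, sub)  # shells are dark; min-composite keeps both
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
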