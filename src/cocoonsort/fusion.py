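"""Integrated feature vector (weight + shape) and z-score normalization.

The classifier consumes a fixed-order nine-component vector per cocoon:

    (W, A, P, lambda1/lambda2, E, C, R, S, AC)

i.e. the weight in grams followed by the shape descriptors.  Because W is in
grams (~1) while A is in pixels (~500), each feature is standardized to zero
mean / unit variance with parameters fitted on the TRAINING split only and
frozen for test/production scoring (fitting on all data would leak test
statistics into the model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .features import ShapeFeatureVector

#: fixed component order of the integrated feature vector
IFV_ORDER = ("W", "A", "P", "axis_ratio", "E", "C", "R", "S", "AC")
IFV_LENGTH = len(IFV_ORDER)


def build_ifv(weight: float, sf: ShapeFeatureVector, split_axes: bool = False) -> np.ndarray:
    """Assemble the integrated feature vector for one cocoon.

    Default is the nine-vector with the moment-axis RATIO as one entry;
    ``split_axes=True`` replaces the ratio by the two axis lengths (a
    ten-vector) for sensitivity experiments.
    """
    if not np.isfinite(weight) or weight <= 0:
        raise DataError(f"weight must be positive and finite, got {weight}")
    if split_axes:
        values = [weight, sf.A, sf.P, sf.lambda1, sf.lambda2, sf.E, sf.C, sf.R, sf.S, sf.AC]
    else:
        values = [weight, sf.A, sf.P, sf.axis_ratio, sf.E, sf.C, sf.R, sf.S, sf.AC]
    ifv = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(ifv)):
        raise DataError("integrated feature vector contains non-finite entries")
    return ifv


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature (mu, sigma) fitted on the training set."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 1:
            raise DataError("mu and sigma must be 1-D vectors of equal length")
        if np.any(self.sigma <= 0):
            raise DataError("sigma entries must be positive")


def fit_normalizer(
    training_ifvs: np.ndarray,
    ddof: int = 0,
    feature_names: tuple[str, ...] = IFV_ORDER,
) -> NormalizationParams:
    """Fit per-feature mean and standard deviation on training vectors.

    Population sd (``ddof=0``) by default; pass ``ddof=1`` for the sample sd.
    A zero-variance feature is a hard error naming the offending feature.
    """
    X = np.atleast_2d(np.asarray(training_ifvs, dtype=float))
    if X.shape[0] < 2:
        raise DataError("need >= 2 training vectors to fit a normalizer")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=ddof)
    if np.any(sigma <= 0):
        j = int(np.argmin(sigma))
        name = feature_names[j] if j < len(feature_names) else f"feature {j}"
        raise DataError(f"feature {name!r} has zero variance on the training set")
    return NormalizationParams(mu=mu, sigma=sigma)


def apply_zscore(ifv: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Entry-wise (x - mu) / sigma; works on one vector or a matrix."""
    X = np.asarray(ifv, dtype=float)
    if X.shape[-1] != params.mu.shape[0]:
        raise DataError(
            f"length mismatch: vector has {X.shape[-1]} entries, "
            f"normalizer expects {params.mu.shape[0]}"
        )
    return (X - params.mu) / params.sigma
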