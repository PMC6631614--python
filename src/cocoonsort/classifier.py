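"""Linear maximum-margin classifier and the stratified hold-out split.

Training solves the soft-margin linear SVM primal

    min_{w,b}  1/2 ||w||^2 + C * sum_i max(0, 1 - y_i (w.x_i + b))

on z-score-normalized feature vectors (libsvm via scikit-learn stands behind
the fit; the contract is the objective, not the solver).  Labels follow the
sorter's convention: 1 = male, 0 = female.  A decision value of exactly zero
maps to female — an arbitrary but pinned tie rule.

Model evaluation uses a single stratified hold-out partition: per gender,
floor(train_frac * n) specimens train the model and the rest test it — the
only rounding rule consistent with the documented per-breed split counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .errors import ConfigError, ConvergenceError, DataError
from .fusion import IFV_ORDER, NormalizationParams, apply_zscore

LABEL_MAP = {1: "male", 0: "female"}


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test index sets of a stratified hold-out split."""

    train_indices: np.ndarray
    test_indices: np.ndarray


def stratified_holdout_split(
    labels: np.ndarray, train_frac: float = 0.6, seed: int = 0
) -> SplitPlan:
    """Stratified hold-out: per gender, floor(train_frac * n) train the model.

    Membership within each gender is randomized by ``seed``; the returned
    index arrays are positions into ``labels``.
    """
    y = np.asarray(labels)
    if y.ndim != 1 or len(y) == 0:
        raise DataError("labels must be a non-empty 1-D sequence")
    if np.any((y != 0) & (y != 1)):
        raise DataError("every record must carry a 0/1 label for splitting")
    if not 0.0 < train_frac < 1.0:
        raise ConfigError(f"train_frac must be in (0, 1), got {train_frac}")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for g in (1, 0):
        idx = np.flatnonzero(y == g)
        rng.shuffle(idx)
        n_train = int(np.floor(train_frac * len(idx)))
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return SplitPlan(
        train_indices=np.sort(np.array(train, dtype=int)),
        test_indices=np.sort(np.array(test, dtype=int)),
    )


@dataclass
class LinearModel:
    """Trained linear classifier with its embedded normalization."""

    w: np.ndarray  # weight vector in normalized-feature space
    b: float
    C_reg: float
    norm_params: NormalizationParams
    feature_order: tuple[str, ...] = IFV_ORDER
    label_map: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.label_map is None:
            self.label_map = dict(LABEL_MAP)


def train_linear_svm(
    X_norm: np.ndarray,
    y: np.ndarray,
    C_reg: float = 1.0,
    norm_params: NormalizationParams | None = None,
    tol: float = 1e-6,
) -> LinearModel:
    """Fit the soft-margin linear SVM on standardized feature vectors."""
    X = np.atleast_2d(np.asarray(X_norm, dtype=float))
    y = np.asarray(y)
    if set(np.unique(y)) != {0, 1}:
        raise DataError("training requires both classes (labels 0 and 1) present")
    if C_reg <= 0:
        raise ConfigError(f"C_reg must be positive, got {C_reg}")
    svc = SVC(kernel="linear", C=C_reg, tol=tol)
    svc.fit(X, y)
    if svc.fit_status_ != 0:
        raise ConvergenceError("SVM solver did not converge")
    # libsvm orders classes [0, 1]; its decision function is positive for
    # class 1 (male), matching our sign convention directly
    w = svc.coef_.ravel().astype(float)
    b = float(svc.intercept_[0])
    if np.linalg.norm(w) == 0:
        raise ConvergenceError("degenerate fit: zero weight vector")
    if norm_params is None:
        norm_params = NormalizationParams(
            mu=np.zeros(X.shape[1]), sigma=np.ones(X.shape[1])
        )
    return LinearModel(w=w, b=b, C_reg=C_reg, norm_params=norm_params)


def fit_classifier(X_raw: np.ndarray, y: np.ndarray, C_reg: float = 1.0) -> LinearModel:
    """Convenience: fit normalizer on the raw training vectors, then the SVM."""
    from .fusion import fit_normalizer

    params = fit_normalizer(X_raw)
    return train_linear_svm(apply_zscore(X_raw, params), y, C_reg, norm_params=params)


def decision_value(model: LinearModel, ifv_raw: np.ndarray) -> np.ndarray | float:
    """Signed margin score w.x_norm + b; > 0 means male."""
    x = apply_zscore(np.asarray(ifv_raw, dtype=float), model.norm_params)
    score = x @ model.w + model.b
    return float(score) if np.ndim(score) == 0 else score

def predict(model: LinearModel, ifv_raw: np.ndarray) -> np.ndarray | int:
    """Predicted label: 1 (male) iff the decision value is strictly positive."""
    score = decision_value(model, ifv_raw)
    out = (np.asarray(score) > 0).astype(int)
    return int(out) if out.ndim == 0 else out


def save_model(model: LinearModel, path: str | Path) -> None:
    """Serialize the model (weights + normalization) as JSON, full precision."""
    payload = {
        "w": [float(v) for v in model.w],
        "b": model.b,
        "C_reg": model.C_reg,
        "mu": [float(v) for v in model.norm_params.mu],
        "sigma": [float(v) for v in model.norm_params.sigma],
        "feature_order": list(model.feature_order),
        "label_map": {str(k): v for k, v in model.label_map.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> LinearModel:
    try:
        payload = json.loads(Path(path).read_text())
        return LinearModel(
            w=np.asarray(payload["w"], dtype=float),
            b=float(payload["b"]),
            C_reg=float(payload["C_reg"]),
            norm_params=NormalizationParams(
                mu=np.asarray(payload["mu"], dtype=float),
                sigma=np.asarray(payload["sigma"], dtype=float),
            ),
            feature_order=tuple(payload["feature_order"]),
            label_map={int(k): v for k, v in payload["label_map"].items()},
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise DataError(f"malformed model file {path}: {exc}") from exc
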