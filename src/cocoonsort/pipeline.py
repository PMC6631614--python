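"""End-to-end orchestration: simulate -> segment -> features -> classify -> report.

:func:`run_experiment` reproduces the full evaluation protocol on a
synthetic batch: stratified 60/40 hold-out, SVM training on z-scored
integrated feature vectors, confusion matrices and the metric suite on both
splits, and a k-trial repeatability measurement.  Repeatability trials rerun
the pipeline from segmentation onward on the same specimens; with
``trial_reimage=True`` each trial re-acquires the image (fresh sensor noise
and floss), emulating repeated physical passes through the imaging station.

:func:`classify_batch` is the production path: images + weights in,
per-cocoon gate verdict, predicted label and output tray out.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .classifier import (
    LinearModel,
    decision_value,
    fit_classifier,
    predict,
    stratified_holdout_split,
)
from .errors import ConfigError, DataError
from .features import compute_shape_features
from .fusion import build_ifv
from .io import read_gray_image, read_weights_csv
from .metrics import compute_metrics, confusion_matrix, repeatability
from .segmentation import (
    DEFAULT_AREA_BOUNDS,
    binarize,
    calibrate_area_gate,
    extract_components,
    otsu_threshold,
    segment_image,
    single_cocoon_gate,
)
from .synthetic import BREEDS, BreedSpec


@dataclass
class RunConfig:
    """Everything one experiment run depends on (seed included)."""

    breed: str | BreedSpec = "PureMysore"
    n_male: int = 35
    n_female: int = 41
    seed: int = 1
    train_frac: float = 0.6
    C_reg: float = 1.0
    trials: int = 4
    area_bounds: tuple[int, int] | None = None  # None -> calibrate from batch
    gate_mode: str = "total"
    fiber_density: float = 4.0
    noise_sd: float = 6.0
    weight_distribution: str = "uniform"
    trial_reimage: bool = False

    def breed_spec(self) -> BreedSpec:
        if isinstance(self.breed, BreedSpec):
            return self.breed
        try:
            return BREEDS[self.breed]
        except KeyError:
            raise ConfigError(
                f"unknown breed {self.breed!r}; expected one of {sorted(BREEDS)}"
            ) from None


def extract_record_features(img: np.ndarray, area_bounds, gate_mode: str = "total"):
    """Segment one image and, if accepted, compute its shape features."""
    verdict = segment_image(img, area_bounds=area_bounds, gate_mode=gate_mode)
    if verdict.verdict != "accept":
        return verdict, None
    return verdict, compute_shape_features(verdict.cocoon)


def _batch_areas(records) -> np.ndarray:
    """Total foreground areas of a batch, gate bypassed (for calibration)."""
    areas = []
    for r in records:
        mask = binarize(r.image, otsu_threshold(r.image))
        areas.append(sum(len(c.filled) for c in extract_components(mask)))
    return np.asarray(areas)


def run_experiment(config: RunConfig) -> dict:
    """Run the full synthetic evaluation protocol; returns the report dict."""
    spec = config.breed_spec()
    records, truth = synthetic.generate_batch(
        spec,
        config.n_male,
        config.n_female,
        seed=config.seed,
        fiber_density=config.fiber_density,
        noise_sd=config.noise_sd,
        weight_distribution=config.weight_distribution,
    )
    if not records:
        raise DataError("experiment needs a non-empty batch")
    bounds = config.area_bounds
    if bounds is None:
        bounds = calibrate_area_gate(_batch_areas(records))

    accepted, features, rejected = [], [], []
    for r in records:
        verdict, sf = extract_record_features(r.image, bounds, config.gate_mode)
        if sf is None:
            rejected.append({"index": r.index, "verdict": verdict.verdict})
        else:
            accepted.append(r)
            features.append(sf)
    if len(accepted) < 4:
        raise DataError("too few accepted specimens to train and test")

    X = np.array([build_ifv(r.weight, sf) for r, sf in zip(accepted, features)])
    y = np.array([r.true_label for r in accepted])
    split = stratified_holdout_split(y, train_frac=config.train_frac, seed=config.seed)
    model = fit_classifier(X[split.train_indices], y[split.train_indices], config.C_reg)

    report: dict = {
        "config": {
            **{
                k: (v if not isinstance(v, BreedSpec) else dataclasses.asdict(v))
                for k, v in dataclasses.asdict(config).items()
            },
            "area_bounds_used": list(bounds),
        },
        "rejected": rejected,
        "split": {
            "train_male": int(np.sum(y[split.train_indices] == 1)),
            "train_female": int(np.sum(y[split.train_indices] == 0)),
            "test_male": int(np.sum(y[split.test_indices] == 1)),
            "test_female": int(np.sum(y[split.test_indices] == 0)),
        },
    }
    for name, idx in (("train", split.train_indices), ("test", split.test_indices)):
        cm = confusion_matrix(y[idx], predict(model, X[idx]))
        report[name] = {
            "cm": {"TM": cm.TM, "TF": cm.TF, "FM": cm.FM, "FF": cm.FF},
            "metrics": compute_metrics(cm).as_dict(),
        }

    test_records = [accepted[i] for i in split.test_indices]
    trial_matrix = _run_trials(test_records, model, bounds, config)
    report["repeatability"] = {
        "k": config.trials,
        "n_records": len(test_records),
        "value": repeatability(trial_matrix) if test_records else float("nan"),
    }
    return report


def _run_trials(test_records, model: LinearModel, bounds, config: RunConfig):
    """Correctness matrix (records x trials) for the repeatability statistic."""
    matrix = []
    for r in test_records:
        row = []
        for trial in range(config.trials):
            img = r.image
            if config.trial_reimage:
                trial_rng = np.random.default_rng(
                    (config.seed * 1_000_003 + r.index * 101 + trial) % (2**31)
                )
                img = synthetic.render_record_image(r.geometry, trial_rng)
            verdict, sf = extract_record_features(img, bounds, config.gate_mode)
            if sf is None:
                row.append(False)
            else:
                row.append(int(predict(model, build_ifv(r.weight, sf))) == r.true_label)
        matrix.append(row)
    return matrix


def classify_batch(
    image_dir: str | Path,
    weights_csv: str | Path,
    model: LinearModel,
    area_bounds: tuple[int, int] = DEFAULT_AREA_BOUNDS,
    gate_mode: str = "total",
) -> pd.DataFrame:
    """Classify every ``<index>.png``/``.tif`` image against its weight row.

    Returns one row per image: gate verdict, foreground area, decision score,
    predicted label and output tray for accepted cocoons; a per-record
    ``error`` entry (batch continues) when the weight row is missing.
    """
    image_dir = Path(image_dir)
    weights = read_weights_csv(weights_csv).set_index("index")
    rows = []
    paths = sorted(
        (p for ext in ("*.png", "*.tif", "*.tiff") for p in image_dir.glob(ext)),
        key=lambda p: (len(p.stem), p.stem),
    )
    for path in paths:
        try:
            index = int(path.stem)
        except ValueError:
            raise DataError(f"image name {path.name} is not an integer index") from None
        row: dict = {"index": index, "verdict": None, "area": None, "score": None,
                     "label": None, "bin": None, "error": None}
        verdict, sf = extract_record_features(read_gray_image(path), area_bounds, gate_mode)
        row["verdict"] = verdict.verdict
        row["area"] = verdict.total_area
        if sf is not None:
            if index not in weights.index:
                row["error"] = "missing weight"
            else:
                ifv = build_ifv(float(weights.loc[index, "weight_g"]), sf)
                label = int(predict(model, ifv))
                row.update(
                    score=float(decision_value(model, ifv)),
                    label=label,
                    bin="male_tray" if label == 1 else "female_tray",
                )
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["index", "verdict", "area", "score", "label", "bin", "error"]
    )
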