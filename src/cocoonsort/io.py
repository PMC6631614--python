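"""File I/O for every pipeline artifact.

Images are 8-bit grayscale PNG/TIFF; tabular artifacts are CSV with pinned
headers (``index,breed,weight_g,label`` for ground truth, ``index,weight_g``
(+ optional ``label``) for weights, ``index`` + the feature columns for
features); models and reports are JSON.  The record ``index`` is the join
key between images and weights — duplicate indices are a hard error.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DataError
from .features import FEATURE_COLUMNS


def read_gray_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit grayscale image; collapses an RGB image whose channels agree."""
    img = iio.imread(path)
    if img.ndim == 3:
        if not (img[..., 0] == img[..., 1]).all():
            raise DataError(f"{path}: expected a grayscale image, got color")
        img = img[..., 0]
    if img.dtype != np.uint8:
        raise DataError(f"{path}: expected 8-bit pixels, got {img.dtype}")
    return img


def write_gray_image(path: str | Path, img: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 PNG."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    for col in cols:
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")


def read_weights_csv(path: str | Path) -> pd.DataFrame:
    """Read ``index,weight_g[,label]``; validates indices, weights, labels."""
    df = pd.read_csv(path)
    _require_columns(df, ("index", "weight_g"), path)
    if df["index"].duplicated().any():
        dup = df["index"][df["index"].duplicated()].iloc[0]
        raise DataError(f"{path}: duplicate cocoon index {dup}")
    if (df["weight_g"] <= 0).any():
        raise DataError(f"{path}: non-positive weight in column weight_g")
    if "label" in df.columns and not df["label"].isin((0, 1)).all():
        bad = df.loc[~df["label"].isin((0, 1)), "label"].iloc[0]
        raise DataError(f"{path}: invalid label {bad!r} (must be 0 or 1)")
    return df


def read_truth_csv(path: str | Path) -> pd.DataFrame:
    df = read_weights_csv(path)
    _require_columns(df, ("label",), path)
    return df


def write_features_csv(path: str | Path, table: pd.DataFrame) -> None:
    cols = ["index", *FEATURE_COLUMNS]
    _require_columns(table, tuple(cols), path)
    table[cols].to_csv(path, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("index", *FEATURE_COLUMNS), path)
    if df["index"].duplicated().any():
        raise DataError(f"{path}: duplicate cocoon index")
    return df


def write_report_json(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
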