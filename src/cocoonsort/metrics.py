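"""Confusion-matrix evaluation, the metric suite, and repeatability.

Naming follows the gender-sorting convention rather than the generic
positive/negative one: with male = 1 and female = 0,

* TM / TF — true male / true female counts (correct predictions per class),
* FM — false male (a female predicted male), FF — false female,
* TMR / TFR — recall of the male / female class,
* MPV / FPV — precision of the male / female class (elsewhere written MPR
  and "FPR"; that FPR is NOT the conventional false-positive rate),
* F1 — harmonic mean of MPV and TMR, i.e. F1 of the male class.

Ratios with a zero denominator are reported as NaN and listed in the
report's ``undefined`` field — never silently zero, which would corrupt
averages.  Repeatability is the fraction of specimens classified correctly
in EVERY one of k repeated full-pipeline trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError


@dataclass(frozen=True)
class ConfusionMatrix:
    TM: int
    TF: int
    FM: int
    FF: int

    def __post_init__(self) -> None:
        if min(self.TM, self.TF, self.FM, self.FF) < 0:
            raise DataError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TM + self.TF + self.FM + self.FF


def confusion_matrix(true_labels, pred_labels) -> ConfusionMatrix:
    """Tally TM/TF/FM/FF from parallel 0/1 label sequences."""
    yt = np.asarray(true_labels)
    yp = np.asarray(pred_labels)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise DataError("label sequences must be 1-D and of equal length")
    for arr, name in ((yt, "true"), (yp, "predicted")):
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise DataError(f"{name} labels must all be 0 or 1")
    return ConfusionMatrix(
        TM=int(np.sum((yt == 1) & (yp == 1))),
        TF=int(np.sum((yt == 0) & (yp == 0))),
        FM=int(np.sum((yt == 0) & (yp == 1))),
        FF=int(np.sum((yt == 1) & (yp == 0))),
    )


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    TMR: float
    TFR: float
    MPV: float
    FPV: float
    F1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "TMR": self.TMR,
            "TFR": self.TFR,
            "MPV": self.MPV,
            "FPV": self.FPV,
            "F1": self.F1,
            "undefined": list(self.undefined),
        }


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class recalls and precisions, male-class F1."""
    if cm.n == 0:
        raise DataError("cannot compute metrics of an empty confusion matrix")
    undefined: list[str] = []
    tmr = _ratio(cm.TM, cm.TM + cm.FF, "TMR", undefined)
    tfr = _ratio(cm.TF, cm.TF + cm.FM, "TFR", undefined)
    mpv = _ratio(cm.TM, cm.TM + cm.FM, "MPV", undefined)
    fpv = _ratio(cm.TF, cm.TF + cm.FF, "FPV", undefined)
    if math.isnan(mpv) or math.isnan(tmr) or mpv + tmr == 0:
        undefined.append("F1")
        f1 = math.nan
    else:
        f1 = 2.0 * mpv * tmr / (mpv + tmr)
    return MetricsReport(
        accuracy=(cm.TM + cm.TF) / cm.n,
        TMR=tmr,
        TFR=tfr,
        MPV=mpv,
        FPV=fpv,
        F1=f1,
        undefined=tuple(undefined),
    )


def repeatability(trial_matrix) -> float:
    """Fraction of records predicted correctly in every trial.

    ``trial_matrix`` is records x trials correctness booleans; a ragged
    matrix is rejected.
    """
    rows = list(trial_matrix)
    if not rows:
        raise DataError("repeatability needs >= 1 record")
    widths = {len(np.atleast_1d(r)) for r in rows}
    if len(widths) != 1 or widths == {0}:
        raise DataError("trial matrix is ragged or has zero trials")
    mat = np.asarray(rows, dtype=bool)
    return float(mat.all(axis=1).mean())


def reconstruct_confusion_from_rates(
    n_male: int,
    n_female: int,
    tmr: float,
    tfr: float,
    atol: float = 5e-4,
) -> ConfusionMatrix:
    """Recover the integer confusion matrix behind printed per-class rates.

    Searches TM in 0..n_male and TF in 0..n_female for counts whose recalls
    match the printed (possibly truncated) 4-decimal TMR/TFR within ``atol``.
    With class sizes below ~1000 the match is unique; ambiguity or absence is
    an error.
    """
    if n_male <= 0 or n_female <= 0:
        raise DataError("class sizes must be positive")
    tms = [tm for tm in range(n_male + 1) if abs(tm / n_male - tmr) <= atol]
    tfs = [tf for tf in range(n_female + 1) if abs(tf / n_female - tfr) <= atol]
    if len(tms) != 1 or len(tfs) != 1:
        raise DataError(
            f"printed rates do not identify a unique confusion matrix "
            f"(candidates: TM={tms}, TF={tfs})"
        )
    tm, tf = tms[0], tfs[0]
    return ConfusionMatrix(TM=tm, TF=tf, FM=n_female - tf, FF=n_male - tm)
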