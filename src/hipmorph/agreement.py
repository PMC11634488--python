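"""Segmentation overlap and measurement reliability between raters/methods.

Overlap between two multi-label masks is summarised per label from the voxel
confusion counts: Dice, Jaccard, conformity coefficient, true positive rate,
true negative rate, positive predictive value and volume ratio. True
negatives are counted over the full image grid (this affects TNR only). The
volume ratio is comparison over ground truth. Undefined metrics are reported
as missing with a machine-readable reason, never as silent zeros.

Reliability between two paired measurement series uses ICC(2,1) (two-way
random effects, absolute agreement, single measurement, with an F-based 95%
confidence interval), Bland-Altman bias and limits of agreement, MAE, RMSE,
Pearson r and prediction R^2 (1 - SS_res/SS_tot with the first series as
ground truth; can be negative).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .dixon_io import LabelMask

__all__ = [
    "OverlapReport",
    "ICCResult",
    "BlandAltman",
    "ErrorStats",
    "overlap_metrics",
    "icc_2_1",
    "bland_altman",
    "error_stats",
]

log = logging.getLogger(__name__)


@dataclass
class OverlapReport:
    label: int
    tp: int
    fp: int
    fn: int
    tn: int
    dice: float | None
    jaccard: float | None
    conformity: float | None
    tpr: float | None
    tnr: float | None
    ppv: float | None
    volume_ratio: float | None
    missing: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "label": self.label, "tp": self.tp, "fp": self.fp,
            "fn": self.fn, "tn": self.tn, "dice": self.dice,
            "jaccard": self.jaccard, "conformity": self.conformity,
            "tpr": self.tpr, "tnr": self.tnr, "ppv": self.ppv,
            "volume_ratio": self.volume_ratio,
        }


def overlap_metrics(a: LabelMask, b: LabelMask, label: int) -> OverlapReport:
    """Voxel-overlap metrics for one label, with ``a`` as ground truth and
    ``b`` as the comparison segmentation."""
    if a.shape != b.shape or not np.allclose(a.affine, b.affine, atol=1e-4):
        raise ValueError("masks are on different grids")
    in_a = a.labels == label
    in_b = b.labels == label
    tp = int((in_a & in_b).sum())
    fp = int((~in_a & in_b).sum())
    fn = int((in_a & ~in_b).sum())
    tn = int((~in_a & ~in_b).sum())

    missing: dict[str, str] = {}

    def ratio(num: float, den: float, name: str, reason: str) -> float | None:
        if den == 0:
            missing[name] = reason
            return None
        return num / den

    dice = ratio(2 * tp, 2 * tp + fp + fn, "dice", "both masks empty for label")
    jaccard = ratio(tp, tp + fp + fn, "jaccard", "both masks empty for label")
    if tp > 0:
        conformity = 1.0 - (fp + fn) / tp
    else:
        conformity = None
        missing["conformity"] = "no true-positive voxels (TP = 0)"
    tpr = ratio(tp, tp + fn, "tpr", "ground-truth mask empty for label")
    tnr = ratio(tn, tn + fp, "tnr", "no true-negative candidates")
    ppv = ratio(tp, tp + fp, "ppv", "comparison mask empty for label")
    volume_ratio = ratio(
        float(in_b.sum()), float(in_a.sum()), "volume_ratio",
        "ground-truth mask empty for label",
    )
    if missing:
        log.warning("label %d: undefined metrics %s", label, sorted(missing))
    return OverlapReport(
        label=int(label), tp=tp, fp=fp, fn=fn, tn=tn,
        dice=dice, jaccard=jaccard, conformity=conformity,
        tpr=tpr, tnr=tnr, ppv=ppv, volume_ratio=volume_ratio,
        missing=missing,
    )


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    msr: float  # between-subject mean square
    msc: float  # between-rater mean square
    mse: float  # residual mean square
    degenerate: bool = False


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measurement ICC.

    ``ratings`` is an n_subjects x k_raters matrix with no missing cells.
    The confidence interval follows the Shrout-Fleiss F-based construction
    with a Satterthwaite denominator degrees-of-freedom approximation.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValueError("ratings contain missing cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(msr, 0.0) and np.isclose(denom, 0.0):
        log.warning("ICC degenerate: zero between-subject variance")
        return ICCResult(float("nan"), float("nan"), float("nan"),
                         msr, msc, mse, degenerate=True)
    icc = (msr - mse) / denom

    # F-based CI (Shrout & Fleiss 1979 / McGraw & Wong 1996)
    if mse == 0 and msc == msr:
        return ICCResult(icc, icc, icc, msr, msc, mse)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lower = upper = icc
    return ICCResult(float(icc), float(lower), float(upper), msr, msc, mse)


class BlandAltman(NamedTuple):
    bias: float
    loa_low: float
    loa_high: float


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltman:
    """Bias = mean(y - x); 95% limits of agreement = bias +/- 1.96 * SD of
    the paired differences (sample SD, n-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd)


class ErrorStats(NamedTuple):
    mae: float
    rmse: float
    pearson_r: float
    r_squared: float


def error_stats(x: np.ndarray, y: np.ndarray) -> ErrorStats:
    """Accuracy of ``y`` as a prediction of the ground truth ``x``.

    R^2 is prediction R^2 (1 - SS_res/SS_tot), not squared correlation, so it
    can be negative; Pearson r is NaN (flagged) when x has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = y - x
    mae = float(np.abs(d).mean())
    rmse = float(np.sqrt((d**2).mean()))
    ss_tot = float(((x - x.mean()) ** 2).sum())
    if ss_tot == 0:
        log.warning("zero variance in ground truth: r and R^2 undefined")
        return ErrorStats(mae, rmse, float("nan"), float("nan"))
    sx, sy = float(np.std(x)), float(np.std(y))
    if sy == 0:
        r = float("nan")
        log.warning("zero variance in comparison series: r undefined")
    else:
        r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    r2 = 1.0 - float((d**2).sum()) / ss_tot
    return ErrorStats(mae, rmse, r, r2)
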