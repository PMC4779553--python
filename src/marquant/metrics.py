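"""Validation statistics: Dice overlap, %LVM, Bland-Altman, correlation, paired tests.

All quantities follow standard segmentation-validation practice: the Dice
similarity coefficient (DSC) measures regional agreement of two masks,
MaR size is expressed as percent of left-ventricular mass (%LVM), and paired
method comparisons use Bland-Altman bias (mean +/- SD of the differences)
with 1.96-SD limits of agreement, Pearson correlation, and two-sided paired
t-tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    0 if the regions do not overlap, 1 if they overlap perfectly.  Voxel
    volume cancels on a shared grid.  Undefined (error) if both are empty.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("Dice undefined: both masks empty")
    return 2.0 * int((a & b).sum()) / denom


def dice_timeframes(masks_a: Mapping[str, np.ndarray],
                    masks_b: Mapping[str, np.ndarray]) -> float:
    """Dice over the joint (ED + ES) voxel sets of two timeframe mask dicts."""
    tfs = sorted(set(masks_a) & set(masks_b))
    if not tfs:
        raise ValueError("no common timeframes")
    a = np.concatenate([np.asarray(masks_a[tf], bool).ravel() for tf in tfs])
    b = np.concatenate([np.asarray(masks_b[tf], bool).ravel() for tf in tfs])
    return dice(a, b)


def mar_percent_lvm(mar_masks: Mapping[str, np.ndarray],
                    myo_masks: Mapping[str, np.ndarray]) -> float:
    """MaR volume as percent of LV myocardial volume, averaged over timeframes.

    Uniform voxel volume and tissue density cancel, so voxel counts suffice.
    """
    percents = []
    for tf, myo in myo_masks.items():
        myo = np.asarray(myo, dtype=bool)
        n_myo = int(myo.sum())
        if n_myo == 0:
            raise ValueError(f"empty myocardium in timeframe {tf}")
        mar = np.asarray(mar_masks[tf], dtype=bool)
        if (mar & ~myo).any():
            raise ValueError(f"MaR mask extends outside the myocardium in {tf}")
        percents.append(100.0 * int(mar.sum()) / n_myo)
    if not percents:
        raise ValueError("no timeframes provided")
    return float(np.mean(percents))


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    n: int


def bland_altman(method: Sequence[float], reference: Sequence[float]) -> BlandAltman:
    """Bland-Altman bias and 1.96-SD limits of agreement of method - reference."""
    m = np.asarray(method, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError("paired 1-D samples required")
    if m.size < 2:
        raise ValueError("Bland-Altman needs n >= 2 pairs")
    d = m - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, m.size)


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples of length >= 2 required")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def paired_ttest_bonferroni(a: Sequence[float], b: Sequence[float],
                            n_comparisons: int = 1) -> tuple[float, float]:
    """Two-sided paired t-test with Bonferroni-adjusted p (capped at 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples of length >= 2 required")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    d = a - b
    if np.allclose(d, d[0]) and d.std(ddof=1) == 0 and d[0] != 0:
        raise ValueError("zero-variance non-zero differences: t undefined")
    res = stats.ttest_rel(a, b)
    t = float(res.statistic)
    if np.isnan(t):
        if np.all(d == 0):  # identical samples: no difference
            return 0.0, 1.0
        raise ValueError("t statistic undefined for these differences")
    return t, float(min(1.0, res.pvalue * n_comparisons))


@dataclass(frozen=True)
class AgreementReport:
    """Summary agreement statistics between a method and a reference."""

    bias: float
    bias_sd: float
    loa_lower: float
    loa_upper: float
    r: float
    dice_mean: float
    dice_sd: float
    n: int

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) if k != "n" else self.n
                for k in ("bias", "bias_sd", "loa_lower", "loa_upper", "r",
                          "dice_mean", "dice_sd", "n")}


def agreement_report(method_lvm: Sequence[float], reference_lvm: Sequence[float],
                     dice_values: Sequence[float]) -> AgreementReport:
    """Combine Bland-Altman, correlation, and Dice summaries for a cohort."""
    ba = bland_altman(method_lvm, reference_lvm)
    d = np.asarray(dice_values, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("Dice values must lie in [0, 1]")
    return AgreementReport(
        bias=ba.bias, bias_sd=ba.sd, loa_lower=ba.loa_lower, loa_upper=ba.loa_upper,
        r=pearson_r(method_lvm, reference_lvm),
        dice_mean=float(d.mean()), dice_sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        n=ba.n,
    )
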