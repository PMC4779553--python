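"""Baseline intensity-threshold methods for MaR quantification.

Three standard competitors, each producing a per-slice intensity threshold
applied to the myocardium of that slice (slice-wise application accounts for
the through-plane intensity gradient):

* 2SD   — remote mean + 2 x remote SD;
* FWHM  — midway between the remote mean and the myocardial maximum;
* Otsu  — histogram threshold minimizing the within-class intensity variance.

The baselines are pure thresholding: no coil correction, no sector priors,
no continuity or LGE post-processing.  The remote region is the myocardium
outside the culprit artery's maximal-extent territory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skimage.filters import threshold_otsu as _skimage_otsu

from .geometry import MaximalExtentModel, SectorMap, remote_region

METHODS = ("2SD", "FWHM", "OTSU")
OTSU_BINS = 256


def threshold_2sd(remote_intensities: np.ndarray) -> float:
    """Remote mean plus two sample standard deviations."""
    r = np.asarray(remote_intensities, dtype=float).ravel()
    if r.size < 2:
        raise ValueError("2SD threshold needs >= 2 remote voxels")
    return float(r.mean() + 2.0 * r.std(ddof=1))


def threshold_fwhm(myocardial_intensities: np.ndarray,
                   remote_intensities: np.ndarray) -> float:
    """Midway between the remote mean and the maximal myocardial intensity."""
    r = np.asarray(remote_intensities, dtype=float).ravel()
    m = np.asarray(myocardial_intensities, dtype=float).ravel()
    if r.size == 0 or m.size == 0:
        raise ValueError("FWHM threshold needs non-empty remote and myocardium")
    return float((r.mean() + m.max()) / 2.0)


def threshold_otsu(myocardial_intensities: np.ndarray, nbins: int = OTSU_BINS) -> float:
    """Otsu's threshold over an equal-width histogram of myocardial intensities."""
    m = np.asarray(myocardial_intensities, dtype=float).ravel()
    if np.unique(m).size < 2:
        raise ValueError("Otsu threshold needs >= 2 distinct intensity values")
    return float(_skimage_otsu(m, nbins=nbins))


@dataclass
class ThresholdResult:
    """Per-slice thresholds and the resulting suprathreshold MaR mask."""

    method: str
    thresholds: Mapping[str, np.ndarray]  # timeframe -> (n_slices,), NaN where invalid
    masks: Mapping[str, np.ndarray]       # timeframe -> boolean volume


def segment_by_threshold(
    images: Mapping[str, np.ndarray],
    myo_masks: Mapping[str, np.ndarray],
    sector_maps: Mapping[str, SectorMap],
    extent: MaximalExtentModel,
    method: str,
    nbins: int = OTSU_BINS,
) -> ThresholdResult:
    """Apply one baseline method slice by slice on uncorrected intensities.

    The mask keeps myocardial voxels strictly above their slice's threshold.
    Slices where the threshold is undefined (e.g. too few remote voxels) are
    left empty with a warning.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    thresholds: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for tf, img in images.items():
        img = np.asarray(img, dtype=float)
        myo = np.asarray(myo_masks[tf], dtype=bool)
        remote = (remote_region(sector_maps[tf], extent)
                  if method in ("2SD", "FWHM") else None)
        thr = np.full(img.shape[0], np.nan)
        mask = np.zeros(img.shape, dtype=bool)
        for s in range(img.shape[0]):
            m = myo[s]
            if not m.any():
                continue
            try:
                if method == "2SD":
                    thr[s] = threshold_2sd(img[s][remote[s]])
                elif method == "FWHM":
                    thr[s] = threshold_fwhm(img[s][m], img[s][remote[s]])
                else:
                    thr[s] = threshold_otsu(img[s][m], nbins=nbins)
            except ValueError as err:
                warnings.warn(f"{method} slice {s}: {err}; left empty")
                continue
            mask[s] = m & (img[s] > thr[s])
        thresholds[tf] = thr
        masks[tf] = mask
    return ThresholdResult(method=method, thresholds=thresholds, masks=masks)
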