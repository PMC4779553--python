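"""Surface-coil intensity correction (processing block 1).

Surface coils impose a smooth multiplicative intensity gradient roughly
proportional to the squared coil distance.  The correction estimates, per
slice, a second-order 2-D polynomial bias field from the log-intensities of
two reference tissue classes — the blood pool and the remote myocardium —
after removing each class's mean log-intensity, so that only the shared
spatial gradient remains.  Division by the exponentiated field flattens the
gradient; intensities are rescaled so the remote-myocardium mean is
preserved.

The correction is optional and self-auditing: it is applied only if it
reduces the coefficient of variation (CoV) in the remote myocardium AND
leaves the culprit-territory mean above the remote mean (myocardium at risk
is hyperintense in CE-SSFP, so a correction that inverts that contrast is
rejected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import MaximalExtentModel, SectorMap, VoxelGrid, extent_region, remote_region

MIN_SAMPLES_PER_CLASS = 7  # more samples than the 6 polynomial coefficients


@dataclass
class BiasFieldModel:
    """Per-slice degree-2 polynomial bias field in normalized in-plane coords.

    ``coeffs[s]`` are the 6 coefficients (1, x, y, x^2, xy, y^2) of the
    log-field on slice ``s``; ``fitted[s]`` is False where the slice had too
    few samples and inherited its nearest fitted neighbour's coefficients.
    """

    coeffs: np.ndarray
    fitted: np.ndarray

    def field(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Reconstruct the strictly positive multiplicative field on a grid."""
        n_slices, rows, cols = shape
        basis = _design(rows, cols)  # (rows*cols, 6)
        out = np.empty(shape, dtype=float)
        for s in range(n_slices):
            out[s] = np.exp(basis @ self.coeffs[s]).reshape(rows, cols)
        return out


def _normalized_coords(rows: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    xh = 2.0 * x / max(cols - 1, 1) - 1.0
    yh = 2.0 * y / max(rows - 1, 1) - 1.0
    return xh, yh


def _design(rows: int, cols: int) -> np.ndarray:
    xh, yh = _normalized_coords(rows, cols)
    xh, yh = xh.ravel(), yh.ravel()
    return np.column_stack([np.ones_like(xh), xh, yh, xh**2, xh * yh, yh**2])


def fit_bias_field(images: np.ndarray, blood_mask: np.ndarray,
                   remote_mask: np.ndarray) -> BiasFieldModel:
    """Least-squares fit of a per-slice degree-2 log-domain bias field.

    Sample voxels are the blood pool and remote myocardium of each slice;
    each voxel's log-intensity minus its class mean log-intensity (per slice)
    is regressed onto the polynomial basis.  Slices where either class has
    fewer than 7 voxels inherit the nearest fitted slice's coefficients.
    """
    images = np.asarray(images, dtype=float)
    n_slices, rows, cols = images.shape
    basis3d = _design(rows, cols).reshape(rows, cols, 6)

    coeffs = np.zeros((n_slices, 6))
    fitted = np.zeros(n_slices, dtype=bool)
    for s in range(n_slices):
        cls_masks = (blood_mask[s], remote_mask[s])
        if any(int(m.sum()) < MIN_SAMPLES_PER_CLASS for m in cls_masks):
            continue
        resid, rows_basis = [], []
        for m in cls_masks:
            vals = images[s][m]
            if np.any(vals <= 0):
                raise ValueError(f"slice {s}: non-positive intensities in bias-field samples")
            logv = np.log(vals)
            resid.append(logv - logv.mean())
            rows_basis.append(basis3d[m])
        y = np.concatenate(resid)
        a = np.vstack(rows_basis)
        coeffs[s], *_ = np.linalg.lstsq(a, y, rcond=None)
        fitted[s] = True

    if not fitted.any():
        raise ValueError(
            "no slice has enough blood-pool and remote samples "
            f"(need >= {MIN_SAMPLES_PER_CLASS} per class) to fit the bias field"
        )
    good = np.flatnonzero(fitted)
    for s in np.flatnonzero(~fitted):
        coeffs[s] = coeffs[good[np.argmin(np.abs(good - s))]]
    return BiasFieldModel(coeffs=coeffs, fitted=fitted)


@dataclass
class CorrectionDecision:
    """Audit record of whether the coil correction was applied and why."""

    applied: bool
    cov_before: float | None = None
    cov_after: float | None = None
    culprit_mean: float | None = None
    remote_mean: float | None = None
    reason: str | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("applied", "cov_before", "cov_after", "culprit_mean",
                 "remote_mean", "reason")}


def _cov(values: np.ndarray) -> float:
    return float(np.std(values) / np.mean(values))


def correct_if_beneficial(
    images: np.ndarray,
    blood_mask: np.ndarray,
    sector_map: SectorMap,
    extent: MaximalExtentModel,
) -> tuple[np.ndarray, CorrectionDecision]:
    """Apply the coil correction only if it helps (see module docstring).

    Returns corrected images and the decision record; on any fit failure the
    input is returned unchanged with ``applied=False`` and a reason (the
    correction is an optional block, so failures degrade gracefully).
    """
    images = np.asarray(images, dtype=float)
    remote = remote_region(sector_map, extent)
    culprit = extent_region(sector_map, extent)
    if not remote.any():
        return images, CorrectionDecision(False, reason="empty remote region")
    try:
        model = fit_bias_field(images, blood_mask, remote)
    except ValueError as err:
        return images, CorrectionDecision(False, reason=f"fit failed: {err}")

    corrected = images / model.field(images.shape)
    # preserve the remote-myocardium mean exactly
    corrected *= images[remote].mean() / corrected[remote].mean()

    cov_before = _cov(images[remote])
    cov_after = _cov(corrected[remote])
    culprit_mean = float(corrected[culprit].mean())
    remote_mean = float(corrected[remote].mean())
    applied = (cov_after < cov_before) and (culprit_mean > remote_mean)
    if applied:
        return corrected, CorrectionDecision(
            True, cov_before, cov_after, culprit_mean, remote_mean)
    reason = ("remote CoV not reduced" if cov_after >= cov_before
              else "culprit mean not above remote mean after correction")
    return images, CorrectionDecision(
        False, cov_before, cov_after, culprit_mean, remote_mean, reason)
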