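"""Synthetic CE-SSFP + LGE phantom studies with ground truth.

The generator emulates the geometry and signal behaviour the segmentation
pipeline targets: an annular left-ventricular myocardium over 8 contiguous
8 mm short-axis slices (1.5 x 1.5 mm in-plane) at end-diastole and
end-systole, a transmural, circumferentially contiguous hyperintense MaR
wedge inside one coronary territory, an infarct sub-wedge with an optional
hypointense microvascular-obstruction (MVO) core, a multiplicative
second-order surface-coil intensity gradient, and additive Gaussian noise.
The matched LGE stack has nulled normal myocardium, a hyperenhanced infarct
wedge, and a hypointense MVO core enclosed within it.

Base intensities (arbitrary units): normal myocardium 1.0, blood pool 1.8,
background 0.1; MVO attenuates CE-SSFP intensity by 0.7 over most of the
wall (radial fraction 0.1-0.9), enough to defeat pure intensity
classification so that the LGE-fusion block is exercised, while the LGE dark
core occupies the mid-wall band 0.3-0.7 so a hyperenhanced rim of at least
two pixels encloses it in-plane.  End-systolic radii are the end-diastolic
ones scaled by 0.85 with mass-preserving wall thickening.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    ARTERIES,
    SliceContours,
    VoxelGrid,
    build_maximal_extent,
    extent_center_sector,
    SECTOR_WIDTH_DEG,
)
from .study import Study

# signal model constants (arbitrary units)
NORMAL_MYO = 1.0
BLOOD_POOL = 1.8
BACKGROUND = 0.1
MVO_ATTENUATION = 0.7
MVO_RADIAL_BAND = (0.1, 0.9)       # CE-SSFP attenuation band (fraction of wall)
LGE_MVO_RADIAL_BAND = (0.3, 0.7)   # LGE dark core band: leaves a bright rim >= 2 px
LGE_NORMAL = 0.2
LGE_INFARCT = 1.0
LGE_MVO = 0.1
LGE_BLOOD = 0.9
LGE_BACKGROUND = 0.05
ES_SCALE = 0.85                    # end-systolic epicardial radius scale


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic study.

    Angles are absolute degrees in the image plane; ``mar_center_deg=None``
    centres the wedge on the culprit territory.  ``noise_sd`` is the additive
    Gaussian SD as a fraction of the normal-myocardium intensity.
    ``coil_coeffs`` are the 6 log-field polynomial coefficients
    (1, x, y, x^2, xy, y^2) in normalized in-plane coordinates, either one
    vector for all slices or one per slice.
    """

    grid: VoxelGrid = VoxelGrid(rows=128, cols=128, n_slices=8)
    epi_radius: float = 30.0        # ED epicardial radius, mm
    endo_radius: float = 20.0       # ED endocardial radius, mm
    culprit: str = "LAD"
    rv_insertion_deg: float = 120.0
    lge_rv_insertion_deg: float = 120.0
    mar_extent_deg: float = 90.0
    mar_center_deg: float | None = None
    contrast: float = 1.3           # MaR / normal intensity ratio
    infarct_extent_deg: float = 50.0
    mvo: bool = True
    mvo_extent_deg: float = 20.0
    coil_coeffs: tuple = (0.0, 0.5, 0.2, 0.3, 0.0, 0.1)
    coil_bias: bool = True
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.culprit not in ARTERIES:
            raise ValueError(f"unknown culprit {self.culprit!r}")
        if self.infarct_extent_deg > self.mar_extent_deg:
            raise ValueError("infarct wedge cannot exceed the MaR wedge")
        if self.mvo_extent_deg > self.infarct_extent_deg:
            raise ValueError("MVO core cannot exceed the infarct wedge")
        if self.contrast < 1.0:
            raise ValueError("CE-SSFP contrast ratio must be >= 1 (MaR is hyperintense)")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if not (0 < self.endo_radius < self.epi_radius):
            raise ValueError("need 0 < endocardial < epicardial radius")


@dataclass
class PhantomCase:
    """A generated study plus the generative ground truth."""

    spec: PhantomSpec
    study: Study
    truth_mar: dict                 # timeframe -> boolean volume
    truth_infarct: np.ndarray       # LGE grid
    truth_mvo: np.ndarray           # LGE grid
    truth_percent_lvm: float


def _circle(cx: float, cy: float, radius: float, n: int = 72) -> np.ndarray:
    t = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([cx + radius * np.cos(t), cy + radius * np.sin(t)])


def _es_radii(epi: float, endo: float) -> tuple[float, float]:
    """End-systolic radii: epicardium scaled, wall area (mass) preserved."""
    epi_es = ES_SCALE * epi
    endo_sq = epi_es**2 - (epi**2 - endo**2)
    if endo_sq <= 0:
        raise ValueError("end-systolic cavity collapses; radii unrealistic")
    return epi_es, float(np.sqrt(endo_sq))


def _in_wedge(theta: np.ndarray, center: float, extent: float) -> np.ndarray:
    return np.abs((theta - center + 180.0) % 360.0 - 180.0) < extent / 2.0


def default_mar_center(spec: PhantomSpec) -> float:
    """Absolute angular centre of the culprit territory at mid level."""
    extent = build_maximal_extent(spec.culprit)
    return (spec.rv_insertion_deg
            + extent_center_sector(extent, 1) * SECTOR_WIDTH_DEG) % 360.0


def generate_case(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom study; deterministic for a fixed spec (incl. seed)."""
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)
    cx = (grid.cols - 1) / 2.0 * grid.in_plane_spacing
    cy = (grid.rows - 1) / 2.0 * grid.in_plane_spacing
    center = default_mar_center(spec) if spec.mar_center_deg is None else spec.mar_center_deg

    x, y = grid.pixel_centers()
    r = np.hypot(x - cx, y - cy)
    theta = np.degrees(np.arctan2(y - cy, x - cx)) % 360.0
    mar_wedge = _in_wedge(theta, center, spec.mar_extent_deg)
    inf_wedge = _in_wedge(theta, center, spec.infarct_extent_deg)
    mvo_wedge = _in_wedge(theta, center, spec.mvo_extent_deg) if spec.mvo else np.zeros_like(mar_wedge)

    radii = {"ED": (spec.epi_radius, spec.endo_radius),
             "ES": _es_radii(spec.epi_radius, spec.endo_radius)}

    coeffs = np.asarray(spec.coil_coeffs, dtype=float)
    if coeffs.ndim == 1:
        coeffs = np.tile(coeffs, (grid.n_slices, 1))
    xh = 2.0 * np.arange(grid.cols) / (grid.cols - 1) - 1.0
    yh = 2.0 * np.arange(grid.rows) / (grid.rows - 1) - 1.0
    XH, YH = np.meshgrid(xh, yh)
    basis = np.stack([np.ones_like(XH), XH, YH, XH**2, XH * YH, YH**2])

    images: dict[str, np.ndarray] = {}
    contours: dict[str, dict[int, SliceContours]] = {}
    truth_mar: dict[str, np.ndarray] = {}
    for tf, (r_epi, r_endo) in radii.items():
        myo2d = (r >= r_endo) & (r < r_epi)
        cavity = r < r_endo
        wall_frac = np.clip((r - r_endo) / (r_epi - r_endo), 0.0, 1.0)
        core2d = (mvo_wedge & myo2d
                  & (wall_frac >= MVO_RADIAL_BAND[0]) & (wall_frac < MVO_RADIAL_BAND[1]))
        base2d = np.full(myo2d.shape, BACKGROUND)
        base2d[cavity] = BLOOD_POOL
        base2d[myo2d] = NORMAL_MYO
        base2d[myo2d & mar_wedge] = NORMAL_MYO * spec.contrast
        base2d[core2d] *= MVO_ATTENUATION

        vol = np.empty(grid.shape)
        tmask = np.empty(grid.shape, dtype=bool)
        for s in range(grid.n_slices):
            bias = np.exp(np.tensordot(coeffs[s], basis, axes=1)) if spec.coil_bias else 1.0
            vol[s] = base2d * bias
            tmask[s] = myo2d & mar_wedge
        vol += rng.normal(0.0, spec.noise_sd * NORMAL_MYO, size=vol.shape)
        images[tf] = vol.astype(np.float32)
        truth_mar[tf] = tmask
        contours[tf] = {s: SliceContours(endo=_circle(cx, cy, r_endo),
                                         epi=_circle(cx, cy, r_epi))
                        for s in range(grid.n_slices)}

    # LGE stack: ED geometry, nulled normal myocardium, bright infarct, dark MVO core
    r_epi, r_endo = radii["ED"]
    myo2d = (r >= r_endo) & (r < r_epi)
    cavity = r < r_endo
    wall_frac = np.clip((r - r_endo) / (r_epi - r_endo), 0.0, 1.0)
    core2d = (mvo_wedge & myo2d
              & (wall_frac >= LGE_MVO_RADIAL_BAND[0])
              & (wall_frac < LGE_MVO_RADIAL_BAND[1]))
    lge2d = np.full(myo2d.shape, LGE_BACKGROUND)
    lge2d[cavity] = LGE_BLOOD
    lge2d[myo2d] = LGE_NORMAL
    lge2d[myo2d & inf_wedge] = LGE_INFARCT
    lge2d[core2d & inf_wedge] = LGE_MVO
    lge = np.tile(lge2d, (grid.n_slices, 1, 1))
    lge = (lge + rng.normal(0.0, spec.noise_sd * NORMAL_MYO, size=lge.shape)).astype(np.float32)
    lge_contours = {s: SliceContours(endo=_circle(cx, cy, r_endo),
                                     epi=_circle(cx, cy, r_epi))
                    for s in range(grid.n_slices)}
    truth_infarct = np.tile(myo2d & inf_wedge, (grid.n_slices, 1, 1))
    truth_mvo = np.tile(core2d & inf_wedge, (grid.n_slices, 1, 1))

    study = Study(grid=grid, images=images, contours=contours,
                  rv_insertion_deg=spec.rv_insertion_deg, culprit=spec.culprit,
                  lge_grid=grid, lge_image=lge, lge_contours=lge_contours,
                  lge_rv_insertion_deg=spec.lge_rv_insertion_deg)
    percents = []
    for tf, (tf_epi, tf_endo) in radii.items():
        myo_count = int(((r >= tf_endo) & (r < tf_epi)).sum()) * grid.n_slices
        percents.append(100.0 * int(truth_mar[tf].sum()) / myo_count)
    pct = float(np.mean(percents))
    return PhantomCase(spec=spec, study=study, truth_mar=truth_mar,
                       truth_infarct=truth_infarct, truth_mvo=truth_mvo,
                       truth_percent_lvm=pct)


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges for a phantom cohort (study conditions)."""

    mar_extent_deg: tuple[float, float] = (60.0, 150.0)
    contrast: tuple[float, float] = (1.2, 1.5)
    noise_sd: tuple[float, float] = (0.05, 0.10)
    infarct_frac: tuple[float, float] = (0.3, 0.6)   # of the MaR wedge
    arteries: tuple[str, ...] = ("LAD", "LCx", "RCA")
    mvo_fraction: float = 0.5                        # of cases with an MVO core

    def __post_init__(self) -> None:
        for lo, hi in (self.mar_extent_deg, self.contrast, self.noise_sd,
                       self.infarct_frac):
            if hi < lo:
                raise ValueError("empty sampling range")
        if not self.arteries:
            raise ValueError("no arteries to sample")


def generate_cohort(n: int, ranges: CohortRanges | None = None,
                    seed: int = 0) -> list[PhantomCase]:
    """Generate ``n`` reproducible phantom cases with spec parameters sampled
    uniformly from ``ranges``; MVO is planted in every other case."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        wedge = rng.uniform(*ranges.mar_extent_deg)
        culprit = ranges.arteries[rng.integers(len(ranges.arteries))]
        base = PhantomSpec(culprit=culprit)
        territory_span = build_maximal_extent(culprit).coverage[1].sum() * SECTOR_WIDTH_DEG
        jitter_half = max(0.0, (territory_span - wedge) / 2.0)
        center = (default_mar_center(base)
                  + rng.uniform(-jitter_half, jitter_half)) % 360.0
        infarct = wedge * rng.uniform(*ranges.infarct_frac)
        has_mvo = (i % 2 == 0) if ranges.mvo_fraction == 0.5 else \
            bool(rng.random() < ranges.mvo_fraction)
        spec = replace(
            base,
            mar_extent_deg=float(wedge),
            mar_center_deg=float(center),
            contrast=float(rng.uniform(*ranges.contrast)),
            noise_sd=float(rng.uniform(*ranges.noise_sd)),
            infarct_extent_deg=float(infarct),
            mvo=has_mvo,
            mvo_extent_deg=float(min(base.mvo_extent_deg, infarct)),
            seed=int(rng.integers(2**31 - 1)),
        )
        cases.append(generate_case(spec))
    return cases
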