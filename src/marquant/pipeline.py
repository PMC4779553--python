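"""A priori regional criteria, LGE fusion, and the full segmentation pipeline.

The automatic algorithm runs four processing blocks per cine timeframe:

1. surface-coil intensity correction (:mod:`marquant.coil`), applied only if
   beneficial;
2. two-class Gaussian-mixture EM classification of myocardial intensities
   (:mod:`marquant.em`), initialized from the culprit artery's maximal-extent
   territory;
3. a priori regional criteria — the EM classification is aggregated sector
   wise within the maximal-extent territory, the largest circumferentially
   contiguous run of MaR sectors per slice is kept, and MaR is assumed
   transmural;
4. fusion of the infarct region from LGE — sectors containing infarct are
   forced into MaR even when microvascular obstruction (MVO) suppresses their
   CE-SSFP intensity.

MaR size is reported as percent of left-ventricular mass (%LVM), averaged
over the available timeframes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .coil import CorrectionDecision, correct_if_beneficial
from .em import EMConfig, GaussianMixtureFit, em_fit, initialize_from_extent, mixture_delta_bic
from .geometry import (
    LEVELS,
    N_SECTORS,
    MaximalExtentModel,
    SectorMap,
    build_maximal_extent,
    divide_sectors,
    endo_centroids,
    extent_center_sector,
    extent_region,
    polygon_mask,
    rasterize_contours,
    remote_region,
)
from .study import Study


@dataclass
class SectorLabels:
    """Boolean MaR flag per (slice, sector); ``fused`` marks LGE-forced sectors."""

    flags: np.ndarray                    # (n_slices, 24) bool
    fused: np.ndarray | None = None      # (n_slices, 24) bool, provenance

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2 or self.flags.shape[1] != N_SECTORS:
            raise ValueError("flags must be (n_slices, 24)")
        if self.fused is None:
            self.fused = np.zeros_like(self.flags)


def classify_sectors(posterior: np.ndarray, sector_map: SectorMap,
                     extent: MaximalExtentModel, cut: float = 0.5) -> SectorLabels:
    """Sector-wise EM classification within the maximal-extent territory.

    A sector is flagged MaR when the mean MaR posterior over its voxels is
    strictly greater than ``cut``; sectors outside the territory are never
    flagged here.
    """
    posterior = np.asarray(posterior, dtype=float)
    if posterior.min() < 0 or posterior.max() > 1:
        raise ValueError("posteriors must lie in [0, 1]")
    labels, levels = sector_map.labels, sector_map.levels
    flags = np.zeros((labels.shape[0], N_SECTORS), dtype=bool)
    n_empty = 0
    for s in range(labels.shape[0]):
        if levels[s] < 0:
            continue
        lab = labels[s]
        myo = lab >= 0
        counts = np.bincount(lab[myo], minlength=N_SECTORS)
        sums = np.bincount(lab[myo], weights=posterior[s][myo], minlength=N_SECTORS)
        in_extent = extent.coverage[levels[s]]
        n_empty += int((in_extent & (counts == 0)).sum())
        with np.errstate(invalid="ignore"):
            mean_post = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        flags[s] = in_extent & (counts > 0) & (mean_post > cut)
    if n_empty:
        warnings.warn(f"{n_empty} territory sectors had no voxels and were left unflagged")
    return SectorLabels(flags=flags)


def _runs(flag_seq: np.ndarray, circular: bool) -> list[tuple[int, int]]:
    """(start, length) of maximal True runs in a sequence, optionally circular."""
    n = len(flag_seq)
    if not flag_seq.any():
        return []
    if flag_seq.all():
        return [(0, n)]
    runs = []
    seq = flag_seq
    offset = 0
    if circular:
        # rotate so the sequence starts on a False element; runs never wrap then
        first_false = int(np.flatnonzero(~flag_seq)[0])
        seq = np.roll(flag_seq, -first_false)
        offset = first_false
    start = None
    for i, f in enumerate(seq):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append(((start + offset) % n, i - start))
            start = None
    if start is not None:
        runs.append(((start + offset) % n, len(seq) - start))
    return runs


def enforce_continuity(labels: SectorLabels, extent: MaximalExtentModel,
                       levels: np.ndarray) -> SectorLabels:
    """Keep only the largest circumferentially contiguous run of MaR sectors.

    Applied per slice over the sectors of the maximal-extent territory
    (circular adjacency restricted to the territory); ties are broken toward
    the run closer to the territory's angular centre.  Flags outside the
    territory (LGE-forced) pass through unchanged.
    """
    out = np.array(labels.flags, copy=True)
    for s in range(out.shape[0]):
        if levels[s] < 0:
            continue
        covered = extent.coverage[levels[s]]
        inside = out[s] & covered
        if not inside.any():
            out[s] = out[s] & ~covered
            continue
        if covered.all():
            order = np.arange(N_SECTORS)
            circular = True
        else:
            start = int(np.flatnonzero(covered & ~np.roll(covered, 1))[0])
            order = np.array([(start + k) % N_SECTORS
                              for k in range(int(covered.sum()))])
            circular = False
        seq = inside[order]
        runs = _runs(seq, circular=circular)
        best_len = max(length for _, length in runs)
        center = extent_center_sector(extent, int(levels[s]))
        best = None
        for start_i, length in runs:
            if length != best_len:
                continue
            mid = (order[start_i] + (length - 1) / 2.0) % N_SECTORS
            d = abs((mid - center + N_SECTORS / 2) % N_SECTORS - N_SECTORS / 2)
            if best is None or d < best[0]:
                best = (d, start_i, length)
        _, start_i, length = best
        keep = np.zeros(N_SECTORS, dtype=bool)
        keep[order[[(start_i + k) % len(order) for k in range(length)]]] = True
        out[s] = (out[s] & ~covered) | keep
    return SectorLabels(flags=out, fused=labels.fused)


def make_transmural(labels: SectorLabels, sector_map: SectorMap) -> np.ndarray:
    """Expand flagged sectors to all their myocardial voxels (endo to epi)."""
    lab = sector_map.labels
    out = np.zeros(lab.shape, dtype=bool)
    for s in range(lab.shape[0]):
        myo = lab[s] >= 0
        out[s][myo] = labels.flags[s][lab[s][myo]]
    return out


@dataclass
class InfarctMask:
    """Binary infarct and microvascular-obstruction (MVO) masks on the LGE grid.

    MVO voxels — hypointense cores fully enclosed by hyperenhanced infarct —
    count as 100 % infarction.
    """

    infarct: np.ndarray
    mvo: np.ndarray
    threshold: float

    def fraction(self) -> np.ndarray:
        """Per-voxel infarct fraction: 1.0 inside the infarct (incl. MVO), else 0."""
        return np.where(self.infarct, 1.0, 0.0)


def lge_infarct_helper(lge_image: np.ndarray, lge_myo: np.ndarray,
                       lge_sector_map: SectorMap, extent: MaximalExtentModel,
                       min_region_frac: float = 0.01) -> InfarctMask:
    """Simplified LGE infarct delineation for block-4 fusion.

    Threshold = remote mean + 1.8 x remote SD; suprathreshold myocardial
    voxels are kept after discarding in-plane connected components smaller
    than ``min_region_frac`` of the slice's myocardial voxel count; enclosed
    hypointense regions are marked MVO and included as 100 % infarction.
    """
    lge_image = np.asarray(lge_image, dtype=float)
    lge_myo = np.asarray(lge_myo, dtype=bool)
    remote = remote_region(lge_sector_map, extent) & lge_myo
    if not remote.any():
        raise ValueError("empty LGE remote region: infarct threshold undefined")
    vals = lge_image[remote]
    thr = float(vals.mean() + 1.8 * vals.std(ddof=1))

    supra = lge_myo & (lge_image > thr)
    filtered = np.zeros_like(supra)
    mvo = np.zeros_like(supra)
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity in plane
    for s in range(supra.shape[0]):
        comp, n = ndimage.label(supra[s], structure=structure)
        if n == 0:
            continue
        min_size = max(1, int(round(min_region_frac * lge_myo[s].sum())))
        sizes = np.bincount(comp.ravel())[1:]
        keep = np.isin(comp, 1 + np.flatnonzero(sizes >= min_size)) & supra[s]
        filtered[s] = keep
        mvo[s] = ndimage.binary_fill_holes(keep) & lge_myo[s] & ~keep
    return InfarctMask(infarct=filtered | mvo, mvo=mvo, threshold=thr)


def sectorize_infarct(infarct: InfarctMask, lge_sector_map: SectorMap) -> np.ndarray:
    """(3 levels, 24 sectors) boolean: which sectors contain infarct per level."""
    out = np.zeros((len(LEVELS), N_SECTORS), dtype=bool)
    labels, levels = lge_sector_map.labels, lge_sector_map.levels
    for s in range(labels.shape[0]):
        if levels[s] < 0:
            continue
        sect = labels[s][infarct.infarct[s] & (labels[s] >= 0)]
        out[levels[s], np.unique(sect)] = True
    return out


def fuse_lge(labels: SectorLabels, infarct_level_sectors: np.ndarray,
             levels: np.ndarray, extent: MaximalExtentModel) -> SectorLabels:
    """Force infarct-containing sectors into MaR (matched by level and index).

    Applied before continuity enforcement; infarct outside the territory is
    still fused (infarct is by definition within MaR) with a warning.
    """
    flags = np.array(labels.flags, copy=True)
    fused = np.array(labels.fused, copy=True)
    outside = 0
    for s in range(flags.shape[0]):
        if levels[s] < 0:
            continue
        add = infarct_level_sectors[levels[s]]
        fused[s] |= add & ~flags[s]
        flags[s] |= add
        outside += int((add & ~extent.coverage[levels[s]]).sum())
    if outside:
        warnings.warn(f"infarct found in {outside} sector slots outside the "
                      "culprit territory; fused into MaR anyway")
    return SectorLabels(flags=flags, fused=fused)


# ---------------------------------------------------------------------------
# Top-level pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters (all defaults are the shipped behaviour)."""

    em: EMConfig = field(default_factory=EMConfig)
    sector_cut: float = 0.5          # mean-posterior cut for sector flagging
    min_region_frac: float = 0.01    # LGE component filter, fraction of myo voxels
    blocks: int = 4                  # 1=EM, 2=+correction, 3=+a priori, 4=+LGE

    def __post_init__(self) -> None:
        if not 1 <= self.blocks <= 4:
            raise ValueError("blocks must be 1..4")


@dataclass
class MaRResult:
    """Final MaR segmentation with full per-block provenance."""

    masks: dict                     # timeframe -> boolean volume
    myo_masks: dict                 # timeframe -> boolean volume
    percent_lvm: float
    provenance: dict                # JSON-serializable audit trail
    infarct: InfarctMask | None = None


def _blood_pool_mask(study: Study, timeframe: str) -> np.ndarray:
    """Endocardial interior eroded by one pixel (avoids the partial-volume rim)."""
    out = np.zeros(study.grid.shape, dtype=bool)
    for s, sc in study.contours[timeframe].items():
        endo = polygon_mask(sc.endo, study.grid)
        out[s] = ndimage.binary_erosion(endo)
    return out


def run_segment_mar(study: Study, config: PipelineConfig | None = None) -> MaRResult:
    """Run the four-block automatic MaR segmentation on a study.

    ``config.blocks`` truncates the pipeline for incremental-value analysis:
    1 = EM classification only (voxel-wise posterior >= 0.5),
    2 = + coil correction, 3 = + a priori regional criteria (sector-wise
    classification, continuity, transmurality), 4 = + LGE infarct fusion.
    Deterministic: same study and config give a bit-identical result.
    """
    config = config or PipelineConfig()
    extent = build_maximal_extent(study.culprit, study.territory_table)

    infarct = None
    infarct_sectors = None
    if config.blocks >= 4:
        if study.has_lge:
            lge_myo = rasterize_contours({"LGE": study.lge_contours},
                                         study.lge_grid, "LGE")
            lge_cents = endo_centroids({"LGE": study.lge_contours}, "LGE")
            lge_smap = divide_sectors(lge_myo, lge_cents,
                                      study.lge_rv_insertion_deg, study.lge_grid)
            infarct = lge_infarct_helper(study.lge_image, lge_myo, lge_smap,
                                         extent, config.min_region_frac)
            infarct_sectors = sectorize_infarct(infarct, lge_smap)
        else:
            warnings.warn("block 4 skipped: no LGE stack in study")

    if len(study.timeframes) < 2:
        warnings.warn("single-timeframe study: %LVM from one timeframe only")

    masks: dict[str, np.ndarray] = {}
    myo_masks: dict[str, np.ndarray] = {}
    percents: list[float] = []
    provenance: dict = {"blocks": config.blocks, "culprit": study.culprit,
                        "timeframes": {}}

    for tf in study.timeframes:
        myo = rasterize_contours(study.contours, study.grid, tf)
        cents = endo_centroids(study.contours, tf)
        smap = divide_sectors(myo, cents, study.rv_insertion_deg, study.grid)
        images = np.asarray(study.images[tf], dtype=float)

        if config.blocks >= 2:
            blood = _blood_pool_mask(study, tf)
            corrected, decision = correct_if_beneficial(images, blood, smap, extent)
        else:
            corrected, decision = images, CorrectionDecision(
                False, reason="correction block disabled")

        x = corrected[myo]
        inside = extent_region(smap, extent)[myo]
        init = initialize_from_extent(x, inside, config.em)
        em_res = em_fit(x, init, config.em)
        delta_bic = mixture_delta_bic(x, em_res.fit)
        post = np.zeros(images.shape, dtype=float)
        if delta_bic > 0:
            post[myo] = em_res.fit.posterior_mar(x)
        else:
            # no evidence of a second intensity class: nothing to segment
            warnings.warn(f"{tf}: mixture not supported over a single Gaussian "
                          "(no MaR intensity signal); empty classification")

        tf_prov: dict = {
            "correction": decision.to_dict(),
            "em": {**em_res.fit.to_dict(), "n_iter": em_res.n_iter,
                   "converged": em_res.converged, "delta_bic": delta_bic},
        }

        if config.blocks <= 2:
            mar = myo & (post >= 0.5)
        else:
            raw = classify_sectors(post, smap, extent, cut=config.sector_cut)
            tf_prov["sectors_em"] = raw.flags.tolist()
            if infarct_sectors is not None:
                raw = fuse_lge(raw, infarct_sectors, smap.levels, extent)
                tf_prov["sectors_fused"] = raw.fused.tolist()
            final = enforce_continuity(raw, extent, smap.levels)
            if infarct_sectors is not None:
                # the fusion contract outranks continuity: infarct sectors stay MaR
                dropped = raw.fused & ~final.flags
                if dropped.any():
                    warnings.warn("continuity dropped fused infarct sectors; restored")
                    final = SectorLabels(flags=final.flags | dropped, fused=raw.fused)
            tf_prov["sectors_final"] = final.flags.tolist()
            mar = make_transmural(final, smap)

        masks[tf] = mar
        myo_masks[tf] = myo
        percents.append(100.0 * int(mar.sum()) / int(myo.sum()))
        tf_prov["percent_lvm"] = percents[-1]
        provenance["timeframes"][tf] = tf_prov

    if infarct is not None:
        provenance["lge"] = {
            "threshold": infarct.threshold,
            "n_infarct_voxels": int(infarct.infarct.sum()),
            "n_mvo_voxels": int(infarct.mvo.sum()),
        }

    return MaRResult(masks=masks, myo_masks=myo_masks,
                     percent_lvm=float(np.mean(percents)),
                     provenance=provenance, infarct=infarct)
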