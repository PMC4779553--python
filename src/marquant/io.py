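"""Readers and writers binding the pipeline to disk.

Primary on-disk format: NIfTI-1 volumes (grid-explicit, widely supported)
plus a JSON annotation sidecar carrying contours (mm point lists per slice
and timeframe), RV insertion angles, and the culprit artery.  DICOM series
are supported read-only.  A study directory is described by a
``study.json`` manifest:

.. code-block:: json

    {"cine": {"ED": "cine_ed.nii", "ES": "cine_es.nii"},
     "lge": "lge.nii",
     "annotations": "annotations.json"}

``lge`` is optional; without it the pipeline skips the infarct-fusion block.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import SliceContours, VoxelGrid
from .phantom import PhantomCase
from .pipeline import MaRResult
from .study import Study

MANIFEST = "study.json"


def _grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    zooms = img.header.get_zooms()[:3]
    if not np.isclose(zooms[0], zooms[1]):
        raise ValueError("anisotropic in-plane spacing is not supported")
    cols, rows, n_slices = img.shape[:3]
    return VoxelGrid(rows=rows, cols=cols, n_slices=n_slices,
                     in_plane_spacing=float(zooms[0]), slice_thickness=float(zooms[2]))


def _volume_to_nifti(vol: np.ndarray, grid: VoxelGrid) -> nib.Nifti1Image:
    # store as (x=col, y=row, z=slice) so NIfTI zooms line up with the grid
    data = np.ascontiguousarray(np.transpose(vol, (2, 1, 0)))
    affine = np.diag([grid.in_plane_spacing, grid.in_plane_spacing,
                      grid.slice_thickness, 1.0])
    return nib.Nifti1Image(data, affine)


def _nifti_to_volume(img: nib.Nifti1Image) -> np.ndarray:
    return np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))


def write_volume(vol: np.ndarray, grid: VoxelGrid, path: Path) -> None:
    nib.save(_volume_to_nifti(vol, grid), str(path))


def read_volume(path: Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    return _nifti_to_volume(img), _grid_from_nifti(img)


def _contours_to_json(contours) -> dict:
    return {str(s): {"endo": sc.endo.tolist(), "epi": sc.epi.tolist()}
            for s, sc in contours.items()}


def _contours_from_json(obj: dict, n_slices: int) -> dict[int, SliceContours]:
    out = {}
    for key, sc in obj.items():
        s = int(key)
        if not 0 <= s < n_slices:
            raise ValueError(f"annotation slice index {s} out of range")
        out[s] = SliceContours(endo=np.asarray(sc["endo"]), epi=np.asarray(sc["epi"]))
    return out


def write_study(case_or_study, out_dir: Path) -> Path:
    """Write a study (or phantom case) directory in the pipeline's input format."""
    study = case_or_study.study if isinstance(case_or_study, PhantomCase) else case_or_study
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"cine": {}, "annotations": "annotations.json"}
    for tf, img in study.images.items():
        name = f"cine_{tf.lower()}.nii"
        write_volume(np.asarray(img), study.grid, out_dir / name)
        manifest["cine"][tf] = name
    ann: dict = {
        "culprit": study.culprit,
        "rv_insertion_deg": {"cine": study.rv_insertion_deg},
        "contours": {"cine": {tf: _contours_to_json(study.contours[tf])
                              for tf in study.images}},
    }
    if study.has_lge:
        write_volume(np.asarray(study.lge_image), study.lge_grid, out_dir / "lge.nii")
        manifest["lge"] = "lge.nii"
        ann["rv_insertion_deg"]["lge"] = study.lge_rv_insertion_deg
        ann["contours"]["lge"] = _contours_to_json(study.lge_contours)
    (out_dir / "annotations.json").write_text(json.dumps(ann))
    (out_dir / MANIFEST).write_text(json.dumps(manifest, indent=2))
    return out_dir


def load_study(path: Path) -> Study:
    """Load and validate a study directory written in the manifest format."""
    path = Path(path)
    manifest = json.loads((path / MANIFEST).read_text())
    ann = json.loads((path / manifest["annotations"]).read_text())
    if "culprit" not in ann:
        raise ValueError("annotations missing the culprit artery")

    images, grids = {}, {}
    for tf, name in manifest["cine"].items():
        images[tf], grids[tf] = read_volume(path / name)
    grid = next(iter(grids.values()))
    if any(g != grid for g in grids.values()):
        raise ValueError("cine timeframes do not share one voxel grid")

    contours = {tf: _contours_from_json(ann["contours"]["cine"][tf], grid.n_slices)
                for tf in images}
    kwargs: dict = {}
    if "lge" in manifest:
        lge_img, lge_grid = read_volume(path / manifest["lge"])
        kwargs = {
            "lge_image": lge_img,
            "lge_grid": lge_grid,
            "lge_contours": _contours_from_json(ann["contours"]["lge"], lge_grid.n_slices),
            "lge_rv_insertion_deg": float(ann["rv_insertion_deg"]["lge"]),
        }
    else:
        warnings.warn("study has no LGE stack; infarct fusion will be skipped")
    return Study(grid=grid, images=images, contours=contours,
                 rv_insertion_deg=float(ann["rv_insertion_deg"]["cine"]),
                 culprit=ann["culprit"], **kwargs)


def write_result(result: MaRResult, grid: VoxelGrid, out_dir: Path) -> Path:
    """Write MaR masks (uint8 NIfTI per timeframe) and the JSON report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for tf, mask in result.masks.items():
        write_volume(mask.astype(np.uint8), grid, out_dir / f"mar_{tf.lower()}.nii")
    report = {"percent_lvm": result.percent_lvm, "provenance": result.provenance}
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    row = {"percent_lvm": result.percent_lvm, "blocks": result.provenance["blocks"],
           **{f"corrected_{tf.lower()}": p["correction"]["applied"]
              for tf, p in result.provenance["timeframes"].items()}}
    pd.DataFrame([row]).to_csv(out_dir / "summary.csv", index=False)
    return out_dir


def read_result_masks(out_dir: Path) -> dict[str, np.ndarray]:
    """Re-read written MaR masks as boolean volumes (round-trip exact)."""
    out_dir = Path(out_dir)
    out = {}
    for p in sorted(out_dir.glob("mar_*.nii")):
        tf = p.stem.split("_", 1)[1].upper()
        vol, _ = read_volume(p)
        out[tf] = vol.astype(bool)
    return out


def read_dicom_series(directory: Path) -> tuple[np.ndarray, VoxelGrid]:
    """Read one short-axis DICOM series (read-only convenience).

    Slices are sorted by InstanceNumber (falling back to SliceLocation).
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: (int(getattr(d, "InstanceNumber", 0)),
                                 float(getattr(d, "SliceLocation", 0.0))))
    vol = np.stack([d.pixel_array.astype(float) for d in datasets])
    first = datasets[0]
    spacing = float(first.PixelSpacing[0])
    thickness = float(getattr(first, "SliceThickness", 8.0))
    rows, cols = vol.shape[1:]
    return vol, VoxelGrid(rows=rows, cols=cols, n_slices=vol.shape[0],
                          in_plane_spacing=spacing, slice_thickness=thickness)
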