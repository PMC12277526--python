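"""NIfTI / FSL-gradient / CSV / JSON input-output."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from dtialps.scheme import AcquisitionScheme
from dtialps.tensor import DWIDataset, DiffusivityMaps
from dtialps.hippocampus import LabelVolume
from dtialps.alps import ROISpec

log = logging.getLogger("dtialps")


def read_dwi(nifti_path, bvals_path, bvecs_path, mask_path=None) -> DWIDataset:
    """Load a 4-D DWI NIfTI with FSL-style bvals/bvecs text tables.

    bvals: one row of b-values; bvecs: three rows of direction components.
    Directions that are off unit norm by more than 1e-3 are renormalized
    with a logged warning. Raises on non-4D images or length mismatches.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D DWI image, got {data.ndim}-D")
    bvals = np.atleast_1d(np.loadtxt(str(bvals_path), dtype=float)).ravel()
    bvecs = np.atleast_2d(np.loadtxt(str(bvecs_path), dtype=float))
    if bvecs.shape[0] != 3:
        bvecs = bvecs.T
    if bvecs.shape[0] != 3:
        raise ValueError("bvecs must have three rows (x, y, z components)")
    if bvals.size != data.shape[-1] or bvecs.shape[1] != data.shape[-1]:
        raise ValueError(
            f"gradient table length mismatch: image has {data.shape[-1]} volumes, "
            f"bvals {bvals.size}, bvecs {bvecs.shape[1]} columns"
        )
    g = bvecs.T.copy()
    nz = bvals > 0
    norms = np.linalg.norm(g[nz], axis=1)
    if np.any(norms == 0):
        raise ValueError("zero gradient direction at b > 0")
    if np.any(np.abs(norms - 1.0) > 1e-3):
        log.warning("renormalizing %d bvecs off unit norm by > 1e-3", int((np.abs(norms - 1) > 1e-3).sum()))
    g[nz] /= norms[:, None]
    g[~nz] = 0.0
    scheme = AcquisitionScheme(bvals, g)
    voxel_size = float(np.mean(img.header.get_zooms()[:3]))
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
    return DWIDataset(
        signal=np.clip(data, 0, None),
        scheme=scheme,
        voxel_size=voxel_size,
        mask=mask,
        affine=np.asarray(img.affine),
    )


def write_dwi(dataset: DWIDataset, nifti_path, bvals_path, bvecs_path) -> None:
    """Write a DWI dataset as NIfTI plus FSL bvals/bvecs text files."""
    img = nib.Nifti1Image(np.asarray(dataset.signal, dtype=np.float32), dataset.affine)
    nib.save(img, str(nifti_path))
    np.savetxt(str(bvals_path), dataset.scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(str(bvecs_path), dataset.scheme.directions.T, fmt="%.9f")


def write_maps(maps: DiffusivityMaps, out_dir, prefix: str = "") -> dict[str, Path]:
    """Write each scalar map as float32 NIfTI preserving the affine."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = maps.affine if maps.affine is not None else np.eye(4)
    paths = {}
    for name in ("dxx", "dyy", "dzz", "fa", "md", "ad", "rd"):
        arr = getattr(maps, name).astype(np.float32)
        p = out_dir / f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr, affine), str(p))
        paths[name] = p
    return paths


def read_labels(nifti_path, names_json=None) -> LabelVolume:
    """Load an integer label volume, with an optional JSON ID→name dictionary."""
    img = nib.load(str(nifti_path))
    arr = np.asarray(img.get_fdata())
    lab = np.rint(arr).astype(np.int32)
    if np.max(np.abs(arr - lab)) > 1e-6:
        raise ValueError("label volume contains non-integer values")
    names = {}
    if names_json is not None:
        with open(names_json) as fh:
            names = {int(k): str(v) for k, v in json.load(fh).items()}
    voxel_size = float(np.mean(img.header.get_zooms()[:3]))
    return LabelVolume(labels=lab, names=names, voxel_size=voxel_size, affine=np.asarray(img.affine))


def read_rois_json(path) -> tuple[ROISpec, ...]:
    """ROI override file: JSON list of {name, side, fiber, center, diameter}."""
    with open(path) as fh:
        entries = json.load(fh)
    rois = tuple(
        ROISpec(
            name=e.get("name", f"{e['side']}_{e['fiber']}"),
            side=e["side"],
            fiber=e["fiber"],
            center=tuple(int(v) for v in e["center"]),
            diameter=float(e.get("diameter", 5.0)),
        )
        for e in entries
    )
    if len(rois) != 4:
        raise ValueError(f"ROI file must define exactly 4 ROIs, found {len(rois)}")
    return rois


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
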