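"""Readers and writers for on-disk artifacts.

NIfTI volumes go through nibabel; the diffusion gradient table uses the FSL
text dialect (.bval: one whitespace-separated row; .bvec: three rows x/y/z).
Tensor volumes are stored with 6 components per voxel in LOWER-triangular
order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz) — the header description records this,
since the ecosystem has competing conventions; in memory the package uses
row-major upper-triangle order (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz).

All writers are deterministic: fixed field order, no timestamps, so identical
inputs give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .glyphs import GlyphMesh
from .invariants import INVARIANT_UNITS, ScalarMap
from .synthetic_phantom import PhantomSpec, ROISet
from .tensor_model import DWIVolume, TensorField

# on-disk (FSL/lower-tri) position of each in-memory component
_MEM_TO_DISK = [0, 1, 3, 2, 4, 5]  # xx,xy,xz,yy,yz,zz -> xx,xy,yy,xz,yz,zz
_DISK_TO_MEM = np.argsort(_MEM_TO_DISK)
TENSOR_DESCRIP = b"tensor lower-tri: Dxx Dxy Dyy Dxz Dyz Dzz [mm^2/s]"


def _save_nifti(path, data, affine, descrip: bytes = b"", dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), np.asarray(affine))
    img.header["descrip"] = descrip[:79]
    # scanner timing metadata is meaningless for synthetic/derived volumes
    img.header["cal_max"] = 0
    img.header["cal_min"] = 0
    nib.save(img, str(path))


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIVolume:
    """Load a 4D DWI NIfTI with its FSL-style gradient table."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected a 4D DWI volume, got {data.ndim}D")
    bvals, bvecs = read_bval_bvec(bval_path, bvec_path)
    if len(bvals) != data.shape[3]:
        raise ValueError(
            f"gradient count mismatch: {len(bvals)} bvals vs {data.shape[3]} volumes"
        )
    te = None
    return DWIVolume(signal=data, bvals=bvals, bvecs=bvecs, affine=img.affine, TE=te)


def read_bval_bvec(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Whitespace-tolerant FSL .bval (one row) / .bvec (three rows) parser."""
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    if bvecs.ndim != 2 or bvecs.shape[1] != 3:
        raise ValueError(f"{bvec_path}: expected 3 rows (x/y/z) of gradient components")
    if bvecs.shape[0] != len(bvals):
        raise ValueError(
            f"gradient count mismatch: {len(bvals)} bvals vs {bvecs.shape[0]} bvecs"
        )
    return bvals, bvecs


def write_dwi(prefix, dwi: DWIVolume) -> tuple[Path, Path, Path]:
    """Write <prefix>.nii.gz / .bval / .bvec (FSL row-major text)."""
    prefix = Path(prefix)
    nii = prefix.with_suffix(".nii.gz")
    _save_nifti(nii, dwi.signal, dwi.affine, b"synthetic DWI signal")
    bval = prefix.with_suffix(".bval")
    bvec = prefix.with_suffix(".bvec")
    with open(bval, "w") as f:
        f.write(" ".join(f"{b:g}" for b in dwi.bvals) + "\n")
    with open(bvec, "w") as f:
        for row in dwi.bvecs.T:
            f.write(" ".join(f"{x:.10f}" for x in row) + "\n")
    return nii, bval, bvec


def write_tensor(path, fld: TensorField) -> Path:
    """Write a tensor field as (x,y,z,6) float32 NIfTI, lower-tri order."""
    path = Path(path)
    _save_nifti(path, fld.D[..., _MEM_TO_DISK], fld.affine, TENSOR_DESCRIP)
    return path


def read_tensor(path, mask: np.ndarray | None = None) -> TensorField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 6:
        raise ValueError(f"{path}: expected (x,y,z,6) tensor volume, got {data.shape}")
    if mask is None:
        mask = np.any(data != 0, axis=3)
    return TensorField(D=data[..., _DISK_TO_MEM], mask=mask, affine=img.affine)


def write_map(path, m: ScalarMap) -> Path:
    """Float32 NIfTI with the invariant name and units in the description.

    The mask is encoded as a zero-filled main volume plus a sidecar
    ``<stem>_mask`` volume, so values stay NaN-free.
    """
    path = Path(path)
    unit = INVARIANT_UNITS.get(m.name.replace("_norm", ""), "")
    desc = f"{m.name} [{unit}]".encode() if unit else m.name.encode()
    vals = np.where(m.mask, m.values, 0.0)
    _save_nifti(path, vals, m.affine, desc)
    base = str(path)
    for ext in (".nii.gz", ".nii"):
        if base.endswith(ext):
            mask_path = base[: -len(ext)] + "_mask" + ext
            break
    else:
        mask_path = base + "_mask.nii.gz"
    _save_nifti(mask_path, m.mask.astype(np.uint8), m.affine, b"mask", dtype=np.uint8)
    return path


def read_map(path, name: str = "") -> ScalarMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar map, got {data.ndim}D")
    base = str(path)
    mask = None
    for ext in (".nii.gz", ".nii"):
        if base.endswith(ext):
            mp = Path(base[: -len(ext)] + "_mask" + ext)
            if mp.exists():
                mask = np.asarray(nib.load(str(mp)).dataobj) > 0
            break
    if not name:
        name = img.header["descrip"].tobytes().decode(errors="ignore").split(" [")[0].strip("\x00")
    return ScalarMap(values=data, mask=mask, affine=img.affine, name=name)


def write_roi(path, rois: ROISet) -> Path:
    path = Path(path)
    _save_nifti(path, rois.labels, rois.affine, b"ROI labels 1=T 2=E 3=GM 4=WM", dtype=np.int16)
    return path


def read_roi(path) -> ROISet:
    img = nib.load(str(path))
    return ROISet(labels=np.asarray(img.dataobj).astype(np.int16), affine=img.affine)


def write_mesh(path, mesh: GlyphMesh, fmt: str | None = None) -> Path:
    """Export a glyph mesh: binary little-endian PLY with uchar RGB, or OBJ
    (positions/faces, plus a ``.colors.csv`` sidecar when colors exist)."""
    path = Path(path)
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    tm = mesh.placed().trimesh if not np.allclose(mesh.transform, np.eye(4)) else mesh.trimesh
    if fmt == "ply":
        path.write_bytes(tm.export(file_type="ply", encoding="binary"))
    elif fmt == "obj":
        path.write_text(tm.export(file_type="obj", include_color=False))
        if mesh.vertex_colors is not None:
            pd.DataFrame(
                np.clip(mesh.vertex_colors, 0, 1), columns=["r", "g", "b"]
            ).to_csv(path.with_suffix(".colors.csv"), index=False, float_format="%.6f")
    else:
        raise ValueError(f"unsupported mesh format {fmt!r} (use ply or obj)")
    return path


def read_mesh(path) -> GlyphMesh:
    tm = trimesh_load(str(path))
    colors = None
    if hasattr(tm.visual, "vertex_colors") and len(tm.visual.vertex_colors):
        colors = np.asarray(tm.visual.vertex_colors[:, :3], dtype=float) / 255.0
    return GlyphMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        vertex_colors=colors,
    )


def trimesh_load(path):
    import trimesh

    return trimesh.load(path, process=False)


def write_phantom_spec(path, spec: PhantomSpec) -> Path:
    path = Path(path)
    d = asdict(spec)
    d["shape"] = list(d["shape"])
    d["voxel_size"] = list(d["voxel_size"])
    d["eigenvalues"] = {k: list(v) for k, v in d["eigenvalues"].items()}
    with open(path, "w") as f:
        yaml.safe_dump(d, f, sort_keys=True)
    return path


def read_phantom_spec(path) -> PhantomSpec:
    with open(path) as f:
        d = yaml.safe_load(f)
    if d.get("shape"):
        d["shape"] = tuple(d["shape"])
    if d.get("voxel_size"):
        d["voxel_size"] = tuple(d["voxel_size"])
    if d.get("core_center"):
        d["core_center"] = tuple(d["core_center"])
    return PhantomSpec(**d)


def write_manifest(path, rows: list[dict]) -> Path:
    """Cohort manifest CSV: subject_id, map_<invariant> paths, roi path."""
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_stats_report(path, stats_obj) -> Path:
    path = Path(path)
    path.write_text(stats_obj.to_json() + "\n")
    return path


def write_means_csv(path, means: pd.DataFrame) -> Path:
    path = Path(path)
    means.to_csv(path, index=False, float_format="%.10g")
    return path
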