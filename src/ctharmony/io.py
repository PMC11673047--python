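"""On-disk formats: NIfTI protocol stacks, DICOM series reading, ROI JSON,
and CSV feature/ICC tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import ProtocolStack, ROI, ROISet


class AlignmentError(ValueError):
    pass


def _affine(pixel_spacing_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_spacing_mm
    return aff


def write_stack(stack: ProtocolStack, out_dir: str | Path) -> Path:
    """One NIfTI per protocol plus a sidecar JSON with labels and target."""
    out = Path(out_dir) / stack.subject_id
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(stack.pixel_spacing_mm)
    for label, img in stack.images.items():
        nib.save(nib.Nifti1Image(img.astype(np.float64), aff), out / f"{label}.nii")
    meta = {
        "subject_id": stack.subject_id,
        "protocols": sorted(stack.images),
        "target_label": stack.target_label,
        "pixel_spacing_mm": stack.pixel_spacing_mm,
    }
    (out / "stack.json").write_text(json.dumps(meta, indent=2))
    return out


def read_stack(stack_dir: str | Path) -> ProtocolStack:
    """Read a directory written by :func:`write_stack`; checks alignment."""
    stack_dir = Path(stack_dir)
    meta = json.loads((stack_dir / "stack.json").read_text())
    images: Dict[str, np.ndarray] = {}
    shape_ref: Optional[Tuple[int, ...]] = None
    aff_ref: Optional[np.ndarray] = None
    for label in meta["protocols"]:
        img = nib.load(stack_dir / f"{label}.nii")
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if shape_ref is None:
            shape_ref, aff_ref = arr.shape, img.affine
        elif arr.shape != shape_ref or not np.allclose(img.affine, aff_ref):
            raise AlignmentError(f"{label}.nii is misaligned with the other protocols")
        images[label] = arr
    return ProtocolStack(
        subject_id=meta["subject_id"],
        images=images,
        target_label=meta["target_label"],
        pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
    )


def read_dicom_series(paths: List[str | Path], labels: List[str],
                      target_label: str, subject_id: str) -> ProtocolStack:
    """Assemble aligned single-slice DICOM files into a protocol stack.

    Files must already be pixel-aligned reconstructions of one acquisition;
    no resampling is performed.
    """
    import pydicom

    images: Dict[str, np.ndarray] = {}
    spacing: Optional[float] = None
    shape_ref = None
    for path, label in zip(paths, labels):
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = arr * slope + intercept
        if shape_ref is None:
            shape_ref = hu.shape
            spacing = float(ds.PixelSpacing[0]) if hasattr(ds, "PixelSpacing") else 1.0
        elif hu.shape != shape_ref:
            raise AlignmentError(f"{path} shape {hu.shape} != {shape_ref}")
        images[label] = hu
    return ProtocolStack(subject_id=subject_id, images=images,
                         target_label=target_label, pixel_spacing_mm=spacing or 1.0)


def write_rois(rois: ROISet, path: str | Path) -> None:
    payload = {
        "pixel_spacing_mm": rois.pixel_spacing_mm,
        "rois": [
            {
                "roi_id": r.roi_id,
                "organ_role": r.organ_role,
                "center": list(r.center),
                "radius_mm": r.radius_mm,
                "slice_index": r.slice_index,
            }
            for r in rois
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_rois(path: str | Path) -> ROISet:
    payload = json.loads(Path(path).read_text())
    rois = [
        ROI(
            roi_id=r["roi_id"],
            organ_role=r["organ_role"],
            center=tuple(r["center"]),
            radius_mm=r["radius_mm"],
            slice_index=r.get("slice_index", 0),
        )
        for r in payload["rois"]
    ]
    return ROISet(rois, pixel_spacing_mm=payload["pixel_spacing_mm"])


def write_roi_masks(rois: ROISet, shape: Tuple[int, int], out_path: str | Path) -> None:
    """Integer label mask NIfTI (ROI index + 1; 0 = outside)."""
    lab = np.zeros(shape, dtype=np.int16)
    for i, roi in enumerate(rois):
        lab[roi.mask(shape, rois.pixel_spacing_mm)] = i + 1
    nib.save(nib.Nifti1Image(lab, _affine(rois.pixel_spacing_mm)), str(out_path))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
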