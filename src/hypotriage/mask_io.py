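"""Reading and writing structure masks and contour stacks.

Masks travel as NIfTI (.nii/.nii.gz, via nibabel) or NRRD (.nrrd, via
SimpleITK); both are binarized at 0.5 on load.  Contour stacks use a small
JSON dialect::

    {"structure": "rectal_wall",
     "slices": [{"z": -12.5, "polygons": [[[x, y], ...], ...]}, ...]}

Only axis-aligned (non-oblique) image geometries are supported; the
anatomical axis labels are recovered from the image orientation so that
direction-dependent operations never depend on array order.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import InvalidContourError
from .geometry import ContourStack, StructureMask

__all__ = [
    "load_mask",
    "save_mask",
    "load_contours",
    "save_contours",
    "load_rtstruct_contours",
]

# World-frame conventions: NIfTI affines are RAS+ (+x right, +y anterior,
# +z superior); ITK/NRRD physical space is LPS (+x left, +y posterior).
_RAS_CODE = {0: ("R", "L"), 1: ("A", "P"), 2: ("S", "I")}
_LPS_CODE = {0: ("L", "R"), 1: ("P", "A"), 2: ("S", "I")}


def _axes_from_matrix(matrix: np.ndarray, world_codes: dict):
    """Map an axis-aligned 3x3 direction/affine block to labels and spacing."""
    labels, spacing, world_axis = [], [], []
    for grid_axis in range(3):
        column = matrix[:, grid_axis]
        j = int(np.argmax(np.abs(column)))
        if not np.allclose(np.delete(column, j), 0.0, atol=1e-6 * max(1.0, abs(column[j]))):
            raise ValueError("oblique image orientations are not supported")
        positive, negative = world_codes[j]
        labels.append(positive if column[j] > 0 else negative)
        spacing.append(abs(column[j]))
        world_axis.append(j)
    if len(set(world_axis)) != 3:
        raise ValueError("degenerate image orientation matrix")
    return tuple(labels), tuple(spacing), world_axis


def load_mask(path) -> StructureMask:
    """Load a binary mask from NIfTI or NRRD (threshold 0.5)."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        return _load_nifti(path)
    if path.suffix.lower() == ".nrrd":
        return _load_nrrd(path)
    raise ValueError(f"unsupported mask format: {path.name}")


def save_mask(mask: StructureMask, path) -> None:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        _save_nifti(mask, path)
    elif path.suffix.lower() == ".nrrd":
        _save_nrrd(mask, path)
    else:
        raise ValueError(f"unsupported mask format: {path.name}")


def _load_nifti(path) -> StructureMask:
    img = nib.load(str(path))
    affine = np.asarray(img.affine, float)
    labels, spacing, world_axis = _axes_from_matrix(affine[:3, :3], _RAS_CODE)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got shape {data.shape}")
    # Origin component along each grid axis, signed so that coordinates
    # increase with index (matches StructureMask's axis-local convention).
    origin = []
    for grid_axis in range(3):
        j = world_axis[grid_axis]
        sign = 1.0 if affine[j, grid_axis] > 0 else -1.0
        origin.append(sign * affine[j, 3])
    return StructureMask(np.asarray(data, float) > 0.5, spacing, tuple(origin), labels)


def _save_nifti(mask: StructureMask, path) -> None:
    affine = np.zeros((4, 4))
    affine[3, 3] = 1.0
    for grid_axis in range(3):
        label = mask.axis_labels[grid_axis]
        for j, (positive, negative) in _RAS_CODE.items():
            if label == positive:
                sign = 1.0
                break
            if label == negative:
                sign = -1.0
                break
        affine[j, grid_axis] = sign * mask.spacing[grid_axis]
        affine[j, 3] = sign * mask.origin[grid_axis]
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))


def _load_nrrd(path) -> StructureMask:
    img = sitk.ReadImage(str(path))
    direction = np.asarray(img.GetDirection(), float).reshape(3, 3)
    labels, unit_spacing, world_axis = _axes_from_matrix(direction, _LPS_CODE)
    spacing = tuple(u * s for u, s in zip(unit_spacing, img.GetSpacing()))
    itk_origin = img.GetOrigin()
    origin = []
    for grid_axis in range(3):
        j = world_axis[grid_axis]
        sign = 1.0 if direction[j, grid_axis] > 0 else -1.0
        origin.append(sign * itk_origin[j])
    data = sitk.GetArrayFromImage(img)  # (z, y, x) index order
    voxels = np.asarray(data, float).transpose(2, 1, 0) > 0.5
    return StructureMask(voxels, spacing, tuple(origin), labels)


def _save_nrrd(mask: StructureMask, path) -> None:
    img = sitk.GetImageFromArray(mask.voxels.astype(np.uint8).transpose(2, 1, 0))
    img.SetSpacing(tuple(float(s) for s in mask.spacing))
    direction = np.zeros((3, 3))
    origin = [0.0, 0.0, 0.0]
    for grid_axis in range(3):
        label = mask.axis_labels[grid_axis]
        for j, (positive, negative) in _LPS_CODE.items():
            if label == positive:
                sign = 1.0
                break
            if label == negative:
                sign = -1.0
                break
        direction[j, grid_axis] = sign
        origin[j] = sign * mask.origin[grid_axis]
    img.SetDirection(tuple(direction.ravel()))
    img.SetOrigin(tuple(origin))
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Contour stacks
# ---------------------------------------------------------------------------

def load_contours(path) -> ContourStack:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    try:
        slices = [(entry["z"], entry.get("polygons", [])) for entry in payload["slices"]]
        return ContourStack(payload["structure"], slices)
    except (KeyError, TypeError) as exc:
        raise InvalidContourError(f"malformed contour JSON in {path}: {exc}") from exc


def save_contours(stack: ContourStack, path) -> None:
    payload = {
        "structure": stack.structure_name,
        "slices": [
            {"z": z, "polygons": [np.asarray(p).tolist() for p in polygons]}
            for z, polygons in stack.slices
        ],
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle)


def load_rtstruct_contours(path, structure_name: str) -> ContourStack:
    """Best-effort import of one ROI from a DICOM RTSTRUCT file.

    Requires pydicom (optional dependency).  Contours are read from the
    patient coordinate system as axial (x, y) polygons stacked along z;
    non-axial or keyhole contours are not handled.
    """
    import pydicom  # deferred: optional dependency

    ds = pydicom.dcmread(str(path))
    roi_number = None
    for roi in getattr(ds, "StructureSetROISequence", []):
        if str(roi.ROIName).strip().lower() == structure_name.strip().lower():
            roi_number = roi.ROINumber
            break
    if roi_number is None:
        raise InvalidContourError(f"no ROI named {structure_name!r} in {path}")
    by_z: dict = {}
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        if roi_contour.ReferencedROINumber != roi_number:
            continue
        for contour in getattr(roi_contour, "ContourSequence", []):
            points = np.asarray(contour.ContourData, float).reshape(-1, 3)
            z = round(float(np.mean(points[:, 2])), 3)
            by_z.setdefault(z, []).append(points[:, :2])
    slices = [(z, by_z[z]) for z in sorted(by_z)]
    return ContourStack(structure_name, slices)
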