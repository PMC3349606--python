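"""On-disk formats: NIfTI volumes plus a JSON geometry sidecar.

Volumes are written as NIfTI-1 with axes (col, row, slice) and voxel sizes
(col spacing, row spacing, slice thickness + gap); in memory everything is
(slice, row, col) with slice 0 most basal.  The sidecar carries the scalar
geometry and orientation fields that NIfTI headers do not model for this
pipeline: pixel_spacing, slice_thickness, slice_gap, slice_order,
rv_insertion_angle (display-counterclockwise radians; scalar or per slice)
and outflow_slices (slice index -> anterior angular interval in the
RV-insertion-anchored frame).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import Orientation, ShortAxisStack
from .phantom import PhantomTruth

SIDECAR_REQUIRED = ("pixel_spacing", "slice_thickness", "slice_gap",
                    "rv_insertion_angle")


class SidecarError(ValueError):
    """Raised when the JSON geometry sidecar is missing or malformed."""


def _affine(stack: ShortAxisStack) -> np.ndarray:
    return np.diag([stack.pixel_spacing[1], stack.pixel_spacing[0],
                    stack.slice_spacing, 1.0])


def _to_nifti_array(vol: np.ndarray) -> np.ndarray:
    # (slice, row, col) -> (col, row, slice)
    return np.ascontiguousarray(np.transpose(vol, (2, 1, 0)))


def _from_nifti_array(vol: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(vol, (2, 1, 0)))


def save_volume(vol: np.ndarray, stack: ShortAxisStack, path: str | Path) -> None:
    """Write one volume (image or mask) aligned with ``stack`` as NIfTI."""
    data = _to_nifti_array(np.asarray(vol))
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, _affine(stack)), str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return _from_nifti_array(np.asarray(nib.load(str(path)).dataobj))


def save_sidecar(stack: ShortAxisStack, orient: Orientation, path: str | Path) -> None:
    angle = orient.rv_insertion_angle
    record = {
        "pixel_spacing": list(stack.pixel_spacing),
        "slice_thickness": stack.slice_thickness,
        "slice_gap": stack.slice_gap,
        "slice_order": stack.slice_order,
        "rv_insertion_angle": list(np.atleast_1d(angle).astype(float))
        if np.ndim(angle) else float(angle),
        "outflow_slices": {str(k): list(v) for k, v in orient.outflow_slices.items()},
        "angle_convention": "display-counterclockwise radians; 0 = +col axis",
    }
    Path(path).write_text(json.dumps(record, indent=2))


def load_sidecar(path: str | Path) -> dict:
    try:
        record = json.loads(Path(path).read_text())
    except FileNotFoundError as exc:
        raise SidecarError(f"sidecar file not found: {path}") from exc
    missing = [k for k in SIDECAR_REQUIRED if k not in record]
    if missing:
        raise SidecarError(
            f"sidecar {path} is missing required field(s): {', '.join(missing)}"
        )
    return record


def load_stack(
    image_path: str | Path,
    mask_path: str | Path,
    sidecar_path: str | Path,
) -> tuple[ShortAxisStack, Orientation]:
    """Load image + myocardial mask + sidecar into a stack and orientation."""
    record = load_sidecar(sidecar_path)
    image = load_volume(image_path).astype(float)
    mask = load_volume(mask_path).astype(bool)
    stack = ShortAxisStack(
        image=image,
        myo_mask=mask,
        pixel_spacing=tuple(record["pixel_spacing"]),
        slice_thickness=float(record["slice_thickness"]),
        slice_gap=float(record["slice_gap"]),
        slice_order=record.get("slice_order", "base-to-apex"),
    )
    angle = record["rv_insertion_angle"]
    orient = Orientation(
        rv_insertion_angle=angle,
        outflow_slices={int(k): tuple(v)
                        for k, v in record.get("outflow_slices", {}).items()},
    )
    return stack, orient


def save_stack(
    stack: ShortAxisStack,
    orient: Orientation,
    image_path: str | Path,
    mask_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    save_volume(stack.image, stack, image_path)
    save_volume(stack.myo_mask, stack, mask_path)
    save_sidecar(stack, orient, sidecar_path)


def save_phantom(truth: PhantomTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write a phantom subject: image, myo mask, truth mask, sidecar, spec echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / "image.nii.gz",
        "myo_mask": out / "myo_mask.nii.gz",
        "mar_truth": out / "mar_truth.nii.gz",
        "sidecar": out / "sidecar.json",
        "spec": out / "phantom_spec.json",
    }
    save_stack(truth.stack, truth.orient, paths["image"], paths["myo_mask"],
               paths["sidecar"])
    save_volume(truth.mar_truth, truth.stack, paths["mar_truth"])
    spec_rec = asdict(truth.spec)
    spec_rec["slice_gain"] = None if truth.spec.slice_gain is None \
        else [float(g) for g in truth.spec.slice_gain]
    paths["spec"].write_text(json.dumps(spec_rec, indent=2, default=str))
    return paths
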