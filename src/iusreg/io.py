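"""Readers and writers for volumes, masks, and landmark files.

Volumes and masks go through SimpleITK (NIfTI-1 ``.nii``/``.nii.gz`` and
MetaImage ``.mhd``/``.mha``). The numpy arrays we expose use the file's own
index order (axis 0 = the header's first axis), so spacing, origin and the
direction matrix transfer verbatim from the header. Landmarks are read from
CSV (``label,fx,fy,fz,mx,my,mz``, header optional) or from MNI Tag Point
Files (``.tag``) as shipped with the RESECT and BITE ultrasound datasets.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .grids import BinaryMask, LandmarkSet, Volume3D

__all__ = [
    "read_volume", "write_volume", "read_mask", "write_mask",
    "read_landmarks", "write_landmarks_csv",
    "read_deformation_field", "write_deformation_field",
]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mhd", ".mha")


class VolumeFormatError(ValueError):
    """Raised for unreadable or structurally invalid image files."""


def _check_path(path) -> str:
    p = str(path)
    low = p.lower()
    if not any(low.endswith(s) for s in _VOLUME_SUFFIXES):
        raise VolumeFormatError(
            f"unsupported volume format for '{p}' "
            f"(expected one of {_VOLUME_SUFFIXES})")
    return p


def _read_image(path) -> sitk.Image:
    p = _check_path(path)
    if not os.path.exists(p):
        raise VolumeFormatError(f"no such file: '{p}'")
    try:
        return sitk.ReadImage(p)
    except RuntimeError as exc:  # SimpleITK wraps all ITK IO failures
        raise VolumeFormatError(f"could not read '{p}': {exc}") from exc


def read_volume(path) -> Volume3D:
    """Read a NIfTI or MetaImage file as a :class:`Volume3D`.

    Header spacing, origin and direction are passed through unmodified;
    intensities are converted to float32.
    """
    img = _read_image(path)
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"'{path}' is {img.GetDimension()}D; a 3D volume is required")
    # GetArrayFromImage returns (z, y, x); transpose back to file order.
    data = sitk.GetArrayFromImage(img).T.astype(np.float32)
    return Volume3D(
        data,
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=np.array(img.GetDirection()).reshape(3, 3),
    )


def _to_image(data: np.ndarray, spacing, origin, direction) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    img.SetDirection(tuple(float(d) for d in np.asarray(direction).ravel()))
    return img


def write_volume(volume: Volume3D, path) -> None:
    """Write a volume; the file round-trips through :func:`read_volume`."""
    p = _check_path(path)
    if not np.all(np.isfinite(volume.data)):
        raise ValueError(f"volume contains NaN/inf voxels; refusing to write '{p}'")
    img = _to_image(volume.data.astype(np.float32), volume.spacing,
                    volume.origin, volume.direction)
    sitk.WriteImage(img, p)


def read_mask(path) -> BinaryMask:
    """Read a binary mask (any nonzero voxel becomes True)."""
    vol = read_volume(path)
    return BinaryMask(vol.data > 0, vol.spacing, vol.origin, vol.direction)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as an 8-bit volume with values {0, 1}."""
    p = _check_path(path)
    img = _to_image(mask.data.astype(np.uint8), mask.spacing, mask.origin,
                    mask.direction)
    sitk.WriteImage(img, p)


def write_deformation_field(field, path) -> None:
    """Write a displacement field as a 3-component vector image."""
    from .grids import DeformationField  # local to avoid cycle in type hints
    assert isinstance(field, DeformationField)
    p = _check_path(path)
    # (3, nx, ny, nz) -> sitk vector image layout (z, y, x, 3)
    arr = np.ascontiguousarray(
        field.displacements.transpose(3, 2, 1, 0).astype(np.float64))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in field.spacing))
    img.SetOrigin(tuple(float(o) for o in field.origin))
    img.SetDirection(tuple(float(d) for d in field.direction.ravel()))
    sitk.WriteImage(img, p)


def read_deformation_field(path):
    from .grids import DeformationField
    img = _read_image(path)
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 3:
        raise VolumeFormatError(
            f"'{path}' is not a 3-component 3D vector image")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
    u = arr.transpose(3, 2, 1, 0).astype(np.float64)
    return DeformationField(
        u,
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=np.array(img.GetDirection()).reshape(3, 3),
    )


# ---------------------------------------------------------------------------
# landmarks

class LandmarkParseError(ValueError):
    pass


def _parse_csv(lines, path) -> LandmarkSet:
    labels, fixed, moving = [], [], []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if ln == 1 and any(not _is_number(p) for p in parts[1:]):
            continue  # header row
        if len(parts) == 6 and all(_is_number(p) for p in parts):
            parts = [f"L{len(labels) + 1}"] + parts
        if len(parts) != 7:
            raise LandmarkParseError(
                f"{path}:{ln}: expected 'label,fx,fy,fz,mx,my,mz', got "
                f"{len(parts)} fields")
        try:
            coords = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise LandmarkParseError(f"{path}:{ln}: {exc}") from exc
        labels.append(parts[0])
        fixed.append(coords[:3])
        moving.append(coords[3:])
    if not fixed:
        raise LandmarkParseError(f"{path}: no landmark rows found")
    return LandmarkSet(np.array(fixed), np.array(moving), labels)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


_TAG_FLOAT = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _parse_tag(lines, path) -> LandmarkSet:
    """Parse an MNI Tag Point File with two points (6 numbers) per tag line."""
    in_points = False
    fixed, moving, labels = [], [], []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not in_points:
            if line.startswith("Points ="):
                in_points = True
                line = line[len("Points ="):].strip()
            else:
                continue
        if not line:
            continue
        body = line.rstrip(";")
        label = None
        m = re.search(r'"([^"]*)"', body)
        if m:
            label = m.group(1)
            body = body[:m.start()]
        nums = [float(x) for x in _TAG_FLOAT.findall(body)]
        if not nums:
            continue
        if len(nums) != 6:
            raise LandmarkParseError(
                f"{path}:{ln}: expected 6 coordinates per tag line "
                f"(two 3D points), got {len(nums)}")
        fixed.append(nums[:3])
        moving.append(nums[3:])
        labels.append(label or f"L{len(labels) + 1}")
    if not fixed:
        raise LandmarkParseError(f"{path}: no tag points found")
    return LandmarkSet(np.array(fixed), np.array(moving), labels)


def read_landmarks(path, dialect: str | None = None) -> LandmarkSet:
    """Read paired landmarks from CSV or an MNI ``.tag`` file.

    Parameters
    ----------
    dialect : {"csv", "mni_tag"}, optional
        Inferred from the file suffix when omitted.
    """
    p = Path(path)
    if dialect is None:
        dialect = "mni_tag" if p.suffix.lower() == ".tag" else "csv"
    if dialect not in ("csv", "mni_tag"):
        raise ValueError(f"unknown landmark dialect '{dialect}'")
    lines = p.read_text().splitlines()
    if dialect == "csv":
        return _parse_csv(lines, p)
    return _parse_tag(lines, p)


def write_landmarks_tag(landmarks: LandmarkSet, path) -> None:
    """Write an MNI Tag Point File with two points per tag line."""
    lines = ["MNI Tag Point File", "Volumes = 2;", "", "Points ="]
    for lab, pf, pm in zip(landmarks.labels, landmarks.points_fixed,
                           landmarks.points_moving):
        coords = " ".join(f"{c:.6f}" for c in np.concatenate([pf, pm]))
        lines.append(f" {coords} \"{lab}\"")
    lines[-1] += ";"
    Path(path).write_text("\n".join(lines) + "\n")


def write_landmarks_csv(landmarks: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("label,fx,fy,fz,mx,my,mz\n")
        for lab, pf, pm in zip(landmarks.labels, landmarks.points_fixed,
                               landmarks.points_moving):
            fh.write(f"{lab}," + ",".join(f"{c:.6f}" for c in pf) + ","
                     + ",".join(f"{c:.6f}" for c in pm) + "\n")
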