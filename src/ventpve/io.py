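"""Readers and writers for slices and masks.

Supported formats: NIfTI (.nii/.nii.gz, HU stored directly), 16-bit
grayscale PNG with a declared intensity offset (stored = HU - offset),
and DICOM (read-only; rescale slope/intercept applied to recover HU).
Masks round-trip as NIfTI uint8 or PNG 0/255.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .types import ImageSlice

PNG_DEFAULT_OFFSET = -1024.0  # stored 0 maps to air


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".png"):
        return "png16"
    if name.endswith((".dcm", ".dicom")):
        return "dicom"
    raise ValueError(f"cannot infer format from file name {path.name!r}")


def read_slice(
    path,
    fmt: str | None = None,
    png_offset: float = PNG_DEFAULT_OFFSET,
    slice_index: int | None = None,
) -> ImageSlice:
    """Read one 2-D CT slice in Hounsfield units.

    ``png_offset`` is the HU value of stored intensity 0 in a 16-bit PNG
    (HU = stored + offset).  A 3-D NIfTI volume requires ``slice_index``
    to pick an axial slice.
    """
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data)
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError(
                    "3-D NIfTI volume: pass slice_index to select an axial slice"
                )
            data = data[:, :, slice_index]
        if data.ndim != 2:
            raise ValueError(f"cannot interpret NIfTI data of shape {data.shape}")
        zooms = img.header.get_zooms()
        spacing = float(zooms[0]) if len(zooms) >= 1 else None
        return ImageSlice(pixels=np.asarray(data, dtype=float), pixel_spacing=spacing)
    if fmt == "png16":
        with Image.open(path) as im:
            data = np.asarray(im, dtype=float)
        if data.ndim != 2:
            raise ValueError("PNG slice must be single-channel grayscale")
        return ImageSlice(pixels=data + png_offset)
    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(str(path))
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = getattr(ds, "RescaleIntercept", None)
        if intercept is None:
            raise ValueError("DICOM file lacks RescaleIntercept; cannot recover HU")
        data = ds.pixel_array.astype(float) * slope + float(intercept)
        spacing = None
        if getattr(ds, "PixelSpacing", None):
            spacing = float(ds.PixelSpacing[0])
        return ImageSlice(pixels=data, pixel_spacing=spacing)
    raise ValueError(f"unknown format {fmt!r}")


def write_slice(
    image: ImageSlice, path, fmt: str | None = None, png_offset: float = PNG_DEFAULT_OFFSET
) -> None:
    """Write a slice as NIfTI (HU stored directly) or 16-bit PNG."""
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt == "nifti":
        nib.save(nib.Nifti1Image(np.asarray(image.pixels), affine=np.eye(4)), str(path))
        return
    if fmt == "png16":
        stored = np.asarray(image.pixels, dtype=float) - png_offset
        if stored.min() < 0 or stored.max() > 65535:
            raise ValueError("HU values do not fit a 16-bit PNG with this offset")
        Image.fromarray(np.rint(stored).astype(np.uint16)).save(path)
        return
    raise ValueError(f"cannot write format {fmt!r}")


def read_mask(path) -> np.ndarray:
    """Read a binary mask (NIfTI or PNG); any nonzero pixel is foreground."""
    path = Path(path)
    fmt = _detect_format(path)
    if fmt == "nifti":
        data = np.squeeze(np.asanyarray(nib.load(str(path)).dataobj))
    elif fmt == "png16":
        with Image.open(path) as im:
            data = np.asarray(im)
    else:
        raise ValueError(f"cannot read mask from format {fmt!r}")
    if data.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {data.shape}")
    return data > 0


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as NIfTI uint8 or PNG 0/255."""
    path = Path(path)
    fmt = _detect_format(path)
    mask = np.asarray(mask, dtype=bool)
    if fmt == "nifti":
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine=np.eye(4)), str(path))
    elif fmt == "png16":
        Image.fromarray((mask * 255).astype(np.uint8)).save(path)
    else:
        raise ValueError(f"cannot write mask to format {fmt!r}")
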