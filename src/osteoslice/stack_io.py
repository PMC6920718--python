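"""Binarized image-stack and specimen-manifest I/O.

The data model assumed by every downstream stage:

* a stack is a 3D boolean volume indexed ``(slice, row, col)``; axis 0 is
  the scan (shaft) axis, in-plane origin is the top-left pixel;
* voxels are isotropic; all geometry is reported in mm via
  ``voxel_size_mm`` (default 0.00689 mm, a typical rodent-femur scan
  resolution);
* any nonzero pixel of an 8-bit export is foreground bone.

Stacks are exchanged either as a single multi-page TIFF or as a directory
of numbered single-slice BMP/PNG images (filename order = slice order).
Per-specimen metadata travels in a small YAML manifest.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError, FormatError, ValidationError

DEFAULT_VOXEL_SIZE_MM = 0.00689

#: manifest keys that must always be present
_REQUIRED_KEYS = ("specimen_id", "group", "voxel_size_mm", "bone_length_mm")
_SLICE_IMAGE_EXTS = (".bmp", ".png", ".tif", ".tiff")


@dataclass
class BinaryStack:
    """Aligned (or raw) binarized voxel volume plus geometry metadata.

    Parameters
    ----------
    voxels : ndarray of bool, shape (n_slices, n_rows, n_cols)
    voxel_size_mm : float
        Isotropic voxel edge length in mm.
    slice_axis_direction : {"distal_increasing", "proximal_increasing"}
        Whether slice index grows toward the distal or the proximal end.
    """

    voxels: np.ndarray
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM
    slice_axis_direction: str = "distal_increasing"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 2 + 1:
            raise ValidationError(
                f"stack must be 3D (slice, row, col); got ndim={self.voxels.ndim}"
            )
        if self.voxels.shape[0] < 1 or 0 in self.voxels.shape:
            raise ValidationError(f"empty stack of shape {self.voxels.shape}")
        if self.voxels.dtype != bool:
            vals = np.unique(self.voxels)
            if not np.isin(vals, (0, 1)).all():
                # 8-bit binarized exports use 0/255; accept any nonzero as bone
                self.voxels = self.voxels > 0
            else:
                self.voxels = self.voxels.astype(bool)
        if not np.isscalar(self.voxel_size_mm):
            sizes = np.asarray(self.voxel_size_mm, dtype=float).ravel()
            if not np.allclose(sizes, sizes[0]):
                raise ValidationError(
                    f"anisotropic voxels are not supported: {sizes.tolist()}"
                )
            self.voxel_size_mm = float(sizes[0])
        if not self.voxel_size_mm > 0:
            raise ValidationError("voxel_size_mm must be positive")
        if self.slice_axis_direction not in ("distal_increasing", "proximal_increasing"):
            raise ValidationError(
                f"unknown slice_axis_direction {self.slice_axis_direction!r}"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def foreground_count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class SpecimenMeta:
    """Per-specimen metadata supplied alongside a stack.

    ``growth_plate_slice`` is the manually identified reference slice (the
    most proximal slice showing a continuous chondrocyte seam); it is user
    metadata, never detected automatically.  ``distal_end_slice`` anchors
    the percent-bone-length frame (100% = distal end).
    """

    specimen_id: str
    group: str
    bone_length_mm: float
    growth_plate_slice: int | None = None
    distal_end_slice: int | None = None

    def __post_init__(self) -> None:
        if not self.bone_length_mm > 0:
            raise ValidationError("bone_length_mm must be positive")

    def validate_against(self, stack: BinaryStack) -> None:
        for name in ("growth_plate_slice", "distal_end_slice"):
            idx = getattr(self, name)
            if idx is not None and not (0 <= idx < stack.n_slices):
                raise ValidationError(
                    f"{name}={idx} outside stack with {stack.n_slices} slices"
                )


def read_manifest(source) -> dict:
    """Parse a YAML manifest from a path, file object, or mapping."""
    if isinstance(source, dict):
        data = dict(source)
    else:
        text = Path(source).read_text() if isinstance(source, (str, os.PathLike)) else source.read()
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError("manifest must be a key-value mapping")
    missing = [k for k in _REQUIRED_KEYS if k not in data or data[k] is None]
    if missing:
        raise ConfigurationError(f"manifest missing required key(s): {', '.join(missing)}")
    return data


def _meta_from_manifest(data: dict) -> SpecimenMeta:
    def _opt_int(key):
        v = data.get(key)
        if v in (None, "unset"):
            return None
        return int(v)

    return SpecimenMeta(
        specimen_id=str(data["specimen_id"]),
        group=str(data["group"]),
        bone_length_mm=float(data["bone_length_mm"]),
        growth_plate_slice=_opt_int("growth_plate_slice"),
        distal_end_slice=_opt_int("distal_end_slice"),
    )


def _read_pages_tiff(path: Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected 2D pages, got array of ndim {arr.ndim}")
    return arr


def _read_slice_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir()
        if p.suffix.lower() in _SLICE_IMAGE_EXTS and not p.name.startswith(".")
    )
    if not files:
        raise FormatError(f"{path}: no slice images found")
    pages = []
    for f in files:
        page = np.asarray(iio.imread(f))
        if page.ndim == 3:  # collapse RGB(A) exports
            page = page[..., 0]
        if page.ndim != 2:
            raise FormatError(f"{f}: slice image is not 2D")
        pages.append(page)
    shapes = {p.shape for p in pages}
    if len(shapes) > 1:
        raise FormatError(f"{path}: inconsistent slice dimensions {sorted(shapes)}")
    return np.stack(pages)


def read_stack(path, manifest) -> tuple[BinaryStack, SpecimenMeta]:
    """Read a binarized stack plus its manifest.

    ``path`` is a multi-page TIFF file or a directory of numbered slice
    images; slice order follows page/filename order.  Any pixel > 0 maps
    to foreground.
    """
    data = read_manifest(manifest)
    meta = _meta_from_manifest(data)
    path = Path(path)
    if path.is_dir():
        raw = _read_slice_dir(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        raw = _read_pages_tiff(path)
    else:
        raise FormatError(f"{path}: expected a multi-page TIFF or a slice directory")
    stack = BinaryStack(
        voxels=raw > 0,
        voxel_size_mm=data["voxel_size_mm"],
        slice_axis_direction=data.get("slice_axis_direction", "distal_increasing"),
    )
    meta.validate_against(stack)
    return stack, meta


def write_stack(stack: BinaryStack, path) -> None:
    """Write a stack as a multi-page TIFF (``.tif``) or a PNG slice directory.

    Round-trip with :func:`read_stack` is the voxel-wise identity.
    """
    path = Path(path)
    data = (stack.voxels.astype(np.uint8)) * 255
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            path.parent.mkdir(parents=True, exist_ok=True)
            tifffile.imwrite(path, data, photometric="minisblack")
        else:
            path.mkdir(parents=True, exist_ok=True)
            width = max(4, len(str(stack.n_slices)))
            for i, page in enumerate(data):
                iio.imwrite(path / f"s{i + 1:0{width}d}.png", page)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot write stack to {path}: {exc}") from exc


def write_manifest(meta: SpecimenMeta, stack: BinaryStack, path) -> None:
    """Serialize metadata back to a YAML manifest."""
    data = {
        "specimen_id": meta.specimen_id,
        "group": meta.group,
        "voxel_size_mm": stack.voxel_size_mm,
        "bone_length_mm": meta.bone_length_mm,
        "growth_plate_slice": meta.growth_plate_slice,
        "distal_end_slice": meta.distal_end_slice,
        "slice_axis_direction": stack.slice_axis_direction,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
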