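"""Volumetric image and mask containers with isotropic spacing, plus file I/O.

All grids in one analysis must share shape and spacing; nothing in this
package resamples. The physical position of a voxel center is
``origin_mm + (index + 0.5) * spacing_mm`` (0-based indices).

NIfTI is the canonical on-disk format. Multi-page TIFF stacks are supported
read-only and carry no reliable 3D spacing, so reading them requires an
explicit ``spacing_mm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "Volume3D",
    "BinaryMask",
    "GridMismatchError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_results",
    "mask_volume_ml",
]

DEFAULT_SPACING_MM = 0.1  # microCT acquisition resolution


class GridMismatchError(ValueError):
    """Raised when two grids that must align differ in shape or spacing."""


def _validate_grid(data: np.ndarray, spacing_mm: float) -> None:
    if data.ndim != 3 or min(data.shape) < 1:
        raise ValueError(f"expected a 3D grid, got shape {data.shape}")
    if not np.isfinite(spacing_mm) or spacing_mm <= 0:
        raise ValueError(f"spacing_mm must be positive, got {spacing_mm}")


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with isotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative intensities in arbitrary CT units.
    spacing_mm : float
        Isotropic voxel edge length in millimetres (default 0.1).
    origin_mm : ndarray of shape (3,)
        Physical coordinate of the grid corner (mm).
    """

    data: np.ndarray
    spacing_mm: float = DEFAULT_SPACING_MM
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _validate_grid(self.data, self.spacing_mm)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.origin_mm.shape != (3,):
            raise ValueError("origin_mm must be a 3-vector")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_center_mm(self, index: np.ndarray) -> np.ndarray:
        """Physical center (mm) of voxel ``index`` (array-like of int triples)."""
        return self.origin_mm + (np.asarray(index, dtype=float) + 0.5) * self.spacing_mm


@dataclass
class BinaryMask:
    """A 3D boolean grid aligned with a :class:`Volume3D`."""

    data: np.ndarray
    spacing_mm: float = DEFAULT_SPACING_MM
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask must be strictly two-valued (0/1)")
            arr = arr.astype(bool)
        self.data = arr
        _validate_grid(self.data, self.spacing_mm)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.origin_mm.shape != (3,):
            raise ValueError("origin_mm must be a 3-vector")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_count(self) -> int:
        return int(self.data.sum())

    def voxel_center_mm(self, index: np.ndarray) -> np.ndarray:
        return self.origin_mm + (np.asarray(index, dtype=float) + 0.5) * self.spacing_mm


def require_same_grid(a: Volume3D | BinaryMask, b: Volume3D | BinaryMask) -> None:
    """Raise :class:`GridMismatchError` unless ``a`` and ``b`` share shape and spacing."""
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.isclose(a.spacing_mm, b.spacing_mm, rtol=0, atol=1e-12):
        raise GridMismatchError(
            f"spacing mismatch: {a.spacing_mm} vs {b.spacing_mm} mm "
            "(resampling is not performed)"
        )


def mask_volume_ml(mask: BinaryMask) -> float:
    """Physical volume of a mask in millilitres (voxels x spacing^3 / 1000)."""
    return mask.voxel_count() * mask.spacing_mm**3 / 1000.0


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    raise ValueError(f"cannot infer format from {path.name}; pass format=")


def read_volume(
    path: str | Path,
    format: str | None = None,
    spacing_mm: float | None = None,
) -> Volume3D:
    """Read a 3D volume from NIfTI or a multi-page TIFF stack.

    NIfTI spacing comes from the header and must be isotropic (anisotropic
    voxels are rejected, never resampled). TIFF stacks carry no reliable 3D
    spacing, so ``spacing_mm`` is mandatory for them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        img = nib.load(str(path))
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        if not np.allclose(zooms, zooms[0], rtol=1e-5, atol=1e-9):
            raise ValueError(
                f"anisotropic voxels {tuple(zooms)} in {path.name}; "
                "the pipeline assumes isotropic spacing"
            )
        header_spacing = float(zooms[0])
        if spacing_mm is not None and not np.isclose(spacing_mm, header_spacing):
            raise ValueError(
                f"spacing override {spacing_mm} conflicts with header {header_spacing}"
            )
        data = np.asarray(img.dataobj)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return Volume3D(data, header_spacing, origin)
    if fmt == "tiff":
        if spacing_mm is None:
            raise ValueError(
                "TIFF stacks carry no 3D spacing metadata; pass spacing_mm explicitly"
            )
        data = tifffile.imread(str(path))
        if data.ndim != 3:
            raise ValueError(f"expected a multi-page TIFF stack, got shape {data.shape}")
        return Volume3D(data, spacing_mm)
    raise ValueError(f"unsupported format {fmt!r}")


def read_mask(
    path: str | Path,
    format: str | None = None,
    spacing_mm: float | None = None,
) -> BinaryMask:
    """Read a binary mask (stored as an integer 0/1 volume)."""
    vol = read_volume(path, format=format, spacing_mm=spacing_mm)
    return BinaryMask(vol.data, vol.spacing_mm, vol.origin_mm)


def write_volume(
    volume_or_mask: Volume3D | BinaryMask,
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write a volume or mask as NIfTI.

    Masks are stored as uint8, float volumes as float32 (lossless for
    integer-valued and mask data; float data round-trips at float32
    precision). TIFF output is deliberately unsupported: the format cannot
    carry the 3D spacing this pipeline depends on.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt != "nifti":
        raise ValueError("only NIfTI output is supported; TIFF is read-only")
    obj = volume_or_mask
    if isinstance(obj, BinaryMask):
        data = obj.data.astype(np.uint8)
    else:
        data = np.asarray(obj.data)
        if data.dtype == bool:
            data = data.astype(np.uint8)
        elif np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
    affine = np.diag([obj.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = obj.origin_mm
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((obj.spacing_mm,) * 3)
    nib.save(img, str(path))


def write_results(study_result, out_dir: str | Path, prefix: str = "study") -> dict[str, Path]:
    """Serialize a study: per-kidney CSV table plus a JSON summary.

    The CSV holds one row per (subject, kidney, depth). The JSON carries
    group medians/ranges and paired-test results and reloads to the same
    structure as :meth:`PairedStudyResult.summary_dict`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{prefix}_per_kidney.csv"
    json_path = out_dir / f"{prefix}_summary.json"
    study_result.to_frame().to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(study_result.summary_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"csv": csv_path, "json": json_path}
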