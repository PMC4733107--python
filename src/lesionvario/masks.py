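"""Grid geometry, binary lesion masks, and NIfTI/manifest IO.

Axis convention: array axis 0 = X (dextral-sinistral), axis 1 = Y
(caudal-rostral), axis 2 = Z (dorsal-ventral).  File headers are not used to
reorient data; callers who know their data are stored in a different order
pass an explicit axis permutation.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ManifestError, MaskFormatError, NonBinaryMaskError

AXES = ("X", "Y", "Z")
AXIS_LABELS = {
    "X": "dextral-sinistral",
    "Y": "caudal-rostral",
    "Z": "dorsal-ventral",
}

#: Tolerance for calling a float voxel value 0 or 1 in lenient reading mode.
BINARY_TOL = 1e-3


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid geometry.

    Parameters
    ----------
    shape
        Voxel counts ``(nx, ny, nz)``; each >= 1.
    spacing
        Edge lengths of one voxel in mm per axis; each > 0.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise MaskFormatError(f"grid shape must be three entries >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise MaskFormatError(
                f"grid spacing must be three positive finite values, got {self.spacing}"
            )
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if len(set(self.spacing)) > 1:
            warnings.warn(
                "anisotropic voxel spacing: per-axis lag distances differ, "
                "directional ranges are not directly comparable",
                stacklevel=3,
            )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


#: Reference MNI grid: 121 x 145 x 121 voxels at 1.5 mm isotropic.
MNI_GRID = GridSpec((121, 145, 121), (1.5, 1.5, 1.5))


@dataclass
class LesionMask:
    """A binary 3D lesion pattern on a :class:`GridSpec`."""

    values: np.ndarray
    grid: GridSpec
    id: str = ""
    exam_date: _dt.date | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise MaskFormatError(f"mask must be 3D, got ndim={arr.ndim}")
        if tuple(arr.shape) != self.grid.shape:
            raise MaskFormatError(
                f"mask shape {arr.shape} does not match grid shape {self.grid.shape}"
            )
        bad = np.count_nonzero((arr != 0) & (arr != 1))
        if bad:
            raise NonBinaryMaskError(
                f"mask '{self.id}' contains {bad} voxel(s) that are neither 0 nor 1"
            )
        self.values = arr.astype(np.uint8, copy=False)

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def lesion_fraction(self) -> float:
        """Foreground fraction p = (# 1-voxels) / (nx * ny * nz)."""
        return self.n_foreground / self.grid.n_voxels

    @property
    def volume_mm3(self) -> float:
        return self.n_foreground * self.grid.voxel_volume_mm3


@dataclass(frozen=True)
class ManifestEntry:
    id: str
    path: Path
    exam_date: _dt.date | None = None


def _permute(arr: np.ndarray, axis_order: str) -> np.ndarray:
    order = axis_order.upper()
    if sorted(order) != ["X", "Y", "Z"]:
        raise MaskFormatError(f"axis_order must be a permutation of 'XYZ', got {axis_order!r}")
    perm = tuple(order.index(ax) for ax in AXES)
    return np.transpose(arr, perm)


def read_mask(
    path: str | Path,
    strict_binary: bool = True,
    axis_order: str = "XYZ",
    id: str | None = None,
    exam_date: _dt.date | None = None,
) -> LesionMask:
    """Read a binary lesion mask from a NIfTI file.

    Voxel spacing is taken from the header zooms.  With ``strict_binary``
    (the default) any value other than exactly 0 or 1 is rejected; without
    it, values within :data:`BINARY_TOL` of 0 or 1 are rounded and anything
    else is still rejected.

    ``axis_order`` names the semantic axes of the *stored* array, e.g.
    ``"YXZ"`` if stored axis 0 runs caudal-rostral; the array is permuted to
    the package's X, Y, Z convention.
    """
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise MaskFormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MaskFormatError(f"{path}: invalid header voxel spacing {zooms}")

    data = np.asarray(data, dtype=np.float64)
    is_binary = np.isin(data, (0.0, 1.0))
    if not is_binary.all():
        n_bad = int(np.count_nonzero(~is_binary))
        if strict_binary:
            raise NonBinaryMaskError(
                f"{path}: {n_bad} voxel(s) are not exactly 0 or 1 (strict_binary)"
            )
        near = (np.abs(data) <= BINARY_TOL) | (np.abs(data - 1.0) <= BINARY_TOL)
        if not near.all():
            n_far = int(np.count_nonzero(~near))
            raise NonBinaryMaskError(
                f"{path}: {n_far} voxel(s) are not within {BINARY_TOL} of 0 or 1"
            )
        data = np.rint(data)

    arr = _permute(data.astype(np.uint8), axis_order)
    spacing = tuple(float(z) for z in _permute_spacing(zooms, axis_order))
    grid = GridSpec(tuple(arr.shape), spacing)
    if id is None:
        id = path.name
        for suffix in (".gz", ".nii"):
            id = id.removesuffix(suffix)
    return LesionMask(arr, grid, id=id, exam_date=exam_date)


def _permute_spacing(zooms: Sequence[float], axis_order: str) -> tuple[float, float, float]:
    order = axis_order.upper()
    perm = tuple(order.index(ax) for ax in AXES)
    return tuple(float(zooms[i]) for i in perm)


def write_mask(mask: LesionMask, path: str | Path) -> Path:
    """Write a mask as uint8 NIfTI-1 with a diagonal affine from the spacing."""
    path = Path(path)
    affine = np.diag(list(mask.grid.spacing) + [1.0])
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, path)
    return path


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a batch/longitudinal manifest (CSV or JSON).

    Expected columns/keys: ``id``, ``path``, optional ``date`` (ISO-8601).
    Row order is preserved.  Two rows with the same id *and* the same date
    are rejected: within a longitudinal series the (id, date) pair must be
    unique, and in a cross-sectional batch (no dates) ids must be unique.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise ManifestError(f"{path}: JSON manifest must be a list of objects")
        records = rows
    else:
        df = pd.read_csv(path, dtype=str)
        if df.empty and "id" not in df.columns:
            return []
        records = df.to_dict("records")

    entries: list[ManifestEntry] = []
    seen: set[tuple[str, str | None]] = set()
    for i, rec in enumerate(records):
        if "id" not in rec or "path" not in rec or pd.isna(rec["id"]) or pd.isna(rec["path"]):
            raise ManifestError(f"{path}: row {i} lacks required 'id'/'path' fields")
        mid = str(rec["id"])
        raw_date = rec.get("date")
        date: _dt.date | None = None
        if raw_date is not None and not pd.isna(raw_date):
            try:
                date = _dt.date.fromisoformat(str(raw_date))
            except ValueError as exc:
                raise ManifestError(f"{path}: row {i}: invalid ISO date {raw_date!r}") from exc
        key = (mid, date.isoformat() if date else None)
        if key in seen:
            raise ManifestError(
                f"{path}: duplicate entry for id={mid!r}" + (f" at date {key[1]}" if date else "")
            )
        seen.add(key)
        mask_path = Path(str(rec["path"]))
        if not mask_path.is_absolute():
            mask_path = path.parent / mask_path
        entries.append(ManifestEntry(mid, mask_path, date))
    return entries
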