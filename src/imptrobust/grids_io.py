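"""Dose grids and ROI masks: containers, validation, and volume file I/O.

Axis convention is fixed throughout the package: axis 0 = L/R, axis 1 = A/P,
axis 2 = S/I.  All values are physical dose in Gy on a regular voxel lattice;
spacing and origin are in millimetres.  Supported on-disk formats are NRRD and
NIfTI-1 for both doses and masks (mask: nonzero = inside), plus read-only
DICOM RT Dose.  No resampling is ever performed: every pairing of grids or of
a grid with a mask requires an identical lattice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from ._errors import (
    EmptyROIError,
    LatticeMismatchError,
    NegativeDoseError,
    NonFiniteDoseError,
    NonPositiveSpacingError,
    NotAVolumeError,
    UnsupportedFormatError,
    ValidationError,
)

#: tolerance (mm) for deciding two lattices are the same
LATTICE_TOL_MM = 1e-6

AXES_CONVENTION = "axis0=L/R;axis1=A/P;axis2=S/I"

Role = Literal["target", "oar"]


def _as_triple(x, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValidationError(f"{name} must have exactly 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class DoseGrid:
    """A dense 3-D scalar dose field (Gy) on a regular lattice.

    Parameters
    ----------
    values
        3-D array of finite, non-negative dose values in Gy.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        Physical position (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise NotAVolumeError(f"not a 3-D volume: payload has {v.ndim} dimension(s)")
        if not np.all(np.isfinite(v)):
            raise NonFiniteDoseError("dose grid contains NaN or Inf")
        if v.size and float(v.min()) < 0.0:
            raise NegativeDoseError(f"dose grid contains negative values (min={v.min():g})")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", _as_triple(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _as_triple(self.origin, "origin"))
        if any(s <= 0 for s in self.spacing):
            raise NonPositiveSpacingError(f"non-positive voxel spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3 (spacing product / 1000)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def same_lattice(self, other: "DoseGrid", tol_mm: float = LATTICE_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin, other.origin))
        )

    def require_same_lattice(self, other: "DoseGrid", what: str = "grid") -> None:
        if not self.same_lattice(other):
            raise LatticeMismatchError(
                f"{what} lattice mismatch: shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}, "
                f"origin {self.origin} vs {other.origin}"
            )

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        """A new grid on the same lattice with different values."""
        return DoseGrid(values, self.spacing, self.origin)


@dataclass(frozen=True)
class ROIMask:
    """Boolean region-of-interest mask aligned to a DoseGrid lattice.

    ``rx`` is the prescription dose (Gy) of the owning plan; V-metrics and
    %Rx normalization refer to it.
    """

    mask: np.ndarray
    name: str
    role: Role
    rx: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise NotAVolumeError(f"ROI mask must be 3-D, got {m.ndim}-D")
        m = m.astype(bool)
        if not m.any():
            raise EmptyROIError(f"ROI '{self.name}' is empty")
        if self.role not in ("target", "oar"):
            raise ValidationError(f"ROI role must be 'target' or 'oar', got {self.role!r}")
        if not self.rx > 0:
            raise ValidationError(f"prescription dose must be > 0, got {self.rx}")
        object.__setattr__(self, "mask", m)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    def require_compatible(self, grid: DoseGrid) -> None:
        if self.mask.shape != grid.shape:
            raise LatticeMismatchError(
                f"ROI '{self.name}' shape {self.mask.shape} does not match "
                f"grid shape {grid.shape}"
            )

    def volume_cc(self, grid: DoseGrid) -> float:
        self.require_compatible(grid)
        return self.voxel_count * grid.voxel_volume_cc


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

Format = Literal["nrrd", "nifti", "dicom_rtdose"]

_SUFFIX_FORMATS = {
    ".nrrd": "nrrd",
    ".nhdr": "nrrd",
    ".nii": "nifti",
    ".gz": "nifti",  # .nii.gz
    ".dcm": "dicom_rtdose",
}


def _infer_format(path: Path) -> Format:
    fmt = _SUFFIX_FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise UnsupportedFormatError(f"cannot infer volume format from suffix of {path.name!r}")
    return fmt  # type: ignore[return-value]


def read_volume(path: str | Path, format: Format | None = None) -> DoseGrid:
    """Read a 3-D scalar volume into a :class:`DoseGrid`.

    Spacing and origin are taken from the file metadata.  DICOM RT Dose pixel
    data are scaled by the file's DoseGridScaling factor into Gy.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "nrrd":
        return _read_sitk(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom_rtdose":
        return _read_rtdose(path)
    raise UnsupportedFormatError(f"unsupported volume format {fmt!r}")


def write_volume(grid: DoseGrid, path: str | Path, format: Format | None = None) -> Path:
    """Write a :class:`DoseGrid` to NRRD or NIfTI-1.

    The written file round-trips through :func:`read_volume` with bitwise-equal
    values; spacing/origin round-trip within 1e-9 mm for exactly representable
    spacings (clinical grids use such values).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nrrd":
        return _write_sitk(grid, path)
    if fmt == "nifti":
        return _write_nifti(grid, path)
    raise UnsupportedFormatError(f"unsupported output format {fmt!r} (writable: nrrd, nifti)")


def _read_sitk(path: Path) -> DoseGrid:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise NotAVolumeError(f"not a 3-D volume: {path.name} has {arr.ndim} dimension(s)")
    values = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    return DoseGrid(values, img.GetSpacing(), img.GetOrigin())


def _write_sitk(grid: DoseGrid, path: Path) -> Path:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(grid.values, (2, 1, 0))))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    img.SetMetaData("axes_convention", AXES_CONVENTION)
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:  # pragma: no cover - depends on filesystem
        raise ValidationError(f"cannot write volume to {path}: {exc}") from exc
    return path


def _read_nifti(path: Path) -> DoseGrid:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise NotAVolumeError(f"not a 3-D volume: {path.name} has {data.ndim} dimension(s)")
    affine = np.asarray(img.affine, dtype=np.float64)
    spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    origin = tuple(float(v) for v in affine[:3, 3])
    return DoseGrid(np.asarray(data, dtype=np.float64), spacing, origin)


def _write_nifti(grid: DoseGrid, path: Path) -> Path:
    import nibabel as nib

    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(grid.values, affine)
    img.header["descrip"] = AXES_CONVENTION.encode()[:79]
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise ValidationError(f"cannot write volume to {path}: {exc}") from exc
    return path


def _read_rtdose(path: Path) -> DoseGrid:
    import pydicom

    ds = pydicom.dcmread(str(path))
    modality = getattr(ds, "Modality", None)
    if modality != "RTDOSE":
        raise UnsupportedFormatError(f"DICOM file {path.name} is not RT Dose (Modality={modality!r})")
    try:
        arr = ds.pixel_array  # (frames, rows, cols)
    except Exception as exc:
        raise UnsupportedFormatError(
            f"cannot decode pixel data of {path.name} (unsupported transfer syntax?): {exc}"
        ) from exc
    if arr.ndim != 3:
        raise NotAVolumeError(f"not a 3-D volume: RT Dose payload has {arr.ndim} dimension(s)")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    values = np.ascontiguousarray(np.transpose(arr.astype(np.float64) * scaling, (2, 1, 0)))
    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector], dtype=np.float64)
    dz = np.diff(offsets)
    if len(dz) and not np.allclose(dz, dz[0], atol=1e-6):
        raise UnsupportedFormatError("non-uniform GridFrameOffsetVector is not supported")
    z_mm = float(dz[0]) if len(dz) else 1.0
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values, (col_mm, row_mm, abs(z_mm)), origin)


def read_mask(
    path: str | Path,
    name: str,
    role: Role,
    rx: float,
    format: Format | None = None,
) -> ROIMask:
    """Read a label volume as an ROI mask (nonzero = inside)."""
    grid = read_volume(path, format=format)
    return ROIMask(grid.values != 0, name=name, role=role, rx=rx)


def write_mask(mask: ROIMask, grid: DoseGrid, path: str | Path, format: Format | None = None) -> Path:
    """Write an ROI mask as a 0/1 label volume on the given grid's lattice."""
    mask.require_compatible(grid)
    label = DoseGrid(mask.mask.astype(np.float64), grid.spacing, grid.origin)
    return write_volume(label, path, format=format)


def extract_axial_slice(grid: DoseGrid, index: int) -> np.ndarray:
    """The 2-D dose matrix at one S/I position (axis 2), values unchanged.

    Intended for external colorwash plotting of robustness maps.
    """
    n = grid.shape[2]
    if not 0 <= index < n:
        raise IndexError(f"axial slice index {index} out of range [0, {n})")
    return np.array(grid.values[:, :, index])


def require_common_lattice(grids: Iterable[DoseGrid]) -> None:
    """Raise LatticeMismatchError unless all grids share one lattice."""
    grids = list(grids)
    for g in grids[1:]:
        grids[0].require_same_lattice(g)
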