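"""Volume data model, file I/O and pipeline configuration.

Conventions
-----------
* Arrays are indexed ``(row, column, slice)``; the slice index is the z axis.
* Indices are 0-based; world coordinates (mm) are ``origin + index * spacing``.
* Undefined voxels ("NA") are carried in a dedicated boolean mask, never as a
  magic number inside the data grid.  On disk, NA is encoded as a sentinel
  recorded in a JSON sidecar next to the image stack.

Supported on-disk formats: multi-page TIFF stacks, directories of per-slice
TIFF files (assembled in lexicographic order), and NIfTI volumes whose header
carries the voxel spacing.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "ImageVolume",
    "TRSeries",
    "T1Map",
    "BinaryMask",
    "PipelineConfig",
    "read_volume",
    "write_volume",
]


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 or not math.isfinite(s) for s in spacing):
        raise ValueError(f"spacing must be three positive finite numbers, got {spacing!r}")
    return spacing


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with voxel geometry.

    Parameters
    ----------
    data:
        3D array, axis order (row, column, slice).
    spacing:
        Voxel edge lengths ``(dx, dy, dz)`` in mm; all positive.
    origin:
        World coordinates of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"data must be 3D, got ndim={data.ndim}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ul(self) -> float:
        """Voxel volume in microliters (1 mm^3 == 1 uL)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def same_geometry(self, other: "ImageVolume | T1Map | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map (N, 3) world mm coordinates to fractional voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass(frozen=True)
class TRSeries:
    """Ordered multi-TR series of T1-weighted volumes sharing one geometry."""

    entries: tuple[tuple[float, ImageVolume], ...]

    def __post_init__(self) -> None:
        entries = tuple((float(tr), vol) for tr, vol in self.entries)
        if len(entries) < 3:
            raise ValueError("a TR series needs at least 3 volumes")
        trs = [tr for tr, _ in entries]
        if any(b <= a for a, b in zip(trs, trs[1:])):
            raise ValueError(f"TR values must be strictly increasing, got {trs}")
        ref = entries[0][1]
        for tr, vol in entries[1:]:
            if not ref.same_geometry(vol):
                raise ValueError(f"volume at TR={tr} ms does not share the series geometry")
        object.__setattr__(self, "entries", entries)

    @property
    def tr_values(self) -> np.ndarray:
        return np.array([tr for tr, _ in self.entries])

    @property
    def geometry(self) -> ImageVolume:
        return self.entries[0][1]

    def stacked(self) -> np.ndarray:
        """Signals as a (n_tr, rows, cols, slices) array."""
        return np.stack([vol.data for _, vol in self.entries], axis=0)


@dataclass(frozen=True)
class T1Map:
    """Voxel-wise longitudinal relaxation times (ms) with an NA mask.

    ``na_mask`` is True exactly where the fit failed or produced a T1 below
    the physical floor (cement, noise-only voxels, superparamagnetic
    artifact).  ``fit_quality`` holds the coefficient of determination of the
    recovery-model fit, defined only where ``na_mask`` is False.
    """

    t1: np.ndarray
    na_mask: np.ndarray
    fit_quality: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        t1 = np.asarray(self.t1, dtype=float)
        na = np.asarray(self.na_mask, dtype=bool)
        fq = np.asarray(self.fit_quality, dtype=float)
        if not (t1.shape == na.shape == fq.shape) or t1.ndim != 3:
            raise ValueError("t1, na_mask and fit_quality must be 3D arrays of one shape")
        object.__setattr__(self, "t1", t1)
        object.__setattr__(self, "na_mask", na)
        object.__setattr__(self, "fit_quality", fq)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape

    def defined(self) -> np.ndarray:
        return ~self.na_mask

    def as_volume(self) -> ImageVolume:
        data = self.t1.copy()
        data[self.na_mask] = np.nan
        return ImageVolume(data, self.spacing, self.origin)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean voxel mask sharing the geometry of its source volume."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("mask must be 3D")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# default calibration range over which the linear relaxivity model is trusted
DEFAULT_VALID_RANGE_MM = (0.1, 5.0)


@dataclass
class PipelineConfig:
    """All tunable parameters of the quantification pipeline.

    ``r1_mM_per_ms`` is the longitudinal relaxivity of the contrast agent in
    mM^-1 ms^-1 (0.0038 for Gd-DTPA at 3-7 T when T1 is expressed in ms).
    ``t1_floor_ms`` is the threshold below which a fitted T1 is declared NA.
    ``cement_density_g_per_mL`` has no default: it must be supplied when an
    implant volume is to be derived from implant weight.
    """

    tr_list_ms: tuple[float, ...] = (1463.0, 2000.0, 3000.0, 5000.0)
    r1_mM_per_ms: float = 0.0038
    bin_width_ms: float = 50.0
    min_component_px: int = 100
    connectivity: int = 6
    spacing_mm: tuple[float, float, float] = (0.3, 0.3, 2.0)
    t1_floor_ms: float = 1.0
    valid_range_mM: tuple[float, float] = DEFAULT_VALID_RANGE_MM
    rng_seed: int = 0
    cement_density_g_per_mL: float | None = None

    def __post_init__(self) -> None:
        for name in ("r1_mM_per_ms", "bin_width_ms", "t1_floor_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        _check_spacing(self.spacing_mm)
        lo, hi = self.valid_range_mM
        if not (0 < lo < hi):
            raise ValueError("valid_range_mM must satisfy 0 < lower < upper")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from a YAML or JSON document; keyword overrides win."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        doc.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tr_list_ms", "spacing_mm", "valid_range_mM"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# Readers / writers


_NA_SENTINEL = -1.0


def read_volume(path: str | Path, spacing: Sequence[float] | None = None) -> ImageVolume:
    """Read a volume from a TIFF stack, a directory of slice TIFFs, or NIfTI.

    ``spacing`` overrides (and for header-less TIFF is required unless a JSON
    sidecar written by :func:`write_volume` is present).  Per-slice files are
    assembled in lexicographic order; a slice-shape mismatch is a hard error.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        pages = [tifffile.imread(p) for p in slices]
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        data = np.stack(pages, axis=-1)  # (row, col, slice)
    elif path.suffix.lower() in (".nii", ".gz") or "".join(path.suffixes).lower().endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
        if spacing is None:
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    else:
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None, ...]
        data = np.moveaxis(pages, 0, -1)  # pages are slices

    if spacing is None:
        if "spacing_mm" in meta:
            spacing = tuple(meta["spacing_mm"])
        else:
            raise ValueError(
                f"{path} carries no voxel spacing; pass spacing= or provide a JSON sidecar"
            )
    origin = tuple(meta.get("origin_mm", (0.0, 0.0, 0.0)))

    data = np.asarray(data)
    if "na_sentinel" in meta and meta["na_sentinel"] is not None:
        data = data.astype(float)
        data[data == meta["na_sentinel"]] = np.nan
    return ImageVolume(data, spacing=spacing, origin=origin)


def write_volume(
    volume: ImageVolume,
    path: str | Path,
    format: str = "tiff",
    dtype: str = "float32",
) -> None:
    """Write a volume as a multi-page TIFF (one page per slice) or NIfTI.

    NaN voxels are encoded with a sentinel recorded in a JSON sidecar along
    with spacing and dtype, so ``read_volume`` restores them losslessly.
    Supported dtypes: ``float32`` and ``uint16``.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    data = np.asarray(volume.data)
    has_na = bool(np.isnan(data).any()) if np.issubdtype(data.dtype, np.floating) else False
    sentinel = _NA_SENTINEL if has_na else None

    if format == "nifti":
        import nibabel as nib

        out = data.astype(np.float32)
        if has_na:
            out = np.where(np.isnan(out), np.float32(sentinel), out)
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(out, affine), str(path))
    elif format == "tiff":
        if dtype == "uint16":
            if has_na:
                raise ValueError("uint16 TIFF cannot encode NA voxels; use float32")
            out = data.astype(np.uint16)
        elif dtype == "float32":
            out = data.astype(np.float32)
            if has_na:
                out = np.where(np.isnan(out), np.float32(sentinel), out)
        else:
            raise ValueError(f"unsupported dtype {dtype!r}")
        pages = np.moveaxis(out, -1, 0)  # slice axis first
        tifffile.imwrite(path, pages, photometric="minisblack")
    else:
        raise ValueError(f"unsupported format {format!r}")

    meta = {
        "spacing_mm": list(volume.spacing),
        "origin_mm": list(volume.origin),
        "dtype": dtype if format == "tiff" else "float32",
        "na_sentinel": sentinel,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Serialize a binary mask as a 0/255 uint8 TIFF stack."""
    vol = ImageVolume(np.where(mask.mask, 255, 0).astype(np.uint16), mask.spacing, mask.origin)
    write_volume(vol, path, format="tiff", dtype="uint16")


def read_mask(path: str | Path, spacing: Sequence[float] | None = None) -> BinaryMask:
    vol = read_volume(path, spacing=spacing)
    return BinaryMask(vol.data > 0, vol.spacing, vol.origin)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json") if path.is_dir() else path.with_suffix(path.suffix + ".json")
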