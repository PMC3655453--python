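"""Landmark-based rigid and deformation registration with trilinear resampling.

Precontrast and postcontrast scans of the same leg are brought into one
frame by user-picked corresponding landmarks (typically on the femur, the
only rigid structure in the field of view).  Two transform families are
supported:

* **Rigid** (rotation + translation), the closed-form least-squares solution
  via the SVD of the landmark cross-covariance, with the determinant sign
  fixed so the rotation is proper.  An optional similarity mode adds one
  uniform scale factor.
* **Deformation**, a dense displacement field obtained by linearly
  interpolating the per-landmark displacement vectors (desired minus current
  position) over a Delaunay tetrahedralization of the landmarks; outside the
  convex hull the nearest landmark's displacement is used, optionally
  tapered to zero over a margin so edge voxels are not extrapolated wildly.

Resampling is pull-back trilinear interpolation; voxels that map outside the
moving volume become NA (NaN).

``compare_t10_methods`` reproduces the method comparison between a
registered voxel-wise native-T1 map and a single isotropic native value, as
difference maps of the resulting concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import cKDTree

from .concentration import DEFAULT_R1, t1_to_concentration
from .io_model import ImageVolume, T1Map
from .threshold_segment import ContrastRegion, SymmetricHistogramStats

__all__ = [
    "LandmarkPairs",
    "RigidTransform",
    "DisplacementField",
    "fit_rigid",
    "fit_deformation",
    "resample",
    "compare_t10_methods",
]


@dataclass(frozen=True)
class LandmarkPairs:
    """Index-paired landmark coordinates in world mm.

    ``fixed`` lives in the postcontrast frame, ``moving`` in the precontrast
    frame; row i of each refers to the same anatomical point.
    """

    fixed: np.ndarray
    moving: np.ndarray

    def __post_init__(self) -> None:
        fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        if fixed.shape != moving.shape or fixed.shape[1] != 3:
            raise ValueError("fixed and moving must be matching (N, 3) arrays")
        object.__setattr__(self, "fixed", fixed)
        object.__setattr__(self, "moving", moving)

    def __len__(self) -> int:
        return self.fixed.shape[0]

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkPairs":
        """Read landmarks from CSV with columns name, fx, fy, fz, mx, my, mz."""
        df = pd.read_csv(path)
        needed = ["fx", "fy", "fz", "mx", "my", "mz"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(f"landmark CSV {path} lacks columns {missing}")
        return cls(df[["fx", "fy", "fz"]].to_numpy(), df[["mx", "my", "mz"]].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            np.hstack([self.fixed, self.moving]),
            columns=["fx", "fy", "fz", "mx", "my", "mz"],
        )
        df.insert(0, "name", [f"p{i}" for i in range(len(self))])
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``x -> scale * R x + t`` (scale = 1 unless similarity)."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tra = np.asarray(self.translation, dtype=float).reshape(3)
        if rot.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-10):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-10):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.translation) @ self.rotation / self.scale


@dataclass(frozen=True)
class DisplacementField:
    """Per-voxel displacement vectors (mm) defined on the fixed grid.

    ``field[..., k]`` is the k-th displacement component; displacement maps a
    fixed-frame position to where the corresponding tissue sits in the fixed
    frame after warping, i.e. the moving-frame sample point is
    ``x_fixed - displacement``.
    """

    field: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        f = np.asarray(self.field, dtype=float)
        if f.ndim != 4 or f.shape[-1] != 3:
            raise ValueError("field must have shape (rows, cols, slices, 3)")
        if not np.isfinite(f).all():
            raise ValueError("displacement field must be finite everywhere")
        object.__setattr__(self, "field", f)


def _rank_of_spread(points: np.ndarray) -> int:
    centered = points - points.mean(axis=0)
    return int(np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())))


def fit_rigid(pairs: LandmarkPairs, allow_scale: bool = False) -> RigidTransform:
    """Least-squares rigid (optionally similarity) transform from landmarks.

    Centroids are subtracted, the cross-covariance is decomposed by SVD, and
    a reflection (det < 0) is corrected by flipping the smallest singular
    direction, minimizing ``sum ||R m_i + t - f_i||^2``.
    """
    if len(pairs) < 3:
        raise ValueError("rigid fit needs at least 3 landmark pairs")
    if _rank_of_spread(pairs.moving) < 2:
        raise ValueError("moving landmarks are collinear; rotation is not determined")
    mov, fix = pairs.moving, pairs.fixed
    mc, fc = mov.mean(axis=0), fix.mean(axis=0)
    m0, f0 = mov - mc, fix - fc
    h = m0.T @ f0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    if allow_scale:
        denom = (m0**2).sum()
        scale = float((s * np.diag(diag)).sum() / denom)
    else:
        scale = 1.0
    tra = fc - scale * rot @ mc
    return RigidTransform(rotation=rot, translation=tra, scale=scale)


def fit_deformation(
    pairs: LandmarkPairs,
    grid: ImageVolume | T1Map,
    taper_margin_mm: float | None = None,
) -> DisplacementField:
    """Dense displacement field from landmark displacements.

    The displacement at each landmark is ``fixed - moving`` (desired minus
    current location after any rigid pre-alignment).  Inside the landmark
    convex hull the field is the barycentric-linear interpolant over the
    Delaunay tetrahedralization; outside, the nearest landmark's
    displacement, tapered linearly to zero over ``taper_margin_mm`` beyond
    the nearest landmark if a margin is given.
    """
    if len(pairs) < 4:
        raise ValueError("deformation fit needs at least 4 landmark pairs")
    if _rank_of_spread(pairs.fixed) < 3:
        raise ValueError("fixed landmarks are coplanar; tetrahedralization is degenerate")
    disp = pairs.fixed - pairs.moving
    shape = grid.shape
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = np.asarray(grid.origin) + idx * np.asarray(grid.spacing)

    lin = LinearNDInterpolator(pairs.fixed, disp)
    values = lin(world)
    outside = ~np.isfinite(values[:, 0])
    if outside.any():
        near = NearestNDInterpolator(pairs.fixed, disp)
        filled = near(world[outside])
        if taper_margin_mm is not None:
            dist, _ = cKDTree(pairs.fixed).query(world[outside])
            weight = np.clip(1.0 - dist / taper_margin_mm, 0.0, 1.0)
            filled = filled * weight[:, None]
        values[outside] = filled
    return DisplacementField(
        field=values.reshape(*shape, 3),
        spacing=grid.spacing,
        origin=grid.origin,
    )


def resample(
    volume: ImageVolume,
    transform: RigidTransform | DisplacementField,
    out_geometry: ImageVolume | T1Map | None = None,
) -> ImageVolume:
    """Pull-back trilinear resampling of ``volume`` onto the fixed grid.

    For a rigid transform mapping moving to fixed coordinates, each output
    voxel at fixed position x samples the input at ``R^T (x - t)``.  For a
    displacement field, the sample point is ``x - displacement(x)``.  Sample
    points outside the input domain become NaN (NA).
    """
    if out_geometry is None:
        out_geometry = volume if isinstance(transform, RigidTransform) else transform
    shape = out_geometry.shape if not isinstance(out_geometry, DisplacementField) else out_geometry.field.shape[:3]
    spacing = np.asarray(out_geometry.spacing)
    origin = np.asarray(out_geometry.origin)
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = origin + idx * spacing

    if isinstance(transform, RigidTransform):
        sample_world = transform.inverse_apply(world)
    elif isinstance(transform, DisplacementField):
        disp = transform.field.reshape(-1, 3)
        if disp.shape[0] != world.shape[0]:
            raise ValueError("displacement field geometry does not match the output grid")
        sample_world = world - disp
    else:
        raise TypeError(f"unsupported transform type {type(transform)!r}")

    coords = (sample_world - np.asarray(volume.origin)) / np.asarray(volume.spacing)
    data = np.asarray(volume.data, dtype=float)
    out = ndimage.map_coordinates(data, coords.T, order=1, mode="constant", cval=np.nan)
    eps = 1e-9
    inside = np.all((coords >= -eps) & (coords <= np.asarray(volume.shape) - 1 + eps), axis=1)
    out[~inside] = np.nan
    return ImageVolume(out.reshape(shape), tuple(spacing), tuple(origin))


def compare_t10_methods(
    pre: T1Map,
    post: T1Map,
    region: ContrastRegion,
    stats: SymmetricHistogramStats,
    rigid: RigidTransform | None = None,
    deformation: DisplacementField | None = None,
    r1: float = DEFAULT_R1,
) -> dict[str, np.ndarray]:
    """Concentration maps under four native-T1 policies and their differences.

    Arms: (a) unregistered voxel-wise T1_0 from ``pre`` as-is, (b) rigidly
    registered ``pre``, (c) deformation-registered ``pre``, (d) a single
    isotropic T1_0 (= ``stats.peak_t1``).  Returns the four concentration
    arrays plus pairwise differences a-d, b-d, c-d; NaN marks NA voxels or
    out-of-support resampling, the white regions of a difference rendering.
    """
    if pre.shape != post.shape:
        raise ValueError("pre and post maps must share geometry")
    rmask = region.mask.mask
    defined = post.defined() & rmask

    def conc_with_t10_map(t10: np.ndarray) -> np.ndarray:
        out = np.full(post.shape, np.nan)
        ok = defined & np.isfinite(t10) & (t10 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (1.0 / post.t1[ok] - 1.0 / t10[ok]) / r1
        out[ok] = np.maximum(raw, 0.0)
        return out

    pre_vol = pre.as_volume()
    arms: dict[str, np.ndarray] = {}
    arms["unregistered"] = conc_with_t10_map(pre_vol.data)
    if rigid is not None:
        arms["rigid"] = conc_with_t10_map(resample(pre_vol, rigid, out_geometry=post).data)
    if deformation is not None:
        arms["deformation"] = conc_with_t10_map(resample(pre_vol, deformation, out_geometry=post).data)
    iso = np.full(post.shape, np.nan)
    ok = defined
    iso[ok] = t1_to_concentration(post.t1[ok], stats.peak_t1, r1)
    arms["isotropic"] = iso

    result = dict(arms)
    for name in ("unregistered", "rigid", "deformation"):
        if name in arms:
            result[f"diff_{name}_minus_isotropic"] = arms[name] - arms["isotropic"]
    return result
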