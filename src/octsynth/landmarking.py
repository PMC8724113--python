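"""Correspondence between dense boundary surfaces and landmark vectors.

A retinal OCT volume's geometric label is a ``SurfaceSet``: K ordered
boundary surfaces given as axial depth ``z_k(x, b)`` over image columns
x and B-scan index b.  For shape modelling each boundary curve is reduced
to a fixed number of corresponded landmarks (default 51 per B-scan, so
51 × 19 = 969 per surface in the default geometry): the first at the
left-most column, the last at the right-most, the middle one anchored at
the foveal column, and the rest evenly spaced within each half.  The
inverse operation interpolates landmarks back onto every column with a
monotone cubic and re-imposes the anatomical non-crossing order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .shape_model import DimensionError, ShapeVector

__all__ = [
    "SurfaceSet",
    "LandmarkGrid",
    "SurfaceError",
    "fovea_columns",
    "extract_landmarks",
    "landmarks_to_surfaces",
    "extract_landmarks_2d",
    "landmarks_to_curves_2d",
]


class SurfaceError(ValueError):
    pass


@dataclass
class SurfaceSet:
    """K non-crossing boundary surfaces of one OCT volume.

    ``surfaces`` has shape (K, B, W): axial depth in voxels per surface,
    B-scan and column.  Depth increases downward (vitreous → choroid).
    """

    surfaces: np.ndarray
    axial_depth: int
    spacing: tuple[float, float, float] | None = None  # (dx, dy, dz) µm/voxel
    volume_id: str = ""

    def __post_init__(self):
        z = np.asarray(self.surfaces, dtype=float)
        if z.ndim != 3:
            raise SurfaceError("surfaces must be a (K, B, W) array")
        if not np.all(np.isfinite(z)):
            raise SurfaceError("surface depths must be finite")
        if np.any(z < 0) or np.any(z >= self.axial_depth):
            raise SurfaceError("surface depths must lie within [0, axial_depth)")
        if np.any(np.diff(z, axis=0) < -1e-9):
            k, b, x = np.unravel_index(
                np.argmin(np.diff(z, axis=0)), np.diff(z, axis=0).shape
            )
            raise SurfaceError(
                f"surfaces cross: z_{k + 2} < z_{k + 1} at B-scan {b}, column {x}"
            )
        self.surfaces = z

    @property
    def n_surfaces(self) -> int:
        return self.surfaces.shape[0]

    @property
    def n_bscans(self) -> int:
        return self.surfaces.shape[1]

    @property
    def width(self) -> int:
        return self.surfaces.shape[2]


@dataclass(frozen=True)
class LandmarkGrid:
    """Sampling layout linking a ShapeVector to surface geometry."""

    n_surfaces: int
    n_bscans: int
    points_per_curve: int
    column_indices: np.ndarray
    axial_depth: int
    width: int

    @property
    def n_landmarks(self) -> int:
        return self.n_surfaces * self.n_bscans * self.points_per_curve


def _landmark_columns(width: int, points_per_curve: int, fovea_column: float) -> np.ndarray:
    """Column positions: ends pinned, middle landmark at the fovea, halves even."""
    p = points_per_curve
    mid = p // 2  # 0-based index of the middle landmark (25 for p=51)
    left = np.linspace(0.0, float(fovea_column), mid + 1)
    right = np.linspace(float(fovea_column), float(width - 1), p - mid)
    return np.concatenate([left, right[1:]])


def fovea_columns(surfaces: SurfaceSet) -> float:
    """Foveal column: minimum total retinal thickness on the central B-scan."""
    central = surfaces.n_bscans // 2
    thickness = surfaces.surfaces[-1, central] - surfaces.surfaces[0, central]
    return float(np.argmin(thickness))


def extract_landmarks(
    surfaces: SurfaceSet,
    points_per_curve: int = 51,
    fovea_column: int | str = "auto",
) -> tuple[ShapeVector, LandmarkGrid]:
    """Sample each boundary curve at corresponded columns.

    Landmarks are ordered surface-major, then B-scan, then column; each
    carries 3D coordinates (x=column, y=B-scan index, z=interpolated depth).
    """
    W = surfaces.width
    if W < points_per_curve:
        raise SurfaceError(
            f"width {W} is narrower than points_per_curve {points_per_curve}"
        )
    if fovea_column == "auto":
        fovea_column = fovea_columns(surfaces)
    fovea_column = float(fovea_column)
    if not 0 <= fovea_column < W:
        raise SurfaceError(f"fovea_column {fovea_column} outside image [0, {W})")

    cols = _landmark_columns(W, points_per_curve, fovea_column)
    grid = LandmarkGrid(
        n_surfaces=surfaces.n_surfaces,
        n_bscans=surfaces.n_bscans,
        points_per_curve=points_per_curve,
        column_indices=cols,
        axial_depth=surfaces.axial_depth,
        width=W,
    )
    xs = np.arange(W, dtype=float)
    pts = []
    for k in range(surfaces.n_surfaces):
        for b in range(surfaces.n_bscans):
            z = np.interp(cols, xs, surfaces.surfaces[k, b])
            pts.append(np.column_stack([cols, np.full_like(cols, b), z]))
    return ShapeVector.from_points(np.concatenate(pts)), grid


def _reconstruct_curve(
    x_lm: np.ndarray, z_lm: np.ndarray, width: int
) -> np.ndarray:
    """Monotone-cubic interpolation of one boundary's landmarks onto all
    columns; landmark abscissae are sorted and made strictly increasing."""
    order = np.argsort(x_lm, kind="stable")
    x = x_lm[order].copy()
    z = z_lm[order]
    # enforce strictly increasing abscissae (sampled shapes can jitter x)
    for i in range(1, x.size):
        if x[i] <= x[i - 1]:
            x[i] = x[i - 1] + 1e-6
    interp = PchipInterpolator(x, z, extrapolate=True)
    return interp(np.arange(width, dtype=float))


def landmarks_to_surfaces(
    x: ShapeVector,
    layout: LandmarkGrid,
    target_width: int | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> SurfaceSet:
    """Rebuild dense surfaces from a (possibly synthesized) landmark vector.

    Non-crossing is enforced by a cumulative-max projection from the top
    surface down, and depths are clamped into [0, axial_depth).
    """
    if x.n_landmarks != layout.n_landmarks or x.dim != 3:
        raise DimensionError("shape vector inconsistent with landmark layout")
    W = int(target_width or layout.width)
    K, B, p = layout.n_surfaces, layout.n_bscans, layout.points_per_curve
    pts = x.points.reshape(K, B, p, 3)
    z = np.empty((K, B, W), dtype=float)
    for k in range(K):
        for b in range(B):
            z[k, b] = _reconstruct_curve(pts[k, b, :, 0], pts[k, b, :, 2], W)
    z = np.maximum.accumulate(z, axis=0)  # ordering projection, top down
    np.clip(z, 0.0, layout.axial_depth - 1e-9, out=z)
    return SurfaceSet(surfaces=z, axial_depth=layout.axial_depth, spacing=spacing)


# --------------------------------------------------------------------------
# 2D variants (DME B-scans: K boundary curves, no B-scan axis)
# --------------------------------------------------------------------------


def extract_landmarks_2d(
    boundaries: np.ndarray,
    axial_depth: int,
    points_per_curve: int = 51,
    fovea_column: int | str = "center",
) -> tuple[ShapeVector, LandmarkGrid]:
    """Landmark a single B-scan's K boundary curves; coordinates are (x, z)."""
    boundaries = np.asarray(boundaries, dtype=float)
    K, W = boundaries.shape
    if W < points_per_curve:
        raise SurfaceError("image narrower than points_per_curve")
    anchor = W // 2 if fovea_column == "center" else float(fovea_column)
    cols = _landmark_columns(W, points_per_curve, anchor)
    grid = LandmarkGrid(
        n_surfaces=K,
        n_bscans=1,
        points_per_curve=points_per_curve,
        column_indices=cols,
        axial_depth=axial_depth,
        width=W,
    )
    xs = np.arange(W, dtype=float)
    pts = []
    for k in range(K):
        z = np.interp(cols, xs, boundaries[k])
        pts.append(np.column_stack([cols, z]))
    return ShapeVector.from_points(np.concatenate(pts)), grid


def landmarks_to_curves_2d(
    x: ShapeVector, layout: LandmarkGrid, target_width: int | None = None
) -> np.ndarray:
    """Rebuild K dense boundary curves (K, W) from a 2D landmark vector."""
    if x.n_landmarks != layout.n_surfaces * layout.points_per_curve or x.dim != 2:
        raise DimensionError("shape vector inconsistent with 2D layout")
    W = int(target_width or layout.width)
    pts = x.points.reshape(layout.n_surfaces, layout.points_per_curve, 2)
    z = np.empty((layout.n_surfaces, W), dtype=float)
    for k in range(layout.n_surfaces):
        z[k] = _reconstruct_curve(pts[k, :, 0], pts[k, :, 1], W)
    z = np.maximum.accumulate(z, axis=0)
    np.clip(z, 0.0, layout.axial_depth - 1e-9, out=z)
    return z
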