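"""Grids, world coordinates, planar contours and polygon utilities.

Every quantity that leaves a module is expressed in world millimetres.
Volumes are stored ``(nz, ny, nx)`` with axis-aligned geometry: voxel
``(i, j, k)`` (slice, row, column) sits at
``origin + (k*sx, j*sy, i*sz)``, i.e. the origin is the *centre* of the
first voxel.  Voxel indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path
from scipy import ndimage

from ._exceptions import DegenerateContourError, InvalidInputError

__all__ = [
    "Volume",
    "Slice2D",
    "PlanarContour",
    "polygon_area_centroid",
    "ensure_ccw",
    "ray_polygon_intersection",
    "densify_polygon",
    "polygon_mask",
    "contour_stack_mask",
]


@dataclass
class Volume:
    """A 3D image (or binary mask) with world-coordinate metadata.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values, slice-major.
    spacing : tuple of float
        Voxel size ``(sx, sy, sz)`` in mm.
    origin : tuple of float
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidInputError(
                f"volume data must be 3D (nz, ny, nx), got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise InvalidInputError("spacing and origin must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise InvalidInputError(f"spacing must be positive, got {self.spacing}")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def in_plane_spacing(self) -> float:
        return min(self.spacing[0], self.spacing[1])

    def slice_z(self, i: int) -> float:
        """World z (mm) of slice ``i``."""
        return self.origin[2] + i * self.spacing[2]

    def slice_zs(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.n_slices) * self.spacing[2]

    def get_slice(self, i: int) -> "Slice2D":
        return Slice2D(
            data=self.data[i],
            spacing=self.spacing[:2],
            origin=self.origin[:2],
            z=self.slice_z(i),
        )

    def index_from_world(self, points: np.ndarray) -> np.ndarray:
        """Map world mm points ``(..., 3)`` (x, y, z) to fractional voxel
        indices ``(..., 3)`` ordered (i, j, k) = (slice, row, col)."""
        p = np.asarray(points, dtype=float)
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        out = np.empty_like(p)
        out[..., 0] = (p[..., 2] - oz) / sz
        out[..., 1] = (p[..., 1] - oy) / sy
        out[..., 2] = (p[..., 0] - ox) / sx
        return out

    def world_from_index(self, idx: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`index_from_world`."""
        q = np.asarray(idx, dtype=float)
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        out = np.empty_like(q)
        out[..., 0] = ox + q[..., 2] * sx
        out[..., 1] = oy + q[..., 1] * sy
        out[..., 2] = oz + q[..., 0] * sz
        return out

    def contains_world(self, point) -> bool:
        i, j, k = self.index_from_world(np.asarray(point, dtype=float))
        nz, ny, nx = self.data.shape
        return (-0.5 <= i <= nz - 0.5) and (-0.5 <= j <= ny - 0.5) and (
            -0.5 <= k <= nx - 0.5
        )


@dataclass
class Slice2D:
    """One transversal slice with in-plane geometry.

    ``data`` is ``(ny, nx)``; a world point ``(x, y)`` maps to the
    fractional index ``((y - oy)/sy, (x - ox)/sx)``.
    """

    data: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    z: float = 0.0

    @property
    def in_plane_spacing(self) -> float:
        return min(self.spacing)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Bilinear interpolation at world-mm points ``(..., 2)``.

        Samples outside the image footprint come back as NaN, which is
        how downstream code detects clipped search regions.
        """
        p = np.asarray(points, dtype=float)
        shape = p.shape[:-1]
        flat = p.reshape(-1, 2)
        yi = (flat[:, 1] - self.origin[1]) / self.spacing[1]
        xi = (flat[:, 0] - self.origin[0]) / self.spacing[0]
        vals = ndimage.map_coordinates(
            self.data.astype(float),
            np.vstack([yi, xi]),
            order=1,
            mode="constant",
            cval=np.nan,
        )
        return vals.reshape(shape)

    def pixel_centers(self) -> np.ndarray:
        """World (x, y) coordinates of all pixel centres, shape (ny*nx, 2)."""
        ny, nx = self.data.shape
        xs = self.origin[0] + np.arange(nx) * self.spacing[0]
        ys = self.origin[1] + np.arange(ny) * self.spacing[1]
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class PlanarContour:
    """A closed planar polygon (mm) at a fixed world z.

    The closing edge from the last vertex back to the first is implicit;
    vertices are not repeated.
    """

    points: np.ndarray  # (N, 2) world mm
    z: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidInputError("contour points must be (N, 2)")
        if self.points.shape[0] < 3:
            raise InvalidInputError("a closed contour needs at least 3 vertices")
        self.z = float(self.z)

    @property
    def centroid(self) -> np.ndarray:
        _, c = polygon_area_centroid(self.points)
        return c


def polygon_area_centroid(pts: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed area and area centroid of a closed polygon (shoelace).

    Degenerate (zero-area) polygons fall back to the vertex mean.
    """
    p = np.asarray(pts, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        return 0.0, p.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return float(area), np.array([cx, cy])


def ensure_ccw(pts: np.ndarray) -> np.ndarray:
    """Return the polygon with counter-clockwise vertex order."""
    area, _ = polygon_area_centroid(pts)
    p = np.asarray(pts, dtype=float)
    return p if area >= 0 else p[::-1].copy()


def ray_polygon_intersection(
    origin: np.ndarray, direction: np.ndarray, pts: np.ndarray
) -> np.ndarray:
    """Farthest intersection of the ray ``origin + t*direction`` (t > 0)
    with a closed polygon's boundary.

    Raises
    ------
    DegenerateContourError
        If the ray misses the boundary entirely (the polygon is not
        star-shaped about ``origin``).
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    a = np.asarray(pts, dtype=float)
    b = np.roll(a, -1, axis=0)
    e = b - a
    ao = a - o
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ao[:, 0] * e[:, 1] - ao[:, 1] * e[:, 0]) / denom
        s = (ao[:, 0] * d[1] - ao[:, 1] * d[0]) / denom
    ok = (np.abs(denom) > 1e-12) & (s >= 0.0) & (s < 1.0) & (t > 1e-12)
    if not ok.any():
        raise DegenerateContourError(
            "ray from centroid does not intersect the contour boundary"
        )
    t_hit = t[ok].max()  # ties resolved by taking the farthest hit
    return o + t_hit * d


def densify_polygon(pts: np.ndarray, max_step: float = 0.5) -> np.ndarray:
    """Resample a closed polygon's boundary at arc spacing <= ``max_step`` mm.

    Each edge is subdivided uniformly; the subdivided points include each
    edge's start vertex but not its end (which starts the next edge), so
    the result has no duplicates.
    """
    p = np.asarray(pts, dtype=float)
    out = []
    for a, b in zip(p, np.roll(p, -1, axis=0)):
        length = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(length / max_step)))
        frac = np.arange(n) / n
        out.append(a + frac[:, None] * (b - a))
    return np.vstack(out)


def polygon_mask(contour: PlanarContour, sl: Slice2D) -> np.ndarray:
    """Rasterize a closed contour onto a slice grid.

    A pixel belongs to the mask iff its centre lies inside the polygon
    (even-odd rule; half-open convention at the boundary).
    """
    ny, nx = sl.data.shape
    verts = np.vstack([contour.points, contour.points[:1]])
    path = Path(verts, closed=True)
    inside = path.contains_points(sl.pixel_centers())
    return inside.reshape(ny, nx)


def contour_stack_mask(
    contours: list[PlanarContour], grid: Volume, z_tol: float | None = None
) -> np.ndarray:
    """Rasterize a stack of per-slice contours into a 3D boolean mask.

    Each contour fills the grid slice whose world z is nearest to the
    contour's z (within ``z_tol``, default half the slice spacing);
    slices without a contour stay empty.
    """
    mask = np.zeros(grid.data.shape, dtype=bool)
    if z_tol is None:
        z_tol = 0.5 * grid.spacing[2] + 1e-9
    zs = grid.slice_zs()
    for c in contours:
        i = int(np.argmin(np.abs(zs - c.z)))
        if abs(zs[i] - c.z) > z_tol:
            continue
        mask[i] |= polygon_mask(c, grid.get_slice(i))
    return mask
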