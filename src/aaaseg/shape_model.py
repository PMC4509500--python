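"""3D point-distribution model of straightened aortic cross sections.

An aneurysm shape is described by 19 transversal slices of 20 equiangular
boundary landmarks (380 points, 1140 scalar coordinates).  Straightening
translates every slice so its landmark centre of mass sits at the origin,
discarding centreline variation: the model captures per-slice dilation and
cross-sectional shape only.  PCA over a training set yields the mean shape
``x̄``, modes ``Φ_i`` and variances ``λ_i``; any plausible shape is

    x = x̄ + Σ_{i<=c} b_i Φ_i,   D_m = Σ b_i²/λ_i <= M_t,

where ``c`` retains a chosen fraction of total variance and the
Mahalanobis bound ``M_t`` is the χ² quantile at probability ``t`` with
``c`` degrees of freedom.  Parameter vectors violating the bound are
scaled back onto the M_t shell by a single proportionality constant
``α = sqrt(M_t / D_m)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._exceptions import (
    DegenerateModelError,
    InvalidInputError,
)
from .geometry import (
    PlanarContour,
    ensure_ccw,
    polygon_area_centroid,
    ray_polygon_intersection,
)

__all__ = [
    "N_SLICES",
    "N_LANDMARKS",
    "LandmarkShape",
    "ShapeModel",
    "ShapeParams",
    "resample_contour_stack",
    "place_landmarks",
    "landmark_contour_stack",
    "straighten",
    "unstraighten",
    "pca_modes",
    "build_shape_model",
    "chi2_threshold",
    "project",
    "reconstruct",
    "constrain",
    "apply_shape_constraint",
    "resample_stack_z",
]

N_SLICES = 19
N_LANDMARKS = 20

# landmark angles: counter-clockwise from anterior (+y)
def landmark_angles(n_landmarks: int = N_LANDMARKS) -> np.ndarray:
    return np.pi / 2 + 2 * np.pi * np.arange(n_landmarks) / n_landmarks


@dataclass
class LandmarkShape:
    """One landmarked aorta: 19 slices x 20 landmarks of (x, y, z) mm.

    ``slice_centroids`` holds the per-slice centre of mass removed by
    :func:`straighten` (present iff ``is_straightened``).
    """

    points: np.ndarray  # (19, 20, 3)
    is_straightened: bool = False
    slice_centroids: np.ndarray | None = None  # (19, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_SLICES, N_LANDMARKS, 3):
            raise InvalidInputError(
                f"landmark shape must be ({N_SLICES}, {N_LANDMARKS}, 3), "
                f"got {self.points.shape}"
            )
        if self.is_straightened:
            if self.slice_centroids is None:
                raise InvalidInputError(
                    "straightened shapes must record their slice centroids"
                )
            self.slice_centroids = np.asarray(self.slice_centroids, dtype=float)
            if self.slice_centroids.shape != (N_SLICES, 3):
                raise InvalidInputError("slice_centroids must be (19, 3)")

    @property
    def n_points(self) -> int:
        return self.points.shape[0] * self.points.shape[1]

    def flatten(self) -> np.ndarray:
        """The 1140-vector form consumed by the PCA machinery."""
        return self.points.reshape(-1).copy()

    @classmethod
    def from_flat(
        cls,
        x: np.ndarray,
        is_straightened: bool = False,
        slice_centroids: np.ndarray | None = None,
    ) -> "LandmarkShape":
        pts = np.asarray(x, dtype=float).reshape(N_SLICES, N_LANDMARKS, 3)
        return cls(pts, is_straightened=is_straightened, slice_centroids=slice_centroids)


@dataclass
class ShapeModel:
    """Trained point-distribution model.

    Attributes
    ----------
    mean_shape : (1140,) mm
    eigenvectors : (1140, c), orthonormal columns Φ_i
    eigenvalues : (c,) mm², sorted descending
    n_training : size of the training set
    variability_fraction : fraction of total variance retained
    t : plausibility probability used for M_t
    m_t : χ² quantile at t with c degrees of freedom
    """

    mean_shape: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    n_training: int
    variability_fraction: float
    t: float
    m_t: float

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.eigenvectors.shape != (self.mean_shape.size, self.eigenvalues.size):
            raise InvalidInputError("eigenvector matrix shape mismatch")
        if np.any(self.eigenvalues <= 0):
            raise InvalidInputError("retained eigenvalues must be positive")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise InvalidInputError("eigenvalues must be sorted descending")

    @property
    def c(self) -> int:
        """Number of retained modes of variation."""
        return int(self.eigenvalues.size)


@dataclass
class ShapeParams:
    """Mode coefficients of a projected shape.

    ``d_m`` is the squared Mahalanobis distance Σ b_i²/λ_i; ``alpha`` is
    the rescaling applied by :func:`constrain` (1.0 when unconstrained).
    """

    b: np.ndarray
    d_m: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)


# ---------------------------------------------------------------------------
# landmarking


def place_landmarks(
    contour: PlanarContour,
    n_landmarks: int = N_LANDMARKS,
    origin: np.ndarray | None = None,
) -> np.ndarray:
    """Place equiangular landmarks on a closed contour by ray casting.

    Rays emanate from ``origin`` (default: the contour's area centroid)
    at angles 90°, 90° + 360/n, ... counter-clockwise, so the first
    landmark is the contour point in the anterior (+y) direction through
    the origin's sagittal (x) coordinate.  When a ray crosses the
    boundary more than once the farthest crossing is taken.

    Returns ``(n_landmarks, 2)`` points in mm.

    Raises :class:`DegenerateContourError` when a ray misses the contour
    (i.e. the contour is not star-shaped about the origin).
    """
    if n_landmarks < 1:
        raise InvalidInputError("n_landmarks must be >= 1")
    pts = ensure_ccw(contour.points)
    if origin is None:
        _, origin = polygon_area_centroid(pts)
    origin = np.asarray(origin, dtype=float)
    out = np.empty((n_landmarks, 2))
    for k, theta in enumerate(landmark_angles(n_landmarks)):
        d = np.array([np.cos(theta), np.sin(theta)])
        out[k] = ray_polygon_intersection(origin, d, pts)
    return out


def resample_contour_stack(
    contours: list[PlanarContour],
    n_slices: int = N_SLICES,
    n_theta: int = 72,
) -> list[PlanarContour]:
    """Interpolate a z-ordered stack of closed contours onto ``n_slices``
    evenly spaced slices.

    Intermediate contours are built by linearly blending the radial
    profiles (about each contour's own centroid) and the centroids of the
    two bracketing input contours.  A target z that coincides with an
    input z returns that contour unchanged.
    """
    if len(contours) < 2:
        raise InvalidInputError("need at least 2 contours to resample a stack")
    zs = np.array([c.z for c in contours])
    order = np.argsort(zs)
    contours = [contours[i] for i in order]
    zs = zs[order]
    if np.any(np.diff(zs) <= 1e-12):
        raise InvalidInputError("contour z positions must be distinct")

    thetas = landmark_angles(n_theta)
    dirs = np.column_stack([np.cos(thetas), np.sin(thetas)])

    def radial_profile(c: PlanarContour) -> tuple[np.ndarray, np.ndarray]:
        pts = ensure_ccw(c.points)
        _, ctr = polygon_area_centroid(pts)
        r = np.empty(n_theta)
        for i in range(n_theta):
            hit = ray_polygon_intersection(ctr, dirs[i], pts)
            r[i] = np.linalg.norm(hit - ctr)
        return r, ctr

    profiles = [None] * len(contours)  # lazy: only computed where needed
    centroids = [None] * len(contours)

    def get_profile(i: int):
        if profiles[i] is None:
            profiles[i], centroids[i] = radial_profile(contours[i])
        return profiles[i], centroids[i]

    target_z = np.linspace(zs[0], zs[-1], n_slices)
    out: list[PlanarContour] = []
    for z in target_z:
        exact = np.where(np.abs(zs - z) < 1e-9)[0]
        if exact.size:
            src = contours[exact[0]]
            out.append(PlanarContour(src.points.copy(), z=float(z)))
            continue
        hi = int(np.searchsorted(zs, z))
        lo = hi - 1
        w = (z - zs[lo]) / (zs[hi] - zs[lo])
        r0, c0 = get_profile(lo)
        r1, c1 = get_profile(hi)
        r = (1 - w) * r0 + w * r1
        ctr = (1 - w) * c0 + w * c1
        pts = ctr[None, :] + r[:, None] * dirs
        out.append(PlanarContour(pts, z=float(z)))
    return out


def landmark_contour_stack(
    contours: list[PlanarContour], n_landmarks: int = N_LANDMARKS
) -> LandmarkShape:
    """Resample a contour stack to 19 slices and landmark each slice.

    Convenience used for training-set preparation; rays originate at each
    contour's own centroid.
    """
    stack = resample_contour_stack(contours, N_SLICES)
    pts = np.empty((N_SLICES, n_landmarks, 3))
    for i, c in enumerate(stack):
        lm = place_landmarks(c, n_landmarks)
        pts[i, :, :2] = lm
        pts[i, :, 2] = c.z
    return LandmarkShape(pts)


# ---------------------------------------------------------------------------
# straightening


def straighten(shape: LandmarkShape) -> LandmarkShape:
    """Translate each slice so its landmark centre of mass is the origin.

    The removed centroids (including each slice's z) are recorded so the
    operation is exactly invertible by :func:`unstraighten`.
    """
    if shape.is_straightened:
        raise InvalidInputError("shape is already straightened")
    centroids = shape.points.mean(axis=1)  # (19, 3)
    pts = shape.points - centroids[:, None, :]
    return LandmarkShape(pts, is_straightened=True, slice_centroids=centroids)


def unstraighten(shape: LandmarkShape) -> LandmarkShape:
    if not shape.is_straightened:
        raise InvalidInputError("shape is not straightened")
    pts = shape.points + shape.slice_centroids[:, None, :]
    return LandmarkShape(pts, is_straightened=False)


# ---------------------------------------------------------------------------
# PCA


def pca_modes(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """PCA of row observations with the 1/(n-1) covariance convention.

    Uses the dual (n x n Gram) eigenproblem when n - 1 < d, which gives
    the identical nonzero spectrum at a fraction of the cost for the
    1140-dimensional shape space.

    Returns ``(mean, eigenvectors, eigenvalues, total_variance)`` with
    eigenvalues sorted descending and numerically-zero modes dropped.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        raise InvalidInputError("PCA needs at least 2 observations")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float((Xc**2).sum() / (n - 1))
    if n - 1 < d:
        G = (Xc @ Xc.T) / (n - 1)
        w, U = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        w, U = w[order], U[:, order]
        keep = w > max(w.max(), 0.0) * 1e-10
        keep &= w > 1e-14
        if not keep.any():
            raise DegenerateModelError("training set has no shape variance")
        w, U = w[keep], U[:, keep]
        V = Xc.T @ U / np.sqrt((n - 1) * w)
    else:
        S = (Xc.T @ Xc) / (n - 1)
        w, V = np.linalg.eigh(S)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        keep = (w > max(w.max(), 0.0) * 1e-10) & (w > 1e-14)
        if not keep.any():
            raise DegenerateModelError("training set has no shape variance")
        w, V = w[keep], V[:, keep]
    return mean, V, w, total_var


def chi2_threshold(c: int, t: float) -> float:
    """χ² inverse CDF at probability ``t`` with ``c`` degrees of freedom.

    This is the Mahalanobis plausibility bound M_t: if the mode
    coefficients are independently Gaussian, D_m follows χ²(c), so a
    fraction ``t`` of genuine shapes satisfies D_m <= M_t.
    """
    if c < 1:
        raise InvalidInputError("degrees of freedom must be >= 1")
    if not 0.0 < t < 1.0:
        raise InvalidInputError("t must lie strictly between 0 and 1")
    return float(stats.chi2.ppf(t, df=c))


def build_shape_model(
    shapes: list[LandmarkShape],
    variability_fraction: float = 0.95,
    t: float = 0.90,
) -> ShapeModel:
    """Train the point-distribution model from straightened shapes.

    ``c`` is the smallest mode count whose cumulative eigenvalue fraction
    reaches ``variability_fraction`` of the total variance; ``M_t`` is
    :func:`chi2_threshold`(c, t).
    """
    if len(shapes) < 2:
        raise InvalidInputError("need at least 2 training shapes")
    if not 0.0 < variability_fraction <= 1.0:
        raise InvalidInputError("variability_fraction must be in (0, 1]")
    for s in shapes:
        if not s.is_straightened:
            raise InvalidInputError("training shapes must be straightened")
    X = np.stack([s.flatten() for s in shapes])
    mean, V, w, total_var = pca_modes(X)
    cum = np.cumsum(w) / total_var
    idx = np.nonzero(cum >= variability_fraction - 1e-12)[0]
    c = int(idx[0]) + 1 if idx.size else int(w.size)
    return ShapeModel(
        mean_shape=mean,
        eigenvectors=V[:, :c],
        eigenvalues=w[:c],
        n_training=len(shapes),
        variability_fraction=variability_fraction,
        t=t,
        m_t=chi2_threshold(c, t),
    )


# ---------------------------------------------------------------------------
# projection / constraint


def project(shape: LandmarkShape, model: ShapeModel) -> ShapeParams:
    """Least-squares mode coefficients of a straightened shape.

    ``b = Φᵀ (x - x̄)`` (the eigenvectors are orthonormal, so this is the
    exact least-squares inverse of the linear shape model).
    """
    if not shape.is_straightened:
        raise InvalidInputError("project() expects a straightened shape")
    x = shape.flatten()
    if x.size != model.mean_shape.size:
        raise InvalidInputError("shape/model dimension mismatch")
    b = model.eigenvectors.T @ (x - model.mean_shape)
    d_m = float(np.sum(b**2 / model.eigenvalues))
    return ShapeParams(b=b, d_m=d_m)


def reconstruct(params: ShapeParams, model: ShapeModel) -> np.ndarray:
    """Flattened shape ``x̄ + Σ b_i Φ_i`` (straightened frame)."""
    return model.mean_shape + model.eigenvectors @ params.b


def constrain(params: ShapeParams, model: ShapeModel) -> ShapeParams:
    """Rescale mode coefficients onto the plausibility shell if needed.

    Shapes with D_m <= M_t pass through unchanged (alpha = 1); otherwise
    every b_i is multiplied by alpha = sqrt(M_t / D_m) so the constrained
    distance equals M_t exactly.  Idempotent.
    """
    if params.d_m <= model.m_t:
        return ShapeParams(b=params.b.copy(), d_m=params.d_m, alpha=1.0)
    alpha = float(np.sqrt(model.m_t / params.d_m))
    b = alpha * params.b
    return ShapeParams(b=b, d_m=float(np.sum(b**2 / model.eigenvalues)), alpha=alpha)


def resample_stack_z(stack: np.ndarray, n_out: int) -> np.ndarray:
    """Linearly resample a (k, m, 3) landmark stack along the slice axis
    onto ``n_out`` evenly spaced virtual slices (normalized parameter)."""
    stack = np.asarray(stack, dtype=float)
    k = stack.shape[0]
    if k == n_out:
        return stack.copy()
    if k < 2:
        raise InvalidInputError("need at least 2 slices to resample in z")
    tau_in = np.linspace(0.0, 1.0, k)
    tau_out = np.linspace(0.0, 1.0, n_out)
    flat = stack.reshape(k, -1)
    out = np.empty((n_out, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(tau_out, tau_in, flat[:, j])
    return out.reshape(n_out, stack.shape[1], 3)


def apply_shape_constraint(stack: np.ndarray, model: ShapeModel) -> np.ndarray:
    """Straighten -> project -> constrain -> reconstruct -> unstraighten.

    ``stack`` is a (k, 20, 3) landmark array in image world mm.  A stack
    with k != 19 slices is linearly resampled in z onto the model's 19
    virtual slices before the constraint and back after.  Per-slice
    centroids (and slice z positions) of the input are preserved exactly.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1:] != (N_LANDMARKS, 3):
        raise InvalidInputError(f"stack must be (k, {N_LANDMARKS}, 3)")
    k = stack.shape[0]
    work = resample_stack_z(stack, N_SLICES)
    shape = LandmarkShape(work)
    s = straighten(shape)
    params = constrain(project(s, model), model)
    recon = LandmarkShape.from_flat(
        reconstruct(params, model),
        is_straightened=True,
        slice_centroids=s.slice_centroids,
    )
    out19 = unstraighten(recon).points
    if k != N_SLICES:
        out = resample_stack_z(out19, k)
    else:
        out = out19
    # pin each slice's centroid (and z) exactly to the input's
    in_centroids = stack.mean(axis=1)
    out_centroids = out.mean(axis=1)
    out = out - out_centroids[:, None, :] + in_centroids[:, None, :]
    out[:, :, 2] = stack[:, :, 2]
    return out
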