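"""Full delineation pipeline: lumen → thrombus boundary → outer wall.

The lumen is segmented once in 3D on the contrast channel with a
region-based (two-phase, Chan–Vese-style) level set grown from a seed
ball.  Its per-slice centroids, mapped into the segmentation channel
through world coordinates, anchor everything downstream: a 2D level set
initialized with a circle at each centroid proposes the first thrombus
contour; 20 equiangular landmarks are then refined by alternating
texture-statistic proposals with the statistical shape restriction until
the landmarks stop moving.  The outer wall is found by an outward-only
positive-gradient search from the thrombus landmarks, capped at a 3 mm
wall thickness, with the same shape restriction.

Everything here is deterministic: the only randomness in the package
lives in the phantom generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import disk_level_set, morphological_chan_vese

from ._exceptions import (
    InvalidInputError,
    LumenFailure,
    RegionFailure,
    RegistrationFailure,
)
from .appearance import extract_region, score_candidates
from .config import PipelineConfig, config_hash
from .geometry import PlanarContour, Slice2D, Volume, contour_stack_mask
from .phantom import StudyPair
from .shape_model import (
    N_LANDMARKS,
    ShapeModel,
    apply_shape_constraint,
    place_landmarks,
)

__all__ = [
    "SegmentationResult",
    "segment_lumen_3d",
    "map_lumen_centroids",
    "init_thrombus",
    "fit_thrombus",
    "search_outer_wall",
    "fit_outer_wall",
    "segment_study",
    "segment_thrombus_only",
    "landmarks_to_contours",
]


@dataclass
class SegmentationResult:
    """Everything the pipeline produced for one study."""

    lumen_mask: Volume
    centroids: list  # per MRI slice: (x, y) mm or None
    slice_indices: list[int]  # MRI slices actually segmented
    thrombus_landmarks: np.ndarray  # (k, 20, 3) world mm
    outer_landmarks: np.ndarray  # (k, 20, 3) world mm
    thrombus_mask: Volume
    outer_mask: Volume
    iterations_thrombus: int
    iterations_outer: int
    converged_thrombus: bool
    converged_outer: bool
    flags: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def thrombus_contours(self) -> list[PlanarContour]:
        return landmarks_to_contours(self.thrombus_landmarks)

    def outer_contours(self) -> list[PlanarContour]:
        return landmarks_to_contours(self.outer_landmarks)


def landmarks_to_contours(stack: np.ndarray) -> list[PlanarContour]:
    """View a (k, 20, 3) landmark stack as per-slice closed contours."""
    return [PlanarContour(s[:, :2], z=float(s[0, 2])) for s in np.asarray(stack, float)]


# ---------------------------------------------------------------------------
# lumen


def segment_lumen_3d(
    mra: Volume, seed: np.ndarray, cfg: PipelineConfig | None = None
) -> Volume:
    """3D region-based level-set lumen segmentation from a seed point.

    The level set starts as a ball of ``seed_ball_radius_mm`` around the
    seed and evolves under a two-phase region model; the connected
    component containing the seed is returned.  The component must be
    brighter than its complement (the lumen is the contrast-filled
    structure) — otherwise the evolution is deemed to have collapsed.
    """
    cfg = cfg or PipelineConfig()
    seed = np.asarray(seed, dtype=float)
    if not mra.contains_world(seed):
        raise InvalidInputError(f"seed {seed.tolist()} lies outside the volume")
    idx = mra.index_from_world(seed)
    nz, ny, nx = mra.data.shape
    zi, yi, xi = np.ogrid[0:nz, 0:ny, 0:nx]
    sx, sy, sz = mra.spacing
    dist2 = (
        ((zi - idx[0]) * sz) ** 2
        + ((yi - idx[1]) * sy) ** 2
        + ((xi - idx[2]) * sx) ** 2
    )
    init = dist2 <= cfg.seed_ball_radius_mm**2
    ls = morphological_chan_vese(
        mra.data.astype(float),
        num_iter=cfg.levelset_iters_3d,
        init_level_set=init.astype(np.int8),
        smoothing=cfg.levelset_smoothing_3d,
    )
    seed_vox = tuple(np.round(idx).astype(int))
    if not ls[seed_vox]:
        raise LumenFailure("level-set evolution collapsed away from the seed")
    labels, _ = ndimage.label(ls)
    comp = labels == labels[seed_vox]
    inside = mra.data[comp]
    outside = mra.data[~comp]
    if outside.size and inside.mean() <= outside.mean():
        raise LumenFailure("seed region is not brighter than its surroundings")
    return Volume(comp, mra.spacing, mra.origin)


def map_lumen_centroids(lumen_mask: Volume, mri: Volume) -> list:
    """Per-MRI-slice lumen centroids (world mm) via world-coordinate
    nearest-neighbour resampling of the lumen mask.

    The "registration" between the two channels is the identity in world
    coordinates (their geometry metadata already places them in the same
    physical frame).  Returns one entry per MRI slice: an (x, y) array
    or None where the lumen does not intersect the slice.
    """
    nz, ny, nx = mri.data.shape
    out = []
    any_overlap = False
    xs = mri.origin[0] + np.arange(nx) * mri.spacing[0]
    ys = mri.origin[1] + np.arange(ny) * mri.spacing[1]
    gx, gy = np.meshgrid(xs, ys)
    mz, my, mx = lumen_mask.data.shape
    for i in range(nz):
        z = mri.slice_z(i)
        pts = np.stack(
            [gx.ravel(), gy.ravel(), np.full(gx.size, z)], axis=-1
        )
        idx = np.round(lumen_mask.index_from_world(pts)).astype(int)
        ok = (
            (idx[:, 0] >= 0)
            & (idx[:, 0] < mz)
            & (idx[:, 1] >= 0)
            & (idx[:, 1] < my)
            & (idx[:, 2] >= 0)
            & (idx[:, 2] < mx)
        )
        vals = np.zeros(gx.size, dtype=bool)
        vals[ok] = lumen_mask.data[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        if vals.any():
            any_overlap = True
            out.append(
                np.array([gx.ravel()[vals].mean(), gy.ravel()[vals].mean()])
            )
        else:
            out.append(None)
    if not any_overlap:
        raise RegistrationFailure("lumen mask does not overlap the MRI volume")
    return out


# ---------------------------------------------------------------------------
# thrombus


def _circle_landmarks(centroid: np.ndarray, radius: float, n: int = N_LANDMARKS):
    th = np.pi / 2 + 2 * np.pi * np.arange(n) / n
    return centroid[None, :] + radius * np.column_stack([np.cos(th), np.sin(th)])


def init_thrombus(
    image: Slice2D,
    centroid: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> tuple[np.ndarray, bool]:
    """Initial thrombus landmarks on one slice via a 2D level set.

    A circle of ``init_circle_radius_mm`` at the lumen centroid seeds a
    region-based level set; the converged front's contour is landmarked
    equiangularly with rays from the lumen centroid.  On failure (front
    collapse, escape to the image border, or a non-star-shaped front)
    the initial circle itself is landmarked and flagged.

    Returns ``(landmarks (20, 2) mm, failed_flag)``.
    """
    cfg = cfg or PipelineConfig()
    centroid = np.asarray(centroid, dtype=float)
    ny, nx = image.data.shape
    ci = (
        (centroid[1] - image.origin[1]) / image.spacing[1],
        (centroid[0] - image.origin[0]) / image.spacing[0],
    )
    if not (0 <= ci[0] < ny and 0 <= ci[1] < nx):
        raise InvalidInputError("centroid lies outside the slice")
    r_px = cfg.init_circle_radius_mm / image.in_plane_spacing
    init = disk_level_set(image.data.shape, center=ci, radius=r_px)
    ls = morphological_chan_vese(
        image.data.astype(float),
        num_iter=cfg.levelset_iters_2d,
        init_level_set=init,
        smoothing=cfg.levelset_smoothing_2d,
    )
    fallback = _circle_landmarks(centroid, cfg.init_circle_radius_mm)
    cy, cx = int(round(ci[0])), int(round(ci[1]))
    if not ls[cy, cx]:
        return fallback, True
    labels, _ = ndimage.label(ls)
    comp = labels == labels[cy, cx]
    border = (
        comp[0].any() or comp[-1].any() or comp[:, 0].any() or comp[:, -1].any()
    )
    min_area_px = np.pi * (2.0 / image.in_plane_spacing) ** 2  # 2 mm circle
    if border or comp.sum() < min_area_px:
        return fallback, True
    contour = _mask_to_contour(comp, image, centroid)
    if contour is None:
        return fallback, True
    try:
        lm = place_landmarks(contour, N_LANDMARKS, origin=centroid)
    except Exception:
        return fallback, True
    return lm, False


def _mask_to_contour(
    mask: np.ndarray, image: Slice2D, inside_point: np.ndarray
) -> PlanarContour | None:
    """Marching-squares contour of a binary mask, in world mm."""
    from matplotlib.path import Path
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    best, best_area = None, 0.0
    for c in contours:
        # rows are y indices, cols are x indices
        pts = np.column_stack(
            [
                image.origin[0] + c[:, 1] * image.spacing[0],
                image.origin[1] + c[:, 0] * image.spacing[1],
            ]
        )
        if pts.shape[0] < 3:
            continue
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if pts.shape[0] < 3:
            continue
        path = Path(np.vstack([pts, pts[:1]]), closed=True)
        if not path.contains_point(inside_point):
            continue
        from .geometry import polygon_area_centroid

        area, _ = polygon_area_centroid(pts)
        if abs(area) > best_area:
            best, best_area = pts, abs(area)
    if best is None:
        return None
    return PlanarContour(best, z=image.z)


def fit_thrombus(
    mri: Volume,
    centroids: list,
    model: ShapeModel,
    cfg: PipelineConfig | None = None,
    initial_landmarks: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int], int, bool, dict]:
    """Iterative texture-proposal / shape-restriction thrombus fit.

    Each iteration proposes, for every landmark, the radial offset that
    maximizes the summed normalized texture statistics in its search
    region, then projects the full landmark stack onto the shape model
    and rescales it inside the plausibility bound.  Iteration stops when
    the largest landmark displacement falls below
    ``tol_factor * in-plane spacing``, or at ``max_iter``.

    Returns ``(landmarks (k,20,3), slice_indices, iterations, converged,
    flags)``.
    """
    cfg = cfg or PipelineConfig()
    slice_indices = _contiguous_slices(centroids)
    if len(slice_indices) < 3:
        raise InvalidInputError("need at least 3 slices with lumen centroids")

    if initial_landmarks is None:
        stacks = []
        flags: dict = {"init_failed_slices": []}
        for s in slice_indices:
            lm, failed = init_thrombus(mri.get_slice(s), centroids[s], cfg)
            if failed:
                flags["init_failed_slices"].append(s)
            stacks.append(np.column_stack([lm, np.full(N_LANDMARKS, mri.slice_z(s))]))
        L = np.stack(stacks)
    else:
        L = np.asarray(initial_landmarks, dtype=float).copy()
        flags = {"init_failed_slices": []}

    tol = cfg.tol_factor * mri.in_plane_spacing
    converged = False
    iters = 0
    flags["region_failures"] = []
    combo = tuple(cfg.combo)
    for it in range(cfg.max_iter):
        iters = it + 1
        proposals = L.copy()
        for si, s in enumerate(slice_indices):
            sl = mri.get_slice(s)
            ctr = centroids[s]
            for j in range(N_LANDMARKS):
                lm = L[si, j, :2]
                u = lm - ctr
                r = np.linalg.norm(u)
                if r < 1e-9:
                    continue
                u = u / r
                region = extract_region(
                    sl,
                    lm,
                    ctr,
                    length_mm=cfg.region_length_mm,
                    width_mm=cfg.region_width_mm,
                    step_mm=cfg.step_factor * sl.in_plane_spacing,
                    landmark_index=j,
                )
                try:
                    off, _ = score_candidates(region, combo, cfg.normalization)
                except RegionFailure:
                    flags["region_failures"].append((s, j))
                    continue
                proposals[si, j, :2] = lm + off * u
        if cfg.use_shape_constraint:
            proposals = apply_shape_constraint(proposals, model)
        disp = float(np.max(np.linalg.norm(proposals - L, axis=-1)))
        L = proposals
        if disp < tol:
            converged = True
            break
    return L, slice_indices, iters, converged, flags


def _contiguous_slices(centroids: list) -> list[int]:
    """Longest contiguous run of slices with a lumen centroid."""
    runs, cur = [], []
    for i, c in enumerate(centroids):
        if c is not None:
            cur.append(i)
        else:
            if cur:
                runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    if not runs:
        return []
    return max(runs, key=len)


# ---------------------------------------------------------------------------
# outer wall


def search_outer_wall(
    image: Slice2D,
    thrombus_landmarks: np.ndarray,
    centroid: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Outward positive-gradient search for the outer wall on one slice.

    For each thrombus landmark the radial intensity profile is sampled
    outward over ``max_wall_thickness_mm`` (averaged over a tangential
    window of the same width) and the offset with the largest strictly
    positive radial derivative — the dark-wall to brighter-surroundings
    transition — is selected.  Profiles with no positive derivative keep
    the minimum wall offset and are flagged.

    Returns ``(outer_landmarks (20, 2), flagged (20,) bool)``.
    """
    cfg = cfg or PipelineConfig()
    centroid = np.asarray(centroid, dtype=float)
    lms = np.asarray(thrombus_landmarks, dtype=float)[:, :2]
    h = cfg.step_factor * image.in_plane_spacing
    n_r = int(round(cfg.max_wall_thickness_mm / h))
    r_off = h * np.arange(0, n_r + 1)
    n_half_t = int(round(0.5 * cfg.max_wall_thickness_mm / h))
    t_off = h * np.arange(-n_half_t, n_half_t + 1)
    out = np.empty_like(lms)
    flagged = np.zeros(len(lms), dtype=bool)
    for j, lm in enumerate(lms):
        u = lm - centroid
        r = np.linalg.norm(u)
        if r < 1e-9:
            out[j] = lm
            flagged[j] = True
            continue
        u = u / r
        v = np.array([-u[1], u[0]])
        pts = (
            lm[None, None, :]
            + r_off[:, None, None] * u[None, None, :]
            + t_off[None, :, None] * v[None, None, :]
        )
        prof = np.nanmean(image.sample(pts), axis=1)
        with np.errstate(invalid="ignore"):
            grad = np.gradient(prof, h)
        cand = np.arange(cfg.min_wall_steps, len(r_off))
        ok = cand[np.isfinite(grad[cand]) & (grad[cand] > 0)]
        if ok.size == 0:
            off = cfg.min_wall_steps * h
            flagged[j] = True
        else:
            best = ok[np.argmax(grad[ok])]  # argmax returns first on ties
            off = r_off[best]
        out[j] = lm + off * u
    return out, flagged


def fit_outer_wall(
    mri: Volume,
    thrombus_landmarks: np.ndarray,
    slice_indices: list[int],
    centroids: list,
    model: ShapeModel,
    cfg: PipelineConfig | None = None,
) -> tuple[np.ndarray, int, bool, dict]:
    """Iterative gradient-proposal / shape-restriction outer-wall fit.

    Proposals always search outward from the (fixed) thrombus landmarks;
    the shape restriction then regularizes the stack, and a radial clamp
    enforces the outward-only and 3 mm thickness invariants landmark by
    landmark.  Convergence rule as in :func:`fit_thrombus`.
    """
    cfg = cfg or PipelineConfig()
    th = np.asarray(thrombus_landmarks, dtype=float)
    h = cfg.step_factor * mri.in_plane_spacing
    flags: dict = {"no_gradient": [], "clamped": []}

    proposals = th.copy()
    for si, s in enumerate(slice_indices):
        lm2, fl = search_outer_wall(mri.get_slice(s), th[si], centroids[s], cfg)
        proposals[si, :, :2] = lm2
        for j in np.nonzero(fl)[0]:
            flags["no_gradient"].append((s, int(j)))

    tol = cfg.tol_factor * mri.in_plane_spacing
    L = th.copy()
    L[:, :, :2] = np.stack([p[:, :2] for p in proposals])
    converged = False
    iters = 0
    for it in range(cfg.max_iter):
        iters = it + 1
        nxt = proposals.copy()
        if cfg.use_shape_constraint:
            nxt = apply_shape_constraint(nxt, model)
        nxt = _clamp_outward(nxt, th, slice_indices, centroids, h, cfg, flags)
        disp = float(np.max(np.linalg.norm(nxt - L, axis=-1)))
        L = nxt
        if disp < tol:
            converged = True
            break
    return L, iters, converged, flags


def _clamp_outward(outer, thrombus, slice_indices, centroids, h, cfg, flags):
    """Clamp outer landmark radii to [r_th + h_min, r_th + 3 mm + h]."""
    out = outer.copy()
    h_min = cfg.min_wall_steps * h
    for si, s in enumerate(slice_indices):
        ctr = centroids[s]
        for j in range(out.shape[1]):
            d_out = out[si, j, :2] - ctr
            r_out = np.linalg.norm(d_out)
            r_th = np.linalg.norm(thrombus[si, j, :2] - ctr)
            lo = r_th + h_min
            hi = r_th + cfg.max_wall_thickness_mm + h
            r_new = min(max(r_out, lo), hi)
            if r_out < 1e-9:
                u = (thrombus[si, j, :2] - ctr) / max(r_th, 1e-9)
                out[si, j, :2] = ctr + r_new * u
                flags["clamped"].append((s, int(j)))
            elif abs(r_new - r_out) > 1e-12:
                out[si, j, :2] = ctr + r_new * (d_out / r_out)
                flags["clamped"].append((s, int(j)))
    return out


# ---------------------------------------------------------------------------
# full pipeline


def segment_study(
    pair: StudyPair,
    seed: np.ndarray,
    model: ShapeModel,
    cfg: PipelineConfig | None = None,
) -> SegmentationResult:
    """Run the full lumen → thrombus → outer-wall pipeline on one study."""
    cfg = cfg or PipelineConfig()
    lumen = segment_lumen_3d(pair.mra, seed, cfg)
    centroids = map_lumen_centroids(lumen, pair.mri)
    th, slices, it_th, conv_th, flags_th = fit_thrombus(
        pair.mri, centroids, model, cfg
    )
    outer, it_out, conv_out, flags_out = fit_outer_wall(
        pair.mri, th, slices, centroids, model, cfg
    )
    th_mask = contour_stack_mask(landmarks_to_contours(th), pair.mri)
    out_mask = contour_stack_mask(landmarks_to_contours(outer), pair.mri)
    return SegmentationResult(
        lumen_mask=lumen,
        centroids=centroids,
        slice_indices=slices,
        thrombus_landmarks=th,
        outer_landmarks=outer,
        thrombus_mask=Volume(th_mask, pair.mri.spacing, pair.mri.origin),
        outer_mask=Volume(out_mask, pair.mri.spacing, pair.mri.origin),
        iterations_thrombus=it_th,
        iterations_outer=it_out,
        converged_thrombus=conv_th,
        converged_outer=conv_out,
        flags={"thrombus": flags_th, "outer": flags_out},
        provenance={"config_hash": config_hash(cfg), "seed": cfg.seed},
    )


def segment_thrombus_only(
    pair: StudyPair,
    seed: np.ndarray,
    model: ShapeModel,
    cfg: PipelineConfig | None = None,
) -> Volume:
    """Lumen + thrombus stages only; returns the thrombus mask.

    Used by the appearance-combination search, which scores combinations
    on the thrombus boundary alone.
    """
    cfg = cfg or PipelineConfig()
    lumen = segment_lumen_3d(pair.mra, seed, cfg)
    centroids = map_lumen_centroids(lumen, pair.mri)
    th, _, _, _, _ = fit_thrombus(pair.mri, centroids, model, cfg)
    mask = contour_stack_mask(landmarks_to_contours(th), pair.mri)
    return Volume(mask, pair.mri.spacing, pair.mri.origin)
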