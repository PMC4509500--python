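"""Synthetic AAA phantom studies.

Each phantom study emulates the two MR channels the pipeline consumes:

* channel 1 (segmentation channel, bSSFP-like): bright intraluminal
  thrombus, a dark 1.5-2.5 mm wall ring, and heterogeneous surroundings;
* channel 2 (angiography channel, FLASH-MRA-like): bright lumen on a
  dark background.

Geometry per slice is a lumen circle nested inside a Fourier-perturbed
thrombus contour, with the outer wall a fixed-thickness offset of the
thrombus.  A mild sinusoidal centreline wobble exercises the
straightening machinery; the radial bulge profile along z mimics the
fusiform dilation of an aneurysm sac.  Optional confounders reproduce
the documented failure scenarios: hypo-/hyperintense structures
adjacent to the outer wall, and a two-component thrombus that traps the
level-set initialization.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``, so datasets are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._exceptions import InvalidInputError
from .geometry import PlanarContour, Volume, contour_stack_mask
from .shape_model import (
    LandmarkShape,
    landmark_contour_stack,
    straighten,
)

__all__ = [
    "PhantomSpec",
    "PhantomStudy",
    "StudyPair",
    "sample_phantom_shape",
    "render_phantom",
    "generate_study",
    "generate_dataset",
    "sample_training_shapes",
]


@dataclass
class StudyPair:
    """The two co-registered channels of one study (world mm geometry)."""

    mri: Volume  # thrombus-contrast channel
    mra: Volume  # lumen-contrast channel


@dataclass
class PhantomSpec:
    """Generating parameters of a phantom study.

    Defaults define the nominal benchmark conditions: 19 slices of
    6 mm thickness on an 80 x 80 grid of 1 mm pixels (a ~108 mm aortic
    section), wall thickness uniform in [1.5, 2.5] mm so the 3 mm search
    limit is non-binding, and channel-1 noise sigma of 2.5, i.e. 5% of
    the 50-unit thrombus/background contrast.
    """

    n_slices: int = 19
    nx: int = 80
    ny: int = 80
    spacing: tuple[float, float, float] = (1.0, 1.0, 6.0)
    # geometry (mm)
    lumen_radius: float = 7.0
    thrombus_radius_base: float = 10.0
    bulge_amplitude_range: tuple[float, float] = (4.0, 8.0)
    bulge_center_range: tuple[float, float] = (0.35, 0.65)
    bulge_width_range: tuple[float, float] = (0.25, 0.45)
    radius_scale_range: tuple[float, float] = (0.85, 1.15)
    fourier_orders: tuple[int, ...] = (2, 3)
    fourier_sigma: float = 0.04
    fourier_max: float = 0.12
    fourier_twist_sigma: float = 0.3
    wall_thickness_range: tuple[float, float] = (1.5, 2.5)
    axis_amplitude_mm: float = 2.0
    min_lumen_margin_mm: float = 1.5
    # channel-1 intensities
    lumen_intensity: float = 160.0
    thrombus_intensity: float = 150.0
    wall_intensity: float = 60.0
    background_intensity: float = 100.0
    background_texture_sigma: float = 8.0
    noise_sigma: float = 2.5
    # channel-2 intensities
    mra_lumen_intensity: float = 200.0
    mra_background_intensity: float = 50.0
    mra_noise_sigma: float = 5.0
    mra_origin_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # confounders: tuple of dicts, e.g. {"kind": "hyper_adjacent"}
    confounders: tuple = ()
    n_theta: int = 72

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise InvalidInputError("need at least 2 slices")
        if self.lumen_radius <= 0 or self.thrombus_radius_base <= 0:
            raise InvalidInputError("radii must be positive")
        lo, hi = self.wall_thickness_range
        if lo <= 0:
            raise InvalidInputError("wall thickness must be positive")

    @property
    def grid_center(self) -> np.ndarray:
        return np.array(
            [(self.nx - 1) / 2 * self.spacing[0], (self.ny - 1) / 2 * self.spacing[1]]
        )

    def with_confounder(self, kind: str, **kw) -> "PhantomSpec":
        return replace(self, confounders=self.confounders + ({"kind": kind, **kw},))


@dataclass
class PhantomStudy:
    """A rendered phantom: image pair, ground truth and provenance."""

    pair: StudyPair
    lumen_mask: Volume
    thrombus_mask: Volume
    outer_mask: Volume
    contours: dict  # {"lumen"|"thrombus"|"outer": list[PlanarContour]}
    seed_point: np.ndarray  # world mm, inside the lumen
    spec: PhantomSpec
    seed: int


def _theta_grid(n: int) -> np.ndarray:
    # anterior-first, counter-clockwise, matching the landmark convention
    return np.pi / 2 + 2 * np.pi * np.arange(n) / n


def sample_phantom_shape(rng: np.random.Generator, spec: PhantomSpec) -> dict:
    """Draw one study's ground-truth contour stacks.

    Returns ``{"lumen": [...], "thrombus": [...], "outer": [...]}``,
    each a list of ``n_slices`` closed planar contours (world mm) at the
    slice z positions.  Nesting (lumen ⊂ thrombus ⊂ outer) is enforced
    by construction and re-checked before returning.
    """
    n = spec.n_slices
    z = np.arange(n) * spec.spacing[2]
    z_norm = np.arange(n) / (n - 1)
    theta = _theta_grid(spec.n_theta)

    scale = rng.uniform(*spec.radius_scale_range)
    wall = rng.uniform(*spec.wall_thickness_range)
    # fusiform sac: Gaussian dilation bulge with per-study amplitude,
    # centre and width along the section
    bulge_amp = rng.uniform(*spec.bulge_amplitude_range)
    bulge_mu = rng.uniform(*spec.bulge_center_range)
    bulge_sd = rng.uniform(*spec.bulge_width_range)
    amps = np.clip(
        rng.normal(0.0, spec.fourier_sigma, size=len(spec.fourier_orders)),
        -spec.fourier_max,
        spec.fourier_max,
    )
    phases = rng.uniform(0.0, 2 * np.pi, size=len(spec.fourier_orders))
    # cross-sectional perturbations twist slowly along z
    twists = rng.normal(0.0, spec.fourier_twist_sigma, size=len(spec.fourier_orders))
    axis_phase = rng.uniform(0.0, 2 * np.pi, size=2)

    lumen, thrombus, outer = [], [], []
    for i in range(n):
        pert = np.zeros_like(theta)
        for k, a, ph, tw in zip(spec.fourier_orders, amps, phases, twists):
            pert = pert + a * np.cos(k * theta - (ph + tw * z_norm[i]))
        r0 = scale * (
            spec.thrombus_radius_base
            + bulge_amp * np.exp(-0.5 * ((z_norm[i] - bulge_mu) / bulge_sd) ** 2)
        )
        r_th = r0 * (1.0 + pert)
        r_lum = min(spec.lumen_radius, float(r_th.min()) - spec.min_lumen_margin_mm)
        if r_lum <= 0:
            raise InvalidInputError("spec violates lumen/thrombus nesting")
        r_th = np.maximum(r_th, r_lum + spec.min_lumen_margin_mm)
        r_out = r_th + wall
        center = spec.grid_center + spec.axis_amplitude_mm * np.array(
            [
                np.sin(2 * np.pi * z_norm[i] + axis_phase[0]),
                np.sin(2 * np.pi * z_norm[i] + axis_phase[1]),
            ]
        )
        d = np.column_stack([np.cos(theta), np.sin(theta)])
        lumen.append(PlanarContour(center + r_lum * d, z=z[i]))
        thrombus.append(PlanarContour(center + r_th[:, None] * d, z=z[i]))
        outer.append(PlanarContour(center + r_out[:, None] * d, z=z[i]))
        if not (r_lum < r_th.min() + 1e-9 and np.all(r_th < r_out)):
            raise InvalidInputError("spec violates contour nesting")
    return {"lumen": lumen, "thrombus": thrombus, "outer": outer}


def _smooth_field(rng: np.random.Generator, shape, sigma_px: float, amp: float):
    field = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(field, sigma=sigma_px)
    sd = field.std()
    if sd > 0:
        field *= amp / sd
    return field


def render_phantom(
    shapes: dict, spec: PhantomSpec, rng: np.random.Generator, seed: int = 0
) -> PhantomStudy:
    """Rasterize contour stacks into the two image channels + ground truth.

    Ground-truth masks are rasterized from exactly the contours used for
    scoring, with the shared rasterizer.  Confounders alter only the
    images, never the ground truth.
    """
    grid = Volume(
        np.zeros((spec.n_slices, spec.ny, spec.nx)), spec.spacing, (0.0, 0.0, 0.0)
    )
    lumen_mask = contour_stack_mask(shapes["lumen"], grid)
    thrombus_mask = contour_stack_mask(shapes["thrombus"], grid)
    outer_mask = contour_stack_mask(shapes["outer"], grid)

    # channel 1: heterogeneous background, dark wall ring, bright thrombus
    ch1 = np.full(grid.data.shape, spec.background_intensity)
    if spec.background_texture_sigma > 0:
        ch1 += _smooth_field(rng, grid.data.shape, 4.0, spec.background_texture_sigma)
    ch1[outer_mask] = spec.wall_intensity
    ch1[thrombus_mask] = spec.thrombus_intensity
    ch1[lumen_mask] = spec.lumen_intensity

    _render_confounders(ch1, shapes, spec, grid, rng, thrombus_mask)

    if spec.noise_sigma > 0:
        ch1 = ch1 + rng.normal(0.0, spec.noise_sigma, size=ch1.shape)

    # channel 2: bright lumen (optionally on a shifted grid)
    mra_origin = tuple(np.asarray(spec.mra_origin_shift, dtype=float))
    mra_grid = Volume(np.zeros(grid.data.shape), spec.spacing, mra_origin)
    # the lumen occupies the same world region; rasterize on the mra grid
    mra_lumen = contour_stack_mask(shapes["lumen"], mra_grid)
    ch2 = np.full(grid.data.shape, spec.mra_background_intensity)
    ch2[mra_lumen] = spec.mra_lumen_intensity
    if spec.mra_noise_sigma > 0:
        ch2 = ch2 + rng.normal(0.0, spec.mra_noise_sigma, size=ch2.shape)

    mid = spec.n_slices // 2
    _, lum_centroid = _slice_centroid(shapes["lumen"][mid])
    seed_point = np.array([lum_centroid[0], lum_centroid[1], shapes["lumen"][mid].z])

    return PhantomStudy(
        pair=StudyPair(
            mri=Volume(ch1, spec.spacing, (0.0, 0.0, 0.0)),
            mra=Volume(ch2, spec.spacing, mra_origin),
        ),
        lumen_mask=Volume(lumen_mask, spec.spacing, (0.0, 0.0, 0.0)),
        thrombus_mask=Volume(thrombus_mask, spec.spacing, (0.0, 0.0, 0.0)),
        outer_mask=Volume(outer_mask, spec.spacing, (0.0, 0.0, 0.0)),
        contours=shapes,
        seed_point=seed_point,
        spec=spec,
        seed=seed,
    )


def _slice_centroid(contour: PlanarContour):
    from .geometry import polygon_area_centroid

    return polygon_area_centroid(contour.points)


def _render_confounders(ch1, shapes, spec, grid, rng, thrombus_mask):
    """Draw confounder structures into channel 1 (in place).

    Confounders only ever alter pixels outside the true thrombus, so the
    ground-truth contours remain valid descriptions of the anatomy; what
    they corrupt is the *appearance* of the wall and surroundings.
    """
    for conf in spec.confounders:
        kind = conf["kind"]
        if kind in ("hyper_adjacent", "hypo_adjacent"):
            angle = float(conf.get("angle_deg", rng.uniform(0.0, 360.0)))
            radius = float(conf.get("radius_mm", 14.0))
            # hyper: as bright as thrombus; hypo: as dark as the wall itself
            default_int = (
                spec.thrombus_intensity
                if kind == "hyper_adjacent"
                else spec.wall_intensity
            )
            intensity = float(conf.get("intensity", default_int))
            z_center = float(conf.get("z_center", rng.uniform(0.3, 0.7)))
            _draw_adjacent_sphere(
                ch1, shapes, spec, grid, angle, radius, intensity, z_center,
                thrombus_mask,
            )
        elif kind == "two_component":
            ring = float(conf.get("ring_thickness_mm", 1.5))
            z_lo = float(conf.get("z_lo", 0.25))
            z_hi = float(conf.get("z_hi", 0.75))
            _draw_split_ring(ch1, shapes, spec, grid, ring, z_lo, z_hi)
        else:
            raise InvalidInputError(f"unknown confounder kind '{kind}'")


def _draw_adjacent_sphere(
    ch1, shapes, spec, grid, angle_deg, radius, intensity, z_center, thrombus_mask
):
    """Sphere centred on the outer boundary, masking the wall ring locally.

    Emulates a compact organ or vessel abutting the aneurysm: a
    hyperintense sphere erases the dark-wall texture cue over a few
    landmarks on a few slices (the wall "blurs" into the structure),
    while a hypointense one makes the wall look thicker than the search
    limit there.  Pixels inside the true thrombus are never touched, so
    the corruption is localized in both angle and z — the isolated-
    misestimation scenario the shape restriction is meant to repair.
    """
    from .geometry import ray_polygon_intersection

    theta = np.deg2rad(angle_deg)
    d = np.array([np.cos(theta), np.sin(theta)])
    n = spec.n_slices
    z_norm = np.arange(n) / (n - 1)
    i_c = int(round(z_center * (n - 1)))
    outer_c = shapes["outer"][i_c]
    _, ctr_c = _slice_centroid(outer_c)
    hit = ray_polygon_intersection(ctr_c, d, outer_c.points)
    r_out = np.linalg.norm(hit - ctr_c)
    sphere_ctr = ctr_c + r_out * d  # in-plane centre, fixed across slices
    z_c = outer_c.z
    for i in range(n):
        dz = grid.slice_z(i) - z_c
        if abs(dz) >= radius:
            continue
        r_slice = np.sqrt(radius**2 - dz**2)
        sl = grid.get_slice(i)
        pc = sl.pixel_centers()
        inside = (np.linalg.norm(pc - sphere_ctr, axis=1) <= r_slice).reshape(
            ch1[i].shape
        )
        inside &= ~thrombus_mask[i]
        ch1[i][inside] = intensity


def _draw_split_ring(ch1, shapes, spec, grid, ring_thickness, z_lo, z_hi):
    """Dark ring inside the thrombus splitting it into two components."""
    n = spec.n_slices
    z_norm = np.arange(n) / (n - 1)
    for i in range(n):
        if not z_lo <= z_norm[i] <= z_hi:
            continue
        th = shapes["thrombus"][i]
        lum = shapes["lumen"][i]
        _, ctr = _slice_centroid(th)
        r_th = np.linalg.norm(th.points - ctr, axis=1).mean()
        r_lum = np.linalg.norm(lum.points - _slice_centroid(lum)[1], axis=1).mean()
        r1 = max(r_lum + 2.0, 0.45 * r_th)
        sl = grid.get_slice(i)
        pc = sl.pixel_centers()
        rr = np.linalg.norm(pc - ctr, axis=1)
        band = ((rr >= r1) & (rr <= r1 + ring_thickness)).reshape(ch1[i].shape)
        ch1[i][band] = spec.wall_intensity


def generate_study(spec: PhantomSpec, seed: int) -> PhantomStudy:
    """Generate one phantom study from an integer seed."""
    rng = np.random.default_rng(seed)
    shapes = sample_phantom_shape(rng, spec)
    return render_phantom(shapes, spec, rng, seed=seed)


def generate_dataset(
    n: int, spec: PhantomSpec, seed: int
) -> tuple[list[PhantomStudy], dict]:
    """Generate ``n`` independent studies with per-study derived seeds.

    Returns the studies and a manifest dict describing exactly how to
    regenerate them.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    studies = [generate_study(spec, s) for s in child_seeds]
    manifest = {
        "n": n,
        "seed": seed,
        "study_seeds": child_seeds,
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in spec.__dict__.items()
        },
    }
    return studies, manifest


def sample_training_shapes(
    n: int, spec: PhantomSpec, seed: int, boundaries: tuple[str, ...] = ("thrombus", "outer")
) -> list[LandmarkShape]:
    """Sample straightened landmark shapes for shape-model training.

    Draws ``n`` phantom geometries and landmarks the requested boundary
    stacks (both thrombus and outer by default, so a single model spans
    the two boundary families the restriction is applied to).
    """
    ss = np.random.SeedSequence(seed)
    out: list[LandmarkShape] = []
    for child in ss.spawn(n):
        rng = np.random.default_rng(child)
        shapes = sample_phantom_shape(rng, spec)
        for key in boundaries:
            lm = landmark_contour_stack(shapes[key])
            out.append(straighten(lm))
    return out
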