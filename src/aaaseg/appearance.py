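"""Texture-statistic boundary appearance model.

Around each landmark a rectangular search region (11 mm radial x 3 mm
tangential, long axis along the landmark-to-lumen-centroid line) is
sampled bilinearly.  Each radial position is a boundary candidate: the
samples strictly inside it form the interior (thrombus side), those
strictly outside form the exterior (wall / surroundings side), and five
texture statistics compare the two:

    dI      = mean(I_in) - mean(I_out)
    dm      = min(I_in)  - min(I_out)
    LmO     = I_candidate - min(I_out)
    std_out = sigma(I_out)
    d_std   = sigma(I_out) - sigma(I_in)

The statistics are min-max normalized across the region's valid
candidates and summed; the candidate maximizing the summed metric is the
boundary proposal.  The default combination is dI + dm + LmO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import InvalidInputError, RegionFailure
from .geometry import Slice2D

__all__ = [
    "STAT_NAMES",
    "TABLE_COMBINATIONS",
    "SearchRegion",
    "TextureStats",
    "extract_region",
    "texture_stats",
    "score_candidates",
    "all_combinations",
    "select_statistic_combination",
]

STAT_NAMES = ("dI", "dm", "LmO", "std_out", "d_std")

# the seven combinations of four or more statistics plus the winning triple
TABLE_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("dI", "dm", "LmO", "std_out", "d_std"),
    ("dI", "dm", "LmO", "std_out"),
    ("dI", "dm", "LmO", "d_std"),
    ("dI", "dm", "std_out", "d_std"),
    ("dI", "LmO", "std_out", "d_std"),
    ("dm", "LmO", "std_out", "d_std"),
    ("dI", "dm", "LmO"),
)


def all_combinations() -> list[tuple[str, ...]]:
    """All 31 non-empty subsets of the five statistics."""
    out = []
    for mask in range(1, 1 << len(STAT_NAMES)):
        out.append(tuple(s for i, s in enumerate(STAT_NAMES) if mask >> i & 1))
    return out


@dataclass
class SearchRegion:
    """Bilinear samples of a rectangular region around one landmark.

    ``samples[i, j]`` is the intensity at radial offset
    ``radial_offsets[i]`` (mm; negative = toward the lumen) and the j-th
    tangential row; NaN marks samples clipped outside the image.
    """

    samples: np.ndarray  # (n_rad, n_tan)
    radial_offsets: np.ndarray  # (n_rad,)
    step_mm: float
    landmark_index: int = -1
    clipped: bool = False

    @property
    def n_candidates(self) -> int:
        return self.samples.shape[0]

    @property
    def central_row(self) -> int:
        return self.samples.shape[1] // 2


@dataclass
class TextureStats:
    """The five boundary statistics for one candidate pixel."""

    dI: float
    dm: float
    LmO: float
    std_out: float
    d_std: float
    valid: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.dI, self.dm, self.LmO, self.std_out, self.d_std])

    @classmethod
    def invalid(cls) -> "TextureStats":
        return cls(np.nan, np.nan, np.nan, np.nan, np.nan, valid=False)


def extract_region(
    image: Slice2D,
    landmark: np.ndarray,
    centroid: np.ndarray,
    length_mm: float = 11.0,
    width_mm: float = 3.0,
    step_mm: float | None = None,
    landmark_index: int = -1,
) -> SearchRegion:
    """Sample the search region centred on ``landmark``.

    The radial axis points from the lumen ``centroid`` through the
    landmark (offset 0 at the landmark, positive outward); the tangential
    axis is its in-plane perpendicular.  Sampling step defaults to half
    the in-plane voxel spacing.  Samples falling outside the image are
    NaN and set the ``clipped`` flag.
    """
    landmark = np.asarray(landmark, dtype=float)
    centroid = np.asarray(centroid, dtype=float)
    u = landmark - centroid
    norm = np.linalg.norm(u)
    if norm < 1e-9:
        raise InvalidInputError("landmark coincides with the lumen centroid")
    u = u / norm
    v = np.array([-u[1], u[0]])
    if step_mm is None:
        step_mm = 0.5 * image.in_plane_spacing
    n_half_r = int(round(0.5 * length_mm / step_mm))
    n_half_t = int(round(0.5 * width_mm / step_mm))
    r_off = step_mm * np.arange(-n_half_r, n_half_r + 1)
    t_off = step_mm * np.arange(-n_half_t, n_half_t + 1)
    pts = (
        landmark[None, None, :]
        + r_off[:, None, None] * u[None, None, :]
        + t_off[None, :, None] * v[None, None, :]
    )
    samples = image.sample(pts)
    return SearchRegion(
        samples=samples,
        radial_offsets=r_off,
        step_mm=float(step_mm),
        landmark_index=landmark_index,
        clipped=bool(np.isnan(samples).any()),
    )


def texture_stats(region: SearchRegion, candidate_radial_offset: float) -> TextureStats:
    """The five statistics at one candidate radial offset.

    Interior samples have radial coordinate strictly below the offset,
    exterior strictly above; the candidate's own radial row belongs to
    neither side and its central-row sample provides the candidate
    intensity.  Candidates with fewer than 2 finite samples on either
    side are marked invalid (standard deviations need >= 2 samples).
    """
    r = region.radial_offsets
    idx = int(np.argmin(np.abs(r - candidate_radial_offset)))
    inner = region.samples[r < r[idx] - 1e-12]
    outer = region.samples[r > r[idx] + 1e-12]
    inner = inner[np.isfinite(inner)]
    outer = outer[np.isfinite(outer)]
    cand = region.samples[idx, region.central_row]
    if inner.size < 2 or outer.size < 2 or not np.isfinite(cand):
        return TextureStats.invalid()
    std_in = float(inner.std())
    std_out = float(outer.std())
    return TextureStats(
        dI=float(inner.mean() - outer.mean()),
        dm=float(inner.min() - outer.min()),
        LmO=float(cand - outer.min()),
        std_out=std_out,
        d_std=std_out - std_in,
    )


def _normalize(col: np.ndarray, mode: str) -> np.ndarray:
    if mode == "minmax":
        lo, hi = col.min(), col.max()
        if hi - lo < 1e-12:
            return np.zeros_like(col)
        return (col - lo) / (hi - lo)
    if mode == "zscore":
        mu, sd = col.mean(), col.std()
        if sd < 1e-12:
            return np.zeros_like(col)
        return (col - mu) / sd
    raise InvalidInputError(f"unknown normalization '{mode}'")


def score_candidates(
    region: SearchRegion,
    combo: tuple[str, ...] = ("dI", "dm", "LmO"),
    normalization: str = "minmax",
) -> tuple[float, np.ndarray]:
    """Score every radial candidate and return the best offset.

    Each included statistic is normalized to [0, 1] across the region's
    valid candidates (min-max by default) and the normalized values are
    summed.  Ties are broken toward the candidate closest to the current
    landmark (smallest |offset|, outward preferred on exact ties).

    Returns ``(best_offset_mm, scores)`` where ``scores`` has one entry
    per radial candidate (NaN for invalid candidates).

    Raises :class:`RegionFailure` when fewer than 3 candidates are valid.
    """
    if not combo:
        raise InvalidInputError("statistic combination must be non-empty")
    unknown = set(combo) - set(STAT_NAMES)
    if unknown:
        raise InvalidInputError(f"unknown statistics: {sorted(unknown)}")
    n = region.n_candidates
    stats = np.full((n, len(STAT_NAMES)), np.nan)
    for i in range(n):
        ts = texture_stats(region, region.radial_offsets[i])
        if ts.valid:
            stats[i] = ts.as_array()
    valid = np.isfinite(stats).all(axis=1)
    if valid.sum() < 3:
        raise RegionFailure(
            f"only {int(valid.sum())} valid candidates in search region"
        )
    scores = np.full(n, np.nan)
    total = np.zeros(int(valid.sum()))
    for name in combo:
        col = stats[valid, STAT_NAMES.index(name)]
        total = total + _normalize(col, normalization)
    scores[valid] = total
    best = np.nanmax(scores)
    ties = np.nonzero(np.abs(scores - best) <= 1e-12)[0]
    offs = region.radial_offsets[ties]
    pick = ties[np.lexsort((-offs, np.abs(offs)))[0]]
    return float(region.radial_offsets[pick]), scores


def select_statistic_combination(
    training_studies,
    shape_model,
    config=None,
    combos: list[tuple[str, ...]] | None = None,
):
    """Rank statistic combinations by mean thrombus Dice on phantoms.

    For each combination the thrombus stage is run on every study in
    leave-one-out fashion and scored against the ground-truth thrombus
    mask.  Because the min-max normalization is training-free, the
    appearance "training" on the remaining studies stores only the
    combination itself, so each held-out segmentation depends on the
    combination alone.

    Returns a pandas DataFrame with columns ``combo`` and ``mean_dice``
    (plus per-study columns), sorted by descending mean Dice.
    """
    import pandas as pd

    from .config import PipelineConfig
    from .evaluation import dice
    from .segmentation import segment_thrombus_only

    if len(training_studies) < 2:
        raise InvalidInputError("combination search needs >= 2 training studies")
    if combos is None:
        combos = list(TABLE_COMBINATIONS)
    if config is None:
        config = PipelineConfig()
    rows = []
    for combo in combos:
        dices = []
        for study in training_studies:
            cfg = config.with_updates(combo=list(combo))
            mask = segment_thrombus_only(study.pair, study.seed_point, shape_model, cfg)
            dices.append(dice(mask.data, study.thrombus_mask.data))
        row = {"combo": "+".join(combo), "mean_dice": float(np.mean(dices))}
        row.update({f"study_{i}": d for i, d in enumerate(dices)})
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("mean_dice", ascending=False)
    return df.reset_index(drop=True)
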