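"""Readers and writers: NIfTI volumes, contour JSON, model bundles.

NIfTI is the canonical volume format (axis-aligned affines only; a file
without usable geometry is a hard error — unit spacing is never assumed
silently).  A minimal DICOM-series reader recovers geometry metadata
from transversal series.  Contours travel as versioned JSON; shape
models as an ``.npz`` bundle with a JSON metadata entry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ._exceptions import InvalidInputError, SchemaError
from .geometry import PlanarContour, Volume
from .shape_model import ShapeModel

__all__ = [
    "read_volume",
    "write_volume",
    "read_contours",
    "write_contours",
    "load_model",
    "save_model",
    "read_dicom_series",
]

CONTOUR_SCHEMA_VERSION = "1"
MODEL_SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# NIfTI volumes


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI with a diagonal affine from its geometry."""
    import nibabel as nib

    sx, sy, sz = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = vol.origin
    # our arrays are (z, y, x); nibabel expects (x, y, z)
    data = np.ascontiguousarray(vol.data.transpose(2, 1, 0))
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume; requires an axis-aligned affine."""
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    lin = affine[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.abs(off_diag).max() > 1e-6:
        raise InvalidInputError(
            f"{path}: only axis-aligned volumes are supported (oblique affine)"
        )
    spacing = np.abs(np.diag(lin))
    if np.any(spacing <= 0):
        raise InvalidInputError(f"{path}: affine carries no usable voxel spacing")
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise InvalidInputError(f"{path}: expected a 3D volume")
    return Volume(
        data.transpose(2, 1, 0).copy(),
        spacing=tuple(spacing),
        origin=tuple(affine[:3, 3]),
    )


# ---------------------------------------------------------------------------
# contour JSON


def write_contours(
    contours: list[PlanarContour], path: str | Path, structure: str = ""
) -> None:
    payload = {
        "schema_version": CONTOUR_SCHEMA_VERSION,
        "structure": structure,
        "units": "mm",
        "slices": [
            {"z": c.z, "points": c.points.tolist()} for c in contours
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_contours(path: str | Path) -> list[PlanarContour]:
    data = json.loads(Path(path).read_text())
    version = data.get("schema_version")
    if version != CONTOUR_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: contour schema version {version!r}, "
            f"expected {CONTOUR_SCHEMA_VERSION!r}"
        )
    return [
        PlanarContour(np.asarray(s["points"], dtype=float), z=float(s["z"]))
        for s in data["slices"]
    ]


# ---------------------------------------------------------------------------
# shape-model bundle


def save_model(model: ShapeModel, path: str | Path) -> None:
    meta = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "n_training": model.n_training,
        "variability_fraction": model.variability_fraction,
        "t": model.t,
        "m_t": model.m_t,
    }
    np.savez(
        path,
        mean_shape=model.mean_shape,
        eigenvectors=model.eigenvectors,
        eigenvalues=model.eigenvalues,
        meta=json.dumps(meta),
    )


def load_model(path: str | Path) -> ShapeModel:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        if meta.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise SchemaError(
                f"{path}: model schema version {meta.get('schema_version')!r}, "
                f"expected {MODEL_SCHEMA_VERSION!r}"
            )
        return ShapeModel(
            mean_shape=npz["mean_shape"],
            eigenvectors=npz["eigenvectors"],
            eigenvalues=npz["eigenvalues"],
            n_training=int(meta["n_training"]),
            variability_fraction=float(meta["variability_fraction"]),
            t=float(meta["t"]),
            m_t=float(meta["m_t"]),
        )


# ---------------------------------------------------------------------------
# minimal DICOM series reader


def read_dicom_series(directory: str | Path) -> Volume:
    """Read an axial DICOM series (geometry metadata + pixel data).

    Slices are ordered by ImagePositionPatient z; requires identity
    in-plane orientation, uniform slice spacing, PixelSpacing and
    ImagePositionPatient present on every slice.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise InvalidInputError(f"no .dcm files in {directory}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        if not hasattr(ds, "ImagePositionPatient") or not hasattr(ds, "PixelSpacing"):
            raise InvalidInputError(f"{f}: missing geometry metadata")
        orient = getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])
        if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-6):
            raise InvalidInputError(f"{f}: only axial identity orientation supported")
        slices.append(ds)
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    zs = np.array([float(d.ImagePositionPatient[2]) for d in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0) or np.ptp(dz) > 1e-3:
            raise InvalidInputError("slice spacing is not uniform and increasing")
        sz = float(dz[0])
    else:
        sz = float(getattr(slices[0], "SliceThickness", 0) or 0)
        if sz <= 0:
            raise InvalidInputError("single slice without SliceThickness")
    first = slices[0]
    sy, sx = (float(v) for v in first.PixelSpacing)  # row spacing, col spacing
    data = np.stack([d.pixel_array for d in slices]).astype(float)
    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[2]),
    )
    return Volume(data, spacing=(sx, sy, sz), origin=origin)
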