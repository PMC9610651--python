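"""Volume, label-map and feature-table I/O with an explicit coordinate convention.

Axis convention
---------------
All 3D grids are indexed ``(axial, lateral, slice)`` with 0-based,
voxel-centered indices.  The axial axis points from the vitreous (top of a
B-scan) towards the choroid, the lateral axis runs across a B-scan, and the
slice axis stacks B-scans.  Physical step lengths per axis are carried by
:class:`GridSpacing` as ``(dx, dy, dz)`` in arbitrary but consistent length
units; they are always explicit input, never assumed from scanner defaults.

Label codes
-----------
``0``    background (everything below the retinal pigment epithelium)
``1-12`` retinal layers in anatomical order, NFL (innermost) to RPE (outermost)
``13``   vitreous (above the retina)

Along every A-scan column the nonzero codes must occur as contiguous runs in
the order vitreous, layer 1, ..., layer 12 (any may be absent in a given
column).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BACKGROUND = 0
VITREOUS = 13
RPE = 12
N_LAYERS = 12
LAYER_CODES = tuple(range(1, N_LAYERS + 1))

_EYES = ("left", "right", "unknown")


class VolumeIOError(ValueError):
    """Raised for unreadable, malformed, or invariant-violating inputs."""


@dataclass(frozen=True)
class GridSpacing:
    """Physical step lengths per grid axis, strictly positive."""

    dx: float = 1.0
    dy: float = 1.0
    dz: float = 1.0

    def __post_init__(self):
        for name, v in (("dx", self.dx), ("dy", self.dy), ("dz", self.dz)):
            if not np.isfinite(v) or v <= 0:
                raise VolumeIOError(f"spacing.{name} must be finite and > 0, got {v}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (float(self.dx), float(self.dy), float(self.dz))

    @classmethod
    def from_any(cls, spacing) -> "GridSpacing":
        if isinstance(spacing, GridSpacing):
            return spacing
        return cls(*(float(s) for s in spacing))


@dataclass
class OCTVolume:
    """A 3D OCT intensity grid with physical voxel spacing.

    ``intensities`` is float, nonnegative and finite with axes
    ``(axial, lateral, slice)``.  Raw scanner intensities and normalized
    (dimensionless) reflectivities are both carried by this type; the
    ``normalized`` flag records which one it is.
    """

    intensities: np.ndarray
    spacing: GridSpacing = field(default_factory=GridSpacing)
    subject_id: str = ""
    eye: str = "unknown"
    normalized: bool = False

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise VolumeIOError(f"volume must be 3D, got {arr.ndim}D shape {arr.shape}")
        if arr.shape[0] < 4 or arr.shape[1] < 4 or arr.shape[2] < 1:
            raise VolumeIOError(
                f"grid too small: {arr.shape}; need axial, lateral >= 4 and slice >= 1"
            )
        if not np.all(np.isfinite(arr)):
            raise VolumeIOError("volume contains non-finite values")
        if not self.normalized and arr.min() < 0:
            raise VolumeIOError("raw volume contains negative intensities")
        if self.eye not in _EYES:
            raise VolumeIOError(f"eye must be one of {_EYES}, got {self.eye!r}")
        self.intensities = arr
        self.spacing = GridSpacing.from_any(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


def _check_column_order(labels: np.ndarray) -> None:
    """Validate the per-column anatomical ordering of nonzero label codes.

    Maps vitreous (13) to rank 0 and layer k to rank k; the nonzero codes of a
    column are valid iff their rank sequence is non-decreasing (a revisit of an
    earlier region would force a decrease).
    """
    rank = np.where(labels == VITREOUS, 0, labels).astype(np.int16)
    nx = labels.shape[0]
    # Forward-fill ranks over background voxels so zeros never break a run.
    nonzero = labels != 0
    idx = np.where(nonzero, np.arange(nx)[:, None, None], -1)
    ffidx = np.maximum.accumulate(idx, axis=0)
    seen = ffidx >= 0
    filled = np.where(seen, np.take_along_axis(rank, np.maximum(ffidx, 0), axis=0), 0)
    drops = (np.diff(filled, axis=0) < 0) & seen[1:]
    if drops.any():
        ax, lat, sl = np.argwhere(drops)[0]
        raise VolumeIOError(
            f"label ordering violated in column (lateral={lat}, slice={sl}) "
            f"near axial index {ax + 1}: retinal layers must appear in "
            "anatomical order vitreous, 1..12 along each A-scan"
        )


@dataclass
class LayerLabelMap:
    """Integer grid assigning each voxel to background/vitreous/one of 12 layers."""

    labels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise VolumeIOError("label map contains non-integer values")
            arr = arr.astype(np.int16)
        if arr.ndim != 3:
            raise VolumeIOError(f"label map must be 3D, got shape {arr.shape}")
        if arr.min() < 0 or arr.max() > VITREOUS:
            bad = int(arr.min()) if arr.min() < 0 else int(arr.max())
            raise VolumeIOError(f"label code {bad} outside the valid range 0..13")
        if not (arr == VITREOUS).any():
            raise VolumeIOError("label map contains no vitreous voxel (code 13)")
        if not (arr == RPE).any():
            raise VolumeIOError("label map contains no RPE voxel (code 12)")
        _check_column_order(arr)
        self.labels = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def layer_mask(self, layer_id: int) -> np.ndarray:
        if not 1 <= layer_id <= N_LAYERS:
            raise VolumeIOError(f"layer_id must be in 1..12, got {layer_id}")
        return self.labels == layer_id


# ---------------------------------------------------------------------------
# volume / label readers and writers
# ---------------------------------------------------------------------------

_FORMATS = ("nifti", "tiff", "npz")


def _infer_format(path: Path) -> str:
    s = "".join(path.suffixes).lower()
    if s.endswith(".nii") or s.endswith(".nii.gz"):
        return "nifti"
    if s.endswith(".tif") or s.endswith(".tiff"):
        return "tiff"
    if s.endswith(".npz"):
        return "npz"
    raise VolumeIOError(f"cannot infer format from file name {path.name!r}")


def _read_array(path, fmt) -> tuple[np.ndarray, GridSpacing | None]:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"file not found: {path}")
    fmt = fmt or _infer_format(path)
    if fmt not in _FORMATS:
        raise VolumeIOError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        spacing = GridSpacing(*(float(z) for z in zooms)) if len(zooms) == 3 else None
        return arr, spacing
    if fmt == "tiff":
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description or ""
        spacing = None
        if desc:
            try:
                meta = json.loads(desc)
                spacing = GridSpacing(*meta["spacing"])
            except (json.JSONDecodeError, KeyError, TypeError):
                spacing = None
        if arr.ndim == 3:  # pages along the slice axis
            arr = np.moveaxis(arr, 0, 2)
        return arr, spacing
    data = np.load(path)
    if "data" not in data:
        raise VolumeIOError(f"{path} is not an octdr array container (missing 'data')")
    spacing = GridSpacing(*data["spacing"]) if "spacing" in data else None
    return data["data"], spacing


def _resolve_spacing(spacing: GridSpacing | None, path) -> GridSpacing:
    if spacing is None:
        warnings.warn(
            f"{path}: no voxel spacing in header, assuming (1, 1, 1)", stacklevel=3
        )
        return GridSpacing()
    return spacing


def read_volume(path, format: str | None = None, subject_id: str = "",
                eye: str = "unknown") -> OCTVolume:
    """Read a 3D intensity volume; axis order ``(axial, lateral, slice)``."""
    arr, spacing = _read_array(path, format)
    if arr.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D volume, got {arr.ndim}D")
    return OCTVolume(arr.astype(float), _resolve_spacing(spacing, path),
                     subject_id=subject_id, eye=eye)


def write_volume(vol: OCTVolume, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_array(vol.intensities, vol.spacing, path, fmt)


def _write_array(arr: np.ndarray, spacing: GridSpacing, path: Path, fmt: str) -> None:
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag((*spacing.as_tuple(), 1.0))
        nib.save(nib.Nifti1Image(np.asarray(arr), affine), str(path))
    elif fmt == "tiff":
        import tifffile

        pages = np.moveaxis(np.asarray(arr), 2, 0)
        tifffile.imwrite(str(path), pages, photometric="minisblack",
                         description=json.dumps({"spacing": spacing.as_tuple()}))
    elif fmt == "npz":
        np.savez_compressed(path, data=np.asarray(arr),
                            spacing=np.array(spacing.as_tuple()))
    else:
        raise VolumeIOError(f"unknown format {fmt!r}")


def read_labels(path, format: str | None = None) -> LayerLabelMap:
    """Read a label map; validates codes and per-column anatomical order."""
    arr, _ = _read_array(path, format)
    if arr.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D label map, got {arr.ndim}D")
    return LayerLabelMap(np.asarray(arr))


def write_labels(labels: LayerLabelMap, path, format: str | None = None,
                 spacing: GridSpacing | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_array(labels.labels.astype(np.int16), spacing or GridSpacing(), path, fmt)


# ---------------------------------------------------------------------------
# subject records and feature tables
# ---------------------------------------------------------------------------

CLASS_NORMAL = "normal"
CLASS_DR = "DR"
CLASSES = (CLASS_NORMAL, CLASS_DR)

KIND_REFLECTIVITY = "reflectivity"
KIND_THICKNESS = "thickness"
KINDS = (KIND_REFLECTIVITY, KIND_THICKNESS)
_KIND_TOKEN = {KIND_REFLECTIVITY: "refl", KIND_THICKNESS: "thick"}
_TOKEN_KIND = {v: k for k, v in _KIND_TOKEN.items()}


@dataclass
class SubjectRecord:
    """One subject: identity, class label, and per-layer feature vectors.

    ``features`` maps ``(kind, layer_id)`` — e.g. ``("thickness", 3)`` — to a
    :class:`~octdr.descriptors.LayerFeatureVector`.
    """

    subject_id: str
    class_label: str
    seed: int = 0
    ground_truth: object | None = None
    features: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise VolumeIOError(
                f"class_label must be one of {CLASSES}, got {self.class_label!r}"
            )

    @property
    def is_dr(self) -> bool:
        return self.class_label == CLASS_DR

    def feature_vector(self, kind: str, layer_id: int) -> np.ndarray:
        return self.features[(kind, layer_id)].values


def write_feature_table(records: Sequence[SubjectRecord], path) -> None:
    """Write one CSV row per subject: subject_id, class, then
    ``layer{L}_{refl|thick}_{stat}`` columns in layer-major order."""
    from .descriptors import LayerFeatureVector  # noqa: F401  (type of values)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    columns: list[str] = []
    rows = []
    for rec in records:
        row: dict = {"subject_id": rec.subject_id, "class": rec.class_label}
        for layer in range(1, N_LAYERS + 1):
            for kind in KINDS:
                fv = rec.features.get((kind, layer))
                if fv is None:
                    continue
                for name, value in zip(fv.stat_names, fv.values):
                    col = f"layer{layer}_{_KIND_TOKEN[kind]}_{name}"
                    row[col] = float(value)
                    if col not in columns:
                        columns.append(col)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["subject_id", "class", *columns])
    # %.17g always round-trips an IEEE double through decimal
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> list[SubjectRecord]:
    from .descriptors import LayerFeatureVector

    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"feature table not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if "subject_id" not in df.columns or "class" not in df.columns:
        raise VolumeIOError(f"{path}: not a feature table (missing id/class columns)")
    # group feature columns by (layer, kind) preserving stat order
    groups: dict[tuple[str, int], list[str]] = {}
    stat_names: dict[tuple[str, int], list[str]] = {}
    for col in df.columns[2:]:
        try:
            layer_tok, kind_tok, stat = col.split("_", 2)
            layer = int(layer_tok.removeprefix("layer"))
            kind = _TOKEN_KIND[kind_tok]
        except (ValueError, KeyError) as exc:
            raise VolumeIOError(f"{path}: unrecognized feature column {col!r}") from exc
        groups.setdefault((kind, layer), []).append(col)
        stat_names.setdefault((kind, layer), []).append(stat)
    records = []
    for _, row in df.iterrows():
        feats = {}
        for key, cols in groups.items():
            vals = row[cols].to_numpy(dtype=float)
            if np.isnan(vals).all():
                continue
            feats[key] = LayerFeatureVector(
                layer_id=key[1], kind=key[0],
                values=vals, stat_names=tuple(stat_names[key]),
            )
        records.append(
            SubjectRecord(subject_id=str(row["subject_id"]),
                          class_label=str(row["class"]), features=feats)
        )
    return records
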