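"""Reading, writing and in-memory containers for CT volumes, label maps and reports.

All coordinate and unit conventions are fixed here:

* Arrays are indexed ``(slice, row, column)`` = ``(z, y, x)``: ``z`` runs
  cranio-caudal with index 0 the most cranial slice, ``y`` anterior-posterior,
  ``x`` right-to-left (so the subject's left lung sits at higher column index).
* ``spacing`` is the voxel edge length in mm per axis, in the same
  ``(z, y, x)`` order; a voxel's volume is the product of the three spacings
  (mm^3) and volumes are reported in ml (mm^3 / 1000).
* Attenuation is in Hounsfield units (water 0, air −1000), stored unscaled.
* All indices are 0-based.

NIfTI-1 is the canonical interchange format; images are reoriented to closest
canonical (RAS) on read and the array transposed so the conventions above hold.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "OrganLabelMap",
    "ORGAN_LABELS",
    "ResultTable",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "write_report",
]

#: Organ label vocabulary shared by every module.
ORGAN_LABELS = {
    "background": 0,
    "left_lung": 1,
    "right_lung": 2,
    "airway": 3,
    "body": 4,
}

LEFT_LUNG = ORGAN_LABELS["left_lung"]
RIGHT_LUNG = ORGAN_LABELS["right_lung"]
AIRWAY = ORGAN_LABELS["airway"]
BODY = ORGAN_LABELS["body"]


@dataclass
class CTVolume:
    """A 3-D attenuation grid (HU) with voxel spacing in mm.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Attenuation in Hounsfield units; must be finite.
    spacing : tuple of float
        Voxel edge lengths in mm, ``(z, y, x)`` order, strictly positive.
    origin : tuple of float
        Physical position (mm) of voxel ``(0, 0, 0)``.
    subject_height_cm : float, optional
        Subject standing height, used for the height-predicted lung mass.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    subject_height_cm: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"not a 3-D volume: got {self.voxels.ndim} dimensions")
        if min(self.voxels.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("attenuation values must be finite (found NaN or inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class OrganLabelMap:
    """Per-voxel organ labels congruent with a :class:`CTVolume`.

    Vocabulary: 0 background, 1 left lung, 2 right lung, 3 airway, 4 body.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"not a 3-D label map: got {self.labels.ndim} dimensions")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.array_equal(rounded, self.labels):
                raise ValueError("labels must be integers")
            self.labels = rounded.astype(np.int16)
        bad = set(np.unique(self.labels)) - set(ORGAN_LABELS.values())
        if bad:
            raise ValueError(f"labels outside the organ vocabulary: {sorted(bad)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def lung_mask(self) -> np.ndarray:
        """Boolean mask of voxels labeled as either lung."""
        return (self.labels == LEFT_LUNG) | (self.labels == RIGHT_LUNG)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_canonical(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"not a 3-D volume: {path} has {data.ndim} dimensions")
    zooms = img.header.get_zooms()[:3]
    # NIfTI arrays are (x, y, z); flip to our (z, y, x) convention.
    data = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return data, spacing, origin


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing[2], spacing[1], spacing[0]
    aff[:3, 3] = origin[2], origin[1], origin[0]
    return aff


def read_volume(path: str | Path) -> CTVolume:
    """Read a 3-D NIfTI image as a :class:`CTVolume` (values taken as HU)."""
    data, spacing, origin = _load_canonical(path)
    data = data.astype(np.float64, copy=False)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"attenuation values must be finite: {path} contains NaN or inf")
    return CTVolume(voxels=data, spacing=spacing, origin=origin)


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a :class:`CTVolume` to NIfTI-1 at full (float64) precision."""
    path = Path(path)
    arr = np.transpose(volume.voxels.astype(np.float64), (2, 1, 0))
    img = nib.Nifti1Image(arr, _affine(volume.spacing, volume.origin))
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    nib.save(img, str(path))
    return path


def read_labelmap(path: str | Path) -> OrganLabelMap:
    """Read an integer organ label map from NIfTI-1."""
    data, spacing, origin = _load_canonical(path)
    return OrganLabelMap(labels=data, spacing=spacing, origin=origin)


def write_labelmap(labelmap: OrganLabelMap, path: str | Path) -> Path:
    """Write an :class:`OrganLabelMap` losslessly (int16) to NIfTI-1."""
    path = Path(path)
    arr = np.transpose(labelmap.labels.astype(np.int16), (2, 1, 0))
    img = nib.Nifti1Image(arr, _affine(labelmap.spacing, labelmap.origin))
    img.header.set_zooms((labelmap.spacing[2], labelmap.spacing[1], labelmap.spacing[0]))
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

@dataclass
class ResultTable:
    """Named scalar results, each carrying a unit, plus a provenance block.

    Provenance records input paths, parameter values, software version and
    seeds so any report can be regenerated. Field order is insertion order and
    serialization is deterministic (no timestamps).
    """

    records: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def add(self, name: str, value, unit: str) -> None:
        if unit is None or unit == "":
            raise ValueError(f"result {name!r} must declare a unit (use 'dimensionless')")
        self.records.append({"name": str(name), "value": value, "unit": str(unit)})

    def as_dict(self) -> dict:
        return {r["name"]: r["value"] for r in self.records}


def write_report(table: ResultTable, path: str | Path, format: str | None = None) -> Path:
    """Serialize a :class:`ResultTable` as CSV or JSON.

    The format is taken from the ``format`` argument or, if absent, from the
    file suffix. CSV carries the records only; JSON additionally embeds the
    provenance block. Serializing the same table twice yields byte-identical
    files.
    """
    path = Path(path)
    if not table.records:
        raise ValueError("no results: the ResultTable is empty")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\r\n")  # RFC 4180 line endings
        writer.writerow(["name", "value", "unit"])
        for rec in table.records:
            writer.writerow([rec["name"], repr(rec["value"]) if isinstance(rec["value"], float) else rec["value"], rec["unit"]])
        path.write_text(buf.getvalue())
    elif fmt == "json":
        payload = {"results": table.records, "provenance": table.provenance}
        path.write_text(json.dumps(payload, indent=2, allow_nan=False) + "\n")
    else:
        raise ValueError(f"unknown report format: {fmt!r} (expected 'csv' or 'json')")
    return path


def read_report(path: str | Path) -> ResultTable:
    """Parse a report written by :func:`write_report` back into a table."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    table = ResultTable()
    if fmt == "csv":
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                value: object = row["value"]
                try:
                    value = int(value)  # type: ignore[arg-type]
                except ValueError:
                    try:
                        value = float(value)  # type: ignore[arg-type]
                    except ValueError:
                        pass
                table.records.append({"name": row["name"], "value": value, "unit": row["unit"]})
    elif fmt == "json":
        payload = json.loads(path.read_text())
        table.records = payload["results"]
        table.provenance = payload.get("provenance", {})
    else:
        raise ValueError(f"unknown report format: {fmt!r}")
    return table
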