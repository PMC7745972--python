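"""Cropping, metadata records (format v1.5) and dataset organization.

Every master image is accompanied by a bounding-box overlay copy and a JSON
metadata record listing, for each cropped subimage, the plant's identity and
its fractional box inside the master.  Records follow the v1.5 field list;
fractional coordinates are written, by default, in the dataset's literal
convention — (0, 0) the image's upper *right* corner, (1, 1) the lower left
— with an explicit ``box_origin`` declaration so readers can also consume
the conventional upper-left origin when configured.
"""

from __future__ import annotations

import math
import re
import shutil
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .geometry import ImageBox

__all__ = [
    "BoxEntry",
    "CameraPoseMeta",
    "MetadataRecord",
    "MetadataSchemaError",
    "LabelerError",
    "crop_subimages",
    "pixel_rect",
    "write_metadata",
    "read_metadata",
    "metadata_json_schema",
    "draw_overlay",
    "organize_outputs",
    "find_box_overlaps",
    "to_record_fractions",
    "from_record_fractions",
]

METADATA_VERSION = "1.5"

MASTER_NAME_RE = re.compile(r"^\d{14}-pose\d+\.(jpg|jpeg|png)$")
BB_NAME_RE = re.compile(r"^\d{14}-pose\d+-bb\.(jpg|jpeg|png)$")
SUBIMAGE_NAME_RE = re.compile(r"^\d{15,}\.(jpg|jpeg|png)$")


class LabelerError(ValueError):
    pass


class MetadataSchemaError(LabelerError):
    """Raised when a record violates the v1.5 schema; names the bad fields."""


def _fraction(v: float) -> float:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"fraction {v} outside [0, 1]")
    return v


class BoxEntry(BaseModel):
    """One labeled subimage inside a master image."""

    model_config = ConfigDict(extra="forbid")

    plant_id: str
    label: str
    scientific_name: str
    position_id: int
    subimage_file_name: str
    date_planted: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    @field_validator("x_min", "x_max", "y_min", "y_max")
    @classmethod
    def _frac(cls, v: float) -> float:
        return _fraction(v)

    @field_validator("subimage_file_name")
    @classmethod
    def _subname(cls, v: str) -> str:
        if not SUBIMAGE_NAME_RE.match(v):
            raise ValueError(f"subimage_file_name {v!r} does not match yyyymmddhhmmss#.jpg")
        return v

    @model_validator(mode="after")
    def _ordered(self) -> "BoxEntry":
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError("box must satisfy min <= max on both axes")
        return self


class CameraPoseMeta(BaseModel):
    """Camera position (mm) plus polar and azimuthal angles (degrees)."""

    model_config = ConfigDict(extra="forbid")

    x: float
    y: float
    z: float
    polar_angle: float
    azimuthal_angle: float


class MetadataRecord(BaseModel):
    """Full v1.5 metadata for one master image."""

    model_config = ConfigDict(extra="forbid")

    version: Literal["1.5"] = METADATA_VERSION
    file_name: str
    bb_file_name: str
    date: str
    time: str
    room: str
    institute: str
    camera: str
    lens: str
    camera_pose: CameraPoseMeta
    bounding_boxes: list[BoxEntry] = Field(default_factory=list)
    #: Orientation of the fractional coordinates: "upper-right" is the
    #: dataset's literal convention ((0,0) at the upper right corner),
    #: "upper-left" the conventional raster origin.
    box_origin: Literal["upper-right", "upper-left"] = "upper-right"

    @field_validator("file_name")
    @classmethod
    def _master(cls, v: str) -> str:
        if not MASTER_NAME_RE.match(v):
            raise ValueError(f"file_name {v!r} does not match yyyymmddhhmmss-pose#.jpg")
        return v

    @field_validator("bb_file_name")
    @classmethod
    def _bb(cls, v: str) -> str:
        if not BB_NAME_RE.match(v):
            raise ValueError(f"bb_file_name {v!r} does not match yyyymmddhhmmss-pose#-bb.jpg")
        return v

    @model_validator(mode="after")
    def _unique_subnames(self) -> "MetadataRecord":
        names = [b.subimage_file_name for b in self.bounding_boxes]
        if len(set(names)) != len(names):
            raise ValueError("subimage_file_name values must be unique within a record")
        return self


def _schema_error(exc: ValidationError) -> MetadataSchemaError:
    fields = sorted({".".join(str(p) for p in e["loc"]) or "<record>" for e in exc.errors()})
    return MetadataSchemaError(f"invalid metadata record; offending field(s): {', '.join(fields)}\n{exc}")


def to_record_fractions(box: ImageBox, origin: str = "upper-right") -> tuple[float, float, float, float]:
    """Internal (top-left) fractional box -> record coordinates for ``origin``."""
    if origin == "upper-left":
        return box.x_min, box.x_max, box.y_min, box.y_max
    if origin == "upper-right":
        return 1.0 - box.x_max, 1.0 - box.x_min, box.y_min, box.y_max
    raise LabelerError(f"unknown box origin {origin!r}")


def from_record_fractions(entry: BoxEntry, origin: str = "upper-right") -> ImageBox:
    """Record coordinates (honoring the declared origin) -> internal top-left box."""
    if origin == "upper-left":
        return ImageBox(entry.x_min, entry.x_max, entry.y_min, entry.y_max)
    if origin == "upper-right":
        return ImageBox(1.0 - entry.x_max, 1.0 - entry.x_min, entry.y_min, entry.y_max)
    raise LabelerError(f"unknown box origin {origin!r}")


def pixel_rect(box: ImageBox, width: int, height: int) -> tuple[int, int, int, int]:
    """Half-open pixel rectangle (r0, r1, c0, c1) via floor(min*dim)..ceil(max*dim)."""
    c0 = math.floor(box.x_min * width)
    c1 = math.ceil(box.x_max * width)
    r0 = math.floor(box.y_min * height)
    r1 = math.ceil(box.y_max * height)
    return r0, min(r1, height), c0, min(c1, width)


def crop_subimages(master: np.ndarray, boxes: Iterable[ImageBox]) -> list[np.ndarray]:
    """Crop one raster per fractional box; crops may differ in size.

    Raises
    ------
    LabelerError
        If the master is empty or a box rounds to a zero-area rectangle.
    """
    master = np.asarray(master)
    if master.size == 0:
        raise LabelerError("master raster is empty")
    h, w = master.shape[:2]
    crops = []
    for box in boxes:
        r0, r1, c0, c1 = pixel_rect(box, w, h)
        if r1 <= r0 or c1 <= c0:
            raise LabelerError(f"box {box} has zero area after rounding on a {w}x{h} raster")
        crops.append(master[r0:r1, c0:c1].copy())
    return crops


def write_metadata(record: MetadataRecord, path: str | Path) -> None:
    """Write a schema-validated record as JSON (sorted keys, stable bytes)."""
    try:
        MetadataRecord.model_validate(record.model_dump())
    except ValidationError as exc:
        raise _schema_error(exc) from exc
    Path(path).write_text(record.model_dump_json(indent=2))


def read_metadata(path: str | Path) -> MetadataRecord:
    """Read and schema-validate a record; errors name the offending fields."""
    try:
        return MetadataRecord.model_validate_json(Path(path).read_text())
    except ValidationError as exc:
        raise _schema_error(exc) from exc


def metadata_json_schema() -> dict:
    """JSON-schema document for the v1.5 record format."""
    return MetadataRecord.model_json_schema()


def draw_overlay(
    master: np.ndarray,
    boxes: Iterable[ImageBox],
    color: tuple[int, int, int] = (255, 40, 40),
    thickness: int = 3,
) -> np.ndarray:
    """Copy of the master with box outlines drawn; differs only on outline pixels."""
    out = np.array(master, copy=True)
    h, w = out.shape[:2]
    for box in boxes:
        r0, r1, c0, c1 = pixel_rect(box, w, h)
        t = max(1, thickness)
        out[r0 : min(r0 + t, r1), c0:c1] = color
        out[max(r1 - t, r0) : r1, c0:c1] = color
        out[r0:r1, c0 : min(c0 + t, c1)] = color
        out[r0:r1, max(c1 - t, c0) : c1] = color
    return out


def find_box_overlaps(boxes: list[ImageBox]) -> list[tuple[int, int]]:
    """Index pairs (i < j) of boxes with positive intersection area."""
    pairs = []
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            if boxes[i].intersection_area(boxes[j]) > 0.0:
                pairs.append((i, j))
    return pairs


def organize_outputs(
    records: Iterable[MetadataRecord],
    run_root: str | Path,
    position_classes: dict[int, str],
) -> dict[str, int]:
    """File subimages into per-class subfolders under ``run_root``; idempotent.

    Subimages are expected at ``run_root`` (as produced by the pipeline) or
    already inside their class folder from a previous invocation.  Returns
    per-class counts.  Raises on a position_id with no assigned class.
    """
    root = Path(run_root)
    counts: dict[str, int] = {}
    for record in records:
        for bb in record.bounding_boxes:
            if bb.position_id not in position_classes:
                raise LabelerError(f"position_id {bb.position_id} has no assigned class")
            cls = position_classes[bb.position_id]
            dest_dir = root / cls
            dest_dir.mkdir(parents=True, exist_ok=True)
            src = root / bb.subimage_file_name
            dest = dest_dir / bb.subimage_file_name
            if src.exists() and not dest.exists():
                shutil.move(str(src), str(dest))
            elif src.exists() and dest.exists():
                src.unlink()  # rerun left a stray copy at the root
            elif not dest.exists():
                raise LabelerError(f"subimage {bb.subimage_file_name} not found at {root}")
            counts[cls] = counts.get(cls, 0) + 1
    return counts
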