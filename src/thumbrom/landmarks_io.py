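"""Landmark frame containers and table I/O.

A *frame* is one image's worth of hand pose: 21 2D keypoints in the
MediaPipe-Hands index convention (0 wrist; 1-4 thumb CMC/MCP/IP/tip; 5-8
index MCP..tip; 9-12 middle; 13-16 ring; 17-20 little), in pixel units with
image-convention y (increasing downward), plus optional metadata: the
goniometric ground-truth abduction angle, the camera azimuth and a subject
identifier.

Two on-disk dialects are supported, both plain text:

* CSV with header
  ``frame_id,subject_id,view_azimuth_deg,true_angle_deg,x0,y0,...,x20,y20``
  (UTF-8, ``.`` decimal separator, empty cell = missing optional field);
* JSON-lines with one object per frame carrying the same keys and a
  ``points`` key holding 21 ``[x, y]`` pairs.

Pixel coordinates are the canonical internal unit.  Normalized detector
output must be converted with :func:`normalize_to_pixels` using the true
image width/height before any feature computation, because anisotropic
normalized coordinates distort angles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

N_LANDMARKS = 21

#: Landmark indices used throughout the package (MediaPipe-Hands convention).
WRIST = 0
THUMB_CMC, THUMB_MCP, THUMB_IP, THUMB_TIP = 1, 2, 3, 4
INDEX_MCP, INDEX_PIP, INDEX_DIP, INDEX_TIP = 5, 6, 7, 8
MIDDLE_MCP = 9
RING_MCP = 13
LITTLE_MCP = 17

_META_COLUMNS = ["frame_id", "subject_id", "view_azimuth_deg", "true_angle_deg"]
_COORD_COLUMNS = [f"{ax}{i}" for i in range(N_LANDMARKS) for ax in ("x", "y")]
CSV_COLUMNS = _META_COLUMNS + _COORD_COLUMNS


@dataclass
class HandLandmarkFrame:
    """One frame of 21 hand landmarks with optional labels.

    Parameters
    ----------
    frame_id
        Non-negative integer, unique within a dataset.
    points
        Array-like of shape (21, 2): pixel coordinates, y increasing
        downward.
    true_angle_deg
        Goniometric ground-truth radial-abduction angle in degrees,
        in [0, 180], or None when unlabeled.
    view_azimuth_deg
        Camera azimuth in degrees (0 = frontal/dorsal view), or None.
    subject_id
        Free-form subject identifier, or None.
    """

    frame_id: int
    points: np.ndarray
    true_angle_deg: float | None = None
    view_azimuth_deg: float | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"frame {self.frame_id}: expected {N_LANDMARKS} 2D points, "
                f"got array of shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError(f"frame {self.frame_id}: non-finite coordinate")
        if int(self.frame_id) < 0:
            raise ValidationError(f"frame_id must be non-negative, got {self.frame_id}")
        self.frame_id = int(self.frame_id)
        if self.true_angle_deg is not None:
            t = float(self.true_angle_deg)
            if not (0.0 <= t <= 180.0) or not math.isfinite(t):
                raise ValidationError(
                    f"frame {self.frame_id}: true_angle_deg {t} outside [0, 180]"
                )
            self.true_angle_deg = t
        if self.view_azimuth_deg is not None:
            self.view_azimuth_deg = float(self.view_azimuth_deg)
        self.points = pts

    @property
    def labeled(self) -> bool:
        return self.true_angle_deg is not None


@dataclass
class LandmarkDataset:
    """An ordered collection of frames plus free-form provenance metadata."""

    frames: list[HandLandmarkFrame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = list(self.frames)
        ids = [f.frame_id for f in self.frames]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate frame_id {dup} in dataset")
        labeled = [f.labeled for f in self.frames]
        if any(labeled) and not all(labeled):
            raise ValidationError(
                "dataset mixes labeled and unlabeled frames; "
                "either all frames carry true_angle_deg or none do"
            )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[HandLandmarkFrame]:
        return iter(self.frames)

    @property
    def labeled(self) -> bool:
        return bool(self.frames) and self.frames[0].labeled

    def labels(self) -> np.ndarray:
        """Ground-truth angles in frame order. Raises if unlabeled."""
        if not self.labeled:
            raise ValidationError("dataset carries no true_angle_deg labels")
        return np.array([f.true_angle_deg for f in self.frames], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f in self.frames:
            row: dict = {
                "frame_id": f.frame_id,
                "subject_id": f.subject_id,
                "view_azimuth_deg": f.view_azimuth_deg,
                "true_angle_deg": f.true_angle_deg,
            }
            flat = f.points.ravel()
            row.update(zip(_COORD_COLUMNS, flat))
            rows.append(row)
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _frame_from_record(record: dict, points: np.ndarray, where: str) -> HandLandmarkFrame:
    try:
        return HandLandmarkFrame(
            frame_id=record["frame_id"],
            points=points,
            true_angle_deg=record.get("true_angle_deg"),
            view_azimuth_deg=record.get("view_azimuth_deg"),
            subject_id=record.get("subject_id"),
        )
    except ValidationError as exc:
        raise FormatError(f"{where}: {exc}") from exc


def _opt_float(value, where: str, what: str) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{where}: non-numeric {what}: {value!r}") from exc


def read_landmark_table(path: str | Path, format: str | None = None) -> LandmarkDataset:
    """Read a landmark dataset from ``path``.

    ``format`` is ``"csv"`` or ``"jsonl"``; when None it is taken from the
    file suffix.  Malformed input raises :class:`FormatError` naming the
    offending row.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        frames = _read_csv(path)
    elif fmt == "jsonl":
        frames = _read_jsonl(path)
    else:
        raise ValidationError(f"unknown landmark table format {fmt!r}")
    try:
        return LandmarkDataset(frames, metadata={"source": str(path), "format": fmt})
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_csv(path: Path) -> list[HandLandmarkFrame]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    frames = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        rec = dict(zip(df.columns, row))
        where = f"{path} line {i}"
        coords = []
        for col in _COORD_COLUMNS:
            val = rec[col]
            if val.strip() == "":
                raise FormatError(f"{where}: empty coordinate cell {col}")
            try:
                coords.append(float(val))
            except ValueError as exc:
                raise FormatError(f"{where}: non-numeric coordinate {col}={val!r}") from exc
        try:
            frame_id = int(float(rec["frame_id"]))
        except ValueError as exc:
            raise FormatError(f"{where}: non-integer frame_id {rec['frame_id']!r}") from exc
        record = {
            "frame_id": frame_id,
            "subject_id": rec["subject_id"] or None,
            "view_azimuth_deg": _opt_float(rec["view_azimuth_deg"], where, "view_azimuth_deg"),
            "true_angle_deg": _opt_float(rec["true_angle_deg"], where, "true_angle_deg"),
        }
        pts = np.array(coords, dtype=float).reshape(N_LANDMARKS, 2)
        frames.append(_frame_from_record(record, pts, where))
    return frames


def _read_jsonl(path: Path) -> list[HandLandmarkFrame]:
    frames = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            where = f"{path} line {lineno}"
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{where}: invalid JSON: {exc}") from exc
            pts = obj.get("points")
            if (not isinstance(pts, list) or len(pts) != N_LANDMARKS
                    or any(not isinstance(p, list) or len(p) != 2 for p in pts)):
                raise FormatError(
                    f"{where}: 'points' must be {N_LANDMARKS} [x, y] pairs"
                )
            arr = []
            for p in pts:
                arr.append([
                    _opt_float(p[0], where, "x") if p[0] is not None else math.nan,
                    _opt_float(p[1], where, "y") if p[1] is not None else math.nan,
                ])
            record = {
                "frame_id": obj.get("frame_id"),
                "subject_id": obj.get("subject_id"),
                "view_azimuth_deg": _opt_float(obj.get("view_azimuth_deg"), where, "view_azimuth_deg"),
                "true_angle_deg": _opt_float(obj.get("true_angle_deg"), where, "true_angle_deg"),
            }
            if record["frame_id"] is None:
                raise FormatError(f"{where}: missing frame_id")
            frames.append(_frame_from_record(record, np.array(arr, dtype=float), where))
    return frames


def write_landmark_table(dataset: LandmarkDataset, path: str | Path,
                         format: str | None = None) -> None:
    """Write ``dataset`` to ``path`` in the documented CSV or JSONL dialect.

    Floats are written with ``repr``-level precision, so a write/read
    round-trip is exact for IEEE doubles.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = dataset.to_dataframe()
        df.to_csv(path, index=False)
    elif fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for f in dataset.frames:
                obj = {
                    "frame_id": f.frame_id,
                    "subject_id": f.subject_id,
                    "view_azimuth_deg": f.view_azimuth_deg,
                    "true_angle_deg": f.true_angle_deg,
                    "points": [[float(x), float(y)] for x, y in f.points],
                }
                fh.write(json.dumps(obj) + "\n")
    else:
        raise ValidationError(f"unknown landmark table format {fmt!r}")


def normalize_to_pixels(frame: HandLandmarkFrame, width: int, height: int) -> HandLandmarkFrame:
    """Convert a frame with normalized [0, 1] coordinates to pixel units.

    ``x' = x * width``, ``y' = y * height``; labels and identifiers are
    unchanged.  Raises :class:`ValidationError` if any coordinate falls
    outside [0, 1] or the image size is non-positive.
    """
    if width <= 0 or height <= 0:
        raise ValidationError(f"image size must be positive, got {width}x{height}")
    pts = frame.points
    if pts.min() < 0.0 or pts.max() > 1.0:
        raise ValidationError(
            f"frame {frame.frame_id}: coordinates outside [0, 1]; "
            "already in pixel units?"
        )
    scaled = pts * np.array([float(width), float(height)])
    return replace(frame, points=scaled)
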