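"""Geometric features of a landmark frame.

Seven scalar parameters summarize the thumb's position relative to the rest
of the hand; they form the design matrix for the regression models.  With
``p_i`` the i-th landmark:

================  =======================================================
tip_joint_angle   interior angle at the wrist between the middle-MCP ray
                  and the thumb-tip ray, angle(p9, p0, p4), degrees
tip_distance      |p4 - p8| / |p0 - p5| — thumb-tip to index-tip distance,
                  normalized by index-MCP (base-axis) length
mp_joint_angle    angle(p9, p0, p2), degrees
mp_distance       |p2 - p5| / |p0 - p5|
ip_joint_angle    angle(p9, p0, p3), degrees
palmsize1         triangle area (p5, p0, p17) — the palm — normalized by
                  |p0 - p5|^2
palmsize2         triangle area (p3, p0, p6) — the thumb/index web —
                  normalized by |p0 - p5|^2
================  =======================================================

Every feature is invariant under rotation, translation and uniform scaling
of the frame.  Normalization of the two areas by the squared index-MCP
length makes them scale-free; it can be disabled (``normalize_palm_areas``)
to obtain raw pixel areas.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ValidationError
from .landmarks_io import HandLandmarkFrame, LandmarkDataset

FEATURE_NAMES = [
    "tip_joint_angle",
    "tip_distance",
    "mp_joint_angle",
    "mp_distance",
    "ip_joint_angle",
    "palmsize1",
    "palmsize2",
]

META_COLUMNS = ["frame_id", "subject_id", "view_azimuth_deg", "true_angle_deg"]


@dataclass(frozen=True)
class FeatureVector:
    tip_joint_angle: float
    tip_distance: float
    mp_joint_angle: float
    mp_distance: float
    ip_joint_angle: float
    palmsize1: float
    palmsize2: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dataclass_fields(self)])

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


def angle_at_vertex(vertex, a, b) -> float:
    """Interior angle at ``vertex`` of the triple (a, vertex, b), degrees.

    Computed as the arccosine of the normalized dot product of the two arm
    vectors, clamped to [-1, 1] to absorb rounding; the result lies in
    [0, 180] and is symmetric in (a, b) and invariant to rotation,
    translation and uniform scaling.
    """
    vertex, a, b = (np.asarray(p, dtype=float) for p in (vertex, a, b))
    u, v = a - vertex, b - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length arm in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def triangle_area(p, q, r) -> float:
    """Absolute (shoelace) area of the triangle (p, q, r); zero iff collinear."""
    p, q, r = (np.asarray(x, dtype=float) for x in (p, q, r))
    u, v = q - p, r - p
    return float(0.5 * abs(u[0] * v[1] - u[1] * v[0]))


def compute_features(frame: HandLandmarkFrame,
                     normalize_palm_areas: bool = True) -> FeatureVector:
    """The seven geometric parameters of one landmark frame.

    Raises :class:`DegenerateGeometryError` when the normalization length
    |p0 - p5| vanishes or an angle arm is degenerate.
    """
    p = frame.points
    base = float(np.linalg.norm(p[0] - p[5]))
    if base == 0.0:
        raise DegenerateGeometryError(
            f"frame {frame.frame_id}: normalization length |p0 - p5| is zero")
    area_norm = base**2 if normalize_palm_areas else 1.0
    return FeatureVector(
        tip_joint_angle=angle_at_vertex(p[0], p[9], p[4]),
        tip_distance=float(np.linalg.norm(p[4] - p[8])) / base,
        mp_joint_angle=angle_at_vertex(p[0], p[9], p[2]),
        mp_distance=float(np.linalg.norm(p[2] - p[5])) / base,
        ip_joint_angle=angle_at_vertex(p[0], p[9], p[3]),
        palmsize1=triangle_area(p[5], p[0], p[17]) / area_norm,
        palmsize2=triangle_area(p[3], p[0], p[6]) / area_norm,
    )


def direct_angle_estimate(frame: HandLandmarkFrame,
                          reference: str = "index_mcp_ray") -> float:
    """Direct coordinate-based abduction estimate, no learning involved.

    The radial abduction angle is approximated by the planar angle at the
    wrist between the thumb-tip ray (0->4) and a reference ray:
    ``index_mcp_ray`` (0->5, default — the 2D analog of the first/second
    metacarpal angle) or ``index_tip_ray`` (0->8).
    """
    refs = {"index_mcp_ray": 5, "index_tip_ray": 8}
    if reference not in refs:
        raise ValidationError(f"unknown reference ray {reference!r}")
    p = frame.points
    return angle_at_vertex(p[0], p[4], p[refs[reference]])


def feature_table(dataset: LandmarkDataset,
                  normalize_palm_areas: bool = True) -> pd.DataFrame:
    """Feature matrix for a dataset: meta columns plus the seven features."""
    rows = []
    for f in dataset:
        row = {
            "frame_id": f.frame_id,
            "subject_id": f.subject_id,
            "view_azimuth_deg": f.view_azimuth_deg,
            "true_angle_deg": f.true_angle_deg,
        }
        row.update(compute_features(f, normalize_palm_areas).as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_NAMES)
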