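"""The seven tape-measure-analog anthropometric measurements per breast.

All distances are over-surface geodesics by default (a tape measure
follows the skin); a Euclidean straight-line mode exists for comparison.
Per side:

``SN_N``
    sternal notch to nipple.
``LBP_N``
    inframammary fold (lower breast pole sticker) to nipple.
``UBP_N``
    derived upper breast pole to nipple ("the shortest UBP-N distance").
``XI_N``
    xiphoid to nipple.
``LABP_N``
    lateral breast pole to nipple.
``BREAST_WIDTH``
    medial-to-lateral breast extent through the nipple: geodesic from the
    medial endpoint (where the sagittal-plane trace on the chest crosses
    the transverse plane through the nipple) to the nipple, plus nipple
    to LaBP.
``IMF_LENGTH``
    length of the inframammary fold: geodesic from the medial fold
    terminus through LBP to the lateral fold terminus.  The termini come
    from two optional extra stickers or from injected points.

A completed automatic run yields exactly 14 records (7 per side).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import trimesh.intersections

from ._spatial import NearestSurface
from .errors import MeasurementError
from .geodesic import DEFAULT_STEINER_PER_EDGE, SurfaceGeodesics
from .landmarks import LandmarkSet, derive_ubp
from .mesh_io import SurfacePoint, TexturedMesh
from .symmetry_stats import MEASUREMENT_NAMES, SymmetryResult, symmetry_index


@dataclass
class Measurement:
    """One anthropometric distance on one breast."""

    name: str
    side: str
    value: float  # cm
    method: str = "automatic"  # "manual" | "automatic"
    path: np.ndarray | None = None  # optional on-surface polyline

    def __post_init__(self) -> None:
        if self.name not in MEASUREMENT_NAMES:
            raise MeasurementError(f"unknown measurement name {self.name!r}")
        if self.value <= 0:
            raise MeasurementError(f"{self.name}({self.side}) must be positive")
        if self.path is not None:
            plen = float(np.linalg.norm(np.diff(self.path, axis=0), axis=1).sum())
            if abs(plen - self.value) > 1e-6:
                raise MeasurementError(
                    f"{self.name}({self.side}): path length {plen} != value {self.value}")


@dataclass
class MeasurementTable:
    """All measurements of one scan."""

    scan_id: str
    records: list[Measurement] = field(default_factory=list)

    def value(self, name: str, side: str) -> float:
        for rec in self.records:
            if rec.name == name and rec.side == side:
                return rec.value
        raise MeasurementError(f"{name}({side}) not in table for scan {self.scan_id}")

    def side_values(self, side: str) -> dict[str, float]:
        return {r.name: r.value for r in self.records if r.side == side}

    def mean_left_right(self, name: str) -> float:
        return 0.5 * (self.value(name, "left") + self.value(name, "right"))

    def per_patient_means(self) -> list[tuple[str, str, float]]:
        """(name, method, mean of left and right) for every complete pair."""
        by_key: dict[tuple[str, str], dict[str, float]] = {}
        for rec in self.records:
            by_key.setdefault((rec.name, rec.method), {})[rec.side] = rec.value
        out = []
        for (name, method), sides in sorted(by_key.items()):
            if "left" in sides and "right" in sides:
                out.append((name, method, 0.5 * (sides["left"] + sides["right"])))
        return out

    def symmetry(self, included: Iterable[str] = MEASUREMENT_NAMES) -> SymmetryResult:
        return symmetry_index(self.side_values("left"), self.side_values("right"),
                              included=included)

    # ------------------------------------------------------------------ CSV io

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"scan_id": self.scan_id, "name": r.name, "side": r.side,
              "method": r.method, "value_cm": r.value} for r in self.records])

    def to_csv(self, path: str | os.PathLike, header_comment: str = "") -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.to_dataframe().to_csv(fh, index=False)

    @staticmethod
    def from_csv(path: str | os.PathLike | io.IOBase) -> list["MeasurementTable"]:
        """Read one or more scans' tables from a measurement CSV."""
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        required = {"scan_id", "name", "side", "method", "value_cm"}
        if not required.issubset(df.columns):
            raise MeasurementError(
                f"measurement CSV must have columns {sorted(required)}")
        tables = []
        for scan_id, group in df.groupby("scan_id", sort=True):
            records = [Measurement(name=row["name"], side=row["side"],
                                   value=float(row["value_cm"]),
                                   method=row["method"])
                       for _, row in group.iterrows()
                       if row["name"] in MEASUREMENT_NAMES]
            tables.append(MeasurementTable(scan_id=str(scan_id), records=records))
        return tables


# ----------------------------------------------------------------- single pairs


def geodesic_distance(mesh: TexturedMesh, a: SurfacePoint, b: SurfacePoint,
                      steiner_per_edge: int = DEFAULT_STEINER_PER_EDGE,
                      engine: SurfaceGeodesics | None = None,
                      ) -> tuple[float, np.ndarray]:
    """Surface distance (cm) and on-surface polyline between two points."""
    if engine is None:
        engine = SurfaceGeodesics(mesh, steiner_per_edge=steiner_per_edge)
    return engine.distance(a, b)


# ------------------------------------------------------------------ measurement


def _nearest_surface_point(mesh: TexturedMesh, point: np.ndarray,
                           nearest: NearestSurface | None = None) -> SurfacePoint:
    if nearest is None:
        nearest = NearestSurface(mesh.vertices, mesh.faces)
    _, fid, bary = nearest.query(np.asarray(point, float))
    return SurfacePoint(int(fid[0]), tuple(bary[0]))


def width_medial_endpoint(mesh: TexturedMesh, lset: LandmarkSet, side: str,
                          nearest: NearestSurface | None = None) -> SurfacePoint:
    """Medial endpoint of BREAST_WIDTH.

    The intersection of the sagittal-plane trace on the chest surface
    with the transverse plane through the nipple: the on-surface midline
    point at nipple height.
    """
    if lset.sagittal_plane is None:
        raise MeasurementError("sagittal plane missing for the width endpoint")
    n_pos = lset.require("N", side).position
    sn = lset.require("SN", "midline").position
    xi = lset.require("XI", "midline").position
    up = sn - xi
    up = up / np.linalg.norm(up)
    tm = mesh.as_trimesh()
    segments = trimesh.intersections.mesh_plane(
        tm, plane_normal=lset.sagittal_plane.normal,
        plane_origin=lset.sagittal_plane.point)
    if len(segments) == 0:
        raise MeasurementError("sagittal plane does not intersect the mesh")
    h = (segments - n_pos) @ up  # (k, 2) heights of segment endpoints
    crossing = (h[:, 0] * h[:, 1]) <= 0
    candidates = []
    for seg, (ha, hb) in zip(segments[crossing], h[crossing]):
        t = 0.5 if ha == hb else ha / (ha - hb)
        candidates.append(seg[0] + t * (seg[1] - seg[0]))
    if not candidates:
        raise MeasurementError(
            "sagittal trace never reaches nipple height: width endpoint undefined")
    candidates = np.asarray(candidates)
    best = candidates[np.argmin(np.linalg.norm(candidates - n_pos, axis=1))]
    return _nearest_surface_point(mesh, best, nearest)


def measure_breast(mesh: TexturedMesh, lset: LandmarkSet, side: str,
                   engine: SurfaceGeodesics | None = None,
                   mode: str = "geodesic",
                   steiner_per_edge: int = DEFAULT_STEINER_PER_EDGE,
                   fold_points: Mapping[str, SurfacePoint] | None = None,
                   ) -> list[Measurement]:
    """The seven measurements of one breast, via surface distances.

    ``fold_points`` may inject the medial/lateral inframammary fold
    termini (keys ``IMF_MED``, ``IMF_LAT``) when no fold stickers were
    detected.
    """
    if side not in ("left", "right"):
        raise MeasurementError(f"side must be left or right, not {side!r}")
    if mode not in ("geodesic", "euclidean"):
        raise MeasurementError(f"unknown distance mode {mode!r}")
    n_lm = lset.require("N", side)
    sn = lset.require("SN", "midline")
    xi = lset.require("XI", "midline")
    lbp = lset.require("LBP", side)
    labp = lset.require("LABP", side)
    ubp = lset.require("UBP", side)

    def fold_terminus(label: str) -> SurfacePoint:
        if fold_points and label in fold_points:
            return fold_points[label]
        lm = lset.get(label, side)
        if lm is None:
            raise MeasurementError(
                f"{label}({side}) absent: provide fold stickers or injected points")
        return lm.point

    imf_med = fold_terminus("IMF_MED")
    imf_lat = fold_terminus("IMF_LAT")
    med_width = width_medial_endpoint(mesh, lset, side)

    if mode == "euclidean":
        def pair(a: SurfacePoint, b: SurfacePoint) -> tuple[float, np.ndarray]:
            pa, pb = mesh.point_at(a), mesh.point_at(b)
            return float(np.linalg.norm(pb - pa)), np.vstack([pa, pb])
        from_n = {t: pair(n_lm.point, t) for t in
                  (sn.point, lbp.point, ubp.point, xi.point, labp.point, med_width)}
        from_lbp = {t: pair(lbp.point, t) for t in (imf_med, imf_lat)}
    else:
        if engine is None:
            engine = SurfaceGeodesics(mesh, steiner_per_edge=steiner_per_edge)
        n_targets = [sn.point, lbp.point, ubp.point, xi.point, labp.point, med_width]
        from_n = dict(zip(n_targets, engine.distances_from(n_lm.point, n_targets)))
        lbp_targets = [imf_med, imf_lat]
        from_lbp = dict(zip(lbp_targets,
                            engine.distances_from(lbp.point, lbp_targets)))

    def rec(name: str, value: float, path: np.ndarray) -> Measurement:
        return Measurement(name=name, side=side, value=value, path=path)

    d_med, p_med = from_n[med_width]
    d_labp, p_labp = from_n[labp.point]
    d_imf_m, p_imf_m = from_lbp[imf_med]
    d_imf_l, p_imf_l = from_lbp[imf_lat]
    return [
        rec("SN_N", *_flip(from_n[sn.point])),
        rec("LBP_N", *_flip(from_n[lbp.point])),
        rec("UBP_N", *_flip(from_n[ubp.point])),
        rec("XI_N", *_flip(from_n[xi.point])),
        rec("LABP_N", *_flip(from_n[labp.point])),
        rec("BREAST_WIDTH", d_med + d_labp,
            np.vstack([p_med[::-1], p_labp[1:]])),
        rec("IMF_LENGTH", d_imf_m + d_imf_l,
            np.vstack([p_imf_m[::-1], p_imf_l[1:]])),
    ]


def _flip(result: tuple[float, np.ndarray]) -> tuple[float, np.ndarray]:
    # distances were computed from N; report paths landmark -> N
    length, path = result
    return length, path[::-1]


def measure_scan(mesh: TexturedMesh, lset: LandmarkSet,
                 scan_id: str | None = None,
                 mode: str = "geodesic",
                 steiner_per_edge: int = DEFAULT_STEINER_PER_EDGE,
                 fold_points: Mapping[str, Mapping[str, SurfacePoint]] | None = None,
                 ) -> MeasurementTable:
    """All 14 automatic measurements of a scan (7 per side).

    Derives the UBP landmarks first if they are not yet present (the
    sagittal plane must already be set).  ``fold_points`` may map side ->
    {IMF_MED, IMF_LAT} -> SurfacePoint for injected fold termini.
    """
    if scan_id is None:
        scan_id = mesh.name or "scan"
    engine = SurfaceGeodesics(mesh, steiner_per_edge=steiner_per_edge) \
        if mode == "geodesic" else None
    for side in ("left", "right"):
        if lset.get("UBP", side) is None:
            derive_ubp(mesh, lset, side)
    records: list[Measurement] = []
    for side in ("left", "right"):
        records.extend(measure_breast(
            mesh, lset, side, engine=engine, mode=mode,
            steiner_per_edge=steiner_per_edge,
            fold_points=(fold_points or {}).get(side)))
    return MeasurementTable(scan_id=scan_id, records=records)
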