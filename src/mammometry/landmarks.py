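"""Anatomical labeling, sagittal plane construction, and the derived UBP.

The 14 sticker landmarks are the sternal notch (SN) and xiphoid (Xi) on
the midline, and per side the nipple (N), lower breast pole (LBP),
lateral breast pole (LaBP), medial and lateral upper breast poles
(MUBP, LUBP) and the coracoid process (CP).  The upper breast pole (UBP)
is not marked: it is derived as the intersection of the MUBP-LUBP
guideline with the parasagittal plane through the nipple, snapped back to
the skin surface.

Frontal 180-degree scans carry no back-of-torso information, so the
sagittal plane cannot use a vertebral landmark.  SN and Xi pin the plane's
vertical in-plane axis; the missing normal direction comes from the
bilateral landmark pairs: the mean left-to-right vector over the N, CP
and LaBP pairs, orthogonalized against the SN-Xi axis.  (SN, Xi and their
midpoint alone are collinear and cannot fix a plane.)

Side convention: with the subject facing the +Z camera and +Y up, the
anatomical left is +X, i.e. ``left = up x facing``.  Axes may be inferred
from the scan itself (``body_axes="auto"``: up from the SN-to-Xi sticker
axis, facing from the mean surface normal), which makes labeling
equivariant under rigid motion of the scan.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._spatial import NearestSurface
from .errors import GeometryError, LabelingError
from .mesh_io import Plane, SurfacePoint, TexturedMesh
from .stickers import StickerDetection

MIDLINE_LABELS = ("SN", "XI")
BILATERAL_LABELS = ("N", "LBP", "LABP", "MUBP", "LUBP", "CP")
AUX_LABELS = ("IMF_MED", "IMF_LAT")
#: bilateral pairs used to stabilize the sagittal plane normal
PLANE_PAIR_LABELS = ("N", "CP", "LABP")

SIDES = ("left", "right")


@dataclass
class Landmark:
    """A labeled point on the scan surface."""

    label: str
    side: str  # "midline" | "left" | "right"
    point: SurfacePoint
    position: np.ndarray
    source: str = "detected"  # "detected" | "derived" | "injected"


@dataclass
class LandmarkSet:
    """The labeled landmarks of one scan plus the sagittal plane."""

    landmarks: dict[tuple[str, str], Landmark] = field(default_factory=dict)
    aux: dict[tuple[str, str], Landmark] = field(default_factory=dict)
    sagittal_plane: Plane | None = None
    up_axis: np.ndarray | None = None

    def get(self, label: str, side: str) -> Landmark | None:
        key = (label, side)
        return self.landmarks.get(key) or self.aux.get(key)

    def require(self, label: str, side: str) -> Landmark:
        lm = self.get(label, side)
        if lm is None:
            from .errors import MeasurementError
            raise MeasurementError(f"{label}({side}) absent from landmark set")
        return lm

    def add(self, lm: Landmark) -> None:
        target = self.aux if lm.label in AUX_LABELS else self.landmarks
        target[(lm.label, lm.side)] = lm

    # ------------------------------------------------------------------ JSON io

    def to_json(self, path: str | os.PathLike) -> None:
        def encode(lm: Landmark) -> dict:
            return {
                "label": lm.label, "side": lm.side, "source": lm.source,
                "face_index": int(lm.point.face_index),
                "barycentric": [float(b) for b in lm.point.barycentric],
                "position": [float(x) for x in lm.position],
            }
        payload = {
            "landmarks": [encode(lm) for _, lm in sorted(self.landmarks.items())],
            "aux": [encode(lm) for _, lm in sorted(self.aux.items())],
        }
        if self.sagittal_plane is not None:
            payload["sagittal_plane"] = {
                "point": self.sagittal_plane.point.tolist(),
                "normal": self.sagittal_plane.normal.tolist(),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "LandmarkSet":
        with open(path) as fh:
            payload = json.load(fh)

        def decode(rec: dict) -> Landmark:
            return Landmark(
                label=rec["label"], side=rec["side"], source=rec.get("source", "injected"),
                point=SurfacePoint(rec["face_index"], tuple(rec["barycentric"])),
                position=np.asarray(rec["position"], dtype=float))

        lset = cls()
        for rec in payload.get("landmarks", []):
            lset.landmarks[(rec["label"], rec["side"])] = decode(rec)
        for rec in payload.get("aux", []):
            lset.aux[(rec["label"], rec["side"])] = decode(rec)
        plane = payload.get("sagittal_plane")
        if plane:
            lset.sagittal_plane = Plane(np.asarray(plane["point"]),
                                        np.asarray(plane["normal"]))
        return lset


# --------------------------------------------------------------------- labeling


def _mean_surface_normal(mesh: TexturedMesh) -> np.ndarray:
    c = mesh.face_corners()
    cross = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
    total = cross.sum(axis=0)  # area-weighted
    norm = np.linalg.norm(total)
    if norm < 1e-12:
        raise LabelingError("cannot infer facing direction from a closed surface")
    return total / norm


def label_landmarks(detections: list[StickerDetection],
                    mesh: TexturedMesh | None = None,
                    body_axes: str = "auto",
                    up_axis=(0.0, 1.0, 0.0),
                    subject_facing=(0.0, 0.0, 1.0),
                    flip_vertical: bool = False,
                    aux_detections: list[StickerDetection] | None = None,
                    ) -> LandmarkSet:
    """Assign anatomical labels and sides to sticker detections.

    Expects exactly 14 detections: one per midline class (SN, Xi) and two
    per bilateral class.  A single combined midline class ``MID`` is also
    accepted; its two members are then told apart by height (SN above Xi).
    With ``body_axes="auto"`` the up direction is the Xi-to-SN sticker
    axis and the facing direction is the mean surface normal (requires
    ``mesh``), making labeling independent of scanner coordinates;
    ``body_axes="config"`` uses the supplied axes, with ``flip_vertical``
    flipping the up direction for upside-down scans.
    """
    groups: dict[str, list[StickerDetection]] = {}
    for det in detections:
        groups.setdefault(det.color_label, []).append(det)

    problems = []
    if "MID" in groups:
        expected = {"MID": 2}
    else:
        expected = {label: 1 for label in MIDLINE_LABELS}
    expected.update({label: 2 for label in BILATERAL_LABELS})
    for label, want in expected.items():
        got = len(groups.get(label, []))
        if got != want:
            problems.append(f"{label}: expected {want}, got {got}")
    extra = set(groups) - set(expected)
    if extra:
        problems.append(f"unexpected classes {sorted(extra)}")
    if problems:
        raise LabelingError("wrong detection count: " + "; ".join(problems))

    up_cfg = np.asarray(up_axis, dtype=float)
    up_cfg /= np.linalg.norm(up_cfg)
    if flip_vertical:
        up_cfg = -up_cfg

    if "MID" in groups:
        a, b = groups["MID"]
        ha, hb = float(a.position_3d @ up_cfg), float(b.position_3d @ up_cfg)
        sn_det, xi_det = (a, b) if ha >= hb else (b, a)
    else:
        sn_det, xi_det = groups["SN"][0], groups["XI"][0]

    if body_axes == "auto":
        up = sn_det.position_3d - xi_det.position_3d
        nu = np.linalg.norm(up)
        if nu < 1e-9:
            raise LabelingError("SN and Xi coincide; cannot infer the up axis")
        up = up / nu
        if mesh is None:
            raise LabelingError("body_axes='auto' needs the mesh to infer facing")
        facing = _mean_surface_normal(mesh)
    else:
        up = up_cfg
        facing = np.asarray(subject_facing, dtype=float)
        facing /= np.linalg.norm(facing)
    facing = facing - (facing @ up) * up
    nf = np.linalg.norm(facing)
    if nf < 1e-9:
        raise LabelingError("facing direction parallel to the up axis")
    facing /= nf
    left_dir = np.cross(up, facing)

    mid = 0.5 * (sn_det.position_3d + xi_det.position_3d)
    lset = LandmarkSet(up_axis=up)
    lset.add(Landmark("SN", "midline", sn_det.surface_point,
                      np.asarray(sn_det.position_3d, float)))
    lset.add(Landmark("XI", "midline", xi_det.surface_point,
                      np.asarray(xi_det.position_3d, float)))

    def assign_pair(label: str, pair: list[StickerDetection],
                    target: dict) -> None:
        lat = [float((d.position_3d - mid) @ left_dir) for d in pair]
        if lat[0] * lat[1] >= 0:
            raise LabelingError(
                f"both {label} stickers lie on the same side of the SN-Xi axis")
        for det, l in zip(pair, lat):
            side = "left" if l > 0 else "right"
            target[(label, side)] = Landmark(
                label, side, det.surface_point, np.asarray(det.position_3d, float))

    for label in BILATERAL_LABELS:
        assign_pair(label, groups[label], lset.landmarks)

    if aux_detections:
        aux_groups: dict[str, list[StickerDetection]] = {}
        for det in aux_detections:
            aux_groups.setdefault(det.color_label, []).append(det)
        for label, pair in aux_groups.items():
            if len(pair) != 2:
                raise LabelingError(
                    f"auxiliary class {label}: expected 2 stickers, got {len(pair)}")
            assign_pair(label, pair, lset.aux)
    return lset


# --------------------------------------------------------------- sagittal plane


def compute_sagittal_plane(lset: LandmarkSet) -> Plane:
    """Sagittal plane through SN and Xi, normal from bilateral pairs.

    The plane is anchored at the SN-Xi midpoint and contains both
    landmarks; its normal (pointing toward the anatomical right) is the
    average of the left-to-right vectors over the N, CP and LaBP pairs,
    orthogonalized against the SN-Xi axis.  Stored on ``lset`` and
    returned.
    """
    sn = lset.require("SN", "midline").position
    xi = lset.require("XI", "midline").position
    axis = sn - xi
    na = np.linalg.norm(axis)
    if na < 1e-9:
        raise GeometryError("SN and Xi coincide; the sagittal plane is undefined")
    axis = axis / na

    vectors = []
    for label in PLANE_PAIR_LABELS:
        left = lset.get(label, "left")
        right = lset.get(label, "right")
        if left is not None and right is not None:
            vectors.append(right.position - left.position)
    if not vectors:
        raise GeometryError("no bilateral landmark pair available for the plane normal")
    normal = np.mean(vectors, axis=0)
    normal = normal - (normal @ axis) * axis
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        raise GeometryError(
            "bilateral left-to-right average is parallel to the SN-Xi axis")
    plane = Plane(point=0.5 * (sn + xi), normal=normal / nn)
    lset.sagittal_plane = plane
    return plane


# ------------------------------------------------------------------ derived UBP


def derive_ubp(mesh: TexturedMesh, lset: LandmarkSet, side: str,
               overshoot_fraction: float = 0.5,
               nearest: NearestSurface | None = None) -> Landmark:
    """Upper breast pole: MUBP-LUBP guideline meets the nipple's parasagittal plane.

    The infinite line through the MUBP and LUBP stickers is intersected
    with the plane through the nipple parallel to the sagittal plane; the
    intersection is snapped to the nearest point on the mesh surface
    (a point off the skin has no tape-measure meaning).  An intersection
    far outside the MUBP-LUBP segment (beyond ``overshoot_fraction`` of
    its length) triggers a warning, not an error.
    """
    if lset.sagittal_plane is None:
        raise GeometryError("sagittal plane missing: call compute_sagittal_plane first")
    m = lset.require("MUBP", side).position
    l = lset.require("LUBP", side).position
    n_pos = lset.require("N", side).position
    normal = lset.sagittal_plane.normal
    direction = l - m
    denom = float(direction @ normal)
    if abs(denom) < 1e-9 * max(np.linalg.norm(direction), 1e-12):
        raise GeometryError(
            f"MUBP-LUBP guideline ({side}) is parallel to the parasagittal plane "
            "through the nipple: UBP undefined")
    t = float((n_pos - m) @ normal) / denom
    if t < -overshoot_fraction or t > 1.0 + overshoot_fraction:
        warnings.warn(
            f"UBP({side}) guideline intersection lies at parameter {t:.2f}, "
            "well outside the MUBP-LUBP segment", stacklevel=2)
    raw = m + t * direction
    if nearest is None:
        nearest = NearestSurface(mesh.vertices, mesh.faces)
    closest, fid, bary = nearest.query(raw)
    lm = Landmark("UBP", side, SurfacePoint(int(fid[0]), tuple(bary[0])),
                  closest[0], source="derived")
    lset.add(lm)
    return lm
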