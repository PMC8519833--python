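"""Colored sticker detection in the scan texture.

Anatomical landmarks are marked on the skin with small colored stickers
before scanning; the scanner bakes them into the texture image.  Each
sticker class is one reference color with a tolerance.  Matching happens
in HSV with a hue-weighted distance (hue damped by saturation so that
near-gray skin pixels cannot match a hue by accident), which is far more
robust to the shading baked into scan textures than raw RGB.

A detected pixel blob is carried onto the 3D surface through the inverse
UV parameterization: every blob pixel center is located in the UV atlas,
expressed barycentrically in its face, lifted to 3D, and the sticker
midpoint is the surface point nearest the 3D centroid of those lifts.

One distinct color is used per anatomical label; left and right stickers
of a bilateral label share the color and are disambiguated geometrically
by the landmarks module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.ndimage as ndi
from shapely import STRtree
from shapely.geometry import Point, Polygon
from skimage.color import rgb2hsv

from ._spatial import NearestSurface
from .errors import DetectionError
from .mesh_io import SurfacePoint, TexturedMesh

#: default palette: one color per anatomical label, side resolved
#: geometrically.  Ten evenly spaced saturated hues (36 degrees apart at
#: S = 0.85, V = 0.88): under the hue-weighted metric every pair is
#: separated by > 125 and skin tone by > 130, comfortably beyond twice
#: the default tolerance of 45.
DEFAULT_STICKER_COLORS: dict[str, dict] = {
    "SN":   {"rgb": (224, 34, 34), "tol": 45.0},    # red
    "XI":   {"rgb": (34, 110, 224), "tol": 45.0},   # azure
    "N":    {"rgb": (186, 34, 224), "tol": 45.0},   # magenta
    "LBP":  {"rgb": (34, 224, 110), "tol": 45.0},   # spring green
    "LABP": {"rgb": (224, 148, 34), "tol": 45.0},   # orange
    "MUBP": {"rgb": (34, 224, 224), "tol": 45.0},   # cyan
    "LUBP": {"rgb": (72, 34, 224), "tol": 45.0},    # blue-violet
    "CP":   {"rgb": (186, 224, 34), "tol": 45.0},   # yellow-green
}

#: optional extra stickers marking the medial/lateral inframammary fold termini
FOLD_STICKER_COLORS: dict[str, dict] = {
    "IMF_MED": {"rgb": (224, 34, 148), "tol": 45.0},  # pink
    "IMF_LAT": {"rgb": (72, 224, 34), "tol": 45.0},   # green
}

#: expected sticker count per label (midline labels appear once, bilateral twice)
EXPECTED_COUNTS: dict[str, int] = {
    "SN": 1, "XI": 1,
    "N": 2, "LBP": 2, "LABP": 2, "MUBP": 2, "LUBP": 2, "CP": 2,
    "IMF_MED": 2, "IMF_LAT": 2,
}

DEFAULT_MIN_BLOB_PX = 5

_HUE_W = 6.0
_SAT_W = 1.0
_VAL_W = 0.5


@dataclass(frozen=True)
class StickerDetection:
    """One detected sticker: its class, surface midpoint and pixel evidence."""

    color_label: str
    surface_point: SurfacePoint
    pixel_count: int
    mean_color: tuple[float, float, float]
    position_3d: np.ndarray


def full_color_spec() -> dict[str, dict]:
    """Default landmark palette plus the fold-terminus stickers."""
    return {**DEFAULT_STICKER_COLORS, **FOLD_STICKER_COLORS}


# ------------------------------------------------------------------ color metric


def _hsv_distance(hsv: np.ndarray, ref_hsv: np.ndarray) -> np.ndarray:
    dh = np.abs(hsv[..., 0] - ref_hsv[0])
    dh = np.minimum(dh, 1.0 - dh)
    s_eff = np.minimum(hsv[..., 1], ref_hsv[1])
    d2 = ((_HUE_W * dh * s_eff * 255.0) ** 2
          + (_SAT_W * (hsv[..., 1] - ref_hsv[1]) * 255.0) ** 2
          + (_VAL_W * (hsv[..., 2] - ref_hsv[2]) * 255.0) ** 2)
    return np.sqrt(d2)


def color_distance(rgb: np.ndarray, ref_rgb: Sequence[float]) -> np.ndarray:
    """Hue-weighted HSV distance between pixels and a reference color.

    Both inputs are 8-bit RGB; the result is scaled so tolerances are
    comparable to 8-bit channel differences.  The hue term is weighted by
    the smaller of the two saturations: hue is meaningless for gray.
    """
    rgb = np.asarray(rgb, dtype=float)
    hsv = rgb2hsv(rgb.reshape(-1, 3)[None] / 255.0)[0].reshape(rgb.shape)
    ref = rgb2hsv(np.asarray(ref_rgb, dtype=float)[None, None] / 255.0)[0, 0]
    return _hsv_distance(hsv, ref)


def _check_spec(color_spec: Mapping[str, Mapping]) -> None:
    labels = sorted(color_spec)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            tol = 2.0 * max(float(color_spec[a]["tol"]), float(color_spec[b]["tol"]))
            sep = float(color_distance(
                np.asarray(color_spec[a]["rgb"], float), color_spec[b]["rgb"]))
            if sep <= tol:
                raise DetectionError(
                    f"overlapping color specifications: {a} and {b} are separated "
                    f"by {sep:.1f} but need more than {tol:.1f}")


# ------------------------------------------------------------------ segmentation

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def segment_sticker_pixels(texture: np.ndarray,
                           color_spec: Mapping[str, Mapping],
                           min_blob_px: int = DEFAULT_MIN_BLOB_PX,
                           ) -> dict[str, list[np.ndarray]]:
    """Find 4-connected pixel blobs matching each sticker color class.

    Returns, per label, blobs as ``(k, 2)`` arrays of (row, col) indices,
    sorted by decreasing size (ties broken by lowest pixel index).  Blobs
    smaller than ``min_blob_px`` are dropped.
    """
    _check_spec(color_spec)
    texture = np.asarray(texture)
    if texture.ndim != 3 or texture.shape[2] != 3:
        raise DetectionError("texture must be an (H, W, 3) RGB array")
    h, w = texture.shape[:2]
    labels = sorted(color_spec)
    hsv = rgb2hsv(texture.astype(float) / 255.0)  # converted once, reused per class
    dists = np.stack([
        _hsv_distance(hsv, rgb2hsv(
            np.asarray(color_spec[l]["rgb"], float)[None, None] / 255.0)[0, 0])
        for l in labels])
    tols = np.array([float(color_spec[l]["tol"]) for l in labels])
    within = dists <= tols[:, None, None]
    best = np.argmin(dists, axis=0)
    out: dict[str, list[np.ndarray]] = {}
    for li, label in enumerate(labels):
        mask = within[li] & (best == li)
        if not mask.any():
            continue
        lab, nblob = ndi.label(mask, structure=_FOUR_CONNECTED)
        if nblob == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        first_px = ndi.minimum(np.arange(h * w).reshape(h, w), labels=lab,
                               index=np.arange(1, nblob + 1))
        order = sorted(range(nblob),
                       key=lambda i: (-sizes[i], first_px[i]))
        blobs = []
        for i in order:
            if sizes[i] < min_blob_px:
                continue
            rows, cols = np.nonzero(lab == i + 1)
            blobs.append(np.column_stack([rows, cols]))
        if blobs:
            out[label] = blobs
    return out


# -------------------------------------------------------------- UV -> surface


class UVLocator:
    """Point-in-triangle queries in the mesh's UV atlas."""

    def __init__(self, mesh: TexturedMesh):
        self.mesh = mesh
        self._tris = [Polygon(c) for c in mesh.uv]
        self._tree = STRtree(self._tris)

    def locate(self, uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Face index and barycentric coordinates per UV point (-1 if unmapped)."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        pts = [Point(p) for p in uv]
        qi, fi = self._tree.query(pts, predicate="intersects")
        faces = np.full(len(uv), -1, dtype=np.int64)
        bary = np.zeros((len(uv), 3))
        if len(qi) == 0:
            return faces, bary
        # barycentric coordinates for all candidate (point, triangle) pairs
        tri = self.mesh.uv[fi]
        v0 = tri[:, 1] - tri[:, 0]
        v1 = tri[:, 2] - tri[:, 0]
        vp = uv[qi] - tri[:, 0]
        det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
        safe = np.where(np.abs(det) < 1e-15, 1.0, det)
        s = (vp[:, 0] * v1[:, 1] - vp[:, 1] * v1[:, 0]) / safe
        t = (v0[:, 0] * vp[:, 1] - v0[:, 1] * vp[:, 0]) / safe
        u = 1.0 - s - t
        valid = ((np.abs(det) >= 1e-15)
                 & (s >= -1e-9) & (t >= -1e-9) & (u >= -1e-9))
        for point_i, face_i, b0, b1, b2 in zip(
                qi[valid], fi[valid], u[valid], s[valid], t[valid]):
            if faces[point_i] >= 0:
                continue
            b = np.clip([b0, b1, b2], 0.0, None)
            faces[point_i] = face_i
            bary[point_i] = b / b.sum()
        return faces, bary


def pixel_centers_to_uv(blob: np.ndarray, texture_shape: tuple[int, int]) -> np.ndarray:
    """UV coordinates of pixel centers; image row 0 maps to V = 1 (top)."""
    h, w = texture_shape
    u = (blob[:, 1] + 0.5) / w
    v = 1.0 - (blob[:, 0] + 0.5) / h
    return np.column_stack([u, v])


def blob_to_surface_point(mesh: TexturedMesh, blob: np.ndarray,
                          locator: UVLocator | None = None,
                          nearest: NearestSurface | None = None,
                          ) -> tuple[SurfacePoint, np.ndarray]:
    """Sticker midpoint: surface point nearest the 3D centroid of the blob.

    Returns the surface point and its 3D position.  Raises
    :class:`DetectionError` when no blob pixel falls inside the UV atlas
    (texture/mesh mismatch).
    """
    blob = np.asarray(blob)
    if blob.size == 0:
        raise DetectionError("empty pixel blob")
    if locator is None:
        locator = UVLocator(mesh)
    uv = pixel_centers_to_uv(blob, mesh.texture.shape[:2])
    faces, bary = locator.locate(uv)
    hit = faces >= 0
    if not hit.any():
        raise DetectionError(
            "blob lies entirely outside the mesh's UV atlas (texture/mesh mismatch)")
    tri = mesh.vertices[mesh.faces[faces[hit]]]
    pts3d = np.einsum("ij,ijk->ik", bary[hit], tri)
    centroid = pts3d.mean(axis=0)
    if nearest is None:
        nearest = NearestSurface(mesh.vertices, mesh.faces)
    closest, fid, b = nearest.query(centroid)
    sp = SurfacePoint(face_index=int(fid[0]), barycentric=tuple(b[0]))
    return sp, closest[0]


# ------------------------------------------------------------------ composition


def detect_stickers(mesh: TexturedMesh,
                    color_spec: Mapping[str, Mapping] | None = None,
                    min_blob_px: int = DEFAULT_MIN_BLOB_PX,
                    expected_counts: Mapping[str, int] | None = None,
                    ) -> list[StickerDetection]:
    """Detect all stickers on a textured mesh.

    Per color class the largest ``expected_counts[label]`` blobs become
    detections (1 for midline labels, 2 for bilateral ones by default).
    Detections are sorted by label, then by decreasing pixel count.
    """
    if color_spec is None:
        color_spec = DEFAULT_STICKER_COLORS
    counts = dict(EXPECTED_COUNTS)
    if expected_counts:
        counts.update(expected_counts)
    blobs_by_label = segment_sticker_pixels(mesh.texture, color_spec, min_blob_px)
    locator = UVLocator(mesh)
    nearest = NearestSurface(mesh.vertices, mesh.faces)
    detections: list[StickerDetection] = []
    for label in sorted(blobs_by_label):
        keep = blobs_by_label[label][: counts.get(label, None)]
        for blob in keep:
            sp, pos = blob_to_surface_point(mesh, blob, locator, nearest)
            mean_color = tuple(
                mesh.texture[blob[:, 0], blob[:, 1]].mean(axis=0).tolist())
            detections.append(StickerDetection(
                color_label=label, surface_point=sp, pixel_count=len(blob),
                mean_color=mean_color, position_3d=pos))
    return detections
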