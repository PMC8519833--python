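"""Textured triangle meshes: loading, validation, cropping, writing.

The scan format is the minimal Wavefront OBJ dialect that photogrammetry
exports and the phantom generator share: ``v`` / ``vt`` records and faces
indexed as ``f v/vt``, with an MTL sidecar naming a diffuse texture map
(``map_Kd``).  Vertex units are centimetres by default; a scale factor
handles millimetre scanners.  Texture coordinates follow the OBJ
convention (V axis pointing up, origin bottom-left) while image row 0 is
the top of the picture, so the texture reader flips V.

A :class:`SurfacePoint` (face index plus barycentric coordinates) is the
exact on-surface location type used throughout the pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from PIL import Image

from .errors import CropError, MeshFormatError

_DEGENERATE_AREA = 1e-12  # cm^2; faces thinner than this are discarded


@dataclass(frozen=True)
class SurfacePoint:
    """A point on a triangle mesh: face index + barycentric coordinates."""

    face_index: int
    barycentric: tuple[float, float, float]

    def __post_init__(self) -> None:
        b = np.asarray(self.barycentric, dtype=float)
        if b.shape != (3,) or np.any(b < -1e-9):
            raise ValueError(f"invalid barycentric coordinates {self.barycentric}")
        if abs(b.sum() - 1.0) > 1e-9:
            raise ValueError(f"barycentric coordinates must sum to 1, got {b.sum()}")


@dataclass(frozen=True)
class Plane:
    """An oriented plane given by a point and a unit normal (cm)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = float(np.linalg.norm(n))
        if norm < 1e-12:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal


# the paper's crop plane (cut at the abdomen) is an ordinary oriented plane
CropPlane = Plane


@dataclass
class TexturedMesh:
    """Triangle mesh in cm with per-face-corner UV mapping and an RGB texture.

    Attributes
    ----------
    vertices : (n, 3) float array, cm
    faces : (m, 3) int array of vertex indices
    uv : (m, 3, 2) float array, texture coordinates per face corner in [0, 1]
    texture : (H, W, 3) uint8 array, RGB
    name : free-text identifier
    """

    vertices: np.ndarray
    faces: np.ndarray
    uv: np.ndarray
    texture: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.uv = np.ascontiguousarray(self.uv, dtype=np.float64)
        self.texture = np.ascontiguousarray(self.texture, dtype=np.uint8)

    # ------------------------------------------------------------------ geometry

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_corners(self) -> np.ndarray:
        """(m, 3, 3) vertex positions per face corner."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        c = self.face_corners()
        cross = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def surface_area(self) -> float:
        return float(self.face_areas().sum())

    def point_at(self, sp: SurfacePoint) -> np.ndarray:
        """3D position of a surface point."""
        tri = self.vertices[self.faces[sp.face_index]]
        return np.asarray(sp.barycentric, dtype=float) @ tri

    def uv_at(self, sp: SurfacePoint) -> np.ndarray:
        """Texture coordinate of a surface point."""
        return np.asarray(sp.barycentric, dtype=float) @ self.uv[sp.face_index]

    def transformed(self, matrix: np.ndarray) -> "TexturedMesh":
        """Apply a 4x4 homogeneous transform to the geometry (texture unchanged)."""
        matrix = np.asarray(matrix, dtype=float)
        v = self.vertices @ matrix[:3, :3].T + matrix[:3, 3]
        return replace(self, vertices=v, faces=self.faces.copy(),
                       uv=self.uv.copy(), texture=self.texture)

    def as_trimesh(self) -> trimesh.Trimesh:
        """Plain geometry view (no texture) for spatial queries."""
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    def connected_component_count(self) -> int:
        import scipy.sparse as sp
        import scipy.sparse.csgraph as csgraph

        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        g = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])),
                          shape=(self.n_vertices, self.n_vertices))
        ncomp, _ = csgraph.connected_components(g, directed=False)
        return int(ncomp)

    # ------------------------------------------------------------------ texture

    def sample_texture(self, uv: np.ndarray) -> np.ndarray:
        """Bilinear texture lookup. ``uv`` is (k, 2) in [0,1], V up; returns (k, 3) floats."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        h, w = self.texture.shape[:2]
        # flip V: v = 1 at image row 0
        x = np.clip(uv[:, 0] * w - 0.5, 0.0, w - 1.0)
        y = np.clip((1.0 - uv[:, 1]) * h - 0.5, 0.0, h - 1.0)
        x0 = np.floor(x).astype(int)
        y0 = np.floor(y).astype(int)
        x1 = np.minimum(x0 + 1, w - 1)
        y1 = np.minimum(y0 + 1, h - 1)
        fx = (x - x0)[:, None]
        fy = (y - y0)[:, None]
        t = self.texture.astype(np.float64)
        return ((t[y0, x0] * (1 - fx) + t[y0, x1] * fx) * (1 - fy)
                + (t[y1, x0] * (1 - fx) + t[y1, x1] * fx) * fy)

    # ------------------------------------------------------------------ checks

    def validate(self) -> None:
        """Raise :class:`MeshFormatError` on any violated structural invariant."""
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be (m, 3)")
        if self.n_faces and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise MeshFormatError("face index out of range")
        if self.uv.shape != (self.n_faces, 3, 2):
            raise MeshFormatError("uv must be (m, 3, 2), one coordinate per face corner")
        if self.n_faces and (self.uv.min() < -1e-9 or self.uv.max() > 1 + 1e-9):
            raise MeshFormatError("UV components must lie in [0, 1]")
        if self.texture.ndim != 3 or self.texture.shape[2] != 3 or min(self.texture.shape[:2]) < 1:
            raise MeshFormatError("texture must be (H, W, 3) with H, W >= 1")
        if self.n_faces and self.face_areas().min() <= _DEGENERATE_AREA:
            raise MeshFormatError("degenerate (zero-area) face present")


# ---------------------------------------------------------------------- loading


def _scan_obj_dialect(obj_path: str) -> None:
    """Cheap pre-pass enforcing the supported OBJ dialect before parsing."""
    has_vt = False
    with open(obj_path, "r", errors="replace") as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "vt":
                has_vt = True
            elif tok[0] == "f":
                if len(tok) - 1 > 4:
                    raise MeshFormatError(
                        f"polygonal face with {len(tok) - 1} corners: only triangles "
                        "and quads are supported")
    if not has_vt:
        raise MeshFormatError(
            "no UV coordinates (vt records) in OBJ: scan unusable for sticker detection")


def load_textured_mesh(obj_path: str | os.PathLike, scale: float = 1.0) -> TexturedMesh:
    """Load an OBJ scan with MTL material and diffuse texture image.

    Parameters
    ----------
    obj_path
        Path to the ``.obj`` file.  The referenced MTL must name a readable
        JPEG or PNG diffuse map.
    scale
        Multiplier taking file units to cm (1.0 for cm scanners, 0.1 for mm).

    Quad faces are triangulated deterministically; faces with more than four
    corners are rejected.  Degenerate (zero-area) triangles are dropped.
    """
    obj_path = os.fspath(obj_path)
    if not os.path.isfile(obj_path):
        raise MeshFormatError(f"scan file not found: {obj_path}")
    _scan_obj_dialect(obj_path)
    try:
        tm = trimesh.load(obj_path, force="mesh", process=False, maintain_order=True)
        uv_vertex = getattr(getattr(tm, "visual", None), "uv", None)
        if uv_vertex is None:
            # quad-face OBJs lose their UVs under maintain_order; retry without
            tm = trimesh.load(obj_path, force="mesh", process=False)
            uv_vertex = getattr(getattr(tm, "visual", None), "uv", None)
    except Exception as exc:  # pragma: no cover - parser internals
        raise MeshFormatError(f"cannot parse OBJ: {exc}") from exc
    if uv_vertex is None:
        raise MeshFormatError("no UV coordinates in OBJ")
    material = getattr(tm.visual, "material", None)
    image = getattr(material, "image", None)
    if image is None:
        raise MeshFormatError(
            "no readable diffuse texture: OBJ must reference an MTL with map_Kd")
    texture = np.asarray(image.convert("RGB"), dtype=np.uint8)
    vertices = np.asarray(tm.vertices, dtype=np.float64) * float(scale)
    faces = np.asarray(tm.faces, dtype=np.int64)
    uv = np.asarray(uv_vertex, dtype=np.float64)[faces]
    mesh = TexturedMesh(vertices=vertices, faces=faces, uv=np.clip(uv, 0.0, 1.0),
                        texture=texture,
                        name=os.path.splitext(os.path.basename(obj_path))[0])
    mesh = _drop_degenerate(mesh)
    mesh.validate()
    return mesh


def _drop_degenerate(mesh: TexturedMesh) -> TexturedMesh:
    keep = mesh.face_areas() > _DEGENERATE_AREA
    if keep.all():
        return mesh
    return replace(mesh, faces=mesh.faces[keep], uv=mesh.uv[keep])


# ---------------------------------------------------------------------- saving


def save_textured_mesh(mesh: TexturedMesh, obj_path: str | os.PathLike) -> None:
    """Write OBJ + MTL + PNG texture so that a reload reproduces the mesh.

    Texture coordinates are written per vertex when all faces agree on a
    vertex's UV (the common case), otherwise one ``vt`` per face corner.
    """
    mesh.validate()
    obj_path = os.fspath(obj_path)
    stem = os.path.splitext(os.path.basename(obj_path))[0]
    directory = os.path.dirname(obj_path) or "."
    mtl_name = stem + ".mtl"
    tex_name = stem + "_tex.png"

    # check per-vertex UV consistency
    vert_uv = np.full((mesh.n_vertices, 2), np.nan)
    consistent = True
    flat_v = mesh.faces.ravel()
    flat_uv = mesh.uv.reshape(-1, 2)
    for vi, tc in zip(flat_v, flat_uv):
        if np.isnan(vert_uv[vi, 0]):
            vert_uv[vi] = tc
        elif not np.allclose(vert_uv[vi], tc, atol=1e-12):
            consistent = False
            break

    lines = [f"mtllib {mtl_name}", f"usemtl {stem}"]
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    if consistent:
        for tc in vert_uv:
            lines.append(f"vt {tc[0]:.9g} {tc[1]:.9g}")
        for f in mesh.faces:
            lines.append(f"f {f[0]+1}/{f[0]+1} {f[1]+1}/{f[1]+1} {f[2]+1}/{f[2]+1}")
    else:
        for tc in flat_uv:
            lines.append(f"vt {tc[0]:.9g} {tc[1]:.9g}")
        for i, f in enumerate(mesh.faces):
            c = 3 * i
            lines.append(f"f {f[0]+1}/{c+1} {f[1]+1}/{c+2} {f[2]+1}/{c+3}")

    try:
        with open(obj_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        with open(os.path.join(directory, mtl_name), "w") as fh:
            fh.write(f"newmtl {stem}\nKd 1 1 1\nmap_Kd {tex_name}\n")
        Image.fromarray(mesh.texture).save(os.path.join(directory, tex_name))
    except OSError as exc:
        raise MeshFormatError(f"cannot write mesh to {obj_path}: {exc}") from exc


# ---------------------------------------------------------------------- cropping


def crop_below_plane(mesh: TexturedMesh, plane: Plane, tol: float = 1e-9) -> TexturedMesh:
    """Keep the sub-mesh on the positive side of ``plane``.

    Faces crossing the plane are split exactly at the plane with linearly
    interpolated positions and texture coordinates.  Split vertices on a
    shared mesh edge are welded so surface connectivity survives the crop.
    """
    mesh.validate()
    d = plane.signed_distance(mesh.vertices)
    if np.all(d >= -tol):
        return replace(mesh, faces=mesh.faces.copy(), uv=mesh.uv.copy())
    if np.all(d < tol):
        raise CropError("empty crop: the plane removes every vertex")

    keep_v = d >= -tol
    new_index = np.full(mesh.n_vertices, -1, dtype=np.int64)
    new_index[keep_v] = np.arange(int(keep_v.sum()))
    new_vertices: list[np.ndarray] = [mesh.vertices[keep_v]]
    n_new = int(keep_v.sum())
    split_cache: dict[tuple[int, int], int] = {}

    def split_vertex(i: int, j: int) -> int:
        nonlocal n_new
        key = (i, j) if i < j else (j, i)
        if key not in split_cache:
            a, b = mesh.vertices[key[0]], mesh.vertices[key[1]]
            da, db = d[key[0]], d[key[1]]
            t = da / (da - db)
            new_vertices.append((a + t * (b - a))[None])
            split_cache[key] = n_new
            n_new += 1
        return split_cache[key]

    def split_uv(face: int, ci: int, cj: int) -> np.ndarray:
        vi, vj = mesh.faces[face, ci], mesh.faces[face, cj]
        t = d[vi] / (d[vi] - d[vj])
        return mesh.uv[face, ci] + t * (mesh.uv[face, cj] - mesh.uv[face, ci])

    out_faces: list[list[int]] = []
    out_uv: list[np.ndarray] = []
    face_inside = keep_v[mesh.faces]
    for fi in range(mesh.n_faces):
        inside = face_inside[fi]
        if inside.all():
            out_faces.append([new_index[v] for v in mesh.faces[fi]])
            out_uv.append(mesh.uv[fi])
            continue
        if not inside.any():
            continue
        # Sutherland-Hodgman clip of the triangle against the half-space
        poly_idx: list[int] = []
        poly_uv: list[np.ndarray] = []
        for c in range(3):
            cn = (c + 1) % 3
            vi, vj = mesh.faces[fi, c], mesh.faces[fi, cn]
            if inside[c]:
                poly_idx.append(new_index[vi])
                poly_uv.append(mesh.uv[fi, c])
            if inside[c] != inside[cn]:
                poly_idx.append(split_vertex(vi, vj))
                poly_uv.append(split_uv(fi, c, cn))
        for k in range(1, len(poly_idx) - 1):  # fan triangulation of the clipped polygon
            out_faces.append([poly_idx[0], poly_idx[k], poly_idx[k + 1]])
            out_uv.append(np.vstack([poly_uv[0], poly_uv[k], poly_uv[k + 1]]))

    if not out_faces:
        raise CropError("empty crop: no face survives the plane")
    cropped = TexturedMesh(
        vertices=np.vstack(new_vertices),
        faces=np.asarray(out_faces, dtype=np.int64),
        uv=np.clip(np.asarray(out_uv, dtype=np.float64), 0.0, 1.0),
        texture=mesh.texture,
        name=mesh.name,
    )
    cropped = _drop_degenerate(cropped)
    cropped = _drop_unreferenced(cropped)
    cropped.validate()
    return cropped


def _drop_unreferenced(mesh: TexturedMesh) -> TexturedMesh:
    used = np.unique(mesh.faces)
    if len(used) == mesh.n_vertices:
        return mesh
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return replace(mesh, vertices=mesh.vertices[used], faces=remap[mesh.faces])
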