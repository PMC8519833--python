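"""Synthetic textured torso scans with known ground truth.

Patient scans cannot be shipped, so validation runs on phantoms: a
frontal half-torso surface built as an elliptical trunk plus two
spherical-cap breast mounds, expressed as a height field z = f(x, y)
over the chest wall (x lateral, y cranial, z anterior, all cm).  Each
mound is a radial bump relative to the local trunk height, joined
through a softplus ramp of small width, which gives a smooth fillet
whose locus — an exact circle in the parameter plane — is the
inframammary fold.

The phantom knows where everything is:

* sticker landmarks sit at analytic positions (midline points on the
  sternal line; mound landmarks at fixed angles on the cap-trunk
  crease); the nearest mesh grid node is moved onto each landmark, so
  landmarks are exact mesh vertices at resolution-independent positions;
* the texture is skin-tone with one filled disc decal per sticker,
  centered at the ground-truth position, plus optional decals marking
  the inframammary fold termini;
* ground-truth measurement lengths are computed on the *smooth* analytic
  surface by a variational geodesic (path-length minimization in the
  parameter plane with analytic gradients), independent of the
  mesh-graph solver the pipeline uses, and follow exactly the endpoint
  definitions of the metrology module.

Asymmetry: ``asymmetry_factor`` scales the left cap radius by
``1 + factor`` (the apex height follows, as a fixed fraction of the
radius); zero gives a perfectly mirror-symmetric phantom in mesh,
texture and ground truth.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .errors import PhantomError
from .mesh_io import TexturedMesh
from .symmetry_stats import MEASUREMENT_NAMES, symmetry_index

#: breast-local crease angles (degrees from the lateral direction)
CREASE_ANGLES = {
    "MUBP": 120.0, "LUBP": 60.0, "LABP": 0.0, "LBP": 270.0,
    "IMF_MED": 210.0, "IMF_LAT": 330.0,
}

_SKIN_RGB = (222, 176, 150)

from .stickers import full_color_spec as _default_palette


def _default_sticker_colors() -> dict[str, tuple[int, int, int]]:
    return {label: tuple(spec["rgb"]) for label, spec in _default_palette().items()}


@dataclass
class PhantomConfig:
    """Geometry, texture and sticker parameters of a synthetic torso."""

    torso_width: float = 32.0      # cm, lateral extent of the cropped scan
    torso_height: float = 26.0     # cm, cranio-caudal extent (crop to clavicle)
    torso_depth: float = 12.0      # cm, anterior half-depth of the trunk
    breast_radius_left: float = 5.6    # cm, cap sphere radius
    breast_radius_right: float = 5.6
    breast_center_offset_left: tuple[float, float, float] = (0.0, 0.0, 0.0)
    breast_center_offset_right: tuple[float, float, float] = (0.0, 0.0, 0.0)
    protrusion_ratio: float = 0.61  # apex height as a fraction of cap radius
    asymmetry_factor: float = 0.0  # 0 = perfectly symmetric
    sticker_radius: float = 0.6    # cm
    sticker_colors: dict = field(default_factory=_default_sticker_colors)
    mesh_resolution: float = 0.6   # cm, target edge length
    texture_px_per_cm: float = 18.0
    blend_smoothness: float = 0.25  # cm, width of the cap-trunk fillet
    skin_noise_sigma: float = 4.0  # 8-bit channel units
    fold_stickers: bool = True     # draw IMF_MED / IMF_LAT terminus decals
    seed: int = 0

    def validate(self) -> None:
        for name in ("torso_width", "torso_height", "torso_depth",
                     "breast_radius_left", "breast_radius_right",
                     "protrusion_ratio", "sticker_radius", "mesh_resolution",
                     "texture_px_per_cm", "blend_smoothness"):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be positive")
        if self.protrusion_ratio >= 1.0:
            raise PhantomError("protrusion_ratio must be < 1 for a spherical cap")
        if self.asymmetry_factor < 0:
            raise PhantomError("asymmetry_factor must be >= 0")
        if self.mesh_resolution > 2.0 * self.sticker_radius:
            raise PhantomError(
                "resolution too coarse: stickers would be covered by fewer "
                "than 3 mesh faces")
        colors = sorted(self.sticker_colors.items())
        for i, (la, ca) in enumerate(colors):
            for lb, cb in colors[i + 1:]:
                dist = math.dist(ca, cb)
                if dist < 60.0:
                    raise PhantomError(
                        f"sticker colors {la} and {lb} are only {dist:.0f} RGB "
                        "units apart (need >= 60)")

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items()}
        payload["sticker_colors"] = {k: list(v) for k, v in self.sticker_colors.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PhantomConfig":
        with open(path) as fh:
            payload = json.load(fh)
        if "sticker_colors" in payload:
            payload["sticker_colors"] = {
                k: tuple(v) for k, v in payload["sticker_colors"].items()}
        for key in ("breast_center_offset_left", "breast_center_offset_right"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class PhantomGroundTruth:
    """What the generator knows: landmark positions, lengths, and the SI."""

    landmark_positions: dict[tuple[str, str], np.ndarray]
    aux_positions: dict[tuple[str, str], np.ndarray]
    measurement_lengths: dict[tuple[str, str], float]
    symmetry_index: float

    def side_lengths(self, side: str) -> dict[str, float]:
        return {name: self.measurement_lengths[(name, side)]
                for name in MEASUREMENT_NAMES}

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "landmark_positions": {f"{l}|{s}": list(map(float, p))
                                   for (l, s), p in self.landmark_positions.items()},
            "aux_positions": {f"{l}|{s}": list(map(float, p))
                              for (l, s), p in self.aux_positions.items()},
            "measurement_lengths": {f"{n}|{s}": float(v)
                                    for (n, s), v in self.measurement_lengths.items()},
            "symmetry_index": float(self.symmetry_index),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PhantomGroundTruth":
        with open(path) as fh:
            payload = json.load(fh)

        def unkey(d, cast):
            return {tuple(k.split("|")): cast(v) for k, v in d.items()}
        return cls(
            landmark_positions=unkey(payload["landmark_positions"], np.asarray),
            aux_positions=unkey(payload["aux_positions"], np.asarray),
            measurement_lengths=unkey(payload["measurement_lengths"], float),
            symmetry_index=float(payload["symmetry_index"]))


# ----------------------------------------------------------------- the surface


class _Mound:
    """One spherical-cap mound expressed as a radial bump over the trunk.

    The bump height above the local chest wall is
    ``sqrt(r^2 - d^2) - (r - p)`` (a spherical cap of radius ``r`` and
    apex height ``p``), which crosses zero at the crease radius
    ``rho = sqrt(r^2 - (r - p)^2)`` — an exact circle in the parameter
    plane regardless of how the trunk tilts underneath.  Beyond 0.98 r
    the profile continues with its tangent line so gradients stay
    bounded.
    """

    def __init__(self, center_xy: np.ndarray, r: float, p: float):
        self.c = np.asarray(center_xy, float)
        self.r = r
        self.p = p
        self.rho = math.sqrt(r * r - (r - p) ** 2)
        self.d_ext = 0.98 * r
        root_ext = math.sqrt(r * r - self.d_ext ** 2)
        self._b_ext = root_ext - (r - p)
        self._slope_ext = -self.d_ext / root_ext

    def bump_grad(self, x, y):
        """Bump height above the trunk and its gradient (vectorized)."""
        dx = x - self.c[0]
        dy = y - self.c[1]
        d = np.hypot(dx, dy)
        inside = d <= self.d_ext
        root = np.sqrt(np.maximum(self.r ** 2 - np.minimum(d, self.d_ext) ** 2, 1e-12))
        b = np.where(inside, root - (self.r - self.p),
                     self._b_ext + self._slope_ext * (d - self.d_ext))
        dbdd = np.where(inside, -d / root, self._slope_ext)
        safe = np.maximum(d, 1e-12)
        return b, dbdd * dx / safe, dbdd * dy / safe


class PhantomSurface:
    """Analytic height field of the phantom and its landmark layout."""

    def __init__(self, config: PhantomConfig):
        config.validate()
        self.config = config
        w, h = config.torso_width, config.torso_height
        self.x0, self.x1 = -w / 2, w / 2
        self.y0, self.y1 = -0.46 * h, 0.54 * h
        self.a = 0.625 * w
        self.b = 1.55 * h
        self.c = config.torso_depth
        self.k = config.blend_smoothness

        af = config.asymmetry_factor
        cx = 0.2375 * w
        cy = -0.0577 * h
        self.mounds: dict[str, _Mound] = {}
        self.lateral_sign = {"left": 1.0, "right": -1.0}
        for side in ("left", "right"):
            sgn = self.lateral_sign[side]
            off = np.asarray(getattr(config, f"breast_center_offset_{side}"), float)
            r = getattr(config, f"breast_radius_{side}")
            if side == "left":
                r *= 1.0 + af
            # apex height scales with the radius: a larger mound protrudes
            # proportionally farther (geometric similarity)
            p = config.protrusion_ratio * r + off[2]
            if not 0 < p < r:
                raise PhantomError(
                    f"protrusion {p:.2f} must lie in (0, radius) for a spherical "
                    f"cap of radius {r:.2f}")
            center = np.array([sgn * cx + off[0], cy + off[1]])
            self.mounds[side] = _Mound(center, r, p)
        # the mounds must stay clear of the midline and of each other
        for side, mound in self.mounds.items():
            clearance = abs(mound.c[0]) - mound.rho
            if clearance < 0.2:
                raise PhantomError(
                    f"{side} breast mound crosses the midline "
                    f"(clearance {clearance:.2f} cm)")

    # -------------------------------------------------------------- height field

    def _trunk_height(self, x, y):
        g = 1.0 - (np.asarray(x) / self.a) ** 2 - (np.asarray(y) / self.b) ** 2
        return self.c * np.sqrt(np.maximum(g, 0.02))

    def _trunk_height_grad(self, x, y):
        g = 1.0 - (x / self.a) ** 2 - (y / self.b) ** 2
        clamped = g <= 0.02
        root = np.sqrt(np.maximum(g, 0.02))
        z = self.c * root
        gx = np.where(clamped, 0.0, -self.c * x / (self.a ** 2 * root))
        gy = np.where(clamped, 0.0, -self.c * y / (self.b ** 2 * root))
        return z, gx, gy

    def height_and_grad(self, x, y):
        """f, df/dx, df/dy of the blended surface (vectorized).

        The mound bumps are joined to the trunk through a softplus ramp
        of width ``blend_smoothness``: where a bump is clearly positive
        the surface is trunk + bump, where clearly negative it is the
        bare trunk, with a C-infinity fillet at the crease in between.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        z, gx, gy = self._trunk_height_grad(x, y)
        z = np.array(z, dtype=float)
        gx = np.array(gx, dtype=float)
        gy = np.array(gy, dtype=float)
        k = self.k
        for mound in self.mounds.values():
            b, bx, by = mound.bump_grad(x, y)
            # softplus(b) = k*log(1 + exp(b/k)), computed stably
            t = b / k
            z = z + k * np.logaddexp(0.0, t)
            sig = 1.0 / (1.0 + np.exp(-np.clip(t, -500, 500)))
            gx = gx + sig * bx
            gy = gy + sig * by
        return z, gx, gy

    def height(self, x, y):
        return self.height_and_grad(x, y)[0]

    # ------------------------------------------------------------------ crease

    def crease_radius(self, side: str, angle_deg: float = 0.0) -> float:
        """Distance from the mound center to the inframammary crease.

        The crease — where the unsmoothed spherical-cap bump height
        crosses zero — is an exact circle in the parameter plane, so the
        radius is independent of the ray angle.
        """
        return self.mounds[side].rho

    # ------------------------------------------------------------ landmark layout

    def landmark_xy(self) -> dict[tuple[str, str], np.ndarray]:
        """Analytic parameter-plane positions of all sticker landmarks."""
        out: dict[tuple[str, str], np.ndarray] = {
            ("SN", "midline"): np.array([0.0, self.y1 - 1.0]),
            # xiphoid: on the midline a little below the inter-mammary line
            ("XI", "midline"): np.array([0.0, self.mounds["left"].c[1] - 2.5]),
        }
        for side, mound in self.mounds.items():
            sgn = self.lateral_sign[side]
            out[("N", side)] = mound.c.copy()
            out[("CP", side)] = np.array([mound.c[0] + sgn * 1.5, self.y1 - 3.6])
            for label, angle in CREASE_ANGLES.items():
                t = self.crease_radius(side, angle)
                th = math.radians(angle)
                out[(label, side)] = mound.c + t * np.array(
                    [sgn * math.cos(th), math.sin(th)])
        return out


# ------------------------------------------------------- variational geodesics


def smooth_geodesic(surface: PhantomSurface, p0, p1,
                    levels: tuple[int, ...] = (8, 16, 32),
                    iters: tuple[int, ...] = (250, 150, 120),
                    oversample: int = 1000) -> tuple[float, np.ndarray]:
    """Geodesic length on the analytic surface between two (x, y) points.

    Minimizes the 3D length of a polyline constrained to the surface over
    its interior parameter-plane points (L-BFGS-B with analytic
    gradients), coarse-to-fine over ``levels`` interior points starting
    from the straight chord.  The returned length is the arc length of
    the optimized path densely resampled on the surface — the polyline
    chord sum systematically undershoots the arc near the high-curvature
    crease fillet, so the raw objective value is never reported.
    Deterministic; independent of any mesh.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if np.allclose(p0, p1):
        z = float(surface.height(p0[0], p0[1]))
        return 0.0, np.array([[p0[0], p0[1], z]])
    def objective(flat: np.ndarray):
        xy = flat.reshape(-1, 2)
        full = np.concatenate([p0[None], xy, p1[None]])
        z, zx, zy = surface.height_and_grad(full[:, 0], full[:, 1])
        pts = np.column_stack([full, z])
        d = np.diff(pts, axis=0)
        seg = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
        u = d / seg[:, None]
        g3 = u[:-1] - u[1:]  # d(total)/d(r_i) for interior points
        gx = g3[:, 0] + g3[:, 2] * zx[1:-1]
        gy = g3[:, 1] + g3[:, 2] * zy[1:-1]
        return float(seg.sum()), np.column_stack([gx, gy]).ravel()

    def resample(xy: np.ndarray, count: int) -> np.ndarray:
        """Arclength-uniform resampling of the parameter-plane polyline."""
        full = np.concatenate([p0[None], xy, p1[None]])
        seg = np.linalg.norm(np.diff(full, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        s /= s[-1]
        t = np.linspace(0.0, 1.0, count + 2)[1:-1]
        return np.column_stack([np.interp(t, s, full[:, 0]),
                                np.interp(t, s, full[:, 1])])

    t0 = np.linspace(0.0, 1.0, levels[0] + 2)[1:-1, None]
    xy = p0 + t0 * (p1 - p0)
    for n, it in zip(levels, iters):
        if len(xy) != n:
            xy = resample(xy, n)
        res = minimize(objective, xy.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": it, "ftol": 1e-14, "gtol": 1e-9})
        xy = res.x.reshape(-1, 2)
    fine = np.concatenate([p0[None], resample(xy, oversample), p1[None]])
    z = surface.height(fine[:, 0], fine[:, 1])
    pts = np.column_stack([fine, z])
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return length, pts


# ------------------------------------------------------------------ generation


def _build_grid(surface: PhantomSurface, resolution: float):
    """Grid vertices and mirror-symmetric triangulation of the height field."""
    w = surface.x1 - surface.x0
    h = surface.y1 - surface.y0
    ncx = max(2, round(w / resolution))
    if ncx % 2:
        ncx += 1  # even cell count: a vertex column sits exactly on the midline
    ncy = max(2, round(h / resolution))
    xs = np.linspace(surface.x0, surface.x1, ncx + 1)
    ys = np.linspace(surface.y0, surface.y1, ncy + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = surface.height(X, Y)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vid = np.arange((ncx + 1) * (ncy + 1)).reshape(ncx + 1, ncy + 1)

    faces = []
    half = ncx // 2
    for i in range(ncx):
        for j in range(ncy):
            v00, v10 = vid[i, j], vid[i + 1, j]
            v01, v11 = vid[i, j + 1], vid[i + 1, j + 1]
            # diagonal choice mirrored about the midline so that the
            # triangulation of a symmetric phantom is exactly symmetric
            if i < half:
                diag = (i + j) % 2
            else:
                diag = 1 - ((ncx - 1 - i + j) % 2)
            if diag == 0:
                faces.append([v00, v10, v11])
                faces.append([v00, v11, v01])
            else:
                faces.append([v00, v10, v01])
                faces.append([v10, v11, v01])
    return xs, ys, vertices, np.asarray(faces, dtype=np.int64)


def _paint_texture(surface: PhantomSurface, decal_xy: dict, rng) -> np.ndarray:
    cfg = surface.config
    w_cm = surface.x1 - surface.x0
    h_cm = surface.y1 - surface.y0
    w_px = max(2, round(w_cm * cfg.texture_px_per_cm))
    h_px = max(2, round(h_cm * cfg.texture_px_per_cm))
    img = np.empty((h_px, w_px, 3), dtype=float)
    img[:] = _SKIN_RGB
    # cm coordinates of pixel centers (row 0 = top = y1)
    px_x = surface.x0 + (np.arange(w_px) + 0.5) / w_px * w_cm
    px_y = surface.y1 - (np.arange(h_px) + 0.5) / h_px * h_cm
    for (label, _side), (lx, ly) in decal_xy.items():
        color = surface.config.sticker_colors.get(label)
        if color is None:
            raise PhantomError(f"no sticker color configured for {label}")
        r = cfg.sticker_radius
        cols = np.nonzero(np.abs(px_x - lx) <= r)[0]
        rows = np.nonzero(np.abs(px_y - ly) <= r)[0]
        if len(cols) == 0 or len(rows) == 0:
            raise PhantomError(f"sticker {label} falls outside the texture")
        dx = px_x[cols] - lx
        dy = px_y[rows] - ly
        mask = dy[:, None] ** 2 + dx[None, :] ** 2 <= r * r
        block = img[np.ix_(rows, cols)]
        block[mask] = color
        img[np.ix_(rows, cols)] = block
    img += rng.normal(0.0, cfg.skin_noise_sigma, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_phantom(config: PhantomConfig | None = None,
                     ) -> tuple[TexturedMesh, PhantomGroundTruth]:
    """Generate one synthetic torso scan and its ground truth.

    Deterministic given ``config.seed``.  The returned mesh satisfies all
    scan invariants; ground-truth landmark positions lie exactly on its
    surface (they are mesh vertices), and measurement lengths are
    geodesics of the analytic surface between those same endpoints.
    """
    if config is None:
        config = PhantomConfig()
    surface = PhantomSurface(config)
    rng = np.random.default_rng(config.seed)
    xs, ys, vertices, faces = _build_grid(surface, config.mesh_resolution)

    analytic = surface.landmark_xy()
    # width medial endpoint: the on-surface midline point at nipple height
    for side in ("left", "right"):
        analytic[("WIDTH_MED", side)] = np.array(
            [0.0, analytic[("N", side)][1]])

    # move the nearest grid node onto each analytic landmark position so
    # that every landmark is an exact mesh vertex, independent of the
    # mesh resolution
    ny = len(ys)
    claimed: dict[int, tuple[float, float]] = {}
    for key in sorted(analytic):
        xy = analytic[key]
        i = int(np.clip(round((xy[0] - xs[0]) / (xs[1] - xs[0])), 1, len(xs) - 2))
        j = int(np.clip(round((xy[1] - ys[0]) / (ys[1] - ys[0])), 1, ny - 2))
        node = i * ny + j
        if node in claimed and not np.allclose(claimed[node], xy):
            raise PhantomError(
                f"landmarks {key} and another share the mesh node at "
                f"({xs[i]:.2f}, {ys[j]:.2f}): resolution too coarse")
        claimed[node] = (float(xy[0]), float(xy[1]))
        vertices[node] = (xy[0], xy[1], float(surface.height(xy[0], xy[1])))

    landmark_xy: dict[tuple[str, str], np.ndarray] = {}
    landmark_pos: dict[tuple[str, str], np.ndarray] = {}
    aux_xy: dict[tuple[str, str], np.ndarray] = {}
    aux_pos: dict[tuple[str, str], np.ndarray] = {}
    for key, xy in analytic.items():
        pos = np.array([xy[0], xy[1], float(surface.height(xy[0], xy[1]))])
        if key[0] in ("IMF_MED", "IMF_LAT", "WIDTH_MED"):
            aux_xy[key] = xy
            aux_pos[key] = pos
        else:
            landmark_xy[key] = xy
            landmark_pos[key] = pos

    # texture with decals at the ground-truth positions
    decals = dict(landmark_xy)
    if config.fold_stickers:
        decals.update({k: v for k, v in aux_xy.items() if k[0] != "WIDTH_MED"})
    texture = _paint_texture(surface, decals, rng)

    # per-vertex UV from the parameter plane
    w_cm = surface.x1 - surface.x0
    h_cm = surface.y1 - surface.y0
    uv_vertex = np.column_stack([(vertices[:, 0] - surface.x0) / w_cm,
                                 (vertices[:, 1] - surface.y0) / h_cm])
    mesh = TexturedMesh(vertices=vertices, faces=faces,
                        uv=np.clip(uv_vertex[faces], 0.0, 1.0), texture=texture,
                        name=f"phantom_seed{config.seed}")
    mesh.validate()

    truth = PhantomGroundTruth(
        landmark_positions=landmark_pos,
        aux_positions=aux_pos,
        measurement_lengths=_ground_truth_lengths(surface, landmark_xy, aux_xy),
        symmetry_index=0.0)
    truth.symmetry_index = symmetry_index(
        truth.side_lengths("left"), truth.side_lengths("right")).symmetry_index
    return mesh, truth


def _ground_truth_lengths(surface: PhantomSurface,
                          landmark_xy: dict, aux_xy: dict,
                          ) -> dict[tuple[str, str], float]:
    lengths: dict[tuple[str, str], float] = {}
    sn = landmark_xy[("SN", "midline")]
    xi = landmark_xy[("XI", "midline")]
    for side in ("left", "right"):
        n = landmark_xy[("N", side)]
        lbp = landmark_xy[("LBP", side)]
        labp = landmark_xy[("LABP", side)]
        ubp = _ubp_xy(surface, landmark_xy, side)
        med = aux_xy[("WIDTH_MED", side)]
        imf_m = aux_xy[("IMF_MED", side)]
        imf_l = aux_xy[("IMF_LAT", side)]
        g = lambda a, b: smooth_geodesic(surface, a, b)[0]
        lengths[("SN_N", side)] = g(sn, n)
        lengths[("LBP_N", side)] = g(lbp, n)
        lengths[("UBP_N", side)] = g(ubp, n)
        lengths[("XI_N", side)] = g(xi, n)
        lengths[("LABP_N", side)] = g(labp, n)
        lengths[("BREAST_WIDTH", side)] = g(med, n) + lengths[("LABP_N", side)]
        lengths[("IMF_LENGTH", side)] = g(imf_m, lbp) + g(lbp, imf_l)
    return lengths


def _nearest_on_surface_xy(surface: PhantomSurface, q: np.ndarray) -> np.ndarray:
    """Parameter coordinates of the surface point Euclidean-nearest to ``q``."""
    def objective(xy):
        z, zx, zy = surface.height_and_grad(xy[0], xy[1])
        d = np.array([xy[0] - q[0], xy[1] - q[1], float(z) - q[2]])
        grad = 2.0 * np.array([d[0] + d[2] * float(zx), d[1] + d[2] * float(zy)])
        return float(d @ d), grad
    res = minimize(objective, q[:2], jac=True, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-16, "gtol": 1e-12})
    return np.asarray(res.x)


def _ubp_xy(surface: PhantomSurface, landmark_xy: dict, side: str) -> np.ndarray:
    """Ground-truth UBP: MUBP-LUBP guideline meets the plane x = x_N.

    The intersection floats above the mound (the guideline is a chord),
    so it is snapped to the Euclidean-nearest surface point — the same
    definition the measurement pipeline uses.
    """
    def lift(xy):
        return np.array([xy[0], xy[1], float(surface.height(xy[0], xy[1]))])
    m = lift(landmark_xy[("MUBP", side)])
    l = lift(landmark_xy[("LUBP", side)])
    x_n = landmark_xy[("N", side)][0]
    denom = l[0] - m[0]
    if abs(denom) < 1e-9:
        raise PhantomError("degenerate UBP guideline in the phantom")
    t = (x_n - m[0]) / denom
    pt = m + t * (l - m)
    return _nearest_on_surface_xy(surface, pt)


def generate_cohort(n_patients: int,
                    base_config: PhantomConfig | None = None,
                    asymmetry_range: tuple[float, float] = (0.0, 0.3),
                    seed: int | None = None,
                    ) -> list[tuple[TexturedMesh, PhantomGroundTruth]]:
    """A reproducible cohort of phantoms with varying asymmetry.

    Asymmetry factors are drawn uniformly from ``asymmetry_range``; each
    phantom gets its own sub-seed.  Deterministic given ``seed`` (which
    defaults to ``base_config.seed``).
    """
    if n_patients < 1:
        raise PhantomError("n_patients must be >= 1")
    lo, hi = asymmetry_range
    if hi < lo:
        raise PhantomError("empty asymmetry range")
    if base_config is None:
        base_config = PhantomConfig()
    if seed is None:
        seed = base_config.seed
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_patients):
        af = float(rng.uniform(lo, hi))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        cfg = replace(base_config, asymmetry_factor=af, seed=sub_seed)
        cohort.append(generate_phantom(cfg))
    return cohort
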