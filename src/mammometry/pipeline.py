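"""The fully automatic measurement pipeline as one call.

Mirrors the interactive workflow: load a scan, detect the colored
stickers, label them anatomically, build the sagittal plane, derive the
upper breast poles, and measure both breasts.
"""

from __future__ import annotations

import logging
import time
from typing import Mapping

from .landmarks import LandmarkSet, compute_sagittal_plane, derive_ubp, label_landmarks
from .mesh_io import TexturedMesh
from .metrology import MeasurementTable, measure_scan
from .stickers import DEFAULT_STICKER_COLORS, FOLD_STICKER_COLORS, detect_stickers

log = logging.getLogger("mammometry")


def analyze_scan(mesh: TexturedMesh,
                 color_spec: Mapping[str, Mapping] | None = None,
                 fold_spec: Mapping[str, Mapping] | None = None,
                 scan_id: str | None = None,
                 mode: str = "geodesic",
                 steiner_per_edge: int = 3,
                 body_axes: str = "auto",
                 up_axis=(0.0, 1.0, 0.0),
                 subject_facing=(0.0, 0.0, 1.0),
                 flip_vertical: bool = False,
                 min_blob_px: int = 5,
                 ) -> tuple[LandmarkSet, MeasurementTable]:
    """Run sticker detection through measurement on one textured scan.

    Returns the labeled landmark set (including the derived UBPs and the
    sagittal plane) and the 14-record measurement table.  Stages are
    logged with timings and counts under the ``mammometry`` logger.
    """
    t0 = time.perf_counter()
    color_spec = dict(color_spec or DEFAULT_STICKER_COLORS)
    fold_spec = dict(fold_spec or FOLD_STICKER_COLORS)
    # one segmentation pass over the combined palette, split afterwards
    combined = detect_stickers(mesh, {**color_spec, **fold_spec},
                               min_blob_px=min_blob_px)
    detections = [d for d in combined if d.color_label in color_spec]
    aux = [d for d in combined if d.color_label in fold_spec]
    log.info("stickers: %d landmark + %d fold detections in %.2fs",
             len(detections), len(aux), time.perf_counter() - t0)

    t0 = time.perf_counter()
    lset = label_landmarks(detections, mesh=mesh, body_axes=body_axes,
                           up_axis=up_axis, subject_facing=subject_facing,
                           flip_vertical=flip_vertical, aux_detections=aux)
    compute_sagittal_plane(lset)
    for side in ("left", "right"):
        derive_ubp(mesh, lset, side)
    log.info("landmarks: %d labeled, plane + UBPs derived in %.2fs",
             len(lset.landmarks), time.perf_counter() - t0)

    t0 = time.perf_counter()
    table = measure_scan(mesh, lset, scan_id=scan_id, mode=mode,
                         steiner_per_edge=steiner_per_edge)
    log.info("metrology: %d measurements in %.2fs",
             len(table.records), time.perf_counter() - t0)
    return lset, table
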