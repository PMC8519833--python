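"""Anatomical labeling, sagittal plane, and the derived upper breast pole."""

import numpy as np
import pytest
import trimesh

from mammometry.errors import GeometryError, LabelingError
from mammometry.landmarks import (LandmarkSet, compute_sagittal_plane,
                                  derive_ubp, label_landmarks)
from mammometry.mesh_io import SurfacePoint
from mammometry.pipeline import analyze_scan
from mammometry.stickers import DEFAULT_STICKER_COLORS, StickerDetection, detect_stickers


def fake_detection(label, position):
    return StickerDetection(color_label=label,
                            surface_point=SurfacePoint(0, (1.0, 0.0, 0.0)),
                            pixel_count=10, mean_color=(0, 0, 0),
                            position_3d=np.asarray(position, dtype=float))


def synthetic_detections(flip_y=1.0):
    """A hand-laid-out torso in config axes (+y up, +z facing, left = +x)."""
    layout = {
        ("SN", 0): (0.0, 12.0, 9.0), ("XI", 0): (0.0, -4.0, 10.0),
        ("N", 1): (7.0, -1.0, 12.0), ("N", -1): (-7.0, -1.0, 12.0),
        ("LBP", 1): (7.0, -6.0, 10.0), ("LBP", -1): (-7.0, -6.0, 10.0),
        ("LABP", 1): (12.0, -1.0, 8.0), ("LABP", -1): (-12.0, -1.0, 8.0),
        ("MUBP", 1): (4.5, 3.0, 10.5), ("MUBP", -1): (-4.5, 3.0, 10.5),
        ("LUBP", 1): (9.5, 3.0, 10.5), ("LUBP", -1): (-9.5, 3.0, 10.5),
        ("CP", 1): (9.0, 10.0, 8.5), ("CP", -1): (-9.0, 10.0, 8.5),
    }
    return [fake_detection(label, (x, flip_y * y, z))
            for (label, _side), (x, y, z) in layout.items()]


class TestLabeling:
    def test_phantom_labels_match_ground_truth(self, asym_analyzed):
        mesh, truth, lset, _ = asym_analyzed
        for (label, side), gt_pos in truth.landmark_positions.items():
            lm = lset.get(label, side)
            assert lm is not None, f"{label}({side}) unlabeled"
            assert np.linalg.norm(lm.position - gt_pos) <= 0.3

    def test_config_axes_labeling(self):
        lset = label_landmarks(synthetic_detections(), body_axes="config")
        assert lset.get("N", "left").position[0] > 0
        assert lset.get("N", "right").position[0] < 0
        assert lset.get("SN", "midline").position[1] > \
            lset.get("XI", "midline").position[1]

    def test_upside_down_scan_with_flip_vertical(self):
        # single midline color class: members distinguished by height only
        relabeled = [fake_detection("MID", d.position_3d)
                     if d.color_label in ("SN", "XI") else d
                     for d in synthetic_detections(flip_y=-1.0)]
        lset = label_landmarks(relabeled, body_axes="config",
                               flip_vertical=True)
        # SN ends up at negative y: the flipped up-axis points to -y
        assert lset.get("SN", "midline").position[1] < \
            lset.get("XI", "midline").position[1]
        # sides are still consistent (one left, one right per pair)
        assert lset.get("N", "left") is not None
        assert lset.get("N", "right") is not None

    def test_missing_class_reported_by_name(self):
        dets = [d for d in synthetic_detections() if d.color_label != "LBP"]
        with pytest.raises(LabelingError, match="LBP"):
            label_landmarks(dets, body_axes="config")

    def test_pair_on_same_side_rejected(self):
        dets = []
        for d in synthetic_detections():
            if d.color_label == "CP" and d.position_3d[0] < 0:
                d = fake_detection("CP", d.position_3d * np.array([-1, 1, 1])
                                   + np.array([1.0, 0, 0]))
            dets.append(d)
        with pytest.raises(LabelingError, match="same side"):
            label_landmarks(dets, body_axes="config")


class TestSagittalPlane:
    def test_symmetric_phantom_plane_is_construction_mirror(
            self, sym_phantom_noiseless):
        mesh, _ = sym_phantom_noiseless
        detections = detect_stickers(mesh, DEFAULT_STICKER_COLORS)
        lset = label_landmarks(detections, mesh=mesh)
        plane = compute_sagittal_plane(lset)
        assert abs(abs(plane.normal[0]) - 1.0) <= 1e-6
        for key in (("SN", "midline"), ("XI", "midline")):
            d = plane.signed_distance(lset.landmarks[key].position[None])[0]
            assert abs(d) <= 1e-6

    def test_plane_contains_sn_and_xi_exactly(self, asym_analyzed):
        _, _, lset, _ = asym_analyzed
        plane = lset.sagittal_plane
        for key in (("SN", "midline"), ("XI", "midline")):
            d = plane.signed_distance(lset.landmarks[key].position[None])[0]
            assert abs(d) <= 1e-9

    def test_sides_fall_on_opposite_signs(self, asym_analyzed):
        _, _, lset, _ = asym_analyzed
        plane = lset.sagittal_plane
        signs = {"left": [], "right": []}
        for (label, side), lm in lset.landmarks.items():
            if side in signs:
                signs[side].append(
                    float(plane.signed_distance(lm.position[None])[0]))
        assert all(s < 0 for s in signs["left"]) != \
            all(s < 0 for s in signs["right"])
        assert len(set(np.sign(signs["left"]))) == 1
        assert len(set(np.sign(signs["right"]))) == 1

    def test_coincident_midline_points_rejected(self):
        lset = LandmarkSet()
        from mammometry.landmarks import Landmark
        p = SurfacePoint(0, (1.0, 0.0, 0.0))
        lset.add(Landmark("SN", "midline", p, np.zeros(3)))
        lset.add(Landmark("XI", "midline", p, np.zeros(3)))
        with pytest.raises(GeometryError, match="coincide"):
            compute_sagittal_plane(lset)

    def test_plane_equivariant_under_rigid_motion(self, sym_phantom):
        mesh, _ = sym_phantom
        t = trimesh.transformations.rotation_matrix(0.5, [0.2, 1, 0.4])
        t[:3, 3] = (3.0, 1.0, -6.0)
        moved = mesh.transformed(t)
        lset1 = label_landmarks(detect_stickers(mesh, DEFAULT_STICKER_COLORS),
                                mesh=mesh)
        lset2 = label_landmarks(detect_stickers(moved, DEFAULT_STICKER_COLORS),
                                mesh=moved)
        p1 = compute_sagittal_plane(lset1)
        p2 = compute_sagittal_plane(lset2)
        np.testing.assert_allclose(p2.point, p1.point @ t[:3, :3].T + t[:3, 3],
                                   atol=1e-8)
        np.testing.assert_allclose(p2.normal, p1.normal @ t[:3, :3].T,
                                   atol=1e-8)


class TestDeriveUBP:
    def test_symmetric_ubp_near_guideline_midpoint(self, sym_analyzed):
        mesh, truth, lset, _ = sym_analyzed
        for side in ("left", "right"):
            ubp = lset.get("UBP", side)
            assert ubp is not None and ubp.source == "derived"
            mid = 0.5 * (lset.get("MUBP", side).position
                         + lset.get("LUBP", side).position)
            # midpoint floats above the mound; UBP is its surface snap
            assert np.linalg.norm(ubp.position[:2] - mid[:2]) < 0.8

    def test_mirrored_ubps_on_symmetric_phantom(self, sym_analyzed):
        _, _, lset, _ = sym_analyzed
        left = lset.get("UBP", "left").position
        right = lset.get("UBP", "right").position
        mirror = right * np.array([-1.0, 1.0, 1.0])
        assert np.linalg.norm(left - mirror) < 0.2

    def test_guideline_parallel_to_plane_rejected(self, sym_analyzed):
        mesh, _, lset, _ = sym_analyzed
        from copy import deepcopy
        from mammometry.landmarks import Landmark
        broken = deepcopy(lset)
        m = broken.get("MUBP", "left")
        # move LUBP so the guideline runs exactly parallel to the sagittal
        # plane (direction orthogonal to the plane normal)
        n = broken.sagittal_plane.normal
        v = np.array([0.0, 2.0, 0.5])
        v -= (v @ n) * n
        broken.add(Landmark("LUBP", "left", m.point, m.position + v))
        broken.landmarks.pop(("UBP", "left"), None)
        with pytest.raises(GeometryError, match="parallel"):
            derive_ubp(mesh, broken, "left")

    def test_json_round_trip(self, tmp_path, sym_analyzed):
        _, _, lset, _ = sym_analyzed
        lset.to_json(tmp_path / "lm.json")
        back = LandmarkSet.from_json(tmp_path / "lm.json")
        assert set(back.landmarks) == set(lset.landmarks)
        assert set(back.aux) == set(lset.aux)
        np.testing.assert_allclose(back.sagittal_plane.normal,
                                   lset.sagittal_plane.normal)
        for key, lm in lset.landmarks.items():
            np.testing.assert_allclose(back.landmarks[key].position,
                                       lm.position)
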