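"""Phantom generator: determinism, symmetry, ground-truth validity."""

from dataclasses import replace

import numpy as np
import pytest

from mammometry.errors import PhantomError
from mammometry.geodesic import SurfaceGeodesics
from mammometry.mesh_io import SurfacePoint
from mammometry.phantom import (PhantomConfig, PhantomSurface, generate_cohort,
                                generate_phantom, smooth_geodesic)
from mammometry.symmetry_stats import MEASUREMENT_NAMES


class TestConfig:
    def test_negative_length_rejected(self):
        with pytest.raises(PhantomError, match="positive"):
            PhantomConfig(torso_width=-1).validate()

    def test_coarse_resolution_rejected(self):
        with pytest.raises(PhantomError, match="too coarse"):
            PhantomConfig(mesh_resolution=2.0, sticker_radius=0.6).validate()

    def test_clashing_sticker_colors_rejected(self):
        cfg = PhantomConfig()
        colors = dict(cfg.sticker_colors)
        colors["SN"] = tuple(np.array(colors["XI"]) + 5)
        with pytest.raises(PhantomError, match="RGB"):
            replace(cfg, sticker_colors=colors).validate()

    def test_midline_overlap_rejected(self):
        with pytest.raises(PhantomError, match="midline"):
            generate_phantom(PhantomConfig(breast_radius_left=14.0))

    def test_json_round_trip(self, tmp_path):
        cfg = PhantomConfig(seed=5, asymmetry_factor=0.2)
        cfg.to_json(tmp_path / "cfg.json")
        assert PhantomConfig.from_json(tmp_path / "cfg.json") == cfg


class TestGeneration:
    def test_deterministic_given_seed(self):
        cfg = PhantomConfig(seed=42, asymmetry_factor=0.1)
        mesh1, truth1 = generate_phantom(cfg)
        mesh2, truth2 = generate_phantom(cfg)
        np.testing.assert_array_equal(mesh1.vertices, mesh2.vertices)
        np.testing.assert_array_equal(mesh1.texture, mesh2.texture)
        assert truth1.measurement_lengths == truth2.measurement_lengths

    def test_landmarks_lie_on_mesh(self, sym_phantom):
        mesh, truth = sym_phantom
        for key, pos in truth.landmark_positions.items():
            d = np.linalg.norm(mesh.vertices - pos, axis=1).min()
            assert d < 1e-6, f"{key} is {d} cm off the mesh"

    def test_landmark_census(self, sym_phantom):
        _, truth = sym_phantom
        labels = sorted(truth.landmark_positions)
        midline = [k for k in labels if k[1] == "midline"]
        assert len(labels) == 14
        assert len(midline) == 2
        assert len(truth.measurement_lengths) == 14

    def test_symmetric_truth(self, sym_phantom):
        _, truth = sym_phantom
        for name in MEASUREMENT_NAMES:
            left = truth.measurement_lengths[(name, "left")]
            right = truth.measurement_lengths[(name, "right")]
            assert left == pytest.approx(right, abs=1e-6)
        assert truth.symmetry_index == pytest.approx(100.0, abs=1e-9)

    def test_symmetric_mesh_mirrors_onto_itself(self, sym_phantom):
        from scipy.spatial import cKDTree
        mesh, _ = sym_phantom
        mirrored = mesh.vertices * np.array([-1.0, 1.0, 1.0])
        dist, _ = cKDTree(mesh.vertices).query(mirrored)
        assert dist.max() < 1e-9

    def test_mirrored_config_mirrors_truth(self):
        cfg = PhantomConfig(seed=6, breast_radius_left=6.0,
                            breast_radius_right=5.2)
        mirrored = replace(cfg, breast_radius_left=5.2, breast_radius_right=6.0)
        _, truth = generate_phantom(cfg)
        _, truth_m = generate_phantom(mirrored)
        for name in MEASUREMENT_NAMES:
            assert truth.measurement_lengths[(name, "left")] == pytest.approx(
                truth_m.measurement_lengths[(name, "right")], abs=1e-6)

    def test_larger_left_radius_gives_longer_left_lengths(self):
        cfg = PhantomConfig(seed=8, breast_radius_left=5.6 * 1.3,
                            breast_radius_right=5.6)
        _, truth = generate_phantom(cfg)
        for name in ("SN_N", "LBP_N", "IMF_LENGTH"):
            assert truth.measurement_lengths[(name, "left")] > \
                truth.measurement_lengths[(name, "right")]

    def test_truth_invariant_under_mesh_refinement(self):
        # lengths come from the analytic surface; endpoints are fixed
        cfg = PhantomConfig(seed=9, asymmetry_factor=0.1)
        _, coarse = generate_phantom(cfg)
        _, fine = generate_phantom(replace(cfg, mesh_resolution=0.3))
        for key, v in coarse.measurement_lengths.items():
            assert fine.measurement_lengths[key] == pytest.approx(v, rel=0.005)


class TestOracleCrossCheck:
    def test_variational_matches_dense_mesh_dijkstra(self):
        """The smooth-surface oracle agrees with an independent dense-mesh
        graph geodesic (global search) to ~1%: same homotopy class, no
        gross under- or over-estimate."""
        cfg = PhantomConfig(seed=12, asymmetry_factor=0.15, mesh_resolution=0.3)
        surface = PhantomSurface(cfg)
        mesh, truth = generate_phantom(cfg)
        engine = SurfaceGeodesics(mesh, steiner_per_edge=4)

        def vertex_sp(pos):
            v = int(np.argmin(np.linalg.norm(mesh.vertices - pos, axis=1)))
            fi = int(np.nonzero((mesh.faces == v).any(axis=1))[0][0])
            corner = int(np.nonzero(mesh.faces[fi] == v)[0][0])
            bary = [0.0, 0.0, 0.0]
            bary[corner] = 1.0
            return SurfacePoint(fi, tuple(bary))

        for name in ("SN_N", "LBP_N", "XI_N", "LABP_N"):
            for side in ("left", "right"):
                a = vertex_sp(truth.landmark_positions[(name.split("_")[0],
                                                        "midline" if name in ("SN_N", "XI_N") else side)]
                              if name in ("SN_N", "XI_N")
                              else truth.landmark_positions[(name[:-2], side)])
                b = vertex_sp(truth.landmark_positions[("N", side)])
                mesh_len = engine.distance(a, b, with_path=False)[0]
                oracle_len = truth.measurement_lengths[(name, side)]
                assert mesh_len == pytest.approx(oracle_len, rel=0.012), \
                    f"{name}/{side}: mesh {mesh_len} vs oracle {oracle_len}"

    def test_smooth_geodesic_beats_chord(self):
        surface = PhantomSurface(PhantomConfig(seed=1))
        xy = surface.landmark_xy()
        a, b = xy[("SN", "midline")], xy[("N", "left")]
        length, path = smooth_geodesic(surface, a, b)
        chord = np.linalg.norm(path[-1] - path[0])
        assert length >= chord
        # path length equals the reported length
        assert np.linalg.norm(np.diff(path, axis=0), axis=1).sum() == \
            pytest.approx(length, rel=1e-12)


class TestCohort:
    def test_cohort_size_and_determinism(self):
        cfg = PhantomConfig(seed=0)
        cohort1 = generate_cohort(3, cfg, asymmetry_range=(0.0, 0.2), seed=5)
        cohort2 = generate_cohort(3, cfg, asymmetry_range=(0.0, 0.2), seed=5)
        assert len(cohort1) == 3
        for (m1, t1), (m2, t2) in zip(cohort1, cohort2):
            np.testing.assert_array_equal(m1.vertices, m2.vertices)
            assert t1.measurement_lengths == t2.measurement_lengths

    def test_zero_patients_rejected(self):
        with pytest.raises(PhantomError, match="n_patients"):
            generate_cohort(0, PhantomConfig())

    def test_empty_range_rejected(self):
        with pytest.raises(PhantomError, match="empty"):
            generate_cohort(2, PhantomConfig(), asymmetry_range=(0.3, 0.1))

    def test_truth_round_trip_json(self, tmp_path, sym_phantom):
        _, truth = sym_phantom
        truth.to_json(tmp_path / "truth.json")
        from mammometry.phantom import PhantomGroundTruth
        back = PhantomGroundTruth.from_json(tmp_path / "truth.json")
        assert back.symmetry_index == truth.symmetry_index
        for key, v in truth.measurement_lengths.items():
            assert back.measurement_lengths[key] == v
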