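"""Reconstruction of vertebral poses from biplanar landmarks."""

from __future__ import annotations

import numpy as np
import pytest

from spineload.geometry import (
    InconsistentProjectionError,
    ReconstructionError,
    angles_to_matrix,
    fit_vertebra,
    fuse_biplanar_point,
    matrix_to_angles,
    reconstruct_spine,
    SpineGeometry,
    VertebraPose,
)
from spineload.landmarks import Landmark2D, LandmarkSet, landmark_sets_from_frame
from spineload.synthetic import SpineRecipe, generate_spine, project_landmarks


def box_landmarks(center, dims, angles, include_pedicles=False, label="T5"):
    """Project an analytic box pose to its landmark set (the oracle)."""
    pose = VertebraPose(label=label, center=np.asarray(center, float), dims=dims, angles=angles)
    out = []
    for view, name, p in pose.canonical_points(include_pedicles=include_pedicles):
        u, v = (p[0], p[2]) if view == "coronal" else (p[0], p[1])
        out.append(Landmark2D(vertebra=label, view=view, name=name, u=float(u), v=float(v)))
    return out


class TestFuseBiplanarPoint:
    def test_identical_views_fuse_exactly(self):
        assert np.allclose(fuse_biplanar_point((100, 0), (100, 0)), [100, 0, 0])

    def test_craniocaudal_coordinate_is_averaged(self):
        fused = fuse_biplanar_point((100.2, 12), (99.8, -7))
        assert np.allclose(fused, [100.0, -7, 12])

    def test_disagreement_beyond_tolerance_raises(self):
        with pytest.raises(InconsistentProjectionError, match="T7"):
            fuse_biplanar_point((100, 0), (110, 0), label="T7")


class TestEulerConvention:
    @pytest.mark.parametrize("angles", [(0, 0, 0), (10, 5, 7), (-20, 15, -8), (29, -29, 29)])
    def test_angle_matrix_round_trip(self, angles):
        R = angles_to_matrix(*angles)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.isclose(np.linalg.det(R), 1.0)
        assert np.allclose(matrix_to_angles(R), angles, atol=1e-9)


class TestFitVertebra:
    def test_unrotated_box_recovered_exactly(self):
        pose = fit_vertebra(box_landmarks([0, 0, 0], (20, 40, 30), (0, 0, 0)))
        assert np.allclose(pose.center, 0, atol=1e-9)
        assert np.allclose(pose.dims, (20, 40, 30), atol=1e-9)
        assert np.allclose(pose.angles, 0, atol=1e-7)
        assert pose.residual_rms < 1e-9

    def test_rotated_box_angles_recovered_to_microdegrees(self):
        lms = box_landmarks([100, 3, -2], (20, 40, 30), (10, 5, 7))
        pose = fit_vertebra(lms)
        assert np.allclose(pose.angles, (10, 5, 7), atol=1e-4)
        assert np.allclose(pose.center, [100, 3, -2], atol=1e-6)

    def test_fit_invariant_to_landmark_order(self, rng):
        lms = box_landmarks([50, -4, 6], (22, 38, 28), (-8, 12, 5))
        shuffled = list(lms)
        rng.shuffle(shuffled)
        a = fit_vertebra(lms)
        b = fit_vertebra(shuffled)
        assert np.allclose(a.angles, b.angles, atol=1e-9)
        assert np.allclose(a.center, b.center, atol=1e-9)

    def test_endplate_area_scales_quadratically(self):
        small = fit_vertebra(box_landmarks([0, 0, 0], (20, 40, 30), (3, 2, 1)))
        big = fit_vertebra(box_landmarks([0, 0, 0], (40, 80, 60), (3, 2, 1)))
        assert np.isclose(big.endplate_area_sup, 4 * small.endplate_area_sup, rtol=1e-9)

    def test_missing_landmarks_raise(self):
        lms = box_landmarks([0, 0, 0], (20, 40, 30), (0, 0, 0))[:-1]
        with pytest.raises(ReconstructionError, match="missing"):
            fit_vertebra(lms)

    def test_noisy_fit_warns_about_poor_residual(self, rng):
        lms = box_landmarks([0, 0, 0], (20, 40, 30), (0, 0, 0))
        noisy = [
            Landmark2D(l.vertebra, l.view, l.name, l.u + rng.normal(0, 6), l.v + rng.normal(0, 6))
            for l in lms
        ]
        with pytest.warns(UserWarning, match="residual"):
            fit_vertebra(noisy, residual_threshold_mm=3.0)


class TestReconstructSpine:
    def test_full_synthetic_set_reconstructs_18_vertebrae(self, physiological_spine):
        ls = project_landmarks(physiological_spine)
        geo = reconstruct_spine(ls)
        assert geo.labels() == [v.label for v in physiological_spine.vertebrae]
        assert len(geo.vertebrae) == 18

    def test_missing_vertebra_names_the_gap(self, physiological_spine):
        ls = project_landmarks(physiological_spine)
        pruned = LandmarkSet(
            subject_id=ls.subject_id,
            landmarks=[l for l in ls.landmarks if l.vertebra != "T7"],
        )
        with pytest.raises(Exception, match="T7"):
            reconstruct_spine(pruned)

    def test_noiseless_round_trip_recovers_poses(self, physiological_spine):
        ls = project_landmarks(physiological_spine, noise_sigma_mm=0.0)
        geo = reconstruct_spine(ls)
        for truth, got in zip(physiological_spine.vertebrae, geo.vertebrae):
            assert np.linalg.norm(truth.center - got.center) < 1e-6
            assert np.allclose(truth.angles, got.angles, atol=1e-4)

    def test_geometry_json_round_trip(self, physiological_spine, tmp_path):
        path = tmp_path / "geo.json"
        physiological_spine.to_json(path)
        back = SpineGeometry.from_json(path)
        for a, b in zip(physiological_spine.vertebrae, back.vertebrae):
            assert np.allclose(a.center, b.center)
            assert np.allclose(a.angles, b.angles)


def test_landmark_csv_round_trip(physiological_spine, tmp_path):
    ls = project_landmarks(physiological_spine, include_pedicles=True)
    path = tmp_path / "lm.csv"
    ls.to_csv(path)
    import pandas as pd

    back = landmark_sets_from_frame(pd.read_csv(path))[0]
    assert len(back.landmarks) == len(ls.landmarks)
    back.validate()
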