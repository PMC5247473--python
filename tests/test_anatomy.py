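"""Anatomical indexes and scoliotic-curve detection."""

from __future__ import annotations

import numpy as np
import pytest

from spineload.anatomy import (
    ScolioticCurve,
    compute_parameters,
    coronal_tilt,
    detect_curves,
)
from spineload.geometry import SpineGeometry, VertebraPose
from spineload.landmarks import VERTEBRA_LABELS
from spineload.synthetic import (
    DEFAULT_DIMS_MM,
    SpineRecipe,
    generate_hips,
    generate_spine,
)


def spine_with_coronal_tilts(tilts: dict[str, float]) -> SpineGeometry:
    """Stack a vertical spine with prescribed per-vertebra coronal tilts."""
    vertebrae = []
    x = 500.0
    for lab in VERTEBRA_LABELS:
        dims = DEFAULT_DIMS_MM[lab]
        vertebrae.append(
            VertebraPose(label=lab, center=[x, 0.0, 0.0], dims=dims,
                         angles=(tilts.get(lab, 0.0), 0.0, 0.0))
        )
        x -= dims[0] + 5.0
    return SpineGeometry(subject_id="tilted", vertebrae=vertebrae)


def mirror_sagittal(g: SpineGeometry) -> SpineGeometry:
    """Mirror a geometry through the sagittal plane (z -> -z)."""
    out = []
    for v in g.vertebrae:
        cor, lat, ax = v.angles
        out.append(
            VertebraPose(label=v.label, center=v.center * np.array([1, 1, -1]),
                         dims=v.dims, angles=(-cor, lat, -ax))
        )
    return SpineGeometry(subject_id=g.subject_id, vertebrae=out)


class TestDetectCurves:
    def test_straight_spine_has_no_curves(self, straight_spine):
        assert detect_curves(straight_spine) == []

    def test_constructed_end_plate_tilts_give_cobb_20(self):
        # +10 at the upper end vertebra, -10 at the lower end, smooth in
        # between: a single curve with CA = 20 measured from those plates.
        tilts = {"T5": 6.0, "T6": 10.0, "T7": 5.0, "T8": 2.0,
                 "T9": -2.0, "T10": -5.0, "T11": -10.0, "T12": -6.0}
        curves = detect_curves(spine_with_coronal_tilts(tilts))
        assert len(curves) == 1
        c = curves[0]
        assert (c.upper_end, c.lower_end) == ("T6", "T11")
        assert c.cobb_deg == pytest.approx(20.0, abs=0.5)

    def test_cobb_below_threshold_is_not_scoliotic(self):
        g = generate_spine(SpineRecipe(cobb_deg=4.0, apex_level="T9"))
        assert detect_curves(g) == []

    def test_generator_closed_loop_recovers_cobb(self):
        g = generate_spine(SpineRecipe(cobb_deg=20.0, apex_level="T9"))
        curves = detect_curves(g)
        assert len(curves) == 1
        assert curves[0].cobb_deg == pytest.approx(20.0, abs=1.0)
        assert curves[0].apex in ("T8", "T9", "T10")

    def test_raising_min_cobb_never_increases_curve_count(self):
        g = generate_spine(SpineRecipe(cobb_deg=15.0, apex_level="T9"))
        counts = [len(detect_curves(g, min_cobb=m)) for m in (0.0, 5.0, 10.0, 20.0)]
        assert counts == sorted(counts, reverse=True)

    def test_curves_are_ordered_and_non_overlapping(self):
        # two opposite bumps -> a double-curve pattern
        tilts = {"T4": 8.0, "T5": 10.0, "T6": 4.0, "T7": -4.0, "T8": -10.0,
                 "T9": -4.0, "T10": 4.0, "T11": 10.0, "T12": 8.0, "L1": -2.0}
        curves = detect_curves(spine_with_coronal_tilts(tilts), min_cobb=0.0)
        assert len(curves) >= 2
        for a, b in zip(curves, curves[1:]):
            ia = VERTEBRA_LABELS.index(a.lower_end)
            ib = VERTEBRA_LABELS.index(b.upper_end)
            assert ia <= ib  # consecutive curves may share an end vertebra

    def test_curve_invariants_validated(self):
        with pytest.raises(ValueError):
            ScolioticCurve(upper_end="T9", lower_end="T5", apex="T7", cobb_deg=10, side="left")
        with pytest.raises(ValueError):
            ScolioticCurve(upper_end="T5", lower_end="T9", apex="T7", cobb_deg=-1, side="left")


class TestComputeParameters:
    def test_straight_vertical_spine_all_zero(self, straight_spine):
        p = compute_parameters(straight_spine)
        assert p.SS == pytest.approx(0.0, abs=1e-9)
        assert p.LL == pytest.approx(0.0, abs=1e-9)
        assert p.TK == pytest.approx(0.0, abs=1e-9)
        assert p.MAR == pytest.approx(0.0, abs=1e-9)
        assert p.curves == []

    def test_constructed_sagittal_profile_recovered(self):
        g = generate_spine(SpineRecipe(lordosis_deg=40.0, kyphosis_deg=35.0, cobb_deg=0.0))
        p = compute_parameters(g)
        assert p.LL == pytest.approx(40.0, abs=0.5)
        assert p.TK == pytest.approx(35.0, abs=0.5)

    def test_mar_keeps_sign_of_extreme_axial_rotation(self, straight_spine):
        vs = []
        for v in straight_spine.vertebrae:
            ax = -8.0 if v.label == "L2" else (3.0 if v.label == "T8" else 0.0)
            vs.append(VertebraPose(v.label, v.center, v.dims, (0.0, 0.0, ax)))
        p = compute_parameters(SpineGeometry(subject_id="s", vertebrae=vs))
        assert p.MAR == pytest.approx(-8.0, abs=1e-9)

    def test_pelvic_incidence_equals_slope_plus_tilt(self):
        r = SpineRecipe(sacral_slope_deg=40.0, pelvic_tilt_deg=12.0)
        g = generate_spine(r)
        p = compute_parameters(g, hips=generate_hips(r, g))
        assert p.PI == pytest.approx(52.0, abs=1e-6)
        assert p.SS == pytest.approx(40.0, abs=1e-9)

    def test_pi_absent_without_hips(self, physiological_spine):
        p = compute_parameters(physiological_spine)
        assert p.PI is None

    @pytest.mark.parametrize(
        "ss,expected", [(30.0, (1, 2)), (40.0, (3,)), (50.0, (4,))]
    )
    def test_roussouly_bands(self, ss, expected):
        g = generate_spine(SpineRecipe(sacral_slope_deg=ss, pelvic_tilt_deg=10.0))
        p = compute_parameters(g)
        assert p.RT in expected
        assert p.rt_automatic

    def test_angles_invariant_under_rigid_translation(self, physiological_spine):
        shifted = SpineGeometry(
            subject_id="shifted",
            vertebrae=[
                VertebraPose(v.label, v.center + np.array([11.0, -7.0, 3.0]), v.dims, v.angles)
                for v in physiological_spine.vertebrae
            ],
        )
        a = compute_parameters(physiological_spine)
        b = compute_parameters(shifted)
        assert a.SS == pytest.approx(b.SS)
        assert a.LL == pytest.approx(b.LL)
        assert a.TK == pytest.approx(b.TK)
        assert a.CA == pytest.approx(b.CA)

    def test_sagittal_mirror_flips_mar_but_not_cobb(self, physiological_spine):
        a = compute_parameters(physiological_spine)
        b = compute_parameters(mirror_sagittal(physiological_spine))
        assert b.MAR == pytest.approx(-a.MAR)
        assert b.CA == pytest.approx(a.CA, abs=1e-9)
        assert b.primary_curve.side != a.primary_curve.side
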