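"""Load post-processing: pressures, normalization, curve loads, statistics."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from spineload.analysis import (
    CohortSubject,
    UndefinedCorrelationError,
    cohort_analysis,
    correlate,
    disk_pressure,
    extract_curve_loads,
    normalize_loads,
)
from spineload.anatomy import ScolioticCurve
from spineload.solver import LoadSolution


def make_solution(forces: dict[str, tuple], converged=True) -> LoadSolution:
    fg = {k: np.asarray(v, dtype=float) for k, v in forces.items()}
    return LoadSolution(
        subject_id="s",
        muscle_forces={},
        joint_forces_global=fg,
        joint_forces_local={k: v.copy() for k, v in fg.items()},
        fdk_displacements={},
        residual_max=0.0,
        converged=converged,
    )


class TestDiskPressure:
    def test_kilonewton_over_ten_cm2(self):
        assert disk_pressure(1000.0, 10.0) == pytest.approx(1.54)

    def test_zero_force_zero_pressure(self):
        assert disk_pressure(0.0, 8.0) == 0.0

    def test_linearity_in_force(self):
        assert disk_pressure(900.0, 7.0) == pytest.approx(2 * disk_pressure(450.0, 7.0))

    def test_round_trip_recovers_force(self):
        F, A = 613.0, 11.8
        assert disk_pressure(F, A) * (A * 1e-4) * 1e6 / 1.54 == pytest.approx(F)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            disk_pressure(100.0, 0.0)


class TestNormalizeLoads:
    def test_weight_force_normalizes_to_one(self):
        sol = make_solution({"L4L5": (461.07, 0, 0)})
        norm = normalize_loads(sol, mass_kg=47.0, g=9.81)
        assert norm[0].F_global[0] == pytest.approx(1.0, abs=1e-4)

    def test_round_trip_identity(self):
        sol = make_solution({"L4L5": (-350.0, 40.0, -9.0)})
        norm = normalize_loads(sol, mass_kg=52.0)
        back = norm[0].F_global * 52.0 * 9.81
        assert np.allclose(back, sol.joint_forces_global["L4L5"], rtol=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            normalize_loads(make_solution({"L4L5": (1, 0, 0)}), mass_kg=0.0)


class TestCurveLoads:
    def test_single_joint_curve_apex_equals_max(self):
        sol = make_solution({"T8T9": (-100.0, 5.0, -3.0)})
        curve = ScolioticCurve("T8", "T9", "T8", 8.0, "left")
        cl = extract_curve_loads(sol, curve)
        assert np.allclose(cl.F_A, cl.F_M)
        assert cl.apex_joint == "T8T9"

    def test_componentwise_sign_preserving_extreme(self):
        sol = make_solution({
            "T6T7": (-10.0, 1.0, -3.0),
            "T7T8": (-20.0, -6.0, 5.0),
            "T8T9": (-15.0, 2.0, -7.0),
        })
        curve = ScolioticCurve("T6", "T9", "T7", 12.0, "left")
        cl = extract_curve_loads(sol, curve)
        assert cl.F_M[0] == -20.0
        assert cl.F_M[1] == -6.0
        assert cl.F_M[2] == -7.0

    def test_curve_outside_solved_range_raises(self):
        sol = make_solution({"T6T7": (0, 0, 0)})
        curve = ScolioticCurve("T6", "T10", "T8", 12.0, "left")
        with pytest.raises(ValueError):
            extract_curve_loads(sol, curve)


class TestCorrelate:
    def test_perfect_linear_relation(self, rng):
        x = rng.normal(0.0, 1.0, 24)
        res = correlate(x, 2 * x + 1, seed=0)
        assert res.coefficient == pytest.approx(1.0)
        assert res.significant

    def test_constant_variable_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate([1.0, 2.0, 3.0, 4.0, 5.0], [2.0] * 5)

    def test_pearson_invariant_to_positive_affine_rescaling(self, rng):
        x = rng.normal(0.0, 1.0, 30)
        y = x + rng.normal(0.0, 0.4, 30)
        a = correlate(x, y, seed=0)
        b = correlate(3.5 * x + 10.0, 0.2 * y - 4.0, seed=0)
        assert a.coefficient == pytest.approx(b.coefficient, abs=1e-12)

    def test_spearman_invariant_to_monotone_transform(self, rng):
        x = rng.uniform(0.5, 3.0, 20)
        z = rng.normal(0.0, 1.0, 20)
        y = np.exp(z**2) + x  # heavily skewed, and log(y) is still non-normal
        a = correlate(x, y, seed=5)
        b = correlate(x, np.log(y), seed=5)
        assert a.method == b.method == "spearman"
        assert a.coefficient == pytest.approx(b.coefficient, abs=1e-12)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        # n = 6: the Monte-Carlo permutation p must agree with the exact
        # enumeration over all 6! orderings within Monte-Carlo error.
        from spineload.analysis import _spearman_permutation_p

        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.1, 1.0, 3.4, 2.9, 6.0, 5.5])
        rho = float(stats.spearmanr(x, y).statistic)
        p_exact = _spearman_permutation_p(x, y, rho, seed=0, n_perm=0, exact=True)
        p_mc = _spearman_permutation_p(x, y, rho, seed=0, n_perm=20000, exact=False)
        se = np.sqrt(p_exact * (1 - p_exact) / 20000)
        assert abs(p_mc - p_exact) < max(4 * se, 0.01)

    def test_seeded_permutation_is_reproducible(self, rng):
        x = rng.uniform(0, 1, 12)
        y = rng.exponential(1.0, 12)
        a = correlate(x, y, seed=42, exact=False)
        b = correlate(x, y, seed=42, exact=False)
        assert a.p_value == b.p_value


class TestCohortAnalysis:
    @staticmethod
    def synth_cohort(n, with_curves=True, n_diverge=0, rng=None):
        rng = rng or np.random.default_rng(0)
        from spineload.anatomy import AnatomicalParameters

        out = []
        for i in range(n):
            ss = float(rng.uniform(25, 55))
            forces = {
                j: (float(-300 - rng.normal(0, 30)), float(-ss + rng.normal(0, 6)), 0.0)
                for j in ("L4L5", "L5S1", "T8T9", "T7T8", "T9T10")
            }
            curve = (
                ScolioticCurve("T7", "T10", "T8", float(rng.uniform(6, 24)), "left")
                if with_curves and i % 4 != 0
                else None
            )
            anatomy = AnatomicalParameters(
                subject_id=f"s{i}", curves=[curve] if curve else [],
                primary_curve=curve, SS=ss, PI=ss + 12.0, LL=ss + 5.0,
                TK=float(rng.uniform(20, 50)), MAR=float(rng.normal(0, 5)),
                RT=int(1 + (ss > 35) + (ss > 45)),
            )
            sol = make_solution(forces, converged=(i >= n_diverge))
            out.append(CohortSubject(anatomy=anatomy, solution=sol, mass_kg=47.0))
        return out

    def test_nonconverged_subjects_are_excluded(self):
        cohort = self.synth_cohort(38, n_diverge=1)
        tables = cohort_analysis(cohort, seed=1)
        assert tables["meta"]["n_converged"].iloc[0] == 37
        assert (tables["lumbosacral"]["n"] == 37).all()

    def test_curve_tables_drop_subjects_without_curves(self):
        cohort = self.synth_cohort(38, n_diverge=1)
        tables = cohort_analysis(cohort, seed=1)
        n_curved = tables["meta"]["n_with_curve"].iloc[0]
        assert n_curved < 37
        assert (tables["apical"]["n"] == n_curved).all()

    def test_constructed_ss_shear_coupling_is_detected(self):
        tables = cohort_analysis(self.synth_cohort(38), seed=1)
        row = tables["lumbosacral"].query("parameter == 'SS' and load == 'Fy_L5S1'").iloc[0]
        assert row.coefficient < 0
        assert row.significant

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError):
            cohort_analysis(self.synth_cohort(3), seed=1)
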