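"""Post-processing of load solutions: normalization, curve loads,
disc pressures and load–anatomy correlations.

Intersegmental forces are normalized by the subject's weight force
(m·g), making them dimensionless and comparable across subjects.  For a
scoliotic curve, the apical load F^A is the force at the joint caudal to
the apex vertebra and F^M collects, componentwise, the value of largest
absolute magnitude among the in-curve joints with its sign preserved
(so an extreme lateral shear keeps its direction).

Disc pressure at a level is the axial intersegmental load over the
superior end-plate area of the caudal vertebra, multiplied by 1.54 —
the empirical ratio of nucleus pressure to average end-plate pressure.

Correlations follow the usual small-cohort practice: Pearson's r with a
two-tailed t-test when both variables pass a Shapiro–Wilk normality
check (α = 0.05), otherwise Spearman's rank coefficient with a seeded
permutation test (exhaustive enumeration when n ≤ 7, 10 000 permutations
otherwise).  No multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anatomy import AnatomicalParameters, ScolioticCurve
from .landmarks import VERTEBRA_INDEX, VERTEBRA_LABELS
from .solver import LoadSolution

__all__ = [
    "NormalizedLoad",
    "CurveLoads",
    "CorrelationResult",
    "disk_pressure",
    "normalize_loads",
    "extract_curve_loads",
    "correlate",
    "cohort_analysis",
    "UndefinedCorrelationError",
]

G_DEFAULT = 9.81
PRESSURE_CORRECTION = 1.54  # nucleus vs average end-plate pressure


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested for a zero-variance variable."""


@dataclass(frozen=True)
class NormalizedLoad:
    """One joint's force divided by the subject weight force (dimensionless)."""

    joint: str
    F_global: np.ndarray
    F_local: np.ndarray


@dataclass(frozen=True)
class CurveLoads:
    """Apical (F_A) and componentwise extreme (F_M) loads of one curve."""

    curve: ScolioticCurve
    apex_joint: str
    F_A: np.ndarray
    F_M: np.ndarray
    in_curve_joints: tuple[str, ...]


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    coefficient: float
    method: str  # "pearson" | "spearman"
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.coefficient <= 1.0 + 1e-12:
            raise ValueError("correlation coefficient outside [-1, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


# ---------------------------------------------------------------------------
# Pressures and normalization
# ---------------------------------------------------------------------------

def disk_pressure(F_axial_N: float, area_cm2: float) -> float:
    """Nucleus disc pressure (MPa) from axial load (N) and end-plate area (cm²).

    The raw average pressure F/A is corrected by the factor 1.54 relating
    nucleus pressure to mean end-plate pressure.
    """
    if area_cm2 <= 0:
        raise ValueError(f"end-plate area must be positive, got {area_cm2}")
    area_m2 = area_cm2 * 1e-4
    return PRESSURE_CORRECTION * F_axial_N / area_m2 / 1e6


def normalize_loads(sol: LoadSolution, mass_kg: float, g: float = G_DEFAULT) -> list[NormalizedLoad]:
    """Divide every joint-force component by the subject weight force m·g."""
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    w = mass_kg * g
    return [
        NormalizedLoad(
            joint=name,
            F_global=sol.joint_forces_global[name] / w,
            F_local=sol.joint_forces_local[name] / w,
        )
        for name in sol.joint_forces_global
    ]


# ---------------------------------------------------------------------------
# Curve loads
# ---------------------------------------------------------------------------

def _curve_joints(curve: ScolioticCurve) -> list[str]:
    iu, il = VERTEBRA_INDEX[curve.upper_end], VERTEBRA_INDEX[curve.lower_end]
    return [VERTEBRA_LABELS[i] + VERTEBRA_LABELS[i + 1] for i in range(iu, il)]


def extract_curve_loads(
    sol: LoadSolution | dict[str, np.ndarray],
    curve: ScolioticCurve,
) -> CurveLoads:
    """Apical and componentwise-extreme loads along one scoliotic curve.

    ``sol`` may be a LoadSolution (its global joint forces are used) or a
    mapping joint name → 3-vector (e.g. already-normalized loads).
    F_A is the force at the joint caudal to the apex vertebra; F_M takes,
    per component, the in-curve value of largest magnitude with its sign.
    """
    forces = sol.joint_forces_global if isinstance(sol, LoadSolution) else sol
    ia = VERTEBRA_INDEX[curve.apex]
    if ia >= len(VERTEBRA_LABELS) - 1:
        raise ValueError(f"apex {curve.apex} has no caudal joint")
    apex_joint = VERTEBRA_LABELS[ia] + VERTEBRA_LABELS[ia + 1]
    joints = _curve_joints(curve)
    missing = [j for j in joints if j not in forces]
    if apex_joint not in forces or missing:
        raise ValueError(
            f"curve joints outside the solved range: {', '.join([apex_joint] * (apex_joint not in forces) + missing)}"
        )
    stack = np.array([np.asarray(forces[j], dtype=float) for j in joints])
    idx = np.argmax(np.abs(stack), axis=0)
    F_M = stack[idx, np.arange(3)]
    return CurveLoads(
        curve=curve,
        apex_joint=apex_joint,
        F_A=np.asarray(forces[apex_joint], dtype=float).copy(),
        F_M=F_M,
        in_curve_joints=tuple(joints),
    )


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def _spearman_permutation_p(
    x: np.ndarray, y: np.ndarray, rho: float, seed: int | None, n_perm: int, exact: bool | None
) -> float:
    """Two-sided permutation p-value for Spearman's rho.

    Exhaustive over all n! orderings when n ≤ 7 (or ``exact=True``),
    otherwise a seeded Monte-Carlo sample of ``n_perm`` permutations with
    the add-one correction.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def rho_of(perm_ry: np.ndarray) -> float:
        return float(np.corrcoef(rx, perm_ry)[0, 1])

    target = abs(rho) - 1e-12
    if exact is None:
        exact = n <= 7
    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(rho_of(ry[list(perm)])) >= target:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if abs(rho_of(rng.permutation(ry))) >= target:
            count += 1
    return (count + 1) / (n_perm + 1)


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    seed: int | None = None,
    names: tuple[str, str] = ("x", "y"),
    n_perm: int = 10_000,
    exact: bool | None = None,
) -> CorrelationResult:
    """Correlate two variables, choosing the method from normality.

    Pearson + two-tailed t-test when both variables pass Shapiro–Wilk at
    α = 0.05; otherwise Spearman + seeded permutation test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("correlate needs two equal-length 1-d samples of n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("correlate requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in {names[0] if np.ptp(x) == 0 else names[1]}"
        )
    normal = (
        stats.shapiro(x).pvalue > 0.05 and stats.shapiro(y).pvalue > 0.05
    )
    if normal:
        r = stats.pearsonr(x, y)
        return CorrelationResult(
            pair=names, coefficient=float(np.clip(r.statistic, -1, 1)),
            method="pearson", p_value=float(r.pvalue), n=len(x),
        )
    rho = float(stats.spearmanr(x, y).statistic)
    p = _spearman_permutation_p(x, y, rho, seed, n_perm, exact)
    return CorrelationResult(
        pair=names, coefficient=float(np.clip(rho, -1, 1)),
        method="spearman", p_value=float(p), n=len(x),
    )


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

@dataclass
class CohortSubject:
    """One cohort member ready for correlation analysis."""

    anatomy: AnatomicalParameters
    solution: LoadSolution
    mass_kg: float


def _table(
    rows: dict[str, list[float]],
    cols: dict[str, list[float]],
    seed: int | None,
) -> pd.DataFrame:
    records = []
    for rname, rvals in rows.items():
        for cname, cvals in cols.items():
            try:
                res = correlate(rvals, cvals, seed=seed, names=(rname, cname))
                rec = {
                    "parameter": rname,
                    "load": cname,
                    "coefficient": res.coefficient,
                    "method": res.method,
                    "p_value": res.p_value,
                    "significant": res.significant,
                    "n": res.n,
                }
            except UndefinedCorrelationError:
                rec = {
                    "parameter": rname, "load": cname, "coefficient": float("nan"),
                    "method": "undefined", "p_value": float("nan"),
                    "significant": False, "n": len(rvals),
                }
            records.append(rec)
    return pd.DataFrame(records)


def cohort_analysis(
    subjects: Sequence[CohortSubject],
    seed: int | None = None,
    min_cobb: float = 5.0,
    g: float = G_DEFAULT,
) -> dict[str, pd.DataFrame]:
    """Correlate anatomical parameters with normalized intersegmental loads.

    Three tables mirror the study design: lumbosacral loads (F_x, F_y at
    L4L5 and L5S1) against the sagittal indexes {SS, PI, LL, RT}; and the
    apical (F^A) and extreme (F^M) loads of the most severe curve against
    {CA, TK, MAR}.  Non-converged subjects are excluded everywhere;
    subjects without a curve above ``min_cobb`` are excluded from the
    curve tables.  Loads are normalized by subject weight before any
    extraction.
    """
    valid = [s for s in subjects if s.solution.converged]
    if len(valid) < 4:
        raise ValueError(f"cohort analysis needs >= 4 converged subjects, got {len(valid)}")

    rows_a: dict[str, list[float]] = {"SS": [], "PI": [], "LL": [], "RT": []}
    cols_a: dict[str, list[float]] = {
        "Fx_L4L5": [], "Fy_L4L5": [], "Fx_L5S1": [], "Fy_L5S1": [],
    }
    have_pi = all(s.anatomy.PI is not None for s in valid)
    for s in valid:
        w = s.mass_kg * g
        rows_a["SS"].append(s.anatomy.SS)
        rows_a["LL"].append(s.anatomy.LL)
        rows_a["RT"].append(float(s.anatomy.RT))
        if have_pi:
            rows_a["PI"].append(float(s.anatomy.PI))
        for lev in ("L4L5", "L5S1"):
            F = s.solution.joint_forces_global[lev] / w
            cols_a[f"Fx_{lev}"].append(float(F[0]))
            cols_a[f"Fy_{lev}"].append(float(F[1]))
    if not have_pi:
        rows_a.pop("PI")
    table_a = _table(rows_a, cols_a, seed)

    curved = [
        s
        for s in valid
        if s.anatomy.primary_curve is not None and s.anatomy.primary_curve.cobb_deg > min_cobb
    ]
    out = {"lumbosacral": table_a}
    if len(curved) >= 4:
        rows_c: dict[str, list[float]] = {"CA": [], "TK": [], "MAR": []}
        cols_fa: dict[str, list[float]] = {"Fx_A": [], "Fy_A": [], "Fz_A": []}
        cols_fm: dict[str, list[float]] = {"Fx_M": [], "Fy_M": [], "Fz_M": []}
        for s in curved:
            w = s.mass_kg * g
            norm = {k: v / w for k, v in s.solution.joint_forces_global.items()}
            cl = extract_curve_loads(norm, s.anatomy.primary_curve)
            rows_c["CA"].append(float(s.anatomy.primary_curve.cobb_deg))
            rows_c["TK"].append(s.anatomy.TK)
            rows_c["MAR"].append(s.anatomy.MAR)
            for i, ax in enumerate("xyz"):
                cols_fa[f"F{ax}_A"].append(float(cl.F_A[i]))
                cols_fm[f"F{ax}_M"].append(float(cl.F_M[i]))
        out["apical"] = _table(rows_c, cols_fa, seed)
        out["curve_max"] = _table(rows_c, cols_fm, seed)
    out["meta"] = pd.DataFrame(
        [
            {
                "n_subjects": len(subjects),
                "n_converged": len(valid),
                "n_with_curve": len(curved),
                "min_cobb_deg": min_cobb,
                "multiple_testing_correction": "none",
            }
        ]
    )
    return out


def pressure_table(
    solutions: Sequence[tuple[LoadSolution, dict[str, float]]],
    levels: Sequence[str] = ("L4L5", "T6T7", "T7T8", "T9T10", "T10T11"),
) -> pd.DataFrame:
    """Mean (SD) nucleus pressures over a cohort at selected disc levels.

    ``solutions`` pairs each LoadSolution with a mapping joint name →
    caudal superior end-plate area (cm²).
    """
    rows = []
    for lev in levels:
        vals = []
        areas = []
        for sol, area_map in solutions:
            if not sol.converged or lev not in sol.joint_forces_local:
                continue
            p = disk_pressure(sol.compression(lev), area_map[lev])
            vals.append(p)
            areas.append(area_map[lev])
        if vals:
            rows.append(
                {
                    "level": lev,
                    "pressure_MPa_mean": float(np.mean(vals)),
                    "pressure_MPa_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "area_cm2_mean": float(np.mean(areas)),
                    "area_cm2_sd": float(np.std(areas, ddof=1)) if len(areas) > 1 else 0.0,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def plot_correlation_map(table: pd.DataFrame, ax=None, title: str | None = None):
    """Basic colour-map plot of one correlation table.

    Rows are anatomical parameters, columns load components; cell colour
    is the coefficient, and significant cells are marked with a star.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    pivot = table.pivot(index="parameter", columns="load", values="coefficient")
    sig = table.pivot(index="parameter", columns="load", values="significant")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(pivot.columns) + 2, 0.8 * len(pivot) + 1.5))
    im = ax.imshow(pivot.values, vmin=-1.0, vmax=1.0, cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            mark = "*" if bool(sig.values[i, j]) else ""
            ax.text(j, i, f"{pivot.values[i, j]:.2f}{mark}", ha="center", va="center", fontsize=9)
    ax.figure.colorbar(im, ax=ax, label="correlation coefficient")
    if title:
        ax.set_title(title)
    return ax
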