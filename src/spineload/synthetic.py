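"""Parametric synthetic spines, biplanar projections and seeded cohorts.

The generator emulates the study population for which the pipeline was
designed: standing adolescents with mild idiopathic scoliosis (Cobb
angles below 24°, body mass around 47 ± 10 kg).  A spine is built by
stacking vertebral boxes along a curve whose sagittal inclinations
interpolate the requested sacral slope, lumbar lordosis and thoracic
kyphosis; scoliosis is added as a half-sine lateral bump realised through
coronal-plane vertebral rotations (so the requested Cobb angle holds by
construction) with axial rotations peaking at the apex, coupled to the
Cobb angle and directed into the curve convexity.

Every stochastic output flows through one seeded NumPy generator, so a
fixed seed reproduces geometry, landmarks and cohorts bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import SpineGeometry, VertebraPose, angles_to_matrix
from .landmarks import (
    CANONICAL_LOCAL,
    CORONAL_NAMES,
    PEDICLE_NAMES,
    SAGITTAL_NAMES,
    Landmark2D,
    LandmarkSet,
    VERTEBRA_INDEX,
    VERTEBRA_LABELS,
)

__all__ = [
    "SpineRecipe",
    "generate_spine",
    "generate_hips",
    "project_landmarks",
    "generate_cohort",
    "DEFAULT_DIMS_MM",
]

#: Typical adolescent vertebral (height, width, depth) in mm, T1→S1.
#: Dimensions grow craniocaudally; lumbar bodies are the largest.
DEFAULT_DIMS_MM: dict[str, tuple[float, float, float]] = {
    "T1": (15.0, 27.0, 17.0),
    "T2": (16.0, 27.5, 18.0),
    "T3": (16.5, 28.0, 19.0),
    "T4": (17.0, 28.5, 20.0),
    "T5": (17.5, 29.0, 21.0),
    "T6": (18.0, 30.0, 22.0),
    "T7": (18.5, 31.0, 23.0),
    "T8": (19.0, 32.0, 24.0),
    "T9": (19.5, 33.5, 25.0),
    "T10": (20.5, 35.0, 26.5),
    "T11": (21.5, 37.0, 28.0),
    "T12": (22.5, 39.0, 29.5),
    "L1": (23.5, 41.0, 30.5),
    "L2": (24.5, 42.5, 31.5),
    "L3": (25.0, 44.0, 32.5),
    "L4": (25.5, 45.5, 33.5),
    "L5": (25.5, 47.0, 34.0),
    "S1": (24.0, 48.0, 32.0),
}

#: Intervertebral disc heights (mm): thinner in the thoracic spine.
_DISC_MM = {**{f"T{i}": 4.0 for i in range(1, 13)}, **{f"L{i}": 8.0 for i in range(1, 6)}}

_THORACIC = [f"T{i}" for i in range(1, 13)]
_LUMBAR = [f"L{i}" for i in range(1, 6)]


class RecipeError(ValueError):
    """Raised for infeasible spine recipes."""


@dataclass(frozen=True)
class SpineRecipe:
    """Full parametric description of one synthetic subject.

    Angles in degrees, masses in kg, noise in mm.  ``axial_coupling`` is
    the apical axial rotation produced per degree of Cobb angle;
    ``convexity`` is the side the scoliotic curve bulges toward.
    """

    subject_id: str = "synthetic"
    stature_scale: float = 1.0
    sacral_slope_deg: float = 40.0
    pelvic_tilt_deg: float = 12.0
    lordosis_deg: float = 45.0
    kyphosis_deg: float = 35.0
    cobb_deg: float = 0.0
    apex_level: str = "T9"
    span_levels: int = 8
    convexity: str = "left"
    axial_coupling: float = 0.5
    mass_kg: float = 47.0
    noise_sigma_mm: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cobb_deg < 0:
            raise RecipeError("cobb_deg must be non-negative")
        if self.convexity not in ("left", "right"):
            raise RecipeError("convexity must be 'left' or 'right'")
        if self.apex_level not in VERTEBRA_INDEX or self.apex_level == "S1":
            raise RecipeError(f"invalid apex level {self.apex_level!r}")
        if self.span_levels < 3:
            raise RecipeError("span must cover at least 3 levels")
        half = self.span_levels // 2
        a = VERTEBRA_INDEX[self.apex_level]
        if a - half < 0 or a + half > VERTEBRA_INDEX["L5"]:
            raise RecipeError(
                f"scoliotic span of {self.span_levels} levels around {self.apex_level} "
                "extends outside T1–L5"
            )
        if self.mass_kg <= 0:
            raise RecipeError("mass must be positive")


#: Cumulative fraction of the lumbar lordosis reached at S1…L1 — the
#: caudal two segments carry most of the arc, as in normal alignment.
_LORDOSIS_FRACTIONS = (0.0, 0.40, 0.65, 0.80, 0.91, 1.0)


def _sagittal_inclinations(r: SpineRecipe, gamma: float = 1.0) -> np.ndarray:
    """Per-vertebra sagittal inclination (deg), T1→S1.

    S1 takes the sacral slope; the lordosis unwinds cranially with a
    caudally-weighted distribution down to L1; the thoracic inclinations
    run from T12 (continuous with L1) to T1 (one kyphosis above T12)
    along a blended linear/quadratic profile.  ``gamma`` sets the blend:
    larger values push the kyphosis apex cranially, letting the mid
    thoracic spine lean posteriorly before the upper levels incline
    forward — the shape degree of freedom used to balance the posture.
    """
    inc = np.zeros(18)
    i_s1, i_l1, i_t12 = 17, 12, 11
    inc[i_s1] = r.sacral_slope_deg
    for n, frac in enumerate(_LORDOSIS_FRACTIONS):  # S1, L5, …, L1
        inc[i_s1 - n] = r.sacral_slope_deg - frac * r.lordosis_deg
    inc_t12 = inc[i_l1]
    for k in range(0, 12):  # T1..T12
        s = (i_t12 - k) / 11.0  # 0 at T12 → 1 at T1
        inc[k] = inc_t12 + r.kyphosis_deg * ((1.0 - gamma) * s + gamma * s * s)
    return inc


def _scoliosis_profiles(r: SpineRecipe) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertebra coronal and axial rotation profiles (deg), T1→S1.

    The coronal rotation runs ±Cobb/2 at the end vertebrae through zero
    at the apex (cosine profile), which makes the end-plate construction
    reproduce the requested Cobb angle exactly.  Axial rotation follows a
    half-sine peaking at the apex with magnitude axial_coupling·Cobb,
    signed into the convexity.
    """
    cor = np.zeros(18)
    ax = np.zeros(18)
    if r.cobb_deg == 0:
        return cor, ax
    half = r.span_levels // 2
    a = VERTEBRA_INDEX[r.apex_level]
    lo, hi = a - half, a + half
    sign = 1.0 if r.convexity == "left" else -1.0
    for k in range(lo, hi + 1):
        s = (k - lo) / (hi - lo)
        cor[k] = sign * (r.cobb_deg / 2.0) * np.cos(np.pi * s)
        ax[k] = sign * r.axial_coupling * r.cobb_deg * np.sin(np.pi * s)
    return cor, ax


def _stack_centers(
    r: SpineRecipe,
    inc: np.ndarray,
    cor: np.ndarray,
    ax: np.ndarray,
    dims: dict[str, tuple],
) -> dict[str, np.ndarray]:
    angles = {
        lab: (float(cor[i]), float(inc[i]), float(ax[i]))
        for i, lab in enumerate(VERTEBRA_LABELS)
    }
    centers: dict[str, np.ndarray] = {"S1": np.zeros(3)}
    for i in range(16, -1, -1):  # L5 up to T1
        lab, below = VERTEBRA_LABELS[i], VERTEBRA_LABELS[i + 1]
        ax_lab = angles_to_matrix(*angles[lab])[:, 0]
        ax_below = angles_to_matrix(*angles[below])[:, 0]
        step = ax_lab + ax_below
        step = step / np.linalg.norm(step)
        gap = dims[below][0] / 2.0 + _DISC_MM[lab] * r.stature_scale + dims[lab][0] / 2.0
        centers[lab] = centers[below] + step * gap
    return centers


#: Kiefer-style per-level weight shares used only to place the weight
#: line during postural balancing (head, arms, per-level trunk ramp).
_BALANCE_HEAD = 0.081
_BALANCE_ARM = 0.100


def _weight_line_offset(centers: dict[str, np.ndarray]) -> float:
    """Anterior (y) offset of the gravity resultant relative to S1, mm."""
    levels = [lab for lab in VERTEBRA_LABELS if lab != "S1"]
    ramp = np.array([1.0 + i / 16.0 for i in range(len(levels))])
    trunk = ramp / ramp.sum() * (1.0 - _BALANCE_HEAD - _BALANCE_ARM)
    y = sum(w * centers[lab][1] for w, lab in zip(trunk, levels))
    y += _BALANCE_HEAD * centers["T1"][1] + _BALANCE_ARM * centers["T4"][1]
    return float(y - centers["S1"][1])


def generate_spine(r: SpineRecipe) -> SpineGeometry:
    """Build the 18-vertebra geometry described by a recipe.

    Vertebrae are stacked caudal→cranial from S1 at the origin, each step
    following the mean body axis of the adjacent vertebrae, so the
    requested rotations integrate into the corresponding spatial curve.
    The thoracic profile shape is then solved (by bisection on its
    linear/quadratic blend) so that the standing weight line falls just
    anterior of S1 — the sagittally balanced posture a standing subject
    adopts.  Sacral slope, lordosis, kyphosis and the scoliotic
    construction are preserved exactly by this balancing step.
    """
    cor, ax = _scoliosis_profiles(r)
    dims = {
        lab: tuple(np.asarray(DEFAULT_DIMS_MM[lab]) * r.stature_scale)
        for lab in VERTEBRA_LABELS
    }

    target_mm = 25.0  # weight line slightly anterior of S1 keeps extensor tone

    def offset_for(gamma: float) -> float:
        inc_g = _sagittal_inclinations(r, gamma)
        return _weight_line_offset(_stack_centers(r, inc_g, cor, ax, dims)) - target_mm

    lo, hi = 0.0, 4.0
    f_lo, f_hi = offset_for(lo), offset_for(hi)
    if f_lo * f_hi > 0:  # unbalanced even at the bounds: take the closer end
        gamma = lo if abs(f_lo) < abs(f_hi) else hi
    else:
        for _ in range(40):
            gamma = 0.5 * (lo + hi)
            f_mid = offset_for(gamma)
            if f_lo * f_mid <= 0:
                hi = gamma
            else:
                lo, f_lo = gamma, f_mid
        gamma = 0.5 * (lo + hi)
    inc = _sagittal_inclinations(r, gamma)
    centers = _stack_centers(r, inc, cor, ax, dims)
    angles = {
        lab: (float(cor[i]), float(inc[i]), float(ax[i]))
        for i, lab in enumerate(VERTEBRA_LABELS)
    }
    vertebrae = [
        VertebraPose(
            label=lab,
            center=centers[lab],
            dims=dims[lab],
            angles=angles[lab],
        )
        for lab in VERTEBRA_LABELS
    ]
    geo = SpineGeometry(subject_id=r.subject_id, vertebrae=vertebrae)
    geo.validate()
    return geo


def generate_hips(r: SpineRecipe, g: SpineGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Femoral-head centres consistent with the recipe's pelvic tilt.

    The hip-axis midpoint lies antero-inferior to the S1 end-plate
    midpoint, tilted ``pelvic_tilt_deg`` from the vertical, so the
    computed pelvic incidence equals sacral slope + pelvic tilt.
    """
    s1 = g.get("S1")
    mid = s1.local_point(1.0, 0.0, 0.0)
    pt = np.radians(r.pelvic_tilt_deg)
    reach = 110.0 * r.stature_scale
    hip_mid = mid + reach * np.array([-np.cos(pt), np.sin(pt), 0.0])
    half_axis = 85.0 * r.stature_scale
    left = hip_mid + np.array([0.0, 0.0, +half_axis])
    right = hip_mid + np.array([0.0, 0.0, -half_axis])
    return left, right


def project_landmarks(
    g: SpineGeometry,
    noise_sigma_mm: float = 0.0,
    seed: int | np.random.Generator | None = None,
    include_pedicles: bool = False,
    hips: tuple[np.ndarray, np.ndarray] | None = None,
) -> LandmarkSet:
    """Project a geometry to its biplanar landmark set.

    Emits the 8 canonical landmarks per vertebra (10 with pedicles) under
    orthographic projection — coronal view (u, v) = (x, z), sagittal
    (u, v) = (x, y) — plus independent Gaussian noise of the given sigma
    on every coordinate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lms: list[Landmark2D] = []
    for v in g.vertebrae:
        for view, name, p in v.canonical_points(include_pedicles=include_pedicles):
            u, vv = (p[0], p[2]) if view == "coronal" else (p[0], p[1])
            if noise_sigma_mm > 0:
                u += rng.normal(0.0, noise_sigma_mm)
                vv += rng.normal(0.0, noise_sigma_mm)
            lms.append(Landmark2D(vertebra=v.label, view=view, name=name, u=float(u), v=float(vv)))
    hip_lms: list[Landmark2D] = []
    if hips is not None:
        for lab, p in zip(("FHL", "FHR"), hips):
            for view in ("coronal", "sagittal"):
                u, vv = (p[0], p[2]) if view == "coronal" else (p[0], p[1])
                if noise_sigma_mm > 0:
                    u += rng.normal(0.0, noise_sigma_mm)
                    vv += rng.normal(0.0, noise_sigma_mm)
                hip_lms.append(
                    Landmark2D(vertebra=lab, view=view, name="center", u=float(u), v=float(vv))
                )
    return LandmarkSet(subject_id=g.subject_id, landmarks=lms, hip_landmarks=hip_lms)


@dataclass
class SyntheticSubject:
    """One cohort member: recipe, landmark set and body mass."""

    recipe: SpineRecipe
    landmarks: LandmarkSet
    mass_kg: float
    hips: tuple[np.ndarray, np.ndarray] | None = None


#: Apex levels and their sampling weights — main-thoracic curves peaking
#: around T8–T9 dominate adolescent idiopathic scoliosis.
_APEX_CHOICES = ("T7", "T8", "T9", "T10", "T11")
_APEX_WEIGHTS = (0.15, 0.30, 0.30, 0.15, 0.10)


def generate_cohort(
    n: int = 38,
    seed: int | None = None,
    scoliosis_prevalence: float = 29.0 / 38.0,
    cobb_max_deg: float = 24.0,
    noise_sigma_mm: float = 0.5,
    include_pedicles: bool = True,
    axial_coupling: float = 0.5,
) -> list[SyntheticSubject]:
    """Sample a seeded cohort emulating the target adolescent population.

    Body mass is normal 47 ± 10 kg truncated above 20 kg; a configured
    fraction of subjects carries a scoliotic curve with Cobb uniform in
    (5°, ``cobb_max_deg``), the rest uniform in (0°, 5°).  The sagittal
    parameters follow the spino-pelvic harmony of normal alignment
    rather than being sampled independently: pelvic incidence is the
    anatomical constant (≈ 50 ± 10°), pelvic tilt regresses on it
    (PT ≈ 0.3·PI − 5), sacral slope is their difference, and lumbar
    lordosis tracks incidence (LL ≈ PI − 5 ± 7); kyphosis is drawn
    independently (≈ 35 ± 10°).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    subjects: list[SyntheticSubject] = []
    for i in range(n):
        mass = float(np.clip(rng.normal(47.0, 10.0), 20.1, None))
        scoliotic = rng.random() < scoliosis_prevalence
        cobb = float(rng.uniform(5.0, cobb_max_deg)) if scoliotic else float(rng.uniform(0.0, 5.0))
        pi = float(np.clip(rng.normal(50.0, 10.0), 35.0, 70.0))
        pt = float(np.clip(0.3 * pi - 5.0 + rng.normal(0.0, 3.0), 2.0, 28.0))
        recipe = SpineRecipe(
            subject_id=f"synth{i:03d}",
            stature_scale=float(np.clip(rng.normal(1.0, 0.06), 0.85, 1.15)),
            sacral_slope_deg=pi - pt,
            pelvic_tilt_deg=pt,
            lordosis_deg=float(np.clip(pi - 5.0 + rng.normal(0.0, 7.0), 25.0, 70.0)),
            kyphosis_deg=float(np.clip(rng.normal(35.0, 10.0), 15.0, 55.0)),
            cobb_deg=cobb,
            apex_level=str(rng.choice(_APEX_CHOICES, p=_APEX_WEIGHTS)),
            span_levels=int(rng.choice([6, 8, 10])),
            convexity="left" if rng.random() < 0.5 else "right",
            axial_coupling=axial_coupling,
            mass_kg=mass,
            noise_sigma_mm=noise_sigma_mm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        geo = generate_spine(recipe)
        hips = generate_hips(recipe, geo)
        lm = project_landmarks(
            geo,
            noise_sigma_mm=noise_sigma_mm,
            seed=np.random.default_rng(recipe.seed),
            include_pedicles=include_pedicles,
            hips=hips,
        )
        subjects.append(SyntheticSubject(recipe=recipe, landmarks=lm, mass_kg=mass, hips=hips))
    return subjects


def write_landmark_cohort(out_dir, subjects: Sequence[SyntheticSubject]) -> None:
    """Write per-subject landmark CSVs plus a metadata table."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        s.landmarks.to_csv(out / f"{s.landmarks.subject_id}_landmarks.csv")
        r = s.recipe
        rows.append(
            {
                "subject_id": s.landmarks.subject_id,
                "mass_kg": s.mass_kg,
                "cobb_deg": r.cobb_deg,
                "apex_level": r.apex_level,
                "convexity": r.convexity,
                "sacral_slope_deg": r.sacral_slope_deg,
                "pelvic_tilt_deg": r.pelvic_tilt_deg,
                "lordosis_deg": r.lordosis_deg,
                "kyphosis_deg": r.kyphosis_deg,
                "stature_scale": r.stature_scale,
                "noise_sigma_mm": r.noise_sigma_mm,
                "seed": r.seed,
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
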