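"""Anatomical indexes and scoliotic-curve structure from reconstructed spines.

All angle measurements are taken from the fitted box model's end-plate
edge directions projected into the relevant plane, keeping them
consistent with the reconstruction rather than re-reading raw landmarks:

* coronal end-plate tilt — angle of the end-plate's width edge in the
  coronal (x, z) plane; the Cobb angle of a curve is the angle between
  the superior end-plate line of its upper end vertebra and the inferior
  end-plate line of its lower end vertebra,
* sagittal inclination — the angle by which the end-plate descends
  anteriorly, relative to the horizontal plane (normal to x); sacral
  slope, lumbar lordosis (S1–L1) and thoracic kyphosis (T1–T12) follow,
* maximum axial rotation (MAR) — the signed axial-plane Euler angle of
  largest magnitude along the spine; positive means a right-hand
  rotation about the craniocaudal x axis,
* pelvic incidence — the angle at the S1 end-plate midpoint between the
  end-plate perpendicular and the line to the hip-axis midpoint;
  reported only when femoral-head positions are supplied.

Curves with Cobb angle above 5° count as scoliotic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import SpineGeometry, VertebraPose
from .landmarks import VERTEBRA_INDEX, VERTEBRA_LABELS

__all__ = [
    "ScolioticCurve",
    "AnatomicalParameters",
    "coronal_tilt",
    "sagittal_inclination",
    "detect_curves",
    "compute_parameters",
    "parameters_to_frame",
]


def coronal_tilt(pose: VertebraPose) -> float:
    """Coronal-plane tilt (deg) of the vertebra's end-plate line.

    Zero for a horizontal end-plate; positive when the left side is
    higher (right-hand rotation about the posteroanterior y axis).  Both
    end-plates of the rigid box are parallel, so one tilt serves both.
    """
    e = pose.rotation @ np.array([0.0, 0.0, 1.0])
    return float(np.degrees(np.arctan2(e[0], e[2])))


def sagittal_inclination(pose: VertebraPose) -> float:
    """Sagittal inclination (deg) of the end-plate vs the horizontal.

    Positive when the plate descends anteriorly (its upward normal tilts
    anteriorly), the usual situation for the sacral end-plate in
    standing.
    """
    e = pose.rotation @ np.array([0.0, 1.0, 0.0])
    return float(np.degrees(np.arctan2(-e[0], e[1])))


@dataclass(frozen=True)
class ScolioticCurve:
    """One coronal-plane curve: end vertebrae, apex, Cobb angle, convexity."""

    upper_end: str
    lower_end: str
    apex: str
    cobb_deg: float
    side: str

    def __post_init__(self) -> None:
        if self.cobb_deg < 0:
            raise ValueError("cobb_deg must be non-negative")
        iu, ia, il = (VERTEBRA_INDEX[v] for v in (self.upper_end, self.apex, self.lower_end))
        if not (iu <= ia <= il):
            raise ValueError("curve requires upper_end ≤ apex ≤ lower_end craniocaudally")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def levels(self) -> list[str]:
        iu, il = VERTEBRA_INDEX[self.upper_end], VERTEBRA_INDEX[self.lower_end]
        return list(VERTEBRA_LABELS[iu : il + 1])


@dataclass
class AnatomicalParameters:
    """The per-subject anatomical indexes extracted from one geometry."""

    subject_id: str
    curves: list[ScolioticCurve] = field(default_factory=list)
    primary_curve: ScolioticCurve | None = None
    SS: float = 0.0
    PI: float | None = None
    LL: float = 0.0
    TK: float = 0.0
    MAR: float = 0.0
    RT: int = 2
    rt_automatic: bool = True  # rule-based typing, flagged as approximate

    @property
    def CA(self) -> float | None:
        """Cobb angle of the most severe curve, if any."""
        return self.primary_curve.cobb_deg if self.primary_curve else None


def _smooth3(x: np.ndarray) -> np.ndarray:
    """3-level moving average with shrinking windows at the ends."""
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - 1), min(len(x), i + 2)
        out[i] = x[lo:hi].mean()
    return out


def _chord_deviation(g: SpineGeometry, labels: Sequence[str], upper: str, lower: str) -> dict[str, np.ndarray]:
    """Perpendicular deviation of each centre from the end-vertebra chord."""
    cu, cl = g.get(upper).center, g.get(lower).center
    axis = cl - cu
    axis = axis / np.linalg.norm(axis)
    out = {}
    for lab in labels:
        v = g.get(lab).center - cu
        out[lab] = v - np.dot(v, axis) * axis
    return out


def detect_curves(g: SpineGeometry, min_cobb: float = 5.0) -> list[ScolioticCurve]:
    """Find coronal curves between consecutive inflections of end-plate tilt.

    The smoothed (3-level moving average) coronal tilt sequence is
    scanned for sign changes; each sign change marks a curve apex region,
    and the curve's end vertebrae are the most-tilted levels on either
    side (ties broken toward the more cranial level).  The Cobb angle is
    measured from the unsmoothed end-plate lines of the end vertebrae;
    the apex is the in-curve vertebra deviating farthest laterally from
    the chord joining the end-vertebra centres.  Only curves with Cobb
    angle strictly above ``min_cobb`` are returned.
    """
    labels = g.labels()
    tilts = np.array([coronal_tilt(v) for v in g.vertebrae])
    s = _smooth3(tilts)
    crossings = [i for i in range(len(s) - 1) if s[i] * s[i + 1] < 0]
    curves: list[ScolioticCurve] = []
    for k, c in enumerate(crossings):
        lo_bound = crossings[k - 1] + 1 if k > 0 else 0
        hi_bound = crossings[k + 1] if k + 1 < len(crossings) else len(s) - 1
        upper_seg = range(lo_bound, c + 1)
        lower_seg = range(c + 1, hi_bound + 1)
        # end vertebrae: the most tilted level of each half (raw tilt;
        # the smoothing only drives the segmentation); cranial on ties
        iu = max(upper_seg, key=lambda i: (abs(tilts[i]), -i))
        il = max(lower_seg, key=lambda i: (abs(tilts[i]), -i))
        if iu == il:
            continue
        upper, lower = labels[iu], labels[il]
        cobb = abs(tilts[iu] - tilts[il])
        members = labels[iu : il + 1]
        dev = _chord_deviation(g, members, upper, lower)
        apex = max(members, key=lambda lab: (abs(dev[lab][2]), -VERTEBRA_INDEX[lab]))
        side = "left" if dev[apex][2] >= 0 else "right"
        if cobb > min_cobb:
            curves.append(
                ScolioticCurve(upper_end=upper, lower_end=lower, apex=apex, cobb_deg=float(cobb), side=side)
            )
    return curves


def _roussouly_type(SS: float, g: SpineGeometry) -> int:
    """Rule-based lumbopelvic sagittal typing (approximate, automatic).

    Types follow the usual sacral-slope bands; the low-slope band splits
    on whether the sagittal lumbar apex sits at or below L4.
    """
    if SS > 45.0:
        return 4
    if SS >= 35.0:
        return 3
    # lumbar sagittal apex: greatest anterior deviation from the T12–S1 chord
    lumbar = [f"L{i}" for i in range(1, 6)]
    dev = _chord_deviation(g, lumbar, "T12", "S1")
    apex = max(lumbar, key=lambda lab: (dev[lab][1], -VERTEBRA_INDEX[lab]))
    return 1 if apex in ("L4", "L5") else 2


def compute_parameters(
    g: SpineGeometry,
    hips: tuple[np.ndarray, np.ndarray] | None = None,
    min_cobb: float = 5.0,
) -> AnatomicalParameters:
    """Compute all anatomical indexes for one reconstructed spine.

    ``hips`` is an optional pair of femoral-head centres (3-vectors, mm);
    without it the pelvic incidence is reported as absent, not zero.
    """
    s1 = g.get("S1")
    SS = sagittal_inclination(s1)
    LL = SS - sagittal_inclination(g.get("L1"))
    TK = sagittal_inclination(g.get("T1")) - sagittal_inclination(g.get("T12"))
    axials = [(v.angles[2], v.label) for v in g.vertebrae]
    mar, _ = max(axials, key=lambda t: (abs(t[0]), -VERTEBRA_INDEX[t[1]]))
    PI: float | None = None
    if hips is not None:
        mid_plate = s1.local_point(1.0, 0.0, 0.0)
        hip_mid = (np.asarray(hips[0], float) + np.asarray(hips[1], float)) / 2.0
        down_normal = -(s1.rotation @ np.array([1.0, 0.0, 0.0]))
        u = hip_mid - mid_plate
        nu = np.linalg.norm(u)
        if nu < 1e-9:
            raise ValueError("hip-axis midpoint coincides with the S1 end-plate midpoint")
        cosang = np.clip(np.dot(down_normal, u / nu), -1.0, 1.0)
        PI = float(np.degrees(np.arccos(cosang)))
    curves = detect_curves(g, min_cobb=min_cobb)
    primary = max(curves, key=lambda c: c.cobb_deg) if curves else None
    return AnatomicalParameters(
        subject_id=g.subject_id,
        curves=curves,
        primary_curve=primary,
        SS=float(SS),
        PI=PI,
        LL=float(LL),
        TK=float(TK),
        MAR=float(mar),
        RT=_roussouly_type(SS, g),
    )


def parameters_to_frame(params: Sequence[AnatomicalParameters]) -> pd.DataFrame:
    """One row per subject with all indexes; curves as label triplets + CA."""
    rows = []
    for p in params:
        rows.append(
            {
                "subject_id": p.subject_id,
                "n_curves": len(p.curves),
                "CA_deg": p.CA,
                "primary_curve": (
                    f"{p.primary_curve.upper_end}-{p.primary_curve.apex}-{p.primary_curve.lower_end}"
                    if p.primary_curve
                    else ""
                ),
                "curve_side": p.primary_curve.side if p.primary_curve else "",
                "SS_deg": p.SS,
                "PI_deg": p.PI,
                "LL_deg": p.LL,
                "TK_deg": p.TK,
                "MAR_deg": p.MAR,
                "RT": p.RT,
                "RT_automatic": p.rt_automatic,
                "curves": ";".join(
                    f"{c.upper_end}-{c.apex}-{c.lower_end}:{c.cobb_deg:.1f}" for c in p.curves
                ),
            }
        )
    return pd.DataFrame(rows)


def write_parameters_csv(path: str | Path, params: Sequence[AnatomicalParameters]) -> None:
    parameters_to_frame(params).to_csv(path, index=False)
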