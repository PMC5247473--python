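"""3D vertebral pose reconstruction from paired coronal/sagittal landmarks.

The stereoradiographic system acquires two simultaneous, spatially
calibrated, true-to-size views, so every 3D point is jointly projected
orthographically onto both images.  The global frame is right-handed with
x craniocaudal (cranially positive), y posteroanterior (anteriorly
positive) and z right-to-left.  The coronal image shows (x, z); the
sagittal image shows (x, y).

Each vertebra is reconstructed by fitting a 9-parameter box model —
centre (3), dimensions (3) and rotation (3) — whose canonical end-plate
extremity points project onto the observed landmarks.  Rotations are
stored both as a (coronal, lateral, axial) angle triple in degrees and as
a rotation matrix; the Euler convention is intrinsic lateral(z) →
coronal(y) → axial(x).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

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
    "VertebraPose",
    "SpineGeometry",
    "fuse_biplanar_point",
    "fit_vertebra",
    "reconstruct_spine",
    "angles_to_matrix",
    "matrix_to_angles",
    "InconsistentProjectionError",
    "ReconstructionError",
    "PoorFitWarning",
]


class InconsistentProjectionError(ValueError):
    """The two views disagree on the shared craniocaudal coordinate."""


class ReconstructionError(RuntimeError):
    """The nonlinear pose fit failed to converge."""


class PoorFitWarning(UserWarning):
    """The pose fit converged with a large landmark residual."""


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------

def angles_to_matrix(coronal_deg: float, lateral_deg: float, axial_deg: float) -> np.ndarray:
    """Rotation matrix for an intrinsic lateral(z) → coronal(y) → axial(x) triple.

    ``coronal`` is the rotation seen in the coronal plane (about y),
    ``lateral`` the sagittal-plane rotation (about z) and ``axial`` the
    axial-plane rotation (about the craniocaudal x axis).  Signs are
    right-handed about each axis.
    """
    return Rotation.from_euler(
        "ZYX", [lateral_deg, coronal_deg, axial_deg], degrees=True
    ).as_matrix()


def matrix_to_angles(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`angles_to_matrix`; returns (coronal, lateral, axial) deg."""
    lat, cor, ax = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
    return float(cor), float(lat), float(ax)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VertebraPose:
    """Reconstructed rigid pose and dimensions of one vertebra.

    ``dims`` is (height, width, depth) in mm along local (x, z, y).
    ``angles`` is the (coronal, lateral, axial) triple in degrees.
    """

    label: str
    center: np.ndarray
    dims: tuple[float, float, float]
    angles: tuple[float, float, float]
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")
        if any(d <= 0 for d in self.dims):
            raise ValueError(f"vertebra {self.label}: dimensions must be positive")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 proper rotation matrix (orthonormal, det +1)."""
        return angles_to_matrix(*self.angles)

    @property
    def height(self) -> float:
        return self.dims[0]

    @property
    def width(self) -> float:
        return self.dims[1]

    @property
    def depth(self) -> float:
        return self.dims[2]

    @property
    def endplate_area_sup(self) -> float:
        """Superior end-plate area in cm², modelled as an ellipse π/4·w·d."""
        return np.pi / 4.0 * self.width * self.depth / 100.0

    def local_point(self, nx: float, ny: float, nz: float) -> np.ndarray:
        """Global position of a normalized local point (units of h/2, d/2, w/2)."""
        h, w, d = self.dims
        local = np.array([nx * h / 2.0, ny * d / 2.0, nz * w / 2.0])
        return self.center + self.rotation @ local

    def canonical_points(self, include_pedicles: bool = False) -> list[tuple[str, str, np.ndarray]]:
        """The canonical landmark points in 3D: (view, name, xyz)."""
        names = [("coronal", n) for n in CORONAL_NAMES] + [
            ("sagittal", n) for n in SAGITTAL_NAMES
        ]
        if include_pedicles:
            names += [("coronal", n) for n in PEDICLE_NAMES]
        out = []
        for view, name in names:
            nx, ny, nz = CANONICAL_LOCAL[(view, name)]
            out.append((view, name, self.local_point(nx, ny, nz)))
        return out


@dataclass
class SpineGeometry:
    """Ordered T1→S1 collection of reconstructed vertebral poses."""

    subject_id: str
    vertebrae: list[VertebraPose] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = [VERTEBRA_INDEX[v.label] for v in self.vertebrae]
        if order != sorted(order):
            raise ValueError("vertebrae must be ordered cranial to caudal")

    def labels(self) -> list[str]:
        return [v.label for v in self.vertebrae]

    def get(self, label: str) -> VertebraPose:
        for v in self.vertebrae:
            if v.label == label:
                return v
        raise KeyError(label)

    def centers(self) -> np.ndarray:
        return np.array([v.center for v in self.vertebrae])

    def validate(self) -> None:
        """Enforce the craniocaudal ordering invariant on centres."""
        x = self.centers()[:, 0]
        if not np.all(np.diff(x) < 0):
            bad = [
                self.vertebrae[i + 1].label
                for i in range(len(x) - 1)
                if x[i + 1] >= x[i]
            ]
            raise ReconstructionError(
                "centres not strictly descending craniocaudally at: " + ", ".join(bad)
            )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "vertebrae": [
                {
                    "label": v.label,
                    "center_mm": v.center.tolist(),
                    "dims_mm": list(v.dims),
                    "angles_deg": list(v.angles),
                    "rotation": v.rotation.tolist(),
                    "residual_rms_mm": v.residual_rms,
                    "endplate_area_sup_cm2": v.endplate_area_sup,
                }
                for v in self.vertebrae
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "SpineGeometry":
        vs = [
            VertebraPose(
                label=e["label"],
                center=np.array(e["center_mm"]),
                dims=tuple(e["dims_mm"]),
                angles=tuple(e["angles_deg"]),
                residual_rms=e.get("residual_rms_mm", 0.0),
            )
            for e in d["vertebrae"]
        ]
        return cls(subject_id=d["subject_id"], vertebrae=vs)

    @classmethod
    def from_json(cls, path: str | Path) -> "SpineGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def fuse_biplanar_point(
    coronal_pt: Sequence[float],
    sagittal_pt: Sequence[float],
    tol_mm: float = 5.0,
    label: str = "",
) -> np.ndarray:
    """Fuse one point observed on both calibrated views into 3D.

    Both views share the craniocaudal u axis; x is taken as the mean of
    the two u readings, y from the sagittal v and z from the coronal v.
    A disagreement of the u readings beyond ``tol_mm`` raises
    :class:`InconsistentProjectionError`.
    """
    u_cor, v_cor = float(coronal_pt[0]), float(coronal_pt[1])
    u_sag, v_sag = float(sagittal_pt[0]), float(sagittal_pt[1])
    if abs(u_cor - u_sag) > tol_mm:
        where = f" at {label}" if label else ""
        raise InconsistentProjectionError(
            f"craniocaudal coordinates disagree{where}: coronal u={u_cor:.2f} mm, "
            f"sagittal u={u_sag:.2f} mm (tolerance {tol_mm:.2f} mm)"
        )
    return np.array([(u_cor + u_sag) / 2.0, v_sag, v_cor])


def _project(view: str, p: np.ndarray) -> np.ndarray:
    """Orthographic projection of a global point onto one view's (u, v)."""
    if view == "coronal":
        return np.array([p[0], p[2]])
    return np.array([p[0], p[1]])


def _initial_guess(obs: list[tuple[str, str, float, float]]) -> np.ndarray:
    """Unrotated-box initial parameters from landmark midpoints/extents."""
    cor = {n: (u, v) for view, n, u, v in obs if view == "coronal"}
    sag = {n: (u, v) for view, n, u, v in obs if view == "sagittal"}
    cx = float(np.mean([u for view, n, u, v in obs if n not in PEDICLE_NAMES]))
    cz = float(np.mean([v for n, (u, v) in cor.items() if n not in PEDICLE_NAMES]))
    cy = float(np.mean([v for n, (u, v) in sag.items()]))
    sup_u = np.mean([cor["sup_left"][0], cor["sup_right"][0], sag["sup_ant"][0], sag["sup_post"][0]])
    inf_u = np.mean([cor["inf_left"][0], cor["inf_right"][0], sag["inf_ant"][0], sag["inf_post"][0]])
    h = max(float(sup_u - inf_u), 1.0)
    w = max(
        float(
            np.mean(
                [cor["sup_left"][1] - cor["sup_right"][1], cor["inf_left"][1] - cor["inf_right"][1]]
            )
        ),
        1.0,
    )
    d = max(
        float(
            np.mean(
                [sag["sup_ant"][1] - sag["sup_post"][1], sag["inf_ant"][1] - sag["inf_post"][1]]
            )
        ),
        1.0,
    )
    # End-plate tilts give first-order angle seeds; axial starts at zero.
    cor_tilt = np.degrees(
        np.arctan2(
            np.mean([cor["sup_left"][0] - cor["sup_right"][0], cor["inf_left"][0] - cor["inf_right"][0]]),
            w,
        )
    )
    lat_tilt = -np.degrees(
        np.arctan2(
            np.mean([sag["sup_ant"][0] - sag["sup_post"][0], sag["inf_ant"][0] - sag["inf_post"][0]]),
            d,
        )
    )
    # Axial rotation seed: foreshortening alone leaves its sign ambiguous,
    # but the pedicle midpoint shifts laterally in first order (the
    # pedicles sit posterior of the centre, so an axial rotation sweeps
    # them sideways).  Seeding from that shift keeps the nonlinear fit on
    # the correct branch.
    ax_seed = 0.0
    if "ped_left" in cor and "ped_right" in cor:
        ped_mid_v = (cor["ped_left"][1] + cor["ped_right"][1]) / 2.0
        ny = CANONICAL_LOCAL[("coronal", "ped_left")][1]  # posterior offset multiplier
        s = np.clip((ped_mid_v - cz) / (ny * d / 2.0), -1.0, 1.0)
        ax_seed = np.degrees(np.arcsin(s))
    return np.array([cx, cy, cz, h, w, d, cor_tilt, lat_tilt, ax_seed])


def fit_vertebra(
    landmarks: Sequence[Landmark2D],
    residual_threshold_mm: float = 3.0,
    use_pedicles: bool | None = None,
) -> VertebraPose:
    """Fit the 9-parameter box pose to one vertebra's landmarks.

    The box's canonical end-plate extremity points (±w/2 along local z on
    each end-plate in the coronal view; ±d/2 along local y in the sagittal
    view; end-plates at ±h/2 along local x) are projected orthographically
    and matched to the observations by nonlinear least squares.  Pedicle
    landmarks, when present, are appended to the system; they chiefly
    condition the axial rotation, which is otherwise observable only
    through projective foreshortening.

    The fit is deterministic (no randomness): it starts from the
    unrotated box implied by the landmark midpoints and extents.
    """
    if not landmarks:
        raise ReconstructionError("no landmarks supplied")
    label = landmarks[0].vertebra
    if use_pedicles is None:
        use_pedicles = any(lm.name in PEDICLE_NAMES for lm in landmarks)
    obs: list[tuple[str, str, float, float]] = []
    for lm in landmarks:
        if lm.vertebra != label:
            raise ReconstructionError("landmarks from multiple vertebrae passed to fit_vertebra")
        if lm.name in PEDICLE_NAMES and not use_pedicles:
            continue
        if (lm.view, lm.name) not in CANONICAL_LOCAL:
            raise ReconstructionError(f"unknown landmark role {lm.view}:{lm.name}")
        obs.append((lm.view, lm.name, lm.u, lm.v))
    got = {(view, n) for view, n, _, _ in obs}
    need = {("coronal", n) for n in CORONAL_NAMES} | {("sagittal", n) for n in SAGITTAL_NAMES}
    if not need <= got:
        missing = ", ".join(sorted(f"{v}:{n}" for v, n in need - got))
        raise ReconstructionError(f"vertebra {label}: missing landmarks: {missing}")

    locals_n = np.array([CANONICAL_LOCAL[(view, n)] for view, n, _, _ in obs])
    targets = np.array([[u, v] for _, _, u, v in obs])
    is_coronal = np.array([view == "coronal" for view, _, _, _ in obs])

    def residuals(theta: np.ndarray) -> np.ndarray:
        c = theta[:3]
        h, w, d = theta[3:6]
        R = angles_to_matrix(theta[6], theta[7], theta[8])
        pts_local = np.column_stack(
            [locals_n[:, 0] * h / 2.0, locals_n[:, 1] * d / 2.0, locals_n[:, 2] * w / 2.0]
        )
        pts = c[None, :] + pts_local @ R.T
        proj = np.where(
            is_coronal[:, None],
            pts[:, [0, 2]],
            pts[:, [0, 1]],
        )
        return (proj - targets).ravel()

    theta0 = _initial_guess(obs)
    try:
        res = least_squares(
            residuals,
            theta0,
            method="lm",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=6000,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise ReconstructionError(f"vertebra {label}: pose fit failed: {exc}") from exc
    if not res.success:
        raise ReconstructionError(f"vertebra {label}: pose fit did not converge ({res.message})")
    theta = res.x
    # A mirrored box (negative dimension) fits identically; fold the sign
    # into the rotation-free representation by taking magnitudes.
    dims = tuple(abs(float(v)) for v in theta[3:6])
    cor, lat, ax = (float(a) for a in theta[6:9])
    # Wrap angles into (-180, 180].
    cor, lat, ax = ((a + 180.0) % 360.0 - 180.0 for a in (cor, lat, ax))
    rms = float(np.sqrt(np.mean(res.fun**2)))
    if rms > residual_threshold_mm:
        warnings.warn(
            f"vertebra {label}: pose fit residual RMS {rms:.2f} mm exceeds "
            f"{residual_threshold_mm:.2f} mm",
            PoorFitWarning,
            stacklevel=2,
        )
    return VertebraPose(
        label=label,
        center=theta[:3].copy(),
        dims=dims,
        angles=(cor, lat, ax),
        residual_rms=rms,
    )


def reconstruct_spine(
    ls: LandmarkSet,
    residual_threshold_mm: float = 3.0,
    use_pedicles: bool | None = None,
) -> SpineGeometry:
    """Reconstruct every landmarked vertebra of one subject.

    Returns one pose per vertebra in cranial-to-caudal order and enforces
    the craniocaudal ordering invariant of the centres.
    """
    ls.validate()
    poses = [
        fit_vertebra(
            ls.for_vertebra(lab),
            residual_threshold_mm=residual_threshold_mm,
            use_pedicles=use_pedicles,
        )
        for lab in ls.vertebra_labels()
    ]
    geo = SpineGeometry(subject_id=ls.subject_id, vertebrae=poses)
    geo.validate()
    return geo


def fuse_hip_landmarks(ls: LandmarkSet, tol_mm: float = 5.0) -> tuple[np.ndarray, np.ndarray] | None:
    """Fuse femoral-head landmarks into two 3D points, if present."""
    if not ls.has_hips():
        return None
    pts = []
    for lab in ("FHL", "FHR"):
        cor = next(lm for lm in ls.hip_landmarks if lm.vertebra == lab and lm.view == "coronal")
        sag = next(lm for lm in ls.hip_landmarks if lm.vertebra == lab and lm.view == "sagittal")
        pts.append(fuse_biplanar_point((cor.u, cor.v), (sag.u, sag.v), tol_mm=tol_mm, label=lab))
    return pts[0], pts[1]
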