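"""Biplanar radiographic landmarks of the thoracolumbar spine.

Landmarks live in the two calibrated, true-to-size orthogonal views of a
standing stereoradiographic acquisition:

* ``coronal`` view: image axes (u, v) map to global (x, z) — craniocaudal
  and right-to-left.
* ``sagittal`` view: image axes (u, v) map to global (x, y) — craniocaudal
  and posteroanterior.

Each vertebra carries a minimum complement of eight landmarks: the lateral
extremities of both end-plates on the coronal view, and the anterior /
posterior extremities of both end-plates on the sagittal view.  Two
optional pedicle landmarks on the coronal view improve the conditioning of
axial-rotation recovery.  Femoral-head landmarks (labels ``FHL``/``FHR``)
may accompany the vertebral set; they are kept apart from the vertebral
complement and are used only for pelvic incidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

#: Ordered vertebral labels, cranial to caudal.
VERTEBRA_LABELS: tuple[str, ...] = tuple(
    [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)] + ["S1"]
)

VERTEBRA_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(VERTEBRA_LABELS)}

#: Femoral-head pseudo-labels accepted in landmark files.
HIP_LABELS: tuple[str, str] = ("FHL", "FHR")

VIEWS = ("coronal", "sagittal")

#: Landmark roles per view.  Coronal: lateral extremities of the superior
#: and inferior end-plates (+ optional pedicles).  Sagittal: anterior and
#: posterior extremities of both end-plates.
CORONAL_NAMES = ("sup_left", "sup_right", "inf_left", "inf_right")
PEDICLE_NAMES = ("ped_left", "ped_right")
SAGITTAL_NAMES = ("sup_ant", "sup_post", "inf_ant", "inf_post")

#: Canonical landmark positions in the vertebra-local frame, expressed as
#: multipliers of (h/2, d/2, w/2) along local (x, y, z): x craniocaudal
#: (height), y posteroanterior (depth), z right-to-left (width).
CANONICAL_LOCAL: dict[tuple[str, str], tuple[float, float, float]] = {
    ("coronal", "sup_left"): (+1.0, 0.0, +1.0),
    ("coronal", "sup_right"): (+1.0, 0.0, -1.0),
    ("coronal", "inf_left"): (-1.0, 0.0, +1.0),
    ("coronal", "inf_right"): (-1.0, 0.0, -1.0),
    # Pedicles sit posterior to the body centre, offset laterally.
    ("coronal", "ped_left"): (0.0, -0.5, +0.6),
    ("coronal", "ped_right"): (0.0, -0.5, -0.6),
    ("sagittal", "sup_ant"): (+1.0, +1.0, 0.0),
    ("sagittal", "sup_post"): (+1.0, -1.0, 0.0),
    ("sagittal", "inf_ant"): (-1.0, +1.0, 0.0),
    ("sagittal", "inf_post"): (-1.0, -1.0, 0.0),
}


class LandmarkError(ValueError):
    """Raised for malformed or incomplete landmark sets."""


@dataclass(frozen=True)
class Landmark2D:
    """A single 2D landmark on one calibrated radiographic view.

    ``u`` runs along the craniocaudal image axis (cranially positive, mm);
    ``v`` runs along the transverse image axis (mm): right-to-left in the
    coronal view, posteroanterior in the sagittal view.
    """

    vertebra: str
    view: str
    name: str
    u: float
    v: float

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise LandmarkError(f"unknown view {self.view!r}")
        ok_labels = VERTEBRA_LABELS + HIP_LABELS
        if self.vertebra not in ok_labels:
            raise LandmarkError(f"unknown vertebra label {self.vertebra!r}")
        import math

        if not (math.isfinite(self.u) and math.isfinite(self.v)):
            raise LandmarkError(
                f"non-finite landmark coordinates for {self.vertebra} {self.view} {self.name}"
            )


@dataclass
class LandmarkSet:
    """All landmarks of one subject over the two views.

    ``landmarks`` holds vertebral landmarks only; femoral-head landmarks,
    when supplied, are kept in ``hip_landmarks``.
    """

    subject_id: str
    landmarks: list[Landmark2D] = field(default_factory=list)
    hip_landmarks: list[Landmark2D] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for lm in list(self.landmarks):
            key = (lm.vertebra, lm.view, lm.name)
            if key in seen:
                raise LandmarkError(f"duplicate landmark {key} in subject {self.subject_id}")
            seen.add(key)

    # -- queries ---------------------------------------------------------
    def vertebra_labels(self) -> list[str]:
        """Labels present, in cranial-to-caudal order."""
        present = {lm.vertebra for lm in self.landmarks}
        return [lab for lab in VERTEBRA_LABELS if lab in present]

    def for_vertebra(self, label: str) -> list[Landmark2D]:
        return [lm for lm in self.landmarks if lm.vertebra == label]

    def validate(self) -> None:
        """Check the contiguity and per-vertebra complement invariants.

        Every present vertebra must carry at least the 4+4 end-plate
        landmarks, and the labels must form a contiguous run ending at S1.
        """
        labels = self.vertebra_labels()
        if not labels:
            raise LandmarkError(f"subject {self.subject_id}: no vertebral landmarks")
        if labels[-1] != "S1":
            raise LandmarkError(
                f"subject {self.subject_id}: landmark run must end at S1 (ends at {labels[-1]})"
            )
        idx = [VERTEBRA_INDEX[lab] for lab in labels]
        gaps = [
            VERTEBRA_LABELS[j]
            for j in range(idx[0], idx[-1] + 1)
            if j not in set(idx)
        ]
        if gaps:
            raise LandmarkError(
                f"subject {self.subject_id}: missing vertebrae in contiguous run: "
                + ", ".join(gaps)
            )
        for lab in labels:
            got = {(lm.view, lm.name) for lm in self.for_vertebra(lab)}
            need_cor = {("coronal", n) for n in CORONAL_NAMES}
            need_sag = {("sagittal", n) for n in SAGITTAL_NAMES}
            missing = (need_cor | need_sag) - got
            if missing:
                raise LandmarkError(
                    f"subject {self.subject_id}: vertebra {lab} missing landmarks: "
                    + ", ".join(sorted(f"{v}:{n}" for v, n in missing))
                )

    def has_pedicles(self) -> bool:
        return any(lm.name in PEDICLE_NAMES for lm in self.landmarks)

    def has_hips(self) -> bool:
        """True when both femoral heads are landmarked on both views."""
        got = {(lm.vertebra, lm.view) for lm in self.hip_landmarks}
        return all((lab, view) in got for lab in HIP_LABELS for view in VIEWS)

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": self.subject_id,
                "vertebra": lm.vertebra,
                "view": lm.view,
                "landmark": lm.name,
                "u_mm": lm.u,
                "v_mm": lm.v,
            }
            for lm in self.landmarks + self.hip_landmarks
        ]
        return pd.DataFrame(rows, columns=["subject_id", "vertebra", "view", "landmark", "u_mm", "v_mm"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def landmark_sets_from_frame(df: pd.DataFrame) -> list[LandmarkSet]:
    """Build one :class:`LandmarkSet` per subject from a landmark table."""
    required = {"subject_id", "vertebra", "view", "landmark", "u_mm", "v_mm"}
    missing = required - set(df.columns)
    if missing:
        raise LandmarkError(f"landmark table missing columns: {sorted(missing)}")
    out: list[LandmarkSet] = []
    for sid, grp in df.groupby("subject_id", sort=True):
        lms: list[Landmark2D] = []
        hips: list[Landmark2D] = []
        for row in grp.itertuples(index=False):
            lm = Landmark2D(
                vertebra=str(row.vertebra),
                view=str(row.view),
                name=str(row.landmark),
                u=float(row.u_mm),
                v=float(row.v_mm),
            )
            (hips if lm.vertebra in HIP_LABELS else lms).append(lm)
        out.append(LandmarkSet(subject_id=str(sid), landmarks=lms, hip_landmarks=hips))
    return out


def read_landmarks_csv(path: str | Path) -> list[LandmarkSet]:
    """Read a landmark CSV (UTF-8, header required) into per-subject sets."""
    return landmark_sets_from_frame(pd.read_csv(path))


def write_landmarks_csv(path: str | Path, sets: Iterable[LandmarkSet]) -> None:
    frames = [ls.to_frame() for ls in sets]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
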