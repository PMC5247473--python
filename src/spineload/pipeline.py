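"""End-to-end subject processing: landmarks → geometry → anatomy → loads."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import AnatomicalParameters, compute_parameters
from .geometry import SpineGeometry, fuse_hip_landmarks, reconstruct_spine
from .landmarks import LandmarkSet
from .model import MechanicalModel, build_model
from .solver import LoadSolution, solve_model

__all__ = ["SubjectResult", "run_subject"]


@dataclass
class SubjectResult:
    """Everything the pipeline computes for one subject."""

    geometry: SpineGeometry
    anatomy: AnatomicalParameters
    model: MechanicalModel
    solution: LoadSolution
    mass_kg: float

    @property
    def endplate_areas(self) -> dict[str, float]:
        """Joint name → caudal-vertebra superior end-plate area (cm²)."""
        out = {}
        for j in self.model.joints:
            out[j.name] = self.geometry.get(j.caudal).endplate_area_sup
        return out


def run_subject(
    landmarks: LandmarkSet,
    mass_kg: float,
    config: dict | None = None,
    hips: tuple[np.ndarray, np.ndarray] | None = None,
    p: int = 3,
    fdk: bool = True,
    min_cobb: float = 5.0,
) -> SubjectResult:
    """Reconstruct, measure, build and solve one subject.

    Femoral-head positions are taken from ``hips`` if given, else fused
    from the landmark set's hip landmarks when present (pelvic incidence
    stays absent otherwise).
    """
    geometry = reconstruct_spine(landmarks)
    if hips is None:
        hips = fuse_hip_landmarks(landmarks)
    anatomy = compute_parameters(geometry, hips=hips, min_cobb=min_cobb)
    model = build_model(geometry, mass_kg, config=config)
    solution = solve_model(model, p=p, fdk=fdk)
    return SubjectResult(
        geometry=geometry, anatomy=anatomy, model=model, solution=solution, mass_kg=mass_kg
    )
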