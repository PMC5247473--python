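"""Assembly of the rigid-body mechanical spine model.

The model has one rigid body per vertebra T1…L5 (massless and
inertia-free, as fits an inverse-static analysis) plus a grounded S1.
Adjacent vertebrae are connected by spherical joints located at the
midpoint of the segment joining their centres; the joints carry a
translational stiffness triple (axial x′, coronal y′, sagittal z′, in
kN/m) used by the force-dependent displacement iteration, and transmit
reaction forces but no reaction moments.  Thoracic segments use the
stiffness of healthy thoracic motion segments; lumbar segments use
values measured under a 500 N compressive preload representative of
standing.

Trunk weight is distributed along the spine with a per-level fraction
table applied anteriorly to each vertebra; head and arm weights are
applied at the T1 superior end-plate midpoint and anteriorly to T4.  A
total of 89 muscle elements in ten anatomical groups (multifidus,
erector spinae, psoas, quadratus lumborum and the oblique abdominals)
act as straight tensile lines between vertebral bodies or between a
vertebra and the pelvic ground; their attachment coordinates are shipped
in normalized vertebral coordinates and scaled by each subject's
reconstructed vertebral dimensions.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import SpineGeometry
from .landmarks import VERTEBRA_INDEX, VERTEBRA_LABELS

__all__ = [
    "Body",
    "JointSpec",
    "MuscleElement",
    "GravityLoad",
    "MechanicalModel",
    "default_config",
    "build_model",
    "distribute_weight",
    "apply_held_load",
    "MUSCLE_GROUPS",
    "ModelError",
    "ConfigError",
]


class ModelError(ValueError):
    """Raised for invalid model construction inputs."""


class ConfigError(ValueError):
    """Raised for inconsistent model configuration."""


#: Muscle groups and their element counts.
MUSCLE_GROUPS: dict[str, int] = {
    "thoracic_multifidus": 12,
    "lumbar_multifidus": 20,
    "longissimus_lumborum": 5,
    "iliocostalis_lumborum": 4,
    "longissimus_thoracis": 12,
    "iliocostalis_thoracis": 8,
    "psoas": 11,
    "quadratus_lumborum": 5,
    "external_oblique": 6,
    "internal_oblique": 6,
}

JOINT_NAMES: tuple[str, ...] = tuple(
    VERTEBRA_LABELS[i] + VERTEBRA_LABELS[i + 1] for i in range(17)
)


# ---------------------------------------------------------------------------
# Default configuration
# ---------------------------------------------------------------------------

def _default_muscle_table() -> list[dict]:
    """The shipped muscle-architecture table in normalized coordinates.

    Attachment points are (level, nx, ny, nz) with multipliers of
    (h/2, d/2, w/2) along local (x, y, z) of the owning vertebra; ground
    attachments are expressed in the sacral frame (level ``S1``) and may
    exceed the unit box to reach iliac-crest, pelvic, rib-cage-width and
    proximal-femur locations.  Element counts per group are fixed;
    coordinates and strengths are overridable through the model
    configuration.

    The layout was designed for static feasibility of standing
    mild-scoliosis postures, which demands distributed segmental torque
    and lateral-bending capability as well as flexor/extensor balance at
    every level: crossed oblique multifidus ladders provide segmental
    torque; wide-set erector lines provide lateral arms; deep anterior
    stabilising lines from the uppermost levels to the pelvis stand in
    for the anterior load path that the (unmodelled) thoracic cage
    provides in vivo.
    """
    t: list[dict] = []

    def add(group, name, origin, insertion):
        t.append({"group": group, "name": name, "origin": origin, "insertion": insertion})

    lumb = [f"L{i}" for i in range(1, 6)]
    below = {"L1": "L3", "L2": "L4", "L3": "L5", "L4": "S1", "L5": "S1"}

    # -- thoracic multifidus (12) ---------------------------------------
    # T1 carries a posterior pair (the single joint below a top body
    # supplies only three reaction components, so the boundary body
    # needs at least three muscle lines of its own); T1 and T3 carry
    # deep anterior stabilising pairs to the pelvis; T3-T7 carry a
    # crossed oblique ladder for segmental torque.
    for s, tag in ((1.0, "l"), (-1.0, "r")):
        add("thoracic_multifidus", f"mf_T1_{tag}", ("T1", -0.3, -1.5, 0.15 * s),
            ("T3", 0.3, -1.2, 0.8 * s))
        for lev in ("T1", "T3"):
            add("thoracic_multifidus", f"mf_{lev}_a{tag}", (lev, 0.0, 0.2767, 0.298 * s),
                ("S1", -1.4, 2.2025, 1.3295 * s))
        for lev, ins in (("T3", "T5"), ("T4", "T6"), ("T5", "T7")):
            add("thoracic_multifidus", f"mf_{lev}_x{tag}", (lev, -0.3, -1.5, 0.0961 * s),
                (ins, 0.3, -1.2, -0.9698 * s))

    # -- lumbar multifidus (20) -----------------------------------------
    # Span-2 pairs on every lumbar level plus a crossed segmental ladder
    # across the thoracolumbar junction (multifidus fascicles from the
    # lower thoracic spinous processes).
    for lev in lumb:
        for s, tag in ((1.0, "l"), (-1.0, "r")):
            add("lumbar_multifidus", f"mf_{lev}_{tag}", (lev, -0.3, -1.5, 0.0963 * s),
                (below[lev], 0.3, -1.2, 0.4984 * s))
    for lev, ins in (("T6", "T8"), ("T7", "T9"), ("T8", "T10"), ("T9", "T11"), ("T10", "T12")):
        for s, tag in ((1.0, "l"), (-1.0, "r")):
            add("lumbar_multifidus", f"mf_{lev}{ins}_{tag}", (lev, -0.3, -1.5, -0.2074 * s),
                (ins, 0.3, -1.2, -0.4557 * s))

    # -- longissimus pars lumborum (5) ----------------------------------
    for i, lev in enumerate(lumb):
        s = 1.0 if i % 2 == 0 else -1.0
        add("longissimus_lumborum", f"lg_l_{lev}", (lev, 0.0, -1.7, 0.35 * s),
            ("S1", -1.2, -1.8, 0.6 * s))
    # -- iliocostalis pars lumborum (4) ---------------------------------
    for i, lev in enumerate(lumb[:4]):
        s = 1.0 if i % 2 == 0 else -1.0
        add("iliocostalis_lumborum", f"ic_l_{lev}", (lev, 0.0, -1.2, 1.1 * s),
            ("S1", -1.0, -0.8, 2.2 * s))

    # -- longissimus pars thoracis (12) ---------------------------------
    # Wide-set long extensor pairs crossing every joint below their
    # origin, down to the sacrum.
    for lev in ("T2", "T4", "T6", "T8", "T10", "T12"):
        for s, tag in ((1.0, "l"), (-1.0, "r")):
            add("longissimus_thoracis", f"lg_t_{lev}_{tag}", (lev, 0.0, -1.6, 2.439 * s),
                ("S1", -1.2, -1.9, 3.3377 * s))
    # -- iliocostalis pars thoracis (8) ---------------------------------
    # Rib-angle-width origins converging to a near-midline sacral
    # anchor: strongly oblique lines supplying lateral and axial moment
    # capacity.
    for lev in ("T5", "T7", "T9", "T11"):
        for s, tag in ((1.0, "l"), (-1.0, "r")):
            add("iliocostalis_thoracis", f"ic_t_{lev}_{tag}", (lev, 0.0, -1.4, 5.8323 * s),
                ("S1", -1.0, -0.9, 0.2189 * s))

    # -- psoas (11) ------------------------------------------------------
    add("psoas", "psoas_T12_r", ("T12", 0.0, 0.6, -0.9), ("S1", -2.6, 1.8, -1.3))
    for lev in lumb:
        for s, tag in ((1.0, "l"), (-1.0, "r")):
            add("psoas", f"psoas_{lev}_{tag}", (lev, 0.0, 0.6, 0.9 * s),
                ("S1", -2.6, 1.8, 1.3 * s))
    # -- quadratus lumborum (5) -----------------------------------------
    for lev, s, tag in (("L1", 1.0, "l"), ("L2", -1.0, "r"), ("L2", 1.0, "l"),
                        ("L3", -1.0, "r"), ("L4", 1.0, "l")):
        add("quadratus_lumborum", f"ql_{lev}_{tag}", (lev, 0.0, -0.3, 1.2 * s),
            ("S1", -1.1, -0.6, 2.0 * s))

    # -- abdominal obliques (6 + 6) -------------------------------------
    # Near-midline anterior flexor lines (the abdominal wall's net
    # anterior load path) on the lower thoracic levels.
    # The wall lies far anterior of the vertebral column (costal margin
    # to pubis/inguinal ligament), which is what gives trunk flexors
    # their long lever arms.
    for lev in ("T8", "T10", "T12"):
        for s, tag in ((1.0, "l"), (-1.0, "r")):
            add("external_oblique", f"eo_{lev}_{tag}", (lev, 0.0, 3.5, -0.0406 * s),
                ("S1", -1.6, 6.0, 0.7482 * s))
    for lev in ("T5", "T9", "T11"):
        for s, tag in ((1.0, "l"), (-1.0, "r")):
            add("internal_oblique", f"io_{lev}_{tag}", (lev, 0.0, 3.0, 0.2013 * s),
                ("S1", -1.6, 5.5, 2.1035 * s))
    return t


def _default_trunk_fractions() -> dict[str, float]:
    """Per-level trunk weight fractions T1…L5, growing caudally."""
    levels = [lab for lab in VERTEBRA_LABELS if lab != "S1"]
    ramp = np.array([1.0 + i / 16.0 for i in range(len(levels))])
    total_trunk = 0.7483 - 0.081 - 0.100
    fr = ramp / ramp.sum() * total_trunk
    return {lab: float(f) for lab, f in zip(levels, fr)}


def default_config() -> dict:
    """The shipped model configuration (deep-copied; freely editable)."""
    return copy.deepcopy(
        {
            "g_m_per_s2": 9.81,
            # Translational joint stiffness triples (x', y', z') in kN/m.
            "stiffness_kN_per_m": {
                "thoracic": (943.0, 86.0, 101.0),
                "lumbar_L1_L3": (2420.0, 397.0, 523.0),
                "lumbar_L4_S1": (2420.0, 473.0, 523.0),
            },
            "weight": {
                # Fraction of body weight carried by the modelled spine:
                # head + arms + distributed trunk.
                "total_fraction": 0.7483,
                "head_fraction": 0.081,
                "arm_fraction": 0.100,
                "trunk_fractions": _default_trunk_fractions(),
                "trunk_anterior_offset_factor": 0.3,
                "arm_level": "T4",
            },
            "held_load": {"anterior_offset_factor": 1.0},
            "muscles": _default_muscle_table(),
            "muscle_strength_N": {
                "thoracic_multifidus": 300.0,
                "lumbar_multifidus": 500.0,
                "longissimus_lumborum": 700.0,
                "iliocostalis_lumborum": 600.0,
                "longissimus_thoracis": 900.0,
                "iliocostalis_thoracis": 700.0,
                "psoas": 800.0,
                "quadratus_lumborum": 400.0,
                "external_oblique": 600.0,
                "internal_oblique": 600.0,
            },
        }
    )


def _stiffness_for(joint_name: str, cfg: dict) -> tuple[float, float, float]:
    """Table row for one joint; T12L1 takes the thoracic row, the lumbar
    rows are named after the cranial vertebra of the segment."""
    table = cfg["stiffness_kN_per_m"]
    if joint_name in ("L4L5", "L5S1"):
        return tuple(table["lumbar_L4_S1"])
    if joint_name in ("L1L2", "L2L3", "L3L4"):
        return tuple(table["lumbar_L1_L3"])
    return tuple(table["thoracic"])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Body:
    label: str
    center: np.ndarray
    rotation: np.ndarray
    dims: tuple[float, float, float]
    grounded: bool = False


@dataclass
class JointSpec:
    """Spherical joint between adjacent vertebrae with translational stiffness."""

    name: str
    cranial: str
    caudal: str
    center: np.ndarray
    stiffness_kN_per_m: tuple[float, float, float]
    frame: np.ndarray
    cranial_arm: np.ndarray
    caudal_arm: np.ndarray

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.stiffness_kN_per_m):
            raise ModelError(f"joint {self.name}: stiffness components must be positive")


@dataclass
class MuscleElement:
    """A straight tensile force element between two attachment points."""

    name: str
    group: str
    origin_body: str
    origin_point: np.ndarray
    insertion_body: str  # vertebra label or "ground"
    insertion_point: np.ndarray
    strength_N: float

    def __post_init__(self) -> None:
        if self.strength_N <= 0:
            raise ModelError(f"muscle {self.name}: strength must be positive")
        if self.insertion_body != "ground":
            if VERTEBRA_INDEX[self.origin_body] >= VERTEBRA_INDEX[self.insertion_body]:
                raise ModelError(
                    f"muscle {self.name}: origin body must be cranial to insertion body"
                )


@dataclass
class GravityLoad:
    """A gravity-aligned point load on one body (force along −x only)."""

    body: str
    point: np.ndarray
    force: np.ndarray
    kind: str = "trunk"

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if abs(self.force[1]) > 1e-12 or abs(self.force[2]) > 1e-12:
            raise ModelError("gravity loads must have zero y and z components")


@dataclass
class MechanicalModel:
    """Rigid vertebrae, stiffness joints, muscles and loads for one subject."""

    subject_id: str
    bodies: dict[str, Body]
    body_order: list[str]
    joints: list[JointSpec]
    muscles: list[MuscleElement]
    loads: list[GravityLoad] = field(default_factory=list)
    mass_kg: float = 0.0
    config: dict = field(default_factory=dict)

    def joint(self, name: str) -> JointSpec:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    def free_bodies(self) -> list[str]:
        return [b for b in self.body_order if not self.bodies[b].grounded]

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.muscles:
            counts[m.group] = counts.get(m.group, 0) + 1
        return counts

    def total_load_magnitude(self) -> float:
        """Sum of the magnitudes of all applied gravity loads, N."""
        return float(sum(np.linalg.norm(l.force) for l in self.loads))

    def validate(self) -> None:
        """Enforce the cohort-model invariants (17 joints, 89 muscles…)."""
        if len(self.joints) != 17:
            raise ModelError(f"expected 17 joints, got {len(self.joints)}")
        if len(self.muscles) != sum(MUSCLE_GROUPS.values()):
            raise ModelError(f"expected 89 muscles, got {len(self.muscles)}")
        if self.group_counts() != MUSCLE_GROUPS:
            raise ModelError(f"muscle group counts {self.group_counts()} != {MUSCLE_GROUPS}")
        grounded = [b for b in self.body_order if self.bodies[b].grounded]
        if grounded != ["S1"]:
            raise ModelError(f"S1 must be the only grounded body, got {grounded}")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "mass_kg": self.mass_kg,
            "bodies": {
                lab: {
                    "center_mm": b.center.tolist(),
                    "rotation": b.rotation.tolist(),
                    "dims_mm": list(b.dims),
                    "grounded": b.grounded,
                }
                for lab, b in self.bodies.items()
            },
            "joints": [
                {
                    "name": j.name,
                    "cranial": j.cranial,
                    "caudal": j.caudal,
                    "center_mm": j.center.tolist(),
                    "stiffness_kN_per_m": list(j.stiffness_kN_per_m),
                    "frame": j.frame.tolist(),
                }
                for j in self.joints
            ],
            "muscles": [
                {
                    "name": m.name,
                    "group": m.group,
                    "origin_body": m.origin_body,
                    "origin_point_mm": m.origin_point.tolist(),
                    "insertion_body": m.insertion_body,
                    "insertion_point_mm": m.insertion_point.tolist(),
                    "strength_N": m.strength_N,
                }
                for m in self.muscles
            ],
            "loads": [
                {
                    "body": l.body,
                    "point_mm": l.point.tolist(),
                    "force_N": l.force.tolist(),
                    "kind": l.kind,
                }
                for l in self.loads
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _mean_rotation(Ra: np.ndarray, Rb: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(np.stack([Ra, Rb])).mean().as_matrix()


def _resolve_point(bodies: dict[str, Body], spec: Sequence) -> tuple[str, np.ndarray]:
    level, nx, ny, nz = spec
    b = bodies[level]
    h, w, d = b.dims
    local = np.array([nx * h / 2.0, ny * d / 2.0, nz * w / 2.0])
    return level, b.center + b.rotation @ local


def build_model(
    g: SpineGeometry,
    mass_kg: float,
    config: dict | None = None,
    include_gravity: bool = True,
) -> MechanicalModel:
    """Assemble the mechanical model from a reconstructed geometry.

    Joints go at the midpoints of adjacent vertebral centres with the
    Table-row stiffness triples; muscle attachments come from the
    configured architecture table scaled by each vertebra's dimensions.
    With ``include_gravity`` the configured weight distribution is
    applied immediately (equivalent to calling :func:`distribute_weight`).
    """
    if mass_kg <= 0:
        raise ModelError("mass must be positive")
    cfg = config if config is not None else default_config()
    missing = [lab for lab in VERTEBRA_LABELS if lab not in g.labels()]
    if missing:
        raise ModelError("geometry missing levels: " + ", ".join(missing))

    bodies: dict[str, Body] = {}
    for v in g.vertebrae:
        bodies[v.label] = Body(
            label=v.label,
            center=v.center.copy(),
            rotation=v.rotation,
            dims=tuple(v.dims),
            grounded=(v.label == "S1"),
        )

    joints: list[JointSpec] = []
    for i in range(17):
        cran, caud = VERTEBRA_LABELS[i], VERTEBRA_LABELS[i + 1]
        bc, bd = bodies[cran], bodies[caud]
        center = (bc.center + bd.center) / 2.0
        joints.append(
            JointSpec(
                name=cran + caud,
                cranial=cran,
                caudal=caud,
                center=center,
                stiffness_kN_per_m=_stiffness_for(cran + caud, cfg),
                frame=_mean_rotation(bc.rotation, bd.rotation),
                cranial_arm=center - bc.center,
                caudal_arm=center - bd.center,
            )
        )

    strengths = cfg["muscle_strength_N"]
    muscles: list[MuscleElement] = []
    for entry in cfg["muscles"]:
        ob, op = _resolve_point(bodies, entry["origin"])
        ib_level, ip = _resolve_point(bodies, entry["insertion"])
        ib = "ground" if bodies[ib_level].grounded else ib_level
        muscles.append(
            MuscleElement(
                name=entry["name"],
                group=entry["group"],
                origin_body=ob,
                origin_point=op,
                insertion_body=ib,
                insertion_point=ip,
                strength_N=float(entry.get("strength_N", strengths[entry["group"]])),
            )
        )

    model = MechanicalModel(
        subject_id=g.subject_id,
        bodies=bodies,
        body_order=list(VERTEBRA_LABELS),
        joints=joints,
        muscles=muscles,
        mass_kg=float(mass_kg),
        config=cfg,
    )
    model.validate()
    if include_gravity:
        distribute_weight(model, mass_kg)
    return model


def distribute_weight(model: MechanicalModel, mass_kg: float) -> MechanicalModel:
    """Apply the configured gravity loads for a subject of ``mass_kg``.

    Per-level trunk loads act at an anterior offset (a configured
    fraction of the vertebral depth) from each vertebral centre; the head
    load acts at the T1 superior end-plate midpoint and the arm load
    anteriorly to the configured arm level.  The per-level fractions plus
    head and arm fractions must sum to the configured total fraction of
    body weight.
    """
    cfg = model.config["weight"]
    g_const = model.config["g_m_per_s2"]
    fractions = cfg["trunk_fractions"]
    total = cfg["head_fraction"] + cfg["arm_fraction"] + sum(fractions.values())
    if abs(total - cfg["total_fraction"]) > 1e-9:
        raise ConfigError(
            f"weight fractions sum to {total:.6f}, configured total is "
            f"{cfg['total_fraction']:.6f}"
        )
    model.loads = [l for l in model.loads if l.kind == "held"]
    model.mass_kg = float(mass_kg)
    W = mass_kg * g_const
    off = cfg["trunk_anterior_offset_factor"]
    for lab, frac in fractions.items():
        b = model.bodies[lab]
        point = b.center + b.rotation @ np.array([0.0, off * b.dims[2], 0.0])
        model.loads.append(
            GravityLoad(body=lab, point=point, force=np.array([-frac * W, 0.0, 0.0]), kind="trunk")
        )
    t1 = model.bodies["T1"]
    head_pt = t1.center + t1.rotation @ np.array([t1.dims[0] / 2.0, 0.0, 0.0])
    model.loads.append(
        GravityLoad(body="T1", point=head_pt, force=np.array([-cfg["head_fraction"] * W, 0.0, 0.0]), kind="head")
    )
    arm_body = model.bodies[cfg["arm_level"]]
    arm_pt = arm_body.center + arm_body.rotation @ np.array([0.0, off * arm_body.dims[2], 0.0])
    model.loads.append(
        GravityLoad(
            body=cfg["arm_level"],
            point=arm_pt,
            force=np.array([-cfg["arm_fraction"] * W, 0.0, 0.0]),
            kind="arm",
        )
    )
    return model


def apply_held_load(
    model: MechanicalModel,
    magnitude_N: float = 380.0,
    level: str = "T3",
    anterior_offset_factor: float | None = None,
) -> MechanicalModel:
    """Add a gravity-oriented held load anterior to one vertebra.

    Emulates holding a weighted bar in front of the body with extended
    arms: a single extra load of ``magnitude_N`` along −x applied at an
    anterior offset (default one vertebral depth) from the named level.
    """
    if level not in model.bodies:
        raise ModelError(f"unknown level {level!r} for held load")
    if magnitude_N < 0:
        raise ModelError("held load magnitude must be non-negative")
    off = (
        anterior_offset_factor
        if anterior_offset_factor is not None
        else model.config.get("held_load", {}).get("anterior_offset_factor", 1.0)
    )
    b = model.bodies[level]
    point = b.center + b.rotation @ np.array([0.0, off * b.dims[2], 0.0])
    model.loads.append(
        GravityLoad(body=level, point=point, force=np.array([-magnitude_N, 0.0, 0.0]), kind="held")
    )
    return model
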