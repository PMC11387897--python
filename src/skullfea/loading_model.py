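"""Build finite-element load cases from feeding biology.

Muscle forces are estimated from the adductor-chamber cross-sectional area
(the subtemporal-fenestra method): total force = area (cm^2) x specific
muscle tension (default 31.5 N/cm^2).  Forces are split across named muscle
groups, resolved to directions, and divided evenly over the nodes of each
insertion patch.  Joint nodes are fully constrained; bite nodes either
receive external point loads (the literal procedure this package mirrors)
or a vertical constraint whose reaction is read as bite force.

Size-vs-shape comparisons use surface-area-equalized scaling: every model
is loaded at the reference model's force-to-surface-area ratio,
F_model,g = F_ref,g * (SA_model / SA_ref), so residual stress differences
reflect shape alone.

Units: areas enter in cm^2 and are converted here (1 cm^2 = 100 mm^2);
forces are N, coordinates mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .fe_solver import LoadCase
from .synthetic_skull import LabeledModel

__all__ = [
    "MuscleGroup",
    "MuscleSpec",
    "ScalingPolicy",
    "BiteConfig",
    "SPECIFIC_TENSION_N_PER_CM2",
    "muscle_force_from_area",
    "distribute_over_nodes",
    "scale_to_reference",
    "build_load_case",
]

SPECIFIC_TENSION_N_PER_CM2 = 31.5  # isometric specific tension of jaw muscle


@dataclass
class MuscleGroup:
    """One muscle group: insertion node-set name and pull direction.

    ``direction`` is either a 3-vector (normalized on resolution) or the
    string ``"toward-point"`` with ``target`` set, in which case unit
    vectors from each insertion node toward the target are averaged.
    """

    name: str
    insertion_set: str
    direction: Sequence[float] | Literal["toward-point"] = (0.0, 0.0, -1.0)
    target: Sequence[float] | None = None
    force_magnitude: float | None = None  # N; None -> derived from area

    def resolve_direction(self, nodes: np.ndarray, insertion: np.ndarray) -> np.ndarray:
        if isinstance(self.direction, str):
            if self.direction != "toward-point":
                raise ValueError(f"unknown direction mode {self.direction!r}")
            if self.target is None:
                raise ValueError(f"group {self.name!r}: toward-point needs a target")
            vecs = np.asarray(self.target, float) - nodes[insertion]
            norms = np.linalg.norm(vecs, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise ValueError(f"group {self.name!r}: target coincides with a node")
            mean = (vecs / norms).mean(axis=0)
        else:
            mean = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(mean)
        if n == 0:
            raise ValueError(f"group {self.name!r}: zero direction")
        return mean / n


@dataclass
class MuscleSpec:
    """Adductor area (cm^2) -> per-group force magnitudes."""

    adductor_area: float
    specific_tension: float = SPECIFIC_TENSION_N_PER_CM2
    group_fractions: dict[str, float] = field(default_factory=lambda: {"adductor": 1.0})

    def __post_init__(self) -> None:
        if self.adductor_area <= 0:
            raise ValueError("adductor area must be positive")
        total = sum(self.group_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group fractions sum to {total}, expected 1")


@dataclass
class ScalingPolicy:
    """Actual-size vs surface-area-equalized force scaling."""

    mode: Literal["actual_size", "sa_equalized"] = "actual_size"
    reference_surface_area: float | None = None  # mm^2
    reference_forces: dict[str, float] | None = None  # N per group
    # alternative reading: apply reference forces verbatim to every model
    equalize: Literal["force_per_area", "reference_force"] = "force_per_area"


@dataclass
class BiteConfig:
    """Bite-point treatment: external loads (default) or vertical constraint."""

    mode: Literal["load", "constrain"] = "load"
    magnitude: float = 0.0  # N total across all bite nodes
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)


def muscle_force_from_area(spec: MuscleSpec) -> dict[str, float]:
    """Per-group force magnitudes (N): area x tension, split by fractions."""
    total = spec.adductor_area * spec.specific_tension
    return {name: total * frac for name, frac in spec.group_fractions.items()}


def distribute_over_nodes(
    total_force: np.ndarray, insertion: np.ndarray
) -> dict[int, np.ndarray]:
    """Divide a total force vector evenly over the insertion nodes."""
    insertion = np.asarray(insertion, dtype=np.int64).ravel()
    if insertion.size == 0:
        raise ValueError("empty insertion set")
    per = np.asarray(total_force, dtype=float) / insertion.size
    return {int(n): per.copy() for n in insertion}


def scale_to_reference(
    forces: Mapping[str, float], model_sa: float, policy: ScalingPolicy
) -> dict[str, float]:
    """Apply the scaling policy to per-group force magnitudes.

    ``sa_equalized`` with the default ``force_per_area`` reading returns
    F_ref,g * (SA_model / SA_ref); the ``reference_force`` reading returns
    the reference forces unchanged.  ``actual_size`` is the identity.
    """
    if policy.mode == "actual_size":
        return dict(forces)
    if policy.reference_surface_area is None or policy.reference_forces is None:
        raise ValueError("sa_equalized mode requires reference SA and forces")
    if policy.reference_surface_area <= 0:
        raise ValueError("reference surface area must be positive")
    if policy.equalize == "reference_force":
        return dict(policy.reference_forces)
    ratio = model_sa / policy.reference_surface_area
    return {g: f * ratio for g, f in policy.reference_forces.items()}


def default_muscle_groups(model: LabeledModel) -> list[MuscleGroup]:
    """Left/right adductor groups pulling each patch toward the bite row
    midpoint (an anterodorsal line of action, the resultant a jaw adductor
    produces on the proxy)."""
    target = model.mesh.nodes[model.bite_nodes].mean(axis=0)
    return [
        MuscleGroup(name=side, insertion_set=f"muscle_adductor_{side}",
                    direction="toward-point", target=tuple(target))
        for side in ("left", "right")
    ]


def build_load_case(
    model: LabeledModel,
    muscles: Sequence[MuscleGroup] | None = None,
    spec: MuscleSpec | None = None,
    bite: BiteConfig | None = None,
    policy: ScalingPolicy | None = None,
) -> LoadCase:
    """Assemble the full load case for one model.

    Joint nodes are constrained in all three translational directions
    (6 nodes x 3 DOF = 18 constrained DOFs).  Muscle magnitudes come from
    explicit ``force_magnitude`` entries or from ``spec`` (area x tension),
    then pass through the scaling policy, then are distributed per node.
    """
    bite = bite or BiteConfig()
    policy = policy or ScalingPolicy()
    lc = LoadCase()

    for n in model.joint_nodes:
        lc.constraints[int(n)] = (0, 1, 2)

    bite_nodes = model.bite_nodes
    if bite.mode == "constrain":
        d = np.argmax(np.abs(bite.direction))
        for n in bite_nodes:
            lc.constraints.setdefault(int(n), ())
            lc.constraints[int(n)] = tuple(sorted(set(lc.constraints[int(n)]) | {int(d)}))
    elif bite.magnitude != 0.0:
        vec = np.asarray(bite.direction, dtype=float)
        vec = vec / np.linalg.norm(vec) * bite.magnitude
        lc.point_loads.update(distribute_over_nodes(vec, bite_nodes))

    if muscles is None and spec is not None:
        muscles = default_muscle_groups(model)
    if muscles:
        if spec is not None:
            by_area = muscle_force_from_area(spec)
        else:
            by_area = {}
        mags: dict[str, float] = {}
        for g in muscles:
            if g.force_magnitude is not None:
                mags[g.name] = g.force_magnitude
            elif g.name in by_area:
                mags[g.name] = by_area[g.name]
            elif len(by_area) == 1 and len(muscles) >= 1:
                # single pooled fraction split evenly over the groups
                mags[g.name] = next(iter(by_area.values())) / len(muscles)
            else:
                raise ValueError(f"no force magnitude for muscle group {g.name!r}")
        mags = scale_to_reference(mags, model.summary.surface_area, policy)
        sets = model.mesh.node_sets
        for g in muscles:
            if g.insertion_set not in sets:
                raise KeyError(
                    f"insertion set {g.insertion_set!r} not in model sets "
                    f"{sorted(sets)}"
                )
            insertion = sets[g.insertion_set]
            direction = g.resolve_direction(model.mesh.nodes, insertion)
            lc.muscle_loads[g.name] = distribute_over_nodes(
                direction * mags[g.name], insertion
            )
    return lc
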