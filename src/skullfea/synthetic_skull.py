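"""Parametric skull-proxy mesh generator.

Fossil crania and mandibles cannot ship with a software package, so the
comparative pipeline is exercised on deterministic tapered-wedge proxies
that reproduce the *loading topology* of a skull feeding analysis: six
constrained joint nodes (three per quadrate/articular hinge), ten bite
nodes (five per premaxillary side), and posterolateral muscle-insertion
patches.  Geometry is a lofted rectangular solid, hex-gridded and split
into tetrahedra by a fixed 6-tet decomposition; shape variation ("gracile"
vs "robust") comes from the posterior depth/width ratio, size variation
from isometric scaling.

Axes: x runs posterior (0) to anterior (length); y is transverse
(left/right about 0); z is dorsoventral (0 at ventral face).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .mesh_io import MeshSummary, TetMesh, element_volumes

__all__ = ["ProxyParams", "LabeledModel", "generate_proxy", "isometric_copy",
           "example_family"]

# fixed 6-tet decomposition of a hexahedron with local corner order
# (i,j,k) bits -> corner index; all six tets share the main diagonal 0-7,
# giving a conforming, orientation-uniform split.
_HEX_TO_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 3, 2, 7],
        [0, 2, 6, 7],
        [0, 6, 4, 7],
        [0, 4, 5, 7],
        [0, 5, 1, 7],
    ]
)


@dataclass(frozen=True)
class ProxyParams:
    """Parameters of one skull proxy.

    ``robusticity`` multiplies posterior depth relative to the gracile
    baseline (robust morphs have deeper, more massive posterior skulls);
    ``anterior_taper`` is the anterior/posterior cross-section ratio;
    ``resolution`` counts elements along the length; ``adductor_area`` is
    the jaw-adductor chamber cross-section in cm^2 used for muscle-force
    estimation.  ``fenestra``, if given, is ((x0, x1), relative height
    fraction) — a transverse window through the solid.
    """

    preset: Literal["cranium", "mandible"] = "cranium"
    length: float = 100.0
    posterior_width: float = 40.0
    posterior_depth: float = 30.0
    anterior_taper: float = 0.35
    robusticity: float = 1.0
    fenestra: tuple[tuple[float, float], float] | None = None
    resolution: int = 12
    adductor_area: float = 20.0
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if min(self.length, self.posterior_width, self.posterior_depth) <= 0:
            raise ValueError("length, width and depth must be positive")
        if not 0 < self.anterior_taper <= 1:
            raise ValueError("anterior_taper must lie in (0, 1]")
        if self.resolution < 4:
            raise ValueError("resolution must be >= 4")
        if self.robusticity <= 0:
            raise ValueError("robusticity must be positive")


@dataclass
class LabeledModel:
    """A proxy tet mesh with the named sets a feeding analysis needs."""

    mesh: TetMesh
    summary: MeshSummary
    adductor_area: float  # cm^2
    label: str = "proxy"
    part: str = "cranium"

    @property
    def bite_nodes(self) -> np.ndarray:
        return self.mesh.node_sets["bite"]

    @property
    def joint_nodes(self) -> np.ndarray:
        return self.mesh.node_sets["joints"]

    @property
    def muscle_patches(self) -> dict[str, np.ndarray]:
        return {
            k.removeprefix("muscle_"): v
            for k, v in self.mesh.node_sets.items()
            if k.startswith("muscle_")
        }


def _nearest_distinct(points: np.ndarray, anchors: np.ndarray, k: int,
                      exclude: set[int]) -> list[int]:
    """k distinct node indices nearest to the anchor row, excluding some."""
    chosen: list[int] = []
    taken = set(exclude)
    for a in anchors:
        d = np.linalg.norm(points - a, axis=1)
        for idx in np.argsort(d, kind="stable"):
            if int(idx) not in taken:
                chosen.append(int(idx))
                taken.add(int(idx))
                break
    if len(chosen) != k:
        raise ValueError("could not select distinct anchor nodes")
    return chosen


def generate_proxy(params: ProxyParams) -> LabeledModel:
    """Build a labeled tapered-wedge proxy from parameters.

    Deterministic for fixed params (the seed only drives optional node
    jitter, default off).  Mandible preset is a shallower, narrower wedge
    sharing the same topology.
    """
    p = params
    depth0 = p.posterior_depth * p.robusticity
    width0 = p.posterior_width
    if p.preset == "mandible":
        depth0 *= 0.45
        width0 *= 0.8

    nx = p.resolution
    ny = max(4, int(round(nx * width0 / p.length)))
    nz = max(4, int(round(nx * depth0 / p.length)))

    xs = np.linspace(0.0, p.length, nx + 1)
    eta = np.linspace(-0.5, 0.5, ny + 1)  # transverse fraction
    zeta = np.linspace(0.0, 1.0, nz + 1)  # dorsoventral fraction

    # lofted cross-sections: linear taper of width and depth to anterior
    t = xs / p.length
    wscale = width0 * (1.0 + (p.anterior_taper - 1.0) * t)
    dscale = depth0 * (1.0 + (p.anterior_taper - 1.0) * t)

    X = np.repeat(xs, (ny + 1) * (nz + 1))
    Y = np.tile(np.repeat(eta, nz + 1), nx + 1) * np.repeat(wscale, (ny + 1) * (nz + 1))
    Z = np.tile(zeta, (nx + 1) * (ny + 1)) * np.repeat(dscale, (ny + 1) * (nz + 1))
    nodes = np.column_stack([X, Y, Z])

    if p.jitter > 0:
        rng = np.random.default_rng(p.seed)
        interior = (
            (X > 0) & (X < p.length)
            & (np.abs(Y) < 0.49 * np.repeat(wscale, (ny + 1) * (nz + 1)))
            & (Z > 0) & (Z < 0.99 * np.repeat(dscale, (ny + 1) * (nz + 1)))
        )
        nodes[interior] += rng.normal(0.0, p.jitter, (int(interior.sum()), 3))

    def nid(i: int, j: int, k: int) -> int:
        return (i * (ny + 1) + j) * (nz + 1) + k

    # fenestra: drop hexes whose centers fall in the window
    fen = p.fenestra
    if fen is not None:
        (fx0, fx1), ffrac = fen
        if not (0 <= fx0 < fx1 <= p.length) or not 0 < ffrac < 1:
            raise ValueError("fenestra window exceeds solid bounds")

    hexes = []
    dx = p.length / nx
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if fen is not None:
                    xc = (i + 0.5) * dx
                    zfrac = (k + 0.5) / nz
                    if fx0 <= xc <= fx1 and abs(zfrac - 0.5) < ffrac / 2:
                        continue
                corners = [
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i, j + 1, k), nid(i + 1, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i, j + 1, k + 1), nid(i + 1, j + 1, k + 1),
                ]
                hexes.append(corners)
    hexes = np.array(hexes, dtype=np.int64)
    tets = hexes[:, _HEX_TO_TETS].reshape(-1, 4)

    # drop orphaned nodes (fenestra may strand a few) and remap
    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes = nodes[used]
    tets = remap[tets]

    # --- named node sets, chosen geometrically ---
    # bite rows: 5 anchors per side along the ventral anterior lateral edge
    # (the premaxillary tooth row); spacing is one free parameter
    row_x = np.linspace(0.82 * p.length, p.length, 5)
    row_halfw = 0.5 * np.interp(row_x, xs, wscale)
    sets: dict[str, np.ndarray] = {}
    bite: list[int] = []
    for sign in (-1.0, 1.0):
        anchors = np.column_stack([row_x, sign * row_halfw, np.zeros(5)])
        bite += _nearest_distinct(nodes, anchors, 5, set(bite))
    sets["bite"] = np.array(bite, dtype=np.int64)

    # joints: 3 anchors per side at the posterior lateral ventral corner
    joints: list[int] = []
    for sign in (-1.0, 1.0):
        anchors = np.column_stack([
            np.array([0.0, 0.04, 0.08]) * p.length,
            sign * 0.5 * width0 * np.ones(3),
            np.full(3, 0.15 * depth0),
        ])
        joints += _nearest_distinct(nodes, anchors, 3, set(bite) | set(joints))
    sets["joints"] = np.array(joints, dtype=np.int64)

    # muscle patches: dorsolateral band at the temporal/coronoid region
    # (0.35-0.60 of length), left and right, excluding joint/bite nodes.
    # Mid-length insertions make the skull work as a lever between the
    # posterior joints and the anterior tooth row.
    excluded = set(joints) | set(bite)
    band = (nodes[:, 0] >= 0.35 * p.length) & (nodes[:, 0] <= 0.60 * p.length)
    dorsal = nodes[:, 2] >= 0.6 * np.interp(nodes[:, 0], xs, dscale)
    halfw = 0.5 * np.interp(nodes[:, 0], xs, wscale)
    for name, sign in (("adductor_left", -1.0), ("adductor_right", 1.0)):
        lateral = sign * nodes[:, 1] >= 0.99 * halfw - 1e-9
        idx = np.flatnonzero(band & dorsal & lateral)
        idx = np.array([i for i in idx if int(i) not in excluded], dtype=np.int64)
        if idx.size == 0:
            raise ValueError("empty muscle patch; increase resolution")
        sets[f"muscle_{name}"] = idx

    mesh = TetMesh(nodes, tets, sets)
    return LabeledModel(
        mesh=mesh,
        summary=element_volumes(mesh),
        adductor_area=p.adductor_area,
        label=f"{p.preset}-proxy",
        part=p.preset,
    )


def isometric_copy(model: LabeledModel, scale: float, label: str | None = None) -> LabeledModel:
    """Geometrically similar copy: coordinates x scale, adductor area x scale^2."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    mesh = TetMesh(
        model.mesh.nodes * scale,
        model.mesh.tets.copy(),
        {k: v.copy() for k, v in model.mesh.node_sets.items()},
    )
    return LabeledModel(
        mesh=mesh,
        summary=element_volumes(mesh),
        adductor_area=model.adductor_area * scale**2,
        label=label or f"{model.label}-x{scale:g}",
        part=model.part,
    )


def _family_params() -> dict[str, ProxyParams]:
    """Shape/size conditions for the packaged example family.

    The gracile morph has a slender posterior skull (depth/width 0.75);
    the robust morph deepens it by 60%.  The large gracile individual is an
    exact isometric enlargement (x2) of the small one, so the family spans
    both a pure size axis and a pure shape axis.
    """
    base = dict(length=100.0, posterior_width=40.0, posterior_depth=30.0,
                anterior_taper=0.35, resolution=12, adductor_area=20.0)
    return {
        "gracile-small": ProxyParams(robusticity=1.0, **base),
        "robust-large": ProxyParams(robusticity=1.6, **base),
    }


def example_family(parts: tuple[str, ...] = ("cranium", "mandible"),
                   resolution: int | None = None) -> list[LabeledModel]:
    """Deterministic three-member family x requested parts.

    Members: gracile-small, gracile-large (isometric x2 copy of
    gracile-small) and robust-large (robusticity 1.6), ordered by surface
    area within each part.
    """
    out: list[LabeledModel] = []
    fp = _family_params()
    for part in parts:
        kw = {} if resolution is None else {"resolution": resolution}
        small = generate_proxy(replace(fp["gracile-small"], preset=part, **kw))
        small.label = "gracile-small"
        large = isometric_copy(small, 2.0, label="gracile-large")
        robust = generate_proxy(replace(fp["robust-large"], preset=part, **kw))
        robust.label = "robust-large"
        out.extend(sorted([small, large, robust],
                          key=lambda m: m.summary.surface_area))
    return out
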