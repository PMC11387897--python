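"""Mesh containers and I/O.

Surface meshes travel as STL (the exchange format used throughout the
pipeline); tetrahedral volume meshes with named node sets use a plain-text
format (``NODES`` / ``TETS`` / ``SET`` blocks, 1-based ids on disk, 0-based
in memory) because STL and VTK carry no set semantics.  Result fields are
exported as legacy ASCII VTK unstructured grids for visualization.

All lengths are mm, areas mm^2, volumes mm^3 (N-mm-MPa unit system).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import trimesh

if TYPE_CHECKING:  # pragma: no cover
    from .fe_solver import SolutionField

__all__ = [
    "SurfaceMesh",
    "TetMesh",
    "MeshSummary",
    "MeshValidationError",
    "read_stl",
    "write_stl",
    "surface_area",
    "element_volumes",
    "read_tetmesh",
    "write_tetmesh",
    "write_results_vtk",
]

DEFAULT_MERGE_TOL = 1e-6  # mm; STL duplicates vertices per facet


class MeshValidationError(ValueError):
    """Raised when a mesh violates a structural invariant."""


@dataclass
class SurfaceMesh:
    """Triangulated surface: ``vertices`` (n,3) mm, ``triangles`` (m,3) ints."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise MeshValidationError("triangle index out of range")
        if self.triangles.size and self.triangles.min() < 0:
            raise MeshValidationError("negative triangle index")


@dataclass
class MeshSummary:
    """Geometric totals for a tetrahedral mesh."""

    surface_area: float
    total_volume: float
    element_volumes: np.ndarray
    element_count: int


@dataclass
class TetMesh:
    """Four-node tetrahedral mesh with named node sets.

    ``nodes`` is (n,3) float mm; ``tets`` is (m,4) int; ``node_sets`` maps a
    set name to an integer index array.  Tets are re-oriented on construction
    so every signed volume is positive (external meshers emit mixed
    orientations); zero-volume elements are rejected.
    """

    nodes: np.ndarray
    tets: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        if self.tets.size and self.tets.max() >= len(self.nodes):
            raise MeshValidationError("tet index out of range")
        self.node_sets = {
            k: np.asarray(v, dtype=np.int64).ravel() for k, v in self.node_sets.items()
        }
        for name, idx in self.node_sets.items():
            if idx.size and (idx.min() < 0 or idx.max() >= len(self.nodes)):
                raise MeshValidationError(f"node set {name!r} references invalid nodes")
        self._fix_orientation()

    def _signed_volumes(self) -> np.ndarray:
        a, b, c, d = (self.nodes[self.tets[:, i]] for i in range(4))
        return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0

    def _fix_orientation(self) -> None:
        if not len(self.tets):
            return
        sv = self._signed_volumes()
        neg = sv < 0
        if neg.any():
            # swap two node indices to flip orientation
            self.tets[neg] = self.tets[neg][:, [0, 2, 1, 3]]
            sv = np.abs(sv)
        bad = np.flatnonzero(sv == 0.0)
        if bad.size:
            raise MeshValidationError(
                f"zero-volume tetrahedra at element indices {bad[:10].tolist()}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def boundary_tris(self) -> np.ndarray:
        """Surface triangles: faces belonging to exactly one tet.

        Faces are returned outward-oriented for positively oriented tets.
        """
        # local faces, outward normals for positive orientation
        faces = np.concatenate(
            [
                self.tets[:, [0, 2, 1]],
                self.tets[:, [0, 1, 3]],
                self.tets[:, [1, 2, 3]],
                self.tets[:, [0, 3, 2]],
            ]
        )
        key = np.sort(faces, axis=1)
        _, inverse, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        return faces[counts[inverse] == 1]

    def surface_mesh(self) -> SurfaceMesh:
        return SurfaceMesh(self.nodes.copy(), self.boundary_tris())


def read_stl(path: str | Path, merge_tol: float = DEFAULT_MERGE_TOL) -> SurfaceMesh:
    """Read an ASCII or binary STL file, merging duplicate vertices.

    Vertices closer than ``merge_tol`` (mm) are collapsed to a single node.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted parse errors
        raise MeshValidationError(f"malformed STL {path}: {exc}") from exc
    if tm.vertices.size == 0:
        raise MeshValidationError(f"STL {path} contains no facets")
    verts = np.asarray(tm.vertices, dtype=float)
    tris = np.asarray(tm.faces, dtype=np.int64)
    verts, tris = _merge_vertices(verts, tris, merge_tol)
    return SurfaceMesh(verts, tris)


def _merge_vertices(
    verts: np.ndarray, tris: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse vertices within ``tol`` by snapping to a grid of pitch tol."""
    if tol <= 0:
        return verts, tris
    key = np.round(verts / tol).astype(np.int64)
    _, first, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    new_verts = verts[first]
    new_tris = inverse[tris]
    # drop triangles that became degenerate after merging
    keep = (
        (new_tris[:, 0] != new_tris[:, 1])
        & (new_tris[:, 1] != new_tris[:, 2])
        & (new_tris[:, 0] != new_tris[:, 2])
    )
    return new_verts, new_tris[keep]


def write_stl(mesh: SurfaceMesh, path: str | Path, binary: bool = True) -> None:
    """Write a surface mesh as STL (binary by default)."""
    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.triangles, process=False
    )
    tm.export(str(path), file_type="stl" if binary else "stl_ascii")


def surface_area(mesh: SurfaceMesh) -> float:
    """Total surface area (mm^2): sum of half cross-product magnitudes."""
    if len(mesh.triangles) == 0:
        raise MeshValidationError("empty surface mesh")
    a = mesh.vertices[mesh.triangles[:, 0]]
    b = mesh.vertices[mesh.triangles[:, 1]]
    c = mesh.vertices[mesh.triangles[:, 2]]
    return float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2.0)


def element_volumes(mesh: TetMesh) -> MeshSummary:
    """Per-element volumes |det([b-a, c-a, d-a])|/6 and totals.

    The boundary surface area of the tet mesh is included so downstream
    force scaling can use it directly.
    """
    sv = mesh._signed_volumes()
    vols = np.abs(sv)
    bad = np.flatnonzero(vols == 0.0)
    if bad.size:
        raise MeshValidationError(
            f"zero-volume tetrahedra at element indices {bad[:10].tolist()}"
        )
    sa = surface_area(mesh.surface_mesh()) if len(mesh.tets) else 0.0
    return MeshSummary(
        surface_area=sa,
        total_volume=float(vols.sum()),
        element_volumes=vols,
        element_count=len(mesh.tets),
    )


# ---------------------------------------------------------------------------
# plain-text tet-mesh format:  NODES n / TETS m / SET name blocks, 1-based ids


def write_tetmesh(mesh: TetMesh, path: str | Path) -> None:
    buf = io.StringIO()
    buf.write(f"NODES {mesh.n_nodes}\n")
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        buf.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
    buf.write(f"TETS {mesh.n_tets}\n")
    for i, t in enumerate(mesh.tets + 1, start=1):
        buf.write(f"{i} {t[0]} {t[1]} {t[2]} {t[3]}\n")
    for name, idx in mesh.node_sets.items():
        buf.write(f"SET {name}\n")
        buf.write(" ".join(str(j + 1) for j in idx) + "\n")
    Path(path).write_text(buf.getvalue())


def read_tetmesh(path: str | Path) -> TetMesh:
    tokens = Path(path).read_text().split()
    pos = 0

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise MeshValidationError(f"truncated tet-mesh file {path}")
        tok = tokens[pos]
        pos += 1
        return tok

    if take() != "NODES":
        raise MeshValidationError(f"{path}: expected NODES header")
    n = int(take())
    nodes = np.empty((n, 3))
    for i in range(n):
        take()  # id, sequential by construction
        nodes[i] = [float(take()), float(take()), float(take())]
    if take() != "TETS":
        raise MeshValidationError(f"{path}: expected TETS header")
    m = int(take())
    tets = np.empty((m, 4), dtype=np.int64)
    for i in range(m):
        take()
        tets[i] = [int(take()) - 1 for _ in range(4)]
    node_sets: dict[str, np.ndarray] = {}
    while pos < len(tokens):
        if take() != "SET":
            raise MeshValidationError(f"{path}: expected SET block")
        name = take()
        ids = []
        while pos < len(tokens) and tokens[pos] != "SET":
            ids.append(int(take()) - 1)
        node_sets[name] = np.array(ids, dtype=np.int64)
    return TetMesh(nodes, tets, node_sets)


# ---------------------------------------------------------------------------
# legacy ASCII VTK unstructured-grid export of a solved field


def write_results_vtk(mesh: TetMesh, fld: "SolutionField", path: str | Path) -> None:
    """Export nodal displacements and per-cell von Mises / principal strain.

    Legacy VTK is used because it is a fixed-layout text format readable by
    ParaView and most mesh viewers.
    """
    if fld.displacements.shape != (mesh.n_nodes, 3):
        raise MeshValidationError(
            f"displacement field has {fld.displacements.shape[0]} nodes, "
            f"mesh has {mesh.n_nodes}"
        )
    if len(fld.von_mises) != mesh.n_tets:
        raise MeshValidationError(
            f"cell field has {len(fld.von_mises)} cells, mesh has {mesh.n_tets}"
        )
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\nskullfea results\nASCII\n")
    buf.write("DATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {mesh.n_nodes} double\n")
    for x, y, z in mesh.nodes:
        buf.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
    buf.write(f"CELLS {mesh.n_tets} {mesh.n_tets * 5}\n")
    for t in mesh.tets:
        buf.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
    buf.write(f"CELL_TYPES {mesh.n_tets}\n")
    buf.write("10\n" * mesh.n_tets)
    buf.write(f"POINT_DATA {mesh.n_nodes}\n")
    buf.write("VECTORS displacement double\n")
    for u in fld.displacements:
        buf.write(f"{u[0]:.9g} {u[1]:.9g} {u[2]:.9g}\n")
    buf.write(f"CELL_DATA {mesh.n_tets}\n")
    buf.write("SCALARS von_mises double 1\nLOOKUP_TABLE default\n")
    for v in fld.von_mises:
        buf.write(f"{v:.9g}\n")
    buf.write("SCALARS max_principal_strain double 1\nLOOKUP_TABLE default\n")
    for v in fld.max_principal_strain:
        buf.write(f"{v:.9g}\n")
    Path(path).write_text(buf.getvalue())


def read_vtk_cell_count(path: str | Path) -> int:
    """Cell count declared in a legacy VTK file (round-trip checking)."""
    for line in Path(path).read_text().splitlines():
        if line.startswith("CELLS "):
            return int(line.split()[1])
    raise MeshValidationError(f"{path}: no CELLS section")
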